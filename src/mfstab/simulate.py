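"""Synthetic experiments with known treatment -> community -> function effects.

Two generators, both fully seeded:

:func:`generate_experiment` builds a complete mechanistic experiment —
design, plant biomasses, litter-/soil-faunal abundances, random trees and
14 function variables.  Effects are injected on latent community states
that both the abundance tables and the functions load on, guaranteeing the
mediation structure the path model assumes: richness stabilizes (noise
shrinks with log2 richness, and species overlap between assemblages rises
with richness), drought and invasion displace and destabilize communities
— fauna more strongly than plants — and the functions inherit community
state plus direct treatment displacement and noise.  Only effect *signs*
are controlled here; standardized coefficients on pair similarities are an
emergent property.

:func:`simulate_path_matrices` instead injects *exact* standardized path
coefficients at the pair level: similarity responses are drawn from the
recursive structural equations on the aspect's pair covariates and stored
in valid similarity matrices.  This is the calibration generator for
parameter-recovery and type-I-error studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .design import (ASSEMBLAGES_PER_RICHNESS, SET_TREATMENTS,
                     ExperimentalDesign, build_design)
from .pairs import RESPONSE_KINDS, extract_pairs
from .sem import PathModelSpec
from .similarity import SimilarityMatrix


@dataclass
class GeneratorConfig:
    """Study conditions for the mechanistic generator.

    Defaults reproduce the reference design dimensions (16-species pool,
    16/10/10/9 assemblages, six complete sets in a 3 drought x 2 invasion
    factorial) and inject the qualitative effect structure: positive
    richness -> stability paths, negative drought/invasion paths that hit
    the faunal communities harder than the plants.
    """

    seed: int = 0
    n_species_pool: int = 16
    assemblages_per_richness: dict = field(
        default_factory=lambda: dict(ASSEMBLAGES_PER_RICHNESS))
    set_treatments: dict = field(default_factory=lambda: dict(SET_TREATMENTS))
    n_fauna_taxa: int = 12
    n_orders: int = 4
    n_functions: int = 14
    # treatment -> community displacement (per disturbance level, log scale)
    drought_shift_plant: float = 0.25
    invasion_shift_plant: float = 0.20
    drought_shift_fauna: float = 0.25
    invasion_shift_fauna: float = 0.25
    # treatment -> within-group destabilization (noise inflation per level)
    drought_destab_plant: float = 0.15
    invasion_destab_plant: float = 0.10
    drought_destab_fauna: float = 1.5
    invasion_destab_fauna: float = 1.5
    drought_destab_function: float = 0.30
    invasion_destab_function: float = 0.20
    # richness -> stability (noise shrink per log2 richness)
    richness_stabilization: float = 0.5
    # treatment -> function displacement
    drought_shift_function: float = 0.5
    invasion_shift_function: float = 0.4
    # community -> fauna / function loadings
    fauna_plant_coupling: float = 1.5
    plant_function_coupling: float = 1.0
    fauna_function_coupling: float = 0.6
    # noise sd per layer
    plant_noise_sd: float = 0.40
    fauna_noise_sd: float = 0.35
    function_noise_sd: float = 0.35

    def expected_signs(self) -> dict[str, str]:
        """Signs of the injected direct treatment -> community paths."""
        return {"richness->s_plant": "+",
                "drought->s_litter_fauna": "-",
                "drought->s_soil_fauna": "-",
                "invasion->s_litter_fauna": "-",
                "invasion->s_soil_fauna": "-",
                "richness->s_multifunctional(total)": "+"}


@dataclass
class SyntheticExperiment:
    """Generated design, abundance/function tables, trees and ground truth."""

    design: ExperimentalDesign
    plant_abundances: pd.DataFrame
    litter_fauna: pd.DataFrame
    soil_fauna: pd.DataFrame
    functions: pd.DataFrame
    plant_tree: TreeNode
    fauna_tree: TreeNode
    taxonomy: dict[str, str]
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_design, write_table, write_tree
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_design(self.design, out / "design.tsv")
        write_table(self.plant_abundances, out / "plant_abundances.tsv")
        write_table(self.litter_fauna, out / "litter_fauna.tsv")
        write_table(self.soil_fauna, out / "soil_fauna.tsv")
        write_table(self.functions, out / "functions.tsv")
        write_tree(self.plant_tree, out / "plant_tree.nwk")
        write_tree(self.fauna_tree, out / "fauna_tree.nwk")
        pd.Series(self.taxonomy, name="order").rename_axis("taxon").to_csv(
            out / "fauna_taxonomy.tsv", sep="\t")


def generate_random_tree(taxa, seed: int | None = None,
                         rng: np.random.Generator | None = None) -> TreeNode:
    """Random rooted bifurcating tree with exponential branch lengths."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("a tree needs at least 2 taxa")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.5))) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right],
                          length=float(rng.exponential(0.5)))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_experiment(cfg: GeneratorConfig | None = None) -> SyntheticExperiment:
    """Generate a complete synthetic experiment under the given conditions."""
    cfg = cfg or GeneratorConfig()
    if max(cfg.assemblages_per_richness) > cfg.n_species_pool:
        raise ValueError("richness level exceeds the species pool")
    rng = np.random.default_rng(cfg.seed)
    design = build_design(seed=int(rng.integers(2**31 - 1)),
                          n_species_pool=cfg.n_species_pool,
                          assemblages_per_richness=cfg.assemblages_per_richness,
                          set_treatments=cfg.set_treatments)
    species = [f"sp{i:02d}" for i in range(1, cfg.n_species_pool + 1)]
    fauna = [f"F{i:02d}" for i in range(1, cfg.n_fauna_taxa + 1)]
    taxonomy = {f: f"O{(i % cfg.n_orders) + 1}" for i, f in enumerate(fauna)}
    plant_tree = generate_random_tree(species, rng=rng)
    fauna_tree = generate_random_tree(fauna, rng=rng)

    # species/taxon-level parameters, drawn once (deterministic per seed)
    mu_sp = rng.normal(1.0, 0.5, size=len(species))
    sens_d_sp = rng.normal(0.0, 1.0, size=len(species))
    sens_i_sp = rng.normal(0.0, 1.0, size=len(species))
    fauna_params = {}
    for comm in ("litter", "soil"):
        fauna_params[comm] = {
            "nu": rng.normal(2.0, 0.5, size=len(fauna)),
            "affinity": rng.normal(0.0, 1.0, size=(len(fauna), len(species))),
            "sens_d": rng.normal(0.0, 1.0, size=len(fauna)),
            "sens_i": rng.normal(0.0, 1.0, size=len(fauna)),
        }
    n_summary = len(species) + 1 + 2 * (len(fauna) + 1)
    loadings = rng.normal(0.0, 1.0, size=(cfg.n_functions, n_summary))
    loadings[:, :len(species) + 1] *= cfg.plant_function_coupling
    loadings[:, len(species) + 1:] *= cfg.fauna_function_coupling
    fn_sens_d = rng.normal(0.0, 1.0, size=cfg.n_functions)
    fn_sens_i = rng.normal(0.0, 1.0, size=cfg.n_functions)

    pots = design.pots
    members = {aid: set(mix) for aid, mix in design.assemblage_catalog.items()}
    sp_index = {s: k for k, s in enumerate(species)}

    plant = np.zeros((len(pots), len(species)))
    fauna_ab = {"litter": np.zeros((len(pots), len(fauna))),
                "soil": np.zeros((len(pots), len(fauna)))}
    funcs = np.zeros((len(pots), cfg.n_functions))

    for p, pot in enumerate(pots.itertuples(index=False)):
        r, d, i = pot.richness, pot.drought, pot.invasion
        stab = 1.0 + cfg.richness_stabilization * np.log2(r)
        sd_plant = cfg.plant_noise_sd * (
            1 + cfg.drought_destab_plant * d + cfg.invasion_destab_plant * i) / stab
        idx = [sp_index[s] for s in members[pot.assemblage_id]]
        logb = (mu_sp[idx]
                - cfg.drought_shift_plant * d * sens_d_sp[idx]
                - cfg.invasion_shift_plant * i * sens_i_sp[idx]
                + rng.normal(0.0, 1.0, size=len(idx)) * sd_plant)
        plant[p, idx] = np.exp(logb)
        x = plant[p] / plant[p].sum()

        sd_fauna = cfg.fauna_noise_sd * (
            1 + cfg.drought_destab_fauna * d + cfg.invasion_destab_fauna * i)
        summaries = [x, [np.log1p(plant[p].sum())]]
        for comm in ("litter", "soil"):
            fp = fauna_params[comm]
            logm = (fp["nu"]
                    + cfg.fauna_plant_coupling * (fp["affinity"] @ x)
                    - cfg.drought_shift_fauna * d * fp["sens_d"]
                    - cfg.invasion_shift_fauna * i * fp["sens_i"]
                    + rng.normal(0.0, 1.0, size=len(fauna)) * sd_fauna)
            ab = np.exp(logm)
            fauna_ab[comm][p] = ab
            y = ab / ab.sum()
            summaries += [y, [np.log1p(ab.sum())]]

        sd_fn = cfg.function_noise_sd * (
            1 + cfg.drought_destab_function * d
            + cfg.invasion_destab_function * i) / stab
        summary = np.concatenate([np.asarray(s, dtype=float) for s in summaries])
        funcs[p] = (loadings @ summary
                    - cfg.drought_shift_function * d * fn_sens_d
                    - cfg.invasion_shift_function * i * fn_sens_i
                    + rng.normal(0.0, 1.0, size=cfg.n_functions) * sd_fn)

    pot_ids = pots["pot_id"].tolist()
    fn_names = [f"fn{k:02d}" for k in range(1, cfg.n_functions + 1)]
    return SyntheticExperiment(
        design=design,
        plant_abundances=pd.DataFrame(plant, index=pot_ids, columns=species)
                           .rename_axis("pot_id"),
        litter_fauna=pd.DataFrame(fauna_ab["litter"], index=pot_ids,
                                  columns=fauna).rename_axis("pot_id"),
        soil_fauna=pd.DataFrame(fauna_ab["soil"], index=pot_ids,
                                columns=fauna).rename_axis("pot_id"),
        functions=pd.DataFrame(funcs, index=pot_ids, columns=fn_names)
                    .rename_axis("pot_id"),
        plant_tree=plant_tree,
        fauna_tree=fauna_tree,
        taxonomy=taxonomy,
        truth={"config": asdict(cfg), "expected_signs": cfg.expected_signs()},
    )


# ---------------------------------------------------------------------------
# exact-coefficient pair-level generator

#: default injected standardized coefficients (reference qualitative pattern)
DEFAULT_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("richness", "s_plant"): 0.40,
    ("drought", "s_plant"): -0.15,
    ("invasion", "s_plant"): -0.15,
    ("richness", "s_litter_fauna"): 0.15,
    ("drought", "s_litter_fauna"): -0.35,
    ("invasion", "s_litter_fauna"): -0.30,
    ("richness", "s_soil_fauna"): 0.15,
    ("drought", "s_soil_fauna"): -0.30,
    ("invasion", "s_soil_fauna"): -0.25,
    ("s_plant", "s_litter_fauna"): 0.15,
    ("s_plant", "s_soil_fauna"): 0.25,
    ("richness", "s_multifunctional"): 0.25,
    ("drought", "s_multifunctional"): -0.15,
    ("invasion", "s_multifunctional"): -0.20,
    ("s_plant", "s_multifunctional"): 0.35,
    ("s_litter_fauna", "s_multifunctional"): 0.10,
    ("s_soil_fauna", "s_multifunctional"): 0.20,
}


@dataclass
class PathCalibratedExperiment:
    """Similarity matrices whose pair observations follow a known SEM."""

    design: ExperimentalDesign
    aspect: str
    spec: PathModelSpec
    coefficients: dict[tuple[str, str], float]
    matrices: dict[str, SimilarityMatrix]


def simulate_path_matrices(aspect: str = "invariability",
                           coefficients: dict[tuple[str, str], float] | None = None,
                           design: ExperimentalDesign | None = None,
                           spec: PathModelSpec | None = None,
                           seed: int | None = None,
                           center: float = 0.5,
                           scale: float = 0.1) -> PathCalibratedExperiment:
    """Inject exact standardized path coefficients at the pair level.

    For the aspect's admissible pairs, mediator and outcome values are
    drawn from the recursive structural equations on the empirically
    standardized pair covariates, with residual variance chosen so every
    variable has unit variance; they are then mapped affinely into [0, 1]
    (standardized coefficients are invariant to affine maps) and stored as
    similarity matrices.  Entries outside the aspect's pair set are filled
    with i.i.d. draws on the node's marginal scale, so that a label
    permutation of a matrix (the Mantel-like null) resamples values with
    the same distribution as the admissible cells carry under no effect.
    """
    design = design or build_design(seed=0)
    spec = spec or PathModelSpec.default(aspect)
    if coefficients is None:
        coefficients = {e: DEFAULT_PATH_COEFFICIENTS[e] for e in spec.edges}
    missing = [e for e in spec.edges if e not in coefficients]
    if missing:
        raise ValueError(f"no coefficient given for edges: {missing}")
    rng = np.random.default_rng(seed)
    pairs = extract_pairs(design, aspect)
    obs = pairs.observations
    n = pairs.n

    z: dict[str, np.ndarray] = {}
    for f in spec.exogenous:
        v = obs[f].to_numpy(dtype=float)
        z[f] = (v - v.mean()) / v.std(ddof=1)
    for node in spec.endogenous:
        syst = np.zeros(n)
        for par in spec.parents(node):
            syst += coefficients[(par, node)] * z[par]
        var_s = syst.var(ddof=1)
        if var_s >= 1.0:
            raise ValueError(f"systematic variance of {node!r} is {var_s:.3f} "
                             ">= 1; reduce the coefficients")
        y = syst + rng.normal(0.0, np.sqrt(1.0 - var_s), size=n)
        z[node] = (y - y.mean()) / y.std(ddof=1)

    pot_ids = design.pot_ids
    pos = {p: k for k, p in enumerate(pot_ids)}
    ia = np.array([pos[p] for p in obs["pot_a"]], dtype=np.intp)
    ib = np.array([pos[p] for p in obs["pot_b"]], dtype=np.intp)
    matrices = {}
    n_pots = len(pot_ids)
    iu, ju = np.triu_indices(n_pots, k=1)
    for node, kind in RESPONSE_KINDS.items():
        background = np.clip(
            center + scale * rng.normal(size=len(iu)), 0.0, 1.0)
        m = np.empty((n_pots, n_pots))
        m[iu, ju] = background
        m[ju, iu] = background
        np.fill_diagonal(m, 1.0)
        if node in z:
            sims = np.clip(center + scale * z[node], 0.0, 1.0)
            m[ia, ib] = sims
            m[ib, ia] = sims
        matrices[kind] = SimilarityMatrix(pot_ids, m, kind=kind,
                                          metric_tag="sem_calibrated")
    return PathCalibratedExperiment(design, aspect, spec, dict(coefficients),
                                    matrices)


def null_coefficients(spec: PathModelSpec) -> dict[tuple[str, str], float]:
    """All-zero coefficient map (the no-effect null generator)."""
    return {e: 0.0 for e in spec.edges}
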