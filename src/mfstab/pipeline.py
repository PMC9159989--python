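"""End-to-end orchestration: from raw tables (or a synthetic experiment) to
similarity matrices, pair datasets, fitted path models, effect
decompositions and permutation/bootstrap inference, with a machine-readable
manifest."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .design import ExperimentalDesign
from .inference import (bootstrap_effects, mantel_test, permanova,
                        permutation_test_all_effects)
from .io import (read_abundances, read_design, read_functions, read_tree,
                 write_table)
from .pairs import ASPECTS, attach_similarities, extract_pairs
from .sem import PathModel, PathModelSpec
from .similarity import (community_similarity, multifunctional_similarity,
                         transform_functions)
from .simulate import GeneratorConfig, SyntheticExperiment, generate_experiment


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    seed: int = 0
    aspects: tuple[str, ...] = ASPECTS
    n_perm: int = 10_000
    n_boot: int = 10_000
    synthetic: GeneratorConfig | None = None
    input_dir: str | None = None
    output_dir: str | None = None
    richness_coding: str = "raw"
    attribution: str = "first"
    permute: str = "dependent"
    run_permanova: bool = True
    run_mantel: bool = True
    edges: tuple[tuple[str, str], ...] | None = None  # override default spec

    def __post_init__(self) -> None:
        unknown = set(self.aspects) - set(ASPECTS)
        if unknown:
            raise ValueError(f"unknown aspects: {sorted(unknown)}")
        if self.synthetic is None and self.input_dir is None:
            self.synthetic = GeneratorConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = GeneratorConfig(**d["synthetic"])
        if "aspects" in d:
            d["aspects"] = tuple(d["aspects"])
        if d.get("edges"):
            d["edges"] = tuple((s, t) for s, t in d["edges"])
        return cls(**d)

    def hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _log(stage: str, t0: float) -> None:
    print(f"[mfstab] {stage} ({time.perf_counter() - t0:.1f}s)", file=sys.stderr)


def load_experiment(cfg: RunConfig):
    """Load input tables from disk or generate a synthetic experiment."""
    if cfg.input_dir is not None:
        d = Path(cfg.input_dir)
        design = read_design(d / "design.tsv")
        plant_tree = read_tree(d / "plant_tree.nwk")
        fauna_tree = read_tree(d / "fauna_tree.nwk")
        return SyntheticExperiment(
            design=design,
            plant_abundances=read_abundances(d / "plant_abundances.tsv",
                                             tree=plant_tree, design=design),
            litter_fauna=read_abundances(d / "litter_fauna.tsv",
                                         tree=fauna_tree, design=design),
            soil_fauna=read_abundances(d / "soil_fauna.tsv",
                                       tree=fauna_tree, design=design),
            functions=read_functions(d / "functions.tsv"),
            plant_tree=plant_tree, fauna_tree=fauna_tree,
            taxonomy={}, truth={},
        )
    return generate_experiment(cfg.synthetic)


def compute_matrices(exp: SyntheticExperiment) -> dict:
    """All four similarity matrices from an experiment's tables."""
    return {
        "plant": community_similarity(exp.plant_abundances, exp.plant_tree,
                                      kind="plant"),
        "litter_fauna": community_similarity(exp.litter_fauna, exp.fauna_tree,
                                             kind="litter_fauna"),
        "soil_fauna": community_similarity(exp.soil_fauna, exp.fauna_tree,
                                           kind="soil_fauna"),
        "multifunctional": multifunctional_similarity(
            transform_functions(exp.functions)),
    }


def analyse_aspect(matrices: dict, design: ExperimentalDesign, aspect: str,
                   cfg: RunConfig, seed: int) -> dict:
    """Fit the aspect's path model and run its inference machinery."""
    spec = (PathModelSpec.default(aspect) if cfg.edges is None else
            PathModelSpec(PathModelSpec.default(aspect).nodes, cfg.edges))
    pairs = extract_pairs(design, aspect, richness_coding=cfg.richness_coding)
    pairs = attach_similarities(pairs, matrices)
    fit = PathModel.from_pairs(pairs, spec).fit()
    dec = fit.effects(attribution=cfg.attribution)
    rng = np.random.default_rng(seed)
    perms = permutation_test_all_effects(
        matrices, design, aspect, spec=spec, n_perm=cfg.n_perm,
        seed=int(rng.integers(2**31 - 1)), permute=cfg.permute,
        attribution=cfg.attribution)
    boots = bootstrap_effects(matrices, design, aspect, spec=spec,
                              n_boot=cfg.n_boot,
                              seed=int(rng.integers(2**31 - 1)),
                              attribution=cfg.attribution)
    return {
        "aspect": aspect,
        "n": pairs.n,
        "fit": {"chi_square": fit.chi_square, "df": fit.df,
                "p_fit": fit.p_fit, "rmsea": fit.rmsea, "n": fit.nobs,
                "r_squared": fit.rsquared,
                "coefficients": {f"{s}->{t}": c
                                 for (s, t), c in fit.params.items()}},
        "decomposition": {
            f: {"direct": e.direct, "indirect": e.indirect, "total": e.total,
                "shares_pct": e.shares()}
            for f, e in dec.factors.items()},
        "permutation": {k: {"observed": r.observed_effect, "p": r.p_value,
                            "p_one_sided": r.p_one_sided, "side": r.side,
                            "n_perm": r.n_permutations}
                        for k, r in perms.items()},
        "bootstrap": {k: {"point": b.point_effect, "mean": b.bootstrap_mean,
                          "sd": b.bootstrap_sd,
                          "bias_corrected_mean": b.bias_corrected_mean,
                          "n_boot": b.n_bootstrap}
                      for k, b in boots.items()},
        "_objects": {"pairs": pairs, "results": fit},
    }


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every configured aspect end to end; write outputs if configured.

    Returns the result bundle: matrices, per-aspect fits/decompositions/
    inference, optional PERMANOVA and Mantel tables, and the manifest.
    """
    t0 = time.perf_counter()
    exp = load_experiment(cfg)
    _log("inputs ready", t0)
    matrices = compute_matrices(exp)
    _log("similarity matrices", t0)

    rng = np.random.default_rng(cfg.seed)
    aspect_results = {}
    for aspect in cfg.aspects:
        aspect_results[aspect] = analyse_aspect(
            matrices, exp.design, aspect, cfg, int(rng.integers(2**31 - 1)))
        _log(f"aspect {aspect}", t0)

    bundle: dict = {"matrices": matrices, "aspects": aspect_results}
    if cfg.run_permanova:
        bundle["permanova"] = {
            kind: permanova(m, exp.design, ["richness", "drought", "invasion"],
                            n_perm=cfg.n_perm,
                            seed=int(rng.integers(2**31 - 1)))
            for kind, m in matrices.items()}
        _log("permanova", t0)
    if cfg.run_mantel:
        mantel = {}
        for kind in ("plant", "litter_fauna", "soil_fauna"):
            r, p = mantel_test(matrices[kind], matrices["multifunctional"],
                               n_perm=cfg.n_perm,
                               seed=int(rng.integers(2**31 - 1)))
            mantel[f"{kind}~multifunctional"] = {"spearman_r": r, "p": p}
        bundle["mantel"] = mantel
        _log("mantel", t0)

    manifest = {
        "package": "mfstab", "version": __version__,
        "seed": cfg.seed, "config_hash": cfg.hash(),
        "aspects": {a: {"n": r["n"]} for a, r in aspect_results.items()},
        "n_perm": cfg.n_perm, "n_boot": cfg.n_boot,
    }
    bundle["manifest"] = manifest

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for kind, m in matrices.items():
            m.to_tsv(out / f"similarity_{kind}.tsv")
        summary: dict = {"manifest": manifest}
        for aspect, res in aspect_results.items():
            res["_objects"]["pairs"].to_tsv(out / f"pairs_{aspect}.tsv")
            summary[aspect] = {k: v for k, v in res.items()
                               if not k.startswith("_")}
        if "permanova" in bundle:
            for kind, tab in bundle["permanova"].items():
                write_table(tab, out / f"permanova_{kind}.tsv")
        if "mantel" in bundle:
            summary["mantel"] = bundle["mantel"]
        (out / "results.json").write_text(json.dumps(summary, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _log("outputs written", t0)
    return bundle
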