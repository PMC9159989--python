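"""Significance and uncertainty machinery for the stability path models.

* Mantel-like permutation test: the pot labels of the tested effect's
  *dependent* similarity matrix are permuted simultaneously over rows and
  columns, pairs are re-extracted and the model refitted, giving a null
  distribution for any direct / indirect / total effect.
* Bootstrap: pots resampled with replacement within each treatment cell;
  pair sets rebuilt and the model refitted per replicate.
* Sequential (Type I) PERMANOVA over an ordered factor list.
* Mantel test (Spearman) between two similarity/distance matrices.
* Taxa-removal contribution: drop in the community-multifunctionality
  similarity correlation when a taxon set is removed.

All permutation p-values use the add-one convention (1 + b) / (m + 1),
counting null draws at or beyond the observed statistic on the observed
sign's side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .design import ExperimentalDesign
from .pairs import (RESPONSE_KINDS, PairDataset, attach_similarities,
                    extract_pair_frame, extract_pairs)
from .sem import (DEFAULT_OUTCOME, PathModel, PathModelError, PathModelSpec,
                  coefficients_from_corr, path_effect, standardize)
from .similarity import SimilarityMatrix, community_similarity


@dataclass(frozen=True)
class EffectSelector:
    """Names one effect in the decomposition: a factor's direct, indirect
    (optionally through one mediator) or total effect on an outcome."""

    source: str
    outcome: str = DEFAULT_OUTCOME
    kind: str = "total"
    mediator: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "indirect", "total"):
            raise ValueError(f"unknown effect kind {self.kind!r}")

    def label(self) -> str:
        if self.kind == "indirect" and self.mediator:
            return f"{self.source}:via:{self.mediator}"
        return f"{self.source}:{self.kind}"


@dataclass
class PermutationResult:
    """Outcome of the Mantel-like permutation test.

    ``p_value`` is two-sided (the sign-selected tail probability doubled,
    capped at 1), which is calibrated: rejecting at alpha gives type-I
    error alpha under the null.  ``p_one_sided`` is the raw add-one tail
    probability on the observed effect's side — the convention usually
    quoted with this test, but anti-conservative by up to a factor of two
    when the sign is chosen after seeing the data.
    """

    observed_effect: float
    null_effects: np.ndarray
    p_value: float
    p_one_sided: float
    n_permutations: int
    side: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


@dataclass
class BootstrapResult:
    point_effect: float
    bootstrap_mean: float
    bootstrap_sd: float
    n_bootstrap: int
    samples: np.ndarray = field(default=None, repr=False)

    @property
    def bias_corrected_mean(self) -> float:
        """2 * point - mean; reported alongside the plain bootstrap mean."""
        return 2.0 * self.point_effect - self.bootstrap_mean


def permutation_pvalue(observed: float,
                       null: np.ndarray) -> tuple[float, float, str]:
    """Two-sided and sign-selected one-sided add-one permutation p-values.

    The one-sided value is (1 + b) / (m + 1) with b the null draws at or
    beyond the observed effect on its own sign's side; the two-sided value
    doubles it (capped at 1), which restores nominal type-I calibration.
    """
    null = np.asarray(null, dtype=float)
    m = len(null)
    if observed >= 0:
        b = int(np.sum(null >= observed))
        side = "greater"
    else:
        b = int(np.sum(null <= observed))
        side = "less"
    one_sided = (1 + b) / (m + 1)
    return min(1.0, 2.0 * one_sided), one_sided, side


# ---------------------------------------------------------------------------
# Mantel-like permutation test for SEM effects

def _aligned_matrices(matrices: dict[str, SimilarityMatrix],
                      pot_ids: list[str]) -> dict[str, np.ndarray]:
    return {k: m.reorder(pot_ids).values for k, m in matrices.items()}


def permutation_test_effects(matrices: dict[str, SimilarityMatrix],
                             design: ExperimentalDesign, aspect: str,
                             effect: EffectSelector,
                             spec: PathModelSpec | None = None,
                             n_perm: int = 10_000, seed: int | None = None,
                             permute: str = "dependent",
                             attribution: str = "first",
                             one_to_one: bool = False) -> PermutationResult:
    """Mantel-like permutation test for one SEM-derived effect.

    Under H0 the tested factor has no effect on the dependent similarity
    matrix, so permuting that matrix's pot labels (rows and columns
    simultaneously) and refitting yields the null distribution of the
    effect.  ``permute='dependent'`` permutes only the outcome's matrix
    (mediator structure kept intact); ``permute='all'`` applies the same
    pot permutation to every endogenous response matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if permute not in ("dependent", "all"):
        raise ValueError("permute must be 'dependent' or 'all'")
    if spec is None:
        spec = PathModelSpec.default(aspect)
    if effect.source not in spec.exogenous:
        raise ValueError(f"effect source {effect.source!r} is not exogenous")
    if effect.outcome not in spec.endogenous:
        raise ValueError(f"effect outcome {effect.outcome!r} is not endogenous")

    pairs = extract_pairs(design, aspect, one_to_one=one_to_one)
    pot_ids = design.pot_ids
    vals = _aligned_matrices(matrices, pot_ids)
    pos = {p: i for i, p in enumerate(pot_ids)}
    ia = np.array([pos[p] for p in pairs.observations["pot_a"]], dtype=np.intp)
    ib = np.array([pos[p] for p in pairs.observations["pot_b"]], dtype=np.intp)

    nodes = list(spec.nodes)
    node_idx = {n: i for i, n in enumerate(nodes)}
    data = np.empty((pairs.n, len(nodes)))
    for j, node in enumerate(nodes):
        if node in RESPONSE_KINDS:
            data[:, j] = vals[RESPONSE_KINDS[node]][ia, ib]
        else:
            data[:, j] = pairs.observations[node].to_numpy(dtype=float)

    paths = spec.paths(effect.source, effect.outcome)

    def effect_of(mat: np.ndarray) -> float:
        z = standardize(mat)
        S = z.T @ z / (len(mat) - 1)
        coefs = coefficients_from_corr(S, spec, node_idx)
        return path_effect(coefs, paths, kind=effect.kind,
                           mediator=effect.mediator, attribution=attribution)

    observed = effect_of(data)

    if permute == "dependent":
        permuted_nodes = [effect.outcome]
    else:
        permuted_nodes = [n for n in spec.endogenous if n in RESPONSE_KINDS]

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    work = data.copy()
    n_pots = len(pot_ids)
    for t in range(n_perm):
        perm = rng.permutation(n_pots)
        pa, pb = perm[ia], perm[ib]
        for node in permuted_nodes:
            work[:, node_idx[node]] = vals[RESPONSE_KINDS[node]][pa, pb]
        null[t] = effect_of(work)
    p, p1, side = permutation_pvalue(observed, null)
    return PermutationResult(observed, null, p, p1, n_perm, side)


def permutation_test_all_effects(matrices, design, aspect,
                                 spec: PathModelSpec | None = None,
                                 outcome: str = DEFAULT_OUTCOME,
                                 kinds: tuple[str, ...] = ("direct", "total"),
                                 n_perm: int = 10_000,
                                 seed: int | None = None,
                                 **kw) -> dict[str, PermutationResult]:
    """Run the permutation test for every exogenous factor and effect kind."""
    if spec is None:
        spec = PathModelSpec.default(aspect)
    rng = np.random.default_rng(seed)
    out = {}
    for f in spec.exogenous:
        for kind in kinds:
            sel = EffectSelector(f, outcome=outcome, kind=kind)
            out[sel.label()] = permutation_test_effects(
                matrices, design, aspect, sel, spec=spec, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)), **kw)
    return out


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_effects(matrices: dict[str, SimilarityMatrix],
                      design: ExperimentalDesign, aspect: str,
                      spec: PathModelSpec | None = None,
                      outcome: str = DEFAULT_OUTCOME,
                      n_boot: int = 10_000, seed: int | None = None,
                      attribution: str = "first",
                      resampler=None) -> dict[str, BootstrapResult]:
    """Bootstrap mean and sd of every direct/indirect/total effect.

    Pots are resampled with replacement within each
    (richness, drought, invasion) cell; pair sets are rebuilt from the
    resampled pots (pairs of two copies of the same pot are dropped) and
    the model refitted.  Replicates whose refit fails (e.g. a constant
    response after a degenerate resample) are skipped with a warning.

    ``resampler`` can replace the cell-wise resampling with any callable
    ``(rng, pot_table) -> pot_table`` (the identity resampler makes the
    bootstrap mean equal the point effect exactly).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if spec is None:
        spec = PathModelSpec.default(aspect)
    rng = np.random.default_rng(seed)

    pairs = attach_similarities(extract_pairs(design, aspect), matrices)
    point_fit = PathModel.from_pairs(pairs, spec).fit()
    point = _decomposition_values(point_fit, outcome, attribution)

    pots = design.pots
    cells = [grp for _, grp in pots.groupby(["richness", "drought", "invasion"])]

    def cell_resampler(rng, pot_table):
        parts = []
        for grp in cells:
            take = rng.integers(0, len(grp), size=len(grp))
            parts.append(grp.iloc[take])
        return pd.concat(parts, ignore_index=True)

    draw = resampler or cell_resampler
    samples: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        boot = draw(rng, pots).copy()
        boot["orig_pot"] = boot["pot_id"].values
        boot["pot_id"] = [f"{p}#{i}" for i, p in enumerate(boot["orig_pot"])]
        frame = extract_pair_frame(boot, aspect)
        orig = boot.set_index("pot_id")["orig_pot"]
        oa = frame["pot_a"].map(orig)
        ob = frame["pot_b"].map(orig)
        frame = frame[(oa != ob).values].copy()
        frame["pot_a"] = oa[oa != ob].values
        frame["pot_b"] = ob[ob != oa].values
        for response, kind in RESPONSE_KINDS.items():
            m = matrices[kind]
            frame[response] = m.values[m.positions(frame["pot_a"].values),
                                       m.positions(frame["pot_b"].values)]
        try:
            fit = PathModel(frame, spec).fit()
        except PathModelError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        for k, v in _decomposition_values(fit, outcome, attribution).items():
            samples[k].append(v)
    out = {}
    for k, v in samples.items():
        arr = np.asarray(v, dtype=float)
        if len(arr) == 0:
            raise PathModelError("every bootstrap replicate failed")
        out[k] = BootstrapResult(point[k], float(arr.mean()),
                                 float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                                 len(arr), samples=arr)
    return out


def _decomposition_values(fit, outcome, attribution) -> dict[str, float]:
    dec = fit.effects(outcome=outcome, attribution=attribution)
    vals = {}
    for f, eff in dec.factors.items():
        vals[f"{f}:direct"] = eff.direct
        for m, v in eff.indirect.items():
            vals[f"{f}:via:{m}"] = v
        vals[f"{f}:total"] = eff.total
    return vals


# ---------------------------------------------------------------------------
# PERMANOVA (sequential / Type I)

def _as_distance(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, SimilarityMatrix):
        return 1.0 - x.values, list(x.ids)
    if isinstance(x, DistanceMatrix):
        return np.array(x.data, dtype=float), list(x.ids)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.index.astype(str))
    raise TypeError(f"cannot interpret {type(x).__name__} as a distance matrix")


def permanova(dm, design, factors: list[str], n_perm: int = 10_000,
              seed: int | None = None,
              categorical: tuple[str, ...] = (),
              exhaustive: bool = False) -> pd.DataFrame:
    """Sequential (Type I) PERMANOVA over an ordered factor list.

    Squared distances are partitioned in the given factor order (each term
    adjusted for the preceding ones), as in the classical distance-based
    MANOVA: the Gower-centered matrix G is projected onto the nested
    column spaces of the cumulative design matrices.  Factors are numeric
    covariates unless listed in ``categorical``.  p-values come from
    permuting pot labels of the distance matrix; ``exhaustive`` enumerates
    every label permutation instead (feasible only for very small n) and
    reports the exact fraction, identity included, with F at or above the
    observed value.
    """
    D, ids = _as_distance(dm)
    pots = (design.pots if isinstance(design, ExperimentalDesign)
            else design).set_index("pot_id").loc[ids]
    n = len(ids)

    blocks = []
    for f in factors:
        col = pots[f]
        if col.nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
        if f in categorical:
            x = pd.get_dummies(col.astype("category"), drop_first=True
                               ).to_numpy(dtype=float)
        else:
            x = col.to_numpy(dtype=float)[:, None]
        blocks.append((f, x))

    X = np.hstack([np.ones((n, 1))] + [b for _, b in blocks])
    Q, R = np.linalg.qr(X)
    if np.abs(np.diag(R)).min() < 1e-10 * np.abs(np.diag(R)).max():
        raise ValueError("design matrix is rank deficient")
    # orthonormal column ranges per factor (Gram-Schmidt order = factor order)
    ranges, start = [], 1
    for f, x in blocks:
        ranges.append((f, start, start + x.shape[1]))
        start += x.shape[1]

    A = D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ A @ J
    ss_total = float(np.trace(G))
    df_res = n - start

    def partition(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.einsum("ik,ij,jk->", Q[:, a:b], Gm, Q[:, a:b]))
                       for _, a, b in ranges])
        ss_res = float(np.trace(Gm)) - float(ss.sum()) - float(
            Q[:, 0] @ Gm @ Q[:, 0])
        return ss, ss_res

    ss_f, ss_res = partition(G)
    dfs = np.array([b - a for _, a, b in ranges])
    F_obs = (ss_f / dfs) / (ss_res / df_res)

    if exhaustive:
        from itertools import permutations as _all_perms
        from math import factorial
        if factorial(n) > 50_000:
            raise ValueError(f"exhaustive enumeration infeasible for n = {n}")
        counts = np.zeros(len(blocks))
        total = 0
        for perm in _all_perms(range(n)):
            ssp, ssrp = partition(G[np.ix_(perm, perm)])
            Fp = (ssp / dfs) / (ssrp / df_res)
            counts += Fp >= F_obs - 1e-12
            total += 1
        pvals = counts / total
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(len(blocks))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ssp, ssrp = partition(G[np.ix_(perm, perm)])
            Fp = (ssp / dfs) / (ssrp / df_res)
            counts += Fp >= F_obs
        pvals = (1 + counts) / (n_perm + 1)

    rows = [{"factor": f, "df": int(d), "SumOfSqs": s,
             "R2": s / ss_total, "F": F, "p": p}
            for (f, _, _), d, s, F, p in zip(ranges, dfs, ss_f, F_obs, pvals)]
    rows.append({"factor": "Residual", "df": df_res, "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"factor": "Total", "df": n - 1, "SumOfSqs": ss_total,
                 "R2": 1.0, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("factor")


# ---------------------------------------------------------------------------
# Mantel test

def mantel_test(a, b, n_perm: int = 10_000, seed: int | None = None,
                method: str = "spearman",
                alternative: str = "two-sided") -> tuple[float, float]:
    """Mantel test between two labelled similarity/distance matrices.

    Correlates corresponding off-diagonal entries (Spearman by default);
    the p-value permutes rows and columns of one matrix simultaneously.
    Similarity matrices are converted to distances (1 - S), which leaves
    the correlation and its significance unchanged when applied to both.
    """
    da, ids_a = _as_distance(a)
    db, ids_b = _as_distance(b)
    if set(ids_a) != set(ids_b):
        raise ValueError("matrices must be labelled with the same pots")
    order = [ids_b.index(i) for i in ids_a]
    db = db[np.ix_(order, order)]
    np.fill_diagonal(da, 0.0)
    np.fill_diagonal(db, 0.0)
    r, p, _ = _skbio_mantel(DistanceMatrix(da, ids_a), DistanceMatrix(db, ids_a),
                            method=method, permutations=n_perm,
                            alternative=alternative, seed=seed)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# taxa-removal contribution

def taxa_removal_contribution(abundances: pd.DataFrame, tree, mf_matrix,
                              design: ExperimentalDesign, aspect: str,
                              removal_sets: dict[str, list[str]],
                              method: str = "spearman",
                              kind: str = "plant") -> pd.Series:
    """Relative contribution of taxon sets to the community-multifunctionality
    stability relationship.

    The contribution of a set is the baseline correlation (over the
    aspect's pairs) between community similarity and multifunctional
    similarity MINUS the same correlation recomputed after removing the
    set from the abundance table (relative abundances renormalize
    implicitly).  A larger drop means a larger contribution.
    """
    pairs = extract_pairs(design, aspect)
    mf = mf_matrix if isinstance(mf_matrix, SimilarityMatrix) else SimilarityMatrix(
        list(mf_matrix.index), np.asarray(mf_matrix), kind="multifunctional")
    s_mf = mf.values[mf.positions(pairs.observations["pot_a"].values),
                     mf.positions(pairs.observations["pot_b"].values)]

    corr = (sps.spearmanr if method == "spearman" else sps.pearsonr)

    def pair_corr(ab: pd.DataFrame) -> float:
        cm = community_similarity(ab, tree, kind=kind)
        s_c = cm.values[cm.positions(pairs.observations["pot_a"].values),
                        cm.positions(pairs.observations["pot_b"].values)]
        return float(corr(s_c, s_mf)[0])

    baseline = pair_corr(abundances)
    out = {}
    for name, taxa in removal_sets.items():
        unknown = sorted(set(taxa) - set(abundances.columns))
        if unknown:
            raise KeyError(f"removal set {name!r} names unknown taxa: {unknown}")
        reduced = abundances.copy()
        reduced[list(taxa)] = 0.0
        if reduced.equals(abundances):
            out[name] = 0.0
            continue
        emptied = reduced.index[(reduced.values <= 0).all(axis=1)].tolist()
        if emptied:
            raise ValueError(
                f"removal set {name!r} empties the community of pots {emptied}")
        out[name] = baseline - pair_corr(reduced)
    return pd.Series(out, name="contribution")


def order_removal_sets(taxonomy: dict[str, str]) -> dict[str, list[str]]:
    """Group taxa by Order rank: {taxon -> order} to {order -> [taxa]}."""
    sets: dict[str, list[str]] = {}
    for taxon, order in taxonomy.items():
        sets.setdefault(order, []).append(taxon)
    return sets
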