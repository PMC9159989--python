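"""Pairwise similarity matrices for communities and multifunctionality.

Community similarity is 1 minus the *normalized* weighted UniFrac distance
between relative-abundance profiles (normalized so the distance lies in
[0, 1] and "1 minus distance" is a valid similarity).  Multifunctional
similarity is 1 minus the Bray-Curtis dissimilarity of the transformed
function profiles.  Single-function similarity between pots i and j is
1 - |V_i - V_j| / (V_i + V_j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode


class SimilarityError(ValueError):
    """Raised when a similarity is undefined or a matrix invariant fails."""


@dataclass
class SimilarityMatrix:
    """Labelled symmetric matrix of pairwise similarities in [0, 1].

    Parameters
    ----------
    ids : sequence of str
        Pot labels, one per row/column.
    values : ndarray
        Symmetric matrix with unit diagonal.
    kind : str
        One of ``multifunctional``, ``plant``, ``litter_fauna``,
        ``soil_fauna``, ``single_function``.
    metric_tag : str
        Provenance of the underlying distance (e.g.
        ``weighted_unifrac_normalized``).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "multifunctional"
    metric_tag: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise SimilarityError("matrix shape does not match the id list")
        if not np.allclose(v, v.T, atol=1e-8):
            raise SimilarityError("similarity matrix is not symmetric")
        if np.isnan(v).any():
            raise SimilarityError("similarity matrix contains NaN")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise SimilarityError(
                f"similarities outside [0, 1]: range [{v.min()}, {v.max()}]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise SimilarityError("similarity matrix diagonal must be 1")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        self._index = {pid: k for k, pid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise SimilarityError("duplicate ids in similarity matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def positions(self, pots) -> np.ndarray:
        """Integer positions of the given pot labels (vectorised lookup)."""
        try:
            return np.array([self._index[p] for p in pots], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(
                f"pot {exc.args[0]!r} is not labelled in the {self.kind} matrix"
            ) from None

    def reorder(self, ids) -> "SimilarityMatrix":
        pos = self.positions(ids)
        return SimilarityMatrix(list(ids), self.values[np.ix_(pos, pos)],
                                kind=self.kind, metric_tag=self.metric_tag)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_distance_condensed(self) -> np.ndarray:
        return squareform(1.0 - self.values, checks=False)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def to_long(self) -> pd.DataFrame:
        """Long-form unordered pair list (upper triangle)."""
        iu, ju = np.triu_indices(self.n, k=1)
        return pd.DataFrame({
            "pot_a": np.array(self.ids)[iu],
            "pot_b": np.array(self.ids)[ju],
            "similarity": self.values[iu, ju],
        })

    @classmethod
    def from_tsv(cls, path, kind: str = "multifunctional",
                 metric_tag: str = "") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.values, kind=kind,
                   metric_tag=metric_tag)


# ---------------------------------------------------------------------------
# function-variable transform

def transform_functions(functions: pd.DataFrame) -> pd.DataFrame:
    """Scale every function variable to V' = (V - min(V)) / sd(V).

    Each column then has minimum 0 and unit sample standard deviation
    (n - 1 denominator), guaranteeing even contribution to global variance
    while keeping all values nonnegative for Bray-Curtis.
    """
    out = {}
    for col in functions.columns:
        v = functions[col].astype(float)
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise SimilarityError(
                f"function variable {col!r} is constant (sd = 0); cannot transform")
        out[col] = (v - v.min()) / sd
    return pd.DataFrame(out, index=functions.index)[functions.columns]


# ---------------------------------------------------------------------------
# similarity constructors

def multifunctional_similarity(functions_transformed: pd.DataFrame,
                               kind: str = "multifunctional") -> SimilarityMatrix:
    """1 minus Bray-Curtis dissimilarity over transformed function profiles."""
    x = functions_transformed.astype(float).values
    if (x < 0).any():
        raise SimilarityError("Bray-Curtis requires nonnegative values; "
                              "apply transform_functions first")
    d = pdist(x, metric="braycurtis")
    if np.isnan(d).any():
        ids = np.asarray(functions_transformed.index)
        iu, ju = np.triu_indices(len(ids), k=1)
        bad = list(zip(ids[iu[np.isnan(d)]], ids[ju[np.isnan(d)]]))
        raise SimilarityError(
            f"Bray-Curtis undefined for all-zero profile pairs: {bad[:5]}")
    return SimilarityMatrix(list(functions_transformed.index.astype(str)),
                            1.0 - squareform(d), kind=kind,
                            metric_tag="bray_curtis")


def _branch_structure(tree: TreeNode, taxa: list[str]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch x taxon subtending-indicator matrix.

    The root's own edge carries no length; tree tips may be a superset of
    the taxa, but every taxon must resolve to exactly one tip.
    """
    tips = [t.name for t in tree.tips()]
    unresolved = sorted(set(taxa) - set(tips))
    if unresolved:
        raise SimilarityError(f"taxa not found as tree leaves: {unresolved}")
    if len(set(tips)) != len(tips):
        raise SimilarityError("tree has duplicated tip names")
    pos = {t: i for i, t in enumerate(taxa)}
    masks: dict[int, np.ndarray] = {}
    lengths, rows = [], []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            m = np.zeros(len(taxa))
            if node.name in pos:
                m[pos[node.name]] = 1.0
        else:
            m = np.sum([masks.pop(id(c)) for c in node.children], axis=0)
        masks[id(node)] = m
        lengths.append(node.length or 0.0)
        rows.append(m)
    return np.asarray(lengths), np.asarray(rows)


def community_similarity(abundances: pd.DataFrame, tree: TreeNode,
                         kind: str = "plant") -> SimilarityMatrix:
    """1 minus normalized weighted UniFrac between relative-abundance profiles.

    For relative-abundance profiles u, v and branches b with length l_b
    subtending proportions U_b, V_b,

        D(u, v) = sum_b l_b |U_b - V_b|  /  sum_b l_b (U_b + V_b),

    the normalized variant, so the distance lies in [0, 1] and 1 - D is a
    valid similarity.  Computed from the branch-indicator matrix directly,
    which keeps continuous abundances (biomasses) exact.  Every taxon must
    map to a tree leaf; pots with zero total abundance are rejected
    (relative abundances undefined).
    """
    totals = abundances.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise SimilarityError(
            f"pots with zero total abundance: {list(abundances.index[totals <= 0])}")
    lengths, indicator = _branch_structure(tree, list(abundances.columns))
    rel = abundances.to_numpy(dtype=float) / totals[:, None]
    weighted = (rel @ indicator.T) * lengths  # per-branch l_b * U_b
    depth = weighted.sum(axis=1)  # = sum_tips root-distance * u_tip
    if (depth <= 0).any():
        raise SimilarityError("a profile subtends zero total branch length")
    num = squareform(pdist(weighted, metric="cityblock"))
    den = depth[:, None] + depth[None, :]
    sim = 1.0 - num / den
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(abundances.index.astype(str)), sim, kind=kind,
                            metric_tag="weighted_unifrac_normalized")


def single_function_similarity(values: pd.Series,
                               kind: str = "single_function") -> SimilarityMatrix:
    """SIM_ij = 1 - |V_i - V_j| / (V_i + V_j) for a nonnegative vector.

    The degenerate 0/0 case (both values zero) yields similarity 1 — two
    absent quantities are maximally similar — with a warning.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise SimilarityError("single-function similarity requires values >= 0")
    num = np.abs(v[:, None] - v[None, :])
    den = v[:, None] + v[None, :]
    zero = den == 0
    if zero[np.triu_indices(len(v), k=1)].any():
        warnings.warn("0/0 in single-function similarity treated as similarity 1",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return SimilarityMatrix(list(pd.Index(values.index).astype(str)), sim,
                            kind=kind, metric_tag="proportional_difference")
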