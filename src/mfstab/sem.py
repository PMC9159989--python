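"""Observed-variable recursive path models (SEM) on pair datasets.

The model is a recursive system of linear equations among measured
variables.  All variables are z-standardized, so each endogenous node's
least-squares regression on its parents yields standardized partial
regression weights — for a recursive model with uncorrelated errors these
equal the maximum-likelihood path coefficients, and can be read as partial
correlations after removing all side effects.  Goodness of fit follows the
covariance-structure convention: with S the sample correlation matrix and
Sigma the model-implied matrix,

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,     chi2 = (n - 1) F,
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))),

df = p(p+1)/2 minus free parameters (edges + exogenous (co)variances +
residual variances).  A saturated model has df = 0 and chi2 = 0.

Direct effects are single-edge coefficients; the indirect effect through a
mediator sums the coefficient products of all multi-edge directed paths
attributed to that mediator (by default the first mediator on the path);
total = direct + sum of indirects, exactly, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .pairs import PairDataset

DEFAULT_MEDIATORS = ("s_plant", "s_litter_fauna", "s_soil_fauna")
DEFAULT_OUTCOME = "s_multifunctional"


class PathModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class PathModelSpec:
    """Directed acyclic path structure among observed variables."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        for s, t in self.edges:
            if s not in nodes or t not in nodes:
                raise PathModelError(f"edge ({s!r}, {t!r}) has an endpoint "
                                     "that is not a declared node")
        if len(set(self.edges)) != len(self.edges):
            raise PathModelError("duplicate edges in spec")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise PathModelError("path model must be acyclic")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.edges}
        return tuple(n for n in self.nodes if n not in targets)

    @property
    def endogenous(self) -> tuple[str, ...]:
        order = list(nx.topological_sort(self.graph()))
        exo = set(self.exogenous)
        return tuple(n for n in order if n not in exo)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.edges if t == node)

    def paths(self, source: str, target: str) -> list[tuple[str, ...]]:
        """All directed paths source -> ... -> target (node sequences)."""
        return [tuple(p) for p in nx.all_simple_paths(self.graph(), source, target)]

    def drop_edge(self, edge: tuple[str, str]) -> "PathModelSpec":
        if tuple(edge) not in self.edges:
            raise PathModelError(f"edge {edge} is not in the spec")
        return PathModelSpec(self.nodes,
                             tuple(e for e in self.edges if e != tuple(edge)))

    def add_edge(self, edge: tuple[str, str]) -> "PathModelSpec":
        return PathModelSpec(self.nodes, self.edges + (tuple(edge),))

    @property
    def n_free_parameters(self) -> int:
        k = len(self.exogenous)
        return len(self.edges) + k * (k + 1) // 2 + len(self.endogenous)

    @property
    def df(self) -> int:
        p = len(self.nodes)
        return p * (p + 1) // 2 - self.n_free_parameters

    @classmethod
    def default(cls, aspect: str = "invariability",
                mediators: tuple[str, ...] = DEFAULT_MEDIATORS,
                outcome: str = DEFAULT_OUTCOME) -> "PathModelSpec":
        """Canonical spec: every treatment factor points at every community
        stability and at multifunctional stability; plant stability also
        points at both faunal stabilities (the plant-to-fauna cascade).

        The ``invasion_resistance`` aspect drops the invasion factor (it
        spans the contrast and is not a pair covariate there).
        """
        factors = {"invariability": ("richness", "drought", "invasion"),
                   "drought_resistance": ("richness", "drought", "invasion"),
                   "invasion_resistance": ("richness", "drought")}[aspect]
        edges: list[tuple[str, str]] = []
        for f in factors:
            for m in mediators:
                edges.append((f, m))
            edges.append((f, outcome))
        plant = mediators[0]
        for m in mediators[1:]:
            edges.append((plant, m))
        for m in mediators:
            edges.append((m, outcome))
        return cls(factors + mediators + (outcome,), tuple(edges))

    @classmethod
    def saturated(cls, nodes: tuple[str, ...],
                  n_exogenous: int = 1) -> "PathModelSpec":
        """Just-identified spec: complete DAG in the given node order."""
        edges = [(nodes[i], nodes[j]) for j in range(n_exogenous, len(nodes))
                 for i in range(j)]
        return cls(tuple(nodes), tuple(edges))


# ---------------------------------------------------------------------------
# fast fitting core (used directly by the permutation machinery)

def standardize(x: np.ndarray) -> np.ndarray:
    """Column-wise z-scores with the n-1 standard deviation."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any() or not np.isfinite(sd).all():
        raise PathModelError("constant variable cannot be standardized")
    return (x - mu) / sd


def coefficients_from_corr(S: np.ndarray, spec: PathModelSpec,
                           index: dict[str, int]) -> dict[tuple[str, str], float]:
    """Standardized path coefficients from a correlation matrix.

    Solves, for each endogenous node, the normal equations
    S[parents, parents] beta = S[parents, node].
    """
    coefs: dict[tuple[str, str], float] = {}
    for node in spec.endogenous:
        par = spec.parents(node)
        pi = [index[p] for p in par]
        ni = index[node]
        try:
            beta = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, ni])
        except np.linalg.LinAlgError as exc:
            raise PathModelError(f"singular design for node {node!r}") from exc
        for p, b in zip(par, beta):
            coefs[(p, node)] = float(b)
    return coefs


def path_effect(coefs: dict[tuple[str, str], float],
                paths: list[tuple[str, ...]],
                kind: str = "total", mediator: str | None = None,
                attribution: str = "first") -> float:
    """Sum of coefficient products over directed paths.

    ``kind`` is ``direct`` (single-edge path), ``total`` (all paths) or
    ``indirect`` (multi-edge paths; with ``mediator`` given, only paths
    attributed to that mediator — the first or last mediator on the path
    per ``attribution``).
    """
    if attribution not in ("first", "last"):
        raise ValueError("attribution must be 'first' or 'last'")
    val = 0.0
    for p in paths:
        prod = 1.0
        for e in zip(p[:-1], p[1:]):
            prod *= coefs[e]
        if kind == "total":
            val += prod
        elif kind == "direct":
            if len(p) == 2:
                val += prod
        elif kind == "indirect":
            if len(p) > 2:
                med = p[1] if attribution == "first" else p[-2]
                if mediator is None or med == mediator:
                    val += prod
        else:
            raise ValueError(f"unknown effect kind {kind!r}")
    return val


# ---------------------------------------------------------------------------
# model / results objects

class PathModel:
    """Recursive path model bound to a dataset.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per observation; must contain every spec node as a column.
    spec : PathModelSpec
    """

    def __init__(self, data: pd.DataFrame, spec: PathModelSpec):
        missing = [n for n in spec.nodes if n not in data.columns]
        if missing:
            raise PathModelError(f"data is missing model variables: {missing}")
        self.spec = spec
        self.data = data
        self.index = {n: i for i, n in enumerate(spec.nodes)}
        self.nobs = len(data)
        max_parents = max((len(spec.parents(n)) for n in spec.endogenous),
                          default=0)
        if self.nobs <= max_parents + 1:
            raise PathModelError(
                f"n = {self.nobs} observations cannot identify a node with "
                f"{max_parents} parents")

    @classmethod
    def from_pairs(cls, pairs: PairDataset,
                   spec: PathModelSpec | None = None) -> "PathModel":
        if spec is None:
            spec = PathModelSpec.default(pairs.aspect)
        return cls(pairs.observations, spec)

    def fit(self) -> "PathResults":
        z = standardize(self.data[list(self.spec.nodes)].to_numpy(dtype=float))
        S = z.T @ z / (self.nobs - 1)
        return self._fit_from_corr(S)

    def _fit_from_corr(self, S: np.ndarray) -> "PathResults":
        spec, index, n = self.spec, self.index, self.nobs
        coefs = coefficients_from_corr(S, spec, index)
        p = len(spec.nodes)
        rsq = {}
        psi = np.zeros(p)
        B = np.zeros((p, p))
        for node in spec.endogenous:
            ni = index[node]
            expl = 0.0
            for par in spec.parents(node):
                B[ni, index[par]] = coefs[(par, node)]
                expl += coefs[(par, node)] * S[index[par], ni]
            rsq[node] = expl
            psi[ni] = 1.0 - expl
        exo_i = [index[e] for e in spec.exogenous]
        Psi = np.zeros((p, p))
        Psi[np.ix_(exo_i, exo_i)] = S[np.ix_(exo_i, exo_i)]
        for node in spec.endogenous:
            ni = index[node]
            Psi[ni, ni] = psi[ni]
        inv_imb = np.linalg.inv(np.eye(p) - B)
        sigma = inv_imb @ Psi @ inv_imb.T
        sign_s, logdet_s = np.linalg.slogdet(S)
        sign_m, logdet_m = np.linalg.slogdet(sigma)
        if sign_s <= 0 or sign_m <= 0:
            raise PathModelError("covariance matrix is not positive definite")
        fml = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
        chi2 = max((n - 1) * fml, 0.0)
        df = spec.df
        if df < 0:
            raise PathModelError(f"negative degrees of freedom ({df})")
        p_fit = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
        # naive asymptotic SEs of standardized weights (descriptive only;
        # inference uses permutation / bootstrap)
        ses = {}
        for node in spec.endogenous:
            par = spec.parents(node)
            pi = [index[q] for q in par]
            cov = psi[index[node]] * np.linalg.inv(S[np.ix_(pi, pi)]) / (n - 1)
            for q, se2 in zip(par, np.diag(cov)):
                ses[(q, node)] = float(np.sqrt(max(se2, 0.0)))
        return PathResults(model=self, corr=S, params=coefs, bse=ses,
                           rsquared=rsq, nobs=n, chi_square=chi2, df=df,
                           p_fit=p_fit, rmsea=rmsea)


@dataclass
class FactorEffects:
    """Direct / indirect / total effect of one exogenous factor."""

    factor: str
    direct: float
    indirect: dict[str, float]
    attribution: str = "first"

    @property
    def indirect_total(self) -> float:
        return sum(self.indirect.values())

    @property
    def total(self) -> float:
        return self.direct + self.indirect_total

    def shares(self) -> dict[str, float]:
        """Percentage shares of the absolute total effect."""
        denom = abs(self.total)
        if denom == 0:
            return {}
        out = {"direct": 100.0 * self.direct / denom,
               "indirect": 100.0 * self.indirect_total / denom}
        for m, v in self.indirect.items():
            out[f"via {m}"] = 100.0 * v / denom
        return out


@dataclass
class EffectDecomposition:
    outcome: str
    factors: dict[str, FactorEffects]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, eff in self.factors.items():
            row = {"factor": f, "direct": eff.direct, "total": eff.total}
            for m, v in eff.indirect.items():
                row[f"via_{m}"] = v
            rows.append(row)
        return pd.DataFrame(rows).set_index("factor")


@dataclass
class PathResults:
    """Fitted path model: standardized coefficients, fit statistics,
    explained variances, and effect decompositions."""

    model: PathModel
    corr: np.ndarray
    params: dict[tuple[str, str], float]
    bse: dict[tuple[str, str], float]
    rsquared: dict[str, float]
    nobs: int
    chi_square: float
    df: int
    p_fit: float
    rmsea: float
    _path_cache: dict = field(default_factory=dict, repr=False)

    @property
    def spec(self) -> PathModelSpec:
        return self.model.spec

    def paths(self, source: str, outcome: str) -> list[tuple[str, ...]]:
        key = (source, outcome)
        if key not in self._path_cache:
            self._path_cache[key] = self.spec.paths(source, outcome)
        return self._path_cache[key]

    def effect(self, source: str, outcome: str = DEFAULT_OUTCOME,
               kind: str = "total", mediator: str | None = None,
               attribution: str = "first") -> float:
        return path_effect(self.params, self.paths(source, outcome),
                           kind=kind, mediator=mediator, attribution=attribution)

    def effects(self, outcome: str = DEFAULT_OUTCOME,
                attribution: str = "first") -> EffectDecomposition:
        """Decompose each exogenous factor's effect on ``outcome``.

        A path through several mediators is attributed to one mediator:
        the first after the factor (default) or the last before the
        outcome.  direct + sum(indirect) = total holds exactly.
        """
        if outcome not in self.spec.endogenous:
            raise PathModelError(f"outcome {outcome!r} is not endogenous")
        mediators = [n for n in self.spec.endogenous if n != outcome]
        out = {}
        for f in self.spec.exogenous:
            paths = self.paths(f, outcome)
            direct = path_effect(self.params, paths, kind="direct")
            indirect = {m: path_effect(self.params, paths, kind="indirect",
                                       mediator=m, attribution=attribution)
                        for m in mediators}
            out[f] = FactorEffects(f, direct, indirect, attribution=attribution)
        return EffectDecomposition(outcome, out)

    def drop_edge_refit(self, edge: tuple[str, str]) -> "PathResults":
        """Refit without one path; df rises by 1 — the chi-square inflation
        measures how much the model destabilizes when the path is deleted."""
        return PathModel(self.model.data, self.spec.drop_edge(edge)).fit()

    def params_frame(self) -> pd.DataFrame:
        rows = [{"source": s, "target": t, "coefficient": c,
                 "se": self.bse.get((s, t), np.nan)}
                for (s, t), c in self.params.items()]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Recursive path model (standardized observed variables)",
            "=" * 62,
            f"n obs: {self.nobs}    chi2: {self.chi_square:.4f}    "
            f"df: {self.df}    p: {self.p_fit:.4f}    RMSEA: {self.rmsea:.4f}",
            "-" * 62,
            f"{'path':<42}{'coef':>10}{'se':>10}",
        ]
        for (s, t), c in self.params.items():
            lines.append(f"{s + ' -> ' + t:<42}{c:>10.4f}{self.bse[(s, t)]:>10.4f}")
        lines.append("-" * 62)
        for node, r2 in self.rsquared.items():
            lines.append(f"R2[{node}] = {r2:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_path_model(pairs: PairDataset,
                   spec: PathModelSpec | None = None) -> PathResults:
    return PathModel.from_pairs(pairs, spec).fit()


def decompose_effects(fit: PathResults, outcome: str = DEFAULT_OUTCOME,
                      attribution: str = "first") -> EffectDecomposition:
    return fit.effects(outcome=outcome, attribution=attribution)


def delete_path_refit(pairs: PairDataset, spec: PathModelSpec,
                      edge: tuple[str, str]) -> PathResults:
    return PathModel.from_pairs(pairs, spec.drop_edge(edge)).fit()
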