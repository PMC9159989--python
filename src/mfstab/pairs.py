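"""Pair datasets for the three stability aspects.

Each stability aspect is a subset of the pot-pair similarity matrix:

* ``invariability`` — all unordered pairs of pots under the *same*
  (richness, drought, invasion) treatment; similarity among replicates
  measures stability against stochastic fluctuation.
* ``drought_resistance`` — pairs of a non-drought pot with a droughted pot
  (level 1 or 2) at the same richness and invasion; the drought covariate
  is the disturbed member's level.
* ``invasion_resistance`` — pairs of a non-invaded pot with an invaded pot
  at the same richness and drought; invasion spans the contrast and is
  dropped as a covariate.

For the reference design these subsets contain 1476, 2148 and 1611 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .design import ExperimentalDesign
from .similarity import SimilarityMatrix

ASPECTS = ("invariability", "drought_resistance", "invasion_resistance")

#: SEM response column -> similarity-matrix kind
RESPONSE_KINDS = {
    "s_plant": "plant",
    "s_litter_fauna": "litter_fauna",
    "s_soil_fauna": "soil_fauna",
    "s_multifunctional": "multifunctional",
}


@dataclass
class PairDataset:
    """Observation table of one stability aspect: one row per admissible pair.

    ``observations`` columns: ``pot_a``, ``pot_b``, the aspect's factor
    covariates, and (after :func:`attach_similarities`) the four similarity
    responses.
    """

    aspect: str
    observations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {self.aspect!r}; expected one of {ASPECTS}")
        df = self.observations
        if (df["pot_a"] == df["pot_b"]).any():
            raise ValueError("self-pairs are not admissible")
        key = df[["pot_a", "pot_b"]].apply(frozenset, axis=1) if len(df) else pd.Series([], dtype=object)
        if key.duplicated().any():
            raise ValueError("an unordered pot pair appears more than once")
        self.observations = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def covariates(self) -> list[str]:
        base = {"invariability": ["richness", "drought", "invasion"],
                "drought_resistance": ["richness", "drought", "invasion"],
                "invasion_resistance": ["richness", "drought"]}[self.aspect]
        return [c for c in base if c in self.observations.columns]

    def to_tsv(self, path) -> None:
        self.observations.to_csv(path, sep="\t", index=False)


def _richness_value(r: np.ndarray, coding: str) -> np.ndarray:
    if coding == "raw":
        return r.astype(float)
    if coding == "log2":
        return np.log2(r.astype(float))
    raise ValueError(f"unknown richness coding {coding!r}")


def extract_pair_frame(df: pd.DataFrame, aspect: str,
                       one_to_one: bool = False,
                       richness_coding: str = "raw") -> pd.DataFrame:
    """Pair skeleton as a plain DataFrame from a pot table.

    Used directly by the bootstrap, where resampled pot instances do not
    form a valid :class:`ExperimentalDesign`.
    """
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
    rows: list[dict] = []

    if aspect == "invariability":
        for (r, d, i), grp in df.groupby(["richness", "drought", "invasion"]):
            for a, b in combinations(grp.itertuples(index=False), 2):
                rows.append({"pot_a": a.pot_id, "pot_b": b.pot_id,
                             "richness": r, "drought": d, "invasion": i})
    elif aspect == "drought_resistance":
        for (r, i), grp in df.groupby(["richness", "invasion"]):
            ctrl = grp[grp["drought"] == 0]
            dist = grp[grp["drought"].isin((1, 2))]
            for a, b in product(ctrl.itertuples(index=False),
                                dist.itertuples(index=False)):
                if one_to_one and a.assemblage_id != b.assemblage_id:
                    continue
                rows.append({"pot_a": a.pot_id, "pot_b": b.pot_id,
                             "richness": r, "drought": b.drought, "invasion": i})
    else:  # invasion_resistance
        for (r, d), grp in df.groupby(["richness", "drought"]):
            ctrl = grp[grp["invasion"] == 0]
            dist = grp[grp["invasion"] == 1]
            for a, b in product(ctrl.itertuples(index=False),
                                dist.itertuples(index=False)):
                if one_to_one and a.assemblage_id != b.assemblage_id:
                    continue
                rows.append({"pot_a": a.pot_id, "pot_b": b.pot_id,
                             "richness": r, "drought": d})
    cols = ["pot_a", "pot_b", "richness", "drought"] + (
        ["invasion"] if aspect != "invasion_resistance" else [])
    obs = pd.DataFrame(rows, columns=cols)
    obs["richness"] = _richness_value(obs["richness"].values, richness_coding)
    obs["drought"] = obs["drought"].astype(float)
    if "invasion" in obs.columns:
        obs["invasion"] = obs["invasion"].astype(float)
    return obs


def extract_pairs(design: ExperimentalDesign, aspect: str,
                  one_to_one: bool = False,
                  richness_coding: str = "raw") -> PairDataset:
    """Build the pair skeleton (covariates only) for one stability aspect.

    ``one_to_one`` restricts cross-treatment pairs to pots sharing an
    assemblage (the strict one-to-one correspondence baseline used for the
    multivariate-vs-univariate comparison).  ``richness_coding`` is ``raw``
    (1, 2, 4, 8) or ``log2``.
    """
    obs = extract_pair_frame(design.pots, aspect, one_to_one=one_to_one,
                             richness_coding=richness_coding)
    return PairDataset(aspect, obs)


def attach_similarities(pairs: PairDataset,
                        matrices: dict[str, SimilarityMatrix]) -> PairDataset:
    """Attach the four similarity responses by symmetric matrix lookup.

    ``matrices`` maps matrix kind (``plant``, ``litter_fauna``,
    ``soil_fauna``, ``multifunctional``) to its :class:`SimilarityMatrix`.
    """
    obs = pairs.observations.copy()
    for response, kind in RESPONSE_KINDS.items():
        if kind not in matrices:
            raise KeyError(f"missing similarity matrix of kind {kind!r}")
        m = matrices[kind]
        ia = m.positions(obs["pot_a"].values)
        ib = m.positions(obs["pot_b"].values)
        obs[response] = m.values[ia, ib]
    return PairDataset(pairs.aspect, obs)
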