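"""Experimental design: pots, assemblages, and treatment structure.

The reference design is a pot experiment crossing plant richness (1, 2, 4
or 8 species drawn from a 16-species pool) with drought (none / moderate /
intensive, coded 0/1/2) and exotic-plant invasion (absent / present, coded
0/1).  A *complete set* contains one pot of each of the 45 distinct plant
assemblages (16 monocultures + 10 two-species + 10 four-species + 9
eight-species mixtures); one complete set is grown under each of the
3 x 2 = 6 treatment combinations, for 270 pots in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RICHNESS_LEVELS = (1, 2, 4, 8)
DROUGHT_LEVELS = (0, 1, 2)
INVASION_LEVELS = (0, 1)

#: distinct assemblages per richness level in the reference design
ASSEMBLAGES_PER_RICHNESS = {1: 16, 2: 10, 4: 10, 8: 9}

#: complete set -> (drought, invasion) in the reference design
SET_TREATMENTS = {
    "S1": (0, 0), "S2": (0, 1),
    "S3": (1, 0), "S4": (1, 1),
    "S5": (2, 0), "S6": (2, 1),
}

DESIGN_COLUMNS = ["pot_id", "assemblage_id", "set_id", "richness", "drought", "invasion"]


class DesignError(ValueError):
    """Raised when a design table violates its invariants."""


@dataclass
class ExperimentalDesign:
    """Pot-level treatment assignments plus the assemblage catalogue.

    Parameters
    ----------
    pots : pandas.DataFrame
        One row per pot with columns ``pot_id``, ``assemblage_id``,
        ``set_id``, ``richness``, ``drought``, ``invasion``.
    assemblage_catalog : dict, optional
        Mapping assemblage id -> tuple of member species names.  Only the
        synthetic generator and the one-to-one baseline mode depend on it.
    """

    pots: pd.DataFrame
    assemblage_catalog: dict[str, tuple[str, ...]] | None = field(default=None)

    def __post_init__(self) -> None:
        df = self.pots
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise DesignError(f"design table is missing columns: {missing}")
        df = df[DESIGN_COLUMNS].copy()
        for col, dom in (("richness", RICHNESS_LEVELS),
                         ("drought", DROUGHT_LEVELS),
                         ("invasion", INVASION_LEVELS)):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            bad = sorted(set(df[col]) - set(dom))
            if bad:
                raise DesignError(f"{col} outside domain {dom}: {bad}")
        if df["pot_id"].duplicated().any():
            dups = df.loc[df["pot_id"].duplicated(), "pot_id"].tolist()
            raise DesignError(f"duplicated pot_id: {dups}")
        if df.duplicated(subset=["assemblage_id", "set_id"]).any():
            raise DesignError("(assemblage_id, set_id) pairs must be unique")
        self.pots = df.reset_index(drop=True)
        if self.assemblage_catalog is not None:
            known = set(self.pots["assemblage_id"])
            extra = set(df["assemblage_id"]) - set(self.assemblage_catalog)
            if extra:
                raise DesignError(f"assemblages missing from catalog: {sorted(extra)}")
            for aid in known:
                n = len(self.assemblage_catalog[aid])
                r = int(df.loc[df["assemblage_id"] == aid, "richness"].iloc[0])
                if n != r:
                    raise DesignError(
                        f"assemblage {aid}: catalog lists {n} species, richness is {r}")

    @property
    def pot_ids(self) -> list[str]:
        return self.pots["pot_id"].tolist()

    @property
    def n_pots(self) -> int:
        return len(self.pots)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentalDesign):
            return NotImplemented
        return (
            self.pots.reset_index(drop=True).equals(other.pots.reset_index(drop=True))
            and self.assemblage_catalog == other.assemblage_catalog
        )


def _sample_assemblages(rng: np.random.Generator, species: list[str],
                        counts: dict[int, int]) -> dict[str, tuple[str, ...]]:
    """Seeded, distinct species mixtures for every assemblage."""
    catalog: dict[str, tuple[str, ...]] = {}
    idx = 1
    for r in sorted(counts):
        if r > len(species):
            raise DesignError(f"richness {r} exceeds the species pool "
                              f"({len(species)} species)")
        seen: set[tuple[str, ...]] = set()
        if r == 1:
            mixtures = [(s,) for s in species[:counts[1]]]
        else:
            mixtures = []
            while len(mixtures) < counts[r]:
                mix = tuple(sorted(rng.choice(species, size=r, replace=False)))
                if mix not in seen:
                    seen.add(mix)
                    mixtures.append(mix)
        for mix in mixtures:
            catalog[f"A{idx:02d}"] = mix
            idx += 1
    return catalog


def build_design(seed: int = 0, n_species_pool: int = 16,
                 assemblages_per_richness: dict[int, int] | None = None,
                 set_treatments: dict[str, tuple[int, int]] | None = None,
                 ) -> ExperimentalDesign:
    """Construct a complete-set design with seeded assemblage compositions.

    Every set contains one pot of each assemblage; each set sits in the
    (drought, invasion) cell given by ``set_treatments``.  Deterministic
    and idempotent for a fixed seed.
    """
    counts = dict(assemblages_per_richness or ASSEMBLAGES_PER_RICHNESS)
    treatments = dict(set_treatments or SET_TREATMENTS)
    rng = np.random.default_rng(seed)
    species = [f"sp{i:02d}" for i in range(1, n_species_pool + 1)]
    catalog = _sample_assemblages(rng, species, counts)
    rows = []
    for set_id, (drought, invasion) in treatments.items():
        for aid, mix in catalog.items():
            rows.append({
                "pot_id": f"{set_id}:{aid}",
                "assemblage_id": aid,
                "set_id": set_id,
                "richness": len(mix),
                "drought": drought,
                "invasion": invasion,
            })
    return ExperimentalDesign(pd.DataFrame(rows), assemblage_catalog=catalog)


def build_reference_design(seed: int = 0) -> ExperimentalDesign:
    """The canonical 270-pot design: 45 distinct assemblages (16/10/10/9 at
    richness 1/2/4/8) in each of six complete sets, one set per
    (drought, invasion) cell.  Species mixtures are sampled without
    replacement from the 16-species pool with the given seed — mixture
    identity only matters to the synthetic generator and the one-to-one
    baseline mode."""
    return build_design(seed=seed)


def design_cell_counts(design: ExperimentalDesign) -> pd.DataFrame:
    """Pots per (richness, drought, invasion) cell, long form."""
    return (design.pots
            .groupby(["richness", "drought", "invasion"])
            .size().rename("n_pots").reset_index())


def expected_pair_counts(design: ExperimentalDesign) -> dict[str, int]:
    """Closed-form pair counts per stability aspect for any design.

    invariability: sum over (drought, invasion) cells and richness levels of
    C(k, 2); drought resistance: sum over invasion levels, disturbed drought
    levels and richness of k0 * kd; invasion resistance: sum over drought
    levels and richness of k0 * k1.
    """
    df = design.pots
    inv = 0
    for (_, _), cell in df.groupby(["drought", "invasion"]):
        for _, grp in cell.groupby("richness"):
            k = len(grp)
            inv += k * (k - 1) // 2
    dro = 0
    for _, cell in df.groupby("invasion"):
        for _, grp in cell.groupby("richness"):
            k0 = int((grp["drought"] == 0).sum())
            for d in (1, 2):
                dro += k0 * int((grp["drought"] == d).sum())
    inva = 0
    for _, cell in df.groupby("drought"):
        for _, grp in cell.groupby("richness"):
            inva += int((grp["invasion"] == 0).sum()) * int((grp["invasion"] == 1).sum())
    return {"invariability": inv, "drought_resistance": dro, "invasion_resistance": inva}
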