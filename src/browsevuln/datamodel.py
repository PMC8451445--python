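"""Shared domain types for the browsing-vulnerability pipeline.

The study design these types encode: 22 cool-temperate deciduous-forest
sites grouped into four deer-establishment-year classes (deer present since
before 1978, 1979-2003, 2004-2011, 2012-2014), each site surveyed with 20
understory plots; browsing damage scored on 10 plant units per species and
site in four ordinal classes; and fecal samples profiled by trnL P6-loop
metabarcoding against a plant reference database.

Tables are thin, validated wrappers around :class:`pandas.DataFrame` so that
every downstream statistic operates on one canonical representation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EstablishmentClass",
    "CLASS_ORDER",
    "Site",
    "CoverageTable",
    "SpeciesTraits",
    "DamageRecord",
    "ReferenceDB",
    "ReadTable",
    "ALLOWED_COVER",
    "LIFE_FORMS",
    "ARCHITECTURES",
]

#: Permitted plot-level cover scores: trace cover is recorded as 1 %, cover
#: above 5 % on a 5 % grid.
ALLOWED_COVER = frozenset({1}) | frozenset(range(5, 101, 5))

LIFE_FORMS = ("annual/biennial", "perennial", "vine", "tree", "shrub")
ARCHITECTURES = ("prostrate", "erect", "rosette", "rosette_seasonal", "tussock")
WOODY = ("tree", "shrub")


class EstablishmentClass(enum.Enum):
    """Deer establishment-year class, ordered oldest to youngest presence."""

    Y1978 = 1
    Y2003 = 2
    Y2011 = 3
    Y2014 = 4

    @property
    def rank(self) -> int:
        """1 = deer established longest (before 1978), 4 = most recent."""
        return self.value

    @classmethod
    def parse(cls, value) -> "EstablishmentClass":
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper()
        if not key.startswith("Y"):
            key = "Y" + key
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown establishment class: {value!r}") from None


#: Classes in fixed oldest-to-youngest order; every 4-vector profile in the
#: pipeline follows this order.
CLASS_ORDER = tuple(EstablishmentClass)


@dataclass(frozen=True)
class Site:
    """One forest site with planar (projected, km) coordinates."""

    site_id: str
    establishment: EstablishmentClass
    surveyed_year: int
    x: float
    y: float
    region: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.x) or not np.isfinite(self.y):
            raise ValueError(f"site {self.site_id}: coordinates must be finite")


class CoverageTable:
    """Plot-level percent cover records: (site_id, plot_id, species_id, coverage).

    Invariants: coverage in the permitted score set, at most one record per
    (site, plot, species), plot ids within 1..20.
    """

    COLUMNS = ("site_id", "plot_id", "species_id", "coverage")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"coverage table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["site_id"] = df["site_id"].astype(str).str.strip()
        df["species_id"] = normalize_species(df["species_id"])
        df["plot_id"] = df["plot_id"].astype(int)
        df["coverage"] = df["coverage"].astype(int)

        bad = ~df["coverage"].isin(list(ALLOWED_COVER))
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"row {row}: coverage {df.loc[row, 'coverage']} not in "
                "{1, 5, 10, ..., 100}"
            )
        if (df["plot_id"] < 1).any() or (df["plot_id"] > 20).any():
            raise ValueError("plot_id must lie in 1..20")
        dup = df.duplicated(subset=["site_id", "plot_id", "species_id"])
        if dup.any():
            key = df.loc[df.index[dup][0], ["site_id", "plot_id", "species_id"]]
            raise ValueError(f"duplicate coverage record: {tuple(key)}")
        # canonical row order makes parsing order-independent
        self.df = df.sort_values(list(self.COLUMNS), kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CoverageTable) and self.df.equals(other.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species_id"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.df["site_id"].unique())

    def site_totals(self) -> pd.DataFrame:
        """Site x species matrix of cover summed over the 20 plots."""
        return (
            self.df.pivot_table(
                index="site_id",
                columns="species_id",
                values="coverage",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
            .sort_index(axis=1)
        )


@dataclass(frozen=True)
class SpeciesTraits:
    """Life form and (for forbs) architecture of one species.

    Architecture is None exactly for woody species, whose architecture
    category coincides with the life form.
    """

    species_id: str
    family: str
    life_form: str
    architecture: str | None = None

    def __post_init__(self):
        if self.life_form not in LIFE_FORMS:
            raise ValueError(f"unknown life form: {self.life_form!r}")
        woody = self.life_form in WOODY
        if woody and self.architecture is not None:
            raise ValueError(
                f"{self.species_id}: woody species carry no separate architecture"
            )
        if not woody and self.architecture is not None:
            if self.architecture not in ARCHITECTURES:
                raise ValueError(f"unknown architecture: {self.architecture!r}")


@dataclass(frozen=True)
class DamageRecord:
    """Counts of sampled plant units per browsing-damage class at one site.

    Classes: CL1 no damage, CL2 1-10 % of the plant damaged, CL3 11-50 %,
    CL4 51-100 %. N is the number of units examined (10 in the field design).
    """

    site_id: str
    species_id: str
    n_cl1: int
    n_cl2: int
    n_cl3: int
    n_cl4: int

    def __post_init__(self):
        counts = (self.n_cl1, self.n_cl2, self.n_cl3, self.n_cl4)
        if any(c < 0 for c in counts):
            raise ValueError("damage class counts must be non-negative")
        if self.N < 1:
            raise ValueError("a damage record needs at least one sampled unit")

    @property
    def N(self) -> int:
        return self.n_cl1 + self.n_cl2 + self.n_cl3 + self.n_cl4


class ReferenceDB:
    """trnL P6-loop reference database: one sequence per plant taxon.

    Taxa whose sequences are byte-identical cannot be told apart by the
    marker; they are linked into a merged ``taxon_group`` whose id is the
    '+'-joined sorted member list.
    """

    def __init__(self, entries: dict[str, str], families: dict[str, str] | None = None):
        if not entries:
            raise ValueError("reference database is empty")
        clean: dict[str, str] = {}
        for taxon, seq in entries.items():
            taxon = str(taxon).strip()
            seq = str(seq).strip().upper()
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"{taxon}: sequence must be non-empty A/C/G/T/N")
            if taxon in clean and clean[taxon] != seq:
                raise ValueError(f"duplicate taxon {taxon} with conflicting sequences")
            clean[taxon] = seq
        self.entries = clean
        self.families = dict(families or {})
        groups: dict[str, list[str]] = {}
        for taxon, seq in clean.items():
            groups.setdefault(seq, []).append(taxon)
        #: sequence -> merged group id (single taxon id when unique)
        self.group_of_sequence = {
            seq: "+".join(sorted(members)) for seq, members in groups.items()
        }
        #: group id -> member taxa
        self.taxon_groups = {
            gid: sorted(members)
            for seq, members in groups.items()
            for gid in [self.group_of_sequence[seq]]
        }

    def __len__(self) -> int:
        return len(self.entries)


class ReadTable:
    """Fecal-sample x plant-taxon read counts plus per-sample unassigned tally."""

    def __init__(
        self,
        counts: pd.DataFrame,
        sample_sites: dict[str, str] | None = None,
        unassigned: pd.DataFrame | None = None,
    ):
        counts = counts.copy()
        arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("read counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("read counts must be integers")
        self.counts = counts.astype(int).sort_index().sort_index(axis=1)
        self.sample_sites = dict(sample_sites or {})
        if unassigned is None:
            unassigned = pd.DataFrame(
                0,
                index=self.counts.index,
                columns=["no_match", "too_short", "low_frequency"],
            )
        self.unassigned = unassigned.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        """Total reads per sample, assigned plus unassigned."""
        return self.counts.sum(axis=1) + self.unassigned.sum(axis=1)


def normalize_species(values) -> pd.Series:
    """Trim and whitespace-collapse species names; matching is exact after this."""
    s = pd.Series(values, dtype="string").str.strip().str.replace(r"\s+", " ", regex=True)
    return s.astype(str)
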