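"""Synthetic browsing studies with planted vulnerability archetypes.

The generator emulates the field design end to end: 22 sites split 5/4/4/9
across the four deer-establishment classes, 20 understory plots per site
scored on the {1, 5, 10, ..., 100} cover grid, damage surveys of 10 plant
units per species and site, and 63 fecal samples whose taxon read counts
follow a Dirichlet-multinomial with class-dependent diet composition and
negative-binomial sequencing depth. Every species carries a planted
archetype:

===========  ==============================  =====================  ==================
archetype    coverage across classes          browsing damage        diet reads
===========  ==============================  =====================  ==================
A            declines with establishment age  high from the start    high at young sites
B            absent where deer oldest         high where present     high at young sites
C            declines with establishment age  grows with age         high at old sites
D            patchy (absent in one class)     grows with age         high at old sites
E            flat                             light                  selected, young-biased
F            flat                             moderate, flat         never detected
neutral      flat                             none                   never detected
===========  ==============================  =====================  ==================

The three ``*_effect`` knobs interpolate each archetype's class profile
toward its own mean: at 0 every profile is flat, producing an exact
permutation-null study; at the default 1 the planted contrasts are strong
enough for the full pipeline to recover the archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CLASS_ORDER,
    CoverageTable,
    DamageRecord,
    EstablishmentClass,
    ReadTable,
    ReferenceDB,
    Site,
)

__all__ = ["SimConfig", "GroundTruth", "SimDataset", "simulate", "fixture_small", "reads_fasta"]

ARCHETYPES = ("A", "B", "C", "D", "E", "F", "neutral")

# class profiles ordered (Y1978, Y2003, Y2011, Y2014) = oldest..youngest presence
_COVER_SHAPE = {
    "A": (0.12, 0.5, 0.8, 1.0),
    "B": (0.0, 1.0, 1.0, 1.0),
    "C": (0.15, 0.5, 0.75, 1.0),
    "D": (1.0, 0.0, 1.0, 1.0),
    "E": (1.0, 1.0, 1.0, 1.0),
    "F": (1.0, 1.0, 1.0, 1.0),
    "neutral": (1.0, 1.0, 1.0, 1.0),
}
# latent browsing intensity on the ordinal-logit scale
_DAMAGE_INTENSITY = {
    "A": (5.0, 4.0, 4.0, 4.0),
    "B": (4.0, 4.0, 4.0, 4.0),
    "C": (4.0, 2.5, 1.0, -1.0),
    "D": (3.0, 1.5, 1.0, -0.5),
    "E": (0.8, 0.8, 0.8, 0.8),
    "F": (2.0, 2.0, 2.0, 2.0),
    "neutral": (-30.0, -30.0, -30.0, -30.0),
}
# relative diet selection weight (zero = never in feces)
_DIET_WEIGHT = {
    "A": (0.5, 1.5, 2.0, 3.0),
    "B": (0.2, 2.0, 2.5, 3.0),
    "C": (3.0, 2.0, 1.0, 0.4),
    "D": (2.5, 1.5, 1.0, 0.4),
    "E": (0.8, 1.5, 2.0, 2.5),
    "F": (0.0, 0.0, 0.0, 0.0),
    "neutral": (0.0, 0.0, 0.0, 0.0),
}
# ordinal-logit cutpoints between CL1|CL2, CL2|CL3, CL3|CL4
_DAMAGE_CUTPOINTS = (1.0, 3.0, 5.0)

_COVER_GRID = np.array([1] + list(range(5, 101, 5)))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters; defaults mirror the emulated field design."""

    n_sites_per_class: tuple[int, int, int, int] = (5, 4, 4, 9)
    n_plots: int = 20
    archetype_counts: dict = field(
        default_factory=lambda: {
            "A": 10, "B": 8, "C": 10, "D": 8, "E": 6, "F": 6, "neutral": 12
        }
    )
    n_fecal_samples: int = 63
    damage_units: int = 10
    read_depth_mean: float = 6700.0
    read_depth_dispersion: float = 2.0
    dirichlet_concentration: float = 40.0
    plot_occupancy: float = 0.55
    base_cover: float = 35.0
    coverage_effect: float = 1.0
    damage_effect: float = 1.0
    diet_effect: float = 1.0
    short_read_rate: float = 0.01

    def validate(self) -> None:
        if sum(self.archetype_counts.values()) < 1:
            raise ValueError("at least one species required")
        if set(self.archetype_counts) - set(ARCHETYPES):
            raise ValueError(f"unknown archetypes: {set(self.archetype_counts) - set(ARCHETYPES)}")
        if any(n < 1 for n in self.n_sites_per_class):
            raise ValueError("every establishment class needs at least one site")
        for p in (self.plot_occupancy, self.short_read_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    archetype: dict[str, str]  # species -> planted archetype
    cover_mean: pd.DataFrame  # species x class expected summed site cover
    diet_proportion: pd.DataFrame  # taxon x class true diet share
    damage_intensity: pd.DataFrame  # species x class latent intensity


@dataclass
class SimDataset:
    config: SimConfig
    seed: int
    sites: dict[str, Site]
    coverage: CoverageTable
    damage: list[DamageRecord]
    read_table: ReadTable
    reference_db: ReferenceDB
    truth: GroundTruth
    short_reads: pd.Series  # per-sample count of planted too-short reads


def _effectify(shape: np.ndarray, effect: float) -> np.ndarray:
    """Interpolate a class profile toward its mean: effect 0 = flat."""
    m = shape.mean()
    return np.clip(m + effect * (shape - m), 0.0, None)


def _snap_cover(values: np.ndarray) -> np.ndarray:
    """Map continuous percent cover onto the {1, 5, ..., 100} field grid."""
    idx = np.abs(values[:, None] - _COVER_GRID[None, :]).argmin(axis=1)
    snapped = _COVER_GRID[idx]
    snapped = np.where(values < 3, 1, snapped)
    return snapped


def _unique_sequences(n: int, rng: np.random.Generator) -> list[str]:
    """n distinct P6-loop-like sequences, lengths 40-90."""
    seqs: set[str] = set()
    out = []
    while len(out) < n:
        length = int(rng.integers(40, 91))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


def simulate(config: SimConfig, seed: int) -> SimDataset:
    """Draw one full synthetic study; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(seed)

    # --- sites: class-longitude gradient on a 300 x 200 km box
    sites: dict[str, Site] = {}
    for ci, cls in enumerate(CLASS_ORDER):
        for j in range(config.n_sites_per_class[ci]):
            sid = f"{cls.name}_s{j + 1}"
            x = 20 + 260 * ci / 3 + rng.normal(0, 25)
            y = rng.uniform(0, 200)
            sites[sid] = Site(sid, cls, int(rng.choice([2016, 2017])), float(x), float(y))
    site_ids = sorted(sites)

    # --- species roster
    species = []
    archetype = {}
    for arch in ARCHETYPES:
        for i in range(config.archetype_counts.get(arch, 0)):
            sp = f"{arch}_sp{i + 1:02d}"
            species.append(sp)
            archetype[sp] = arch
    species.sort()

    class_names = [c.name for c in CLASS_ORDER]
    occ = {}
    cover_mu = {}
    dmg_int = {}
    diet_w = {}
    for sp in species:
        arch = archetype[sp]
        shape = _effectify(np.array(_COVER_SHAPE[arch]), config.coverage_effect)
        occ[sp] = config.plot_occupancy * shape
        cover_mu[sp] = config.base_cover * (0.4 + 0.6 * shape)
        dmg = np.array(_DAMAGE_INTENSITY[arch])
        dmg_int[sp] = dmg.mean() + config.damage_effect * (dmg - dmg.mean())
        w = np.array(_DIET_WEIGHT[arch])
        diet_w[sp] = _effectify(w, config.diet_effect) if w.any() else w

    # --- plot-level coverage
    rows = []
    present_at_site: dict[str, set[str]] = {s: set() for s in site_ids}
    for sid in site_ids:
        ci = sites[sid].establishment.rank - 1
        for sp in species:
            p = occ[sp][ci]
            if p <= 0:
                continue
            hits = np.flatnonzero(rng.random(config.n_plots) < p)
            if hits.size == 0:
                continue
            raw = rng.gamma(2.0, cover_mu[sp][ci] / 2.0, size=hits.size)
            cov = _snap_cover(np.clip(raw, 0.5, 100))
            for plot, c in zip(hits + 1, cov):
                rows.append((sid, int(plot), sp, int(c)))
            present_at_site[sid].add(sp)
    coverage = CoverageTable(
        pd.DataFrame(rows, columns=["site_id", "plot_id", "species_id", "coverage"])
    )

    # --- damage survey: 10 units per species present at a site
    cut = np.array(_DAMAGE_CUTPOINTS)
    damage: list[DamageRecord] = []
    for sid in site_ids:
        ci = sites[sid].establishment.rank - 1
        for sp in sorted(present_at_site[sid]):
            lam = dmg_int[sp][ci]
            p_ge = 1.0 / (1.0 + np.exp(-(lam - cut)))  # P(class > j)
            probs = np.diff(np.concatenate([[1.0], p_ge, [0.0]])) * -1
            counts = rng.multinomial(config.damage_units, probs)
            damage.append(DamageRecord(sid, sp, *map(int, counts)))

    # --- reference database: one unique P6-like sequence per species
    seqs = _unique_sequences(len(species), rng)
    reference_db = ReferenceDB(dict(zip(species, seqs)))

    # --- fecal samples: Dirichlet-multinomial diet, NB depth
    diet_mat = np.array([diet_w[sp] for sp in species])  # species x class
    detectable = diet_mat.sum(axis=1) > 0
    taxa = [sp for sp, d in zip(species, detectable) if d]
    diet_mat = diet_mat[detectable]
    class_prop = diet_mat / diet_mat.sum(axis=0, keepdims=True)

    sample_sites = {}
    counts = np.zeros((config.n_fecal_samples, len(taxa)), dtype=int)
    short_counts = np.zeros(config.n_fecal_samples, dtype=int)
    nb_n = config.read_depth_dispersion
    nb_p = nb_n / (nb_n + config.read_depth_mean)
    sample_names = []
    for i in range(config.n_fecal_samples):
        sid = site_ids[i % len(site_ids)]
        name = f"F{i + 1:03d}"
        sample_names.append(name)
        sample_sites[name] = sid
        ci = sites[sid].establishment.rank - 1
        depth = int(rng.negative_binomial(nb_n, nb_p)) + 1
        n_short = int(rng.binomial(depth, config.short_read_rate))
        alpha = config.dirichlet_concentration * class_prop[:, ci]
        p = rng.dirichlet(np.clip(alpha, 1e-6, None))
        counts[i] = rng.multinomial(depth - n_short, p)
        short_counts[i] = n_short
    counts_df = pd.DataFrame(counts, index=sample_names, columns=taxa)
    counts_df = counts_df.loc[:, counts_df.sum(axis=0) > 0]
    read_table = ReadTable(counts_df, sample_sites=sample_sites)

    truth = GroundTruth(
        archetype=archetype,
        cover_mean=pd.DataFrame(
            {sp: config.n_plots * occ[sp] * cover_mu[sp] for sp in species},
            index=class_names,
        ).T,
        diet_proportion=pd.DataFrame(class_prop, index=taxa, columns=class_names),
        damage_intensity=pd.DataFrame(
            {sp: dmg_int[sp] for sp in species}, index=class_names
        ).T,
    )
    return SimDataset(
        config=config,
        seed=seed,
        sites=sites,
        coverage=coverage,
        damage=damage,
        read_table=read_table,
        reference_db=reference_db,
        truth=truth,
        short_reads=pd.Series(short_counts, index=sample_names),
    )


def reads_fasta(dataset: SimDataset, seed: int | None = None) -> dict[str, list[str]]:
    """Materialise each sample's reads as sequence strings.

    Assigned reads are exact copies of the taxon's reference sequence;
    planted short reads are 10-mers (below any sensible length filter). The
    per-sample read count equals the planted depth, and read order is
    shuffled so downstream order-invariance is exercised.
    """
    rng = np.random.default_rng(dataset.seed if seed is None else seed)
    out: dict[str, list[str]] = {}
    entries = dataset.reference_db.entries
    for sample in dataset.read_table.samples:
        reads: list[str] = []
        for taxon, n in dataset.read_table.counts.loc[sample].items():
            if n > 0:
                reads.extend([entries[taxon]] * int(n))
        for _ in range(int(dataset.short_reads[sample])):
            reads.append("".join(rng.choice(list("ACGT"), size=10)))
        rng.shuffle(reads)
        out[sample] = reads
    return out


def fixture_small(seed: int = 7) -> SimDataset:
    """Miniature study for unit tests and docs: 4 sites (one per class),
    12 species covering every archetype, 8 fecal samples, shallow reads."""
    config = SimConfig(
        n_sites_per_class=(1, 1, 1, 1),
        n_plots=10,
        archetype_counts={"A": 2, "B": 2, "C": 2, "D": 2, "E": 1, "F": 1, "neutral": 2},
        n_fecal_samples=8,
        read_depth_mean=300.0,
        short_read_rate=0.02,
    )
    return simulate(config, seed)
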