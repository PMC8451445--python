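"""Readers and writers for the pipeline's external formats.

Everything tabular is UTF-8 CSV with a mandatory header row; sequences are
FASTA (optionally gzipped). FASTA headers for the reference database follow
the convention ``>taxon_id [family]`` — the first whitespace-delimited token
is the taxon id, an optional second token the family.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    CoverageTable,
    DamageRecord,
    EstablishmentClass,
    ReadTable,
    ReferenceDB,
    Site,
    SpeciesTraits,
    normalize_species,
)

__all__ = [
    "read_coverage_table",
    "read_sites",
    "read_traits",
    "read_damage_records",
    "read_reference_db",
    "read_fasta_sequences",
    "write_matrix",
    "read_matrix",
    "read_read_table",
    "write_read_table",
]


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage_table(path) -> CoverageTable:
    """Read plot-level cover records; raises on any malformed row."""
    df = pd.read_csv(path)
    df = df.rename(columns={"site": "site_id", "plot": "plot_id", "species": "species_id"})
    return CoverageTable(df)


def read_sites(path) -> dict[str, Site]:
    df = pd.read_csv(path)
    sites = {}
    for _, row in df.iterrows():
        site = Site(
            site_id=str(row["site_id"]).strip(),
            establishment=EstablishmentClass.parse(row["establishment"]),
            surveyed_year=int(row["surveyed_year"]),
            x=float(row["x"]),
            y=float(row["y"]),
            region=str(row["region"]) if "region" in df.columns and pd.notna(row.get("region")) else None,
        )
        if site.site_id in sites:
            raise ValueError(f"duplicate site_id {site.site_id}")
        sites[site.site_id] = site
    return sites


def read_traits(path) -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path)
    df["species_id"] = normalize_species(df["species_id"])
    traits = {}
    for _, row in df.iterrows():
        arch = row.get("architecture")
        traits[row["species_id"]] = SpeciesTraits(
            species_id=row["species_id"],
            family=str(row.get("family", "")),
            life_form=str(row["life_form"]),
            architecture=None if pd.isna(arch) or arch == "" else str(arch),
        )
    return traits


def read_damage_records(path) -> list[DamageRecord]:
    df = pd.read_csv(path)
    df["species_id"] = normalize_species(df["species_id"])
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                DamageRecord(
                    site_id=str(row["site_id"]).strip(),
                    species_id=row["species_id"],
                    n_cl1=int(row["n_cl1"]),
                    n_cl2=int(row["n_cl2"]),
                    n_cl3=int(row["n_cl3"]),
                    n_cl4=int(row["n_cl4"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"damage table row {i}: {exc}") from exc
    return records


def read_reference_db(path) -> ReferenceDB:
    """Parse a P6-loop reference FASTA into a deduplicated database."""
    entries: dict[str, str] = {}
    families: dict[str, str] = {}
    with _open_maybe_gz(Path(path)) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            parts = rec.description.split()
            taxon = parts[0]
            seq = str(rec.seq).upper()
            if taxon in entries and entries[taxon] != seq:
                raise ValueError(
                    f"duplicate taxon {taxon} with conflicting sequences"
                )
            entries[taxon] = seq
            if len(parts) > 1:
                families[taxon] = parts[1]
    if not entries:
        raise ValueError(f"empty reference FASTA: {path}")
    return ReferenceDB(entries, families)


def read_fasta_sequences(path) -> tuple[list[str], list[str]]:
    """Return (read ids, sequences) from a FASTA / FASTA.gz file."""
    ids, seqs = [], []
    with _open_maybe_gz(Path(path)) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
    return ids, seqs


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labelled matrix as CSV; reals keep 12 significant digits."""
    if matrix.size == 0:
        raise ValueError("refusing to write an empty matrix")
    matrix.to_csv(path, float_format="%.12g", index_label="id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_read_table(table: ReadTable, counts_path, unassigned_path=None) -> None:
    write_matrix(table.counts, counts_path)
    if unassigned_path is not None:
        write_matrix(table.unassigned, unassigned_path)


def read_read_table(counts_path, sites_of_samples=None, unassigned_path=None) -> ReadTable:
    counts = read_matrix(counts_path)
    unassigned = read_matrix(unassigned_path) if unassigned_path else None
    return ReadTable(counts, sample_sites=sites_of_samples, unassigned=unassigned)
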