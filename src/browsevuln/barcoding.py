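"""Assignment of fecal trnL P6-loop amplicon reads to plant taxa.

The P6 loop is short (mean read length around 75 bp here), so assignment is
by exact sequence identity against the reference database: a read counts
toward a taxon iff it equals that taxon's reference sequence byte for byte.
Taxa sharing an identical P6 sequence are indistinguishable and receive one
merged taxon-group column. Reads that match nothing are tallied per sample
under one of three reasons: ``no_match`` (no reference sequence equals the
read, or the read contains non-nucleotide characters), ``too_short`` (below
``min_len``), or ``low_frequency`` (the matched taxon's within-sample
proportion fell below ``min_prop`` and its reads were discarded).

Every input read lands in exactly one bucket, so per sample
``assigned + unassigned == total``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ReadTable, ReferenceDB

__all__ = ["AssignmentResult", "dereplicate_reads", "assign_reads", "proportions", "trim_fixed"]

log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass
class AssignmentResult:
    table: ReadTable

    @property
    def counts(self) -> pd.DataFrame:
        return self.table.counts

    @property
    def unassigned(self) -> pd.DataFrame:
        return self.table.unassigned

    def totals(self) -> pd.Series:
        return self.table.totals()


def dereplicate_reads(reads) -> list[tuple[str, int]]:
    """Collapse reads to (unique sequence, multiplicity) pairs.

    Pairs are sorted by descending multiplicity, ties broken
    lexicographically, so output is independent of input order.
    """
    counter = Counter(str(r).strip().upper() for r in reads)
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


def trim_fixed(seq: str, prefix: str = "", suffix: str = "") -> str:
    """Optional fixed primer trimming; off (empty affixes) by default."""
    if prefix and seq.startswith(prefix):
        seq = seq[len(prefix):]
    if suffix and seq.endswith(suffix):
        seq = seq[: -len(suffix)]
    return seq


def assign_reads(
    reads_by_sample: dict[str, list[str]],
    db: ReferenceDB,
    min_len: int = 20,
    min_prop: float = 0.001,
    sample_sites: dict[str, str] | None = None,
) -> AssignmentResult:
    """Assign each sample's reads to taxon groups by exact match.

    ``min_prop`` acts within a sample: any taxon group whose share of the
    sample's matched reads is below it has those reads moved to the
    ``low_frequency`` bucket. Raising ``min_prop`` therefore never increases
    a count. The result is deterministic and invariant to read order.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not (0 <= min_prop < 1):
        raise ValueError("min_prop must lie in [0, 1)")

    lookup = db.group_of_sequence
    groups = sorted(db.taxon_groups)
    counts = pd.DataFrame(0, index=sorted(reads_by_sample), columns=groups)
    unassigned = pd.DataFrame(
        0, index=counts.index, columns=["no_match", "too_short", "low_frequency"]
    )

    for sample, reads in reads_by_sample.items():
        for seq, mult in dereplicate_reads(reads):
            if len(seq) < min_len:
                unassigned.loc[sample, "too_short"] += mult
            elif set(seq) - _NUCLEOTIDES:
                unassigned.loc[sample, "no_match"] += mult
            elif seq in lookup:
                counts.loc[sample, lookup[seq]] += mult
            else:
                unassigned.loc[sample, "no_match"] += mult
        matched = counts.loc[sample].sum()
        if matched > 0 and min_prop > 0:
            low = counts.loc[sample] / matched < min_prop
            low &= counts.loc[sample] > 0
            moved = int(counts.loc[sample, low].sum())
            counts.loc[sample, low] = 0
            unassigned.loc[sample, "low_frequency"] += moved
        if counts.loc[sample].sum() == 0 and len(reads) > 0:
            log.warning("sample %s: no reads assigned to any taxon", sample)

    return AssignmentResult(ReadTable(counts, sample_sites=sample_sites, unassigned=unassigned))


def proportions(table: ReadTable) -> pd.DataFrame:
    """Per-sample read proportions: each taxon's reads over the sample's
    assigned total. Samples with zero assigned reads are dropped with a
    warning rather than producing NaN rows."""
    totals = table.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.warning(
            "dropping %d sample(s) with zero assigned reads: %s",
            int(zero.sum()),
            list(table.counts.index[zero]),
        )
    kept = table.counts.loc[~zero]
    return kept.div(kept.sum(axis=1), axis=0)
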