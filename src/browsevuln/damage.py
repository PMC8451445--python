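"""Mean damage grade (MDG) scoring of browsing damage.

Field crews classify each of N sampled plant units (ramets for forbs,
current-year shoots for woody plants) into four ordinal damage classes:
CL1 no damage, CL2 1-10 % of the plant browsed, CL3 11-50 %, CL4 51-100 %.
The per-species, per-site score is the weighted mean

    MDG = (0*CL1 + 5*CL2 + 30*CL3 + 75*CL4) / N

which ranges from 0 (untouched) to 75 (every unit more than half browsed).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .datamodel import CoverageTable, DamageRecord, EstablishmentClass, Site

__all__ = ["MDG_WEIGHTS", "mdg", "mdg_matrix", "g4_species"]

MDG_WEIGHTS = (0.0, 5.0, 30.0, 75.0)


def mdg(record: DamageRecord) -> float:
    """Mean damage grade of one species x site record, in [0, 75]."""
    counts = (record.n_cl1, record.n_cl2, record.n_cl3, record.n_cl4)
    return float(sum(w * c for w, c in zip(MDG_WEIGHTS, counts)) / record.N)


def mdg_matrix(records: Iterable[DamageRecord]) -> pd.DataFrame:
    """Species x site MDG matrix; unsurveyed pairs stay NaN, never zero.

    A zero means ten examined units with no damage; a missing cell means the
    species was not sampled at that site — the distinction matters for every
    mean taken downstream.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    for rec in records:
        key = (rec.species_id, rec.site_id)
        if key in seen:
            raise ValueError(f"duplicate damage record for species/site {key}")
        seen.add(key)
        rows.append({"species_id": rec.species_id, "site_id": rec.site_id, "mdg": mdg(rec)})
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    return (
        df.pivot(index="species_id", columns="site_id", values="mdg")
        .sort_index()
        .sort_index(axis=1)
    )


def g4_species(
    coverage: CoverageTable,
    mdg_mat: pd.DataFrame,
    sites: dict[str, Site],
    strict: bool = False,
) -> list[str]:
    """Species absent from every oldest-establishment (Y1978) site's
    vegetation plots yet browsed at younger-establishment sites.

    These species plausibly disappeared from the long-established sites
    because of browsing. ``strict=False`` (default) requires browsing
    evidence (MDG > 0) in at least one site of at least one other class;
    ``strict=True`` demands it in every one of the three other classes.
    """
    old_sites = {s for s, site in sites.items() if site.establishment is EstablishmentClass.Y1978}
    other_classes = [c for c in EstablishmentClass if c is not EstablishmentClass.Y1978]
    sites_of_class = {
        c: {s for s, site in sites.items() if site.establishment is c} for c in other_classes
    }

    present_in_old = set(
        coverage.df.loc[coverage.df["site_id"].isin(old_sites), "species_id"].unique()
    )

    out = []
    if mdg_mat.empty:
        return out
    for species in mdg_mat.index:
        if species in present_in_old:
            continue
        row = mdg_mat.loc[species]
        browsed_classes = [
            c
            for c in other_classes
            if any(row.get(s, np.nan) > 0 for s in sites_of_class[c])
        ]
        ok = len(browsed_classes) == len(other_classes) if strict else len(browsed_classes) >= 1
        if ok:
            out.append(species)
    return sorted(out)
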