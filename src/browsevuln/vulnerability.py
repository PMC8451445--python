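"""Integration of the three cluster analyses into vulnerability groups A-F.

The three evidence streams — understory coverage profiles, browsing-damage
(MDG) profiles, and fecal-DNA read-proportion profiles — are each clustered
separately. Cluster indices are arbitrary, so each cluster is first given a
*semantic* label read off its centroid shape (profiles ordered oldest to
youngest deer establishment, Y1978..Y2014):

* coverage cluster: ``decline`` iff the centroid's Y1978 value is the
  minimum of the 4-vector and clearly below its peak (cover lost where
  deer have been longest), otherwise ``no_decline``;
* damage cluster: ``early`` if damage is already high at the youngest
  establishment class (centroid value there at least half the peak),
  ``gradual`` if damage peaks at Y1978 and is low at Y2014, else ``other``;
* diet cluster: ``recent`` if read share is clearly higher at the youngest
  class than at Y1978, ``old`` for the reverse, else ``other``.

A species is *early-browsed* when its damage cluster is early, it belongs
to the G4 list (absent from Y1978 sites yet browsed elsewhere), or its diet
cluster is recent; any other species with browsing or diet evidence is
*late-browsed*. The editable rule table then maps (coverage evidence,
timing, evidence-stream presence) to groups: A early-browsed + coverage
decline, B early-browsed + coverage unknown, C late-browsed + decline,
D late-browsed + unknown, E/F coverage unaffected (E with diet evidence,
F damage-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusteringOutcome

__all__ = [
    "VulnerabilityAssignment",
    "load_rule_table",
    "coverage_semantics",
    "damage_semantics",
    "diet_semantics",
    "classify",
    "detection_overlap",
]

GROUPS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class VulnerabilityAssignment:
    species_id: str
    group: str  # A..F or "unclassified"
    coverage_evidence: str  # decline | no_decline | unknown
    mdg_evidence: str  # early | gradual | other | g4 | absent
    dna_evidence: str  # recent | old | other | absent
    timing: str  # early | late | none
    detected_in_both: bool
    rule_id: str


def load_rule_table(path=None) -> list[dict]:
    """Load the A-F integration rules (default: the packaged rule table)."""
    if path is None:
        text = resources.files("browsevuln.data").joinpath("rules_default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rules = yaml.safe_load(text)["rules"]
    for rule in rules:
        if not {"id", "when", "group"} <= set(rule):
            raise ValueError(f"rule missing id/when/group: {rule}")
    return rules


# ---------------------------------------------------------------------------
# centroid semantics


def _normalized(centroid: np.ndarray) -> np.ndarray | None:
    c = np.asarray(centroid, dtype=float)
    m = c.max()
    if m <= 0:
        return None
    return c / m


def coverage_semantics(centroid, margin: float = 0.75) -> str:
    """A cluster shows coverage decline when its centroid's Y1978 value is
    the minimum of the 4-vector and clearly below the peak (at most
    ``margin`` of it); near-flat centroids whose argmin falls on Y1978 by
    noise alone are not declines."""
    c = np.asarray(centroid, dtype=float)
    if c.max() <= 0 or np.allclose(c, c[0]):
        return "no_decline"
    if c[0] == c.min() and c[0] <= margin * c.max():
        return "decline"
    return "no_decline"


def damage_semantics(centroid) -> str:
    c = _normalized(centroid)
    if c is None:
        return "other"
    if c[3] >= 0.5:
        return "early"
    if int(np.argmax(c)) == 0:
        return "gradual"
    return "other"


def diet_semantics(centroid) -> str:
    c = _normalized(centroid)
    if c is None:
        return "other"
    if c[3] - c[0] >= 0.25:
        return "recent"
    if c[0] - c[3] >= 0.25:
        return "old"
    return "other"


def _semantic_map(outcome: ClusteringOutcome | None, kind: str) -> dict[str, str]:
    """species -> semantic label, from that species' cluster centroid."""
    if outcome is None:
        return {}
    fn = {"coverage": coverage_semantics, "mdg": damage_semantics, "reads": diet_semantics}[kind]
    # centroids on the scaled axes carry the shape; semantics read off them
    sem_of_cluster = {
        cluster + 1: fn(outcome.centers[cluster]) for cluster in range(len(outcome.centers))
    }
    return {sp: sem_of_cluster[int(lab)] for sp, lab in outcome.labels.items()}


# ---------------------------------------------------------------------------
# classification


def classify(
    coverage_outcome: ClusteringOutcome | None,
    mdg_outcome: ClusteringOutcome | None,
    dna_outcome: ClusteringOutcome | None,
    g4_list=(),
    rule_table: list[dict] | None = None,
    species: list[str] | None = None,
) -> list[VulnerabilityAssignment]:
    """Assign every species to one vulnerability group.

    The species universe defaults to everything appearing in the damage
    stream (MDG clustering or G4 list) or the DNA stream, mirroring the
    integration over taxa included in either analysis; pass ``species`` to
    classify an explicit list instead. Each assignment records the rule
    that fired; species matching no rule come back ``unclassified``.
    """
    rules = rule_table if rule_table is not None else load_rule_table()
    cov_sem = _semantic_map(coverage_outcome, "coverage")
    mdg_sem = _semantic_map(mdg_outcome, "mdg")
    dna_sem = _semantic_map(dna_outcome, "reads")
    g4 = set(g4_list)

    if species is None:
        universe = sorted(set(mdg_sem) | g4 | set(dna_sem))
    else:
        universe = sorted(set(species))

    out = []
    for sp in universe:
        in_damage = sp in mdg_sem or sp in g4
        in_dna = sp in dna_sem
        mdg_ev = "g4" if sp in g4 else mdg_sem.get(sp, "absent")
        dna_ev = dna_sem.get(sp, "absent")
        cov_ev = cov_sem.get(sp, "unknown")

        if mdg_ev in ("early", "g4") or dna_ev == "recent":
            timing = "early"
        elif in_damage or in_dna:
            timing = "late"
        else:
            timing = "none"

        evidence = {
            "coverage": cov_ev,
            "timing": timing,
            "has_damage": in_damage,
            "has_dna": in_dna,
        }
        group, rule_id = "unclassified", "no-rule"
        for rule in rules:
            if all(evidence[f] in accepted for f, accepted in rule["when"].items()):
                group, rule_id = rule["group"], rule["id"]
                break
        out.append(
            VulnerabilityAssignment(
                species_id=sp,
                group=group,
                coverage_evidence=cov_ev,
                mdg_evidence=mdg_ev,
                dna_evidence=dna_ev,
                timing=timing,
                detected_in_both=in_damage and in_dna,
                rule_id=rule_id,
            )
        )
    return out


def assignments_frame(assignments: list[VulnerabilityAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in assignments]).set_index("species_id")


def detection_overlap(
    damage_species, dna_species, assignments: list[VulnerabilityAssignment] | None = None
) -> pd.DataFrame:
    """Flag species detected in both the damage survey and the fecal DNA.

    With ``assignments`` given, the result also carries each species'
    vulnerability group so overlap can be summarised per group.
    """
    damage_species, dna_species = set(damage_species), set(dna_species)
    rows = []
    group_of = {a.species_id: a.group for a in assignments} if assignments else {}
    for sp in sorted(damage_species | dna_species):
        rows.append(
            {
                "species_id": sp,
                "in_damage": sp in damage_species,
                "in_dna": sp in dna_species,
                "both": sp in damage_species and sp in dna_species,
                "group": group_of.get(sp, ""),
            }
        )
    return pd.DataFrame(rows).set_index("species_id")
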