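"""Membrane-composition indexes derived from a fatty-acid profile.

All indexes are linear functionals of the mol% vector except the SFA/UFA
ratio, so group means of per-subject indexes equal indexes of mean profiles
for the linear ones. Definitions:

* ACL, average chain length: mol%-weighted mean carbon number, grouping by
  chain length only, irrespective of unsaturation.
* Class totals: SFA, UFA, MUFA, PUFA and the omega subsets PUFAn-3/PUFAn-6.
* DBI, double bond index: weights 1..6 on mono- through hexaenoic classes —
  double bonds per 100 acyl chains.
* PI, peroxidizability index: empirical relative peroxidation propensities,
  weights 0.025/1/2/4/6/8 on mono- through hexaenoic classes. Monoenes are
  nearly peroxidation-resistant, hence the near-zero weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

from .fa_model import PANEL, Cohort, CompositionProfile, FattyAcid, classify

__all__ = [
    "IndexSet",
    "INDEX_NAMES",
    "PI_WEIGHTS",
    "compute_acl",
    "compute_class_totals",
    "compute_dbi",
    "compute_pi",
    "compute_index_set",
    "cohort_indexes",
]

#: PI weight per double-bond count (DBI weight is the count itself).
PI_WEIGHTS: dict[int, float] = {1: 0.025, 2: 1.0, 3: 2.0, 4: 4.0, 5: 6.0, 6: 8.0}


@dataclass(frozen=True)
class IndexSet:
    """The derived indexes for one profile; class totals in mol%."""

    ACL: float
    SFA: float
    UFA: float
    MUFA: float
    PUFA: float
    PUFAn3: float
    PUFAn6: float
    DBI: float
    PI: float
    SFA_UFA: float  # NaN when UFA == 0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


INDEX_NAMES: tuple[str, ...] = tuple(f.name for f in fields(IndexSet))


def _panel_values(profile: CompositionProfile,
                  panel: tuple[FattyAcid, ...]) -> list[tuple[FattyAcid, float]]:
    return [(fa, profile.get(fa.canonical_name)) for fa in panel]


def compute_acl(profile: CompositionProfile,
                panel: tuple[FattyAcid, ...] = PANEL) -> float:
    """Average chain length in carbon atoms per chain."""
    return sum(fa.carbons * v for fa, v in _panel_values(profile, panel)) / 100.0


def compute_dbi(profile: CompositionProfile,
                panel: tuple[FattyAcid, ...] = PANEL) -> float:
    """Double bond index: Σ double_bonds × mol%, over unsaturated species."""
    return sum(fa.double_bonds * v for fa, v in _panel_values(profile, panel))


def compute_pi(profile: CompositionProfile,
               panel: tuple[FattyAcid, ...] = PANEL) -> float:
    """Peroxidizability index with weights 0.025/1/2/4/6/8 for 1-6 double bonds."""
    return sum(PI_WEIGHTS.get(fa.double_bonds, 0.0) * v
               for fa, v in _panel_values(profile, panel))


def compute_class_totals(profile: CompositionProfile,
                         panel: tuple[FattyAcid, ...] = PANEL
                         ) -> dict[str, float]:
    """Mol% totals by saturation class plus the SFA/UFA ratio.

    ``SFA_UFA`` is NaN (undefined) when UFA is zero.
    """
    sfa = mufa = pufa = n3 = n6 = 0.0
    for fa, v in _panel_values(profile, panel):
        cls = classify(fa)
        if cls == "SFA":
            sfa += v
        elif cls == "MUFA":
            mufa += v
        else:
            pufa += v
            if fa.series == "n-3":
                n3 += v
            elif fa.series == "n-6":
                n6 += v
    ufa = mufa + pufa
    ratio = sfa / ufa if ufa > 0 else math.nan
    return {"SFA": sfa, "UFA": ufa, "MUFA": mufa, "PUFA": pufa,
            "PUFAn3": n3, "PUFAn6": n6, "SFA_UFA": ratio}


def compute_index_set(profile: CompositionProfile,
                      panel: tuple[FattyAcid, ...] = PANEL) -> IndexSet:
    totals = compute_class_totals(profile, panel)
    return IndexSet(
        ACL=compute_acl(profile, panel),
        DBI=compute_dbi(profile, panel),
        PI=compute_pi(profile, panel),
        **totals,
    )


def cohort_indexes(cohort: Cohort) -> pd.DataFrame:
    """Tidy table of per-subject indexes: one row per subject x region."""
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "subject_id": p.meta.subject_id,
            "region": p.meta.region,
            "age": p.meta.age,
        }
        row.update(compute_index_set(p, cohort.panel).as_dict())
        rows.append(row)
    return pd.DataFrame(rows,
                        columns=["subject_id", "region", "age", *INDEX_NAMES])


def index_from_name(name: str):
    """Resolve an index name to its single-profile computation (for the CLI)."""
    if name not in INDEX_NAMES:
        raise KeyError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
    return lambda profile: getattr(compute_index_set(profile), name)
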