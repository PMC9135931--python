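"""Surrogate desaturase, elongase and peroxisomal beta-oxidation activities.

Each activity is estimated as the mol% ratio of a biosynthetic product to
its immediate substrate in the same profile (e.g. delta-9 desaturase on the
n-9 branch as 18:1n-9 / 18:0). These are composition-derived indices, not
measured enzymatic rates. Because both numerator and denominator share the
compositional closure factor, the ratios are invariant to renormalization.

The peroxisomal beta-oxidation surrogate (PbOx = 22:6n-3 / 24:6n-3) reflects
the final, peroxisome-dependent shortening step of docosahexaenoic acid
synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .fa_model import Cohort, CompositionProfile, FattyAcid, parse_fatty_acid_name

__all__ = [
    "RatioDefinition",
    "builtin_ratio_table",
    "estimate_activities",
    "cohort_activities",
    "load_ratio_table",
    "DEFAULT_EPSILON",
]

#: Denominator mol% below which a ratio is reported as undefined (NaN).
#: Measured compositions bottom out around 0.02 mol%, far above this.
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class RatioDefinition:
    """A named product/substrate ratio with its enzyme family."""

    name: str
    numerator: FattyAcid
    denominator: FattyAcid
    family: str  # desaturase | elongase | peroxisomal

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError(f"{self.name}: numerator equals denominator")
        if self.family not in ("desaturase", "elongase", "peroxisomal"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    @property
    def key(self) -> str:
        """Machine-safe identifier for output columns."""
        return (self.name.replace(" ", "").replace("(", "_").replace(")", "")
                .replace("-", "").rstrip("_"))


_BUILTIN = [
    # desaturases
    ("D9D (n-7)", "16:1n-7", "16:0", "desaturase"),
    ("D9D (n-9)", "18:1n-9", "18:0", "desaturase"),
    ("D5D (n-6)", "20:4n-6", "20:3n-6", "desaturase"),
    ("D6D (n-3) (a)", "18:4n-3", "18:3n-3", "desaturase"),
    ("D6D (n-3) (b)", "24:6n-3", "24:5n-3", "desaturase"),
    # elongases
    ("Elovl3 (n-9) (a)", "20:1n-9", "18:1n-9", "elongase"),
    ("Elovl3 (n-9) (b)", "22:1n-9", "20:1n-9", "elongase"),
    ("Elovl3 (n-9) (c)", "24:1n-9", "22:1n-9", "elongase"),
    ("Elovl6", "18:0", "16:0", "elongase"),
    ("Elovl1-3-7 (a)", "20:0", "18:0", "elongase"),
    ("Elovl1-3-7 (b)", "22:0", "20:0", "elongase"),
    ("Elovl1-3-7 (c)", "24:0", "22:0", "elongase"),
    ("Elovl5 (n-6)", "20:2n-6", "18:2n-6", "elongase"),
    ("Elovl2-5 (n-6)", "22:4n-6", "20:4n-6", "elongase"),
    ("Elovl2-5 (n-3)", "22:5n-3", "20:5n-3", "elongase"),
    ("Elovl2 (n-3)", "24:5n-3", "22:5n-3", "elongase"),
    # peroxisomal beta-oxidation
    ("PbOx", "22:6n-3", "24:6n-3", "peroxisomal"),
]


def builtin_ratio_table() -> list[RatioDefinition]:
    """The 17 standard ratios: 5 desaturase, 11 elongase, 1 peroxisomal."""
    return [
        RatioDefinition(name, parse_fatty_acid_name(num),
                        parse_fatty_acid_name(den), family)
        for name, num, den, family in _BUILTIN
    ]


def load_ratio_table(path: str) -> list[RatioDefinition]:
    """Load a custom ratio table from YAML/JSON: a list of
    ``{name, numerator, denominator, family}`` mappings."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError("ratio table must be a list of mappings")
    return [
        RatioDefinition(e["name"], parse_fatty_acid_name(e["numerator"]),
                        parse_fatty_acid_name(e["denominator"]), e["family"])
        for e in entries
    ]


def estimate_activities(profile: CompositionProfile,
                        definitions: list[RatioDefinition] | None = None,
                        epsilon: float = DEFAULT_EPSILON) -> dict[str, float]:
    """Product/substrate ratios for one profile, keyed by ratio name.

    A ratio is NaN when its denominator is below ``epsilon`` mol%. Raises
    :class:`~brainfa.fa_model.MissingSpeciesError` if a definition references
    a species absent from the profile.
    """
    if definitions is None:
        definitions = builtin_ratio_table()
    out: dict[str, float] = {}
    for d in definitions:
        num = profile.get(d.numerator.canonical_name)
        den = profile.get(d.denominator.canonical_name)
        out[d.name] = num / den if den >= epsilon else math.nan
    return out


def cohort_activities(cohort: Cohort,
                      definitions: list[RatioDefinition] | None = None,
                      epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Tidy per-subject activity table (columns use machine-safe keys)."""
    if definitions is None:
        definitions = builtin_ratio_table()
    keymap = {d.name: d.key for d in definitions}
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "subject_id": p.meta.subject_id,
            "region": p.meta.region,
            "age": p.meta.age,
        }
        acts = estimate_activities(p, definitions, epsilon)
        row.update({keymap[name]: value for name, value in acts.items()})
        rows.append(row)
    cols = ["subject_id", "region", "age", *(d.key for d in definitions)]
    return pd.DataFrame(rows, columns=cols)
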