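"""Fatty-acid nomenclature, composition data model, table I/O, and closure checks.

Compositions are expressed in mol%: the molar share of each fatty acid among
all quantified fatty acids of a sample, which sums ("closes") to 100. The
closure constraint induces dependence among the parts and is enforced
explicitly here rather than assumed.

Fatty acids are named in shorthand ``C:D`` (carbons:double bonds), with
unsaturated species carrying an omega-series suffix, e.g. ``22:6n-3``
(docosahexaenoic acid). Both the hyphenated (``n-3``) and compact (``n3``)
series spellings occur in the literature; the parser accepts both and the
canonical form is hyphenated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "FattyAcid",
    "FattyAcidParseError",
    "MissingSpeciesError",
    "SubjectMeta",
    "CompositionProfile",
    "Cohort",
    "ValidationReport",
    "PANEL",
    "PANEL_NAMES",
    "REGIONS",
    "REGION_ANATOMY",
    "parse_fatty_acid_name",
    "classify",
    "validate_profile",
    "renormalize",
    "read_cohort",
    "write_cohort",
]


class FattyAcidParseError(ValueError):
    """A fatty-acid name could not be parsed; the message names the bad token."""


class MissingSpeciesError(KeyError):
    """A profile lacks panel species required by the requested computation."""


_SERIES = {"3": "n-3", "6": "n-6", "7": "n-7", "9": "n-9"}

_NAME_RE = re.compile(r"^(\d+):(\d+)(?:n-?(\d+))?$")


@dataclass(frozen=True, order=True)
class FattyAcid:
    """One acyl species: chain length, unsaturation, and omega series.

    ``series`` is ``"saturated"`` exactly when ``double_bonds == 0``;
    otherwise one of ``n-3``, ``n-6``, ``n-7``, ``n-9`` (position of the
    first double bond counted from the methyl end).
    """

    carbons: int
    double_bonds: int
    series: str

    def __post_init__(self) -> None:
        if self.carbons % 2 != 0 or not 12 <= self.carbons <= 26:
            raise FattyAcidParseError(
                f"carbon count {self.carbons!r} outside the even 12-26 range")
        if not 0 <= self.double_bonds <= 6:
            raise FattyAcidParseError(
                f"double-bond count {self.double_bonds!r} outside 0-6")
        if self.double_bonds == 0:
            if self.series != "saturated":
                raise FattyAcidParseError(
                    f"series {self.series!r} invalid for a saturated chain")
        elif self.series not in _SERIES.values():
            raise FattyAcidParseError(
                f"series token {self.series!r} not one of n-3/n-6/n-7/n-9")

    @property
    def canonical_name(self) -> str:
        if self.double_bonds == 0:
            return f"{self.carbons}:0"
        return f"{self.carbons}:{self.double_bonds}{self.series}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


def parse_fatty_acid_name(name: str) -> FattyAcid:
    """Parse ``"22:6n-3"`` / ``"22:6n3"`` / ``"16:0"`` into a :class:`FattyAcid`."""
    if not isinstance(name, str) or not name.strip():
        raise FattyAcidParseError("empty fatty-acid name")
    token = name.strip()
    m = _NAME_RE.match(token)
    if m is None:
        raise FattyAcidParseError(f"malformed fatty-acid name {token!r}")
    carbons, double_bonds, series_digit = m.groups()
    c, d = int(carbons), int(double_bonds)
    if d == 0:
        if series_digit is not None:
            raise FattyAcidParseError(
                f"saturated chain {token!r} must not carry a series suffix")
        return FattyAcid(c, 0, "saturated")
    if series_digit is None:
        raise FattyAcidParseError(
            f"unsaturated chain {token!r} lacks an n-series suffix")
    if series_digit not in _SERIES:
        raise FattyAcidParseError(
            f"series token 'n{series_digit}' in {token!r} not one of n3/n6/n7/n9")
    return FattyAcid(c, d, _SERIES[series_digit])


def classify(fa: FattyAcid) -> str:
    """SFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
    if fa.double_bonds == 0:
        return "SFA"
    if fa.double_bonds == 1:
        return "MUFA"
    return "PUFA"


#: The 25-species study panel, in stable serialization order.
PANEL: tuple[FattyAcid, ...] = tuple(
    parse_fatty_acid_name(n)
    for n in (
        "14:0", "16:0", "16:1n-7", "18:0", "18:1n-9", "18:1n-7", "18:2n-6",
        "18:3n-3", "18:4n-3", "20:0", "20:1n-9", "20:2n-6", "20:3n-6",
        "20:4n-6", "20:5n-3", "22:0", "22:1n-9", "22:4n-6", "22:5n-6",
        "22:5n-3", "22:6n-3", "24:0", "24:1n-9", "24:5n-3", "24:6n-3",
    )
)

PANEL_NAMES: tuple[str, ...] = tuple(fa.canonical_name for fa in PANEL)

#: Region codes and the anatomical structures they denote.
REGION_ANATOMY: dict[str, str] = {
    "olive": "olive (medulla oblongata)",
    "vermis": "upper vermis (cerebellum)",
    "substantia_nigra": "substantia nigra",
    "thalamus": "thalamus",
    "hippocampus": "hippocampus",
    "caudate": "head of the caudate nucleus",
    "putamen": "anterior putamen",
    "occipital": "occipital cortex areas 17-18",
    "parietal": "parietal cortex area 7",
    "temporal": "inferior temporal cortex area 20",
    "entorhinal": "entorhinal cortex",
    "frontal": "frontal cortex area 8",
    "cingulate": "cingulate gyrus area 24",
}

REGIONS: tuple[str, ...] = tuple(REGION_ANATOMY)

_SEXES = {"male", "female", "unknown"}

_META_COLUMNS = ["subject_id", "region", "age", "sex", "pmt_hours"]


@dataclass(frozen=True)
class SubjectMeta:
    """Sample metadata: donor, brain region, age, sex, post-mortem delay."""

    subject_id: str
    region: str
    age: float
    sex: str = "unknown"
    pmt_hours: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(
                f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex {self.sex!r} not in {_SEXES}")
        if self.pmt_hours is not None and self.pmt_hours < 0:
            raise ValueError("pmt_hours must be nonnegative")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of closure/positivity validation for one profile."""

    closure_deviation: float
    negative_species: tuple[str, ...]
    missing_species: tuple[str, ...]
    valid: bool


@dataclass(frozen=True)
class CompositionProfile:
    """One subject x region vector of mol% over the fatty-acid panel.

    ``values`` maps canonical fatty-acid names to mol%. Species absent from
    the mapping are *missing*, which is distinct from an explicit 0: missing
    species invalidate index computation, because silently treating them as
    zero would bias chain-length and unsaturation indexes.
    """

    meta: SubjectMeta
    values: Mapping[str, float]

    def total(self) -> float:
        return float(sum(self.values.values()))

    def get(self, name: str) -> float:
        try:
            return float(self.values[name])
        except KeyError:
            raise MissingSpeciesError(
                f"species {name!r} missing from profile "
                f"{self.meta.subject_id}/{self.meta.region}") from None


def validate_profile(profile: CompositionProfile, tau: float = 1.0,
                     panel: Iterable[FattyAcid] = PANEL) -> ValidationReport:
    """Report closure deviation, negative entries and missing panel species.

    A profile is valid iff |sum - 100| <= ``tau`` mol%, no entry is negative,
    and every panel species is present.
    """
    negatives = tuple(n for n, v in profile.values.items() if v < 0)
    missing = tuple(fa.canonical_name for fa in panel
                    if fa.canonical_name not in profile.values)
    deviation = abs(profile.total() - 100.0)
    valid = deviation <= tau and not negatives and not missing
    return ValidationReport(deviation, negatives, missing, valid)


def renormalize(profile: CompositionProfile) -> CompositionProfile:
    """Rescale so the composition closes to exactly 100 mol%.

    Ratios between species are preserved; raises on a zero-sum profile.
    """
    total = profile.total()
    if total <= 0:
        raise ValueError("cannot renormalize a profile with nonpositive sum")
    scale = 100.0 / total
    return replace(profile,
                   values={n: v * scale for n, v in profile.values.items()})


@dataclass
class Cohort:
    """A collection of composition profiles sharing one panel.

    ``(subject_id, region)`` pairs are unique; extra per-sample metadata
    columns read from disk are preserved in ``extra``.
    """

    profiles: list[CompositionProfile]
    panel: tuple[FattyAcid, ...] = PANEL
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        keys = [(p.meta.subject_id, p.meta.region) for p in self.profiles]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (subject_id, region) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[CompositionProfile]:
        return iter(self.profiles)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.meta.region, None)
        return tuple(seen)

    def subset(self, region: str) -> "Cohort":
        return Cohort([p for p in self.profiles if p.meta.region == region],
                      panel=self.panel)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: metadata columns followed by one column per species."""
        names = [fa.canonical_name for fa in self.panel]
        rows = []
        for p in self.profiles:
            row: dict[str, object] = {
                "subject_id": p.meta.subject_id,
                "region": p.meta.region,
                "age": p.meta.age,
                "sex": p.meta.sex,
                "pmt_hours": p.meta.pmt_hours,
            }
            for n in names:
                row[n] = p.values.get(n)
            rows.append(row)
        return pd.DataFrame(rows, columns=_META_COLUMNS + names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   panel: tuple[FattyAcid, ...] = PANEL) -> "Cohort":
        missing = [c for c in ("subject_id", "region", "age")
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        if frame.empty:
            raise ValueError("no data rows")
        # map raw column headers to canonical species names
        colmap: dict[str, str] = {}
        extra_cols: list[str] = []
        for col in frame.columns:
            if col in _META_COLUMNS:
                continue
            try:
                colmap[col] = parse_fatty_acid_name(str(col)).canonical_name
            except FattyAcidParseError:
                extra_cols.append(col)
        present = set(colmap.values())
        absent = [fa.canonical_name for fa in panel
                  if fa.canonical_name not in present]
        if absent:
            raise ValueError(
                f"cohort table lacks columns for panel species: {absent}")
        profiles = []
        for _, row in frame.iterrows():
            pmt = row.get("pmt_hours")
            meta = SubjectMeta(
                subject_id=str(row["subject_id"]),
                region=str(row["region"]),
                age=float(row["age"]),
                sex=str(row.get("sex", "unknown") or "unknown"),
                pmt_hours=None if pmt is None or pd.isna(pmt) else float(pmt),
            )
            values = {canon: float(row[raw]) for raw, canon in colmap.items()
                      if pd.notna(row[raw])}
            profiles.append(CompositionProfile(meta, values))
        extra = frame[["subject_id", "region"] + extra_cols] if extra_cols else None
        return cls(profiles, panel=panel, extra=extra)


def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(path: str, sep: str | None = None,
                panel: tuple[FattyAcid, ...] = PANEL) -> Cohort:
    """Read a wide CSV/TSV cohort table (UTF-8, header row mandatory)."""
    frame = pd.read_csv(path, sep=_infer_sep(path, sep), comment="#")
    if frame.empty:
        raise ValueError(f"no data rows in {path}")
    return Cohort.from_frame(frame, panel=panel)


def write_cohort(cohort: Cohort, path: str, sep: str | None = None,
                 header_comments: Iterable[str] = ()) -> None:
    """Write a cohort as a wide CSV/TSV; round-trips with :func:`read_cohort`."""
    frame = cohort.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep=_infer_sep(path, sep), index=False)
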