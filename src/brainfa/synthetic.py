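"""Seeded synthetic cohorts emulating regional brain fatty-acid compositions.

The generator is anchored to packaged reference templates: published
group-level mean ± SEM compositions (25 fatty acids) for 13 human brain
regions in a middle-aged (< 60 y, n = 9) and an elderly (>= 60 y, n = 8)
group of healthy donors aged 40-80.

Noise model (logistic-normal style): per-species abundances are drawn
log-normally around the template mean and the vector is then closed to
100 mol%. This guarantees the two structural facts of compositional data -
strict positivity and closure - at the price of small compensatory coupling
between species. Per-species log-scale SDs are calibrated by the delta
method so that the closed composition's between-subject SD approximately
equals SEM * sqrt(n) from the template. Optional age effects are linear
slopes on the log-abundance scale injected before closure, so a trend on
one species induces small anti-trends elsewhere, mirroring real
compositional coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files

import numpy as np
import pandas as pd

from .fa_model import (
    PANEL,
    PANEL_NAMES,
    REGIONS,
    Cohort,
    CompositionProfile,
    SubjectMeta,
)

__all__ = [
    "RegionTemplate",
    "AgeEffectSpec",
    "SimulationConfig",
    "reference_table",
    "template_from_fixture",
    "reference_profile",
    "simulate_subject",
    "simulate_cohort",
    "STUDY_AGES",
    "DEFAULT_GROUP_N",
]

#: Ages of the 17 donors of the reference cohort (years).
STUDY_AGES: tuple[int, ...] = (40, 40, 44, 45, 46, 48, 52, 52, 57,
                               61, 66, 67, 70, 75, 76, 77, 79)

#: Reference group sizes (9 donors < 60 y, 8 donors >= 60 y).
DEFAULT_GROUP_N: dict[str, int] = {"middle_aged": 9, "elderly": 8}

#: Printed SEMs are rounded to 0.01 and can appear as 0.00; this floor
#: (half the printed resolution) keeps calibrated noise strictly positive.
SEM_FLOOR = 0.005

#: Cap on the per-species log-scale SD. A handful of sub-0.1 mol% template
#: cells carry SEMs as large as their mean; uncapped, the delta-method
#: calibration would explode there.
SIGMA_CAP = 1.0

_FIXTURE = "data/reference_templates.csv"
_TABLE_CACHE: pd.DataFrame | None = None


def reference_table() -> pd.DataFrame:
    """The packaged reference fixture as a tidy DataFrame.

    Columns: region, group, variable, mean, sem, stars, sig. ``variable``
    covers the 25 panel species plus the derived indexes (ACL, class totals,
    DBI, PI, SFA_UFA) and the PbOx surrogate; ``stars`` is the published
    pre-FDR star coding of the elderly group and ``sig`` the published
    FDR-adjusted significance column.
    """
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        with files("brainfa").joinpath(_FIXTURE).open("r", encoding="utf-8") as fh:
            _TABLE_CACHE = pd.read_csv(fh, keep_default_na=False,
                                       na_values=[""],
                                       dtype={"stars": str})
        _TABLE_CACHE["stars"] = _TABLE_CACHE["stars"].fillna("")
    return _TABLE_CACHE.copy()


@dataclass(frozen=True)
class RegionTemplate:
    """Mean ± SEM mol% template for one region x age group."""

    region: str
    group: str
    means: pd.Series  # index: canonical panel names, closes to ~100
    sems: pd.Series
    n: int

    def closed_means(self) -> pd.Series:
        return self.means * (100.0 / self.means.sum())


def template_from_fixture(region: str, group: str,
                          n: int | None = None) -> RegionTemplate:
    """Template for one region/group; ``n`` overrides the default group size."""
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}")
    if group not in DEFAULT_GROUP_N:
        raise KeyError(f"unknown group {group!r}; "
                       f"expected one of {tuple(DEFAULT_GROUP_N)}")
    table = reference_table()
    sub = table[(table["region"] == region) & (table["group"] == group)]
    sub = sub.set_index("variable")
    means = sub.loc[list(PANEL_NAMES), "mean"].astype(float)
    sems = sub.loc[list(PANEL_NAMES), "sem"].astype(float)
    return RegionTemplate(region, group, means, sems,
                          n if n is not None else DEFAULT_GROUP_N[group])


def reference_profile(region: str, group: str,
                      renormalized: bool = False) -> CompositionProfile:
    """The template mean composition as a profile (for index computations)."""
    t = template_from_fixture(region, group)
    means = t.closed_means() if renormalized else t.means
    age = 50.0 if group == "middle_aged" else 70.0
    meta = SubjectMeta(subject_id=f"ref_{group}", region=region, age=age)
    return CompositionProfile(meta, means.to_dict())


@dataclass(frozen=True)
class AgeEffectSpec:
    """A linear age trend on one species' log abundance, injected pre-closure.

    ``slope`` is per year; the trend is centred at ``age_ref`` so the
    template mean is reproduced at the reference age.
    """

    fatty_acid: str
    slope: float
    age_ref: float = 60.0

    def __post_init__(self) -> None:
        if self.fatty_acid not in PANEL_NAMES:
            raise ValueError(f"{self.fatty_acid!r} not in the panel")
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic cohort draw.

    ``ages`` may be an explicit tuple (e.g. :data:`STUDY_AGES`); when None,
    ``n_subjects`` ages are drawn uniformly on ``age_range`` (the reference
    cohort spans 40-80 y). ``template_group`` selects the baseline template;
    ``noise_scale`` multiplies the calibrated log-SDs (0 gives noise-free
    profiles equal to the renormalized template means).
    """

    seed: int
    n_subjects: int = 17
    ages: tuple[float, ...] | None = None
    age_range: tuple[float, float] = (40.0, 80.0)
    regions: tuple[str, ...] = REGIONS
    template_group: str = "middle_aged"
    effects: tuple[AgeEffectSpec, ...] = ()
    noise_scale: float = 1.0
    group_n: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_N))


def _log_sigmas(template: RegionTemplate, noise_scale: float) -> np.ndarray:
    """Delta-method calibration: target closed-scale SD is SEM * sqrt(n), so
    the log-scale SD is approximately that divided by the mean."""
    sems = np.maximum(template.sems.to_numpy(dtype=float), SEM_FLOOR)
    means = template.means.to_numpy(dtype=float)
    sd_target = sems * math.sqrt(template.n)
    return noise_scale * np.minimum(sd_target / means, SIGMA_CAP)


# Closing a vector of independent log-normals slightly biases its closed-scale
# means (the expectation of a ratio is not the ratio of expectations). The
# pre-closure means are therefore calibrated once per template by an internal,
# fixed-seed Monte-Carlo loop with common random numbers, so that the closed
# composition is mean-unbiased for the renormalized template. The internal
# stream is separate from (and does not consume) the user's generator.
_CALIBRATION_DRAWS = 200_000
_CALIBRATION_SEED = 987_654_321


@lru_cache(maxsize=128)
def _calibrated_means(means_key: tuple, sigma_key: tuple) -> tuple:
    means = np.array(means_key)
    sigma = np.array(sigma_key)
    target = 100.0 * means / means.sum()
    if not sigma.any():
        return tuple(means)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    z = rng.standard_normal((_CALIBRATION_DRAWS, len(means)))
    adjusted = means.copy()
    for _ in range(4):
        x = adjusted * np.exp(sigma * z - 0.5 * sigma**2)
        closed_mean = (100.0 * x / x.sum(axis=1, keepdims=True)).mean(axis=0)
        adjusted = adjusted * target / closed_mean
    return tuple(adjusted)


def simulate_subject(template: RegionTemplate, age: float,
                     effects: tuple[AgeEffectSpec, ...] = (),
                     rng: np.random.Generator | None = None,
                     noise_scale: float = 1.0,
                     meta: SubjectMeta | None = None) -> CompositionProfile:
    """Draw one profile around the template; closure is exact by construction.

    Log-abundances are mean-corrected (minus sigma^2/2) so the pre-closure
    expectation of each species equals its template mean.
    """
    rng = rng or np.random.default_rng(0)
    sigma = _log_sigmas(template, noise_scale)
    means = np.array(_calibrated_means(
        tuple(template.means.to_numpy(dtype=float)), tuple(sigma)))
    log_x = np.log(means) - 0.5 * sigma**2 + sigma * rng.standard_normal(len(means))
    for eff in effects:
        i = PANEL_NAMES.index(eff.fatty_acid)
        log_x[i] += eff.slope * (age - eff.age_ref)
    x = np.exp(log_x)
    x *= 100.0 / x.sum()
    if meta is None:
        meta = SubjectMeta(subject_id="sim", region=template.region, age=age)
    return CompositionProfile(meta, dict(zip(PANEL_NAMES, x)))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Seeded cohort: shared subjects across regions, full metadata.

    The same donor (subject_id, age, sex, post-mortem delay) appears in
    every configured region with an independent regional profile, so
    cross-region per-subject correlation analyses are well defined.
    """
    rng = np.random.default_rng(config.seed)
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
    else:
        lo, hi = config.age_range
        ages = rng.uniform(lo, hi, size=config.n_subjects)
    n = len(ages)
    sexes = rng.choice(["male", "female"], size=n, p=[12 / 17, 5 / 17])
    pmt = rng.uniform(2.0, 14.7, size=n)
    profiles = []
    for region in config.regions:
        template = template_from_fixture(region, config.template_group)
        for i in range(n):
            meta = SubjectMeta(subject_id=f"S{i + 1:03d}", region=region,
                               age=float(ages[i]), sex=str(sexes[i]),
                               pmt_hours=round(float(pmt[i]), 2))
            profiles.append(simulate_subject(template, float(ages[i]),
                                             config.effects, rng,
                                             config.noise_scale, meta=meta))
    return Cohort(profiles, panel=PANEL)
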