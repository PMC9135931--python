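"""Group comparison, FDR adjustment, and age-continuum correlation analysis.

The analysis dichotomizes donors into a middle-aged (< 60 years) and an
elderly (>= 60 years) group and compares every fatty acid, derived index and
the peroxisomal beta-oxidation surrogate per region with a two-sample
t-test, then controls the false discovery rate per region with the
Benjamini-Hochberg step-up procedure at a maximum discovery rate Q.
Age treated as a continuum is analyzed with Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .activities import builtin_ratio_table, estimate_activities
from .fa_model import Cohort, PANEL_NAMES
from .indexes import INDEX_NAMES, cohort_indexes

__all__ = [
    "ComparisonConfig",
    "split_age_groups",
    "t_test_two_sample",
    "t_from_summary",
    "percent_change",
    "bh_adjust",
    "significance_stars",
    "spearman_age",
    "run_group_comparison",
    "run_age_correlation",
    "correlation_matrix",
    "COMPARISON_VARIABLES",
]

#: Default per-region comparison family: every panel species, every derived
#: index, and the peroxisomal beta-oxidation surrogate.
COMPARISON_VARIABLES: tuple[str, ...] = (*PANEL_NAMES, *INDEX_NAMES, "PbOx")


@dataclass(frozen=True)
class ComparisonConfig:
    """Knobs of the two-group comparison.

    ``age_cut`` in years (donors with age >= cut are elderly); ``alpha`` is
    the per-test significance level used for star coding; ``Q`` the maximum
    false discovery rate of the BH step-up; ``t_variant`` chooses the pooled-
    variance Student test or Welch's unequal-variance test. All p-values are
    two-sided.
    """

    age_cut: float = 60.0
    alpha: float = 0.05
    Q: float = 0.10
    t_variant: str = "student_pooled"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.Q < 1:
            raise ValueError("Q must be in (0, 1)")
        if self.t_variant not in ("student_pooled", "welch"):
            raise ValueError(f"unknown t_variant {self.t_variant!r}")


def split_age_groups(cohort: Cohort, age_cut: float = 60.0
                     ) -> tuple[Cohort, Cohort]:
    """Partition into (middle-aged, elderly); age exactly at the cut is elderly."""
    mid = [p for p in cohort if p.meta.age < age_cut]
    eld = [p for p in cohort if p.meta.age >= age_cut]
    return (Cohort(mid, panel=cohort.panel), Cohort(eld, panel=cohort.panel))


def t_test_two_sample(x, y, config: ComparisonConfig | None = None
                      ) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p), NaN when degenerate."""
    config = config or ComparisonConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return (math.nan, math.nan)
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return (0.0, 1.0)
        return (math.nan, math.nan)
    res = sps.ttest_ind(x, y, equal_var=config.t_variant == "student_pooled")
    return (float(res.statistic), float(res.pvalue))


def t_from_summary(mean1: float, sem1: float, n1: int,
                   mean2: float, sem2: float, n2: int,
                   config: ComparisonConfig | None = None
                   ) -> tuple[float, float]:
    """Two-sample t-test reconstructed from printed mean ± SEM and n.

    The Welch variant works directly on the SEMs: t = (m2 - m1)/sqrt(sem1^2 +
    sem2^2) with Welch-Satterthwaite degrees of freedom. The pooled variant
    rebuilds per-group SDs as sem * sqrt(n) and pools them.
    """
    config = config or ComparisonConfig()
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if config.t_variant == "welch":
        se2_1, se2_2 = sem1**2, sem2**2
        t = (mean2 - mean1) / math.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
    else:
        sd1, sd2 = sem1 * math.sqrt(n1), sem2 * math.sqrt(n2)
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        t = (mean2 - mean1) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return (float(t), float(p))


def percent_change(mean_mid: float, mean_eld: float) -> float:
    """Signed percent change of the elderly mean relative to the middle-aged."""
    if not mean_mid > 0:
        return math.nan
    return 100.0 * (mean_eld - mean_mid) / mean_mid


def bh_adjust(p_values, Q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and discovery flags.

    q(i) = min_{j >= i} m * p_(j) / j on the sorted p-values, mapped back to
    the input order; a test is a discovery iff q <= Q. NaN p-values are
    passed through as NaN / non-discoveries and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rejected, q_ok, _, _ = multipletests(p[ok], alpha=Q, method="fdr_bh")
        q[ok] = q_ok
        flags[ok] = rejected
    return q, flags


def significance_stars(p: float, thresholds=(0.05, 0.01, 0.001)) -> str:
    """Star coding: * p<0.05, ** p<0.01, *** p<0.001 (empty otherwise)."""
    if p is None or math.isnan(p):
        return ""
    return "*" * sum(p < t for t in thresholds)


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray,
                      rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho by full enumeration."""
    n = len(x_rank)
    perms = np.array(list(itertools.permutations(range(n))))
    y_perm = y_rank[perms]  # (n!, n)
    xc = x_rank - x_rank.mean()
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    rho = (yc @ xc) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def spearman_age(values, ages, exact_max_n: int = 9) -> dict[str, float]:
    """Spearman rank correlation of one variable with age.

    Ties receive average ranks. The p-value uses the t-approximation
    t = rho * sqrt((n-2)/(1-rho^2)); for n <= ``exact_max_n`` the exact
    two-sided permutation p (full enumeration of rank orders) is used
    instead. Returns ``{"rho": ..., "p": ..., "n": ...}`` with NaNs for a
    constant variable or n < 3.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    keep = ~(np.isnan(v) | np.isnan(a))
    v, a = v[keep], a[keep]
    n = len(v)
    if n < 3 or np.all(v == v[0]) or np.all(a == a[0]):
        return {"rho": math.nan, "p": math.nan, "n": n}
    rho = float(sps.spearmanr(v, a).statistic)
    if n <= exact_max_n:
        p = _exact_spearman_p(sps.rankdata(v), sps.rankdata(a), rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return {"rho": rho, "p": p, "n": n}


def _variable_table(cohort: Cohort) -> pd.DataFrame:
    """Per-subject tidy table of all comparison variables for a cohort."""
    frame = cohort.to_frame()[["subject_id", "region", "age", *PANEL_NAMES]]
    idx = cohort_indexes(cohort)
    frame = frame.merge(idx.drop(columns="age"), on=["subject_id", "region"])
    pbox = [estimate_activities(p, _PBOX_DEF)["PbOx"] for p in cohort]
    frame["PbOx"] = pbox
    return frame


_PBOX_DEF = [d for d in builtin_ratio_table() if d.name == "PbOx"]


def run_group_comparison(cohort: Cohort,
                         variables: tuple[str, ...] = COMPARISON_VARIABLES,
                         config: ComparisonConfig | None = None
                         ) -> pd.DataFrame:
    """Middle-aged vs elderly comparison of every variable, per region.

    Returns one row per region x variable with group summaries, the t-test,
    the percent change of group means, star coding from the raw p, and the
    BH-adjusted q with a discovery flag at ``config.Q`` (the BH family is
    all variables within one region). Regions where either age group is
    empty are skipped with a ``skipped_regions`` attribute on the result.
    """
    config = config or ComparisonConfig()
    table = _variable_table(cohort)
    rows: list[dict[str, object]] = []
    skipped: list[str] = []
    for region in cohort.regions:
        sub = table[table["region"] == region]
        mid = sub[sub["age"] < config.age_cut]
        eld = sub[sub["age"] >= config.age_cut]
        if mid.empty or eld.empty:
            skipped.append(region)
            continue
        for var in variables:
            x = mid[var].to_numpy(dtype=float)
            y = eld[var].to_numpy(dtype=float)
            t, p = t_test_two_sample(x, y, config)
            m_mid, m_eld = float(np.nanmean(x)), float(np.nanmean(y))
            rows.append({
                "region": region,
                "variable": var,
                "mean_mid": m_mid,
                "sem_mid": float(sps.sem(x, nan_policy="omit")),
                "n_mid": int(np.sum(~np.isnan(x))),
                "mean_eld": m_eld,
                "sem_eld": float(sps.sem(y, nan_policy="omit")),
                "n_eld": int(np.sum(~np.isnan(y))),
                "t_stat": t,
                "p_raw": p,
                "pct_change": percent_change(m_mid, m_eld),
                "sig_flags": significance_stars(p),
            })
    result = pd.DataFrame(rows)
    if not result.empty:
        q = np.full(len(result), np.nan)
        disc = np.zeros(len(result), dtype=bool)
        for region, grp in result.groupby("region", sort=False):
            qi, fi = bh_adjust(grp["p_raw"].to_numpy(), config.Q)
            q[grp.index] = qi
            disc[grp.index] = fi
        result["q_adj"] = q
        result["discovery"] = disc
    result.attrs["skipped_regions"] = skipped
    result.attrs["config"] = config
    return result


def run_age_correlation(cohort: Cohort,
                        variables: tuple[str, ...] = COMPARISON_VARIABLES,
                        Q: float = 0.10,
                        exact_max_n: int = 9) -> pd.DataFrame:
    """Spearman correlation with age for every variable, per region, with
    per-region BH adjustment. One row per region x variable."""
    table = _variable_table(cohort)
    rows = []
    for region in cohort.regions:
        sub = table[table["region"] == region]
        ages = sub["age"].to_numpy(dtype=float)
        for var in variables:
            res = spearman_age(sub[var].to_numpy(dtype=float), ages,
                               exact_max_n=exact_max_n)
            rows.append({"region": region, "variable": var,
                         "rho": res["rho"], "p_raw": res["p"], "n": res["n"]})
    result = pd.DataFrame(rows)
    if not result.empty:
        q = np.full(len(result), np.nan)
        disc = np.zeros(len(result), dtype=bool)
        for region, grp in result.groupby("region", sort=False):
            qi, fi = bh_adjust(grp["p_raw"].to_numpy(), Q)
            q[grp.index] = qi
            disc[grp.index] = fi
        result["q_adj"] = q
        result["discovery"] = disc
    return result


def correlation_matrix(cohort: Cohort, index_name: str,
                       alpha: float = 0.05, min_pairs: int = 3
                       ) -> dict[str, pd.DataFrame]:
    """Region x region Spearman correlation of one per-subject index.

    Subjects are matched across regions by ``subject_id`` with pairwise-
    complete deletion. Returns ``{"rho", "p", "significant"}`` DataFrames;
    cells with fewer than ``min_pairs`` shared subjects are NaN. The matrix
    is symmetric with a unit diagonal.
    """
    idx = cohort_indexes(cohort)
    wide = idx.pivot(index="subject_id", columns="region", values=index_name)
    regions = list(cohort.regions)
    rho = pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)
    pmat = pd.DataFrame(np.zeros((len(regions), len(regions))),
                        index=regions, columns=regions)
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1:]:
            pair = wide[[r1, r2]].dropna()
            if len(pair) < min_pairs:
                r = p = math.nan
            else:
                res = sps.spearmanr(pair[r1], pair[r2])
                r, p = float(res.statistic), float(res.pvalue)
            rho.loc[r1, r2] = rho.loc[r2, r1] = r
            pmat.loc[r1, r2] = pmat.loc[r2, r1] = p
    return {"rho": rho, "p": pmat, "significant": pmat <= alpha}
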