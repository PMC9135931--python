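"""Statistical engine: t-tests, BH step-up, Spearman, pipeline behavior."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from brainfa.fa_model import PANEL_NAMES
from brainfa.stats import (
    ComparisonConfig,
    bh_adjust,
    correlation_matrix,
    percent_change,
    run_group_comparison,
    significance_stars,
    spearman_age,
    split_age_groups,
    t_from_summary,
    t_test_two_sample,
)
from brainfa.synthetic import (
    STUDY_AGES,
    SimulationConfig,
    simulate_cohort,
)


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t-test, written independently."""
    n1, n2 = len(x), len(y)
    v1 = sum((xi - sum(x) / n1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - sum(y) / n2) ** 2 for yi in y) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (sum(x) / n1 - sum(y) / n2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def bh_stepup_oracle(p, Q):
    """Classic BH rejection set by exhaustive scan of step-up thresholds."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * Q / m:
            k_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_huge_separation(self):
        t, p = t_test_two_sample([1.0, 1.001, 0.999],
                                 [100.0, 100.001, 99.999])
        assert p < 0.001

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, rng.integers(3, 12))
        y = rng.normal(0.5, 2, rng.integers(3, 12))
        t, p = t_test_two_sample(x, y)
        t0, p0 = pooled_t_oracle(list(x), list(y))
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(1, 1, size=7)
        t1, p1 = t_test_two_sample(x, y)
        t2, p2 = t_test_two_sample(3 * x - 5, 3 * y - 5)
        assert t2 == pytest.approx(t1, abs=1e-10)
        assert p2 == pytest.approx(p1, abs=1e-10)


class TestTFromSummary:
    def test_reference_group_difference_is_significant(self):
        """Reconstructed from printed olive 14:0 group summaries (star-coded
        significant in the source)."""
        for variant in ("welch", "student_pooled"):
            _, p = t_from_summary(1.84, 0.19, 9, 1.29, 0.12, 8,
                                  ComparisonConfig(t_variant=variant))
            assert p < 0.05

    def test_equal_means_give_null(self):
        t, p = t_from_summary(5.0, 0.2, 9, 5.0, 0.3, 8)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_doubling_sems_halves_t(self):
        cfg = ComparisonConfig(t_variant="welch")
        t1, _ = t_from_summary(1.0, 0.1, 9, 2.0, 0.2, 8, cfg)
        t2, _ = t_from_summary(1.0, 0.2, 9, 2.0, 0.4, 8, cfg)
        assert t2 == pytest.approx(t1 / 2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 0.1, 1, 2, 0.1, 8)
        with pytest.raises(ValueError):
            t_from_summary(1, 0.0, 9, 2, 0.1, 8)


class TestPercentChange:
    def test_reference_claims(self):
        assert round(percent_change(1.84, 1.29)) == -30
        assert round(percent_change(0.23, 0.28)) == 22
        assert round(percent_change(0.05, 0.19)) == 280

    def test_equal_and_undefined(self):
        assert percent_change(5.0, 5.0) == 0.0
        assert math.isnan(percent_change(0.0, 1.0))


class TestBH:
    def test_single_p(self):
        q, flags = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)
        assert flags[0]

    def test_all_ones_no_discoveries(self):
        _, flags = bh_adjust([1.0] * 10)
        assert not flags.any()

    def test_nan_passthrough(self):
        q, flags = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not flags[1]
        assert flags[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(20))
    def test_discoveries_match_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        q, flags = bh_adjust(p, Q=0.10)
        np.testing.assert_array_equal(flags, bh_stepup_oracle(p, 0.10))
        # q monotone nondecreasing along the p-ranking
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_age([1, 2, 3, 4, 5], [40, 50, 60, 70, 80])
        assert res["rho"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(2 / 120)  # both extreme orderings

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        v, a = rng.normal(size=12), rng.uniform(40, 80, 12)
        r1 = spearman_age(v, a)
        r2 = spearman_age(-v, a)
        assert r2["rho"] == pytest.approx(-r1["rho"], abs=1e-12)
        assert r2["p"] == pytest.approx(r1["p"], abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        v, a = rng.uniform(1, 2, 15), rng.uniform(40, 80, 15)
        r1 = spearman_age(v, a)
        r2 = spearman_age(np.exp(v), a)
        assert r2["rho"] == pytest.approx(r1["rho"], abs=1e-12)

    def test_constant_variable_undefined(self):
        res = spearman_age([1.0] * 6, [40, 45, 50, 55, 60, 65])
        assert math.isnan(res["rho"])

    @pytest.mark.parametrize("n", [5, 6])
    def test_exact_p_matches_independent_enumeration(self, n):
        rng = np.random.default_rng(n)
        v = rng.normal(size=n)
        a = rng.uniform(40, 80, size=n)
        res = spearman_age(v, a)
        rho_obs = abs(sps.spearmanr(v, a).statistic)
        count = sum(
            abs(sps.spearmanr(np.asarray(perm), a).statistic) >= rho_obs - 1e-12
            for perm in itertools.permutations(v))
        assert res["p"] == pytest.approx(count / math.factorial(n), abs=1e-12)


class TestPipeline:
    def test_study_age_split(self):
        cohort = simulate_cohort(SimulationConfig(
            seed=5, ages=STUDY_AGES, regions=("olive",)))
        mid, eld = split_age_groups(cohort)
        assert (len(mid), len(eld)) == (9, 8)

    def test_age_sixty_is_elderly(self, make_profile):
        from brainfa.fa_model import Cohort

        p60 = make_profile({n: 4.0 for n in PANEL_NAMES}, subject_id="a",
                           age=60.0)
        p59 = make_profile({n: 4.0 for n in PANEL_NAMES}, subject_id="b",
                           age=59.9)
        mid, eld = split_age_groups(Cohort([p60, p59]))
        assert [p.meta.subject_id for p in eld] == ["a"]

    def test_extreme_shift_is_discovered(self):
        """A 5-pooled-SD group shift on one species survives FDR at Q=0.10."""
        from brainfa.synthetic import AgeEffectSpec

        cohort = simulate_cohort(SimulationConfig(
            seed=13, ages=STUDY_AGES, regions=("vermis",),
            effects=(AgeEffectSpec("20:4n-6", slope=0.05),)))
        res = run_group_comparison(cohort)
        row = res[res["variable"] == "20:4n-6"].iloc[0]
        assert row["discovery"]
        assert row["sig_flags"] != ""

    def test_empty_group_region_skipped(self):
        cohort = simulate_cohort(SimulationConfig(
            seed=4, ages=(41.0, 45.0, 50.0, 55.0), regions=("olive",)))
        res = run_group_comparison(cohort)
        assert res.empty
        assert res.attrs["skipped_regions"] == ["olive"]

    def test_stars_consistent_with_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.2) == ""


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self):
        cohort = simulate_cohort(SimulationConfig(
            seed=8, n_subjects=12, regions=("olive", "vermis", "thalamus")))
        mats = correlation_matrix(cohort, "ACL")
        rho = mats["rho"].to_numpy()
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_monotone_copy_has_unit_correlation(self, make_profile):
        from brainfa.fa_model import Cohort

        profiles = []
        rng = np.random.default_rng(3)
        for i in range(8):
            x = rng.uniform(0.1, 1, len(PANEL_NAMES))
            x *= 100 / x.sum()
            values = dict(zip(PANEL_NAMES, x))
            profiles.append(make_profile(values, subject_id=f"s{i}",
                                         region="olive", age=50 + i))
            # same composition in a second region -> identical index ranking
            profiles.append(make_profile(values, subject_id=f"s{i}",
                                         region="vermis", age=50 + i))
        mats = correlation_matrix(Cohort(profiles), "DBI")
        assert mats["rho"].loc["olive", "vermis"] == pytest.approx(1.0)

    def test_too_few_shared_subjects_undefined(self, make_profile):
        from brainfa.fa_model import Cohort

        values = None
        profiles = []
        rng = np.random.default_rng(9)
        for i in range(2):
            x = rng.uniform(0.1, 1, len(PANEL_NAMES))
            x *= 100 / x.sum()
            values = dict(zip(PANEL_NAMES, x))
            profiles.append(make_profile(values, subject_id=f"s{i}",
                                         region="olive", age=50 + i))
            profiles.append(make_profile(values, subject_id=f"s{i}",
                                         region="vermis", age=50 + i))
        mats = correlation_matrix(Cohort(profiles), "ACL")
        assert math.isnan(mats["rho"].loc["olive", "vermis"])
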