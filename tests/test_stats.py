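import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slnet import (CohortDesign, bca_interval, bootstrap_group_means,
                   family_bootstrap, gen_metric_cohort, group_differences,
                   outlier_policy, paired_bias, partial_correlation,
                   significance_tier, transform_for_normality)
from slnet.recording import ConfigurationError
from slnet.stats import DegenerateDistributionWarning


def iid_table(values):
    """One-member families: family bootstrap reduces to the classical one."""
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(values))],
        "family_id": [f"f{i}" for i in range(len(values))],
        "group": "A", "wave": 1, "sex": "F", "value": values,
    })


class TestFamilyBootstrap:
    def test_single_family_degenerate(self):
        df = iid_table([1.0, 2.0, 3.0]).assign(family_id="f0")
        res = family_bootstrap(df, lambda d: d["value"].mean(), n_boot=50, seed=0)
        assert np.ptp(res.values) == 0.0

    def test_seeded_determinism(self):
        df = iid_table(np.arange(20.0))
        a = family_bootstrap(df, lambda d: d["value"].mean(), n_boot=100, seed=3)
        b = family_bootstrap(df, lambda d: d["value"].mean(), n_boot=100, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_iid_bootstrap_se_matches_classical(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(80)
        df = iid_table(vals)
        res = family_bootstrap(df, lambda d: d["value"].mean(), n_boot=2000, seed=4)
        classical_se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert res.se == pytest.approx(classical_se, rel=0.10)

    def test_matches_vectorized_group_mean_path(self):
        # generic resampler and the multinomial fast path follow the same law
        rng = np.random.default_rng(2)
        design = CohortDesign(groups=(("A", 30),), coupling_by_group={"A": 0},
                              members_per_family=2, seed=8)
        cohort = gen_metric_cohort(design, {"A": 0.0})
        slow = family_bootstrap(cohort, lambda d: d["value"].mean(),
                                n_boot=2000, seed=5)
        _, _, reps, _ = bootstrap_group_means(cohort, "value", n_boot=2000, seed=5)
        assert slow.values.mean() == pytest.approx(reps[:, 0].mean(), abs=0.01)
        assert slow.values.std() == pytest.approx(reps[:, 0].std(), rel=0.1)


class TestBcaInterval:
    def test_symmetric_distribution_close_to_percentile(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(60)
        df = iid_table(vals)
        res = family_bootstrap(df, lambda d: d["value"].mean(), n_boot=4000, seed=1)
        lo, hi = bca_interval(res.values, res.observed, res.jackknife, alpha=0.05)
        plo, phi = np.quantile(res.values, [0.025, 0.975])
        spread = res.se
        assert lo == pytest.approx(plo, abs=0.4 * spread)
        assert hi == pytest.approx(phi, abs=0.4 * spread)

    def test_degenerate_distribution_zero_width_with_warning(self):
        with pytest.warns(DegenerateDistributionWarning):
            lo, hi = bca_interval(np.full(100, 1.5), 1.5, np.full(5, 1.5))
        assert lo == hi == 1.5

    def test_matches_scipy_reference_on_skewed_sample(self):
        # independent oracle: scipy's BCa on the same i.i.d. sample
        rng = np.random.default_rng(42)
        vals = rng.exponential(1.0, size=40)
        df = iid_table(vals)
        res = family_bootstrap(df, lambda d: d["value"].mean(), n_boot=9999, seed=2)
        lo, hi = bca_interval(res.values, res.observed, res.jackknife, alpha=0.05)
        ref = sps.bootstrap((vals,), np.mean, method="BCa", n_resamples=9999,
                            confidence_level=0.95, random_state=7)
        assert lo == pytest.approx(ref.confidence_interval.low, abs=0.1 * res.se * 3)
        assert hi == pytest.approx(ref.confidence_interval.high, abs=0.1 * res.se * 3)

    def test_reduces_to_percentile_when_unbiased_and_no_acceleration(self):
        dist = np.linspace(-1, 1, 2001)
        jack = np.zeros(10)  # zero skew -> zero acceleration
        lo, hi = bca_interval(dist, 0.0, jack, alpha=0.05)
        np.testing.assert_allclose([lo, hi], np.quantile(dist, [0.025, 0.975]),
                                   atol=1e-2)


class TestGroupDifferences:
    def test_nine_groups_yield_fifteen_comparisons(self):
        rng = np.random.default_rng(0)
        frames = []
        for gi in range(9):
            t = iid_table(rng.standard_normal(8))
            t["group"] = f"g{gi}"
            t["family_id"] = [f"g{gi}f{i}" for i in range(len(t))]
            frames.append(t)
        df = pd.concat(frames, ignore_index=True)
        comps = group_differences(df, "value", n_boot=200, seed=1)
        assert len(comps) == 15
        assert sum(c.step == 1 for c in comps) == 8
        assert sum(c.step == 2 for c in comps) == 7

    def test_planted_two_sd_difference_power(self):
        hits = 0
        n_runs = 100
        for run in range(n_runs):
            design = CohortDesign(groups=(("A", 15), ("B", 15)),
                                  coupling_by_group={"A": 0, "B": 0},
                                  members_per_family=2, seed=run)
            cohort = gen_metric_cohort(design, {"A": 0.0, "B": 2.0}, sd=1.0)
            comps = group_differences(cohort, "value", alpha=0.01,
                                      n_boot=500, seed=run + 1)
            assert comps[0].observed > 0  # correct sign
            hits += comps[0].significant
        assert hits >= 95

    def test_seeded_determinism(self):
        design = CohortDesign(groups=(("A", 10), ("B", 10)),
                              coupling_by_group={"A": 0, "B": 0},
                              members_per_family=2, seed=3)
        cohort = gen_metric_cohort(design, {"A": 0.0, "B": 1.0})
        a = group_differences(cohort, "value", n_boot=300, seed=7)
        b = group_differences(cohort, "value", n_boot=300, seed=7)
        assert [(c.ci_low, c.ci_high) for c in a] == \
               [(c.ci_low, c.ci_high) for c in b]


class TestSignificanceTier:
    def test_nested_tiers_reflect_effect_strength(self):
        rng = np.random.default_rng(3)
        jack = rng.standard_normal(20) * 0.01
        strong = rng.normal(1.0, 0.1, size=5000)   # far from zero
        weak = rng.normal(0.30, 0.1, size=5000)    # ~3 sigma from zero
        null = rng.normal(0.0, 0.1, size=5000)
        assert significance_tier(strong, 1.0, jack) == 0.0001
        assert significance_tier(weak, 0.30, jack) == 0.01
        assert significance_tier(null, 0.0, jack) is None


class TestPartialCorrelation:
    def test_constant_covariate_equals_plain_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        r, _ = partial_correlation(x, y, np.ones(100), n_boot=50, seed=1)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        r, _ = partial_correlation(x, x, z, n_boot=50, seed=1)
        assert r == pytest.approx(1.0)

    def test_recovers_known_partial_correlation(self):
        # x = z + u1, y = z + u2 with corr(u1, u2) = 0.5: removing z leaves
        # exactly the planted partial correlation
        rng = np.random.default_rng(7)
        n = 500
        z = rng.standard_normal(n)
        u = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        x, y = z + u[:, 0], z + u[:, 1]
        r, (lo, hi) = partial_correlation(x, y, z, n_boot=500, seed=2)
        assert r == pytest.approx(0.5, abs=0.12)
        assert lo < r < hi

    def test_constant_input_rejected(self):
        with pytest.raises(ConfigurationError):
            partial_correlation(np.ones(30), np.arange(30.0),
                                np.random.default_rng(0).standard_normal(30))

    def test_sex_adjustment_with_table(self):
        design = CohortDesign(groups=(("A", 60),), coupling_by_group={"A": 0.5},
                              members_per_family=1, seed=9, with_volumes=True)
        from slnet import gen_cohort
        from slnet.synthetic import CouplingSpec
        # metric proportional to coupling: volumes were built to correlate
        cohort = gen_cohort(design, CouplingSpec(n_channels=6, duration=0.2,
                                                 band=(6, 13)))
        tab = cohort.table.assign(metric=lambda d: d["coupling"])
        r, (lo, hi) = partial_correlation("metric", "wmv", ["sex"], data=tab,
                                          n_boot=300, seed=3)
        assert r > 0.3
        assert lo > 0


class TestTransforms:
    def test_reciprocal_transform_preserves_order(self):
        out = transform_for_normality([1.0, 2.0, 4.0], "L")
        np.testing.assert_allclose(out, [-1.0, -0.5, -0.25])
        assert (np.diff(out) > 0).all()

    def test_log_transform_of_unit_sl_is_zero(self):
        assert transform_for_normality([1.0], "sl")[0] == 0.0

    def test_c_passes_through(self):
        v = np.array([0.2, 0.4])
        np.testing.assert_array_equal(transform_for_normality(v, "C"), v)

    def test_correlation_sign_preserved(self):
        rng = np.random.default_rng(11)
        cov = rng.standard_normal(200)
        sl_vals = np.exp(cov + 0.3 * rng.standard_normal(200))
        before = np.corrcoef(cov, sl_vals)[0, 1]
        after = np.corrcoef(cov, transform_for_normality(sl_vals, "sl"))[0, 1]
        assert np.sign(before) == np.sign(after)
        lvals = 1.0 + np.exp(-cov)
        before = np.corrcoef(cov, lvals)[0, 1]
        after = np.corrcoef(cov, transform_for_normality(lvals, "L"))[0, 1]
        assert np.sign(before) == np.sign(after)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            transform_for_normality([0.0, 1.0], "sl")
        with pytest.raises(ConfigurationError):
            transform_for_normality([-2.0], "L")


class TestPairedBias:
    def test_identical_scorings_zero_bias(self):
        a = np.array([1.0, 2.0, 3.0])
        bias, corrected = paired_bias(a, a)
        assert bias == 0.0
        np.testing.assert_array_equal(corrected, a)

    def test_constant_offset_fully_removed(self):
        a = np.array([1.0, 2.0, 3.0])
        bias, corrected = paired_bias(a, a - 0.05)
        assert bias == pytest.approx(0.05)
        np.testing.assert_allclose(corrected, a)

    def test_correction_unbiased_under_noise(self):
        rng = np.random.default_rng(13)
        gaps = []
        for _ in range(500):
            truth = rng.standard_normal(30)
            a = truth + 0.1 * rng.standard_normal(30)
            b = truth - 0.08 + 0.1 * rng.standard_normal(30)
            _, corrected = paired_bias(a, b)
            gaps.append(a.mean() - corrected.mean())
        assert np.mean(gaps) == pytest.approx(0.0, abs=1e-12)

    def test_unpaired_subject_rejected(self):
        with pytest.raises(ConfigurationError):
            paired_bias([1.0, 2.0], [1.0])
        with pytest.raises(ConfigurationError):
            paired_bias([1.0, np.nan], [1.0, 2.0])


class TestOutlierPolicy:
    def test_equal_values_none_removed(self):
        retained, flagged = outlier_policy(np.ones(10))
        assert len(flagged) == 0 and len(retained) == 10

    def test_single_extreme_value_flagged(self):
        rng = np.random.default_rng(14)
        v = rng.standard_normal(103)
        v = np.append(v, 10.0 * v.std())
        retained, flagged = outlier_policy(v, z_cut=4.0)
        assert list(flagged) == [103]

    def test_gaussian_sample_rarely_flagged(self):
        rng = np.random.default_rng(15)
        v = rng.standard_normal((104, 3))
        _, flagged = outlier_policy(v, z_cut=4.0)
        assert len(flagged) <= 1
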