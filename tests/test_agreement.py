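"""Unit and property tests for the method-agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpoagree.agreement import (agreement_suite, agreement_table,
                                bland_altman, bland_altman_table, olp_fit,
                                ols_fit, pearson_r)
from lpoagree.errors import DegenerateDataError, InsufficientDataError

from conftest import make_dataset

# reference dataset used across operations (oracle values hand-computed from
# the product-moment / normal-equation / sd-ratio formulas)
X5 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
Y5 = np.array([1.2, 2.1, 2.9, 4.2, 4.8])


class TestPearson:
    def test_perfect_lines(self):
        ds = make_dataset(X5, 2 * X5 + 1)
        res = pearson_r(ds)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-8
        assert pearson_r(make_dataset(X5, -X5)).r == pytest.approx(-1.0)

    def test_product_moment_hand_value(self):
        res = pearson_r(make_dataset(X5, Y5))
        assert res.r == pytest.approx(0.99527, abs=1e-4)

    @pytest.mark.parametrize("member", ["plasma", "saliva"])
    def test_degenerate_member_raises(self, member):
        const = np.full(5, 2.0)
        ds = (make_dataset(const, Y5) if member == "plasma"
              else make_dataset(X5, const))
        with pytest.raises(DegenerateDataError):
            pearson_r(ds)

    def test_too_few_pairs_raises(self):
        with pytest.raises(InsufficientDataError):
            make_dataset([1, 2], [1, 2])


class TestOLS:
    def test_identity_line(self):
        fit = ols_fit(make_dataset(X5, X5))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_saliva(self):
        fit = ols_fit(make_dataset(X5, np.full(5, 3.0)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0)

    def test_normal_equations_hand_value(self):
        fit = ols_fit(make_dataset(X5, Y5))
        assert fit.slope == pytest.approx(0.93, abs=1e-10)
        assert fit.intercept == pytest.approx(0.25, abs=1e-10)
        assert fit.slope_ci[0] < 0.93 < fit.slope_ci[1]


class TestOLP:
    def test_identity_no_bias(self):
        fit = olp_fit(make_dataset(X5, X5 + np.array([0.01, -0.01, 0.0, 0.01, -0.01])))
        assert fit.b == pytest.approx(1.0, abs=0.02)
        assert not fit.differential_bias and not fit.proportional_bias

    def test_exact_proportionality(self):
        fit = olp_fit(make_dataset([1.0, 2.0, 3.0], [2.0, 4.0, 6.0]))
        assert fit.b == pytest.approx(2.0)
        assert fit.a == pytest.approx(0.0, abs=1e-12)

    def test_sd_ratio_hand_value(self):
        fit = olp_fit(make_dataset(X5, Y5))
        assert fit.b == pytest.approx(0.9345, abs=1e-3)
        assert fit.a == pytest.approx(0.2365, abs=1e-3)
        assert fit.b_ci[0] <= fit.b <= fit.b_ci[1]
        assert fit.a_ci[0] <= fit.a <= fit.a_ci[1]

    def test_analytic_ci_matches_bootstrap(self, rng):
        """The F-based slope interval and a 20,000-resample percentile
        bootstrap of the same estimator agree in width at n = 12."""
        x, y = rng.multivariate_normal(
            [0.5, 0.5], 0.12**2 * np.array([[1, 0.85], [0.85, 1]]), size=12).T
        ds = make_dataset(x, y)
        analytic = olp_fit(ds, ci_method="analytic")
        boot = olp_fit(ds, ci_method="bootstrap", n_boot=20_000, rng=rng)
        w_a = analytic.b_ci[1] - analytic.b_ci[0]
        w_b = boot.b_ci[1] - boot.b_ci[0]
        assert abs(w_a - w_b) / w_a < 0.25

    def test_zero_correlation_raises(self):
        # symmetric cross: sample covariance exactly 0
        x = np.array([-1.0, 1.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, -1.0, 1.0])
        with pytest.raises(DegenerateDataError, match="r = 0"):
            olp_fit(make_dataset(x, y))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_olp_ols_identity_and_symmetry(self, seed):
        """|b_OLP| = |b_OLS| / |r| and b_OLP(x, y) = 1 / b_OLP(y, x); the
        OLP slope always dominates the OLS slope in magnitude."""
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 31))
        x = r.normal(size=n)
        y = 0.5 * x + r.normal(scale=0.8, size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        ds_xy, ds_yx = make_dataset(x, y), make_dataset(y, x)
        olp = olp_fit(ds_xy)
        ols = ols_fit(ds_xy)
        assert abs(olp.b) == pytest.approx(abs(ols.slope) / abs(olp.r), abs=1e-10)
        assert abs(olp.b) >= abs(ols.slope) - 1e-12
        assert olp_fit(ds_yx).b == pytest.approx(1.0 / olp.b, rel=1e-10)


class TestBlandAltman:
    def test_exact_equality_degenerates_cleanly(self):
        ba = bland_altman(make_dataset(X5, X5))
        assert ba.mean_diff == 0.0 and ba.sd_diff == 0.0
        assert ba.degenerate
        assert not ba.differential_bias and not ba.proportional_bias
        assert ba.outside_loa_count == 0

    def test_constant_offset(self):
        ba = bland_altman(make_dataset(X5, X5 + 5))
        assert ba.mean_diff == pytest.approx(5.0)
        assert ba.sd_diff == 0.0
        assert ba.differential_bias        # point CI at 5 excludes 0
        assert not ba.proportional_bias    # differences independent of means

    def test_hand_computed_loa(self):
        diffs = np.array([0.1, -0.2, 0.0, 0.3, -0.1])
        ds = make_dataset(X5, X5 + diffs)
        ba = bland_altman(ds)
        assert ba.mean_diff == pytest.approx(0.02)
        assert ba.sd_diff == pytest.approx(0.192354, abs=1e-5)
        assert ba.loa_low == pytest.approx(0.02 - 1.96 * ba.sd_diff)
        assert ba.loa_high == pytest.approx(0.02 + 1.96 * ba.sd_diff)
        assert ba.loa_low == pytest.approx(-0.357, abs=1e-3)
        assert ba.loa_high == pytest.approx(0.397, abs=1e-3)
        assert ba.mean_diff_ci[0] <= ba.mean_diff <= ba.mean_diff_ci[1]
        assert ba.loa_low_ci[0] <= ba.loa_low <= ba.loa_low_ci[1]

    @given(st.floats(-50, 50), st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_translation_equivariance(self, shift, seed):
        """Adding c to both members leaves mean_diff, sd_diff, LoA width and
        the OLP slope unchanged."""
        r = np.random.default_rng(seed)
        x = r.normal(size=10)
        y = x + r.normal(scale=0.3, size=10)
        base = bland_altman(make_dataset(x, y))
        moved = bland_altman(make_dataset(x + shift, y + shift))
        assert moved.mean_diff == pytest.approx(base.mean_diff, abs=1e-9)
        assert moved.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)
        assert (moved.loa_high - moved.loa_low) == pytest.approx(
            base.loa_high - base.loa_low, abs=1e-9)
        b0 = olp_fit(make_dataset(x, y)).b
        b1 = olp_fit(make_dataset(x + shift, y + shift)).b
        assert b1 == pytest.approx(b0, abs=1e-9)


class TestAgreementSuite:
    def test_near_equality_all_rows_clean(self, rng):
        datasets = []
        for analyte in ("DC", "TC", "SB"):
            for phase in ("F", "L"):
                for tp in ("pre", "post"):
                    x = rng.uniform(1, 2, size=12)
                    datasets.append(make_dataset(x, x, analyte, phase, tp))
        rows = agreement_suite(datasets)
        assert len(rows) == 12
        for row in rows:
            assert row.error is None
            assert row.olp.b == pytest.approx(1.0)
            assert row.olp.a == pytest.approx(0.0, abs=1e-12)
            assert not row.olp.differential_bias
            assert not row.olp.proportional_bias
            assert not row.ba.differential_bias

    def test_row_order_is_analyte_phase_timepoint(self, rng):
        datasets = [make_dataset(rng.uniform(1, 2, 5), rng.uniform(1, 2, 5),
                                 a, p, t)
                    for t in ("post", "pre") for p in ("L", "F")
                    for a in ("SB", "TC", "DC")]
        rows = agreement_suite(datasets)
        labels = [r.dataset.label for r in rows]
        assert labels[:4] == ["DC/F/pre", "DC/F/post", "DC/L/pre", "DC/L/post"]
        assert labels[8:] == ["SB/F/pre", "SB/F/post", "SB/L/pre", "SB/L/post"]

    def test_empty_list_raises(self):
        with pytest.raises(InsufficientDataError):
            agreement_suite([])

    def test_failed_rows_marked_without_aborting(self, rng):
        good = make_dataset(rng.uniform(1, 2, 8), rng.uniform(1, 2, 8), "DC")
        bad = make_dataset(np.full(5, 1.0), rng.uniform(1, 2, 5), "TC")
        rows = agreement_suite([good, bad])
        assert rows[0].error is None
        assert rows[1].error is not None and "DegenerateDataError" in rows[1].error
        table = agreement_table(rows)
        assert table.loc[1, "error"] is not None
        assert len(bland_altman_table(rows)) == 2

    def test_bonferroni_adjusts_correlation_p(self, rng):
        x = rng.normal(size=10)
        ds = make_dataset(x, x + rng.normal(scale=0.5, size=10))
        row = agreement_suite([ds], bonferroni_family=3)[0]
        assert row.pearson.p_adjusted == pytest.approx(
            min(1.0, row.pearson.p * 3))


class TestNoBiasCalibration:
    def test_no_bias_cohorts_rarely_flag_bias(self, rng):
        """With true slope 1, intercept 0, r = 0.9 and n = 12, the summary
        table's bias flags (OLP intercept and slope) both stay false in at
        least 90% of 200 replicate strata."""
        from lpoagree.simulate import sample_correlated_pairs
        clean = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = sample_correlated_pairs(12, 0.9, rng, mu=0.5, sd=0.12)
            fit = olp_fit(make_dataset(x, y))
            clean += not (fit.differential_bias or fit.proportional_bias)
        assert clean / n_rep >= 0.90

    def test_per_flag_false_positive_rate_is_nominal(self, rng):
        """Over 1,000 no-bias strata at n = 12, rho = 0.85, each of the four
        bias flags (OLP intercept/slope, Bland-Altman mean-diff/prop-slope)
        fires at the nominal alpha = 5% +- 2%."""
        from lpoagree.simulate import sample_correlated_pairs
        per_flag = np.zeros(4)
        n_rep = 1000
        for _ in range(n_rep):
            x, y = sample_correlated_pairs(12, 0.85, rng, mu=0.5, sd=0.12)
            ds = make_dataset(x, y)
            fit = olp_fit(ds)
            ba = bland_altman(ds)
            per_flag += [fit.differential_bias, fit.proportional_bias,
                         ba.differential_bias, ba.proportional_bias]
        assert np.all(np.abs(per_flag / n_rep - 0.05) <= 0.02)
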