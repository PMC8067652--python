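import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm

from microlvm import interactions as ia
from microlvm.interactions import (
    ConditionalCurve,
    CpmError,
    ShiftRecord,
    conditional_spearman,
    count_shifts,
    detect_shift,
    fit_cpm,
    partial_spearman,
    psr,
)


class TestFitCpm:
    def test_intercept_only_equals_empirical_cdf(self, rng):
        y = rng.negative_binomial(2, 0.3, size=60).astype(float)
        fit = fit_cpm(y)
        for m, v in enumerate(fit.y_values[:-1]):
            assert expit(fit.gamma[m]) == pytest.approx((y <= v).mean(), abs=1e-6)

    def test_binary_reduces_to_logistic_regression(self, rng):
        x = rng.standard_normal(120)
        y = (rng.random(120) < expit(0.8 * x - 0.2)).astype(float)
        fit = fit_cpm(y, x[:, None])
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.theta[0] == pytest.approx(ref.params[1], abs=1e-5)
        assert -fit.gamma[0] == pytest.approx(ref.params[0], abs=1e-5)

    def test_binary_probit_matches_statsmodels(self, rng):
        x = rng.standard_normal(150)
        y = (rng.random(150) < stats.norm.cdf(0.6 * x)).astype(float)
        fit = fit_cpm(y, x[:, None], link="probit")
        ref = sm.Probit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.theta[0] == pytest.approx(ref.params[1], abs=1e-4)

    def test_constant_response_error(self):
        with pytest.raises(CpmError, match="constant"):
            fit_cpm(np.ones(20))

    def test_non_finite_response_error(self):
        y = np.arange(20, dtype=float)
        y[3] = np.nan
        with pytest.raises(CpmError):
            fit_cpm(y)

    def test_too_few_observations(self):
        with pytest.raises(CpmError):
            fit_cpm(np.arange(5, dtype=float))

    def test_cutpoints_nondecreasing(self, rng):
        y = rng.poisson(8.0, size=80).astype(float)
        Z = rng.standard_normal((80, 2))
        fit = fit_cpm(y, Z)
        assert np.all(np.diff(fit.gamma) > 0)

    def test_fitted_cdf_monotone_in_value(self, rng):
        y = rng.poisson(5.0, size=60).astype(float)
        Z = rng.standard_normal((60, 1))
        fit = fit_cpm(y, Z)
        zfix = np.zeros((len(fit.y_values), 1))
        cdf = fit.cdf_leq(fit.y_values, np.tile(Z[:1], (len(fit.y_values), 1)))
        assert np.all(np.diff(cdf) >= -1e-12)


class TestPsr:
    def test_range_and_zero_mean(self, rng):
        y = rng.standard_normal(100)
        fit = fit_cpm(y)
        p = psr(fit, y)
        assert np.all(p >= -1) and np.all(p <= 1)
        assert abs(p.mean()) < 0.02

    def test_median_of_odd_tiefree_sample_is_zero(self, rng):
        y = rng.standard_normal(101)
        p = psr(fit_cpm(y), y)
        assert p[np.argsort(y)[50]] == pytest.approx(0.0, abs=1e-12)

    def test_maximum_value(self, rng):
        n = 100
        y = rng.standard_normal(n)
        p = psr(fit_cpm(y), y)
        assert p.max() == pytest.approx((n - 1) / n, abs=1e-9)

    def test_intercept_only_reproduces_midranks(self, rng):
        y = rng.integers(0, 6, size=80).astype(float)  # heavy ties
        p = psr(fit_cpm(y), y)
        n = len(y)
        midrank_cdf = (stats.rankdata(y, method="average") - 0.5) / n
        np.testing.assert_allclose(p, 2 * midrank_cdf - 1, atol=1e-9)


class TestPartialSpearman:
    def test_matches_classical_spearman_without_adjustment(self, rng):
        x = rng.standard_normal(100)
        y = x + 0.5 * rng.standard_normal(100)
        rho, _ = partial_spearman(x, y, n_boot=0)
        classic = stats.spearmanr(x, y).statistic
        assert abs(rho - classic) < 0.02

    def test_monotone_invariance(self, rng):
        x = rng.standard_normal(100)
        y = x + rng.standard_normal(100)
        r1, _ = partial_spearman(x, y, n_boot=0)
        r2, _ = partial_spearman(np.exp(x), y ** 3, n_boot=0)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_symmetry(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        assert partial_spearman(x, y, n_boot=0)[0] == \
            pytest.approx(partial_spearman(y, x, n_boot=0)[0], abs=1e-12)

    def test_confounder_removed(self, rng):
        z = rng.standard_normal(500)
        x = z + 0.3 * rng.standard_normal(500)
        y = z + 0.3 * rng.standard_normal(500)
        rho, _ = partial_spearman(x, y, z[:, None], n_boot=0)
        assert abs(rho) < 0.1

    def test_null_independence(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        z = rng.standard_normal(1000)
        rho, _ = partial_spearman(x, y, z[:, None], n_boot=0)
        assert abs(rho) < 0.07

    def test_bootstrap_ci_covers_estimate(self, rng):
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60)
        rho, (lo, hi) = partial_spearman(x, y, n_boot=200, seed=1)
        assert lo < rho < hi

    def test_constant_input_error(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(50), np.arange(50.0))


class TestConditionalSpearman:
    def test_point_estimates_only_without_bootstrap(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        m = rng.standard_normal(80)
        curve = conditional_spearman(x, y, m, n_boot=0)
        assert curve.boot_rho is None
        assert np.isnan(curve.ci_lower).all()
        assert len(curve.grid) == 9

    def test_rho_within_bounds(self, rng):
        x = rng.standard_normal(100)
        y = x + rng.standard_normal(100)
        m = rng.standard_normal(100)
        curve = conditional_spearman(x, y, m, n_boot=0)
        assert np.all(np.abs(curve.rho) <= 1)

    def test_grid_outside_range_error(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(ValueError, match="range"):
            conditional_spearman(x, x, np.linspace(0, 1, 50), grid=[2.0], n_boot=0)

    def test_nonpositive_bandwidth_error(self, rng):
        x = rng.standard_normal(50)
        m = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="bandwidth"):
            conditional_spearman(x, x, m, bandwidth=0.0, n_boot=0)

    def test_constant_dependence_not_flagged(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal(200)
        x = z + rng.standard_normal(200)
        y = z + rng.standard_normal(200)
        m = rng.standard_normal(200)
        curve = conditional_spearman(x, y, m, n_boot=200, seed=4)
        rec = detect_shift(curve)
        assert rec.diff_ci[0] < 0 < rec.diff_ci[1]


class TestDetectShift:
    def _curve(self, rho_lo, rho_hi, spread=0.05, n_boot=200):
        rng = np.random.default_rng(0)
        grid = np.quantile(np.linspace(0, 1, 101), np.arange(0.1, 0.91, 0.1))
        rho = np.linspace(rho_lo, rho_hi, 9)
        boot = rho[None] + rng.normal(0, spread, size=(n_boot, 9))
        return ConditionalCurve(grid=grid, rho=rho,
                                ci_lower=np.quantile(boot, 0.025, axis=0),
                                ci_upper=np.quantile(boot, 0.975, axis=0),
                                n_boot=n_boot, bandwidth=0.1,
                                modifier=np.linspace(0, 1, 101), boot_rho=boot)

    def test_positive_shift_significant(self):
        rec = detect_shift(self._curve(-0.5, 0.5))
        assert rec.direction == "positive shift"
        assert rec.significant
        assert rec.sign_change

    def test_flat_curve_not_significant(self):
        rec = detect_shift(self._curve(0.3, 0.3, spread=0.1))
        assert not rec.significant

    def test_weakening_counts_as_negative_shift(self):
        rec = detect_shift(self._curve(0.6, 0.1))
        assert rec.direction == "negative shift"
        assert rec.significant
        assert not rec.sign_change

    def test_direction_matches_sign_of_difference(self):
        rec = detect_shift(self._curve(0.1, 0.4))
        assert rec.direction == "positive shift"
        assert np.sign(rec.rho_high - rec.rho_low) > 0


class TestCountShifts:
    def _record(self, pairing, modifier, direction, significant=True):
        return ShiftRecord(pair=("A", "B"), pairing=pairing, modifier=modifier,
                           rho_low=0.0, rho_high=0.5 if direction == "positive shift" else -0.5,
                           direction=direction, significant=significant)

    def test_counts_only_significant(self):
        records = [self._record("Bact-Bact", "C:N", "positive shift")] * 3 + \
                  [self._record("Bact-Bact", "C:N", "positive shift", significant=False)]
        table = count_shifts(records)
        assert table.loc["Bact-Bact", ("C:N", "positive shift")] == 3

    def test_empty_input_all_zero(self):
        table = count_shifts([])
        assert (table.to_numpy() == 0).all()

    def test_single_cell(self):
        table = count_shifts([self._record("Fung-Fung", "pH", "negative shift")])
        assert table.loc["Fung-Fung", ("pH", "negative shift")] == 1
        assert table.to_numpy().sum() == 1


class TestPhylumScan:
    def test_scan_on_injected_pair(self):
        from microlvm import synthetic
        from microlvm.synthetic import GroundTruth
        n = 150
        env, _ = synthetic.simulate_environment(
            n, seed=1, covariates=["C:N", "elevation", "pH"])
        t = 4
        truth = GroundTruth(alpha=np.zeros(n), beta0=np.full(t, np.log(30.0)),
                            beta=np.zeros((t, 3)), loadings=np.full((t, 1), 1e-9),
                            phi=np.full(t, 2.0))
        counts = synthetic.simulate_community(env, truth, seed=2)
        records, curves = ia.scan_shifts(counts, env, modifiers=["C:N"],
                                         n_boot=60, seed=3, min_prevalence=1)
        assert records
        assert all(r.pairing in {"Bact-Bact", "Fung-Fung", "Bact-Fung"} for r in records)
        assert all(r.modifier == "C:N" for r in records)

    def test_phylum_table_sums_orders(self, toy_counts):
        table = ia.phylum_table(toy_counts)
        assert table.to_numpy().sum() == toy_counts.counts.sum()
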