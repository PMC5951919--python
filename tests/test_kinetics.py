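"""Exponential-survival fitting, rate constants and ultra-stable decay."""

import numpy as np
import pytest

from smkinetics.kinetics import (
    TimeLapseDecay,
    classify_heterogeneity,
    fit_exponential_survival,
    fit_ultrastable_decay,
    fraction_at_time,
    kd_from_rates,
    koff_from_bound,
    kon_from_unbound,
    select_model,
    subtract_bleach_rate,
)
from smkinetics.simulate import discretize_durations, simulate_dwells, simulate_timelapse

DT = 0.1


def _dwells(components, n, seed):
    return discretize_durations(simulate_dwells(components, n, seed=seed), DT)


class TestExponentialSurvival:
    def test_single_rate_recovery(self):
        """5000 dwells at 0.24 /s recover the rate within 5%."""
        d = _dwells([(0.24, 1.0)], 5000, seed=0)
        fit = fit_exponential_survival(d, n_components=1, n_bootstrap=50, seed=1)
        assert abs(fit.rates[0] / 0.24 - 1) < 0.05
        assert fit.rate_se[0] < 0.02

    def test_ls_and_mle_agree_on_large_sample(self):
        d = _dwells([(0.3, 1.0)], 20_000, seed=2)
        mle = fit_exponential_survival(d, n_components=1, method="mle", n_bootstrap=0)
        ls = fit_exponential_survival(d, n_components=1, method="ls", n_bootstrap=0)
        assert abs(mle.rates[0] / ls.rates[0] - 1) < 0.03

    def test_ls_exact_on_quantile_constructed_dwells(self):
        """Noiseless dwells placed at exponential quantiles fit exactly by LS."""
        lam, n = 0.5, 500
        u = (np.arange(1, n + 1) - 0.5) / n
        d = -np.log(1 - u) / lam  # empirical survival equals the model exactly
        fit = fit_exponential_survival(d, n_components=1, method="ls",
                                       n_bootstrap=0, frame_interval_s=1e-9,
                                       min_frames=0)
        assert abs(fit.rates[0] / lam - 1) < 1e-3

    def test_mixture_recovery_core_parameters(self):
        """n = 2000 from the core dissociation mixture: weights within 0.05."""
        d = _dwells([(0.23, 0.72), (1 / 34.2, 0.28)], 2000, seed=3)
        fit = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
        assert abs(fit.weights[0] - 0.72) < 0.05
        assert abs(fit.rates[0] / 0.23 - 1) < 0.15
        assert abs(fit.rates[1] / (1 / 34.2) - 1) < 0.15

    def test_fit_invariants(self):
        d = _dwells([(0.4, 0.6), (0.05, 0.4)], 1000, seed=4)
        fit = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
        assert np.isclose(fit.weights.sum(), 1.0)
        assert fit.rates[0] >= fit.rates[1]
        assert np.allclose(fit.rates * fit.lifetimes, 1.0)

    def test_censored_dwells_enter_likelihood(self):
        """Right-censoring at ~20% biases the MLE rate by <= 2%."""
        rng = np.random.default_rng(5)
        lam = 0.25
        d = rng.exponential(1 / lam, 20_000)
        censor_at = rng.exponential(1 / 0.0625, 20_000)  # ~20% censored
        obs = discretize_durations(np.minimum(d, censor_at), DT)
        cens = censor_at < d
        fit = fit_exponential_survival(obs, cens, n_components=1, n_bootstrap=0)
        assert 0.15 < cens.mean() < 0.25
        assert abs(fit.rates[0] / lam - 1) <= 0.02

    def test_all_censored_raises(self):
        d = _dwells([(0.2, 1.0)], 100, seed=6)
        with pytest.raises(ValueError):
            fit_exponential_survival(d, np.ones(100, bool), n_components=1)

    def test_too_few_dwells_raise(self):
        d = _dwells([(0.2, 1.0)], 10, seed=7)
        with pytest.raises(ValueError):
            fit_exponential_survival(d, n_components=1)

    def test_equal_rate_mixture_flagged_degenerate(self):
        d = _dwells([(0.2, 1.0)], 2000, seed=8)
        fit = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
        assert fit.degenerate

    @pytest.mark.parametrize("ratio", [5.0, 8.0, 15.0])
    @pytest.mark.parametrize("w_fast", [0.3, 0.5, 0.7])
    def test_recovery_grid(self, ratio, w_fast):
        """Median recovery over seeded replicates: rates 10%, weights 0.05."""
        slow, fast = 0.04, 0.04 * ratio
        r_fast, r_slow, ws = [], [], []
        for seed in range(20):
            d = _dwells([(fast, w_fast), (slow, 1 - w_fast)], 2000, seed=100 + seed)
            fit = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
            r_fast.append(fit.rates[0])
            r_slow.append(fit.rates[1])
            ws.append(fit.weights[0])
        assert abs(np.median(r_fast) / fast - 1) < 0.10
        assert abs(np.median(r_slow) / slow - 1) < 0.10
        assert abs(np.median(ws) - w_fast) < 0.05


class TestModelSelection:
    def test_single_rate_data_prefers_one_component(self):
        d = _dwells([(0.24, 1.0)], 2000, seed=9)
        f1 = fit_exponential_survival(d, n_components=1, n_bootstrap=0)
        f2 = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
        assert select_model(f1, f2).n_components == 1

    def test_separated_mixture_prefers_two_components(self):
        d = _dwells([(0.5, 0.6), (0.05, 0.4)], 2000, seed=10)
        f1 = fit_exponential_survival(d, n_components=1, n_bootstrap=0)
        f2 = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
        assert select_model(f1, f2).n_components == 2

    def test_mismatched_dwell_sets_raise(self):
        d1 = _dwells([(0.2, 1.0)], 500, seed=11)
        d2 = _dwells([(0.2, 1.0)], 600, seed=12)
        f1 = fit_exponential_survival(d1, n_components=1, n_bootstrap=0)
        f2 = fit_exponential_survival(d2, n_components=2, n_bootstrap=0)
        with pytest.raises(ValueError):
            select_model(f1, f2)


class TestRateConstants:
    def test_kon_examples(self):
        """kon = 1/(tau * c): 165 s at 16 nM gives 0.379e6 /M/s."""
        assert np.isclose(kon_from_unbound(165.0, 16e-9), 0.3788e6, rtol=1e-3)
        assert np.isclose(kon_from_unbound(100.0, 10e-9), 1.0e6)
        assert np.isclose(kon_from_unbound(49.7, 25e-9), 0.805e6, rtol=1e-3)

    def test_koff_examples(self):
        assert np.isclose(koff_from_bound(34.2), 0.0292, atol=5e-4)
        assert np.isclose(koff_from_bound(1.0), 1.0)
        assert np.isclose(koff_from_bound(24.5), 0.0408, atol=5e-4)

    def test_kd_examples(self):
        """Kd = koff/kon: 0.24 / 0.79e6 is ~300 nM."""
        assert np.isclose(kd_from_rates(0.24, 0.79e6) * 1e9, 304.0, atol=1.0)
        assert np.isclose(kd_from_rates(0.05, 1e6) * 1e9, 50.0)

    def test_dimensional_round_trip(self):
        kon = kon_from_unbound(80.0, 20e-9)
        koff = koff_from_bound(5.0)
        kd = kd_from_rates(koff, kon)
        assert np.isclose(kd, koff / kon)
        assert np.isclose(kon_from_unbound(1 / (kd * kon / koff * 1.0), 1.0), kd * kon / koff)

    @pytest.mark.parametrize("fn,args", [
        (kon_from_unbound, (0.0, 1e-9)),
        (kon_from_unbound, (10.0, -1e-9)),
        (koff_from_bound, (0.0,)),
        (kd_from_rates, (0.0, 1e6)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    def test_bleach_subtraction(self):
        d = _dwells([(0.25, 1.0)], 2000, seed=13)
        fit = fit_exponential_survival(d, n_components=1, n_bootstrap=0)
        corr = subtract_bleach_rate(fit, 1 / 64)
        assert np.isclose(corr.rates[0], fit.rates[0] - 1 / 64)
        assert np.allclose(corr.weights, fit.weights)


class TestHeterogeneity:
    def _fit(self, seed=14):
        d = _dwells([(0.23, 0.72), (1 / 34.2, 0.28)], 3000, seed=seed)
        return fit_exponential_survival(d, n_components=2, n_bootstrap=0)

    def test_short_dwell_molecule_is_fast(self):
        fit = self._fit()
        labels = classify_heterogeneity({"m": np.array([0.4, 0.8, 0.5, 0.9])}, fit)
        assert labels["m"] == "fast"

    def test_single_dwell_is_indeterminate(self):
        fit = self._fit()
        labels = classify_heterogeneity({"m": np.array([5.0])}, fit)
        assert labels["m"] == "indeterminate"

    def test_static_mixture_class_fractions(self):
        """An 80/20 static mixture of well-separated classes is recovered."""
        rng = np.random.default_rng(15)
        fast_rate, slow_rate = 1.4, 0.034
        d = _dwells([(fast_rate, 0.5), (slow_rate, 0.5)], 4000, seed=16)
        fit = fit_exponential_survival(d, n_components=2, n_bootstrap=0)
        mols = {}
        for i in range(400):
            rate = fast_rate if i < 320 else slow_rate
            mols[i] = discretize_durations(rng.exponential(1 / rate, 8), DT)
        labels = classify_heterogeneity(mols, fit)
        vals = np.array(list(labels.values()))
        frac_fast = np.mean(vals == "fast")
        frac_med = np.mean(vals == "medium")
        assert abs(frac_fast - 0.8) < 0.07
        assert abs(frac_med - 0.2) < 0.07


class TestUltrastableDecay:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0, 20.01, 1 / 3)
        decay = TimeLapseDecay(t, 0.69 * np.exp(-t / 69.8))
        fit = fit_ultrastable_decay(decay)
        assert np.isclose(fit.a0, 0.69, atol=1e-6)
        assert np.isclose(fit.lifetime_min, 69.8, atol=1e-3)

    def test_koff_slow_conversion(self):
        t = np.arange(0, 20.01, 1 / 3)
        decay = TimeLapseDecay(t, 0.69 * np.exp(-t / 69.8))
        fit = fit_ultrastable_decay(decay)
        assert np.isclose(fit.koff_slow_per_s, 2.39e-4, atol=2e-6)

    def test_binomial_noise_recovery(self):
        """n0 = 1e4 spots: A0 and lifetime recovered within 5%."""
        tl = simulate_timelapse(10_000, 0.69, 69.8, seed=17)
        fit = fit_ultrastable_decay(TimeLapseDecay(tl.times_min, tl.fractions))
        assert abs(fit.a0 / 0.69 - 1) < 0.05
        assert abs(fit.lifetime_min / 69.8 - 1) < 0.05

    def test_increasing_counts_warn(self):
        t = np.arange(6.0)
        with pytest.warns(UserWarning):
            fit = fit_ultrastable_decay(TimeLapseDecay(t, np.linspace(0.2, 0.6, 6)))
        assert fit.increasing_warning

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_ultrastable_decay(TimeLapseDecay(np.arange(4.0), np.full(4, 0.5)))


class TestFractionAtTime:
    def test_ten_minute_survival(self):
        """0.69 * exp(-10/69.8) is the ~60% retained fraction."""
        assert np.isclose(fraction_at_time(0.69, 69.8, 10.0), 0.598, atol=0.001)

    def test_limits(self):
        assert fraction_at_time(0.69, 69.8, 0.0) == 0.69
        assert np.isclose(fraction_at_time(1.0, 5.0, 5.0), np.exp(-1))
        with pytest.raises(ValueError):
            fraction_at_time(0.5, 0.0, 1.0)
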