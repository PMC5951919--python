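"""FRET efficiencies, histograms, mixture fits and Förster distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smkinetics.fret import (
    ForsterModel,
    FretTrace,
    build_fret_histogram,
    distance_to_fret,
    fit_gaussian_mixture,
    fret_efficiency,
    fret_to_distance,
    transition_density,
)
from smkinetics.simulate import FretState, SimulationConfig, simulate_smfret_trace
from smkinetics.traces import IntensityTrace


def _fret_trace_from_samples(e):
    e = np.asarray(e, dtype=float)
    return FretTrace(e_series=e, valid=np.ones(len(e), bool), frame_interval_s=0.1)


def _hist_from_samples(e, bin_width=0.02):
    return build_fret_histogram([_fret_trace_from_samples(e)],
                                frames_per_trace=len(e), bin_width=bin_width)


class TestFretEfficiency:
    def test_simple_ratio(self):
        tr = IntensityTrace(0.1, np.full(20, 70.0), np.full(20, 30.0))
        ft = fret_efficiency(tr, bleach_frame=None)
        assert np.allclose(ft.e_series[ft.valid], 0.30)

    def test_background_correction(self):
        tr = IntensityTrace(0.1, np.full(20, 170.0), np.full(20, 130.0),
                            background_donor=100.0, background_acceptor=100.0)
        ft = fret_efficiency(tr)
        assert np.allclose(ft.e_series[ft.valid], 0.30)

    def test_zero_acceptor_gives_zero(self):
        tr = IntensityTrace(0.1, np.full(20, 100.0), np.zeros(20))
        ft = fret_efficiency(tr)
        assert np.allclose(ft.e_series[ft.valid], 0.0)

    def test_frames_after_bleach_invalid(self):
        donor = np.r_[np.full(50, 300.0), np.zeros(50)]
        acceptor = np.r_[np.full(50, 300.0), np.zeros(50)]
        tr = IntensityTrace(0.1, donor, acceptor)
        ft = fret_efficiency(tr)
        assert ft.n_valid == 50
        assert not ft.valid[50:].any()

    def test_nonpositive_denominator_invalid(self):
        donor = np.full(20, 50.0)
        donor[3] = -60.0
        tr = IntensityTrace(0.1, donor, np.full(20, 50.0))
        ft = fret_efficiency(tr, bleach_frame=None)
        assert not ft.valid[3]


class TestHistogram:
    def test_count_conservation(self):
        """Pooled counts equal sum over traces of min(50, valid frames)."""
        rng = np.random.default_rng(0)
        traces = [_fret_trace_from_samples(rng.normal(0.5, 0.1, n))
                  for n in (30, 50, 80, 200)]
        hist = build_fret_histogram(traces, frames_per_trace=50)
        assert hist.n_samples == 30 + 50 + 50 + 50
        assert hist.counts.sum() == hist.n_samples

    def test_constant_efficiency_occupies_one_bin(self):
        hist = _hist_from_samples(np.full(500, 0.41))
        assert (hist.counts > 0).sum() == 1

    def test_three_state_bin_masses_match_weights(self):
        """Bin mass per component matches generator weights (multinomial err)."""
        cfg = SimulationConfig(
            n_frames=50, noise_sd=0.0, intensity_on=600.0,
            bleach_lifetime_cy5_s=1e9, bleach_lifetime_cy3_s=1e9,
            fret_states=(FretState(0.52, 0.05, 0.60), FretState(0.09, 0.05, 0.30),
                         FretState(0.92, 0.03, 0.10)),
        )
        pooled = []
        for seed in range(200):
            _, gt = simulate_smfret_trace(cfg, seed=seed)
            pooled.append(gt.e_true)
        e = np.concatenate(pooled)
        n = len(e)
        for mean, weight in [(0.52, 0.60), (0.09, 0.30), (0.92, 0.10)]:
            mass = np.mean(np.abs(e - mean) < 0.2)
            # molecule-level assignment: 200 molecules, binomial in molecules
            se = np.sqrt(weight * (1 - weight) / 200)
            assert abs(mass - weight) < 4 * se


class TestGaussianMixture:
    def test_single_gaussian_recovery(self):
        """n = 5000 samples from N(0.28, 0.13) recover the mean to 0.01."""
        rng = np.random.default_rng(12)
        hist = _hist_from_samples(rng.normal(0.28, 0.13, 5000))
        fit = fit_gaussian_mixture(hist, 1)
        assert fit.converged
        assert abs(fit.means[0] - 0.28) < 0.01
        assert abs(fit.sds[0] - 0.13) < 0.02

    def test_two_delta_fractions_exact(self):
        """Two narrow peaks at 0.1 (90%) and 0.9 (10%) split exactly."""
        rng = np.random.default_rng(21)
        e = np.r_[rng.normal(0.10, 0.02, 1800), rng.normal(0.90, 0.02, 200)]
        hist = _hist_from_samples(e)
        fit = fit_gaussian_mixture(hist, 2)
        assert fit.converged
        assert np.allclose(fit.fractions, [0.9, 0.1], atol=0.01)
        assert abs(fit.means[0] - 0.10) < 0.02
        assert abs(fit.means[1] - 0.90) < 0.02

    def test_three_state_recovery_major_mean(self):
        """Core-riboswitch-like histogram: major mean within 0.02 of 0.52."""
        rng = np.random.default_rng(3)
        comp = rng.choice(3, size=10_000, p=[0.90, 0.09, 0.01])
        means = np.array([0.52, 0.09, 0.92])[comp]
        sds = np.array([0.12, 0.12, 0.07])[comp]
        hist = _hist_from_samples(np.clip(rng.normal(means, sds), -0.2, 1.2))
        fit = fit_gaussian_mixture(hist, 3)
        assert fit.converged
        assert abs(fit.major_mean - 0.52) < 0.02
        assert np.isclose(fit.fractions.sum(), 1.0, atol=1e-6)

    def test_self_consistency_refit(self):
        """Refitting a histogram synthesized from the fit reproduces it."""
        rng = np.random.default_rng(5)
        hist = _hist_from_samples(rng.normal(0.4, 0.1, 4000))
        fit = fit_gaussian_mixture(hist, 1)
        synth = rng.normal(fit.means[0], fit.sds[0], 100_000)
        refit = fit_gaussian_mixture(_hist_from_samples(synth), 1)
        assert abs(refit.means[0] - fit.means[0]) < 0.005
        assert abs(refit.sds[0] - fit.sds[0]) < 0.005

    def test_too_few_occupied_bins_raise(self):
        hist = _hist_from_samples(np.full(100, 0.5))
        with pytest.raises(ValueError):
            fit_gaussian_mixture(hist, 2)


class TestForsterDistance:
    @pytest.mark.parametrize(
        "e,expected",
        [(0.5, 54.0), (0.28, 63.2), (0.85, 40.4), (0.92, 35.9)],
    )
    def test_distance_inversion(self, e, expected):
        assert abs(fret_to_distance(e) - expected) < 0.05

    def test_distance_to_fret(self):
        assert np.isclose(distance_to_fret(54.0), 0.5)
        assert abs(distance_to_fret(63.2) - 0.28) < 0.001
        # monotone decay to zero at large distance
        rs = np.linspace(60, 200, 50)
        es = np.array([distance_to_fret(r) for r in rs])
        assert (np.diff(es) < 0).all() and es[-1] < 0.01

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fret_to_distance(bad)
        with pytest.raises(ValueError):
            distance_to_fret(-1.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_round_trip_identity(self, e):
        """distance -> efficiency inverts exactly across the working range."""
        assert abs(distance_to_fret(fret_to_distance(e)) - e) < 1e-9

    def test_custom_r0(self):
        model = ForsterModel(r0=60.0)
        assert np.isclose(fret_to_distance(0.5, model), 60.0)
        with pytest.raises(ValueError):
            ForsterModel(r0=-1.0)


class TestTransitionDensity:
    def test_static_traces_empty(self):
        counts, _ = transition_density([np.full(100, 0.5), np.full(50, 0.1)])
        assert counts.sum() == 0

    def test_alternating_trace_two_peaks(self):
        seq = np.tile([0.52, 0.92], 10)  # 19 transitions
        counts, edges = transition_density([seq], bin_width=0.05)
        assert counts.sum() == 19
        i52 = np.searchsorted(edges, 0.52) - 1
        i92 = np.searchsorted(edges, 0.92) - 1
        assert counts[i52, i92] == 10
        assert counts[i92, i52] == 9

    def test_dynamic_subpopulation_peaks_at_state_means(self):
        """Hopping molecules put density at the generator state means."""
        cfg = SimulationConfig(
            n_frames=2000, noise_sd=0.0,
            fret_states=(FretState(0.52, 0.0, 0.5), FretState(0.92, 0.0, 0.5)),
            fret_transition_rate_per_s=0.5,
            bleach_lifetime_cy5_s=1e9, bleach_lifetime_cy3_s=1e9,
        )
        seqs = []
        for seed in range(10):
            _, gt = simulate_smfret_trace(cfg, seed=seed)
            means = np.array([0.52, 0.92])[gt.fret_state_seq]
            seqs.append(means)
        counts, edges = transition_density(seqs, bin_width=0.02)
        assert counts.sum() > 100
        b, a = np.unravel_index(np.argmax(counts), counts.shape)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert min(abs(centers[b] - 0.52), abs(centers[b] - 0.92)) < 0.02
        assert min(abs(centers[a] - 0.52), abs(centers[a] - 0.92)) < 0.02
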