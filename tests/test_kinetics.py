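"""Survival distributions, rate-spectrum inference, bound fractions."""

import math

import numpy as np
import pytest

from smtrack import kinetics
from smtrack.kinetics import SurvivalDistribution

from conftest import make_track, make_trackset

FIVE_RATES = np.array([3e-3, 2e-2, 0.2, 1.3, 10.0])
FIVE_FREQS = np.array([0.03, 0.06, 0.13, 0.26, 0.52])


def sampled_survivals(rng, rates, freqs, a, n_births,
                      taus=(0.05, 0.3, 1.5, 5.0),
                      nmin=None):
    """Synthetic survival distributions: exponential lifetimes from a rate
    mixture, geometric per-frame loss, per-condition minimum span."""
    nmin = nmin or {0.05: 3, 0.3: 2, 1.5: 2, 5.0: 2}
    out = []
    for tau in taus:
        ks = rng.choice(rates, size=n_births, p=freqs)
        m = np.minimum(np.floor(rng.exponential(1.0 / ks) / tau).astype(int) + 1,
                       rng.geometric(a, size=n_births))
        m = m[m >= nmin[tau]]
        out.append(SurvivalDistribution(tau_tl=tau, durations_s=(m - 1) * tau,
                                        min_span_frames=nmin[tau]))
    return out


class TestBuildSurvival:
    def test_counting_function(self):
        s = SurvivalDistribution(1.0, [1.0, 1.0, 2.0, 5.0],
                                 min_span_frames=1)
        assert s.counts([1.0, 2.0, 5.0]).tolist() == [4, 2, 1]
        assert s.counts(0.0)[0] == s.n_tracks

    def test_from_tracksets(self):
        trs = [make_track(range(n), [(0, 0)] * n, track_id=n)
               for n in (2, 3, 5)]
        ts = make_trackset(trs, tau=1.0)
        survs = kinetics.build_survival({1.0: [ts]}, min_span_frames=2)
        assert survs[0].n_tracks == 3
        assert survs[0].durations_s.tolist() == [1.0, 2.0, 4.0]

    def test_exponential_slope(self):
        """ln N(>=t) of k=0.2/s lifetimes decays with slope -0.2."""
        rng = np.random.default_rng(0)
        k, tau = 0.2, 1.0
        durations = (np.floor(rng.exponential(1 / k, 10_000) / tau)) * tau
        s = SurvivalDistribution(tau, durations, min_span_frames=1)
        t = np.arange(0, 15.0, tau)
        logn = np.log(s.counts(t))
        # discrete sampling: slope of log-geometric = ln p per frame
        slope = np.polyfit(t, logn, 1)[0]
        expect = math.log(math.exp(-k * tau))
        assert slope == pytest.approx(expect, rel=0.1)

    def test_empty_condition_flagged(self):
        survs = kinetics.build_survival({1.0: []})
        assert survs[0].is_empty


class TestGridSpectrum:
    def test_single_rate_recovery(self):
        """One k=0.2/s population with 1% bleaching: >= 80% of the weight
        lands within half a decade of the truth and the loss is found."""
        rng = np.random.default_rng(1)
        survs = sampled_survivals(rng, [0.2], [1.0], 0.01, 4000)
        spec = kinetics.grid_spectrum(survs)
        sel = (spec.rates >= 0.2 / math.sqrt(10)) & (spec.rates <= 0.2 * math.sqrt(10))
        assert spec.weights[sel].sum() >= 0.8
        assert spec.per_frame_loss == pytest.approx(0.01, abs=0.01)

    def test_five_rate_recovery_from_sampled_survivals(self):
        rng = np.random.default_rng(2)
        survs = sampled_survivals(rng, FIVE_RATES, FIVE_FREQS, 0.02, 4000)
        spec = kinetics.grid_spectrum(survs)
        assert all(kinetics.clusters_recovered(spec, FIVE_RATES))

    def test_refit_idempotence(self):
        """Survivals regenerated exactly from a one-rate model refit to the
        same spectrum (weights within 1e-3 in total variation; the ridge
        term is off since it deliberately blurs exact spikes)."""
        k0 = float(kinetics.default_rate_grid()[30])  # exactly on the grid
        taus = (0.3, 1.5, 5.0)
        survs = []
        for tau in taus:
            # deterministic counting data following the pure model
            m = np.arange(2, 120)
            counts = np.round(5e6 * np.exp(-k0 * (m - 1) * tau)).astype(int)
            durations = np.repeat((m - 1) * tau, np.maximum(np.diff(
                -np.concatenate([counts, [0]])), 0))
            survs.append(SurvivalDistribution(tau, durations,
                                              min_span_frames=2))
        spec1 = kinetics.grid_spectrum(survs, per_frame_loss=0.0,
                                       regularization=0.0)
        assert np.abs(spec1.weights).argmax() == 30
        # regenerate survivals from the fitted spectrum and refit
        survs2 = []
        for tau in taus:
            m = np.arange(2, 120)
            model = np.zeros(len(m), dtype=float)
            for w, k in zip(spec1.weights, spec1.rates):
                model += w * np.exp(-k * (m - 1) * tau)
            counts = np.round(5e6 * model).astype(int)
            durations = np.repeat((m - 1) * tau, np.maximum(np.diff(
                -np.concatenate([counts, [0]])), 0))
            survs2.append(SurvivalDistribution(tau, durations,
                                               min_span_frames=2))
        spec2 = kinetics.grid_spectrum(survs2, per_frame_loss=0.0,
                                       regularization=0.0)
        assert np.abs(spec1.weights - spec2.weights).sum() < 1e-3

    def test_weights_normalized_nonnegative(self):
        rng = np.random.default_rng(3)
        survs = sampled_survivals(rng, [0.05, 1.0], [0.5, 0.5], 0.02, 2000)
        spec = kinetics.grid_spectrum(survs)
        assert np.all(spec.weights >= 0)
        assert spec.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            kinetics.grid_spectrum([SurvivalDistribution(1.0, [])])


class TestResampling:
    def test_zero_resamples_empty(self):
        rng = np.random.default_rng(4)
        survs = sampled_survivals(rng, [0.2], [1.0], 0.02, 500)
        env = kinetics.resample_spectrum(survs, n_resamples=0)
        assert env.shape[0] == 0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        survs = sampled_survivals(rng, [0.2], [1.0], 0.02, 800)
        e1 = kinetics.resample_spectrum(survs, n_resamples=5, seed=42)
        e2 = kinetics.resample_spectrum(survs, n_resamples=5, seed=42)
        assert np.array_equal(e1, e2)

    def test_envelope_median_close_to_full_fit(self):
        """Median resampled spectrum stays within total variation 0.1 of
        the full-data spectrum."""
        rng = np.random.default_rng(6)
        survs = sampled_survivals(rng, FIVE_RATES, FIVE_FREQS, 0.02, 4000)
        spec = kinetics.grid_spectrum(survs)
        env = kinetics.resample_spectrum(survs, n_resamples=19, seed=7)
        med = np.median(env, axis=0)
        med = med / med.sum()
        assert 0.5 * np.abs(med - spec.weights).sum() < 0.1


class TestClusterWeights:
    def test_full_grid_conserves_weight(self):
        rng = np.random.default_rng(8)
        survs = sampled_survivals(rng, [0.2], [1.0], 0.02, 1000)
        spec = kinetics.grid_spectrum(survs)
        w = kinetics.cluster_weights(spec, [(1e-5, 1e3)])
        assert w[0] == pytest.approx(100.0)

    def test_empty_interval_zero(self):
        rng = np.random.default_rng(9)
        survs = sampled_survivals(rng, [0.2], [1.0], 0.02, 1000)
        spec = kinetics.grid_spectrum(survs)
        assert kinetics.cluster_weights(spec, [(1e3, 1e4)])[0] == 0.0

    def test_five_state_weights_near_truth(self):
        """Cluster weights within +/- 5 points of the birth-state mixture."""
        rng = np.random.default_rng(10)
        survs = sampled_survivals(rng, FIVE_RATES, FIVE_FREQS, 0.02, 16_000)
        spec = kinetics.grid_spectrum(survs)
        half = math.sqrt(10)
        intervals = [(k / half, k * half) for k in FIVE_RATES]
        w = kinetics.cluster_weights(spec, intervals)
        for wi, fi in zip(w, 100 * FIVE_FREQS):
            assert abs(wi - fi) <= 5.0


class TestBoundFractions:
    def test_arithmetic_example(self):
        """N_long=10, N_short=30, 60 singles: BF=0.4, BF_long=0.25."""
        tracks = []
        tid = 0
        for _ in range(10):  # long bound: spans a dark period (2 bursts)
            tracks.append(make_track([0, 1, 2], [(0, 0)] * 3, track_id=tid))
            tid += 1
        for _ in range(30):  # short bound: one full burst
            tracks.append(make_track([0, 1], [(0, 0)] * 2, track_id=tid))
            tid += 1
        for _ in range(60):  # unbound: single detections
            tracks.append(make_track([0], [(0, 0)], track_id=tid))
            tid += 1
        ts = make_trackset(tracks)
        res = kinetics.itm_bound_fractions([ts], frames_per_burst=2)
        assert res.bf == pytest.approx(0.4)
        assert res.bf_long == pytest.approx(0.25)

    def test_all_single_detections(self):
        ts = make_trackset([make_track([0], [(0, 0)], track_id=i)
                            for i in range(5)])
        res = kinetics.itm_bound_fractions([ts])
        assert res.bf == 0.0

    def test_pooled_vs_mean_with_unequal_movies(self):
        ts_big = make_trackset(
            [make_track([0, 1, 2], [(0, 0)] * 3, track_id=i) for i in range(9)]
            + [make_track([0], [(0, 0)], track_id=9)])
        ts_small = make_trackset([make_track([0], [(0, 0)], track_id=0)])
        res = kinetics.itm_bound_fractions([ts_big, ts_small])
        assert res.bf == pytest.approx(9 / 11)  # pooled over summed counts
        assert res.bf_mean == pytest.approx((0.9 + 0.0) / 2)

    def test_simulated_itm_classification(self):
        """Two-state ITM simulation: pooled BF_long within 3 binomial s.e.
        of the fraction of molecules that survive a dark period."""
        import pandas as pd

        from smtrack import linking, simulate

        k_long, k_short = 0.05, 5.0
        frac_long = 0.3
        scen = simulate.SimScenario(
            molecules_per_frame=3,
            states=[simulate.BindingState(k_long, frac_long),
                    simulate.BindingState(k_short, 1 - frac_long)],
            bleach_prob_per_frame=0.001,
            timelapse_conditions=[1.0], n_frames=200)
        # interlaced scheme: bursts of 2 frames 0.05 s apart, 5 s dark
        burst_starts = np.arange(100) * 5.0
        frame_times = np.ravel([burst_starts, burst_starts + 0.05], order="F")
        rng = np.random.default_rng(11)
        tss = []
        n_long_true = n_bound_true = 0
        for _ in range(4):
            trajs = simulate.simulate_trajectories(
                scen, 0, rng_seed=rng, frame_times=frame_times)
            locs = simulate.sample_localizations(trajs, 0.02, rng_seed=rng)
            params = linking.TrackingParams(tracking_radius_um=0.5)
            tss.append(linking.nearest_neighbour_link(locs, params, 1.0))
            for t in trajs:
                if t.n_frames >= 2:
                    n_bound_true += 1
                    if t.frames[-1] // 2 > t.frames[0] // 2:
                        n_long_true += 1
        res = kinetics.itm_bound_fractions(tss, frames_per_burst=2)
        truth = n_long_true / n_bound_true
        se = math.sqrt(truth * (1 - truth) / n_bound_true)
        assert abs(res.bf_long - truth) <= 3 * se + 0.02
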