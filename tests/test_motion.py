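"""Jump statistics, diffusion fits, confinement, angles, maps, traces."""

import math

import numpy as np
import pytest

from smtrack import motion, simulate
from smtrack.linking import TrackingParams, TrackSet

from conftest import make_track, make_trackset


def brownian_track(rng, d, tau, n, start=(0.0, 0.0), track_id=0):
    steps = rng.normal(0, math.sqrt(2 * d * tau), (n - 1, 2))
    pos = np.concatenate([[start], start + np.cumsum(steps, axis=0)])
    return make_track(range(n), pos, track_id=track_id)


def sample_truncated_jumps(rng, d_values, amps, tau, n, c2_um2):
    """Mixture of Brownian jump vectors with |r| truncated at the radius."""
    out = np.empty((n, 2))
    comp = rng.choice(len(d_values), size=n, p=amps)
    s_max = math.sqrt(c2_um2)
    for i in range(n):
        d = d_values[comp[i]]
        while True:
            v = rng.normal(0, math.sqrt(2 * d * tau), 2)
            if math.hypot(*v) <= s_max:
                out[i] = v
                break
    return out


class TestJumpHistogram:
    def test_immobile_track_first_bin(self):
        tr = make_track(range(10), [(1.0, 1.0)] * 10)
        counts, edges = motion.jump_histogram(make_trackset([tr]), 0.05)
        assert counts[0] == 9 and counts.sum() == 9

    def test_one_jump_per_track_counts_tracks(self):
        trs = [make_track(range(5), [(i, 0.0)] * 5, track_id=i)
               for i in range(4)]
        ts = make_trackset(trs)
        counts, _ = motion.jump_histogram(ts, 0.1, jumps_per_track=1)
        assert counts.sum() == 4

    def test_mode_near_rayleigh_peak(self):
        """Brownian jumps peak near sqrt(2 D tau * 2)."""
        rng = np.random.default_rng(0)
        d, tau = 1.0, 0.05
        trs = [brownian_track(rng, d, tau, 100, track_id=i) for i in range(100)]
        ts = make_trackset(trs, tau=tau)
        bin_size = 0.02
        counts, edges = motion.jump_histogram(ts, bin_size)
        mode = edges[np.argmax(counts)] + bin_size / 2
        assert mode == pytest.approx(math.sqrt(2 * d * tau), abs=2 * bin_size)

    def test_gap_jumps_omitted(self):
        tr = make_track([0, 1, 3], [(0, 0), (0.1, 0), (0.2, 0)],
                        gap_flags=[False, False, True])
        counts, _ = motion.jump_histogram(make_trackset([tr]), 0.05)
        assert counts.sum() == 1


class TestCumulativeJumpFit:
    def test_single_population_recovery(self):
        rng = np.random.default_rng(1)
        d, tau = 0.5, 0.05
        c2 = 10 * 4 * d * tau  # generous truncation
        jumps = sample_truncated_jumps(rng, [d, d], [0.5, 0.5], tau, 10_000,
                                       c2 * 4 * tau)
        fit = motion.fit_cumulative_jumps(jumps, 2, tau=tau, c2=c2)
        # amplitudes are split arbitrarily between equal components; the
        # faster component carries the recovered D
        d_eff = float(np.dot(fit.amplitudes, fit.diffusion_coeffs))
        assert d_eff == pytest.approx(d, rel=0.10)

    def test_two_population_recovery_with_truncation(self):
        """D = 0.01/1.0 µm²/s at A1 = 0.4 recovered within 15% / 0.05 from
        1e4 radius-truncated jumps."""
        rng = np.random.default_rng(2)
        tau = 0.05
        s = 0.6  # µm tracking radius
        c2 = s**2 / (4 * tau)
        jumps = sample_truncated_jumps(rng, [0.01, 1.0], [0.4, 0.6], tau,
                                       10_000, s**2)
        fit = motion.fit_cumulative_jumps(jumps, 2, tau=tau, c2=c2)
        assert fit.diffusion_coeffs[0] == pytest.approx(0.01, rel=0.15)
        assert fit.diffusion_coeffs[1] == pytest.approx(1.0, rel=0.15)
        assert fit.amplitudes[0] == pytest.approx(0.4, abs=0.05)
        assert fit.adj_r_squared > 0.99

    def test_truncation_limit_matches_untruncated_model(self):
        """With C2 -> inf the truncated model reduces to the plain mixture."""
        x = np.linspace(0.001, 5.0, 200)
        params = {"a1": 0.4, "d1": 0.05, "d2": 1.0}
        trunc = motion._cumulative_model(x, params, 2, 0.0, 1e12)
        plain = (0.4 * (1 - np.exp(-x / 0.05))
                 + 0.6 * (1 - np.exp(-x / 1.0)))
        assert np.allclose(trunc, plain, atol=1e-9)

    def test_omitting_truncation_inflates_d(self):
        """Fitting truncated jumps without the cutoff term biases D up
        relative to the truncation-aware fit (the term's purpose)."""
        rng = np.random.default_rng(3)
        tau = 0.05
        s = 0.35
        d_true = 1.0
        jumps = sample_truncated_jumps(rng, [0.01, d_true], [0.3, 0.7], tau,
                                       8000, s**2)
        with_term = motion.fit_cumulative_jumps(
            jumps, 2, tau=tau, c2=s**2 / (4 * tau))
        without = motion.fit_cumulative_jumps(jumps, 2, tau=tau, c2=1e9)
        assert with_term.diffusion_coeffs[1] == pytest.approx(d_true, rel=0.2)
        assert without.diffusion_coeffs[1] < with_term.diffusion_coeffs[1]

    def test_too_few_jumps_rejected(self):
        with pytest.raises(ValueError):
            motion.fit_cumulative_jumps(np.ones((5, 2)), 2, tau=0.05, c2=1.0)


class TestConfinement:
    def test_confined_radius_recovery(self):
        """Reflecting-disc diffusion: R recovered within 20%."""
        rng = np.random.default_rng(4)
        R, d, tau, n = 0.2, 0.05, 0.01, 1000
        pos = np.zeros((n, 2))
        p = np.zeros(2)
        for i in range(1, n):
            step = rng.normal(0, math.sqrt(2 * d * tau), 2)
            q = p + step
            r = math.hypot(*q)
            if r > R:  # reflect at the circular boundary
                q *= (2 * R - r) / r
            p = q
            pos[i] = p
        tr = make_track(range(n), pos)
        res = motion.msd_and_confinement(tr, tau, alpha_threshold=0.7)
        assert res.confined
        assert res.R == pytest.approx(R, rel=0.2)

    def test_free_diffusion_mostly_not_confined(self):
        """Free Brownian tracks have alpha ~ 1; the single-track estimate is
        noisy, so test the ensemble: mean alpha near 1 and a large majority
        classified as unconfined at threshold 0.7."""
        rng = np.random.default_rng(5)
        results = [motion.msd_and_confinement(
            brownian_track(rng, 1.0, 0.05, 400), 0.05, alpha_threshold=0.7)
            for _ in range(20)]
        alphas = [r.alpha for r in results]
        assert np.mean(alphas) == pytest.approx(1.0, abs=0.15)
        assert np.mean([not r.confined for r in results]) >= 0.8

    def test_plateau_is_r_squared_plus_offset(self):
        """Large-lag limit of the confined-circle model."""
        R, offset = 0.3, 0.01
        t = np.array([1e6])
        msd_inf = R**2 * (1 - np.exp(-4 * 1.0 * t / R**2)) + offset
        assert msd_inf[0] == pytest.approx(R**2 + offset)

    def test_short_track_rejected(self):
        tr = make_track(range(4), [(0, 0)] * 4)
        with pytest.raises(ValueError):
            motion.msd_and_confinement(tr, 0.05)


class TestJumpAngles:
    def test_collinear_zero_degrees(self):
        tr = make_track(range(3), [(1, 0), (2, 0), (3, 0)])
        angles = motion.jump_angles(make_trackset([tr]))
        assert angles.tolist() == [0.0]

    def test_reversal_180_degrees(self):
        tr = make_track(range(3), [(0, 0), (1, 0), (0, 0)])
        angles = motion.jump_angles(make_trackset([tr]))
        assert angles.tolist() == [180.0]

    def test_gap_adjacent_angles_omitted(self):
        tr = make_track([0, 1, 3, 4],
                        [(0, 0), (1, 0), (2, 0), (3, 0)],
                        gap_flags=[False, False, True, False])
        assert len(motion.jump_angles(make_trackset([tr]))) == 0

    def test_brownian_angles_uniform(self):
        """Isotropy: chi-square test against uniform over 18 bins."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(6)
        trs = [brownian_track(rng, 1.0, 0.05, 200, track_id=i)
               for i in range(60)]
        angles = motion.jump_angles(make_trackset(trs))
        assert len(angles) > 10_000
        # P(angle in [a, a+da]) is uniform for isotropic jumps
        counts, _ = np.histogram(angles, bins=18, range=(0, 180))
        assert chisquare(counts).pvalue > 0.01


class TestMaps:
    def test_localization_map_counts(self, locs_factory):
        locs = locs_factory([0, 1, 2], [(0.08, 0.08)] * 3)  # same pixel
        hm = motion.localization_map(locs, (10, 10), 0.16)
        assert hm.grid.sum() == 3
        assert hm.grid[0, 0] == 3

    def test_upscale_preserves_total(self, locs_factory):
        rng = np.random.default_rng(7)
        locs = locs_factory(range(50), rng.uniform(0, 1.6, (50, 2)))
        h1 = motion.localization_map(locs, (10, 10), 0.16, scale=1)
        h2 = motion.localization_map(locs, (10, 10), 0.16, scale=2)
        assert h1.grid.sum() == h2.grid.sum() == 50

    def test_jump_map_single_jump_uniform_value(self):
        tr = make_track([0, 1], [(0.1, 0.1), (1.3, 0.9)])
        ts = make_trackset([tr])
        hm = motion.jump_distance_map(ts, (10, 10), 0.16)
        length = math.hypot(1.2, 0.8)
        touched = hm.grid[hm.grid > 0]
        assert len(touched) >= 5
        assert np.allclose(touched, length)


class TestIntensityTrace:
    def test_flat_then_drop_after_bleach(self):
        """Constant synthetic spot: flat trace during the track, drop to
        background in the 20-frame tail."""
        n_on, n_total = 10, 40
        stack = np.full((n_total, 32, 32), 100.0)
        for f in range(n_on):
            stack[f, 15, 15] += 90.0
        tr = make_track(range(n_on), [(15 * 0.16, 15 * 0.16)] * n_on)
        frames, trace, kx, ky = motion.intensity_trace(stack, tr, 0.16)
        assert len(frames) == n_on + 20
        assert np.allclose(trace[:n_on], 100.0 + 90.0 / 9)
        assert np.allclose(trace[n_on:], 100.0)
        assert kx.shape[0] == n_on + 20

    def test_tail_clipped_at_movie_end(self):
        stack = np.zeros((12, 16, 16))
        tr = make_track(range(10), [(1.0, 1.0)] * 10)
        frames, trace, _, _ = motion.intensity_trace(stack, tr, 0.16)
        assert frames[-1] == 11

    def test_window_mean_arithmetic(self):
        """3x3 window on a single bright pixel: (spot + 8 bg)/9."""
        stack = np.full((1, 16, 16), 10.0)
        stack[0, 8, 8] = 100.0
        tr = make_track([0], [(8 * 0.16, 8 * 0.16)])
        _, trace, _, _ = motion.intensity_trace(stack, tr, 0.16)
        assert trace[0] == pytest.approx((100 + 8 * 10) / 9)
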