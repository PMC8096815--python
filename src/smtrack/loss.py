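"""Tracking-loss theory for nearest-neighbour linking of immobile molecules.

Per frame, a track of a bound molecule is falsely terminated either because
the apparent jump (diffusion + localization error) exceeds the tracking
radius s, or because a nearby detection is erroneously linked instead.  With
the effective squared jump distance

    sigma^2(tau) = sigma0^2 + 4 D tau

and the dimensionless radius z = s^2 / sigma^2, the out-of-radius loss is
a_z = exp(-z) and the erroneous-link loss in the low-density expansion is
a_NN = 0.76 * pi * rho * sigma^2 with rho the spot density per frame.
Allowing one gap frame recovers a fraction f (at most 0.5) of the
out-of-radius losses, giving the total per-frame loss

    a_tr = a_NN + a_z * (1 - f) * (1 - a_NN).

The gap-recovery fraction is a correlated bivariate Gaussian integral over
the two consecutive apparent jumps; their correlation c = -sigma0^2 /
(2 sigma^2) arises because the shared localization error of the middle
(undetected) position enters both jumps with opposite sign.  This module
evaluates that integral deterministically and inverts the loss model for the
tracking radius that achieves a user-chosen loss probability, using the
empirical (radius-truncated) jump variance of the data at each iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.laguerre import laggauss
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import erf as _erf

__all__ = [
    "MotionNoiseModel",
    "LossBudget",
    "RadiusCalibration",
    "effective_sigma_sq",
    "out_of_radius_prob",
    "erroneous_link_prob",
    "erroneous_link_coefficient_mc",
    "jump_correlation",
    "gap_recovery_fraction",
    "gap_recovery_fraction_mc",
    "total_loss_prob",
    "min_bound_track_length",
    "radius_for_loss",
    "measure_tracking_loss",
]

ERRONEOUS_LINK_COEFF = 0.76


@dataclass(frozen=True)
class MotionNoiseModel:
    """Effective jump statistics of a bound molecule."""

    sigma0_sq: float  # µm², squared localization error (jump contribution)
    D: float  # µm²/s
    tau_tl: float  # s

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be > 0")
        if self.D < 0 or self.tau_tl <= 0:
            raise ValueError("D must be >= 0 and tau_tl > 0")

    @property
    def sigma_sq(self) -> float:
        return effective_sigma_sq(self.sigma0_sq, self.D, self.tau_tl)

    @property
    def jump_corr(self) -> float:
        return jump_correlation(self.sigma0_sq, self.sigma_sq)


@dataclass(frozen=True)
class LossBudget:
    """All per-frame loss quantities for one (s, sigma^2, rho) setting."""

    s: float  # µm
    sigma_sq: float  # µm²
    rho: float  # spots / µm² / frame
    z: float
    a_z: float
    a_nn: float
    f: float
    a_gap: float  # unconditional final out-of-radius loss with one gap frame
    a_tr: float


def effective_sigma_sq(sigma0_sq: float, D: float, tau_tl: float) -> float:
    """sigma^2(tau) = sigma0^2 + 4 D tau, the mean squared apparent jump."""
    if sigma0_sq < 0 or D < 0 or tau_tl < 0:
        raise ValueError("inputs must be >= 0")
    return sigma0_sq + 4.0 * D * tau_tl


def out_of_radius_prob(s: float, sigma_sq: float) -> float:
    """Probability exp(-s^2/sigma^2) that one apparent jump exceeds s."""
    if s < 0:
        raise ValueError("s must be >= 0")
    return math.exp(-(s * s) / sigma_sq)


def erroneous_link_prob(rho: float, sigma_sq: float,
                        coeff: float = ERRONEOUS_LINK_COEFF) -> float:
    """Erroneous-link loss a_NN = coeff * pi * rho * sigma^2 (low-density
    expansion), clipped to 1.  Warns when the expansion leaves its domain
    of validity (a_NN > 0.5)."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    a = coeff * math.pi * rho * sigma_sq
    if a > 0.5:
        import warnings

        warnings.warn("a_NN > 0.5: small-density expansion invalid")
    return min(a, 1.0)


def erroneous_link_coefficient_mc(
    n_samples: int = 10_000_000,
    seed: int | np.random.Generator = 0,
    window_halfwidth: float = 6.0,
    chunk: int = 2_000_000,
) -> tuple[float, float]:
    """Monte-Carlo evaluation of the erroneous-link integral's dimensionless
    coefficient a_NN / (pi rho sigma^2).

    Two consecutive apparent jumps r1, r2 are drawn from the radially
    symmetric density p(r) = exp(-r^2/sigma^2)/(pi sigma^2); the disturbing
    spot is uniform in a window large relative to sigma.  A configuration is
    a final loss when the disturber is closer to the expected position than
    the true detection (|r1| > |r#|) and the follow-up detection is closer to
    the disturbed new track than to the erroneously linked one
    (|r1 + r2 - r#| > |r2|).  Returns (coefficient, standard error).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    L = window_halfwidth
    hits = 0
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        r1 = rng.normal(0.0, math.sqrt(0.5), (m, 2))
        r2 = rng.normal(0.0, math.sqrt(0.5), (m, 2))
        rh = rng.uniform(-L, L, (m, 2))
        cond = ((np.hypot(r1[:, 0], r1[:, 1]) > np.hypot(rh[:, 0], rh[:, 1]))
                & (np.hypot(*(r1 + r2 - rh).T) > np.hypot(r2[:, 0], r2[:, 1])))
        hits += int(cond.sum())
        done += m
    p = hits / n_samples
    area = (2.0 * L) ** 2
    coeff = area * p / math.pi
    se = area * math.sqrt(p * (1.0 - p) / n_samples) / math.pi
    return coeff, se


def jump_correlation(sigma0_sq: float, sigma_sq: float) -> float:
    """Correlation c of two consecutive apparent jumps.

    The middle detection's localization error enters both jumps with
    opposite sign, giving c = -sigma0^2 / (2 sigma^2) in (-1/2, 0]."""
    if sigma_sq < sigma0_sq:
        raise ValueError("sigma_sq must be >= sigma0_sq")
    return -sigma0_sq / (2.0 * sigma_sq)


# --- gap-recovery integral ---------------------------------------------------

def _recovery_prob_given_u(u: np.ndarray, s: float, c: float, sigma_sq: float,
                           n_leg: int = 160) -> np.ndarray:
    """P(recovery | first jump length u > s) under the correlated model.

    Conditional on r1 = (u, 0), the second jump r2 is Gaussian with mean
    c*r1 and per-axis variance (1-c^2) sigma^2/2, so the return position
    v = r1 + r2 is Gaussian around (1+c) u.  Recovery requires v inside the
    tracking disc (|v| <= s) and closer to the track than to the disturbed
    new track (v_x <= u/2).  The y-integral is analytic (erf); the
    x-integral uses Gauss-Legendre nodes.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    var = (1.0 - c * c) * sigma_sq / 2.0
    sd = math.sqrt(var)
    mu = (1.0 + c) * u  # mean of v_x; v_y has mean 0
    xn, xw = leggauss(n_leg)
    hi = np.minimum(s, u / 2.0)
    lo = -s
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    x = mid[:, None] + half[:, None] * xn[None, :]
    w = half[:, None] * xw[None, :]
    yb = np.sqrt(np.maximum(s * s - x * x, 0.0))
    fx = np.exp(-0.5 * ((x - mu[:, None]) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    py = _erf(yb / (sd * math.sqrt(2.0)))
    out = np.sum(w * fx * py, axis=1)
    out[hi <= lo] = 0.0
    return np.clip(out, 0.0, 1.0)


def gap_recovery_fraction(z: float, c: float, n_laguerre: int = 120,
                          n_leg: int = 160) -> float:
    """Fraction f of out-of-radius losses recovered by one gap frame.

    f = (a_z - a_Gap)/a_z where a_Gap is the unconditional probability that
    the molecule leaves the radius and is finally lost despite the gap frame.
    Evaluated by deterministic quadrature of the correlated bivariate
    Gaussian integral; 0 <= f <= 0.5.
    """
    if z <= 0:
        raise ValueError("z must be > 0")
    if not (-1.0 < c <= 0.0):
        raise ValueError("c must be in (-1, 0]")
    sigma_sq = 1.0
    s = math.sqrt(z)
    # radial measure of |r1|: with t = u^2/sigma^2, P(t > z) = e^-z and the
    # conditional excess w = t - z is Exp(1); integrate with Gauss-Laguerre.
    wn, ww = laggauss(n_laguerre)
    u = np.sqrt(sigma_sq * (z + wn))
    p_rec = _recovery_prob_given_u(u, s, c, sigma_sq, n_leg=n_leg)
    f = float(np.dot(ww, p_rec))
    if not np.isfinite(f):
        raise RuntimeError("gap integral did not converge")
    return float(np.clip(f, 0.0, 1.0))


def gap_recovery_fraction_mc(z: float, c: float, n_samples: int = 1_000_000,
                             seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Independent Monte-Carlo oracle for the gap-recovery fraction.

    Simulates the full six-dimensional error model: three localization
    errors g1..g3 and two true displacements h1, h2 build the consecutive
    apparent jumps r1 = h1 - g1 + g2 and r2 = h2 - g2 + g3; the implied
    correlation is c = -sigma0^2/(2 sigma^2).  Returns (f, standard error
    of f)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma_sq = 1.0
    s = math.sqrt(z * sigma_sq)
    sigma0_sq = max(0.0, -2.0 * c * sigma_sq)
    h_var = sigma_sq - sigma0_sq  # = 4 D t
    g = rng.normal(0.0, math.sqrt(sigma0_sq / 4.0), (3, n_samples, 2))
    h = rng.normal(0.0, math.sqrt(h_var / 2.0), (2, n_samples, 2))
    r1 = h[0] - g[0] + g[1]
    r2 = h[1] - g[1] + g[2]
    v = r1 + r2
    norm = lambda a: np.hypot(a[:, 0], a[:, 1])
    left = norm(r1) > s
    rec = left & (norm(v) <= s) & (norm(v) <= norm(r2))
    n_left = int(left.sum())
    if n_left == 0:
        return 0.0, 0.0
    f = rec.sum() / n_left
    se = math.sqrt(f * (1.0 - f) / n_left)
    return float(f), float(se)


def total_loss_prob(s: float, sigma_sq: float, rho: float,
                    gap_enabled: bool = True,
                    c: float | None = None,
                    sigma0_sq: float | None = None) -> LossBudget:
    """Total per-frame tracking loss a_tr = a_NN + a_z (1-f)(1-a_NN).

    With the gap frame disabled f = 0.  The jump correlation c needed for
    the gap integral is derived from sigma0_sq when given, else taken from
    ``c``, else 0 (no localization-error correlation).
    """
    z = s * s / sigma_sq
    a_z = out_of_radius_prob(s, sigma_sq)
    a_nn = erroneous_link_prob(rho, sigma_sq)
    if gap_enabled:
        if c is None:
            c = (jump_correlation(sigma0_sq, sigma_sq)
                 if sigma0_sq is not None else 0.0)
        f = gap_recovery_fraction(z, c)
    else:
        f = 0.0
    a_gap = a_z * (1.0 - f)
    a_tr = a_nn + a_gap * (1.0 - a_nn)
    return LossBudget(s=s, sigma_sq=sigma_sq, rho=rho, z=z, a_z=a_z,
                      a_nn=a_nn, f=f, a_gap=a_gap, a_tr=a_tr)


def min_bound_track_length(s: float, tau_tl: float, sigma0_sq: float,
                           d_free: float, p_free: float = 2e-3,
                           n_max: int = 50) -> int:
    """Minimum number of consecutive in-radius frames to call a track bound.

    Chosen as the smallest n >= 2 such that a freely diffusing molecule
    (coefficient d_free) stays within the tracking radius for n consecutive
    detections with probability below ``p_free``: each free jump stays inside
    with probability 1 - exp(-z_free), z_free = s^2/(sigma0^2 + 4 d_free tau).
    """
    z_free = s * s / effective_sigma_sq(sigma0_sq, d_free, tau_tl)
    p_stay = -math.expm1(-z_free)  # 1 - exp(-z_free)
    if p_stay <= 0:
        return 2
    n = 2
    while p_stay ** (n - 1) >= p_free and n < n_max:
        n += 1
    return n


@dataclass
class RadiusCalibration:
    s: float  # µm
    n_min_bound: int
    budget: LossBudget
    s_history: list[float] = field(default_factory=list)
    sigma_sq_history: list[float] = field(default_factory=list)
    converged: bool = True


def _solve_z_for_target(rhs: float, c: float, gap_enabled: bool) -> float:
    """Solve exp(-z) * (1 - f(z, c)) = rhs for z."""
    if not gap_enabled:
        return -math.log(rhs)

    def g(z):
        return math.exp(-z) * (1.0 - gap_recovery_fraction(z, c)) - rhs

    lo, hi = 1e-6, 60.0
    if g(lo) < 0:  # target above the achievable range: radius ~ 0
        return lo
    return brentq(g, lo, hi, xtol=1e-10, rtol=1e-12)


def radius_for_loss(
    target_a_tr: float,
    localizations: pd.DataFrame,
    tau_tl: float,
    sigma0_sq: float,
    rho: float | None = None,
    area_um2: float | None = None,
    d_free: float = 10.0,
    s0: float | None = None,
    tol: float = 1e-2,
    gap_enabled: bool = True,
    max_iter: int = 100,
    max_gap_frames: int | None = None,
    min_frames_before_gap: int = 2,
    on_unreachable: str = "raise",
) -> RadiusCalibration:
    """Tracking radius that achieves a target per-frame loss probability.

    No closed form exists for s(a_tr), so the model is inverted iteratively:
    at each step the data is re-tracked with the current radius s_i, the mean
    of squared linked jump distances gives the radius-truncated variance
    estimate sigma^2(s_i), the target is solved for the dimensionless radius
    z (gap recovery included), the truncation of the jump distribution at
    s_i is corrected by z -> z (1-e^-z)/(1-(1+z)e^-z), and the radius is
    updated.  Iteration stops when the relative change of s falls below
    ``tol`` (default 1e-2).

    ``rho`` (spots per µm² per frame) is estimated from the data and
    ``area_um2`` when not given.  Raises ValueError when the target loss is
    below the erroneous-link floor a_NN at this density.
    """
    from .linking import TrackingParams, nearest_neighbour_link

    if not 0.0 < target_a_tr < 1.0:
        raise ValueError("target_a_tr must be in (0, 1)")
    if rho is None:
        if area_um2 is None:
            raise ValueError("give either rho or area_um2")
        n_frames = localizations["frame"].nunique()
        rho = len(localizations) / n_frames / area_um2

    if max_gap_frames is None:
        max_gap_frames = 1 if gap_enabled else 0

    # starting radius: 3x the raw r.m.s. jump guess from sigma0 alone is a
    # poor guess when diffusion dominates, so take a coarse first pass with a
    # generous radius to estimate sigma^2
    if s0 is None:
        s0 = 3.0 * math.sqrt(sigma0_sq + 4.0 * 1e-3 * tau_tl)
    s = float(s0)
    history, sig_history = [s], []
    converged = False
    for _ in range(max_iter):
        params = TrackingParams(tracking_radius_um=s,
                                max_gap_frames=max_gap_frames,
                                min_frames_before_gap=min_frames_before_gap)
        ts = nearest_neighbour_link(localizations, params, tau_tl)
        jumps = np.concatenate([tr.jumps() for tr in ts.tracks]
                               + [np.empty((0, 2))])
        if len(jumps) < 10:
            raise ValueError("too few linked jumps to estimate sigma^2")
        sigma_sq_trunc = float(np.mean(jumps[:, 0] ** 2 + jumps[:, 1] ** 2))
        sig_history.append(sigma_sq_trunc)
        c = jump_correlation(min(sigma0_sq, sigma_sq_trunc), sigma_sq_trunc)
        a_nn = erroneous_link_prob(rho, sigma_sq_trunc)
        if target_a_tr <= a_nn:
            if on_unreachable == "floor":
                # best effort: choose the radius at which the added
                # out-of-radius loss is negligible against the
                # erroneous-link floor (a_z(1-f) = floor/10)
                rhs = 0.1 * a_nn / (1.0 - a_nn)
            else:
                raise ValueError(
                    f"loss target unreachable at this density: a_NN={a_nn:.4g}"
                    f" >= target {target_a_tr:.4g}")
        else:
            rhs = (target_a_tr - a_nn) / (1.0 - a_nn)
        z_tilde = _solve_z_for_target(rhs, c, gap_enabled)
        # truncation correction: the measured sigma^2 is the mean over the
        # jump distribution cut at the tracking radius
        ez = math.exp(-z_tilde)
        corr = z_tilde * (1.0 - ez) / (1.0 - (1.0 + z_tilde) * ez)
        s_new = math.sqrt(sigma_sq_trunc * corr)
        history.append(s_new)
        if abs(s_new - s) / s < tol:
            s = s_new
            converged = True
            break
        s = s_new

    # final budget at the untruncated variance implied by the fixed point
    sigma_sq = s * s / z_tilde if z_tilde > 0 else sigma_sq_trunc
    budget = total_loss_prob(s, sigma_sq, rho, gap_enabled=gap_enabled,
                             sigma0_sq=min(sigma0_sq, sigma_sq))
    n_min = min_bound_track_length(s, tau_tl, sigma0_sq, d_free)
    return RadiusCalibration(s=s, n_min_bound=n_min, budget=budget,
                             s_history=history, sigma_sq_history=sig_history,
                             converged=converged)


def measure_tracking_loss(tracksets, truth_frames=None) -> tuple[float, int]:
    """Empirical per-frame loss of single-molecule movies.

    Each trackset must come from a movie containing exactly one (immortal)
    molecule detected in every frame.  For each frame transition t -> t+1 the
    molecule is followed iff its detections at t and t+1 belong to the same
    track, or the track bridged t+1 as a gap and holds the molecule again at
    t+2.  Returns (loss probability per frame, number of transitions).
    """
    if not isinstance(tracksets, (list, tuple)):
        tracksets = [tracksets]
    losses = 0
    n_trans = 0
    for ts in tracksets:
        owner: dict[int, int] = {}  # frame -> track_id of the single detection
        gap_at: dict[int, int] = {}  # bridged frame -> track_id
        for tr in ts.tracks:
            for i, f in enumerate(tr.frames):
                owner[int(f)] = tr.track_id
                if tr.gap_flags[i]:
                    gap_at[int(f) - 1] = tr.track_id
        frames = sorted(owner)
        t = 0
        while t < len(frames) - 1:
            f = frames[t]
            n_trans += 1
            if owner.get(f + 1) == owner[f]:
                t += 1
            elif gap_at.get(f + 1) == owner[f]:
                # recovered via gap: transitions f and f+1 both survived
                n_trans += 1
                t += 2
            else:
                losses += 1
                t += 1
    return (losses / n_trans if n_trans else math.nan), n_trans
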