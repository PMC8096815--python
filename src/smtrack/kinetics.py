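"""Residence-time kinetics across time-lapse conditions.

Track lifetimes of bound molecules are collected into survival-time
distributions per frame-cycle time tau.  A track spanning m frames reports a
molecule that stayed bound for at least (m-1) tau seconds AND survived
(m-1) per-frame loss events (photobleaching plus tracking loss), so the
expected number of tracks lasting at least m frames is

    N_tau(>= m) = c_tau * sum_k w_k * exp(-k (m-1) tau) * (1-a)^(m-1)

with the dissociation-rate spectrum w over a fixed logarithmic rate grid
and ONE per-frame loss probability a shared by all conditions (this is what
calibrating the tracking radii to a constant loss per frame buys: bleaching
and tracking loss combine into a single correctable factor).  Solving all
conditions jointly for w (non-negative least squares over the grid, small
ridge penalty, sqrt-count residual weights) and scanning/refining a turns
the inverse Laplace transform into a well-behaved minimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls

__all__ = [
    "SurvivalDistribution",
    "RateSpectrum",
    "BoundFractionResult",
    "build_survival",
    "grid_spectrum",
    "resample_spectrum",
    "cluster_weights",
    "detect_clusters",
    "clusters_recovered",
    "itm_bound_fractions",
    "default_rate_grid",
]


@dataclass
class SurvivalDistribution:
    """Counting function N(>= t) of track lifetimes for one condition."""

    tau_tl: float  # s
    durations_s: np.ndarray  # sorted track lifetimes, s
    min_span_frames: int = 2  # shortest track (in frames) admitted

    def __post_init__(self) -> None:
        self.durations_s = np.sort(np.asarray(self.durations_s, dtype=float))

    @property
    def n_tracks(self) -> int:
        return len(self.durations_s)

    @property
    def is_empty(self) -> bool:
        return self.n_tracks == 0

    def counts(self, t: np.ndarray | float) -> np.ndarray:
        """N(>= t): number of tracks lasting at least t seconds."""
        t = np.atleast_1d(t)
        return len(self.durations_s) - np.searchsorted(
            self.durations_s, t, side="left")

    def frame_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(m, N(>= m frames)) over the observed span range."""
        spans = np.round(self.durations_s / self.tau_tl).astype(int) + 1
        m = np.arange(self.min_span_frames, spans.max() + 1)
        counts = np.array([(spans >= mi).sum() for mi in m])
        return m, counts


@dataclass
class RateSpectrum:
    rates: np.ndarray  # 1/s, strictly increasing log grid
    weights: np.ndarray  # non-negative, sum to 1
    per_frame_loss: float  # fitted combined bleaching + tracking loss
    scales: dict[float, float] = field(default_factory=dict)
    residual: float = math.nan
    resamples: np.ndarray | None = None  # (n_resamples, n_rates) envelope

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class BoundFractionResult:
    n_long: int
    n_short: int
    n_unbound: int
    bf: float  # bound fraction (pooled)
    bf_long: float  # long-lived fraction of the bound (pooled)
    per_movie: pd.DataFrame | None = None
    bf_mean: float = math.nan  # mean of per-movie values
    bf_long_mean: float = math.nan


def default_rate_grid(n: int = 60, lo: float = 1e-4, hi: float = 1e2) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), n)


def build_survival(tracksets_by_condition: dict[float, list],
                   min_span_frames: dict[float, int] | int = 2,
                   ) -> list[SurvivalDistribution]:
    """Survival distributions per time-lapse condition.

    ``tracksets_by_condition`` maps tau_tl to a list of TrackSets; track
    lifetimes (gap frames included) shorter than the per-condition minimum
    span are discarded.  Empty conditions yield empty (flagged)
    distributions.
    """
    from .linking import track_survival_times

    out = []
    for tau in sorted(tracksets_by_condition):
        nmin = (min_span_frames[tau] if isinstance(min_span_frames, dict)
                else min_span_frames)
        durs = [track_survival_times(ts, min_span_frames=nmin)
                for ts in tracksets_by_condition[tau]]
        durs = np.concatenate(durs) if durs else np.empty(0)
        out.append(SurvivalDistribution(tau_tl=tau, durations_s=durs,
                                        min_span_frames=nmin))
    return out


def _design(surv: SurvivalDistribution, rates: np.ndarray, a: float):
    m, counts = surv.frame_counts()
    decay = np.exp(-np.outer((m - 1) * surv.tau_tl, rates))
    if a > 0:
        decay *= ((1.0 - a) ** (m - 1))[:, None]
    y = counts / counts[0]
    wt = np.sqrt(y)
    return decay, y, wt


def _fit_weights(designs, lam: float, n_rates: int, n_alt: int = 12):
    """Alternating per-condition scale / global NNLS solve at fixed a."""
    scales = [1.0] * len(designs)
    w = None
    eye = math.sqrt(lam) * np.eye(n_rates) if lam > 0 else None
    for _ in range(n_alt):
        blocks = [wt[:, None] * (ci * K) for (K, y, wt), ci in zip(designs, scales)]
        target = [wt * y for (K, y, wt) in designs]
        if eye is not None:
            blocks.append(eye)
            target.append(np.zeros(n_rates))
        w, _ = nnls(np.vstack(blocks), np.concatenate(target))
        for i, (K, y, wt) in enumerate(designs):
            pred = K @ w
            num = float((wt * wt * pred) @ y)
            den = float((wt * wt * pred) @ pred)
            scales[i] = num / den if den > 0 else 1.0
    resid = sum(float(np.sum((wt * (y - ci * (K @ w))) ** 2))
                for (K, y, wt), ci in zip(designs, scales))
    return w, scales, resid


def grid_spectrum(
    survivals: list[SurvivalDistribution],
    rate_grid: np.ndarray | None = None,
    regularization: float = 1e-4,
    loss_bounds: tuple[float, float] = (0.0, 0.8),
    n_loss_coarse: int = 81,
    per_frame_loss: float | None = None,
) -> RateSpectrum:
    """Global inverse-Laplace fit of all survival distributions.

    Returns the normalized weight spectrum over the rate grid together with
    the fitted shared per-frame loss (pass ``per_frame_loss`` to fix it).
    Raises ValueError when no non-empty condition is available.
    """
    survivals = [s for s in survivals if not s.is_empty]
    if not survivals:
        raise ValueError("all survival distributions are empty")
    rates = default_rate_grid() if rate_grid is None else np.asarray(rate_grid)
    if np.any(np.diff(rates) <= 0):
        raise ValueError("rate_grid must be strictly increasing")

    # identifiability: a rate whose component has decayed below the floor at
    # the first observable time point of every condition is unconstrained by
    # the data; its weights are amplitudes at t=0, so leaving such columns in
    # lets astronomic raw amplitudes fit sub-count noise.  Exclude them.
    t_min = min((s.min_span_frames - 1) * s.tau_tl for s in survivals)
    identifiable = np.exp(-rates * max(t_min, 1e-12)) >= 1e-3
    if not identifiable.any():
        raise ValueError("no identifiable rates on the grid for this data")
    sub_rates = rates[identifiable]

    def solve(a: float):
        designs = [_design(s, sub_rates, a) for s in survivals]
        w_sub, scales, resid = _fit_weights(designs, regularization,
                                            len(sub_rates))
        w = np.zeros(len(rates))
        w[identifiable] = w_sub
        return w, scales, resid

    if per_frame_loss is not None:
        a_best = float(per_frame_loss)
    else:
        cand = np.linspace(loss_bounds[0], loss_bounds[1], n_loss_coarse)
        resids = [solve(a)[2] for a in cand]
        i = int(np.argmin(resids))
        lo = cand[max(i - 1, 0)]
        hi = cand[min(i + 1, len(cand) - 1)]
        res = minimize_scalar(lambda a: solve(a)[2], bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-4})
        a_best = float(res.x)

    w, scales, resid = solve(a_best)
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum fit collapsed to zero weights")
    return RateSpectrum(
        rates=rates, weights=w / total, per_frame_loss=a_best,
        scales={s.tau_tl: c for s, c in zip(survivals, scales)},
        residual=resid)


def resample_spectrum(
    survivals: list[SurvivalDistribution],
    n_resamples: int = 499,
    fraction: float = 0.8,
    seed: int | np.random.Generator = 0,
    refit_loss: bool = False,
    **fit_kwargs,
) -> np.ndarray:
    """Spectrum envelope from resampling: each resample draws
    floor(fraction * n) track durations without replacement per condition
    and refits.  Returns an (n_resamples, n_rates) array of weight spectra.

    By default the shared per-frame loss is fixed at the full-data fit
    (``refit_loss=True`` refits it per resample).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if n_resamples <= 0:
        rates = fit_kwargs.get("rate_grid")
        n_rates = len(rates) if rates is not None else len(default_rate_grid())
        return np.empty((0, n_rates))
    full = grid_spectrum(survivals, **fit_kwargs)
    out = np.empty((n_resamples, len(full.rates)))
    for i in range(n_resamples):
        sub = []
        for s in survivals:
            if s.is_empty:
                sub.append(s)
                continue
            k = int(math.floor(fraction * s.n_tracks))
            idx = rng.choice(s.n_tracks, size=k, replace=False)
            sub.append(SurvivalDistribution(
                tau_tl=s.tau_tl, durations_s=s.durations_s[idx],
                min_span_frames=s.min_span_frames))
        spec = grid_spectrum(
            sub, per_frame_loss=None if refit_loss else full.per_frame_loss,
            **fit_kwargs)
        out[i] = spec.weights
    return out


def cluster_weights(spectrum: RateSpectrum,
                    intervals: list[tuple[float, float]]) -> np.ndarray:
    """Sum of spectrum weights with rate inside each interval, in percent."""
    out = []
    for lo, hi in intervals:
        sel = (spectrum.rates >= lo) & (spectrum.rates <= hi)
        out.append(100.0 * float(spectrum.weights[sel].sum()))
    return np.asarray(out)


def detect_clusters(spectrum: RateSpectrum, min_weight: float = 0.01,
                    max_gap_decades: float = 0.35) -> pd.DataFrame:
    """Contiguous groups of non-negligible grid weights.

    Grid points with weight > 1e-4 are grouped when their log-rate gap is
    below ``max_gap_decades``; groups with total weight below ``min_weight``
    are dropped.  Returns a table with the weighted geometric-mean rate, the
    total weight, the support bounds and the support width in decades.
    """
    sel = np.nonzero(spectrum.weights > 1e-4)[0]
    clusters = []
    current: list[int] = []
    for idx in sel:
        if current and (math.log10(spectrum.rates[idx])
                        - math.log10(spectrum.rates[current[-1]])) > max_gap_decades:
            clusters.append(current)
            current = []
        current.append(idx)
    if current:
        clusters.append(current)
    rows = []
    for cl in clusters:
        wsum = float(spectrum.weights[cl].sum())
        if wsum < min_weight:
            continue
        logr = np.log10(spectrum.rates[cl])
        mode = 10 ** float(np.average(logr, weights=spectrum.weights[cl]))
        rows.append((mode, wsum, spectrum.rates[cl[0]], spectrum.rates[cl[-1]],
                     float(logr[-1] - logr[0])))
    return pd.DataFrame(rows, columns=[
        "rate", "weight", "rate_lo", "rate_hi", "width_decades"])


def clusters_recovered(spectrum: RateSpectrum, true_rates,
                       half_decades: float = 0.5,
                       min_weight: float = 0.01,
                       max_width_decades: float = 1.0) -> list[bool]:
    """Whether each true rate is resolved by the spectrum.

    A rate k counts as recovered when a cluster of total weight >=
    ``min_weight`` either has its weighted mode inside the window
    [k/10^half, k*10^half], or is *localized* (contiguous support spanning
    at most ``max_width_decades``) with support overlapping the window.
    Degenerate fits (weight smeared over many decades, or piled up at a
    grid edge away from k) therefore do not count as recovery even when
    some of their mass falls inside the window.
    """
    cl = detect_clusters(spectrum, min_weight=min_weight)
    out = []
    for k in np.asarray(true_rates, dtype=float):
        lo, hi = k * 10 ** (-half_decades), k * 10 ** (half_decades)
        mode_in = (cl["rate"] >= lo) & (cl["rate"] <= hi)
        overlap = ((cl["rate_hi"] >= lo) & (cl["rate_lo"] <= hi)
                   & (cl["width_decades"] <= max_width_decades))
        out.append(bool((mode_in | overlap).any()))
    return out


def itm_bound_fractions(tracksets: list, frames_per_burst: int = 2,
                        ) -> BoundFractionResult:
    """Bound fractions from interlaced time-lapse movies.

    Acquisition frames come in bursts of ``frames_per_burst`` consecutive
    frames separated by a long dark period; the frame index determines the
    burst as frame // frames_per_burst.  Tracks surviving at least one dark
    period (detections in >= 2 bursts) are long bound; tracks of >= 2
    consecutive frames within one burst are short bound; single detections
    are unbound.  BF = N_bound/(N_bound + N_unbound) and BF_long =
    N_long/(N_long + N_short), per movie, as the movie mean, and pooled
    over summed counts.
    """
    rows = []
    for i, ts in enumerate(tracksets):
        n_long = n_short = n_unbound = 0
        for tr in ts.tracks:
            bursts = np.unique(np.asarray(tr.frames) // frames_per_burst)
            if len(bursts) >= 2:
                n_long += 1
            elif tr.n_detections >= 2:
                n_short += 1
            else:
                n_unbound += 1
        n_bound = n_long + n_short
        rows.append((
            i, n_long, n_short, n_unbound,
            n_bound / (n_bound + n_unbound) if n_bound + n_unbound else math.nan,
            n_long / n_bound if n_bound else math.nan,
        ))
    df = pd.DataFrame(rows, columns=[
        "movie", "n_long", "n_short", "n_unbound", "bf", "bf_long"])
    n_long = int(df["n_long"].sum())
    n_short = int(df["n_short"].sum())
    n_unbound = int(df["n_unbound"].sum())
    n_bound = n_long + n_short
    return BoundFractionResult(
        n_long=n_long, n_short=n_short, n_unbound=n_unbound,
        bf=n_bound / (n_bound + n_unbound) if n_bound + n_unbound else math.nan,
        bf_long=n_long / n_bound if n_bound else math.nan,
        per_movie=df,
        bf_mean=float(df["bf"].mean()),
        bf_long_mean=float(df["bf_long"].mean()),
    )
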