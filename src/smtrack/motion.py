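"""Mobility analyses on tracks: jump-distance statistics, cumulative
squared-displacement diffusion fits, MSD/confinement, jump angles, spatial
maps and intensity traces."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit

from .linking import Track, TrackSet

__all__ = [
    "DiffusionFitResult",
    "ConfinementResult",
    "HeatMap",
    "jump_histogram",
    "fit_cumulative_jumps",
    "msd",
    "msd_and_confinement",
    "jump_angles",
    "localization_map",
    "jump_distance_map",
    "intensity_trace",
]


@dataclass
class DiffusionFitResult:
    amplitudes: np.ndarray  # sum to 1
    diffusion_coeffs: np.ndarray  # µm²/s, ascending
    conf_int: dict[str, tuple[float, float]]  # 95 % CIs
    adj_r_squared: float
    c2: float  # upper jump-bound on the X = r²/(4 tau) scale, µm²/s


@dataclass
class ConfinementResult:
    confined: bool
    alpha: float  # MSD power-law exponent
    R: float = math.nan  # µm, confinement radius
    d_star: float = math.nan  # µm²/s, local diffusion coefficient
    offset: float = math.nan  # µm², localization-precision plateau offset
    mean_jump_um: float = math.nan


@dataclass
class HeatMap:
    grid: np.ndarray
    bin_scale: float  # bins per original pixel (2 = upscaled x2)
    kind: str  # "localizations" | "jump_distance"


def _all_jumps(trackset: TrackSet, jumps_per_track: int | None = None
               ) -> np.ndarray:
    """Jump vectors of all tracks, gap-crossing jumps omitted; optionally at
    most the first ``jumps_per_track`` jumps of each track (one jump per
    track minimizes the weight bias of immobile over mobile molecules)."""
    chunks = []
    for tr in trackset.tracks:
        j = tr.jumps()
        if jumps_per_track is not None:
            j = j[:jumps_per_track]
        if len(j):
            chunks.append(j)
    return np.concatenate(chunks) if chunks else np.empty((0, 2))


def jump_histogram(trackset: TrackSet, bin_size_um: float,
                   jumps_per_track: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of jump distances between consecutive frames.

    Returns (counts, bin_edges); all jump events are conserved in the
    counts.  ``bin_size_um`` sets the bin width."""
    if bin_size_um <= 0:
        raise ValueError("bin_size_um must be > 0")
    jumps = _all_jumps(trackset, jumps_per_track)
    r = np.hypot(jumps[:, 0], jumps[:, 1])
    hi = max(r.max() if len(r) else bin_size_um, bin_size_um)
    edges = np.arange(0.0, hi + bin_size_um, bin_size_um)
    counts, edges = np.histogram(r, bins=edges)
    return counts, edges


def _cumulative_model(x, params, n_components, c1, c2):
    """Brownian mixture CDF of X = r²/(4 tau), the last component normalized
    for the truncation of jumps at the tracking radius."""
    amps = [params[f"a{i}"] for i in range(1, n_components)]
    ds = [params[f"d{i}"] for i in range(1, n_components + 1)]
    out = 0.0
    for a, d in zip(amps, ds[:-1]):
        out = out + a * (1.0 - np.exp(-x / d))
    a_last = 1.0 - sum(amps)
    d_last = ds[-1]
    norm = np.exp(-c1 / d_last) - np.exp(-c2 / d_last)
    out = out + a_last * (np.exp(-c1 / d_last) - np.exp(-x / d_last)) / norm
    return out


def fit_cumulative_jumps(
    trackset_or_jumps,
    n_components: int = 2,
    tau: float | None = None,
    c2: float | None = None,
    jumps_per_track: int | None = None,
    n_points: int = 200,
) -> DiffusionFitResult:
    """Fit the cumulative distribution of squared jump distances.

    The variable is X = (dx² + dy²)/(4 tau); the model is a mixture of
    ``n_components`` (2 or 3) Brownian components whose fastest term is
    normalized by exp(-C1/D) - exp(-C2/D) to account for the truncation of
    jump distances at the tracking radius (C1 = 0, C2 = s²/(4 tau)).  The
    empirical CDF is evaluated at ``n_points`` quantiles of X (no binning
    loss).  Returns amplitudes, diffusion coefficients (ascending), 95 %
    confidence intervals and the adjusted R².
    """
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    if isinstance(trackset_or_jumps, TrackSet):
        ts = trackset_or_jumps
        tau = ts.frame_cycle_time if tau is None else tau
        if c2 is None:
            c2 = ts.params.tracking_radius_um**2 / (4.0 * tau)
        jumps = _all_jumps(ts, jumps_per_track)
        x = (jumps[:, 0] ** 2 + jumps[:, 1] ** 2) / (4.0 * tau)
    else:
        if tau is None:
            raise ValueError("tau required for a raw jump array")
        jumps = np.asarray(trackset_or_jumps, dtype=float)
        r_sq = (jumps[:, 0] ** 2 + jumps[:, 1] ** 2
                if jumps.ndim == 2 else jumps**2)
        x = r_sq / (4.0 * tau)
        if c2 is None:
            c2 = float(x.max()) * 1.0000001
    if len(x) < 10 * n_components:
        raise ValueError("too few jumps for a stable fit")
    x = np.sort(x)
    q = (np.arange(1, len(x) + 1)) / len(x)
    if len(x) > n_points:
        take = np.unique(np.linspace(0, len(x) - 1, n_points).astype(int))
        x, q = x[take], q[take]

    params = lmfit.Parameters()
    med = float(np.median(x))
    if n_components == 2:
        params.add("a1", value=0.5, min=0.0, max=1.0)
        params.add("d1", value=med / 5, min=1e-8)
        params.add("d2", value=med * 5, min=1e-8)
    else:
        params.add("a1", value=0.3, min=0.0, max=1.0)
        params.add("a2", value=0.3, min=0.0, max=1.0)
        params.add("d1", value=med / 10, min=1e-8)
        params.add("d2", value=med, min=1e-8)
        params.add("d3", value=med * 10, min=1e-8)

    def resid(p):
        return _cumulative_model(x, p.valuesdict(), n_components, 0.0, c2) - q

    res = lmfit.minimize(resid, params, method="least_squares")
    if not res.success:
        raise RuntimeError(
            f"cumulative jump fit did not converge (residual {res.chisqr:.3g})")
    v = res.params.valuesdict()
    amps = np.array([v[f"a{i}"] for i in range(1, n_components)]
                    + [1.0 - sum(v[f"a{i}"] for i in range(1, n_components))])
    ds = np.array([v[f"d{i}"] for i in range(1, n_components + 1)])
    order = np.argsort(ds)
    amps, ds = amps[order], ds[order]
    ss_res = float(np.sum(res.residual**2))
    ss_tot = float(np.sum((q - q.mean()) ** 2))
    n, k = len(x), res.nvarys
    adj_r2 = 1.0 - (1.0 - (1.0 - ss_res / ss_tot)) * (n - 1) / (n - k - 1)
    cis = {}
    for name, par in res.params.items():
        sd = par.stderr if par.stderr is not None else math.nan
        cis[name] = (par.value - 1.96 * sd, par.value + 1.96 * sd)
    return DiffusionFitResult(amplitudes=amps, diffusion_coeffs=ds,
                              conf_int=cis, adj_r_squared=adj_r2, c2=c2)


def msd(track: Track, tau: float, max_lag_fraction: float = 1 / 3
        ) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over overlapping displacement pairs.

    Lags are limited to span/3 (bias/variance compromise).  Gap-bridged
    detections participate at their true frame distance.  Returns
    (t_lag seconds, msd µm²)."""
    frames = track.frames
    pos = track.positions
    span = frames[-1] - frames[0]
    max_lag = max(1, int(span * max_lag_fraction))
    lags, vals = [], []
    for lag in range(1, max_lag + 1):
        diffs = []
        fset = {f: i for i, f in enumerate(frames)}
        for f, i in fset.items():
            j = fset.get(f + lag)
            if j is not None:
                d = pos[j] - pos[i]
                diffs.append(d[0] ** 2 + d[1] ** 2)
        if diffs:
            lags.append(lag * tau)
            vals.append(float(np.mean(diffs)))
    return np.asarray(lags), np.asarray(vals)


def msd_and_confinement(track: Track, tau: float,
                        alpha_threshold: float = 0.7) -> ConfinementResult:
    """Confined-diffusion analysis of one track.

    The time-averaged MSD is fitted with the power law 4 D t^alpha (log-log
    least squares); tracks with alpha <= threshold are fitted with the
    confined-circle model MSD = R² (1 - exp(-4 D* t / R²)) + offset.
    Requires >= 5 detections.
    """
    if track.n_detections < 5:
        raise ValueError("track too short for MSD analysis (need >= 5)")
    t, m = msd(track, tau)
    if len(t) < 3:
        raise ValueError("too few MSD lags")
    coeffs = np.polyfit(np.log(t), np.log(np.maximum(m, 1e-12)), 1)
    alpha = float(coeffs[0])
    jumps = track.jumps()
    mean_jump = float(np.mean(np.hypot(jumps[:, 0], jumps[:, 1]))) if len(jumps) else math.nan
    if alpha > alpha_threshold:
        return ConfinementResult(confined=False, alpha=alpha,
                                 mean_jump_um=mean_jump)
    params = lmfit.Parameters()
    plateau = float(np.max(m))
    params.add("R", value=math.sqrt(max(plateau, 1e-9)), min=1e-6)
    params.add("d_star", value=max(m[0] / (4 * t[0]), 1e-9), min=0.0)
    params.add("offset", value=0.0, min=-plateau, max=plateau)

    def resid(p):
        R = p["R"].value
        return (R**2 * (1.0 - np.exp(-4.0 * p["d_star"].value * t / R**2))
                + p["offset"].value - m)

    res = lmfit.minimize(resid, params, method="least_squares")
    v = res.params.valuesdict()
    return ConfinementResult(confined=True, alpha=alpha, R=float(v["R"]),
                             d_star=float(v["d_star"]),
                             offset=float(v["offset"]),
                             mean_jump_um=mean_jump)


def jump_angles(trackset: TrackSet) -> np.ndarray:
    """Angles (degrees, [0, 180]) between consecutive jump vectors of each
    track; angles involving jumps across gap frames are omitted."""
    out = []
    for tr in trackset.tracks:
        if tr.n_detections < 3:
            continue
        d = np.diff(tr.positions, axis=0)
        ok = ~tr.gap_flags[1:]
        for i in range(len(d) - 1):
            if not (ok[i] and ok[i + 1]):
                continue
            n1 = np.linalg.norm(d[i])
            n2 = np.linalg.norm(d[i + 1])
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(np.dot(d[i], d[i + 1]) / (n1 * n2), -1.0, 1.0)
            out.append(math.degrees(math.acos(cosang)))
    return np.asarray(out)


def localization_map(localizations: pd.DataFrame, shape_px: tuple[int, int],
                     pixel_size_um: float, scale: float = 1.0) -> HeatMap:
    """2D histogram of sub-pixel localizations.

    ``scale`` > 1 upscales (super-resolved bins), < 1 merges pixels.  Bin
    values are detection counts; the total equals the number of
    localizations that fall inside the image."""
    H, W = shape_px
    nh, nw = int(round(H * scale)), int(round(W * scale))
    x = localizations["x_um"].to_numpy() / pixel_size_um * scale
    y = localizations["y_um"].to_numpy() / pixel_size_um * scale
    grid, _, _ = np.histogram2d(y, x, bins=(nh, nw),
                                range=((0, nh), (0, nw)))
    return HeatMap(grid=grid.astype(int), bin_scale=scale, kind="localizations")


def _supercover_pixels(x0, y0, x1, y1):
    """All integer grid cells crossed by the segment (x0,y0)-(x1,y1): exact
    traversal via the parameter values where the segment crosses pixel
    boundaries (supercover)."""
    dx, dy = x1 - x0, y1 - y0
    ts = [0.0, 1.0]
    if dx != 0:
        lo, hi = sorted((x0, x1))
        for gx in range(int(math.ceil(lo)), int(math.floor(hi)) + 1):
            ts.append((gx - x0) / dx)
    if dy != 0:
        lo, hi = sorted((y0, y1))
        for gy in range(int(math.ceil(lo)), int(math.floor(hi)) + 1):
            ts.append((gy - y0) / dy)
    ts = sorted(t for t in ts if 0.0 <= t <= 1.0)
    cells = set()
    for a, b in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (a + b)
        cells.add((int(math.floor(x0 + tm * dx)), int(math.floor(y0 + tm * dy))))
    cells.add((int(math.floor(x0)), int(math.floor(y0))))
    cells.add((int(math.floor(x1)), int(math.floor(y1))))
    return cells


def jump_distance_map(trackset: TrackSet, shape_px: tuple[int, int],
                      pixel_size_um: float, scale: float = 1.0) -> HeatMap:
    """Mean jump distance per bin: a virtual line per jump assigns its
    length (µm) to every bin the line touches; bins are normalized by the
    number of jump events that touched them."""
    H, W = shape_px
    nh, nw = int(round(H * scale)), int(round(W * scale))
    total = np.zeros((nh, nw))
    count = np.zeros((nh, nw), dtype=int)
    for tr in trackset.tracks:
        p = tr.positions / pixel_size_um * scale
        for i in range(len(p) - 1):
            if tr.gap_flags[i + 1]:
                continue
            d = tr.positions[i + 1] - tr.positions[i]
            length = math.hypot(d[0], d[1])
            for cx, cy in _supercover_pixels(p[i, 0], p[i, 1],
                                             p[i + 1, 0], p[i + 1, 1]):
                if 0 <= cy < nh and 0 <= cx < nw:
                    total[cy, cx] += length
                    count[cy, cx] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return HeatMap(grid=mean, bin_scale=scale, kind="jump_distance")


def intensity_trace(stack: np.ndarray, track: Track, pixel_size_um: float,
                    window: int = 3, tail: int = 20,
                    kymo_halfwidth: int = 3
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean intensity in a window around the spot centre per frame, plus
    per-axis kymographs.

    The trace covers the track's frames and continues ``tail`` frames past
    the end with the window frozen at the last position (clipped at the
    movie end), so tracking losses and bleaching steps remain visible.
    Kymographs maximum-project the other spatial dimension inside a strip of
    half-width ``kymo_halfwidth``.  Returns (frames, trace, kymo_x, kymo_y).
    """
    n_frames, H, W = stack.shape
    half = window // 2
    kh = kymo_halfwidth
    frames_out, trace = [], []
    kx, ky = [], []
    pos_px = {int(f): (p / pixel_size_um) for f, p in
              zip(track.frames, track.positions)}
    last_frame = int(track.frames[-1])
    end = min(last_frame + tail, n_frames - 1)
    current = pos_px[int(track.frames[0])]
    for f in range(int(track.frames[0]), end + 1):
        current = pos_px.get(f, current)
        c = int(round(current[0]))
        r = int(round(current[1]))
        r0, r1 = max(0, r - half), min(H, r + half + 1)
        c0, c1 = max(0, c - half), min(W, c + half + 1)
        frames_out.append(f)
        trace.append(float(stack[f, r0:r1, c0:c1].mean()))
        kr0, kr1 = max(0, r - kh), min(H, r + kh + 1)
        kc0, kc1 = max(0, c - kh), min(W, c + kh + 1)
        kx.append(stack[f, kr0:kr1, :].max(axis=0))  # x vs t, y projected
        ky.append(stack[f, :, kc0:kc1].max(axis=1))  # y vs t, x projected
    return (np.asarray(frames_out), np.asarray(trace),
            np.asarray(kx), np.asarray(ky))
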