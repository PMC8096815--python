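"""Spot detection: à-trous wavelet enhancement, local-maximum candidate
selection, and sub-pixel refinement with an integrated 2D Gaussian fit."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d, maximum_filter
from scipy.optimize import least_squares
from scipy.special import erf

__all__ = [
    "SpotCandidate",
    "Localization",
    "FitRejected",
    "wavelet_filter",
    "mad_threshold",
    "detect_candidates",
    "refine_localization",
    "detect_frame",
    "detect_movie",
]

# cubic B-spline scaling kernel of the à-trous transform
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class SpotCandidate:
    row: int
    col: int
    filtered_value: float


@dataclass(frozen=True)
class Localization:
    x: float  # sub-pixel column, 0-based, pixel centre at integers
    y: float  # sub-pixel row
    frame_index: int
    amplitude: float
    background: float
    fit_width: float
    roi_id: int | None = None


class FitRejected(ValueError):
    """Raised when the Gaussian refinement fails (divergence, non-positive
    amplitude, or the fitted centre drifting off the candidate)."""


def _atrous_smooth(image: np.ndarray, level: int) -> np.ndarray:
    """One smoothing step of the à-trous transform at the given level
    (kernel taps spaced 2**level apart, mirror boundary)."""
    spacing = 2**level
    kernel = np.zeros(4 * spacing + 1)
    kernel[::spacing] = _B3
    out = convolve1d(image, kernel, axis=0, mode="mirror")
    return convolve1d(out, kernel, axis=1, mode="mirror")

def wavelet_filter(frame: np.ndarray, n_levels: int = 2,
                   combine: str = "sum") -> np.ndarray:
    """Band-pass enhancement of diffraction-limited spots.

    The image is decomposed with the à-trous B-spline wavelet; the detail
    planes of levels 1..n_levels are combined (``"sum"``: linear band-pass,
    the default; ``"product"``: the multiscale product used by some detectors).
    The response to a constant image is ~0 and the response peaks at the
    centres of PSF-sized blobs.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    details = []
    smooth = frame
    for level in range(n_levels):
        nxt = _atrous_smooth(smooth, level)
        details.append(smooth - nxt)
        smooth = nxt
    if combine == "sum":
        return np.sum(details, axis=0)
    if combine == "product":
        return np.prod(details, axis=0)
    raise ValueError(f"unknown combine mode {combine!r}")


def mad_threshold(filtered: np.ndarray, k: float = 6.0) -> float:
    """Suggested detection threshold: k times the robust standard deviation
    (1.4826 * MAD) of the filtered image.  Suggested, never silently applied."""
    mad = np.median(np.abs(filtered - np.median(filtered)))
    return k * 1.4826 * float(mad)


def detect_candidates(
    filtered: np.ndarray,
    threshold: float,
    roi_mask: np.ndarray | None = None,
    merge_radius: float = 2.0,
) -> list[SpotCandidate]:
    """Strict 3x3 local maxima of the filtered image above the threshold.

    Candidates closer than ``merge_radius`` pixels are merged keeping the
    brighter one (one PSF should yield one candidate).  Returned sorted by
    descending filter response.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    filt = np.asarray(filtered, dtype=float)
    neighbour_max = maximum_filter(filt, size=3, mode="nearest")
    is_max = (filt >= neighbour_max) & (filt >= threshold)
    # strictness: demote plateau pixels that tie with a neighbour but are not
    # the first in scan order
    rows, cols = np.nonzero(is_max)
    if roi_mask is not None:
        keep = np.asarray(roi_mask, dtype=bool)[rows, cols]
        rows, cols = rows[keep], cols[keep]
    vals = filt[rows, cols]
    order = np.argsort(-vals)
    rows, cols, vals = rows[order], cols[order], vals[order]
    out: list[SpotCandidate] = []
    for r, c, v in zip(rows, cols, vals):
        if any((r - o.row) ** 2 + (c - o.col) ** 2 < merge_radius**2 for o in out):
            continue
        out.append(SpotCandidate(int(r), int(c), float(v)))
    return out


def _gauss_model(params, rows, cols):
    x0, y0, amp, bg, width = params
    s = math.sqrt(2.0) * width
    gy = 0.5 * (erf((rows - y0 + 0.5) / s) - erf((rows - y0 - 0.5) / s))
    gx = 0.5 * (erf((cols - x0 + 0.5) / s) - erf((cols - x0 - 0.5) / s))
    peak = (0.5 * (erf(0.5 / s) - erf(-0.5 / s))) ** 2
    return bg + amp / peak * np.outer(gy, gx)


def refine_localization(
    frame: np.ndarray,
    candidate: SpotCandidate,
    frame_index: int = 0,
    window: int = 7,
    init_width: float = 1.0,
    border_margin: int = 2,
) -> Localization:
    """Least-squares fit of a pixel-integrated 2D Gaussian plus constant
    background in a window around the candidate.

    The fit window is clipped at the image borders; candidates whose centre
    lies closer than ``border_margin`` pixels to a border are rejected, as
    are diverged fits and fits with non-positive amplitude (FitRejected).
    """
    img = np.asarray(frame, dtype=float)
    H, W = img.shape
    r, c = candidate.row, candidate.col
    if (r < border_margin or r >= H - border_margin
            or c < border_margin or c >= W - border_margin):
        raise FitRejected("candidate too close to the image border")
    half = window // 2
    r0, r1 = max(0, r - half), min(H, r + half + 1)
    c0, c1 = max(0, c - half), min(W, c + half + 1)
    patch = img[r0:r1, c0:c1]
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    bg0 = float(patch.min())
    amp0 = float(patch[r - r0, c - c0] - bg0)
    p0 = [float(c), float(r), max(amp0, 1.0), bg0, init_width]
    bounds = ([c0 - 1, r0 - 1, 0.0, -np.inf, 0.3],
              [c1, r1, np.inf, np.inf, window])

    def resid(p):
        return (_gauss_model(p, rows, cols) - patch).ravel()

    sol = least_squares(resid, p0, bounds=bounds, method="trf",
                        xtol=1e-10, ftol=1e-10, max_nfev=200)
    x0, y0, amp, bg, width = sol.x
    if not sol.success and sol.status <= 0:
        raise FitRejected("fit did not converge")
    if amp <= max(1e-9, 1e-6 * max(1.0, abs(bg))):
        raise FitRejected("non-positive fitted amplitude")
    if abs(x0 - c) > 2.0 or abs(y0 - r) > 2.0:
        raise FitRejected("fitted centre drifted off the candidate")
    return Localization(x=float(x0), y=float(y0), frame_index=frame_index,
                        amplitude=float(amp), background=float(bg),
                        fit_width=float(width))


def detect_frame(
    frame: np.ndarray,
    threshold: float,
    frame_index: int = 0,
    roi_mask: np.ndarray | None = None,
    n_levels: int = 2,
    window: int = 7,
) -> list[Localization]:
    """Full detection on one frame: filter, candidates, refinement.
    Rejected fits are dropped silently here; use the lower-level functions
    to inspect rejections."""
    filtered = wavelet_filter(frame, n_levels=n_levels)
    locs = []
    for cand in detect_candidates(filtered, threshold, roi_mask=roi_mask):
        try:
            locs.append(refine_localization(frame, cand, frame_index=frame_index,
                                            window=window))
        except FitRejected:
            continue
    return locs


def detect_movie(
    stack: np.ndarray,
    threshold: float,
    pixel_size_um: float = 0.16,
    roi_mask: np.ndarray | None = None,
    n_levels: int = 2,
    window: int = 7,
) -> pd.DataFrame:
    """Detect all frames of a stack; returns the standard localization table
    (frame, x_px, y_px, x_um, y_um, amplitude, background)."""
    rows = []
    for i, frame in enumerate(stack):
        for loc in detect_frame(frame, threshold, frame_index=i,
                                roi_mask=roi_mask, n_levels=n_levels,
                                window=window):
            rows.append((i, loc.x, loc.y, loc.x * pixel_size_um,
                         loc.y * pixel_size_um, loc.amplitude, loc.background))
    return pd.DataFrame(rows, columns=[
        "frame", "x_px", "y_px", "x_um", "y_um", "amplitude", "background"])
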