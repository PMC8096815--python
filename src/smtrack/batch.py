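"""Data-set scanning, movie/ROI/CSV I/O and the analysis batch structure.

A batch binds movies (with per-movie frame-cycle times parsed from their
filenames), detection/tracking parameters per condition and the produced
result tables, and serializes as a plain directory of YAML + CSV so results
always carry the exact parameters that produced them.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import detect_movie, mad_threshold, wavelet_filter
from .linking import TrackingParams, TrackSet, nearest_neighbour_link

logger = logging.getLogger("smtrack")

__all__ = [
    "MovieEntry",
    "DataSet",
    "AnalysisBatch",
    "scan_folders",
    "run_batch",
    "export_tracks",
    "read_roi_mask",
    "read_tracks_csv",
    "write_tracks_csv",
]

LOC_COLUMNS = ["frame", "x_px", "y_px", "x_um", "y_um", "amplitude", "background"]
TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um", "gap_flag"]


@dataclass
class MovieEntry:
    path: Path
    frame_cycle_time: float  # s
    roi_path: Path | None = None


@dataclass
class DataSet:
    name: str
    movies: list[MovieEntry] = field(default_factory=list)
    unmatched: list[Path] = field(default_factory=list)

    def conditions(self) -> dict[float, list[MovieEntry]]:
        out: dict[float, list[MovieEntry]] = {}
        for m in self.movies:
            out.setdefault(m.frame_cycle_time, []).append(m)
        return out


def scan_folders(root, filename_pattern: str, name: str | None = None,
                 roi_suffix: str = "_roi") -> DataSet:
    """Recursively discover TIFF movies and parse frame-cycle times.

    ``filename_pattern`` is a regular expression with a named group
    ``tau_ms`` or ``tau_s`` giving the frame-cycle time in the corresponding
    unit (no heuristics: unmatched files are reported in
    ``DataSet.unmatched``).  A sibling file with the ``roi_suffix`` inserted
    before the extension is attached as the movie's ROI mask.
    """
    root = Path(root)
    pattern = re.compile(filename_pattern)
    ds = DataSet(name=name or root.name)
    tiffs = sorted(root.rglob("*.tif")) + sorted(root.rglob("*.tiff"))
    for path in tiffs:
        if roi_suffix in path.stem:
            continue
        m = pattern.search(path.name)
        if not m:
            ds.unmatched.append(path)
            continue
        groups = m.groupdict()
        if "tau_ms" in groups and groups["tau_ms"] is not None:
            tau = float(groups["tau_ms"]) / 1000.0
        elif "tau_s" in groups and groups["tau_s"] is not None:
            tau = float(groups["tau_s"])
        else:
            ds.unmatched.append(path)
            continue
        roi = path.with_name(path.stem + roi_suffix + path.suffix)
        ds.movies.append(MovieEntry(
            path=path, frame_cycle_time=tau,
            roi_path=roi if roi.exists() else None))
    if not ds.movies:
        logger.warning("no movies matched under %s", root)
    return ds


def read_roi_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_tracks_csv(path, trackset: TrackSet) -> None:
    trackset.to_dataframe().to_csv(path, index=False)


def read_tracks_csv(path, params: TrackingParams | None = None,
                    frame_cycle_time: float | None = None) -> TrackSet:
    df = pd.read_csv(path)
    if frame_cycle_time is None:
        # recover tau from the stored time column
        sub = df[df["frame"] > 0]
        frame_cycle_time = float((sub["time_s"] / sub["frame"]).iloc[0]) \
            if len(sub) else 1.0
    if params is None:
        # unknown provenance: permissive placeholder params
        params = TrackingParams(tracking_radius_um=math.inf)
    return TrackSet.from_dataframe(df, params, frame_cycle_time)


@dataclass
class AnalysisBatch:
    """All inputs, parameters and results of one processing run."""

    dataset: DataSet
    detection_threshold_k: float  # threshold = k * robust sd of the filtered image
    tracking: dict[float, TrackingParams]  # per frame-cycle time
    pixel_size_um: float = 0.16
    seed: int = 0
    localizations: dict[str, pd.DataFrame] = field(default_factory=dict)
    tracks: dict[str, TrackSet] = field(default_factory=dict)
    survivals: dict[float, np.ndarray] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "dataset": self.dataset.name,
            "pixel_size_um": self.pixel_size_um,
            "detection_threshold_k": self.detection_threshold_k,
            "seed": self.seed,
            "tracking": {
                str(tau): {
                    "tracking_radius_um": p.tracking_radius_um,
                    "max_gap_frames": p.max_gap_frames,
                    "min_frames_before_gap": p.min_frames_before_gap,
                    "min_track_length_bound": p.min_track_length_bound,
                } for tau, p in self.tracking.items()},
            "movies": [{"path": str(m.path), "tau": m.frame_cycle_time}
                       for m in self.dataset.movies],
            "errors": self.errors,
        }
        with open(out / "batch.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        for key, df in self.localizations.items():
            df.to_csv(out / f"{key}_locs.csv", index=False)
        for key, ts in self.tracks.items():
            write_tracks_csv(out / f"{key}_tracks.csv", ts)
        for tau, durs in self.survivals.items():
            pd.DataFrame({"duration_s": durs}).to_csv(
                out / f"survival_tau{tau:g}.csv", index=False)
        return out


def run_batch(
    dataset: DataSet,
    tracking: dict[float, TrackingParams],
    detection_threshold_k: float = 6.0,
    pixel_size_um: float = 0.16,
    stages: tuple[str, ...] = ("detect", "track", "analyze"),
    seed: int = 0,
) -> AnalysisBatch:
    """Apply detection, linking and survival analysis to every movie.

    Per-movie failures are isolated: the error is logged and recorded in
    ``batch.errors`` and the remaining movies still run.  The detection
    threshold is ``detection_threshold_k`` times the robust standard
    deviation of each movie's filtered first frame (the suggestion is
    computed per movie, applied explicitly here as the batch's policy).
    """
    batch = AnalysisBatch(dataset=dataset, tracking=dict(tracking),
                          detection_threshold_k=detection_threshold_k,
                          pixel_size_um=pixel_size_um, seed=seed)
    from .linking import track_survival_times

    for entry in dataset.movies:
        key = entry.path.stem
        try:
            tau = entry.frame_cycle_time
            params = tracking[tau]
            if "detect" in stages:
                stack = tifffile.imread(entry.path)
                if stack.ndim == 2:
                    stack = stack[None]
                thr = mad_threshold(wavelet_filter(stack[0].astype(float)),
                                    k=detection_threshold_k)
                roi = read_roi_mask(entry.roi_path) if entry.roi_path else None
                locs = detect_movie(stack, thr, pixel_size_um=pixel_size_um,
                                    roi_mask=roi)
                batch.localizations[key] = locs
            if "track" in stages:
                locs = batch.localizations[key]
                batch.tracks[key] = nearest_neighbour_link(
                    locs, params, tau, source=key)
            if "analyze" in stages:
                ts = batch.tracks[key]
                durs = track_survival_times(
                    ts, min_span_frames=params.min_track_length_bound)
                prev = batch.survivals.get(tau, np.empty(0))
                batch.survivals[tau] = np.concatenate([prev, durs])
        except Exception as exc:  # noqa: BLE001 - per-movie isolation
            logger.exception("movie %s failed", entry.path)
            batch.errors[key] = f"{type(exc).__name__}: {exc}"
    return batch


def export_tracks(batch: AnalysisBatch, out_dir, format: str = "csv") -> list[Path]:
    """One tracks CSV per movie with the documented stable schema."""
    if format != "csv":
        raise ValueError("only csv export is supported")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for key, ts in batch.tracks.items():
        p = out / f"{key}_tracks.csv"
        write_tracks_csv(p, ts)
        paths.append(p)
    return paths
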