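"""Model-free nearest-neighbour linking with optional one-frame gap bridging.

The assignment between two frames is symmetric-greedy: all candidate pairs
within the tracking radius are sorted by distance and linked greedily, each
spot and each track used at most once.  A track that found no continuation in
frame t+1 may bridge one gap: its candidate pairs to frame t+2 (true Euclidean
distance from the last seen position) compete in the same greedy pass with
ordinary continuations and implicitly with new-track creation, so a spot
claimed by a closer ordinary continuation is never stolen by a gap bridge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackingParams",
    "Track",
    "TrackSet",
    "nearest_neighbour_link",
    "segment_bound",
    "track_survival_times",
]


@dataclass(frozen=True)
class TrackingParams:
    """Linking parameters.

    ``assignment`` selects how contested spots are resolved between frame
    pairs: ``"track_order"`` (default) lets each existing track, oldest
    first, claim its nearest unused spot within the radius — each track sees
    its plain nearest neighbour, which is the process the tracking-loss
    theory describes; ``"greedy"`` sorts all candidate pairs by distance and
    links globally (symmetric mutual-nearest behaviour, fewer erroneous
    links at high density).
    """

    tracking_radius_um: float
    max_gap_frames: int = 0
    min_frames_before_gap: int = 2
    min_track_length_bound: int = 2
    assignment: str = "track_order"

    def __post_init__(self) -> None:
        if self.tracking_radius_um <= 0:
            raise ValueError("tracking_radius_um must be > 0")
        if self.max_gap_frames not in (0, 1):
            raise ValueError("max_gap_frames must be 0 or 1")
        if self.assignment not in ("track_order", "greedy"):
            raise ValueError("assignment must be 'track_order' or 'greedy'")


@dataclass
class Track:
    track_id: int
    frames: np.ndarray  # strictly increasing frame indices of detections
    positions: np.ndarray  # (n, 2) x, y in µm
    gap_flags: np.ndarray  # bool; True where the PREVIOUS frame was bridged

    @property
    def n_detections(self) -> int:
        return len(self.frames)

    @property
    def span_frames(self) -> int:
        """Number of frames spanned, gap frames included."""
        return int(self.frames[-1] - self.frames[0]) + 1

    def jumps(self, include_gap: bool = False) -> np.ndarray:
        """Displacement vectors between consecutive detections; jumps across
        bridged gap frames are excluded unless requested."""
        if self.n_detections < 2:
            return np.empty((0, 2))
        d = np.diff(self.positions, axis=0)
        if include_gap:
            return d
        return d[~self.gap_flags[1:]]


@dataclass
class TrackSet:
    tracks: list[Track]
    params: TrackingParams
    frame_cycle_time: float  # s
    source: str = ""

    def __len__(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for f, (x, y), g in zip(tr.frames, tr.positions, tr.gap_flags):
                rows.append((tr.track_id, int(f), float(f) * self.frame_cycle_time,
                             x, y, bool(g)))
        return pd.DataFrame(rows, columns=[
            "track_id", "frame", "time_s", "x_um", "y_um", "gap_flag"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, params: TrackingParams,
                       frame_cycle_time: float, source: str = "") -> "TrackSet":
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            tracks.append(Track(
                track_id=int(tid),
                frames=g["frame"].to_numpy(dtype=int),
                positions=g[["x_um", "y_um"]].to_numpy(dtype=float),
                gap_flags=(g["gap_flag"].to_numpy(dtype=bool)
                           if "gap_flag" in g else np.zeros(len(g), bool)),
            ))
        return cls(tracks, params, frame_cycle_time, source)


class _OpenTrack:
    __slots__ = ("track_id", "frames", "positions", "gap_flags", "last_frame")

    def __init__(self, track_id: int, frame: int, pos: np.ndarray):
        self.track_id = track_id
        self.frames = [frame]
        self.positions = [pos]
        self.gap_flags = [False]
        self.last_frame = frame

    def append(self, frame: int, pos: np.ndarray, gap: bool) -> None:
        self.frames.append(frame)
        self.positions.append(pos)
        self.gap_flags.append(gap)
        self.last_frame = frame


def nearest_neighbour_link(
    localizations: pd.DataFrame,
    params: TrackingParams,
    frame_cycle_time: float = 1.0,
    source: str = "",
) -> TrackSet:
    """Link a localization table (columns frame, x_um, y_um) into tracks.

    Spots that cannot be linked to an existing track start a new track.  With
    ``max_gap_frames=1`` a track whose first segment has at least
    ``min_frames_before_gap`` detections may bridge a single missing frame;
    the bridged frame is flagged on the following detection.
    """
    if len(localizations) == 0:
        return TrackSet([], params, frame_cycle_time, source)
    df = localizations.sort_values("frame")
    frames = df["frame"].to_numpy(dtype=int)
    pos = df[["x_um", "y_um"]].to_numpy(dtype=float)

    # duplicate detections are legal but suspicious
    dup = df.duplicated(subset=["frame", "x_um", "y_um"]).to_numpy()
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate localizations kept")

    radius = params.tracking_radius_um
    by_frame: dict[int, np.ndarray] = {
        f: pos[frames == f] for f in np.unique(frames)}

    open_tracks: list[_OpenTrack] = []
    done: list[_OpenTrack] = []
    next_id = 0
    all_frames = sorted(by_frame)
    for f in all_frames:
        spots = by_frame[f]
        # candidate track ends: ordinary (last seen f-1), gap (last seen f-2)
        eligible: list[int] = []
        for ti, tr in enumerate(open_tracks):
            lag = f - tr.last_frame
            if lag == 1 or (lag == 2 and params.max_gap_frames == 1
                            and len(tr.frames) >= params.min_frames_before_gap):
                eligible.append(ti)
        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        if params.assignment == "greedy":
            cands: list[tuple[float, int, int]] = []
            for ti in eligible:
                tr = open_tracks[ti]
                d = np.hypot(*(spots - tr.positions[-1]).T)
                for si in np.nonzero(d <= radius)[0]:
                    cands.append((float(d[si]), ti, int(si)))
            cands.sort(key=lambda t: (t[0], open_tracks[t[1]].track_id, t[2]))
            for dist, ti, si in cands:
                if ti in used_tracks or si in used_spots:
                    continue
                open_tracks[ti].append(f, spots[si],
                                       gap=(f - open_tracks[ti].last_frame == 2))
                used_tracks.add(ti)
                used_spots.add(si)
        else:
            # track_order: established tracks (>= 2 detections, no gap
            # pending) claim their nearest free spot oldest-first — each
            # sees its plain nearest neighbour, as the loss theory assumes;
            # freshly started one-detection tracks and gap bridges then
            # compete by distance.
            phase1 = [ti for ti in eligible
                      if f - open_tracks[ti].last_frame == 1
                      and len(open_tracks[ti].frames) >= 2]
            for ti in sorted(phase1, key=lambda i: open_tracks[i].track_id):
                tr = open_tracks[ti]
                if len(spots) == 0:
                    break
                d = np.hypot(*(spots - tr.positions[-1]).T)
                d[list(used_spots)] = np.inf
                si = int(np.argmin(d))
                if d[si] > radius:
                    continue
                tr.append(f, spots[si], gap=False)
                used_tracks.add(ti)
                used_spots.add(si)
            cands = []
            for ti in eligible:
                if ti in used_tracks or ti in set(phase1):
                    continue
                tr = open_tracks[ti]
                d = np.hypot(*(spots - tr.positions[-1]).T)
                for si in np.nonzero(d <= radius)[0]:
                    if si not in used_spots:
                        cands.append((float(d[si]), ti, int(si)))
            cands.sort(key=lambda t: (t[0], open_tracks[t[1]].track_id, t[2]))
            for dist, ti, si in cands:
                if ti in used_tracks or si in used_spots:
                    continue
                open_tracks[ti].append(f, spots[si],
                                       gap=(f - open_tracks[ti].last_frame == 2))
                used_tracks.add(ti)
                used_spots.add(si)
        for si in range(len(spots)):
            if si not in used_spots:
                open_tracks.append(_OpenTrack(next_id, f, spots[si]))
                next_id += 1
        # close tracks that can no longer be continued
        still_open = []
        for tr in open_tracks:
            max_lag = 1 + (params.max_gap_frames
                           if len(tr.frames) >= params.min_frames_before_gap else 0)
            if f - tr.last_frame >= max_lag and tr.last_frame < f:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
    done.extend(open_tracks)

    tracks = [
        Track(
            track_id=tr.track_id,
            frames=np.asarray(tr.frames, dtype=int),
            positions=np.asarray(tr.positions, dtype=float),
            gap_flags=np.asarray(tr.gap_flags, dtype=bool),
        )
        for tr in sorted(done, key=lambda t: t.track_id)
    ]
    return TrackSet(tracks, params, frame_cycle_time, source)


def segment_bound(
    trackset: TrackSet,
    min_track_length_bound: int | None = None,
    radius_um: float | None = None,
) -> tuple[list[Track], list[Track]]:
    """Split tracks into (bound, mobile) by the time spent within an area.

    A track is bound iff it contains at least ``min_track_length_bound``
    consecutive detections that all lie within ``radius_um`` of the running
    centroid of the window.  The defaults come from the tracking parameters
    (min length) and the tracking radius.
    """
    if min_track_length_bound is None:
        min_track_length_bound = trackset.params.min_track_length_bound
    if radius_um is None:
        radius_um = trackset.params.tracking_radius_um
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    bound, mobile = [], []
    for tr in trackset.tracks:
        if _has_confined_window(tr.positions, min_track_length_bound, radius_um):
            bound.append(tr)
        else:
            mobile.append(tr)
    return bound, mobile


def _has_confined_window(p: np.ndarray, min_len: int, radius: float) -> bool:
    """True if some window of >= min_len consecutive points stays within
    ``radius`` of its running centroid while the window grows."""
    n = len(p)
    if n < min_len:
        return False
    if min_len <= 1:
        return True
    for i in range(n - min_len + 1):
        centroid = p[i].astype(float).copy()
        confined_len = 1
        for j in range(i + 1, n):
            centroid += (p[j] - centroid) / (j - i + 1)
            window = p[i:j + 1]
            if np.any(np.hypot(*(window - centroid).T) > radius):
                break
            confined_len = j - i + 1
            if confined_len >= min_len:
                return True
    return False


def track_survival_times(trackset: TrackSet,
                         min_span_frames: int = 1) -> np.ndarray:
    """Track lifetimes in seconds: (frames spanned - 1) * frame-cycle time.
    Gap frames count toward the span (bridging preserves the temporal
    information).  Tracks spanning fewer than ``min_span_frames`` frames are
    excluded."""
    tau = trackset.frame_cycle_time
    spans = np.array([tr.span_frames for tr in trackset.tracks], dtype=int)
    spans = spans[spans >= min_span_frames]
    return (spans - 1) * tau
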