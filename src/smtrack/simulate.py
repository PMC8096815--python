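"""Synthetic single-molecule time-lapse data.

Ground truth is generated event-driven (Gillespie direct method) rather than
by small fixed time steps: for each molecule the times of dissociation and
photobleaching are drawn first, and positions are only evaluated at the frame
times that the molecule is actually alive.  Movies are rendered by placing an
integrated 2D Gaussian PSF per visible molecule on a noisy background.

Two levels of output are supported:

* coordinate level — detected positions = true positions + localization
  error; this skips rendering/detection and is used for large tracking-loss
  and rate-spectrum experiments;
* image level — 16-bit movie stacks for exercising the detection pipeline.

Motion blur is not simulated; frames are point samples of the trajectory at
the frame-cycle times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from scipy.special import erf

__all__ = [
    "BindingState",
    "SimScenario",
    "GroundTruthTrajectory",
    "SyntheticMovie",
    "gillespie_event_times",
    "simulate_trajectories",
    "sample_localizations",
    "render_movie",
    "write_movie",
    "write_ground_truth",
    "write_scenario",
    "read_scenario",
    "immobile_single_spot",
    "five_state_low_density",
    "five_state_scenario",
]


@dataclass(frozen=True)
class BindingState:
    """One chromatin-binding state of the simulated molecule.

    dissociation_rate : 1/s, rate of leaving the state (track-terminating).
    relative_frequency : probability that a newly appearing molecule is born
        in this state.
    diffusion_coeff : µm²/s apparent diffusion coefficient while in the state.
    """

    dissociation_rate: float
    relative_frequency: float
    diffusion_coeff: float = 1e-3

    def __post_init__(self) -> None:
        if self.dissociation_rate <= 0:
            raise ValueError("dissociation_rate must be > 0")
        if not 0.0 <= self.relative_frequency <= 1.0:
            raise ValueError("relative_frequency must be in [0, 1]")


@dataclass
class SimScenario:
    """Full parameterization of a synthetic time-lapse experiment."""

    molecules_per_frame: int
    states: list[BindingState]
    bleach_prob_per_frame: float
    timelapse_conditions: list[float]  # frame-cycle times tau_tl, s
    exposure_time: float = 0.05  # s
    n_frames: int = 400
    frame_size: tuple[int, int] = (100, 100)  # (H, W) pixels
    psf_width: float = 1.0  # px, Gaussian sigma
    pixel_size_um: float = 0.16
    snr: float = 25.0
    d_bound: float = 1e-3  # µm²/s
    d_free: float = 10.0  # µm²/s
    loc_error_um: float = 0.02  # per-axis localization error sd, µm
    lognormal_shape: float = 0.3
    background_mean: float = 100.0
    background_spread: float = 20.0  # full width of the uniform noise
    structure_sigmas: tuple[float, float] = (2.0, 10.0)  # band-pass DoG, px
    structure_amplitude: float = 2.0  # counts (s.d. of the structured part)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("scenario needs at least one binding state")
        total = sum(s.relative_frequency for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state frequencies must sum to 1, got {total}")
        if not 0.0 <= self.bleach_prob_per_frame <= 1.0:
            raise ValueError("bleach_prob_per_frame must be in [0, 1]")
        if any(t <= 0 for t in self.timelapse_conditions):
            raise ValueError("all frame-cycle times must be > 0")
        if self.n_frames <= 0 or min(self.frame_size) <= 0:
            raise ValueError("n_frames and frame_size must be positive")

    @property
    def sigma0_sq(self) -> float:
        """Squared localization-error contribution to the jump variance, µm²."""
        return 4.0 * self.loc_error_um**2

    def bleach_rate(self, tau_tl: float) -> float:
        """Continuous bleaching rate equivalent to the per-frame probability.

        The per-frame probability a is converted to -ln(1-a)/tau so that the
        event clock and the per-frame survival (1-a)**n agree exactly.
        """
        a = self.bleach_prob_per_frame
        if a >= 1.0:
            return math.inf
        return -math.log1p(-a) / tau_tl


@dataclass
class GroundTruthTrajectory:
    """True positions (µm) of one molecule at the frames it is alive."""

    trajectory_id: int
    frames: np.ndarray  # frame indices where the molecule is visible
    positions: np.ndarray  # (n, 2) true x, y in µm
    state_id: int
    appearance_time: float  # s
    bleach_time: float  # s; inf if the track ended by dissociation
    dissociation_time: float  # s; inf if bleached first

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SyntheticMovie:
    stack: np.ndarray  # (n_frames, H, W) uint16
    frame_cycle_time: float
    ground_truth: list[GroundTruthTrajectory]
    pixel_size_um: float


def gillespie_event_times(
    rates: dict[str, float], rng: np.random.Generator | int,
    t_max: float = math.inf, max_events: int = 1000,
) -> list[tuple[float, str]]:
    """Event times of competing exponential clocks (Gillespie direct method).

    ``rates`` maps event kinds to rates in 1/s.  Returns (time, kind) pairs
    with strictly increasing times up to ``t_max`` (at most ``max_events``
    of them).  Waiting times are drawn from Exp(sum of rates) and the kind
    proportionally to the individual rates.  All rates must be >= 0 with at
    least one > 0.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    kinds = list(rates)
    vals = np.asarray([rates[k] for k in kinds], dtype=float)
    if np.any(vals < 0):
        raise ValueError("rates must be >= 0")
    total = vals.sum()
    if total <= 0:
        raise ValueError("no events possible: all rates are zero")
    probs = vals / total
    events: list[tuple[float, str]] = []
    t = 0.0
    while len(events) < max_events:
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        events.append((t, kinds[rng.choice(len(kinds), p=probs)]))
    return events


def _first_event(scenario: SimScenario, state: BindingState, tau_tl: float,
                 rng: np.random.Generator) -> tuple[float, float]:
    """(dissociation_time, bleach_time) for one molecule, relative to birth."""
    k_off = state.dissociation_rate
    k_bleach = scenario.bleach_rate(tau_tl)
    t_diss = rng.exponential(1.0 / k_off) if k_off > 0 else math.inf
    t_bleach = rng.exponential(1.0 / k_bleach) if k_bleach > 0 else math.inf
    return t_diss, t_bleach


def simulate_trajectories(
    scenario: SimScenario,
    condition_index: int,
    rng_seed: int | np.random.Generator | None = None,
    frame_times: np.ndarray | None = None,
) -> list[GroundTruthTrajectory]:
    """Ground-truth trajectories for one time-lapse condition.

    The number of visible molecules per frame is held at
    ``scenario.molecules_per_frame``: whenever a molecule ends (dissociation
    or photobleaching) a replacement appears in the next frame at a uniform
    random position with its state drawn from the relative frequencies, so
    the spot density stays stationary.

    ``frame_times`` overrides the uniform frame grid (used e.g. for
    interlaced acquisition schemes); by default frames sit at multiples of
    the condition's frame-cycle time.
    """
    if not scenario.states:
        raise ValueError("scenario has no binding states")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    tau = scenario.timelapse_conditions[condition_index]
    if frame_times is None:
        frame_times = np.arange(scenario.n_frames) * tau
    frame_times = np.asarray(frame_times, dtype=float)
    n_frames = len(frame_times)
    H, W = scenario.frame_size
    freqs = np.array([s.relative_frequency for s in scenario.states])
    extent = (W * scenario.pixel_size_um, H * scenario.pixel_size_um)

    trajectories: list[GroundTruthTrajectory] = []
    next_id = 0
    for _slot in range(scenario.molecules_per_frame):
        birth_frame = 0
        while birth_frame < n_frames:
            state_id = int(rng.choice(len(freqs), p=freqs))
            state = scenario.states[state_id]
            birth_time = frame_times[birth_frame]
            t_diss, t_bleach = _first_event(
                scenario, state, tau, rng)
            t_end = birth_time + min(t_diss, t_bleach)
            visible = np.nonzero(
                (frame_times >= birth_time) & (frame_times < t_end))[0]
            if len(visible) == 0:
                # died before its first frame; slot is refilled next frame
                birth_frame += 1
                next_id += 1
                continue
            pos0 = rng.uniform((0.0, 0.0), extent)
            d_state = state.diffusion_coeff
            dts = np.diff(frame_times[visible])
            steps = rng.normal(
                0.0, 1.0, (len(visible) - 1, 2)) * np.sqrt(2 * d_state * dts)[:, None]
            positions = pos0 + np.concatenate(
                [np.zeros((1, 2)), np.cumsum(steps, axis=0)])
            trajectories.append(GroundTruthTrajectory(
                trajectory_id=next_id,
                frames=visible,
                positions=positions,
                state_id=state_id,
                appearance_time=birth_time,
                bleach_time=birth_time + t_bleach if t_bleach < t_diss else math.inf,
                dissociation_time=birth_time + t_diss if t_diss <= t_bleach else math.inf,
            ))
            next_id += 1
            birth_frame = visible[-1] + 1
    return trajectories


def sample_localizations(
    trajectories: Sequence[GroundTruthTrajectory],
    loc_error_um: float,
    rng_seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Coordinate-level detections: true positions plus localization error.

    Returns a localization table (frame, x_um, y_um, trajectory_id) as the
    spot-detection stage would produce it, with per-axis Gaussian error of
    standard deviation ``loc_error_um``.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    frames, xs, ys, ids = [], [], [], []
    for tr in trajectories:
        noisy = tr.positions + rng.normal(0.0, loc_error_um, tr.positions.shape)
        frames.append(tr.frames)
        xs.append(noisy[:, 0])
        ys.append(noisy[:, 1])
        ids.append(np.full(len(tr.frames), tr.trajectory_id))
    if not frames:
        return pd.DataFrame(columns=["frame", "x_um", "y_um", "trajectory_id"])
    df = pd.DataFrame({
        "frame": np.concatenate(frames).astype(int),
        "x_um": np.concatenate(xs),
        "y_um": np.concatenate(ys),
        "trajectory_id": np.concatenate(ids).astype(int),
    })
    return df.sort_values(["frame", "trajectory_id"], ignore_index=True)


def _integrated_gaussian(shape: tuple[int, int], x0: float, y0: float,
                         sigma: float, amplitude: float,
                         stamp_radius: int = 4) -> tuple[np.ndarray, tuple]:
    """Pixel-integrated Gaussian stamp; returns (stamp, (r0, r1, c0, c1))."""
    H, W = shape
    r0 = max(0, int(math.floor(y0)) - stamp_radius)
    r1 = min(H, int(math.floor(y0)) + stamp_radius + 1)
    c0 = max(0, int(math.floor(x0)) - stamp_radius)
    c1 = min(W, int(math.floor(x0)) + stamp_radius + 1)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((0, 0)), (0, 0, 0, 0)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    s = math.sqrt(2.0) * sigma
    gy = 0.5 * (erf((rows - y0 + 0.5) / s) - erf((rows - y0 - 0.5) / s))
    gx = 0.5 * (erf((cols - x0 + 0.5) / s) - erf((cols - x0 - 0.5) / s))
    peak = (0.5 * (erf(0.5 / s) - erf(-0.5 / s))) ** 2
    stamp = amplitude / peak * np.outer(gy, gx)
    return stamp, (r0, r1, c0, c1)


def render_movie(
    trajectories: Sequence[GroundTruthTrajectory],
    scenario: SimScenario,
    condition_index: int,
    rng_seed: int | np.random.Generator | None = None,
) -> SyntheticMovie:
    """Render ground-truth trajectories into a 16-bit movie stack.

    Each visible molecule contributes an integrated 2D Gaussian of width
    ``psf_width`` centred at its sub-pixel position.  The peak amplitude is
    drawn per spot from a lognormal distribution whose median is
    ``snr * sd(background noise)``.  The background is a uniform-noise floor
    plus a weak difference-of-Gaussians-filtered random field approximating
    non-uniform cellular background.  Spots whose centre falls outside the
    frame are not rendered.
    """
    if scenario.psf_width <= 0:
        raise ValueError("psf_width must be > 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    H, W = scenario.frame_size
    n_frames = scenario.n_frames
    px = scenario.pixel_size_um
    bg_sd = scenario.background_spread / math.sqrt(12.0)
    median_amp = scenario.snr * bg_sd

    stack = np.empty((n_frames, H, W), dtype=np.uint16)
    from scipy.ndimage import gaussian_filter

    spots_by_frame: dict[int, list[tuple[float, float]]] = {}
    for tr in trajectories:
        for f, (x_um, y_um) in zip(tr.frames, tr.positions):
            spots_by_frame.setdefault(int(f), []).append((x_um / px, y_um / px))

    for f in range(n_frames):
        frame = scenario.background_mean + rng.uniform(
            -scenario.background_spread / 2, scenario.background_spread / 2, (H, W))
        if scenario.structure_amplitude > 0:
            field_ = rng.standard_normal((H, W))
            s1, s2 = scenario.structure_sigmas
            structure = gaussian_filter(field_, s1) - gaussian_filter(field_, s2)
            sd = structure.std()
            if sd > 0:
                frame += scenario.structure_amplitude / sd * structure
        for x_px, y_px in spots_by_frame.get(f, ()):
            if not (0 <= x_px < W and 0 <= y_px < H):
                continue
            amp = rng.lognormal(math.log(median_amp), scenario.lognormal_shape)
            stamp, (r0, r1, c0, c1) = _integrated_gaussian(
                (H, W), x_px, y_px, scenario.psf_width, amp)
            frame[r0:r1, c0:c1] += stamp
        stack[f] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)

    return SyntheticMovie(
        stack=stack,
        frame_cycle_time=scenario.timelapse_conditions[condition_index],
        ground_truth=list(trajectories),
        pixel_size_um=px,
    )


# ---------------------------------------------------------------------------
# presets for the three standard study scenarios
# ---------------------------------------------------------------------------

_FIVE_RATES = (3e-3, 2e-2, 0.2, 1.3, 10.0)
_FIVE_FREQS = (0.03, 0.06, 0.13, 0.26, 0.52)


def immobile_single_spot(seed: int = 0) -> SimScenario:
    """One effectively immortal, non-bleaching immobile spot (loss-curve
    validation): dissociation and bleaching rates are negligible (1e-15)."""
    return SimScenario(
        molecules_per_frame=1,
        states=[BindingState(dissociation_rate=1e-15, relative_frequency=1.0)],
        bleach_prob_per_frame=1e-15,
        timelapse_conditions=[0.05, 1.0, 5.0],
        n_frames=500,
        seed=seed,
    )


def five_state_scenario(molecules_per_frame: int, seed: int = 0) -> SimScenario:
    """Five binding states (rates 3e-3 … 10 /s at frequencies 3–52 %),
    1 % photobleaching per frame, four time-lapse conditions."""
    states = [BindingState(k, f) for k, f in zip(_FIVE_RATES, _FIVE_FREQS)]
    return SimScenario(
        molecules_per_frame=molecules_per_frame,
        states=states,
        bleach_prob_per_frame=0.01,
        timelapse_conditions=[0.05, 0.3, 1.5, 5.0],
        n_frames=400,
        seed=seed,
    )


def five_state_low_density(seed: int = 0) -> SimScenario:
    """The five-state scenario at 5 molecules per 100x100 px frame."""
    return five_state_scenario(5, seed=seed)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_movie(path, movie: SyntheticMovie) -> None:
    """Write the rendered stack as a multi-page 16-bit TIFF."""
    tifffile.imwrite(path, movie.stack, photometric="minisblack")


def write_ground_truth(path, trajectories: Sequence[GroundTruthTrajectory]) -> None:
    rows = []
    for tr in trajectories:
        for f, (x, y) in zip(tr.frames, tr.positions):
            rows.append((tr.trajectory_id, int(f), x, y, tr.state_id, True))
    pd.DataFrame(rows, columns=[
        "trajectory_id", "frame", "x_um", "y_um", "state_id", "alive",
    ]).to_csv(path, index=False)


def write_scenario(path, scenario: SimScenario) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(scenario), fh, sort_keys=False)


def read_scenario(path) -> SimScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["states"] = [BindingState(**s) for s in data["states"]]
    data["frame_size"] = tuple(data["frame_size"])
    data["structure_sigmas"] = tuple(data["structure_sigmas"])
    return SimScenario(**data)
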