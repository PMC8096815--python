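import math

import numpy as np
import pandas as pd
import pytest

from smtrack import linking, simulate


@pytest.fixture(scope="session")
def single_spot_scenario():
    return simulate.immobile_single_spot()


@pytest.fixture(scope="session")
def rendered_single_spot():
    """One noiseless-position immobile spot rendered at SNR 25; returns
    (frame as float array, true position in px, scenario)."""
    scen = simulate.SimScenario(
        molecules_per_frame=1,
        states=[simulate.BindingState(1e-15, 1.0)],
        bleach_prob_per_frame=1e-15,
        timelapse_conditions=[1.0],
        n_frames=1)
    pos_px = np.array([50.0, 50.0])
    traj = simulate.GroundTruthTrajectory(
        trajectory_id=0, frames=np.array([0]),
        positions=pos_px[None] * scen.pixel_size_um, state_id=0,
        appearance_time=0.0, bleach_time=math.inf, dissociation_time=math.inf)
    movie = simulate.render_movie([traj], scen, 0, rng_seed=11)
    return movie.stack[0].astype(float), pos_px, scen


def make_locs(frames, positions):
    """Localization table from parallel (frame, (x, y)) sequences (µm)."""
    positions = np.asarray(positions, dtype=float)
    return pd.DataFrame({
        "frame": np.asarray(frames, dtype=int),
        "x_um": positions[:, 0],
        "y_um": positions[:, 1],
    })


def make_track(frames, positions, tau=1.0, track_id=0, gap_flags=None):
    frames = np.asarray(frames, dtype=int)
    positions = np.asarray(positions, dtype=float)
    if gap_flags is None:
        gap_flags = np.zeros(len(frames), dtype=bool)
    return linking.Track(track_id=track_id, frames=frames,
                         positions=positions,
                         gap_flags=np.asarray(gap_flags, dtype=bool))


def make_trackset(tracks, tau=1.0, radius=1.0):
    params = linking.TrackingParams(tracking_radius_um=radius)
    return linking.TrackSet(list(tracks), params, tau)


@pytest.fixture
def trackset_factory():
    return make_trackset


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def locs_factory():
    return make_locs
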