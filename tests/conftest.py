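"""Shared fixtures: grids, scenes, and the expensive pipeline runs.

The free-swim pipeline run is session-scoped because the recovery and
permutation-significance checks both consume it.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import efishgrid as eg
from efishgrid.io_cli import poses_to_frame

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def lab_grid() -> eg.GridGeometry:
    """3x3 electrode grid at 30 cm spacing, centered in the lab tank."""
    return eg.GridGeometry.regular((3, 3), 30.0, origin=(45.0, 30.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_states(rng: np.random.Generator, n: int) -> list[eg.DipoleState]:
    """Random poses inside the tank, kept off the electrode plane."""
    out = []
    for _ in range(n):
        out.append(
            eg.DipoleState(
                rng.uniform(10, 140),
                rng.uniform(10, 110),
                rng.uniform(3, 18),
                rng.uniform(0, 2 * np.pi),
            )
        )
    return out


@pytest.fixture(scope="session")
def free_swim_run():
    """Full pipeline on the free-swimming validation scenario (seed 1).

    Returns a dict with the scene, truth table, frequency tracks, pose
    estimates and matched pose pairs; shared by the recovery and
    permutation-test checks.
    """
    seed = 1
    scene = eg.free_swim_scene(duration=40.0, seed=seed)
    samples, truth = eg.synthesize_recording(scene)
    tcfg = eg.TrackerConfig()
    tracks = eg.track_frequencies(samples, scene.fs, scene.grid.n_electrodes, tcfg)
    assert tracks, "frequency tracking found no tracks"
    track = tracks[0]
    obs = [
        eg.measured_observation(track, c.t, scene.grid, tcfg)
        for c in track.candidates
    ]
    tv = truth["t"].to_numpy()
    true_states = [
        eg.DipoleState(*truth.iloc[int(np.argmin(np.abs(tv - o.t)))][
            ["x", "y", "z", "theta"]
        ])
        for o in obs
    ]
    sigma = eg.calibrate_sigma_obs(obs, true_states, scene.grid)
    fcfg = eg.FilterConfig(
        bounds=((0.0, 150.0), (0.0, 120.0), (0.0, 20.0)),
        sigma_obs=sigma,
        seed=seed,
    )
    ests = eg.track_pose(obs, scene.grid, fcfg)
    pose_df = poses_to_frame({0: ests})
    pose_df["track_id"] = "fish1"
    pairs = eg.pairs_from_tables(
        truth, pose_df, scene.grid, time_tolerance=tcfg.hop / 2
    )
    return {
        "scene": scene,
        "truth": truth,
        "tracks": tracks,
        "estimates": ests,
        "pairs": pairs,
        "sigma_obs": sigma,
    }
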