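"""Shared fixtures: small synthetic datasets with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from stackpol.sim import (
    KineticsSimParams,
    MovieParams,
    StackSimParams,
    generate_interface_trajectory,
    render_bead_movie,
    sample_dissociation_times,
)


@pytest.fixture(scope="session")
def small_events():
    """2000 uncensored exponential lifetimes at k = 0.01/s."""
    return sample_dissociation_times(
        KineticsSimParams(k_off=0.01, n_tethers=2000, t_end=2000.0,
                          frame_interval=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def bead_movie():
    """50-tether movie with clusters and debris; mean lifetime 100 frames."""
    ds = sample_dissociation_times(
        KineticsSimParams(k_off=0.002, n_tethers=50, t_end=2000.0,
                          frame_interval=5.0, seed=2)
    )
    params = MovieParams(noise_sigma=5.0, n_clustered=2, n_debris=3, seed=5)
    return render_bead_movie(ds, params), ds


@pytest.fixture(scope="session")
def strong_stack_traj():
    """Strong-stack (G|C-like) interface trajectory, 4000 frames, 300 K."""
    return generate_interface_trajectory(
        StackSimParams(delta_g=-2.1, base_5p="G", base_3p="C",
                       n_frames=4000, seed=21)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
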