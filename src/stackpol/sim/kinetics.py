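"""Synthetic force-clamp dissociation data.

Under a constant-force clamp, tether dissociation is a first-order process:
the surviving fraction decays as ``y(t) = y0 + A * exp(-k t)``, where the
baseline ``y0`` collects tethers that never dissociate (nonspecifically
stuck beads, multiply-tethered beads that survive the run). The generator
inverts that model: each non-baseline tether draws an exponential lifetime
with rate ``k_off``, lifetimes beyond the observation window are censored,
and all observed times are snapped to the camera's save grid so the
generator and the event detector share a time base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from stackpol.datatypes import DissociationDataset


@dataclass(frozen=True)
class KineticsSimParams:
    """Ground-truth parameters for one simulated force-clamp run.

    Parameters
    ----------
    k_off
        True dissociation rate, 1/s.
    n_tethers
        Number of tethers in the field of view.
    t_end
        Observation window, seconds (``inf`` disables end-of-run censoring).
    frame_interval
        Save-grid spacing, seconds (0 disables snapping). Default 5 s,
        i.e. the 0.2 fps save rate of long force-clamp runs.
    baseline_frac
        Fraction of tethers that never dissociate (the ``y0`` baseline).
    seed
        RNG seed; identical seeds give bit-identical datasets.
    """

    k_off: float
    n_tethers: int
    t_end: float = math.inf
    frame_interval: float = 5.0
    baseline_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_off) and self.k_off > 0):
            raise ValueError(f"k_off must be finite and positive, got {self.k_off}")
        if self.n_tethers < 1:
            raise ValueError("n_tethers must be >= 1")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if not 0.0 <= self.baseline_frac < 1.0:
            raise ValueError("baseline_frac must be in [0, 1)")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be non-negative")


def sample_dissociation_times(
    params: KineticsSimParams, replicate_id: int = 0
) -> DissociationDataset:
    """Draw one synthetic dissociation dataset.

    Baseline tethers and tethers whose exponential lifetime exceeds
    ``t_end`` are recorded at ``t_end`` with ``censored = 1``. Observed
    times are snapped *up* to the save grid (a dissociation is first seen
    on the next saved frame).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_tethers

    is_baseline = rng.random(n) < params.baseline_frac
    times = rng.exponential(1.0 / params.k_off, size=n)

    if params.frame_interval > 0:
        times = np.ceil(times / params.frame_interval) * params.frame_interval
        # a lifetime of exactly 0 would be invisible; first grid point
        times = np.maximum(times, params.frame_interval)

    censored = is_baseline | (times > params.t_end)
    if np.isfinite(params.t_end):
        times = np.where(censored, params.t_end, times)
    else:
        times = np.where(is_baseline, np.inf, times)

    events = pd.DataFrame(
        {
            "tether_id": np.arange(n),
            "time_s": times,
            "censored": censored.astype(int),
            "replicate_id": replicate_id,
        }
    )
    return DissociationDataset(
        events=events,
        t_end=params.t_end,
        frame_interval=params.frame_interval,
    )
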