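"""Shared in-memory containers passed between the pipeline stages.

The two analysis arms exchange data through a small set of plain
dataclasses wrapping pandas/numpy objects:

* :class:`DissociationDataset` — per-tether dissociation times with
  censoring flags (force-clamp arm).
* :class:`ImageStack` — a bead movie plus acquisition metadata and a
  ground-truth sidecar when synthetic.
* :class:`InterfaceSpec` / :class:`InterfaceTrajectory` — the two
  nick-interface nucleotides tracked through a coordinate trajectory
  (geometry arm).
* :class:`RhoThetaSeries` — the per-frame (rho, theta) projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("tether_id", "time_s", "censored", "replicate_id")


@dataclass
class DissociationDataset:
    """Per-tether dissociation events from one or more force-clamp runs.

    Parameters
    ----------
    events
        One row per tether with columns ``tether_id``, ``time_s`` (seconds
        from time zero), ``censored`` (0/1; 1 means the tether survived to
        the end of the observation window), ``replicate_id``.
    t_end
        Observation window length in seconds (``inf`` if uncensored).
    frame_interval
        Acquisition grid spacing in seconds; event times lie on this grid.
    time_zero
        Absolute time (s) of the first frame after reaching target force.
        Event times are already relative to it.
    """

    events: pd.DataFrame
    t_end: float
    frame_interval: float
    time_zero: float = 0.0

    def __post_init__(self) -> None:
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        if (self.events["time_s"] < 0).any():
            raise ValueError("negative dissociation times")

    @property
    def n_total(self) -> int:
        return len(self.events)

    @property
    def n_censored(self) -> int:
        return int(self.events["censored"].sum())

    @property
    def times(self) -> np.ndarray:
        return self.events["time_s"].to_numpy(dtype=float)

    @property
    def censored(self) -> np.ndarray:
        return self.events["censored"].to_numpy(dtype=bool)

    def with_events(self, events: pd.DataFrame) -> "DissociationDataset":
        return replace(self, events=events.reset_index(drop=True))

    @staticmethod
    def concat(datasets: list["DissociationDataset"]) -> "DissociationDataset":
        if not datasets:
            raise ValueError("no datasets to concatenate")
        t_end = max(d.t_end for d in datasets)
        frames = [d.events for d in datasets]
        out = pd.concat(frames, ignore_index=True)
        return DissociationDataset(out, t_end, datasets[0].frame_interval,
                                   datasets[0].time_zero)


@dataclass
class ImageStack:
    """A grayscale movie of tethered beads.

    ``frames`` has shape (n_frames, height, width); pixel units are
    arbitrary camera counts. ``sidecar`` carries acquisition metadata and,
    for synthetic movies, the ground-truth object list (never rendered into
    the pixels themselves).
    """

    frames: np.ndarray
    frame_interval: float
    time_zero: float = 0.0
    sidecar: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_times(self) -> np.ndarray:
        return self.time_zero + np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class InterfaceSpec:
    """Identifies the two nucleotides flanking the nick in a trajectory.

    ``res_id_5p``/``res_id_3p`` are residue numbers; ``base_5p``/``base_3p``
    the base letters (the stack is written 5'X|3'Y). ``anchor_res_ids`` are
    the positionally restrained terminal nucleotides used for frame
    alignment.
    """

    res_id_5p: int
    res_id_3p: int
    base_5p: str
    base_3p: str
    anchor_res_ids: tuple[int, ...]
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.res_id_5p == self.res_id_3p:
            raise ValueError("interface residues must be distinct")
        for b in (self.base_5p, self.base_3p):
            if b not in "ACGT":
                raise ValueError(f"unknown base letter {b!r}")

    @property
    def stack_label(self) -> str:
        return f"{self.base_5p}|{self.base_3p}"


@dataclass
class InterfaceTrajectory:
    """Per-frame coordinates of interface + anchor residues, in nm.

    ``coords`` has shape (n_frames, n_atoms, 3). ``atoms`` has one row per
    atom with columns ``atom_name``, ``res_id``, ``res_name``, ``chain``.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    spec: InterfaceSpec
    temperature: float
    frame_dt_ps: float
    state_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_indices(self, res_id: int) -> np.ndarray:
        return np.flatnonzero(self.atoms["res_id"].to_numpy() == res_id)

    def residue_coords(self, frame: int, res_id: int) -> dict[str, np.ndarray]:
        idx = self.atom_indices(res_id)
        names = self.atoms["atom_name"].to_numpy()[idx]
        return {n: self.coords[frame, i] for n, i in zip(names, idx)}

    def frame_times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt_ps


@dataclass
class RhoThetaSeries:
    """Per-frame (rho, theta) projection of one trajectory.

    ``data`` columns: ``frame``, ``time_ps``, ``rho_nm``, ``theta_deg``,
    ``flag`` (empty string for usable frames, otherwise a reason such as
    ``degenerate_projection``).
    """

    data: pd.DataFrame
    temperature: float
    frame_dt_ps: float
    label: str = ""

    def usable(self) -> pd.DataFrame:
        return self.data[self.data["flag"] == ""]

    @property
    def rho(self) -> np.ndarray:
        return self.usable()["rho_nm"].to_numpy(dtype=float)

    @property
    def theta(self) -> np.ndarray:
        return self.usable()["theta_deg"].to_numpy(dtype=float)
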