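"""Readers and writers for the on-disk formats shared between stages.

* dissociation events — CSV with a ``# key = value`` metadata header
  (units carried in column names);
* bead movies — multi-frame TIFF plus a JSON sidecar with acquisition
  metadata and, for synthetic movies, ground truth;
* interface trajectories — multi-model PDB (Angstrom, standard nucleotide
  atom/residue naming) plus a JSON sidecar carrying temperature, frame
  spacing, and the interface spec;
* (rho, theta) series — plain CSV.

Coordinates are nm in memory and Angstrom in PDB files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from stackpol.datatypes import (
    EVENT_COLUMNS,
    DissociationDataset,
    ImageStack,
    InterfaceSpec,
    InterfaceTrajectory,
    RhoThetaSeries,
)

NM_PER_ANGSTROM = 0.1


# --- events CSV -------------------------------------------------------------

def write_events(dataset: DissociationDataset, path: str | Path) -> None:
    """Write an event table with metadata header lines (# key = value)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# t_end_s = {dataset.t_end}\n")
        fh.write(f"# frame_interval_s = {dataset.frame_interval}\n")
        fh.write(f"# time_zero_s = {dataset.time_zero}\n")
        dataset.events.to_csv(fh, index=False)


def read_events(path: str | Path) -> DissociationDataset:
    """Read an event table written by :func:`write_events`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty events file")
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, val = line.lstrip("# ").split("=", 1)
            meta[key.strip()] = float(val)
    from io import StringIO

    events = pd.read_csv(StringIO(text), comment="#")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return DissociationDataset(
        events=events,
        t_end=meta.get("t_end_s", math.inf),
        frame_interval=meta.get("frame_interval_s", 0.0),
        time_zero=meta.get("time_zero_s", 0.0),
    )


def write_track_events(events: pd.DataFrame, qc: dict, path: str | Path) -> None:
    """Write per-bead tracking outcomes plus a QC-count sidecar."""
    path = Path(path)
    events.to_csv(path, index=False)
    with path.with_suffix(".qc.json").open("w") as fh:
        json.dump(qc, fh, indent=1)


# --- movies -----------------------------------------------------------------

def write_movie(stack: ImageStack, path: str | Path) -> None:
    """Write a movie as multi-frame TIFF + JSON sidecar (<path>.json)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    sidecar = dict(stack.sidecar)
    sidecar.setdefault("frame_interval_s", stack.frame_interval)
    sidecar.setdefault("time_zero_s", stack.time_zero)
    with path.with_suffix(path.suffix + ".json").open("w") as fh:
        json.dump(sidecar, fh, indent=1, default=_jsonify)


def read_movie(path: str | Path) -> ImageStack:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar: dict[str, Any] = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    return ImageStack(
        frames=np.asarray(frames),
        frame_interval=float(sidecar.get("frame_interval_s", 1.0)),
        time_zero=float(sidecar.get("time_zero_s", 0.0)),
        sidecar=sidecar,
    )


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --- trajectories -----------------------------------------------------------

def write_trajectory(traj: InterfaceTrajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB + JSON sidecar (<path>.json)."""
    path = Path(path)
    n_frames, n_atoms, _ = traj.coords.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = traj.coords / NM_PER_ANGSTROM
    stack.set_annotation("atom_name",
                         traj.atoms["atom_name"].to_numpy(dtype="U6"))
    stack.set_annotation("res_id", traj.atoms["res_id"].to_numpy(dtype=int))
    stack.set_annotation("res_name",
                         traj.atoms["res_name"].to_numpy(dtype="U5"))
    stack.set_annotation("chain_id",
                         traj.atoms["chain"].to_numpy(dtype="U4"))
    stack.set_annotation("element", np.array(
        [n[0] for n in traj.atoms["atom_name"]], dtype="U2"))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))

    spec = traj.spec
    sidecar = {
        "temperature_K": traj.temperature,
        "frame_dt_ps": traj.frame_dt_ps,
        "n_frames": int(n_frames),
        "interface": {
            "res_id_5p": spec.res_id_5p,
            "res_id_3p": spec.res_id_3p,
            "base_5p": spec.base_5p,
            "base_3p": spec.base_3p,
            "anchor_res_ids": list(spec.anchor_res_ids),
            "chain": spec.chain,
        },
    }
    if traj.state_labels is not None:
        sidecar["state_labels"] = traj.state_labels.tolist()
    with path.with_suffix(path.suffix + ".json").open("w") as fh:
        json.dump(sidecar, fh, default=_jsonify)


def read_trajectory(path: str | Path,
                    sidecar_path: str | Path | None = None
                    ) -> InterfaceTrajectory:
    """Read a multi-model PDB trajectory plus its JSON sidecar.

    Validates the model count against the sidecar's ``n_frames`` and the
    interface residues' atom names against the six-membered-ring set.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(Path(sidecar_path).read_text())

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"{path}: failed to parse multi-model PDB: {exc}")
    coords = stack.coord * NM_PER_ANGSTROM
    n_frames = coords.shape[0]
    if "n_frames" in sidecar and sidecar["n_frames"] != n_frames:
        raise ValueError(
            f"{path}: sidecar promises {sidecar['n_frames']} frames, "
            f"file has {n_frames} (file truncated at frame {n_frames}?)"
        )
    atoms = pd.DataFrame({
        "atom_name": stack.atom_name,
        "res_id": stack.res_id.astype(int),
        "res_name": stack.res_name,
        "chain": stack.chain_id,
    })
    iface = sidecar["interface"]
    spec = InterfaceSpec(
        res_id_5p=int(iface["res_id_5p"]),
        res_id_3p=int(iface["res_id_3p"]),
        base_5p=iface["base_5p"],
        base_3p=iface["base_3p"],
        anchor_res_ids=tuple(iface["anchor_res_ids"]),
        chain=iface.get("chain", "A"),
    )
    for res_id in (spec.res_id_5p, spec.res_id_3p):
        names = set(atoms.loc[atoms["res_id"] == res_id, "atom_name"])
        needed = {"N1", "C2", "N3", "C4", "C5", "C6"}
        if not needed <= names:
            raise ValueError(
                f"{path}: residue {res_id} lacks ring atoms "
                f"{sorted(needed - names)}"
            )
    labels = sidecar.get("state_labels")
    return InterfaceTrajectory(
        coords=coords,
        atoms=atoms,
        spec=spec,
        temperature=float(sidecar.get("temperature_K", math.nan)),
        frame_dt_ps=float(sidecar.get("frame_dt_ps", math.nan)),
        state_labels=None if labels is None else np.asarray(labels),
    )


# --- (rho, theta) series ----------------------------------------------------

def write_rho_theta(series: RhoThetaSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# temperature_K = {series.temperature}\n")
        fh.write(f"# frame_dt_ps = {series.frame_dt_ps}\n")
        fh.write(f"# label = {series.label}\n")
        series.data.to_csv(fh, index=False)


def read_rho_theta(path: str | Path) -> RhoThetaSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, val = line.lstrip("# ").split("=", 1)
            meta[key.strip()] = val.strip()
    from io import StringIO

    data = pd.read_csv(StringIO(text), comment="#",
                       keep_default_na=False,
                       dtype={"flag": str})
    return RhoThetaSeries(
        data=data,
        temperature=float(meta.get("temperature_K", "nan")),
        frame_dt_ps=float(meta.get("frame_dt_ps", "nan")),
        label=meta.get("label", ""),
    )
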