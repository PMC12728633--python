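"""The (rho, theta) order parameter of a nicked stacking interface.

Each trajectory frame is reduced to two numbers describing the relative
conformation of the interface nucleotides:

* ``rho`` — the Euclidean distance (nm) between the geometric centers of
  the two bases' six-membered rings (purines contribute their
  pyrimidine-like ring, which carries the same N1..C6 atom names);
* ``theta`` — the angle in [0, 180] degrees between the two bases'
  Watson-Crick-face bisector vectors after projection into the xy-plane,
  from the geometric (dot-product) definition of the angle.

The xy-plane is made well defined by first superposing every frame onto a
reference whose helix axis lies along z, using only the positionally
restrained terminal (anchor) nucleotides, so a global rigid motion of the
input frame cannot leak into (rho, theta).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from stackpol.constants import (
    RING_ATOM_NAMES,
    WC_FACE_CARBONS,
)
from stackpol.datatypes import InterfaceSpec, InterfaceTrajectory, RhoThetaSeries

AtomMap = dict[str, np.ndarray]


class MissingRingAtomError(ValueError):
    """A residue lacks one of the six-membered-ring atoms."""


def ring_center(atoms: AtomMap, base: str | None = None) -> np.ndarray:
    """Unweighted geometric center of the six-membered-ring atoms (nm)."""
    missing = [n for n in RING_ATOM_NAMES if n not in atoms]
    if missing:
        where = f" of base {base!r}" if base else ""
        raise MissingRingAtomError(f"missing ring atoms{where}: {missing}")
    return np.mean([np.asarray(atoms[n], dtype=float) for n in RING_ATOM_NAMES],
                   axis=0)


def wc_face_vector(atoms: AtomMap, base: str) -> np.ndarray:
    """Unit vector from the ring center through the Watson-Crick face.

    The face is flanked by two ring carbons — C2/C6 for purines, C2/C4
    for pyrimidines; the vector points from the ring center through their
    midpoint.
    """
    if base not in WC_FACE_CARBONS:
        raise ValueError(f"unknown base letter {base!r}")
    c_a, c_b = WC_FACE_CARBONS[base]
    center = ring_center(atoms, base)
    mid = 0.5 * (np.asarray(atoms[c_a], dtype=float)
                 + np.asarray(atoms[c_b], dtype=float))
    v = mid - center
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("degenerate Watson-Crick face vector")
    return v / norm


def align_frame(
    frame: np.ndarray, reference: np.ndarray, anchor_idx: np.ndarray
) -> np.ndarray:
    """Rigid least-squares superposition of ``frame`` onto ``reference``.

    Only the ``anchor_idx`` atoms enter the fit (Kabsch); the returned
    array is the whole frame under that transform. Raises on fewer than
    three, or collinear, anchors.
    """
    anchor_idx = np.asarray(anchor_idx)
    if anchor_idx.size < 3:
        raise ValueError("need at least 3 anchor atoms")
    a = np.asarray(frame, dtype=float)[anchor_idx]
    b = np.asarray(reference, dtype=float)[anchor_idx]
    a_c, b_c = a.mean(axis=0), b.mean(axis=0)
    if np.linalg.matrix_rank(a - a_c, tol=1e-9) < 2:
        raise ValueError("anchor atoms are collinear")
    rot, _ = Rotation.align_vectors(b - b_c, a - a_c)
    return (np.asarray(frame, dtype=float) - a_c) @ rot.as_matrix().T + b_c


def projected_angle(
    v1: np.ndarray, v2: np.ndarray, eps: float = 1e-6
) -> tuple[float, bool]:
    """Angle (deg, in [0, 180]) between two vectors projected onto xy.

    Returns ``(theta, degenerate)``; ``degenerate`` is True when either
    projected vector is shorter than ``eps`` (the base plane is nearly
    perpendicular to xy and theta is meaningless).
    """
    p1 = np.array([v1[0], v1[1]])
    p2 = np.array([v2[0], v2[1]])
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 < eps or n2 < eps:
        return float("nan"), True
    cosang = np.clip(np.dot(p1, p2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang))), False


def rho_theta_frame(
    atoms_5p: AtomMap, atoms_3p: AtomMap, base_5p: str, base_3p: str
) -> tuple[float, float, bool]:
    """(rho, theta) of one already-aligned frame.

    Returns ``(rho_nm, theta_deg, degenerate)``.
    """
    c5 = ring_center(atoms_5p, base_5p)
    c3 = ring_center(atoms_3p, base_3p)
    rho = float(np.linalg.norm(c5 - c3))
    v5 = wc_face_vector(atoms_5p, base_5p)
    v3 = wc_face_vector(atoms_3p, base_3p)
    theta, degenerate = projected_angle(v5, v3)
    return rho, theta, degenerate


def project_rho_theta(
    traj: InterfaceTrajectory,
    reference: np.ndarray | None = None,
    align: bool = True,
    drop_degenerate: bool = False,
) -> RhoThetaSeries:
    """Project a whole trajectory into the (rho, theta) coordinate system.

    Every frame is first superposed onto ``reference`` (default: the
    trajectory's own first frame) using the anchor residues, then reduced
    with :func:`rho_theta_frame`. Degenerate projections are flagged in
    the ``flag`` column (and kept, preserving frame counts) unless
    ``drop_degenerate``.
    """
    spec = traj.spec
    anchor_idx = np.concatenate(
        [traj.atom_indices(r) for r in spec.anchor_res_ids]
    )
    if reference is None:
        reference = traj.coords[0]

    idx5 = traj.atom_indices(spec.res_id_5p)
    idx3 = traj.atom_indices(spec.res_id_3p)
    names5 = traj.atoms["atom_name"].to_numpy()[idx5]
    names3 = traj.atoms["atom_name"].to_numpy()[idx3]

    rows = []
    times = traj.frame_times_ps()
    for i in range(traj.n_frames):
        frame = traj.coords[i]
        if align:
            frame = align_frame(frame, reference, anchor_idx)
        atoms_5p = dict(zip(names5, frame[idx5]))
        atoms_3p = dict(zip(names3, frame[idx3]))
        rho, theta, degenerate = rho_theta_frame(
            atoms_5p, atoms_3p, spec.base_5p, spec.base_3p
        )
        flag = "degenerate_projection" if degenerate else ""
        rows.append((i, times[i], rho, theta, flag))

    data = pd.DataFrame(
        rows, columns=["frame", "time_ps", "rho_nm", "theta_deg", "flag"]
    )
    if drop_degenerate:
        data = data[data["flag"] == ""].reset_index(drop=True)
    return RhoThetaSeries(
        data=data,
        temperature=traj.temperature,
        frame_dt_ps=traj.frame_dt_ps,
        label=spec.stack_label,
    )
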