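"""Synthetic nicked-interface trajectories.

The generator emulates what an all-atom simulation of a nicked 12-bp
duplex shows at the nick: the two interface bases spend most of their time
stacked at a stable ring-center separation of ~0.5 nm, with transient
unstacking excursions whose frequency grows as the stack weakens (less
negative dG) or the temperature rises. Mechanically it is a two-state
(stacked <-> unstacked) Markov chain over frames:

* per-frame unstacking probability  ``p_u = nu_u * exp(dG / (R T))``
* per-frame restacking probability  ``p_s = nu_s`` (constant)

so both a weaker stack and a hotter bath increase excursion frequency.
Only orderings across dG / temperature are meaningful; the attempt
frequencies are free constants, mirroring the fact that simulated
temperatures are not expected to match experimental ones.

In the stacked state the 5' base fluctuates about the ideal B-form stacked
step (Gaussian rho noise, mean-reverting theta rotation); in the unstacked
state rho is inflated and theta near-uniform. An optional second stacked
substate at a distinct (rho, theta) offset reproduces the bimodal cloud
seen for C|G, where the 5' C can also sit over the five-membered ring of
the G. Terminal-nucleotide anchor atoms are held fixed in every frame,
mimicking position restraints that prevent end fraying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stackpol.constants import (
    BASE_RING_FRAME_NM,
    BFORM_RISE_NM,
    BFORM_TWIST_DEG,
    HELIX_AXIS_OFFSET_NM,
    R_KCAL,
    RESIDUE_NAMES,
    RING_ATOM_NAMES,
)
from stackpol.datatypes import InterfaceSpec, InterfaceTrajectory
from stackpol.geometry import wc_face_vector

#: Step indices (in units of helical steps from the 3' interface base) and
#: residue ids of the minimal scene: two restrained terminal anchors plus
#: the two interface nucleotides of a nicked 12-bp duplex.
_ANCHOR_LAYOUT = ((-5, 1, "T"), (6, 12, "A"))
_RES_ID_3P = 6
_RES_ID_5P = 7

STATE_STACKED_A = 0
STATE_STACKED_B = 1
STATE_UNSTACKED = 2


def n_frames_for_run(duration_ns: float, save_interval_ps: float) -> int:
    """Number of saved frames for a production run of ``duration_ns``."""
    if duration_ns <= 0 or save_interval_ps <= 0:
        raise ValueError("duration and save interval must be positive")
    return int(round(duration_ns * 1000.0 / save_interval_ps))


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _base_at_step(base: str, step: int | float) -> dict[str, np.ndarray]:
    """Ring atoms of ``base`` placed at helical step ``step``, axis on +z."""
    if base not in BASE_RING_FRAME_NM:
        raise ValueError(f"unknown base letter {base!r}")
    off = np.array([HELIX_AXIS_OFFSET_NM[0], HELIX_AXIS_OFFSET_NM[1], 0.0])
    rot = _rot_z(BFORM_TWIST_DEG * step)
    rise = np.array([0.0, 0.0, BFORM_RISE_NM * step])
    return {
        name: rot @ (xyz - off) + rise
        for name, xyz in BASE_RING_FRAME_NM[base].items()
    }


def ideal_stacked_step(
    base_5p: str,
    base_3p: str,
    rise_nm: float = BFORM_RISE_NM,
    twist_deg: float = BFORM_TWIST_DEG,
    axis_offset_nm: tuple[float, float] = HELIX_AXIS_OFFSET_NM,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Idealized B-form coordinates of a 5'X|3'Y stacked dinucleotide step.

    Returns ``(atoms_5p, atoms_3p)``: the six-membered-ring atoms (names
    N1..C6, coordinates in nm) of the two bases. The 3' base sits at z = 0;
    the 5' base is rotated by ``twist_deg`` about the helix axis (+z,
    passing through ``axis_offset_nm`` of the standard base frame) and
    raised by ``rise_nm``. Deterministic; defaults reproduce the ~0.5 nm
    stable ring-center stacking distance.
    """
    for b in (base_5p, base_3p):
        if b not in BASE_RING_FRAME_NM:
            raise ValueError(f"unknown base letter {b!r}")
    off = np.array([axis_offset_nm[0], axis_offset_nm[1], 0.0])
    atoms_3p = {n: xyz - off for n, xyz in BASE_RING_FRAME_NM[base_3p].items()}
    rot = _rot_z(twist_deg)
    rise = np.array([0.0, 0.0, rise_nm])
    atoms_5p = {
        n: rot @ (xyz - off) + rise
        for n, xyz in BASE_RING_FRAME_NM[base_5p].items()
    }
    return atoms_5p, atoms_3p


@dataclass(frozen=True)
class StackSimParams:
    """Two-state interface dynamics parameters.

    Parameters
    ----------
    delta_g
        Stacking free energy driving the unstacking rate, kcal/mol
        (negative = stabilizing).
    temperature
        Bath temperature, K.
    n_frames, frame_dt
        Saved frames and save interval (ps); 10,000 x 25 ps emulates a
        250 ns production run.
    base_5p, base_3p
        Interface base letters (the stack 5'X|3'Y).
    rho_stacked_mean, rho_stacked_sd
        Stacked-state ring-center distance mean/SD, nm. ``None`` mean uses
        the ideal B-form step distance for this base combination.
    theta_diffusion
        Per-frame variance (deg^2) of the mean-reverting theta rotation in
        the stacked state.
    unstacked_rho_scale
        Scale (nm) of the exponential rho inflation while unstacked; 0
        degenerates the unstacked state to the stacked geometry.
    bimodal, bimodal_offset
        Enable a second stacked substate at ``(drho_nm, dtheta_deg)`` from
        the primary one.
    attempt_freq, restack_prob
        Per-frame unstacking attempt frequency and restacking probability.
    rigid_jitter
        Apply a random global rigid transform to every frame (exercises
        anchor-based alignment downstream).
    """

    delta_g: float
    temperature: float = 300.0
    n_frames: int = 10000
    frame_dt: float = 25.0
    base_5p: str = "A"
    base_3p: str = "A"
    rho_stacked_mean: float | None = None
    rho_stacked_sd: float = 0.03
    theta_diffusion: float = 9.0
    unstacked_rho_scale: float = 0.4
    bimodal: bool = False
    bimodal_offset: tuple[float, float] = (-0.12, 70.0)
    bimodal_weight: float = 0.35
    attempt_freq: float = 0.5
    restack_prob: float = 0.2
    rigid_jitter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.rho_stacked_mean is not None and self.rho_stacked_mean <= 0:
            raise ValueError("rho_stacked_mean must be positive")
        for b in (self.base_5p, self.base_3p):
            if b not in "ACGT":
                raise ValueError(f"unknown base letter {b!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed -> Haar-uniform rotation
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _reflect_theta(theta: float) -> float:
    """Fold an angle into [0, 180] by reflection at the boundaries."""
    theta = theta % 360.0
    return 360.0 - theta if theta > 180.0 else theta


def generate_interface_trajectory(params: StackSimParams) -> InterfaceTrajectory:
    """Simulate the two-state stacked/unstacked interface dynamics.

    Returns an :class:`InterfaceTrajectory` whose per-frame coordinates
    hold the two interface residues (moving) plus two terminal anchor
    residues (fixed); ``state_labels`` records the hidden state of each
    frame for validation against downstream detectors.
    """
    rng = np.random.default_rng(params.seed)

    ideal_5p, ideal_3p = ideal_stacked_step(params.base_5p, params.base_3p)
    c3 = np.mean(list(ideal_3p.values()), axis=0)
    c5_ideal = np.mean(list(ideal_5p.values()), axis=0)
    v0 = c5_ideal - c3
    rho_ideal = float(np.linalg.norm(v0))
    rho_mean = params.rho_stacked_mean if params.rho_stacked_mean is not None \
        else rho_ideal

    # signed ideal WC-face angle in the xy-plane: its magnitude is the
    # projected theta of the ideal step, its sign tells which way a +z
    # rotation of the 5' base moves theta
    v5 = wc_face_vector(ideal_5p, params.base_5p)
    v3 = wc_face_vector(ideal_3p, params.base_3p)
    signed = np.degrees(
        np.arctan2(v3[0] * v5[1] - v3[1] * v5[0], v3[0] * v5[0] + v3[1] * v5[1])
    )
    theta_ideal = abs(float(signed))
    theta_sign = 1.0 if signed >= 0 else -1.0

    # hidden-state chain: weaker stack and hotter bath both raise p_unstack
    rt = R_KCAL * params.temperature
    p_unstack = min(1.0, params.attempt_freq * float(np.exp(params.delta_g / rt)))
    p_restack = params.restack_prob
    p_subswitch = 0.005
    # OU persistence for theta in the stacked state; re-entries draw from
    # the stationary law so the theta marginal stays Gaussian
    ou_phi = 0.97
    theta_sd_stat = float(np.sqrt(params.theta_diffusion / (1.0 - ou_phi**2)))

    # atom bookkeeping: anchors first, then 3' and 5' interface residues
    records: list[tuple[str, int, str]] = []
    fixed_coords: list[np.ndarray] = []
    for step, res_id, base in _ANCHOR_LAYOUT:
        atoms = _base_at_step(base, step)
        for name in RING_ATOM_NAMES:
            records.append((name, res_id, RESIDUE_NAMES[base]))
            fixed_coords.append(atoms[name])
    n_anchor_atoms = len(records)
    for res_id, base in ((_RES_ID_3P, params.base_3p), (_RES_ID_5P, params.base_5p)):
        for name in RING_ATOM_NAMES:
            records.append((name, res_id, RESIDUE_NAMES[base]))
    atoms_df = pd.DataFrame(records, columns=["atom_name", "res_id", "res_name"])
    atoms_df["chain"] = "A"

    ideal_3p_arr = np.array([ideal_3p[n] for n in RING_ATOM_NAMES])
    ideal_5p_arr = np.array([ideal_5p[n] for n in RING_ATOM_NAMES])
    anchor_arr = np.array(fixed_coords)

    n = params.n_frames
    coords = np.empty((n, len(records), 3))
    states = np.empty(n, dtype=int)

    state = STATE_STACKED_A
    theta = theta_ideal
    sub_offsets = {STATE_STACKED_A: (0.0, 0.0),
                   STATE_STACKED_B: params.bimodal_offset}

    for i in range(n):
        # -- state transitions
        if state == STATE_UNSTACKED:
            if rng.random() < p_restack:
                if params.bimodal and rng.random() < params.bimodal_weight:
                    state = STATE_STACKED_B
                else:
                    state = STATE_STACKED_A
                theta = theta_ideal + sub_offsets[state][1] + \
                    rng.normal(0.0, theta_sd_stat)
        else:
            if rng.random() < p_unstack:
                state = STATE_UNSTACKED
            elif params.bimodal and rng.random() < p_subswitch:
                state = (STATE_STACKED_B if state == STATE_STACKED_A
                         else STATE_STACKED_A)
                theta = theta_ideal + sub_offsets[state][1] + \
                    rng.normal(0.0, theta_sd_stat)
        states[i] = state

        # -- latent (rho, theta) for this frame
        if state == STATE_UNSTACKED and params.unstacked_rho_scale > 0:
            # clearly separated from the stacked basin: an offset plus an
            # exponential tail, both proportional to the scale
            rho_t = rho_mean + params.unstacked_rho_scale * (
                0.75 + rng.exponential(1.0))
            theta_t = rng.uniform(0.0, 180.0)
        else:
            drho, dtheta = sub_offsets.get(state, (0.0, 0.0))
            rho_t = rho_mean + drho + rng.normal(0.0, params.rho_stacked_sd) \
                if params.rho_stacked_sd > 0 else rho_mean + drho
            target = theta_ideal + dtheta
            if params.theta_diffusion > 0:
                theta = target + ou_phi * (theta - target) + \
                    rng.normal(0.0, np.sqrt(params.theta_diffusion))
            else:
                theta = target
            theta_t = _reflect_theta(theta)
        rho_t = max(rho_t, 1e-3)

        # -- realize atom coordinates: 3' base fixed, 5' base repositioned
        rot = _rot_z(theta_sign * (theta_t - theta_ideal))
        top = (ideal_5p_arr - c5_ideal) @ rot.T + c3 + v0 * (rho_t / rho_ideal)
        frame = np.concatenate([anchor_arr, ideal_3p_arr, top], axis=0)

        if params.rigid_jitter:
            q = _random_rotation(rng)
            t = rng.uniform(-1.0, 1.0, size=3)
            frame = frame @ q.T + t
        coords[i] = frame

    spec = InterfaceSpec(
        res_id_5p=_RES_ID_5P,
        res_id_3p=_RES_ID_3P,
        base_5p=params.base_5p,
        base_3p=params.base_3p,
        anchor_res_ids=tuple(r for _, r, _ in _ANCHOR_LAYOUT),
    )
    return InterfaceTrajectory(
        coords=coords,
        atoms=atoms_df,
        spec=spec,
        temperature=params.temperature,
        frame_dt_ps=params.frame_dt,
        state_labels=states,
    )
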