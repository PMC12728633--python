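"""Physical constants, instrument parameters, and idealized B-form geometry.

Values are grouped by which arm of the analysis consumes them: the
force-clamp kinetics arm (gas constant, centrifuge geometry, bead mass)
and the trajectory-geometry arm (base ring coordinates, helical
parameters).
"""

from __future__ import annotations

import numpy as np

# --- thermodynamics ---------------------------------------------------------

#: Gas constant in kcal mol^-1 K^-1 (used in dG = R*T*ln(k1/k2)).
R_KCAL = 1.987e-3

#: Default "room temperature" for free-energy extraction, in kelvin.
ROOM_TEMPERATURE_K = 298.15

# --- centrifuge force microscope (CFM) --------------------------------------

#: Calibrated effective (buoyancy-corrected) mass of a 2.8 um
#: streptavidin-coated magnetic bead, in grams.
BEAD_EFFECTIVE_MASS_G = 6.9e-12

#: Radial distance from the rotor axis to the sample chamber, in metres.
ROTOR_RADIUS_M = 0.119

#: Rotor speed used for the 15 pN force clamp, in rotations per minute.
FORCE_CLAMP_RPM = 1291.0

#: Image save rate during force-clamp runs (frames per second).
SAVE_FPS = 0.2

# --- MD-style trajectory bookkeeping ----------------------------------------

#: Production run length (ns) and coordinate save interval (ps) that the
#: synthetic trajectory generator emulates; 250 ns / 25 ps = 10,000 frames.
PRODUCTION_NS = 250.0
SAVE_INTERVAL_PS = 25.0

#: Simulated temperature ladder, kelvin.
TEMPERATURE_LADDER_K = (300.0, 320.0, 340.0, 360.0, 380.0, 400.0)

# --- single-stack free energies (kcal/mol) ----------------------------------

#: Measured single base-stack free energies for all 16 ordered dinucleotide
#: combinations across a nick, keyed "X|Y" where X is the 5' base and Y the
#: 3' base. Values are (mean, standard error) in kcal/mol from force-clamp
#: experiments; used here as ground truth when parameterizing the
#: dissociation-time generator.
STACKING_DELTA_G_KCAL: dict[str, tuple[float, float]] = {
    "A|A": (-2.3, 0.2),
    "G|A": (-2.3, 0.2),
    "C|A": (-1.1, 0.1),
    "T|A": (-1.1, 0.1),
    "A|G": (-1.42, 0.04),
    "G|G": (-1.8, 0.2),
    "C|G": (-1.0, 0.1),
    "T|G": (-1.1, 0.2),
    "A|C": (-1.9, 0.1),
    "G|C": (-2.1, 0.1),
    "C|C": (-0.6, 0.1),
    "T|C": (-0.9, 0.2),
    "A|T": (-1.5, 0.2),
    "G|T": (-1.7, 0.1),
    "C|T": (-0.5, 0.1),
    "T|T": (-0.8, 0.2),
}

# --- idealized B-form geometry ----------------------------------------------

#: Helical rise per base step, nm.
BFORM_RISE_NM = 0.34

#: Helical twist per base step, degrees (right-handed about +z).
BFORM_TWIST_DEG = 36.0

#: In-plane position of the helix axis expressed in the standard base
#: reference frame, nm. A fiber-model-style displacement calibrated once so
#: that the ring-center distance rho of an ideal stacked step falls at the
#: stable stacking distance (~0.5 nm) for every ordered base combination.
HELIX_AXIS_OFFSET_NM = (0.0, -0.195)

#: Six-membered-ring heavy atoms in the standard base reference frame
#: (Tsukuba convention, idealized bases), coordinates in nm with the base
#: plane at z = 0. Purines contribute their six-membered (pyrimidine-like)
#: ring, which carries the same atom names.
BASE_RING_FRAME_NM: dict[str, dict[str, np.ndarray]] = {
    "A": {
        "N1": np.array([-0.0668, 0.0532, 0.0]),
        "C2": np.array([-0.1912, 0.1023, 0.0]),
        "N3": np.array([-0.2320, 0.2290, 0.0]),
        "C4": np.array([-0.1267, 0.3124, 0.0]),
        "C5": np.array([0.0071, 0.2771, 0.0]),
        "C6": np.array([0.0369, 0.1398, 0.0]),
    },
    "G": {
        "N1": np.array([-0.0700, 0.0641, 0.0]),
        "C2": np.array([-0.1999, 0.1087, 0.0]),
        "N3": np.array([-0.2342, 0.2364, 0.0]),
        "C4": np.array([-0.1265, 0.3177, 0.0]),
        "C5": np.array([0.0071, 0.2833, 0.0]),
        "C6": np.array([0.0424, 0.1460, 0.0]),
    },
    "C": {
        "N1": np.array([-0.1285, 0.4542, 0.0]),
        "C2": np.array([-0.1472, 0.3158, 0.0]),
        "N3": np.array([-0.0391, 0.2344, 0.0]),
        "C4": np.array([0.0837, 0.2868, 0.0]),
        "C5": np.array([0.1056, 0.4275, 0.0]),
        "C6": np.array([-0.0023, 0.5068, 0.0]),
    },
    "T": {
        "N1": np.array([-0.1284, 0.4500, 0.0]),
        "C2": np.array([-0.1462, 0.3135, 0.0]),
        "N3": np.array([-0.0298, 0.2407, 0.0]),
        "C4": np.array([0.0994, 0.2897, 0.0]),
        "C5": np.array([0.1106, 0.4338, 0.0]),
        "C6": np.array([-0.0024, 0.5057, 0.0]),
    },
}

#: Canonical order of the six-membered-ring atom names.
RING_ATOM_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")

#: Ring carbons flanking the Watson-Crick face, per base class: C2/C6 for
#: purines, C2/C4 for pyrimidines.
WC_FACE_CARBONS: dict[str, tuple[str, str]] = {
    "A": ("C2", "C6"),
    "G": ("C2", "C6"),
    "C": ("C2", "C4"),
    "T": ("C2", "C4"),
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Deoxyribonucleotide residue names used in PDB output.
RESIDUE_NAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
BASE_FROM_RESIDUE = {v: k for k, v in RESIDUE_NAMES.items()}
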