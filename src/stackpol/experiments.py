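"""End-to-end in-silico experiments combining the generators and pipelines.

These drivers reproduce the study designs: a stacked construct and its
no-stack control are measured side by side at fixed force, each as several
replicate fields of tethers, and the stacking free energy is recovered
from the fitted off-rate ratio. Used by the analysis scripts and the
acceptance checks; all randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stackpol.constants import R_KCAL, ROOM_TEMPERATURE_K, STACKING_DELTA_G_KCAL
from stackpol.datatypes import DissociationDataset
from stackpol.kinetics import EnergyResult, measure_stacking_energy
from stackpol.sim import KineticsSimParams, sample_dissociation_times


@dataclass(frozen=True)
class RecoveryDesign:
    """Design of one simulated stacked-vs-control comparison.

    ``k_ctrl`` is the control construct's true off-rate; the stacked
    construct's rate is ``k_ctrl * exp(dg_true / RT)``. Each replicate is
    an independent field of ``n_tethers`` tethers observed for
    ``t_end_factor`` mean lifetimes (the default 5 leaves < 1% censored,
    matching runs carried on until > 95% of tethers dissociate).
    """

    k_ctrl: float = 0.01
    n_tethers: int = 500
    n_replicates: int = 3
    frame_interval: float = 5.0
    t_end_factor: float = 5.0
    temperature: float = ROOM_TEMPERATURE_K
    n_bins: int = 50


def simulate_construct_pair(
    dg_true: float, design: RecoveryDesign, seed: int
) -> tuple[DissociationDataset, DissociationDataset]:
    """Simulate replicate dissociation datasets for a stacked/control pair."""
    rt = R_KCAL * design.temperature
    k_stack = design.k_ctrl * float(np.exp(dg_true / rt))
    reps_s, reps_c = [], []
    for i in range(design.n_replicates):
        reps_s.append(sample_dissociation_times(
            KineticsSimParams(
                k_off=k_stack,
                n_tethers=design.n_tethers,
                t_end=design.t_end_factor / k_stack,
                frame_interval=design.frame_interval,
                seed=seed + i,
            ),
            replicate_id=i,
        ))
        reps_c.append(sample_dissociation_times(
            KineticsSimParams(
                k_off=design.k_ctrl,
                n_tethers=design.n_tethers,
                t_end=design.t_end_factor / design.k_ctrl,
                frame_interval=design.frame_interval,
                seed=seed + 1000 + i,
            ),
            replicate_id=i,
        ))
    return (DissociationDataset.concat(reps_s),
            DissociationDataset.concat(reps_c))


def recover_stacking_energy(
    dg_true: float, design: RecoveryDesign | None = None, seed: int = 1
) -> EnergyResult:
    """Simulate a construct pair and run the full kinetics pipeline.

    The returned :class:`EnergyResult` carries the recovered dG and its
    propagated uncertainty; comparing against ``dg_true`` closes the
    generator -> binning -> exponential fit -> RT ln ratio loop.
    """
    if design is None:
        design = RecoveryDesign()
    stacked, control = simulate_construct_pair(dg_true, design, seed)
    return measure_stacking_energy(
        stacked, control, n_bins=design.n_bins,
        temperature=design.temperature,
    )


def recover_table(
    labels: list[str] | None = None,
    design: RecoveryDesign | None = None,
    seed: int = 1,
) -> dict[str, EnergyResult]:
    """Recover dG for several measured stack polarities (X|Y labels)."""
    if labels is None:
        labels = sorted(STACKING_DELTA_G_KCAL)
    out = {}
    for offset, label in enumerate(labels):
        dg_true, _ = STACKING_DELTA_G_KCAL[label]
        out[label] = recover_stacking_energy(
            dg_true, design, seed + 10000 * offset)
    return out
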