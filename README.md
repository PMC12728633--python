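# stackpol

Polarity-resolved DNA base-stacking energetics: force-clamp dissociation
kinetics and nicked-interface trajectory geometry, with seeded synthetic
data generators so every stage runs and is testable end to end.

## The problem

Bases stacked across a nick in a DNA duplex contribute a small free energy
(−0.5 to −2.5 kcal/mol) that depends not only on which two bases stack but
on their 5′→3′ polarity: a 5′G stacked on a 3′C (written G|C) is
substantially more stable than C|G. Two experimental/computational routes
quantify this:

1. **Force-clamp kinetics.** Microspheres tethered by a short duplex are
   held at constant centrifugal force, F = m_eff·ω²·r (≈15 pN at
   1291 rpm for a 6.9×10⁻¹² g bead at r = 0.119 m). Tether dissociation
   is first-order, so the surviving fraction decays as
   y(t) = y₀ + A·e^(−kt). Comparing a stacked construct's off-rate k₁
   with its no-stack control's k₂ under an Arrhenius picture gives the
   stacking free energy:

   ΔG_stack = RT·ln(k₁/k₂),  σ_ΔG = RT·√((σ₁/k₁)² + (σ₂/k₂)²).

2. **Interface geometry.** Coordinate trajectories of the two nucleotides
   flanking the nick are reduced to a 2-D order parameter: ρ, the distance
   between the six-membered-ring centers of the two bases, and θ ∈ [0°,
   180°], the angle between their Watson–Crick-face bisector vectors
   projected into the helix-normal plane. Stable stacks sit near
   ρ ≈ 0.5 nm while rotating in θ; weak stacks make frequent ρ excursions,
   and C|G shows a bimodal stacked state (the 5′C can also sit over the
   G's five-membered ring).

This package implements both pipelines — bead-movie tracking and event
calling, survival-curve fitting and energy extraction, (ρ, θ) projection,
polar densities, occupancies, and mixture-model bimodality detection —
plus generators that synthesize dissociation datasets, bead movies, and
interface trajectories with known ground truth.

## Worked example

Recover a stacking energy through the full kinetics pipeline: simulate a
stacked/control construct pair whose true off-rate ratio encodes
−2.1 kcal/mol (k_ctrl = 0.01 s⁻¹, 500 tethers × 3 replicates), then bin,
fit, and extract:

```python
from stackpol.experiments import RecoveryDesign, recover_stacking_energy

result = recover_stacking_energy(-2.1, RecoveryDesign(), seed=1)
print(f"dG = {result.delta_g:+.3f} +/- {result.sigma_delta_g:.3f} kcal/mol")
print(f"k_stack = {result.k_stack.mean:.3e} 1/s, "
      f"k_ctrl = {result.k_ctrl.mean:.3e} 1/s")
```

prints

```
dG = -2.094 +/- 0.008 kcal/mol
k_stack = 2.984e-04 1/s, k_ctrl = 1.023e-02 1/s
```

i.e. the pipeline returns the generating energy within its propagated
uncertainty, with the stacked construct dissociating ~34× slower than the
control. The geometry arm in three lines:

```python
from stackpol.sim import StackSimParams, generate_interface_trajectory
from stackpol import geometry, ensemble

traj = generate_interface_trajectory(
    StackSimParams(delta_g=-2.1, base_5p="G", base_3p="C", seed=21))
series = geometry.project_rho_theta(traj)
print(ensemble.stacked_fraction(series))   # 0.937 at 300 K
```

The numbered scripts under `analysis/` run the complete study: simulate
all 16 polarities and recover their energies (max recovery error
0.045 kcal/mol over the 16 cells, seed 1), track a synthetic bead movie
(50/50 event times within ±1 frame), and project/summarize trajectory
ensembles across the 300–400 K ladder (stacked occupancy falls with
temperature; G|C ≥ C|G and A|C ≥ C|A at every temperature; C|G alone
splits into two stacked clusters). Their small summary tables are written
to `results/`, bulky intermediates to `scratch/`.

A `stackpol` CLI exposes the same stages
(`simulate-kinetics`, `simulate-movie`, `simulate-traj`, `track`, `fit`,
`project`, `ensemble`, `report`); see `stackpol --help`.

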