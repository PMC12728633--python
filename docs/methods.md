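# Methods

This note documents the models behind `stackpol`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
design choices made where the problem was genuinely open.

## Force-clamp kinetics model

A tether under constant force dissociates as a first-order process. The
observable is the fraction of tethers remaining, fitted as

    y(t) = y0 + A · exp(−k t)

where `y0` absorbs the non-dissociating baseline (stuck beads, multiple
tethers that outlive the run) and `A ≈ 1 − y0`. Censored tethers — those
still bound when the run ends — enter the survival curve as survivors in
every bin and are absorbed by `y0`; their event times are never imputed.

The survival curve bins the window `[0, t_end]` into a fixed number of
bins (default **50**, constant across every dataset of one comparison, so
bin *width* adapts when experiment durations differ by orders of
magnitude). The value at a bin is the fraction of tethers whose event
time exceeds the bin's left edge. The fit is unweighted nonlinear least
squares (`scipy.optimize.curve_fit`) with initial guesses `y0` = terminal
bin, `A` = first bin − `y0`, `k = ln 2 / t_half` read off the curve;
occupancy weighting is available behind a flag but off by default, since
nothing in the measurement model prefers it. A bin-robustness diagnostic
(`bin_robustness`) refits at twice the bin count; fitted rates on
well-sampled data move by well under 5%.

Replicates are fitted individually; a construct's off-rate is the
replicate mean ± SD. Where replicates were pooled upstream,
`pool_replicates` re-partitions tethers into random near-equal groups
(default 3, seeded).

The applied force is `F = m_eff · ω² · r` with defaults
`m_eff = 6.9×10⁻¹² g` (calibrated effective bead mass), `r = 0.119 m`,
and 1291 rpm → 15.0 pN.

The stacking free energy compares a stacked construct (1) to its
no-stack control (2) under an Arrhenius picture, where the stack raises
the activation barrier by its binding free energy:

    ΔG = R T (ln k1 − ln k2),   R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹

computed as a log *difference* so antisymmetry under swapping the rates
is exact in floating point. Uncertainty is first-order (delta-method)
propagation of the two rate SDs. The analysis temperature defaults to
**298.15 K** ("room temperature"; config-overridable — the experiments
specify no number).

## Dissociation-time generator

`sample_dissociation_times` inverts the model above: exponential
lifetimes at rate `k_off`, a `baseline_frac` of never-dissociating
tethers, censoring past `t_end`, and snapping of observed times *up* to
the acquisition grid (default 5 s, the 0.2 fps save rate of long runs),
so the generator and the event detector share one time base. Snapping
biases each construct's fitted rate by under 0.5% under the default
designs, and symmetrically, so it cancels in the off-rate ratio.

The standard recovery design (`RecoveryDesign`) is 500 tethers × 3
replicates per construct, `k_ctrl = 0.01 s⁻¹`, windows of 5 mean
lifetimes (>99% dissociation, matching runs carried past 95%
dissociation). Under this design the full pipeline recovers generating
energies across all 16 base combinations with errors well inside
0.15 kcal/mol.

## Bead movies and tracking

`render_bead_movie` draws each tether as a soft-edged disk (dark on
light by default; polarity and noise are config options since the real
camera model is not specified) that reverts to background + Gaussian
noise from its dissociation frame onward. Deliberately touching bead
pairs (centers two radii apart) and irregular multi-lobed debris are
injected as screening fixtures. Ground truth lives only in a JSON
sidecar, never in the pixels, so the tracking arm cannot cheat.

Detection runs a circular Hough transform (scikit-image `hough_circle`)
over radii 3–8 px on a Canny edge map. Because the normalized Hough
accumulator discriminates poorly at small radii (few perimeter pixels),
candidates are ranked for non-maximum suppression by a *circularity
score*: the magnitude of the Pearson correlation between the local patch
and an ideal disk template of the detected radius (≈0.99 for clean
beads, ≤0.78 for debris and touching pairs, ≤0.4 for noise). Screening
then excludes, in order: candidates below the circularity threshold
(default **0.85**, calibrated on generator fixtures to sit between the
bead and debris score distributions), remaining pairs closer than
`min_separation` (12 px; both members marked), and out-of-range radii.
The rule outcome is independent of candidate order.

Each accepted bead's signal is the unbiased per-frame intensity variance
over a fixed disk at its first-frame position — no re-tracking; tether
sway is part of the variance signal. Event calling median-smooths the
trace (window 5), estimates the bound level B and unbound level U as the
medians of the upper and lower halves of the smoothed trace split at its
range midpoint (position-independent, unlike a fixed initial window, so
beads that dissociate early in the run are still called correctly), and
reports the first frame where the trace crosses below
`B − f·(B − U)` (default f = **0.5**) and stays there for **5** frames.
Traces with more than one distinct downward level shift — detected by
greedy binary segmentation into piecewise-constant levels with a minimum
segment length of 10 frames — are excluded as likely multiple tethers.
Constant or drop-free traces (drop < 25% of B) are censored. Event times
are invariant to a global intensity offset because variance is.

On default-noise synthetic movies the end-to-end pipeline recovers
≥95% (typically 100%) of accepted beads' event times within ±1 frame.
Known limitation: a bead whose tether breaks within the first ~2 frames
is indistinguishable from debris or noise and is not called.

## Idealized stacked geometry

`ideal_stacked_step` builds a 5′X|3′Y stacked dinucleotide from standard
base reference frame ring coordinates (Tsukuba-convention idealized
bases; source recorded in `constants.py`) and fiber B-form helical
parameters: rise 3.4 Å and right-handed twist 36° about a helix axis on
+z. With the axis through the base-frame origin, purine six-ring centers
sit only ~2.1 Å off-axis and the step distance comes out near 0.36 nm;
the axis is therefore placed at a calibrated in-plane offset
(0, −1.95 Å) — a fiber-model-style displacement chosen once so that all
16 ordered steps land between 0.42 and 0.54 nm, consistent with the
~0.5 nm stable stacking distance that dynamic ensembles show. Purines
contribute their six-membered ring, which carries the same N1…C6 atom
names as pyrimidine rings, so one code path serves all bases.

## The (ρ, θ) order parameter

For each frame:

* ρ = ‖c₅′ − c₃′‖, the distance between the unweighted geometric centers
  of the two six-membered rings (nm);
* θ = arccos of the normalized dot product of the two Watson–Crick-face
  bisector vectors — each runs from a ring center through the midpoint of
  the face-flanking ring carbons — after zeroing their z-components,
  reported in degrees on [0, 180].

Two readings were genuinely open and are pinned down as follows, each
isolated behind one function so it can be swapped:

* **Face carbons**: C2/C6 for purines, C2/C4 for pyrimidines
  (`WC_FACE_CARBONS`).
* **Projection plane**: the lab xy-plane of an anchor-aligned frame.
  Every frame is rigidly superposed (Kabsch, `scipy` rotations) onto a
  reference whose helix axis lies along z, using only the restrained
  terminal-nucleotide anchor atoms. This makes (ρ, θ) invariant to any
  global rigid motion of the raw frame (verified to <10⁻⁶); projection
  onto the instantaneous base plane is a documented alternative, not
  implemented.

Frames whose projected vectors are shorter than 10⁻⁶ (base plane nearly
perpendicular to xy) are flagged `degenerate_projection` and kept, so
frame counts (10,000 per production run) are preserved; dropping is
opt-in. Internal units are nm and degrees; PDB I/O converts to/from Å
(multi-model PDB via biotite; coordinates round-trip to the format's
10⁻³ Å precision).

## Interface-dynamics generator

`generate_interface_trajectory` emulates what all-atom simulation of a
nicked duplex shows at the nick, without any force field: a two-state
(stacked ↔ unstacked) Markov chain over saved frames with

    p_unstack = ν_u · exp(ΔG / RT),   p_restack = ν_s

(defaults ν_u = 0.5, ν_s = 0.2 per frame). Both a weaker stack (less
negative ΔG) and a hotter bath raise the excursion rate; only *orderings*
across ΔG and temperature are meaningful, because the attempt frequencies
are free constants — mirroring the fact that simulated temperatures need
not match experimental ones. Defaults: 10,000 frames at 25 ps (a 250 ns
production run), temperature ladder 300–400 K in 20 K steps.

Stacked-state geometry fluctuates about the ideal step: Gaussian ρ noise
(SD 0.03 nm) and a mean-reverting (AR(1), persistence 0.97) θ rotation
with per-frame variance 9 deg², whose stationary SD ≈ 12° reproduces the
visible θ rotation of stable stacks; re-entries draw θ from the
stationary law so the stacked θ marginal is exactly Gaussian. Unstacked
frames inflate ρ by an offset-plus-exponential tail scaled by
`unstacked_rho_scale` (default 0.4 nm → excursions to ~1–2 nm) with
near-uniform θ; a scale of zero degenerates the trajectory to the ideal
geometry exactly, which the tests exploit. The optional bimodal mode adds
a second stacked substate at (Δρ, Δθ) = (−0.12 nm, +70°) with weight
0.35 — an inner cluster like the C-over-five-membered-ring geometry seen
for C|G. Terminal anchor residues are held fixed (the analogue of
position restraints against end fraying) and define the alignment frame;
an optional per-frame random rigid jitter exercises the alignment.

What the generator does **not** emulate: force-field energetics, solvent
and ions, hydrogen-bond structure, sequence-dependent helical parameter
variation, or correlated multi-nucleotide motions. Passing tests
therefore validate the *analysis pipelines* (projection, summaries,
detection) and internal consistency of the kinetic mapping — not the
molecular mechanics of real nicked DNA.

## Ensemble summaries

An *excursion* is a maximal run of consecutive frames with ρ above a
cutoff; the cutoff defaults to **0.75 nm**, far enough above the
~0.5 nm stacked distance to flag genuine unstacking rather than in-state
fluctuation (only the stable distance, not an unstacking threshold, is
empirically given). `stacked_fraction` is the fraction of usable frames
at or below the cutoff. Polar densities are normalized 2-D histograms
over (ρ, θ) with flagged frames excluded and counted.

Bimodality detection fits 1- and 2-component full-covariance Gaussian
mixtures (scikit-learn, 5 seeded initializations) and accepts the
2-component model only if it improves the BIC by a margin (default 10).
The fit runs directly in the (ρ, θ) plane, restricted to the stacked
basin (ρ ≤ cutoff): there the θ marginal is far from the 0°/180°
reflection boundaries, the substates are near-Gaussian, and — unlike in
Cartesianized polar coordinates, where a strong stack rotating freely in
θ at fixed ρ traces a curved arc that spuriously favors two components —
model selection cleanly separates unimodal from bimodal dynamics (each
≥90% of seeded runs, typically 20/20). θ-wraparound would matter only
for clusters hugging 0°/180° and is a documented limitation. Cluster
means are reported in (ρ, θ); each cluster's *centroid frame* is the
member frame nearest its mean under per-dimension whitening.

## Problem sizes

Defaults were chosen so the full study runs on a laptop: recovery
designs of 1500 tethers per construct, movies of 50 beads × ~400 frames
at 256², trajectory ensembles of 10,000 frames (analysis scripts) or
1500–4000 frames (tests), 20-seed detector calibrations. All generators
and stochastic analyses take explicit integer seeds, and identical seeds
give bit-identical outputs.
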