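# Methods

This note documents the models, conventions and numerical choices behind
`anchordepth`, and what the synthetic-data generators do and do not emulate.

## Geometry

Structures are flat atom tables (serial, name, residue, chain, element,
coordinate in Å, mass in amu). Masses come from an element lookup
(H 1.008 … P 30.974); unknown elements fall back to 12.0 amu with a logged
warning — centers of mass here feed depth analysis, not thermodynamics, so a
carbon-mass fallback is harmless. Residue numbering is taken verbatim from
the PDB author numbering; only the first alternate location of an atom is
kept (logged). "Backbone" means atom names {N, CA, C, O}.

Superposition is least-squares optimal (Kabsch, via SVD). Atoms are paired
**strictly by order within the selection**; a count mismatch is an error,
never silently re-paired — silent re-pairing is the classic source of wrong
RMSDs. Superposition requires ≥3 non-collinear pairs (collinearity checked
by matrix rank at 1e−8). RMSD is unweighted; whether published loop-RMSD
figures used mass-weighting is generally unstated, and unweighted is the
common convention for backbone selections. Exact-fit RMSDs bottom out at the
SVD noise floor (~1e−7 Å), which the tests treat as zero at 1e−6.

## Membrane layers and depths

Layers are z-levels (mean ± sd of the layer atoms' z), not fitted planes:
systems are built with the membrane normal along z, matching simulation
practice, and the depth metric is defined against "the level of" a layer.
Leaflets are split at the lipid-atom center of mass (overridable); per
leaflet the ordering P outermost → CO → C5 toward the core is asserted
whenever all three layers are present. Lipid atom names per layer class are
configuration (defaults "P", "CO", "C5") because lipid nomenclature varies
across force fields.

Depths are reported as unsigned distances with a separate inserted-beyond
flag; a site exactly at a layer counts as **not** inserted. The proximal
leaflet defaults to the one whose P layer is nearest the protein COM.
Distance bins are half-open and lower-inclusive: [0,5) close, [5,10) near,
[10,15) intermediate, [15,∞) far. Published prose uses both "<4 Å" and
"<5 Å" for "close to phosphate"; 5 Å is the default edge and the 4 Å variant
is available by passing different edges.

## Trajectory analytics

Insertion events are maximal runs where the loop-COM CV sits at least
`min_depth` beyond the P layer on the core side for at least `min_dwell` ns.
Runs separated by gaps shorter than `min_dwell/2` are merged first — there is
no published event formalism, so the gap rule is this package's choice, and
event counts are monotonically non-increasing in both thresholds (tested).
In production use the per-frame P layer should be recomputed (membranes
drift in z); the scripted synthetic membranes are static, so the pipeline
passes the planted level.

Conformer classification fits each frame's loop backbone to basal and
pre-active references; the label is the nearer reference when the two RMSDs
differ by at least a margin (default 0.5 Å), else "ambiguous". A trailing-
window average RMSD (default last 30% of frames, mirroring a
last-30-ns-of-100-ns reporting convention) is returned as the summary.

Best-frame selection is deliberately lexicographic, matching the two-step
procedure it models: superpose the frame's domain backbone on the reference
complex first, then rank frames by |transformed CO-layer z − reference CO
plane z|, breaking ties by domain RMSD, then frame index. A weighted-sum
score is available via `weights=` but is not the default.

## Well-tempered metadynamics engine

Units: kcal/mol, Å, ps, K, amu; k_B = 0.0019872 kcal/mol/K; force/mass →
acceleration conversion 418.4 (kcal/mol/Å)/amu = Å/ps². The integrator is
BAOAB Langevin splitting with defaults friction 1 ps⁻¹, dt 0.002 ps,
T 300 K, and an effective CV mass of 50 amu (loop-scale); a stability guard
rejects dt·ω ≥ 0.1 estimated from the local curvature near the start point.
All-atom integrator machinery (constraint algorithms, hydrogen mass
repartitioning) is explicitly not modeled.

Hills are Gaussians deposited every `pace` ps with the well-tempered height
rule w = w₀·exp(−V_b/k_BΔT), ΔT = (γ−1)T; γ→∞ recovers standard
metadynamics, and hills tempered below 1e−12 kcal/mol are dropped. Bias
evaluation sums the full ledger (no grids or splines): ledgers here are
≤10⁵ hills and exactness beats speed at desk scale. Defaults are w₀ = 2
kcal/mol, σ = 0.2 Å, γ = 15, pace 2 ps.

Walls are one-sided harmonics V = κ·Δ² **without** the ½ factor — the
convention of the common metadynamics plugins whose κ values are quoted in
the literature; a `half_factor` switch is provided. The restraint described
for the motivating system (two bounds on opposite sides of the membrane
region) is realized as one upper and one lower wall with configurable
limits, defaults 14 and 20 in the CV's units.

The free energy is the standard well-tempered point estimate
F̂(s) = −(γ/(γ−1))·V_b(s), gauge-fixed to min F̂ = 0 on the grid; no
time-averaged or reweighted estimators are provided. Wells are local minima
above a prominence threshold; locations are refined by a 3-point parabola
and widths are the basin half-width at 1 k_BT above the minimum (for a
parabolic well of curvature k this equals √(2k_BT/k), which the tests use as
a closed form).

Convergence at desk scale: the double-well benchmark (minima ±1 Å, barrier
3 kcal/mol) uses the production hill parameters and 150k steps (300 ps,
150 hills) per seed; five seeds recover the minima to <0.1 Å on average and
the barrier to well within 20%, and the across-seed spread of barrier
estimates shrinks when runs are 4× longer. Recovering the *curvature* of a
weak harmonic well (k = 2 kcal/mol/Å², features ~1 kcal/mol) is a harder
target: with 2 kcal/mol hills the bias ripples exceed the signal, so that
check runs with gentler hills (w₀ = 0.25, pace 0.5 ps, γ = 5, walls ±1.5 Å,
800 ps), recovering k within 15%. The equipartition check (Var(s) = k_BT/k)
averages three seeded 800 ps runs because a single run of that length
carries ~7% stochastic error on the variance estimate.

## Fluorescence

The quenching statistic uses the background-subtracted **integrated**
intensity over the full 420–600 nm window (trapezoid), not peak height —
the methods convention for these experiments integrates spectra — with peak
height available as a switch. Control pairing (tempoyl ↔ methyl palmitate,
doxyl ↔ stearate) is hard-wired with an override. Negative efficiencies are
reported as negative and flagged, never clipped: an apparent fluorescence
increase under the spin-labeled lipid is a control-side carboxyl artifact,
not a distance readout.

λmax uses 3-point quadratic interpolation by default (deterministic,
sub-grid on a 2 nm step). On a broad (~28 nm σ) band the intensity
difference between adjacent grid points near the top is ~0.25% of the peak,
so percent-level point noise dominates the 3-point estimate; a
noise-robust `method="centroid"` (intensity-weighted mean wavelength above
half maximum) is provided for noisy spectra. Blue-shift significance is
Δλ = λmax(unbound) − λmax(bound) ≥ 10 nm.

Beer–Lambert arithmetic: rhodopsin from the 500 nm bleach
(ε = 0.0408 μM⁻¹cm⁻¹), bimane from A380 (ε = 0.005), arrestin from A280
(ε = 0.02076) after subtracting the bimane's ≈equal contribution at 280 nm
(A380 > A280 is an error); labeling efficiency = [bimane]/[arrestin], 0 in
the unlabeled limit.

## Concordance

Tempoyl quenching is compared against Dist_P and doxyl against Dist_C5,
following the spin-label depths (head-group region vs acyl-chain C5). The
rank statistic is a tie-corrected Spearman correlation of efficiency vs
−distance (degenerate constant columns are reported as 0 with a flag rather
than NaN). The categorical statistic labels a site concordant when
(dist ≤ 10 Å and Q ≥ 10%) or (dist > 15 Å and Q < 10%); sites between the
edges are indeterminate and excluded from the denominator, as are
negative-quenching sites. Both statistics are this package's extension —
the source comparisons are qualitative — and their thresholds are exposed.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec (seed included): membranes are
three pseudo-atoms per lipid (P/CO/C5) on jittered flat layers of an
80 × 80 Å patch (defaults: P ±20 Å, CO ±17.5 Å, C5 ±12 Å, 100 lipids per
leaflet, z-jitter σ 0.3 Å); the toy C-domain carries the 16-site mutant
panel (72, 75, 94, 139, 159, 161, 163, 197, 229, 230, 251, 271, 334, 339,
342, 344) at planted depths plus an 11-residue anchor loop with two
backbone conformers (planted fit-RMSD ≥ 2 Å) and a rigid core block;
trajectories realize piecewise-linear CV paths by rigid z-translation with
isotropic Gaussian coordinate noise and scripted conformer flips; spectra
are single Gaussian bands (λmax 470 nm, σ 28 nm) with planted quenching
factors, planted blue-shifts, multiplicative Gaussian noise (default 1%)
and a deterministic instrument baseline.

None of this reproduces real physics: no lipid conformations, no membrane
deformation or curvature, no force fields, no coupled protein dynamics, no
instrument response curves. Passing tests therefore demonstrate that the
**analysis chain is correct and self-consistent** (planted truths are
recovered at stated tolerances), not that the scientific conclusions of any
particular study are reproduced — the full-scale trajectories and raw
spectra behind published numbers are not public, and quantities like a
1.83 Å loop RMSD or a 2.7±1.8 Å insertion well are not reproducible at desk
scale. The pipeline's default planted panel mirrors the published
qualitative pattern (deep 344-loop insertion in the dark-state pre-complex,
head-group engagement and 197-loop recruitment in the light-activated
high-affinity complex, negative quenching at a few dark-state doxyl sites)
so that the concordance stage has realistic structure to work on.

## Problem sizes

Default test and acceptance-script sizes: 101-frame scripted trajectories,
60–100 lipids per leaflet, 150k-step (300 ps) metadynamics runs with 5
seeds (and 600k-step runs for the convergence-spread check), 400k-step
unbiased runs for equipartition, and 5 × 5–20 replicate spectrum sets.
These sizes were chosen so each suite gives stable statistics while the
whole pipeline remains a desk-scale computation.

## Known limitations

- Layers are flat z-levels; tilted or deformed membranes are out of scope.
- The metadynamics engine is 1D with analytic potentials only; the FES
  estimator is the instantaneous −(γ/(γ−1))V_b, which carries hill-scale
  ripples on weak features.
- Quencher depth is not fitted (no parallax/distribution analysis); the
  package reports raw efficiencies and their geometric concordance only.
- Trajectory I/O covers multi-model PDB (plus an optional runtime NPZ
  cache); DCD/XTC readers are intentionally not a dependency.
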