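# anchordepth

Analytics for how a peripheral protein loop anchors in a lipid bilayer,
combining two complementary readouts: **membrane-insertion depths measured
from structures and coordinate trajectories**, and **depth-dependent
fluorescence quenching measured from emission spectra** — plus the tooling to
ask whether the two agree.

The motivating system is the C-edge of visual arrestin: two loops at the
distal edge of the C-domain β-sandwich (the 344-loop, residues ~336–344, and
the 197-loop) that insert into the rod-cell membrane when arrestin engages
phosphorylated rhodopsin. The same questions recur for any peripheral
membrane anchor: *how deep does each residue sit relative to the lipid
layers, is there a free-energy well at that depth, and do spin-label
quenching experiments see the same geometry?*

## What the package computes

**Depth metrics.** A bilayer is summarized as flat z-layers: the phosphate
(P) layer, the acyl-chain carbon-5 (C5) layer, and the carbonyl (CO) plane,
per leaflet (mean z ± spread of the layer atoms). For a residue site with Cα
position z, the depth metrics are

    Dist_P  = |z − ⟨z_P⟩|,    Dist_C5 = |z − ⟨z_C5⟩|

with a separate flag for whether the site lies beyond the layer on the
membrane-core side. Distances are binned (<5 Å "close", 5–10, 10–15, >15 Å
"far"; a 4 Å variant is configurable).

**Trajectory analytics.** Per-frame loop centre-of-mass z (the insertion
collective variable), insertion-event detection (maximal dwells ≥ a depth
threshold beyond the P layer, with sub-dwell gap merging), classification of
frames against basal vs pre-active loop conformer references by fitted
backbone RMSD, domain-stability RMSD with loops excluded, and two-step
best-frame selection against a reference complex: align each frame's domain
backbone (Kabsch), then pick the frame whose transformed lipid-carbonyl
layer best matches the reference carbonyl plane.

**Well-tempered metadynamics (1D toy engine).** BAOAB Langevin dynamics on
analytic potentials with Gaussian hill deposition

    V_b(s) = Σ_k w_k exp(−(s−s_k)²/2σ²),   w_k = w₀ exp(−V_b(s_k)/k_B ΔT),

ΔT = (γ−1)T, one-sided harmonic walls V = κΔ², and the standard
well-tempered free-energy estimator F̂(s) = −(γ/(γ−1)) V_b(s), followed by
well localization (location, depth, half-width at 1 k_BT). Defaults mirror
the biased-simulation design of the motivating study: w₀ = 2 kcal/mol,
σ = 0.2 Å, γ = 15, one hill per 2 ps, κ = 100, T = 300 K.

**Fluorescence quenching.** Emission spectra (420–600 nm, 2 nm grid) are
background-subtracted, normalized to the unbound-protein spectrum, and
integrated (trapezoid); the quenching efficiency of a spin-labeled fatty
acid versus its matched unlabeled control is

    Q(%) = 100 · (1 − F_spinlabeled / F_unlabeled_control),

with tempoyl (head-group-level spin label) paired to methyl palmitate and
doxyl (C5-level) paired to stearate. Negative efficiencies are flagged, not
clipped. λmax is located at sub-grid resolution and blue-shifts ≥ 10 nm on
binding are classified significant. Beer–Lambert arithmetic converts
absorbance readings into rhodopsin / arrestin / bimane concentrations and a
labeling efficiency.

**Concordance.** Depth maps and quenching tables are joined per site
(tempoyl ↔ Dist_P, doxyl ↔ Dist_C5) and agreement is quantified by a
tie-corrected Spearman correlation of efficiency vs −distance and a
categorical close↔quenched / far↔unquenched agreement fraction. These numeric
statistics are an extension; the underlying comparison in the literature is
qualitative.

**Synthetic data.** Every input has a seeded generator with ground truth
returned alongside: jittered pseudo-lipid membranes (P/CO/C5 atoms per
lipid, 80 × 80 Å patch), a toy C-domain with a 16-site Cα panel and two
planted loop conformers, scripted insertion/flip trajectories, and
Gaussian-band spectrum grids with planted quenching and shifts.

## Worked example

```python
from anchordepth import synth, fluor

spectra, background, truth = synth.make_spectrum_set(synth.SpectrumSpec(site=342, seed=7))
quench, shifts, table = fluor.analyze_spectrum_set(spectra.values(), background=background)
print(table.to_string(index=False))
```

```
 site state quencher  efficiency_pct  negative_quenching  shift_nm  shift_significant
  342  dark  tempoyl       10.883412               False 10.992225               True
  342  dark    doxyl       30.178637               False 10.992225               True
  342 light  tempoyl       30.786642               False 12.914538               True
  342 light    doxyl       21.836633               False 12.914538               True
```

The generator planted efficiencies of 11/30% (dark) and 31/22% (light) with
a 13 nm blue-shift and 1% spectral noise; the recovered table matches to a
fraction of a percentage point, and the site reads as deeply inserted in the
dark state (doxyl ≫ tempoyl) but shifted toward the head-group region on
light activation.

```python
import numpy as np
from anchordepth import metadyn

dw = metadyn.ToyPotential.double_well(barrier=3.0, minimum=1.0)
walls = (metadyn.WallSpec("upper", 2.5, 100.0), metadyn.WallSpec("lower", -2.5, 100.0))
state = metadyn.BiasState()          # hill height 2 kcal/mol, sigma 0.2 A, gamma 15
metadyn.run_biased(dw, state, walls, metadyn.LangevinParams(seed=1), steps=150_000, s0=-1.0)
profile = metadyn.reconstruct_fes(state, np.arange(-2, 2.0001, 0.02))
barrier, wells = metadyn.two_well_barrier(profile, prominence=1.0)
print(f"wells at {wells[0].location:+.2f} and {wells[1].location:+.2f} A, "
      f"barrier {barrier:.2f} kcal/mol from {len(state.hills)} hills")
```

```
wells at -0.90 and +1.00 A, barrier 2.89 kcal/mol from 150 hills
```

A 300 ps well-tempered run recovers the planted minima (±1 Å) and the
3 kcal/mol barrier to within sampling error.

The full end-to-end run (membrane + trajectory + spectra → depth map,
quenching table, concordance report, metadynamics demo) is one call:

```bash
anchordepth pipeline --seed 1 --out out/
```

which writes `report.json`, `depth_map.csv`, `quenching.csv`,
`concordance_records.csv` and a PLUMED-style `hills.dat`.

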