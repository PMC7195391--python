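# kinkgate

Trajectory-analysis pipeline for the two-gate conduction mechanism of
tetrameric K⁺ channels, built around the MthK pore domain.

Lipid composition modulates the ion permeation rate of MthK without
touching the selectivity filter directly. The mechanistic chain runs
through the inner helix: each of the four copies switches between a
**kinked** conformation (broken Val81 O–Gly85 H and Leu82 O–Thr86 H
backbone hydrogen bonds, bending angle ≈ 43° at the Gly83 hinge, closed
filter entrance) and a **bent** conformation (H-bonds formed, ≈ 30°, open
filter entrance — but with the Phe87 side chain swung into the central
cavity, dehydrating it). Opening one gate closes the other: conduction
requires an *asymmetric* tetramer with some subunits bent and some kinked.
`kinkgate` computes every link of that chain from a topology + trajectory
and ships a synthetic trajectory generator that plants the same
statistical structure with known ground truth, so each analysis stage is
verifiable at desk scale.

Intended users: computational biophysicists analysing (possibly restrained)
MD trajectories of tetrameric channels in membranes, and anyone needing a
planted-truth test bed for permeation/gating analysis code.

## What it computes

| Quantity | Definition |
|---|---|
| State labels | per frame/subunit, from d(Val81 O–Gly85 H): bent < 0.27 nm, kinked > 0.45 nm, hysteresis inside the band |
| Bent-state fraction *f*_bent | mean bent indicator over frames and subunits (one permanently bent subunit of four ⇒ 25 %) |
| Ionic current | *I* = (*n*₊ − *n*₋)·*e*/*t* from full filter traversals (three-compartment automaton, periodic-aware) |
| Applied voltage | *V* = *E*·*L* (constant-field protocol; 0.0325 V nm⁻¹ × 9.2308 nm ⇒ 300 mV) |
| Gate geometry | Thr59 Oγ–Oγ, Thr59/Gly61 backbone-O, Pro19 Cα–Cα ring distances; Ile84–Thr59 side-chain distance; Phe87-CoF distance |
| Axial profiles | density and "free energy" −ln(ρ/ρ_max) in k_BT for K⁺ and water; barrier heights; HOLE-style pore radius |
| Membrane | phosphate-leaflet thickness, mean ± SEM |
| Functional modes | PLS regression of superposed backbone coordinates on the bending angle; extreme (kinked/bent) reconstructions |
| Crosstalk table | crossing rate resolved by tetramer configuration *n*_bent ∈ 0…4 |

## Worked example

```python
from kinkgate.synthetic import preset_conduction_regime, generate
from kinkgate.conformation import compute_descriptors
from kinkgate.permeation import analyze_permeation, voltage_from_field

spec = preset_conduction_regime("high_current")   # bent fraction ~0.30 conditions
spec.n_frames = 10000                      # 1 us at 0.1 ns/frame
spec.seed = 42
topology, frames, truth = generate(spec)

desc = compute_descriptors(frames, topology)
records, current = analyze_permeation(frames, topology)

print(f"voltage          : {voltage_from_field(spec.field_v_per_nm, spec.box[2]):.1f} mV")
print(f"bent fraction    : {desc.states.f_bent:.3f} (planted {truth.f_bent:.3f})")
print(f"Thr59 Og-Og gate : {desc.d_ogog.mean():.3f} nm")
print(f"Phe87-CoF        : {desc.d_cof.mean():.3f} nm")
print(f"K+ crossings     : {len(records)} (planted {truth.n_events})")
print(f"ionic current    : {current:.2f} pA")
```

prints

```
voltage          : 300.0 mV
bent fraction    : 0.302 (planted 0.302)
Thr59 Og-Og gate : 0.512 nm
Phe87-CoF        : 0.785 nm
K+ crossings     : 34 (planted 34)
ionic current    : 5.45 pA
```

The classifier recovers the planted bent fraction exactly, the filter-gate
ring distance sits between the all-kinked (0.497 nm) and all-bent
(0.533 nm) planted limits, every planted crossing is detected, and the
current lands on the ~6 pA scale of the high-conduction regime.

For real trajectories, replace the generator with
`trajectory_io.load_topology(...)` + `trajectory_io.iter_frames(...)` —
the analysis functions take the same `(frames, topology)` pair.

## Analysis scripts

The study itself lives in `analysis/`, one thin driver per stage, each
writing its tables under `results/`:

1. `01_generate_replicates.py` — 4 preset conditions × 3 replicates × 1 µs;
   specs + ground-truth summary (trajectories regenerate from seed).
2. `02_conformation_analysis.py` — descriptors, state classification, the
   (bending angle, d_VG) two-mode histogram.
3. `03_permeation_analysis.py` — crossings, currents, mean ± SEM per preset.
4. `04_profiles_analysis.py` — pore radius and water/K⁺ profiles for the
   restrained kinked vs bent states; membrane thickness.
5. `05_functional_modes.py` — FMA of the inner-helix kink, extreme
   conformations as a two-model PDB.
6. `06_crosstalk_report.py` — replicate summary, gp1/gp2 split,
   correlations, configuration-resolved conductance.

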