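# Methods

## The model

The analysis treats each inner helix of the tetramer as a two-state
system. The discriminating observable is the distance between the Val81
backbone oxygen and the Gly85 amide hydrogen (d_VG): formed hydrogen bond
(**bent** state, open filter entrance, Phe87 in the cavity) versus broken
bond (**kinked** state, closed filter entrance, Phe87 outward). The second
hydrogen bond (Leu82 O–Thr86 H), the bending angle at the Gly83 hinge, the
Ile84–Thr59 side-chain contact, the Thr59 Oγ ring and the Phe87-CoF
distance are corroborating descriptors of the same transition, computed
independently so that their mutual correlations are informative rather
than built in.

Assumptions inherited by every stage: the z axis is the membrane normal
and pore axis (a config rotation is the user's responsibility; there is no
auto-detection); boxes are orthorhombic (triclinic input is rejected
explicitly); distances use the minimum-image convention; units are nm, ns,
degrees and pA throughout, converted once at the file boundary.

## State classification

`classify_state` labels a subunit bent when d_VG < t_low (default
0.27 nm, a standard H-bond distance criterion) and kinked when
d_VG > t_high (default 0.45 nm, safely outside bonding); inside the band
the previous label is kept. The hysteresis suppresses label flicker while
d_VG sits near the barrier; a single-cutoff mode (band midpoint) is
available for comparison. The first frame inside the band takes the nearer
threshold, ties going to kinked (the majority state). No published cutoff
exists for this distance — the histogram bimodality constrains it only
loosely — so both thresholds are configurable.

The bent-state fraction is the mean bent indicator over frames and
subunits; one permanently bent subunit of four gives exactly 25 %.
Sampling error of this fraction for a two-state Markov chain is *not*
binomial in the frame count: the variance of the time average over
duration T is ≈ 2 f(1−f)/((k_kb+k_bk)·T) per chain, which is what the
recovery tests use.

## Geometry descriptors

Cross-subunit "ring" distances default to the mean of the two
opposite-subunit (diagonal) distances, with an all-pairs mode available;
the diagonal convention also defines the Ile84 side-chain COM ring
distance. The Ile84–Thr59 side-chain distance is intra-subunit by default
(the residues contact within a subunit in the fold); side chains are
non-backbone heavy atoms including Cβ, mass-weighted, hydrogens excluded.
The bending angle is the angle between principal axes of the Cα sets
before and after the hinge, each axis oriented N→C, so a straight helix
reads 0°. Helix ranges (inner 71–98, hinge 83) are configuration entries
with MthK defaults.

For hydrogen-free topologies the H-bond descriptor falls back to the
heavy-atom O–N distance (flag), and the classification thresholds shift by
+0.1 nm, the canonical N–H bond-length correction.

## Permeation counting

No standard definition of a "permeation event" exists for trajectory
postprocessing, so the detector is operationalized conservatively: the
filter slab is bounded by the Thr59 Oγ plane and the topmost filter
carbonyl plane (± a 0.1 nm margin), and an event requires the visited-
compartment history below → inside → above (outward, +1) or the reverse
(−1). Bounces and partial entries count nothing, which makes the count
robust to long S4-site dwells. Ions are tracked by unwrapped z only; under
an applied field an ion recirculates through the periodic boundary, so the
compartment index is computed on the periodically *lifted* axis (interval
2k/2k+1/2k+2 per box image) — a wrap then reads as continued forward
motion and cannot fire a phantom reverse event. The automaton is verified
against an independently written brute-force enumerator, exhaustively on
all 3⁶ short compartment sequences and on random walks.

Outward (+z) is positive current; I = (n₊ − n₋)·e/t with CODATA
e = 1.602176634·10⁻¹⁹ C. Replicate aggregation reports mean ± SEM (sample
SD/√n); for a single replicate the SEM is reported missing, never 0.
Events are attributed to the tetramer configuration at their entry frame;
because an event spans frames, configurations adjacent in time to
high-rate configurations inherit a small excess — visible in the pooled
configuration table and documented here rather than corrected.

## Axial profiles and pore radius

Profiles count selected atoms inside a cylinder (default radius 0.5 nm)
around the per-frame xy COM of the filter Cα atoms, binned in z (default
0.05 nm, resolving the ~0.3 nm site spacing) relative to the Thr59 Oγ
plane, so different replicates superpose. The "free energy" is
−ln(ρ/ρ_max) in k_BT — under voltage this is a nonequilibrium ensemble
average, hence the quotation marks; the zero is the densest bin because
the true bulk reference is unidentifiable, and only differences (barrier
heights) are used. Zero-count bins are masked, never 0 or ∞.

The pore radius is computed per z-slice as min(xy distance to axis − vdW
radius) over protein heavy atoms in the slab, clamped to [0, r_max] —
fixed-axis slices by default (cheap, sufficient for gate trends), with an
optional per-slice grid search of the centre (0.02 nm step) for HOLE-like
output. This deviates from full HOLE sphere propagation deliberately;
empty slices report r_max with a flag.

Membrane thickness splits phosphates into leaflets by z relative to their
COM per frame and reports the mean inter-leaflet distance ± SEM.

## Functional mode analysis

FMA is implemented as partial least squares — the established formulation
for extracting the collective mode maximally correlated with a scalar
order parameter — on superposed backbone coordinates (N, Cα, C, O; side
chains excluded), with the bending angle of one designated subunit as the
default target. Superposition is a Kabsch fit (tested against an
independent quaternion solver). Frames are time-correlated, so model
validation uses a contiguous 50/50 train/validation split and
cross-validation uses contiguous folds; random splits would be
over-optimistic. Component count is chosen by the one-standard-error rule,
flagged unreliable when the best validation correlation is below 0.5.
Extreme conformations are the training-mean structure displaced along the
unit coefficient vector to the 1st/99th percentile projections; they are
reported in the aligned frame, so comparisons to external structures
require a superposition first.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes —
and only that. Geometry is schematic: helices are parametrized Cα traces
with the named key atoms; only the measured descriptors are planted
faithfully. It is not a physical model: no forces, no integration, no
excluded volume, no water structure, no lipid packing. Subunit chains are
independent continuous-time Markov chains (no cooperativity), sampled
exactly via exponential dwells and started from the stationary
distribution so time averages are unbiased. Crossing ions traverse the
filter in a fixed 2 ns so events are unambiguous at the default
0.1 ns/frame; after a traversal the ion re-enters from the far side, as it
would physically under a periodic field.

Defaults define the study conditions:

* templates: d_VG 0.55/0.20 nm, bending angle 43°/30°, Phe87-CoF
  0.836/0.666 nm, Ile84–Thr59 0.54/0.59 nm (kinked/bent), Thr59 Oγ ring
  0.497→0.533 nm as the bent count grows 0→4 — the restrained-simulation
  benchmark values for this channel;
* switching rates high/mid/low presets at stationary bent fractions
  0.30/0.125/0.03 with total rate 0.05 ns⁻¹ (dwells tens of ns, many
  transitions per µs replicate);
* crossing-rate map λ(n_bent) = {3, 55, 55, 15, 18} events/µs, chosen so
  the preset ensembles land on the ~6 / ~4 / <2 pA current scales, with
  the all-bent configuration suppressed despite its wide filter gate (the
  crosstalk's non-monotonic end) — λ[0] and λ[4] never exceed λ[1..2];
* coordinate noise σ = 0.01 nm (template separation ≫ 5σ, so ≥99 % label
  accuracy is an honest bar), box 8×8×9.2308 nm with field 0.0325 V nm⁻¹
  (300 mV), membrane thickness 3.6 nm, cavity waters 12→2 as bent subunits
  accumulate.

An equilibrium mode replaces driven crossings by i.i.d. Boltzmann samples
from a planted U(z) (flat, harmonic, double-well, Gaussian barrier) for
validating the density → free-energy inversion against a closed form.

Because the generator shares the repository's topology conventions, a
passing pipeline demonstrates correctness of the *computations* on data
with the assumed structure. It does not demonstrate robustness to what
real trajectories add: force-field artefacts, cooperative gating, rapid
recrossings at the state barrier, ions pausing inside the filter across
frames, anisotropic noise, protein drift and rotation (exercised only
through the superposition step), or imperfect atom naming beyond the
H/HN alias.

## Numerical conventions and degenerate inputs

Unwrapping corrects inter-frame jumps ≥ box/2 by the nearest box multiple
and preserves the first value. Selections resolve deterministically;
empty selections warn rather than fail, and each descriptor enforces its
own requirements (exactly one atom/COM per subunit for ring distances,
four protein subunits for tetramer descriptors, glycine rejected where a
side chain is required). Single-frame series pass through unwrapping
unchanged; all-zero densities, fully masked barrier regions, monolayer
phosphate input and collinear superposition selections raise explicit
errors. All stochastic steps (generator, bootstrap) run from seeded
NumPy generators; identical seeds give bit-identical trajectories, ground
truth and report files.

## Open choices made here

Analysis stride and equilibration discard default to 1 and 0 (config
options, not guesses). The gp1/gp2 replicate split uses a bent-fraction
cutoff of 0.125 — half a subunit's worth of bent occupancy — with a median
rule as alternative, since no numeric rule is published. Replicate lengths
in the analysis scripts (1 µs) and the acceptance script (2 µs per
replicate, three replicates per condition) were sized so that Poisson
counting error separates the preset groups cleanly.
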