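# Methods

This note records the model behind each stage of the pipeline, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Phosphate peak search

The map is held on an orthogonal grid and sigma-scaled (values in units of
the map standard deviation above the mean); every threshold in the package
lives on this scale. Peaks are found by thresholding at a ladder of contour
levels (default 1σ to 7σ in 0.25σ steps), partitioning each thresholded map
into face-connected (6-neighbour) components and keeping the densest grid
point of each component. Face connectivity was chosen because it matches
the simplest flood-fill oracle; it is an argument of `find_peaks` in effect
through the level ladder and dedup radius, and the one observable
consequence is that a peak dominates its face neighbours above the contour
but not necessarily diagonal ones (those may belong to a different region).
Peaks closer than 0.75 × the smallest voxel spacing are duplicates; the
densest survives. Peak positions stay on grid nodes by construction — the
peak is literally the densest point of its region, not an interpolated
maximum. The search runs once per map and is cached on the grid object,
keyed by (levels, dedup radius).

## Sugar center and C1′

For a phosphate pair at distance d (pairs beyond 10 Å are not traceable),
the sugar center G is predicted in a cylindrical frame with origin P5′ and
axis toward P3′:

* radial: r(d) = a₁d² + a₂d + a₃ with a₁ = −0.186, a₂ = 1.623, a₃ = −0.124;
* axial: z(d) = b₁d + b₂ with b₁ = 0.440, b₂ = 0.910;
* azimuth ξ: scanned at 2° resolution and refined by golden section to
  maximize the summed 10-point segment density along G→P5′ and G→P3′;
  exact ties resolve to the smallest ξ in [0°, 360°).

C1′ is placed at the empirical mean offset (−1.036, 0.202, −0.601) Å in a
local frame at G: x is the bisector of G→P5′ and G→P3′, z is the unit
normal of the P5′–G–P3′ plane ((G→P5′) × (G→P3′)), and y = x × z completes
the triad (equivalently z = y × x). This orientation is pinned empirically:
on ideal A-form geometry the measured mean C1′ offset in this frame is
(−1.031, 0.222, −0.649), i.e. the tabulated constant is reproduced to
about 0.05 Å per component. On the synthetic A-form fixtures the C1′
prediction from the true sugar center is accurate to 0.05 Å, and the
r/z regressions to ~0.04 Å; the dominant end-to-end error source is the
on-grid quantization of peak positions (up to ~0.4 Å at 0.5 Å voxels) and
a small systematic azimuth bias of straight-segment density scoring on
sharp maps (~10° at the default blur).

All regression constants default to the tabulated values above and are
overridable through the `regression` section of the JSON config.

## Candidate scoring

Each peak within 10 Å of the chain end (minus peaks already claimed by the
trace) becomes a candidate next phosphate with its own G and C1′. Component
scores:

* `s_dist`, `s_angle_p`, `s_angle_s` — likelihood curves for the P–P
  distance, P–P–P angle and C1′–P–C1′ angle, evaluated in likelihood-ratio
  units (curve value over curve maximum, in [0, 1]) so that curves over
  different dimensions share a scale;
* `s_density` — the mean sigma level over the 22 sampled points (ten per
  G-segment, plus G and the candidate phosphate).

The published weights (w_dist = 5, w_angle_p = w_angle_s = 1,
w_density = 15; first step w′_dist = 1, w′_density = 10) are applied to
these commensurable terms. Two combination rules are implemented. The
default is the weighted log-sum (equivalently a weighted product): a
candidate whose angle likelihood is near zero is vetoed regardless of how
dense its path is, which is what makes unattended batch tracing robust —
on clean mixed-conformer 7-mers the additive rule followed a parallel
"sugar track" of non-phosphate peaks in 1 of 4 fixtures while the product
rule recovered ≥ 6/7 phosphates in all of them. The additive rule
(`combine="sum"`) remains selectable and behaves better on very noisy maps,
where the log compresses the density contrast that separates true from
spurious peaks; unattended tracing of noisy maps is outside the tested
envelope either way (interactively, candidate overrides cover it).

## Likelihood curves

The four reference curves (distance, two angles, pseudo-χ) are Gaussian
kernel density estimates tabulated on fixed grids with Silverman bandwidths
and linear interpolation. They are regenerated at run time from an
ideal-geometry ensemble: jittered A-form helices (torsion noise σ = 8°,
~10% syn χ) plus one forward-built fragment per library conformer, all with
0.25 Å seeded coordinate noise. The coordinate noise matters: it makes the
curve widths reflect the positional uncertainty of surveyed and traced
coordinates, without it the distance curve is so sharp that grid-quantized
peak positions fall off it. The angular curves live on [0°, 180°]; the
pseudo-χ curve is periodic and floored at 1% of its maximum so an unusual
(e.g. syn) rotation can never be excluded outright by good density. Curves
serialize to JSON (`grid`, `density`, `bandwidth`, `floor`, `periodic`) so
externally derived tables can be dropped in unchanged.

## Base placement

A 5 Å probe vector from C1′ (about the pyrimidine C1′–C4 span) is scanned
over the hemisphere pointing away from the backbone — the angle to the
bisector of C1′→P5′ and C1′→P3′ must lie in [90°, 180°] — at 5° pitch with
a 1° local rescan. A generic pyrimidine is laid along the probe (C4 on the
ray) and spun about it to maximize

s_base = s_ring_density + w_chi · s_pseudo-χ,  w_chi = 1,

where the ring density sums the sigma-scaled map at the six ring atoms
(exocyclic O2 and N4/O4 are ignored) and the pseudo-χ prior
(P–C1′–N9–N1 for purines, P–C1′–N1–N3 for pyrimidines) is evaluated in
likelihood-ratio units so the two terms are commensurable. The base is then
mutated to the requested type: same-family mutations keep the fitted ring
atoms and rebuild only the exocyclics; purine↔pyrimidine swaps draw the new
base in the same plane with the purine C4–C5 bond midpoint on the
pyrimidine's C1′→C4 direction. The in-plane mirror left open by that
alignment is resolved by pseudo-χ agreement between old and new base — the
glycosidic nitrogen itself sits almost on the alignment axis, so a
nearest-nitrogen rule would be ill-conditioned.

Because a lone pyrimidine ring is nearly two-fold symmetric in density, the
fitted base can land in a mirrored or χ-flipped orientation when C1′ is a
few tenths of an ångström off. Batch tracing therefore finishes with a
discrete orientation check: the four variants generated by 180° rotations
about the probe and glycosidic axes are re-scored against the full base
(all atoms, now type-specific and asymmetric) plus the pseudo-χ prior plus
a geometric prior that the glycosidic bond make its ideal angle (≈119.5°,
a constant of ideal nucleoside geometry) with the direction from the sugar
centroid through C1′. This is the batch stand-in for the interactive
flip/review step. Flips follow the standard rules: pyrimidines rotate 180°
about C1′→mid(C4–C5), purines about the glycosidic axis; both are
involutions.

## Suite conformer prediction

The bundled library holds 52 conformers (46 full members plus the six
promoted ones: 2g, 2u, 2z, 3g, 5n, 5r) with mean torsions and the sugar
puckers implied by their δ values. Within each pucker band the δ means are
collapsed to the band-representative values 84° (C3′-endo) and 145°
(C2′-endo) so that adjacent suites' shared sugar always has one consistent
δ target; the real within-band spread is a few degrees and carries almost
no anchor-space information.

The predictor is a deliberately pluggable stand-in (see
`SuiteClassifier`): each suite's five anchors (C1′ᵢ₋₁, Pᵢ, C1′ᵢ, Pᵢ₊₁,
C1′ᵢ₊₁) are reduced to a 9-dimensional rotation-invariant shape vector —
four consecutive distances, three planar angles, and the pseudotorsion pair
η′ = C1′ᵢ₋₁–Pᵢ–C1′ᵢ–Pᵢ₊₁, θ′ = Pᵢ–C1′ᵢ–Pᵢ₊₁–C1′ᵢ₊₁. Each conformer is
scored by an isotropic Gaussian around the shape of its reference suite,
forward-built once from the torsion means in a canonical flanking context
(A-form-like continuation chosen by pucker), making the classifier
self-consistent with the coordinate machinery. The feature scales (0.45 Å
for distances, 6° for angles, 12° for pseudotorsions) are fixed at the
measurement-noise magnitudes implied by ~0.3 Å anchor uncertainty. Scores
are softmax-normalized to sum to one per suite. Two pseudotorsions alone do
not separate 52 classes at this noise level; the full shape vector gives
top-1 ≈ 79% and top-3 ≈ 98% under 0.3 Å anchor jitter. Conformer abundance
is deliberately not used as a prior.

Whole-trace assignment maximizes the summed log scores by dynamic
programming subject to the chaining invariant that the ending pucker of
each suite equals the leading pucker of the next (independent per-suite
argmaxes can be unbuildable). Terminal suites without flanking anchors are
reported and filled by the chaining step.

Traffic-light flags: yellow when the runner-up scores more than 0.5× the
winner, orange above 0.72× (so a 0.29/0.40 split flags orange), red when
the build residual — the circular RMSD of the built suite's torsions from
its assigned means — exceeds 30°. All three thresholds are config values;
the orange ratio is calibrated to the single published worked example and
documented as such.

## Coordinate calculation

Building is a Cartesian restrained minimization (L-BFGS-B with analytic
gradients; iteration cap 500, gradient tolerance 1e−4):

| term | target | weight (default) |
|---|---|---|
| bonds | ideal lengths | 300 Å⁻² |
| angles | ideal values | 50 rad⁻² |
| suite torsions | assigned conformer means | 20 rad⁻² |
| ν0, ν1, ν4 | pseudorotation targets for the assigned pucker | 50 rad⁻² |
| phosphate position | traced anchor | 100 Å⁻² |
| density | −weight × Σ trilinear map value at atoms | 10 |

The sugar ring is flexible — only the three ν torsions are restrained, with
targets from the pseudorotation formula ν_j = τ_m cos(P + 144°(j−2)) at
τ_m = 38° and P = 15° (C3′-endo) or 160° (C2′-endo). Base atoms stay fixed
at their fitted positions and couple to the backbone through glycosidic
bond/angle restraints. The spring constants other than the density weight
are this package's calibration, chosen so that on noise-free fixtures the
phosphate anchors are satisfied within 0.3 Å and suite torsions within
~5°; all are config-exposed. Initialization is deterministic: the assigned
conformers are forward-built into an ideal chain which is rigidly aligned
onto the anchors, so the minimizer starts in the intended basin and rigid
motions of the inputs produce rigidly moved outputs.

Rotamerization extracts P/C1′/base anchors from an existing model for a
nucleotide span, re-predicts the spanned suites, and re-minimizes only the
span (plus the preceding sugar, which the first suite shares). Junction
geometry is preserved by heminucleotide torsion restraints taken from the
pre-existing coordinates: α/β/γ of the first rebuilt nucleotide at the 5′
side and ε/ζ of the last at the 3′ side (dropped with a log entry at chain
termini). Atoms outside the span are returned bit-identical.

## Synthetic data

The generator forward-builds chains in internal coordinates from suite
torsion means (ribose rings completed by a small least-squares solve
against ring geometry and ν targets), then renders maps by placing an
isotropic Gaussian at every atom, amplitude proportional to atomic number
(so phosphorus dominates, as in experimental maps) and width
σ² = σ₀² + B/(8π²) with σ₀ = 0.6 Å. The default blur B = 40 Å² gives
σ ≈ 0.95 Å, matching a ~3 Å-resolution map under the σ ≈ resolution/π
rule; maps use 0.5 Å voxels and a 4.5 Å margin. Optional white noise is
seeded and expressed in units of the clean map's standard deviation.
Everything is byte-deterministic given the spec (fixed seed).

What the generator does *not* emulate: Fourier truncation ripple, phase
error, solvent contribution, anisotropy, OP1/OP2 atoms and hydrogens
(models carry the P/O5′/C5′/C4′/C3′/O3′/C2′/C1′/O4′/O2′ + base atom set),
crystal packing, and non-RNA density (ions, waters) that produces false
peaks in real maps. Passing the synthetic acceptance suite therefore shows
the pipeline is internally consistent and accurate under clean conditions
approximating a good 3 Å map; it does not bound performance on
experimental maps, where peak recovery and base placement are known to be
substantially harder. Problem sizes in the tests and the acceptance script
(7- and 12-nucleotide chains, 10 jitter replicates per conformer) were
chosen as the smallest sets on which the measured rates are stable.

The default study conditions — 12-mer A-form fixture at 0.5 Å voxels and
default blur, 0.25σ noise for the degraded condition, 0.3 Å anchor jitter
for conformer recovery — are fixed in the acceptance script and mirrored by
`tests/test_acceptance.py`.

## Known limitations

* Unattended tracing assumes clean, well-phased density; on noisy maps the
  candidate override mechanism (`--pick step:index`) is the intended
  workflow, as the default scoring rule can follow spurious peaks.
* The conformer predictor is a geometric stand-in, not a reimplementation
  of the published prediction method; it is self-consistent with the
  builder but its absolute accuracy on experimental coordinates is
  untested. The classifier interface is pluggable for that reason.
* Non-orthogonal map cells are rejected in this version.
* The bundled conformer table carries approximate mean torsions with
  band-harmonized δ values; applications needing the authoritative library
  values should replace `data/conformers.json`.
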