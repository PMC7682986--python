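# Methods

## Scope and model

`polarimap` quantifies how a crosslinker (here: talin-activated vinculin)
organizes actin filaments, through three largely independent analyses that
share conventions and a synthetic-data generator:

1. **Filament polarity in 3D bundles.** Actin filaments are polar
   (barbed/pointed ends). In sub-tomogram averaging, each boxed segment's
   refined orientation — after undoing the rotations applied during
   pre-alignment, projection and helical refinement — carries a psi angle
   (first ZYZ Euler rotation about z) that differs by 180° between the two
   possible polarities of the filament it came from. Per bundle, the psi
   histogram is therefore bimodal with modes half a turn apart.
2. **Equilibrium binding.** With ligand well below its dissociation
   constant and substrate well above it, the locally bound ligand follows
   the mass-action law B = Bmax·A/(K_D + A); the apparent K_D comes from a
   nonlinear least-squares fit of calibrated, background-corrected
   two-channel fluorescence data.
3. **Kinetics.** Filament elongation, bundle zippering, curvature, filament
   counts and branch density are read off TIRF time-lapse data
   (kymographs or tip/length traces), with length ↔ subunit conversion
   through the actin helical rise.

## Polarity pipeline

**Pose-chain inversion.** Orientations are ZYZ intrinsic Euler triples in
degrees, psi first (`R = Rz(psi)·Ry(tilt)·Rz(rot)`). A segment's
in-tomogram orientation is `T1⁻¹·…·Tn⁻¹·R_refined` for the ordered applied
transforms `T1…Tn`; each transform is validated as a proper rotation
(orthonormal, det +1) before inversion. Angles are wrapped to [−180°, 180°).
Near gimbal lock (tilt → 0° or 180°) psi and rot are individually
degenerate; the extraction resolves this by zeroing the third angle, which
keeps psi usable, and the generator and tests avoid tilt within 5° of the
degeneracy.

**Mode detection.** Per bundle (not globally), a von Mises kernel density
estimate (bandwidth 10°, i.e. kappa = 1/σ² in radians, evaluated on a 0.5°
grid) seeds a 2-cluster circular k-means: assign by circular distance,
recompute circular means, iterate to a fixed point. If the smaller cluster
holds < 5% of the larger one's mass the bundle is reported single-mode with
a warning and the separation is undefined. Cluster A is the more populated
mode (ties: the smaller angle), and segment classification assigns the
circularly nearer mode, exact midpoints going to A — both rules exist only
to make reruns reproducible.

**Vote and filter.** A filament's polarity is the majority of its segment
labels; the majority confidence score is max(n_A, n_B)/(n_A + n_B) ∈
[0.5, 1]. Filaments scoring below 2/3 are excluded; the comparison is
inclusive (exactly 2/3 is kept), since the exclusion rule is stated as
"< 2/3". Ties (0.5) always fall below the cutoff, so no separate tie policy
is needed downstream.

**Neighborhood analysis.** For each kept segment, the up-to-3 nearest
segments of *distinct* neighboring filaments within a 40 nm 3D radius
define its neighborhood (KD-tree search on segment centers). The default
"per-filament" semantics — one relation to the nearest segment of each of
the up-to-k nearest distinct filaments — keeps the neighborhood
filament-level, so one adjacent filament cannot monopolize all k slots; a
"per-segment" option (k nearest foreign segments regardless of filament) is
provided because the source description admits either reading. Relations
are directed (counted from every source segment). Each relation is UP
(uniform polarity) if the two filaments' voted polarities match, MP (mixed)
otherwise, and the bundle score is

    S = (MPs − UPs) / (MPs + UPs)  ∈ [−1, +1],

−1 for a fully uniform bundle, +1 when every counted relation is mixed; it
is undefined (error) when no relations exist. S is invariant under a global
polarity flip and under segment reordering. Inter-filament spacing is the
per-segment distance to the nearest segment of any other filament,
summarized per bundle as median and mean ± sd; segment centers (spaced
16.5 nm, dense relative to ~10–30 nm spacings) stand in for fitted axes,
avoiding axis-fitting choices.

**Segment→filament linking** (optional; ground-truth ids are the default
pathway, mirroring the original manual assignment): greedy chaining of
segments within a 33 nm gap (2× segment spacing) and 20° axial deviation;
when two mutually incompatible continuations are available the chain stops,
so ambiguous junctions yield shorter unambiguous pieces.

## Binding quantification

The vinculin channel is thresholded (Otsu by default, fixed value
optional); the background — median intensity outside the mask, a robust
choice the source does not specify — is subtracted from both channels.
Ratio images are per-pixel vinculin/actin inside the mask, excluding pixels
whose corrected actin signal is ≤ 0. Calibration to concentration is a
zero-intercept least-squares slope over 3–5 labelled-protein standards
(closed form Σ C·I / Σ C²), scale-equivariant by construction. The
saturation fit runs on concentration-calibrated values by default (an
intensity-space fit of uncalibrated data is the same code path).

Fit details: `scipy.optimize.curve_fit` with KD, Bmax ≥ 0; default
weighting is iteratively reweighted least squares with sigma proportional
to the model value (3 reweighting passes), the matched estimator when noise
scales with signal as fluorescence-intensity noise does — ordinary
unweighted LS is available. Confidence intervals use the parameter
covariance with a t-distribution on n − 2 df at the 95% level (the level is
a package convention; the source reports intervals without stating one).
A fitted KD below 10⁻³ of the lowest measured concentration flags a
no-curvature boundary; very wide CIs warn.

Line-scan plateau: the profile is averaged over the scan width; candidate
plateau regions are contiguous runs where the profile stays within 10% of
its running median, broken at intensity discontinuities; the run containing
the profile center is preferred (else the longest), must span ≥ 1/4 of the
profile and be genuinely flat about its own median. Ramps therefore have no
plateau (warning, NaN).

## Kinetics

Elongation and zippering rates are ordinary least-squares slopes of tip
position (nm) or zippered length (µm) versus time, hence invariant to
time/space origin. Conversions: rate[subunits/s] = rate[nm/s]/2.76, and
k_on = rate[subunits/s]/[actin, µM]. The 2.76 nm (27.6 Å) rise per subunit
is the constant that makes 38 µm/min ≡ 230 subunits/s at the printed
precision (229.47 exactly).

Kymographs sample each frame along a path (skimage `profile_line`, averaged
across the width); the tip per frame is the maximum intensity drop along
the row, and manual traces are accepted wherever automatic edge tracking
would be unreliable. Curvature of a 2D trace: moving-average smoothing
(default window 5 samples, to be scaled with sampling density and noise),
then 1/R of the circumscribed circle through vertices one window apart on
either side — the wide baseline keeps residual localization noise out of
the second difference; the maximum over vertices is reported. Filament
count is the bundle's integrated profile over a single-filament reference
from the same imaging conditions, rounded (raw ratio also returned). Branch
density is junction nodes (degree ≥ 3) per µm of total filament length.

## Synthetic data: what it does and does not emulate

The generator produces parallel straight filaments on a square lattice
(filament axes along +x, segments every 16.5 nm, ~0.7 µm filaments ≈ 40
segments at full length; defaults use shorter filaments for speed),
polarity patterns uniform / checkerboard-alternating / Bernoulli(p), psi
angles at μ for '+' and μ+180° for '−' with wrapped-normal noise, and
optional positional jitter. Noise models throughout are the simplest ones
matching the measurements' character: wrapped-normal for angles,
multiplicative normal (constant CV) for intensities, additive normal for
tip positions. The angular noise σ of refined orientations is not reported
by upstream refinement software in a quotable form; the default σ = 10° was
chosen once as a realistic scatter for sub-tomogram orientation refinement
and is a free parameter.

Deliberately not modeled: image-formation physics (PSF, TIRF evanescent
decay), tomographic projection/missing wedge, filament curvature at segment
scale (bundles are locally straight over 16.5 nm), photobleaching, and
refinement failure modes other than angular noise. Passing tests therefore
demonstrate the correctness of the *analysis* given poses/images of the
assumed error structure, not robustness to raw-data pathologies.

Every generator is bit-reproducible given its spec (seed included).

## Problem sizes and defaults

Default analysis parameters: segment spacing 16.5 nm, neighborhood radius
40 nm, k = 3, confidence cutoff 2/3 (inclusive), rise 2.76 nm, CI level
95%, KDE bandwidth 10°. Test and acceptance problem sizes — bundles of
5–40 filaments × 10–20 segments, 25-point saturation curves at 5% CV, 10
growth traces of 61 frames, ≤ 500-segment brute-force comparisons — are
desk-scale choices that keep the full suite in a few seconds while leaving
every statistical check well-powered.

## Known limitations

- Mode detection assumes at most two psi modes per bundle; three-way mixed
  orientations would need a larger cluster count.
- The greedy linker is a convenience, not a reconstruction of the original
  manual curation; it deliberately fragments ambiguous junctions and so
  underestimates filament lengths (lengths are not used downstream).
- The kymograph edge tracker assumes a single bright filament per path and
  monotone growth; crossing structures need manual traces.
- `interfilament_spacing` reports segment-center distances; for spacings
  approaching the segment spacing (≲ 16.5 nm) this can overestimate the
  true axis-to-axis distance by up to half a segment spacing in the worst
  alignment.
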