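# Methods

This note records the models behind each stage, the parameters that
matter, and what the synthetic benchmarks do and do not demonstrate.

## Optical model

The focal field is scalar (Debye): per z-plane, a defocus phase
`exp(i·kz·z)` with `kz = √((n·k0)² − kt²)` is applied to the sampled
pupil and the lateral field is a direct 2D Fourier transform onto the
requested grid (default 25-nm sampling over 2.4 µm, 96 pupil samples;
the transform conserves pupil power at conjugate sampling).  The pupil
is uniform inside the aperture (NA 1.35, silicone immersion n 1.40);
the aplanatic √cosθ apodization is applied only where aberration
sensitivity is the point, because a uniform pupil makes the equal-area
top-hat cancellation exact but also makes its zero mathematically
immune to pure primary spherical aberration (the phase term is even in
ρ² about the equal-area radius), which would hide the sensitivity the
aberration analysis measures.

Depletion suppresses emission by `exp(−ln2 · ζ · I_dep/I_peak)` — a CW
approximation without explicit time gating.  ζ (peak depletion
intensity over the fluorophore saturation intensity) is the resolution
knob: the fluorescence-confinement FWHM follows ≈ `(1+c·ζ)^(−1/2)` for
a quadratic pattern minimum.  The saturation intensity of the dye is
not part of the model, so ζ is calibrated rather than derived:
`calibrate_isotropic` fits ζ together with the z/xy power split so that
both lateral and axial FWHM land near the 130-nm isotropic target.  The
split must be co-fitted because in the scalar model the combined
pattern rises quartically with lateral offset (both the vortex m=2 ring
and the top-hat's focal-plane ring are ∝ ρ⁴ near the axis) but only
quadratically with defocus, so a single ζ at a fixed 80/20 split
over-sharpens the axial direction first; experimentally the split is
likewise set during alignment.  The calibrated values (ζ ≈ 78, split
≈ 0.10/0.90 at 96 pupil samples) are a property of this model, not a
measurement.

Near-axis exponents of vortex patterns are estimated by regressing
`log I` on `[1, log ρ, ρ²]` over ρ ∈ [0.2, 0.6] of the ring radius; the
ρ² regressor absorbs the ring envelope, whose neglect would bias the
plain log–log slope low by ~0.15–0.6.

The detection PSF is the flat-pupil focal intensity at the emission
wavelength integrated over a hard pinhole disk (0.8 Airy units by
default; 0.6 supported).

## Phantom

Structures grow as collision-aware random-walk tubes (100-nm steps,
direction jitter 0.25 rad, walls reflect) rasterized as sphere-swept
paths: dendrites (radius 250–450 nm) decorated with spines at
1.7 µm⁻¹ (Poisson along the arclength; neck 50–150 nm, head
150–400 nm, length uniform 0.5–4.0 µm, straight, oriented on the
hemisphere away from the dendrite axis), glia (350–700 nm), thin axons
(75–150 nm).  Spine bases are marched to the actual rasterized parent
surface, and candidate paths are probed against the occupancy volume so
cores never interpenetrate.

Remaining space joins the nearest structure (distance-transform
partition) and ECS clefts are carved around the partition boundaries:
the cleft half-width is set to the largest distance level below the 13%
ECS target and the remainder is taken from the next distance shell by a
deterministic coordinate hash, so the achieved fraction is essentially
exact and reproducible across re-rasterizations.  Direct core–core
contacts are resolved by carving the locally larger instance, keeping
thin necks intact while preserving the ≥1-voxel cleft guarantee.
Clefts come out 1–2 voxels (50–100 nm) wide — at the lower edge of
realism (real brain ECS clefts are ~20–40 nm, i.e. sub-voxel) and
deliberately so: they put the boundary-evidence problem in the
PSF-diluted regime the shadow-imaging method actually faces.

Morphodynamics is geometric only: spine tips displace by a Gaussian
with RMS magnitude `morph_step` (default 150 nm), head radii jitter by
`morph_step/4`, and the volume is re-rasterized with identical ids.  No
biophysical growth model is implied.

Randomness is split into per-purpose streams (geometry, spines,
puncta, evolution) from the master seed, so adding structures does not
reshuffle existing ones.

## Acquisition

Expected counts are `dwell · (brightness · (density ⊛ PSF) + background)`
with independent Poisson draws per voxel.  `brightness_scale = 1.0`
photons/µs per unit dye density puts the 70-µs image at ~35–40 mean ECS
counts (typical photon-counting STED); background is 0.005 photons/µs.
The low/high pair is formed by binomial thinning `Binomial(counts,
10/70)` — distributionally identical to recording the first 10 µs of
each 70-µs dwell, hence voxel-exact and low ≤ high everywhere.  The
same thinning gives the 50:50 detector split (summing restores counts
exactly) and the interleaved duplicate-split control.  Detector
dead-time, drift, bleaching and depth-dependent PSF degradation are not
modeled.  Stored 16-bit TIFFs may use the inverted convention
(65535 − counts).

## Restoration

The deterministic baseline applies the Anscombe transform
`2√(x+3/8)`, Gaussian smoothing, and the closed-form exact unbiased
inverse.  The smoothing σ adapts to exposure as `(70 µs/dwell)^(1/4)`
(σ = 1.0 voxel at 70 µs, ≈1.6 at 10 µs): in the VST domain noise is
unit variance at every rate while contrast scales as √dwell, so this
keeps the boundary-evidence SNR roughly constant.  The trainable
restorer is a linear 5³ receptive-field ridge regression in the VST
domain fitted on low→high/7 pairs (input and target share the
count-rate scale); ensemble members differ only by the seed of their
training-patch sample, and their per-voxel standard deviation is the
uncertainty readout.  A blind-spot mode (center voxel masked) covers
single-channel self-supervised denoising.  These are desk-scale
stand-ins for CNN restorers by design; all validation runs on the
deterministic baseline so no learning is required to reproduce results.

## Segmentation

Boundary evidence `b` is the restored intensity passed through a
sigmoid centred between the Otsu class means, scaled to 0.15 of their
separation.  At 13% ECS all dye sits in thin clefts whose amplitude the
PSF dilutes to mid-range, so a plain min–max normalization cannot
separate instances at agglomeration thresholds in [0.2, 0.4]; the
sigmoid saturates everything confidently dye-filled.  Edge affinities
are `1 − max(b(v), b(v+unit))`.  Two variants serve different stages:
watershed flooding uses the plain affinities (thin cross-sections stay
alive), while agglomeration is scored on affinities whose evidence is
greyscale-dilated ±1 voxel along the edge axis, so an interface
crossing a thin dye sheet always sees the sheet's peak voxel — this
single change removed nearly all false merges in testing.

Per z-slice, seeds are connected components where the in-slice affinity
support exceeds 0.6 (at 0.9 no seed ever forms inside 1–2-voxel-wide
neurite cross-sections and thin axons and spine necks vanish), flooding
is masked at support 0.05, and fragment ids are globally offset.  The
fragment graph is merged greedily by count-weighted mean affinity until
the best edge falls below θ (default 0.3, the midpoint of the validated
0.2–0.4 range), with deterministic (score, id-pair) tie-breaks.
Postprocessing removes segments with fewer than 10 voxels or spanning
fewer than 2 z-planes, enforces 26-connectivity, and compacts ids in
size order.  A final fill floods voxels whose evidence stays below 0.9
from the surviving instances, so only confident cleft cores remain ECS;
this leaves partition metrics unchanged while making segment extents
(and hence the ECS estimate) meaningful.

The trainable affinity backend is a per-channel logistic regression on
the 3³ neighborhoods of both edge endpoints (54 features), trained on
phantom ground-truth affinities with optional 8-fold axis-mirror
test-time averaging (affinity channels are re-mirrored with the
one-voxel shift a flipped forward edge requires).

## Morphometry

Instance skeletons come from 3D topological thinning with
distance-transform radii; leaf branches shorter than 2 voxels are
pruned and every remaining leaf is extended along its local tangent to
the mask boundary (thinning retracts endpoints by about one local
radius — without the extension a 1.45-µm test cylinder measures
1.15 µm).  Spine length is measured separately, because thinning
collapses on the blob-like territories that space-filling ground truth
produces: the central axis is the in-mask shortest path from base to
tip (after a closing that bridges sub-voxel surface intrusions),
simplified by taut-string line-of-sight substitution to remove both the
26-connectivity length inflation (~5–8%) and the lateral wander of
equal-cost lattice paths; the straight offsets from base and tip to the
path ends are included.  On generated spines this recovers lengths with
≈0.036 µm MAE and the same small positive bias.

Puncta are detected as local maxima of the scale-normalized Laplacian
of Gaussian above median + 8·MAD with intensity-weighted subvoxel
refinement, and assigned to the nearest segment surface within 300 nm
using z-compressed distances (factor 3) to account for the confocal
axial elongation; a punctum on a spine counts as `spine_head` when its
nearest skeleton position lies beyond the neck midpoint.  F/F0 traces
divide per-frame ROI means by the first frame.

## Evaluation

Partition metrics (adapted Rand error, variation of information in
bits, split ratios at a 2% overlap floor) are computed on the joint
foreground of both volumes.  Spine detection uses greedy one-to-one
nearest matching and the +1/−1/+0.5 scoring rule.  Tracing walks
ground-truth skeletons at 100-nm steps recording the dominant predicted
label in a 1-voxel-radius neighborhood; dominant-label handovers are
split events, labels claimed by several skeletons are merge events, and
error-free segments are maximal unshared runs (with a single skeleton
only splits are observable).  Morphodynamics comparisons align two
single-structure masks by the IoU-maximizing integer translation and
report IoU plus the symmetric 95th-percentile surface displacement.

## Problem sizes and reproducibility

The default phantom is 10 × 10 × 5 µm (200 × 200 × 100 voxels); the
test suite and demo additionally use a 6.4 × 6.4 × 3.2 µm variant with
the same composition for the heavier multi-replicate studies.  Optics
runs at 96 pupil samples on 25-nm grids.  On these sizes the full test
suite takes ~3 minutes and `scripts/acceptance.py` about one minute on
one CPU.  Every stochastic step draws from an explicit seed;
re-running any stage with the same configuration is bit-identical.

## What passing these benchmarks does — and does not — show

The phantoms reproduce the *geometry and statistics* the method needs
(shadow contrast, dense packing, thin clefts, sub-resolution necks,
Poisson counting at realistic photon budgets) but not tissue realism:
no organelles, no myelin, no dye diffusion gradients, no aberration
growth with depth, no motion during acquisition, and cleft widths at
the voxel scale rather than below it.  Segmentation quality on the
phantoms (adapted Rand error ~0.01–0.07) therefore bounds what the
algorithmic pipeline can do under ideal labeling, not what it achieves
in living tissue, where published spine-detection rates (~73–83%) and
tracing error rates reflect proofreading of far harder data.  The
restoration comparison (restored-low strictly better than raw-low and
within a few adapted-Rand points of the 70-µs exposure) is the
synthetic analogue of the light-budget argument, under the same caveat.
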