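# Methods

`octarep` re-implements, as a tested pipeline, a repeatability analysis of
en-face OCTA (optical coherence tomography angiography) quantification:
how stable are vessel area density (VAD), skeletonized vessel length (VL),
and choriocapillaris (CC) flow-deficit metrics under (a) repeat
acquisitions of the same eye and (b) contrast changes applied to the same
image, as a function of the binarization thresholding algorithm and of the
image processing applied before thresholding.

## Pipeline

Every analysis follows the same chain:

    8-bit en-face image
      -> optional processing (one of: contrast x1.5, contrast x2.0,
         histogram normalization, CLAHE, rigid registration — applied
         independently, never chained)
      -> one of 11 binarization thresholds (white = flow)
      -> metrics (VAD everywhere; VL on retinal slabs; flow-deficit count
         and mean size on inverted CC masks)
      -> ICC repeatability statistics

### Image operations

* **Contrast**: `f(p) = a (p − 128) + 128`, `a ∈ {1.0, 1.5, 2.0}`, rounded
  half-away-from-zero and clipped to `[0, 255]`. 128 is the fixed point; on
  a full-range image any `a > 1` clips both tails, and the clip is the only
  part of the transform that is not strictly monotone and injective.
* **Histogram normalization**: stretch so min → 0, max → 255, after
  saturating 0.3% of pixels (0.15% per tail, anchors from the cumulative
  histogram).
* **CLAHE**: tile grid of `ceil(size/127)` per axis, 256 histogram bins,
  slope (clip) limit 3.0, bilinear blending of tile lookup tables.
  Implemented in-package: tile histograms are clipped with uniform excess
  redistribution iterated to convergence, and each tile mapping is anchored
  at its first bin so a slope limit of 1 is exactly the identity.
* **Rigid registration**: translation from upsampled phase correlation,
  rotation from a coarse grid (±3°, 0.5° step) refined by bounded scalar
  minimization of the plain cross-correlation residual. On phantoms with
  known jitter the recovery error is below 0.5 px and 0.25°. Estimation
  failure (flat images, non-finite residuals) returns the identity
  transform with a warning instead of raising, so a batch run survives a
  bad image. The first acquisition of each subject is the reference.

### Thresholding

Five global methods compute one threshold per image from its 256-bin
histogram: iterative-intermeans ("default", with the extreme occupied bins
ignored — the legacy variant, which differs from plain isodata exactly on
histograms with heavy extreme-bin mass), Huang's fuzzy-entropy minimum,
isodata (smallest intermeans fixpoint; the intermeans map is monotone on
the occupied range, so a fixpoint always exists), floor-of-mean, and Otsu
(smallest maximizer of between-class variance).

Six local methods threshold each pixel from a circular disc neighborhood
(default radius 15 px; 43.9 µm on a 1024 px / 3 mm raster, 104.9 µm at
429 px, 148.0 µm at 304 px), with replicate border padding: Bernsen
(midgray, with a low-contrast rule), mean, median, Niblack
(`mean + k·std`, k = 0.2), Otsu on the neighborhood histogram, and
Phansalkar (`t = m (1 + p e^{−qm} + k(s/r − 1))` with mean and std
normalized to [0, 1]; k = 0.25, r = 0.5, p = 2, q = 10). Method constants
follow the conventions of the plugin family these algorithms entered the
field through, and all are overridable.

One tie rule is used everywhere: white iff pixel **strictly greater** than
threshold. A second border mode (`border="ignore"`) restricts
neighborhoods to in-image pixels; with a radius beyond the image diagonal
every local method then degenerates to its global counterpart, which is
how the local implementations are cross-checked. Local means are computed
with unit-weight kernels so sums stay exact in floating point and the
strict tie rule is bit-reproducible.

Key invariance: local median (and, absent clipping, every
affine-equivariant local threshold — mean, Niblack, Otsu) commutes with
strictly increasing injective pointwise maps, so its binarization is
bit-identical across contrast gains whenever nothing clips. This is the
mechanism behind perfect contrast-repeatability entries for rank-based
local thresholds on CC images.

### Metrics

* VAD: percent white pixels. `VAD(mask) + VAD(~mask) = 100` exactly.
* VL: skeleton pixel count after binary thinning (1-px medial lines,
  8-connected); an optional Euclidean mode sums inter-pixel steps
  (1 orthogonal, √2 diagonal).
* Flow deficits (CC): invert the mask, label 8-connected components, no
  size filter, edge-touching components included; count and mean area.
  Zero deficits report a missing mean, never 0.
  `count × mean size = total black area` exactly.
* Vessel-density index and CC flow-deficit percentage are deliberately not
  computed (FD% is available as `100 − VAD`).

### Repeatability statistics

* One-way random effects `ICC(1) = (MSB − MSW) / (MSB + (k−1) MSW)` for
  repeat acquisitions.
* Two-way mixed effects for fixed conditions (contrast levels), reported
  as single-rater consistency `ICC(3,1) = (MSR − MSE) / (MSR + (k−1) MSE)`.
  Consistency is the natural form when a fixed condition shifts all
  subjects systematically; absolute agreement ICC(2,1) is available as an
  option. Contrast-change ICCs are computed per repeat image
  (subjects × gains) and arithmetically averaged over the repeats.
* Classification: high above 0.80, low below 0.50; the boundary values
  fall in the moderate band (the cutoffs are strict inequalities).
  Negative estimates are retained and read as low repeatability.
  Zero-variance grids yield a missing ICC with a warning, never 0 or 1.
* ΔICC = ICC(processed) − ICC(unprocessed), with reporting bins
  (≤ 0, improvement deciles to 0.5, > 0.5).

Both estimators agree with explicit sums-of-squares oracles to 1e-10 and
with an independent implementation (pingouin) in the test suite, and the
one-way estimator recovers σ²_b/(σ²_b + σ²_w) on simulated 50×3 grids.

## Synthetic cohorts

No real scans are publicly deposited, so the generator emulates the study
design: subjects × repeat acquisitions per plexus (FRL/SCP/DCP retinal
slabs, CC) and device profile, with hierarchical seeding
(master → subject → acquisition) making every cohort a deterministic
function of one seed. The defaults describe a healthy-eye cohort imaged
three times per device, 3 × 3 mm field.

**Retinal phantom.** A branching random-walk vessel tree grown inward from
the border with decaying caliber; growth continues until vessel coverage
reaches a density-controlled target (8–30% of the field), so coverage
tracks the density parameter instead of inheriting the large realization
variance of a fixed number of walks. The capillary background is
band-pass-filtered noise passed through `exp(0.7·mesh)`: a dark-skewed
continuum with a long bright tail and no histogram valley, which is the
operating regime of exported angiograms — roughly a fifth of the mass
collapses onto 0 under a 1.5× contrast gain. A central foveal avascular
zone (FAZ, default radius 300 µm) suppresses intensity to a noisy floor;
truth masks record FAZ and vessel pixels. Intensities are stretched to the
full 0–255 range on 0.2/99.8 percentile anchors (so real mass, not an
outlier, sits at the bounds); a no-clip switch instead maps to [65, 191],
where gains up to 2.0 are strictly monotone and injective — the setting
for contrast-invariance analyses.

**CC phantom.** Flat mid-gray granular texture (smoothed noise) with
Poisson-placed dark elliptical flow deficits (default 45/mm², mean radius
14 µm, darkened 80%), recorded in a truth mask together with the planted
count. The displayed contrast is inset to the middle 44% of the range:
a homogeneous CC slab has no saturated vessel mass, so contrast gains up
to 2.0 essentially do not clip it even under acquisition exposure jitter —
which is exactly why affine-equivariant local thresholds are near-perfectly
contrast-repeatable on CC and not on retinal slabs. The deficit load is
chosen jointly with the planted-count recovery check: at these densities
Boolean-model overlap merges about 7% of deficits, inside the ±10%
tolerance.

**Acquisition model.** Per repeat: a smooth elastic perturbation of vessel
appearance (sub-pixel), a rigid shift (≤ 3 px) and rotation (≤ 1°),
a multiplicative exposure gain (sd 0.10) with additive offset (sd 6), and
fresh additive noise (sd 6) — then clipping to the cohort's intensity
range and rounding to 8 bits. Zero scales reproduce the template
bit-exactly. Repeat-scan exposure variation is the dominant driver of the
idiosyncratic retinal contrast response: under full-range clipping, two
acquisitions of the same eye respond differently to the same gain.

**Between-subject spread** is deliberately small (vessel density sd 0.015,
FAZ radius sd 25 µm, subject brightness sd 3%, small appearance sds):
healthy eyes are structurally similar, and that low between-subject
variance is itself part of why ICCs in healthy cohorts are modest.
CC deficit load (density sd 13/mm², radius sd 3 µm) carries the CC
between-subject signal.

**What the phantoms do not model**: biophysically realistic flow,
projection artifacts, segmentation-boundary errors, pathology, vendor
post-processing. Passing tests demonstrate the pipeline's statistical
machinery and the qualitative regimes (rank-invariance on no-clip images,
FAZ mis-binarization by local thresholds, retinal-below-CC contrast
repeatability under clipping); they do not certify quantitative agreement
with any particular device's real-eye ICCs.

## Problem sizes

The default experiment configuration mirrors the study layout
(13 subjects × 3 repeats, 1024 px rasters). The test suite and the
reproduction script run the same pipeline at bench scale — 128–256 px
rasters, 8–12 subjects, 2–3 repeats — which preserves every mechanism
(pitch is tied to the 3 mm field, so the 15 px radius simply corresponds
to a larger physical radius, as it does across real devices).

## Numerical conventions

* Rounding: half-away-from-zero everywhere 8-bit values are produced.
* Coordinates: row-major, origin top-left, 0-based.
* 16-bit and float rasters are rescaled to [0, 255] by max-range division
  at load time.
* Ties at thresholds: `p == t` is black, uniformly.
* Undefined statistics propagate as missing values (`NaN`/`None`), never
  as sentinel numbers.
* Determinism: all randomness flows from `numpy` `SeedSequence` spawns of
  one master seed; re-running a manifest reproduces tables bit-exactly.
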