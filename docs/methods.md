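# Methods

This note documents the modelling choices behind `dynaface`: what each stage
assumes, the parameters that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Registration (the appearance front end)

Each frame is related to a common reference image by a dense backward warp:
`warped(p) = frame(p + d(p))` should equal the reference. The estimator in
`mcgm.estimate_warp` is a coarse-to-fine multi-channel gradient method:

* image pyramid with ×2 steps, up to 4 levels, stopping when the short side
  would drop below 12 px;
* per level, 3 warp/re-linearise cycles. Each cycle warps the frame by the
  current field, computes Gaussian-derivative spatial gradients (σ = 1 px)
  of the warped frame, and solves a per-pixel 2×2 least-squares system for
  the incremental displacement, pooling the normal equations over a Gaussian
  window (σ = 3 px) and over colour channels, with Tikhonov regularisation
  λ = 1e−3. Updates are clamped to ±1 px per cycle for stability;
* a final Gaussian smoothing of the field (σ = 2 px).

The backend is exposed as a plain callable so an alternative gradient-model
implementation can be swapped in. Assumptions: brightness constancy,
smooth small-to-moderate deformations (a few pixels at the working
resolution), no occlusion handling. The method estimates registration
fields, not instantaneous image velocities.

The reference image is estimated iteratively (`build_reference`): the seed
is the middle frame of the median-duration clip (a deterministic stand-in
for "some representative frame"); each of 3 passes registers every frame to
the current reference and replaces it with the mean warped texture. The
mean squared distance between warped textures and the reference is recorded
per pass and is non-increasing in practice. The returned features are those
of the final pass; the reference image itself is not consumed by
back-projection (only warps and textures are), it is retained for
visualisation and diagnostics.

Warp inversion (`invert_warp`, needed to render reconstructed textures back
into each frame's own geometry) uses the fixed-point iteration
`d⁻¹ ← −d(p + d⁻¹(p))`, which converges for the smooth, small-amplitude
fields produced here. Injectivity is checked first via the Jacobian of
`p + d(p)`; convergence requires a composition residual ≤ 0.05 px on ≥ 99%
of interior pixels (interior margin = max displacement + 1 px).

## Lossless PCA

Both levels use `pca_core.fit_lossless`: economy SVD of the centred data
matrix, retaining all n − 1 components. In the wide-data regime (features ≫
samples) this is exact — cumulative explained variance is 1 to machine
precision and training samples round-trip through transform/inverse
transform at ~1e−13. Variances are normalised by n − 1; component signs are
fixed by making each component's largest-magnitude element positive. The
warp channels can be rescaled relative to the texture channels before PCA
via `channel_scale`; the default is 1 (no rescaling), since the relative
weighting of shape and texture is a free choice with no canonical value.

## Temporal alignment

Alignment is driven by audio amplitude envelopes (magnitude of the Hilbert
analytic signal), because vocal amplitude modulations give sharp, repeatable
landmarks. Parameters, with defaults:

* **onset detection**: smoothed envelope (20 ms moving average) must exceed
  10% of its maximum for ≥ 30 ms; onset = rise − 80 ms (two video frames),
  clamped at 0 and rounded to the nearest 40 ms frame time. The threshold
  rule operationalises "the initial rise"; a manual override parameter
  substitutes for hand corrections.
* **decimation**: ×10 polyphase FIR, zero-phase, edge-padded
  (48 kHz → 4.8 kHz), which keeps DC exactly and everything below the new
  Nyquist essentially untouched.
* **DTW**: asymmetric step pattern with the *reference as query* — each
  reference sample is matched to exactly one clip sample (steps advance the
  reference index by 1 and the clip index by 0, 1 or 2), so every aligned
  series has the reference length by construction. Open begin/end: the
  first row of the cost table is unconstrained and the path may end at any
  clip sample, so clip extremities need not match. Local cost is the
  squared envelope difference, which makes each DTW pass the exact
  minimiser of the objective tracked across iterations (mean squared
  distance of aligned envelopes to the reference).
* **iterations**: 3. The initial reference is the clip closest to the
  median duration; after each pass the reference becomes the mean aligned
  envelope. All envelopes, including the reference, are rescaled to unit L²
  norm each iteration so loudness differences cannot drive the warp.
* **video curves**: linear interpolation of the audio-rate curve at video
  frame times (192 envelope samples per frame at 25 fps), then 4 prepended
  points continuing backwards at gradient exactly 1 (the 45° pre-onset
  extension, 160 ms).

A structural property worth noting: the aligned timeline carries a
*time-gauge freedom* — it is anchored to the initial reference clip's
timeline, since any common monotone re-parameterisation of the reference is
a fixed point of the iteration. Recovery tests therefore compare estimated
curves against the compositional truth `g_clip ∘ g_ref⁻¹` rather than
against `g_clip` alone.

Curve gradients are forward differences with the last value repeated
(length T_ref), making curve ↔ gradients a bijection given the anchor;
reconstruction is a cumulative sum anchored at 0, i.e. reconstructed clips
start at the aligned window's start. Negative reconstructed gradients
(possible at extreme caricature weights) are clipped to 1e−3 with a
warning — this is precisely the distortion regime of weights outside [0, 1].

## Second-order model and caricaturing

Clip vectors are `[aligned scores (frame-major), curve gradients]`, giving
T_ref·K₁ + T_ref dimensions; no per-component standardisation is applied
before the second PCA (an optional flag could be added, but unweighted
concatenation is the default since any reweighting changes what "deviation"
means). The caricature chain is linear from PCA₂ scores down to McGM
features, so weight-w representations are exact affine mixes; the only
non-linear steps are warp inversion and the final resampling, which bound
rendered-frame reconstruction error (interior MAE ~1e−2 at w = 1).
Unsharp masking (σ = 2 px, amount = 1) is applied only at render time, so
stored features are unmodified; both parameters are configurable and have
no canonical values.

## The synthetic data generator

`fixtures.make_dataset` emulates exactly the structure the pipeline relies
on: a smooth textured base scene (band-limited noise at two spatial scales
plus a central face-like blob) deformed by k = 3 smooth displacement modes
(random 2-D cosine series of order ≤ 2, Gram-Schmidt orthogonalised, peak
magnitude 2.5 px), per-clip smooth amplitude curves, a per-clip monotone
time-warp with slope in [0.7, 1.4] (mean 1), a silence-then-bump-train
audio envelope on a 440 Hz carrier at 48 kHz, and i.i.d. Gaussian pixel
noise (sd 0.005 by default).

Two deliberate design decisions:

* **Amplitude curves are centred across clips** (and share one global scale
  putting the largest clip's peak displacement at 1.5 px). The dataset's
  average behaviour is therefore the neutral base pose, and clips are
  purely idiosyncratic deviations — the regime in which caricature
  weighting has a clean interpretation and in which the pooled mean warp
  magnitude is provably non-decreasing in w on [0, 1] (it is convex in w
  and minimised at the centred mean). An individual clip's motion can still
  dip before rising if its deviation anti-aligns with the small residual
  average motion; in real speech data, where clips share a common gesture,
  the motion–weight relation is likewise a property of the pooled
  distribution, not of every clip.
* **Displacements stay small** (≤ 1.5 px peak). Small smooth fields keep
  backward warps invertible, keep the registration problem within the
  linearisation regime, and keep the quadratic field-composition terms (the
  gap between a warp and its inverse) well below the planted signal so
  subspace-recovery tests are meaningful.

What the generator does **not** emulate: photorealistic faces, illumination
change, occlusion (blinks, hands), out-of-plane rotation, appearance change
over time, correlated sensor noise, reverberant or noisy audio, and
speaker-specific spectro-temporal structure beyond amplitude bumps. Passing
tests demonstrate the machinery is correct and self-consistent in this
regime; they do not certify registration or alignment accuracy on real
video, where larger non-smooth motion and audio noise will dominate error
budgets.

## Validation problem sizes

The test suite and acceptance script run the full pipeline at 48×48 px
(32×32 for orchestration tests) with 6–8 clips of ~1.2–1.6 s at 25 fps, 20
clips for DTW recovery, and 128×128 only for pure reshaping checks. These
sizes keep the registration-heavy stages quick while leaving every
contract — dimensionality counts, exactness, recovery errors in px and
frames — identical in form to the 128×128 working resolution.

## Degenerate inputs and tie-breaks

Constant images register with a zero warp and a warning; flat envelopes
align with identity curves and a warning; warp-curve coordinates outside a
clip's frame range are clamped with a warning; DTW step ties prefer the
smallest clip-index advance; the median-duration clip (ties: lowest index)
seeds both the registration reference and the alignment reference; silent
clips raise at onset detection rather than guessing.

## Known limitations

* Gradient-model registration assumes brightness constancy and smooth
  motion; fast large-amplitude gestures at the working resolution would
  need more pyramid levels or a different backend.
* Warp inversion — and hence rendering — fails loudly on folded
  (non-injective) reconstructed fields, which extreme weights (|w| well
  outside [0, 1]) can produce; anti-caricaturing within [0, 1] is the
  intended operating range.
* Lossless PCA memory scales with (total frames) × (H·W·5); at 128×128 and
  thousands of frames the feature matrix is several GiB, so long corpora
  need either lossy truncation or out-of-core SVD, neither of which is
  implemented.
* Face detection and word-level speech timestamps are inputs, not features:
  crop regions and word onsets come from sidecar metadata or user-supplied
  callables.
* One model is fitted per phrase type (and per subject); no morphing across
  models is provided.
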