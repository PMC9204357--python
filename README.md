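# dynaface

**Two-level PCA active appearance modelling of dynamic facial behaviours,
with dynamic (anti-)caricaturing.**

Faces in the real world move. Most face-space models — and most caricaturing
techniques built on them — operate on static images, treating each frame as
an independent sample and discarding the temporal structure of behaviours
like speech. `dynaface` implements a fully reversible pipeline that models
*spatiotemporal* variation in short video clips of a single person's facial
behaviour, and uses it to morph clips continuously between an individual
performance and the average performance: anti-caricatures, caricatures and
anti-faces of biological motion, rendered as ordinary video frames.

It is intended for researchers in face perception and computational social
neuroscience who need parametric control over how much a natural facial
behaviour deviates from an average — without driving an artificial avatar.

## The model

1. **Registration (appearance features).** Every frame of every clip is
   registered to a common reference image by a dense backward warp field
   estimated with a coarse-to-fine multi-channel gradient method. The
   reference is refined iteratively (3 passes): register all frames, average
   the warped ("shape-free") textures, re-register. Each frame becomes a
   5-channel image — warp components *dx*, *dy* plus warped R, G, B — which
   at the 128×128 working resolution vectorises to 128·128·5 = 81,920
   dimensions.

2. **First-order PCA.** With *n* frames in total, the frames-by-features
   matrix supports a *lossless* PCA: all *n* − 1 components are retained, so
   100% of variance is explained and every training frame reconstructs
   exactly. Each clip is now a multivariate timeseries of PCA₁ scores whose
   components encode modes of spatial variation (head pose, mouth and eye
   shape, texture).

3. **Temporal alignment.** Clips differ in vocalisation onset and speaking
   rate. The Hilbert amplitude envelope of each audio track is re-cut at the
   detected onset (initial rise − 80 ms, rounded to a frame), decimated
   ×10 (48 kHz → 4.8 kHz), and aligned to a common reference envelope by
   dynamic time warping (asymmetric step, open begin/end, unit-L² rescaling,
   3 reference-refinement iterations). The warping curves are interpolated
   to the 25 fps video rate and extended at 45° for 4 frames before the
   onset; they resample every clip's PCA₁ timeseries onto one reference
   timeline.

4. **Second-order PCA.** Each aligned timeseries is vectorised (frame-major)
   and its warping-curve gradients appended — the gradients carry the clip's
   own temporal scale, so the timescale can be reconstructed. A second
   lossless PCA over clips (*n*_clips − 1 components) yields the PCA₂ space:
   the origin is the average aligned timeseries; each clip is its
   spatiotemporal deviation from that average.

5. **Caricaturing.** Scaling a clip's PCA₂ scores by a weight *w* and
   back-projecting the whole chain (inverse PCA₂ → warping curve from
   gradients → unwarp to own timescale → inverse PCA₁ → 5-channel features →
   warp inversion → texture resampling → unsharp masking) renders

   | *w* | result |
   |-----|--------|
   | 0   | the average sequence |
   | (0, 1) | anti-caricature |
   | 1   | the original clip |
   | > 1 | caricature |
   | < 0 | anti-face |

   Every stage is linear up to the final resampling, so the representation
   at weight *w* is exactly *w*·**x** + (1 − *w*)·**x̄** in clip-vector
   space — including duration, which interpolates between the mean and the
   original clip length. The degree of motion in any rendered sequence is
   quantified objectively as the mean magnitude √(dx² + dy²) of the warp
   channels.

## Worked example

The package ships a synthetic-clip generator with full ground truth (known
spatial deformation modes, time-warps and audio envelopes), so the whole
pipeline can be exercised without any recordings:

```python
import numpy as np
from dynaface import fixtures, pipeline, spatiotemporal
from dynaface.spatiotemporal import CaricatureRequest

clips, truths = fixtures.make_dataset(6, fixtures.FixtureConfig(), seed=0)
model, report = pipeline.fit_appearance_model(
    [seq for seq, _ in clips], [aud for _, aud in clips],
    pipeline.PipelineConfig(out_size=48))

print(f"frames: {report['n_frames_total']}, PCA1 components: {report['pca1_components']}")
print(f"PCA1 explained variance: {100 * report['pca1_explained_ratio']:.4f}%")
print(f"clips: {report['n_clips']}, PCA2 components: {report['pca2_components']}")
print(f"aligned timeline: {model.t_ref} frames")

for w in (0.0, 0.5, 1.0):
    frames, _ = spatiotemporal.backproject_mcgm(model, CaricatureRequest("clip_0002", w))
    per_frame, _ = spatiotemporal.motion_magnitudes(frames)
    print(f"w={w:3.1f}: {len(frames)} frames, mean motion {per_frame.mean():.3f} px")

anti = spatiotemporal.caricature(CaricatureRequest("clip_0002", 0.5), model)
print(f"rendered anti-caricature: {anti.n_frames} frames of "
      f"{anti.shape[0]}x{anti.shape[1]} px")
```

prints

```
frames: 205, PCA1 components: 204
PCA1 explained variance: 100.0000%
clips: 6, PCA2 components: 5
aligned timeline: 28 frames
w=0.0: 25 frames, mean motion 0.185 px
w=0.5: 26 frames, mean motion 0.143 px
w=1.0: 27 frames, mean motion 0.253 px
rendered anti-caricature: 26 frames of 48x48 px
```

The lossless PCAs keep *n* − 1 components at each level (204 of 205 frames,
5 of 6 clips) with 100% variance explained. The reconstructed clip duration
moves from the average (25 frames at *w* = 0) to the clip's own length
(27 frames at *w* = 1). Mean warp magnitude measures how far each rendered
frame deviates from the reference pose; pooled over clips it increases
monotonically with *w*, though an individual clip — like this one, a
below-average mover whose idiosyncratic motion partly cancels the residual
average motion — can dip before rising.

The same pipeline is available from the shell:

```bash
dynaface generate --n-clips 8 --size 48 --seed 0 --out data/
dynaface run --dataset data/ --out model/
dynaface caricature --model-dir model/good_news --clip clip_0002 --weight 0.5 --out render/
dynaface metrics --model-dir model/good_news --out motion.csv
```

## Layout

```
src/dynaface/
  fixtures.py        synthetic ground-truth clip generator
  media_io.py        clip I/O, cropping, anti-aliased down-sampling
  mcgm.py            dense gradient-model registration, 5-channel features,
                     warp application/inversion, iterative reference
  pca_core.py        lossless PCA (shared by both levels)
  temporal.py        Hilbert envelopes, onset detection, DTW alignment,
                     warping-curve arithmetic
  spatiotemporal.py  clip vectors, second-order PCA, caricaturing,
                     motion metric, component visualisation
  pipeline.py        end-to-end orchestration, configuration, serialization
  cli.py             command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
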