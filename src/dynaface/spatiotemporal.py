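"""Second-order PCA, dynamic caricaturing, and the motion-magnitude metric.

After temporal alignment every clip is a (T_ref, K1) timeseries of
first-order PCA scores.  Vectorising each timeseries (frame-major) and
appending the clip's video-rate warping-curve gradients turns every clip
into a single sample of dimension T_ref*K1 + T_ref; a second lossless PCA
over these samples yields the spatiotemporal (second-order) space.  Its
origin is the average aligned timeseries, and each clip's embedding encodes
its spatiotemporal deviation from that average.

Scaling a clip's embedding by a weight w and back-projecting through the
whole chain — inverse second-order PCA, gradients -> warping curve, unwarp
to the clip's own timescale, inverse first-order PCA per frame, 5-channel
un-vectorisation, warp-field inversion, texture resampling, unsharp
masking — renders an anti-caricature (0 < w < 1), the original clip (w = 1),
the average sequence (w = 0), a caricature (w > 1) or an anti-face (w < 0).
Because every stage is linear (up to the final resampling), the
representation at weight w is exactly ``w * clip + (1 - w) * mean`` in
clip-vector space, and the reconstructed duration interpolates between the
mean and original durations.

The degree of biological motion in any rendered sequence is quantified
objectively as the per-pixel magnitude of the (dx, dy) warp channels —
larger values mean frames deviate more from the reference pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from . import pca_core
from .mcgm import ReferenceModel, apply_warp, invert_warp, unvectorize
from .media_io import FrameSequence
from .pca_core import PcaModel
from .temporal import (WarpCurve, curve_gradients, gradients_to_curve,
                       unwarp_timeseries)

__all__ = [
    "ClipVector",
    "CaricatureRequest",
    "AppearanceModel",
    "build_clip_vectors",
    "split_clip_vector",
    "fit_second_order",
    "reconstruct_clip_vector",
    "backproject_mcgm",
    "render_mcgm_sequence",
    "caricature",
    "unsharp_mask",
    "motion_magnitudes",
    "visualize_component",
]


@dataclass
class ClipVector:
    """One clip as a point in the pre-PCA2 feature space.

    ``values`` = vectorized aligned scores (frame-major: frame 0's K1
    components, then frame 1's, ...) followed by the T_ref warping-curve
    gradients.
    """

    values: np.ndarray
    clip_id: str
    t_ref: int
    k1: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.t_ref * self.k1 + self.t_ref:
            raise ValueError(
                f"clip vector length {self.values.size} inconsistent with "
                f"T_ref={self.t_ref}, K1={self.k1}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clip vector contains non-finite values")


@dataclass
class CaricatureRequest:
    """Which clip to re-render and at what weight.

    w = 0 reproduces the average sequence, w = 1 the original clip,
    0 < w < 1 anti-caricatures, w > 1 caricatures, w < 0 anti-faces.
    """

    clip_id: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError("caricature weight must be finite")


@dataclass
class AppearanceModel:
    """Fitted two-level model for one phrase-type.

    Bundles everything back-projection needs: both PCA models, the clip
    embeddings, per-clip video warping curves, frame geometry and rendering
    parameters.
    """

    pca1: PcaModel
    pca2: PcaModel
    reference: ReferenceModel
    clip_ids: list
    curves: list                  # per-clip video-rate WarpCurve
    aligned_scores: list          # per-clip (T_ref, K1) arrays
    embeddings: np.ndarray        # (n_clips, K2)
    t_ref: int
    k1: int
    height: int
    width: int
    fps: float = 25.0
    channel_scale: float = 1.0
    unsharp_sigma: float = 2.0
    unsharp_amount: float = 1.0

    def clip_index(self, clip_id: str) -> int:
        try:
            return self.clip_ids.index(clip_id)
        except ValueError:
            raise ValueError(f"unknown clip id {clip_id!r}") from None


def build_clip_vectors(aligned: list, curves: list,
                       clip_ids: list | None = None) -> list:
    """Assemble per-clip feature vectors from aligned scores and curves.

    All clips must share T_ref and K1; each vector is the frame-major
    flattening of the aligned scores followed by the curve gradients.
    """
    if len(aligned) != len(curves):
        raise ValueError("need exactly one warping curve per clip")
    shapes = {np.asarray(a).shape for a in aligned}
    if len(shapes) != 1:
        raise ValueError(f"aligned timeseries shapes differ: {shapes}")
    t_ref, k1 = shapes.pop()
    clip_ids = clip_ids or [f"clip_{i:04d}" for i in range(len(aligned))]
    out = []
    for scores, curve, cid in zip(aligned, curves, clip_ids):
        if len(curve) != t_ref:
            raise ValueError(
                f"curve length {len(curve)} != T_ref {t_ref} for {cid}"
            )
        vec = np.concatenate([np.asarray(scores, np.float64).ravel(),
                              curve_gradients(curve)])
        out.append(ClipVector(vec, clip_id=cid, t_ref=t_ref, k1=k1))
    return out


def split_clip_vector(values: np.ndarray, t_ref: int,
                      k1: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a clip vector back into ((T_ref, K1) scores, T_ref gradients)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size != t_ref * k1 + t_ref:
        raise ValueError("clip vector length inconsistent with (T_ref, K1)")
    return values[:t_ref * k1].reshape(t_ref, k1), values[t_ref * k1:]


def fit_second_order(vectors: list) -> PcaModel:
    """Lossless PCA over clip vectors (K2 = n_clips - 1 components)."""
    if len(vectors) < 3:
        raise ValueError("second-order PCA needs at least 3 clips")
    X = np.stack([v.values for v in vectors])
    return pca_core.fit_lossless(X)


def reconstruct_clip_vector(model: AppearanceModel, request: CaricatureRequest
                            ) -> np.ndarray:
    """Weighted back-projection from the second-order space to clip-vector
    space: inverse PCA2 of ``w *`` the clip's embedding.

    By linearity this equals ``w * clip_vector + (1 - w) * mean`` exactly.
    """
    idx = model.clip_index(request.clip_id)
    scores2 = request.weight * model.embeddings[idx]
    return pca_core.inverse_transform(model.pca2, scores2)


def backproject_mcgm(model: AppearanceModel, request: CaricatureRequest
                     ) -> tuple[list, WarpCurve]:
    """Back-project a weighted clip to McGM feature frames on its own
    timescale.

    Returns the reconstructed :class:`McgmFrame` list and the reconstructed
    video warping curve (anchored at 0).
    """
    vec = reconstruct_clip_vector(model, request)
    scores_aligned, grads = split_clip_vector(vec, model.t_ref, model.k1)
    curve = gradients_to_curve(grads, anchor=0.0, rate=model.fps)
    clip_scores = unwarp_timeseries(scores_aligned, curve)
    features = pca_core.inverse_transform(model.pca1, clip_scores)
    frames = [unvectorize(f, model.height, model.width,
                          scale=model.channel_scale) for f in features]
    return frames, curve


def render_mcgm_sequence(mcgm_frames: list, fps: float = 25.0,
                         clip_id: str = "", unsharp_sigma: float = 2.0,
                         unsharp_amount: float = 1.0) -> FrameSequence:
    """Render 5-channel frames to image space.

    Each frame's warp is inverted and used to spatially unwarp the
    shape-free texture back to the frame's own geometry; contrast is then
    enhanced by unsharp masking.
    """
    rendered = []
    for i, m in enumerate(mcgm_frames):
        try:
            inv = invert_warp(m.warp)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"cannot invert reconstructed warp of frame {i}: {exc}"
            ) from exc
        img = apply_warp(np.clip(m.texture, 0.0, 1.0), inv)
        rendered.append(unsharp_mask(img, sigma=unsharp_sigma,
                                     amount=unsharp_amount))
    return FrameSequence(np.stack(rendered), fps=fps, clip_id=clip_id)


def caricature(request: CaricatureRequest,
               model: AppearanceModel) -> FrameSequence:
    """Render a dynamic (anti-)caricature of a training clip.

    Full back-projection chain: weight the clip's second-order embedding,
    invert PCA2, split scores from warp gradients, rebuild the warping
    curve, unwarp the aligned scores to the reconstructed timescale, invert
    PCA1 per frame, un-vectorise to 5-channel features, invert the warp
    fields and resample the textures to image space, then unsharp-mask.
    """
    frames, _ = backproject_mcgm(model, request)
    cid = f"{request.clip_id}_w{request.weight:g}"
    return render_mcgm_sequence(frames, fps=model.fps, clip_id=cid,
                                unsharp_sigma=model.unsharp_sigma,
                                unsharp_amount=model.unsharp_amount)


def unsharp_mask(image: np.ndarray, sigma: float = 2.0,
                 amount: float = 1.0) -> np.ndarray:
    """Contrast enhancement: ``clip(img + amount * (img - blur(img)), 0, 1)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=np.float64)
    sig = (sigma, sigma, 0) if image.ndim == 3 else sigma
    blurred = gaussian_filter(image, sig)
    return np.clip(image + amount * (image - blurred), 0.0, 1.0)


def motion_magnitudes(mcgm_frames: list) -> tuple[np.ndarray, np.ndarray]:
    """Objective motion metric from the warp channels.

    Per pixel, ``sqrt(dx^2 + dy^2)`` measures how far a frame deviates from
    the reference pose.  Returns ``(per_frame_mean, pooled)``: the mean
    magnitude of each frame and the pooled per-pixel distribution over all
    frames (for KDE / boxplot export).
    """
    if not mcgm_frames:
        raise ValueError("need at least one frame")
    mags = [m.warp.magnitude() for m in mcgm_frames]
    per_frame = np.array([m.mean() for m in mags])
    pooled = np.concatenate([m.ravel() for m in mags])
    return per_frame, pooled


def visualize_component(model: PcaModel, pc_index: int,
                        sd_multiples=(-3, -2, -1, 0, 1, 2, 3)) -> np.ndarray:
    """Back-project points along one principal axis.

    Returns one feature-space reconstruction per standard-deviation
    multiple; multiple 0 reproduces the mean.  For a first-order model the
    rows un-vectorise to single 5-channel images; for a second-order model
    they are clip vectors that expand to full sequences.
    """
    if not 0 <= pc_index < model.m:
        raise ValueError(f"component index {pc_index} out of range [0, {model.m})")
    sd = float(np.sqrt(model.explained_variance[pc_index]))
    out = np.empty((len(tuple(sd_multiples)), model.d))
    for i, mult in enumerate(sd_multiples):
        scores = np.zeros(model.m)
        scores[pc_index] = mult * sd
        out[i] = pca_core.inverse_transform(model, scores)
    return out
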