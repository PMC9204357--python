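"""Dense gradient-model registration and 5-channel appearance features.

Every frame of every clip is registered to a common reference image by a
dense backward warp field: ``warped(p) = frame(p + d(p))`` should match the
reference.  Stacking the two warp components with the "shape-free" RGB
texture obtained by applying the warp gives a 5-channel feature image per
frame (dx, dy, R, G, B); at 128x128 this is the 81,920-dimensional feature
vector the first-order PCA operates on.

The registration backend is a classic multi-channel gradient method: a
coarse-to-fine image pyramid where each level solves, per pixel, a
Tikhonov-regularised least-squares system built from Gaussian-derivative
spatial gradients pooled over a local Gaussian window, warping and
re-linearising a few times per level.  The backend is a plain callable
``(image, reference, config) -> WarpField`` so an alternative gradient-model
implementation can be swapped in without touching the rest of the pipeline.

The reference image is itself estimated iteratively: all frames are first
registered to a seed frame, the reference is replaced by the mean of the
warped textures, and the process repeats (three passes by default) so the
reference converges to an average face in an average pose.

Warp fields are inverted (for back-projecting reconstructed textures to
image space) by fixed-point iteration, valid for the smooth, small-amplitude
fields produced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize

from .media_io import FrameSequence

__all__ = [
    "WarpField",
    "McgmFrame",
    "ReferenceModel",
    "RegistrationConfig",
    "estimate_warp",
    "apply_warp",
    "invert_warp",
    "build_reference",
    "vectorize",
    "unvectorize",
]


@dataclass
class WarpField:
    """Dense per-pixel 2-D displacement, backward convention.

    ``dx`` displaces along columns (x), ``dy`` along rows (y), in pixels:
    sampling the source at ``(row + dy, col + dx)`` produces the registered
    image.
    """

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=np.float64)
        self.dy = np.asarray(self.dy, dtype=np.float64)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 2:
            raise ValueError("dx and dy must be equal-shape 2-D arrays")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("warp field contains non-finite values")
        diag = float(np.hypot(*self.dx.shape))
        if max(np.abs(self.dx).max(), np.abs(self.dy).max()) > diag:
            raise ValueError("warp displacement exceeds the image diagonal")

    @property
    def shape(self) -> tuple:
        return self.dx.shape

    def magnitude(self) -> np.ndarray:
        """Per-pixel Euclidean displacement magnitude."""
        return np.hypot(self.dx, self.dy)


@dataclass
class McgmFrame:
    """5-channel feature of one frame: warp to the reference + shape-free RGB."""

    warp: WarpField
    texture: np.ndarray

    def __post_init__(self) -> None:
        self.texture = np.asarray(self.texture, dtype=np.float64)
        if self.texture.ndim != 3 or self.texture.shape[-1] != 3:
            raise ValueError("texture must be (H, W, 3)")
        if self.texture.shape[:2] != self.warp.shape:
            raise ValueError("texture and warp dimensions disagree")
        if not np.all(np.isfinite(self.texture)):
            raise ValueError("texture contains non-finite values")


@dataclass
class ReferenceModel:
    """Final average reference image and registration bookkeeping.

    ``objective_history`` records, per reference-refinement pass, the mean
    squared difference between the warped textures and the reference they
    were registered to; it should be non-increasing.
    """

    reference_image: np.ndarray
    n_iterations: int = 3
    channel_scale: float = 1.0
    objective_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        ref = np.asarray(self.reference_image, dtype=np.float64)
        if ref.min() < -1e-9 or ref.max() > 1 + 1e-9:
            raise ValueError("reference image must lie in [0, 1]")
        self.reference_image = ref


@dataclass
class RegistrationConfig:
    """Tunables of the pyramid gradient-model backend.

    n_levels: pyramid depth (x2 steps); iters_per_level: warp/re-linearise
    cycles; grad_sigma: Gaussian-derivative scale for spatial gradients;
    window_sigma: local pooling window for the normal equations; tikhonov:
    ridge added to the 2x2 systems; field_sigma: final smoothing of the
    displacement field; max_step: per-iteration update clamp (px).
    """

    n_levels: int = 4
    iters_per_level: int = 3
    grad_sigma: float = 1.0
    window_sigma: float = 3.0
    tikhonov: float = 1e-3
    field_sigma: float = 2.0
    min_size: int = 12
    max_step: float = 1.0


def _as_chw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[..., None]
    if image.ndim != 3:
        raise ValueError(f"expected (H, W[, C]) image, got shape {image.shape}")
    return image


def _sample(image: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Bilinear backward sampling at p + d(p), edge-clamped."""
    h, w = dx.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rows + dy, cols + dx])
    out = np.empty(image.shape)
    for c in range(image.shape[-1]):
        out[..., c] = map_coordinates(image[..., c], coords, order=1,
                                      mode="nearest")
    return out


def apply_warp(image: np.ndarray, warp: WarpField) -> np.ndarray:
    """Warp an image by a backward displacement field.

    Samples ``image`` at ``p + d(p)`` with bilinear interpolation;
    out-of-bounds coordinates are clamped to the image edge.
    """
    img = _as_chw(image)
    if img.shape[:2] != warp.shape:
        raise ValueError(
            f"image shape {img.shape[:2]} != warp shape {warp.shape}"
        )
    out = _sample(img, warp.dx, warp.dy)
    return out[..., 0] if np.asarray(image).ndim == 2 else out


def estimate_warp(image: np.ndarray, reference: np.ndarray,
                  config: RegistrationConfig | None = None) -> WarpField:
    """Estimate the backward warp registering ``image`` to ``reference``.

    Coarse-to-fine gradient descent on the linearised brightness-constancy
    residual: at each pyramid level the current field warps the image, the
    residual to the reference and the Gaussian-derivative gradients of the
    warped image form per-pixel 2x2 normal equations (pooled over a Gaussian
    window, ridge-regularised), and the solution increments the field.
    Deterministic; constant images yield a zero warp with a warning.
    """
    cfg = config or RegistrationConfig()
    img = _as_chw(image)
    ref = _as_chw(reference)
    if img.shape != ref.shape:
        raise ValueError(f"image {img.shape} and reference {ref.shape} differ")

    if img.std() < 1e-8 or ref.std() < 1e-8:
        warnings.warn("constant image(s): registration returns a zero warp")
        return WarpField(np.zeros(img.shape[:2]), np.zeros(img.shape[:2]))

    # Build pyramids, coarse last.
    pyr_img, pyr_ref = [img], [ref]
    while (len(pyr_img) < cfg.n_levels
           and min(pyr_img[-1].shape[:2]) // 2 >= cfg.min_size):
        for pyr in (pyr_img, pyr_ref):
            h, w = pyr[-1].shape[:2]
            pyr.append(resize(pyr[-1], (h // 2, w // 2), order=1,
                              anti_aliasing=True, mode="reflect",
                              preserve_range=True))

    dx = np.zeros(pyr_img[-1].shape[:2])
    dy = np.zeros_like(dx)
    for level in range(len(pyr_img) - 1, -1, -1):
        il, rl = pyr_img[level], pyr_ref[level]
        if dx.shape != il.shape[:2]:
            sy = il.shape[0] / dx.shape[0]
            sx = il.shape[1] / dx.shape[1]
            dx = resize(dx, il.shape[:2], order=1, mode="edge",
                        preserve_range=True) * sx
            dy = resize(dy, il.shape[:2], order=1, mode="edge",
                        preserve_range=True) * sy
        for _ in range(cfg.iters_per_level):
            warped = _sample(il, dx, dy)
            gx = gaussian_filter(warped, (cfg.grad_sigma, cfg.grad_sigma, 0),
                                 order=(0, 1, 0))
            gy = gaussian_filter(warped, (cfg.grad_sigma, cfg.grad_sigma, 0),
                                 order=(1, 0, 0))
            err = rl - warped
            pool = lambda a: gaussian_filter(a, cfg.window_sigma)
            axx = pool((gx * gx).sum(-1)) + cfg.tikhonov
            ayy = pool((gy * gy).sum(-1)) + cfg.tikhonov
            axy = pool((gx * gy).sum(-1))
            bx = pool((gx * err).sum(-1))
            by = pool((gy * err).sum(-1))
            det = axx * ayy - axy * axy
            ux = (ayy * bx - axy * by) / det
            uy = (axx * by - axy * bx) / det
            np.clip(ux, -cfg.max_step, cfg.max_step, out=ux)
            np.clip(uy, -cfg.max_step, cfg.max_step, out=uy)
            dx = dx + ux
            dy = dy + uy
    if cfg.field_sigma > 0:
        dx = gaussian_filter(dx, cfg.field_sigma)
        dy = gaussian_filter(dy, cfg.field_sigma)
    return WarpField(dx, dy)


def invert_warp(warp: WarpField, tol: float = 0.05,
                max_iter: int = 50) -> WarpField:
    """Invert a smooth backward warp by fixed-point iteration.

    Solves ``d_inv(p) = -d(p + d_inv(p))`` so that composing the warp with
    its inverse is the identity:  ``d(p + d_inv(p)) + d_inv(p) ~ 0``.
    Requires the map ``p -> p + d(p)`` to be injective (positive Jacobian
    determinant everywhere); convergence is declared when at least 99% of
    interior pixels have a composition residual <= ``tol``.
    """
    dx, dy = warp.dx, warp.dy
    # Injectivity check via the Jacobian of p + d(p).
    jyy, jyx = np.gradient(dy)
    jxy, jxx = np.gradient(dx)
    det = (1.0 + jxx) * (1.0 + jyy) - jxy * jyx
    if det.min() <= 0:
        r, c = np.unravel_index(int(np.argmin(det)), det.shape)
        raise ValueError(
            f"warp folds over (non-positive Jacobian {det.min():.3f} "
            f"at pixel ({r}, {c})); cannot invert"
        )

    margin = int(np.ceil(warp.magnitude().max())) + 1
    h, w = dx.shape
    interior = np.zeros((h, w), dtype=bool)
    if h > 2 * margin and w > 2 * margin:
        interior[margin:h - margin, margin:w - margin] = True
    else:
        interior[:] = True

    stack = np.stack([dx, dy], axis=-1)
    ix = -dx.copy()
    iy = -dy.copy()
    residual = np.full_like(dx, np.inf)
    for _ in range(max_iter):
        d_at = _sample(stack, ix, iy)
        ix, iy = -d_at[..., 0], -d_at[..., 1]
        d_chk = _sample(stack, ix, iy)
        residual = np.hypot(d_chk[..., 0] + ix, d_chk[..., 1] + iy)
        if np.mean(residual[interior] <= tol) >= 0.99:
            return WarpField(ix, iy)
    raise RuntimeError(
        "warp inversion did not converge: "
        f"{100 * np.mean(residual[interior] <= tol):.1f}% of interior pixels "
        f"within tol={tol} (max residual {residual[interior].max():.3f} px)"
    )


def build_reference(sequences: list[FrameSequence], n_iterations: int = 3,
                    config: RegistrationConfig | None = None,
                    backend=None) -> tuple[ReferenceModel, list[list[McgmFrame]]]:
    """Register all frames to an iteratively refined average reference.

    The seed reference is the middle frame of the median-duration clip.  Each
    pass registers every frame to the current reference, extracts warped
    (shape-free) textures, and replaces the reference with their mean.  After
    ``n_iterations`` passes the features of the final pass are returned
    together with the final averaged reference.

    Returns
    -------
    (ReferenceModel, features)
        ``features[c][t]`` is the :class:`McgmFrame` of frame ``t`` of clip
        ``c``, registered to the last pass's reference.
    """
    if not sequences:
        raise ValueError("no frame sequences given")
    total = sum(s.n_frames for s in sequences)
    if total < 2:
        raise ValueError("need at least 2 frames in total")
    shapes = {s.shape for s in sequences}
    if len(shapes) > 1:
        raise ValueError(f"clips have inconsistent frame shapes: {shapes}")
    register = backend or estimate_warp

    # Deterministic seed: middle frame of the median-duration clip.
    order = sorted(range(len(sequences)),
                   key=lambda i: (sequences[i].n_frames, i))
    seed_clip = sequences[order[(len(order) - 1) // 2]]
    reference = seed_clip.frames[seed_clip.n_frames // 2].copy()

    history: list[float] = []
    features: list[list[McgmFrame]] = []
    for _ in range(n_iterations):
        features = []
        sq_sum = 0.0
        textures_sum = np.zeros_like(reference)
        for seq in sequences:
            clip_feats = []
            for frame in seq.frames:
                w = register(frame, reference, config)
                tex = apply_warp(frame, w)
                clip_feats.append(McgmFrame(warp=w, texture=tex))
                sq_sum += float(np.mean((tex - reference) ** 2))
                textures_sum += tex
            features.append(clip_feats)
        history.append(sq_sum / total)
        reference = np.clip(textures_sum / total, 0.0, 1.0)

    ref_model = ReferenceModel(reference_image=reference,
                               n_iterations=n_iterations,
                               objective_history=history)
    return ref_model, features


def vectorize(mcgm: McgmFrame, scale: float = 1.0) -> np.ndarray:
    """Flatten a 5-channel frame to a vector of length H*W*5.

    Fixed channel order (dx, dy, R, G, B), row-major within each channel;
    the warp channels are multiplied by ``scale`` (divided again on
    :func:`unvectorize`), allowing the relative weight of shape versus
    texture in the PCA to be adjusted.
    """
    return np.concatenate([
        mcgm.warp.dx.ravel() * scale,
        mcgm.warp.dy.ravel() * scale,
        mcgm.texture[..., 0].ravel(),
        mcgm.texture[..., 1].ravel(),
        mcgm.texture[..., 2].ravel(),
    ])


def unvectorize(vector: np.ndarray, height: int, width: int,
                scale: float = 1.0) -> McgmFrame:
    """Inverse of :func:`vectorize`; exact round trip."""
    vector = np.asarray(vector, dtype=np.float64)
    n = height * width
    if vector.shape != (5 * n,):
        raise ValueError(
            f"expected a vector of length {5 * n} for {height}x{width}, "
            f"got {vector.shape}"
        )
    ch = vector.reshape(5, height, width)
    warp = WarpField(ch[0] / scale, ch[1] / scale)
    texture = np.stack([ch[2], ch[3], ch[4]], axis=-1)
    return McgmFrame(warp=warp, texture=texture)
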