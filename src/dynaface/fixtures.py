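"""Synthetic clip generator with known spatial modes, time-warps and audio.

Real inputs to the pipeline are short videos of a talking face with paired
audio.  The generator emulates the properties the pipeline actually relies
on, with full ground truth:

* a base scene (smooth textured image) deformed over time by ``k`` known
  smooth displacement modes, each clip driven by its own smooth amplitude
  curves — these play the role of facial movements;
* a per-clip monotone time-warp ``g`` mapping the common reference timeline
  to the clip's own timeline (speaking-rate variation), applied to both the
  video and the audio;
* an audio track that is silent until a per-clip onset and then carries a
  warped train of Gaussian amplitude bumps (the "syllables" a DTW can latch
  onto), synthesised on a 440 Hz carrier at 48 kHz;
* additive i.i.d. pixel noise.

Conventions: ``g`` is strictly increasing with slope in [0.7, 1.4] and maps
reference time -> clip time, so clip content at clip time ``tau`` shows the
reference state ``g^{-1}(tau)``; before the audio onset the mapping continues
at slope 1.  Frames are rendered by backward-warping the base image with the
summed mode field (bilinear sampling), matching the registration module's
convention so recovery tests compare like with like.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import media_io
from .media_io import AudioSignal, FrameSequence
from .mcgm import WarpField, apply_warp

__all__ = [
    "FixtureConfig",
    "SyntheticTruth",
    "make_modes",
    "make_base_image",
    "make_clip",
    "make_dataset",
    "write_dataset",
]

#: Reference-time margin (s) of pre-vocalisation motion included in clips.
PRE_ONSET_S = 0.2
#: Gaussian bump centres (s, reference time after onset) and width (s).
BUMP_TIMES_S = (0.06, 0.21, 0.36, 0.51, 0.66)
BUMP_SIGMA_S = 0.02
CARRIER_HZ = 440.0


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic dataset.

    Defaults: 48x48 px frames at 25 fps, 48 kHz audio, 3 planted modes,
    reference vocalisation 0.8 s, clip onsets in [0.42, 0.62] s, peak planted
    displacement 1.5 px, pixel noise sd 0.005, warp slopes within [0.7, 1.4]
    with mean 1.
    """

    height: int = 48
    width: int = 48
    k_modes: int = 3
    fps: float = 25.0
    audio_rate: float = 48000.0
    ref_duration_s: float = 0.8
    onset_range_s: tuple = (0.42, 0.62)
    peak_displacement_px: float = 1.5
    noise_sd: float = 0.005
    slope_base_range: tuple = (0.825, 1.175)
    slope_mod_max: float = 0.125


@dataclass
class SyntheticTruth:
    """Ground truth for one clip.

    ``timewarp_ref_s``/``timewarp_clip_s`` sample the strictly increasing
    map g: reference time -> clip time on [0, ref_duration]; amplitude
    curves are defined on the reference frame grid starting ``PRE_ONSET_S``
    before the vocalisation onset.
    """

    mode_fields: list            # k arrays of shape (H, W, 2): (dx, dy)
    amplitude_curves: np.ndarray  # (R, k) on the reference frame grid
    timewarp_ref_s: np.ndarray
    timewarp_clip_s: np.ndarray
    audio_onset_s: float
    noise_sd: float
    seed: int
    fps: float = 25.0
    audio_rate: float = 48000.0
    base_image: np.ndarray | None = None  # shared base scene, kept for tests

    def __post_init__(self) -> None:
        self.amplitude_curves = np.asarray(self.amplitude_curves, np.float64)
        self.timewarp_ref_s = np.asarray(self.timewarp_ref_s, np.float64)
        self.timewarp_clip_s = np.asarray(self.timewarp_clip_s, np.float64)
        if len(self.mode_fields) < 1:
            raise ValueError("need at least one mode field")
        if not np.all(np.isfinite(self.amplitude_curves)):
            raise ValueError("amplitude curves must be finite")
        if np.any(np.diff(self.timewarp_clip_s) <= 0):
            raise ValueError("timewarp must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def warp(self, ref_s):
        """Evaluate g at reference times (identity extension for t < 0)."""
        ref_s = np.asarray(ref_s, dtype=np.float64)
        out = np.interp(ref_s, self.timewarp_ref_s, self.timewarp_clip_s)
        neg = ref_s < 0
        return np.where(neg, ref_s, out)

    def warp_inv(self, clip_s):
        """Evaluate g^{-1} at clip times (identity extension for t < 0)."""
        clip_s = np.asarray(clip_s, dtype=np.float64)
        out = np.interp(clip_s, self.timewarp_clip_s, self.timewarp_ref_s)
        neg = clip_s < 0
        return np.where(neg, clip_s, out)

    def displacement_at(self, ref_s: float) -> WarpField:
        """Planted displacement field at a reference time (sum over modes)."""
        grid = (ref_s + PRE_ONSET_S) * self.fps
        amps = np.array([
            np.interp(grid, np.arange(self.amplitude_curves.shape[0]),
                      self.amplitude_curves[:, k])
            for k in range(len(self.mode_fields))
        ])
        d = sum(a * m for a, m in zip(amps, self.mode_fields))
        return WarpField(d[..., 0], d[..., 1])

    def frame_ref_times(self, n_frames: int) -> np.ndarray:
        """Reference time of each rendered frame of the clip."""
        tau = np.arange(n_frames) / self.fps - self.audio_onset_s
        return self.warp_inv(tau)


def make_modes(k: int, height: int, width: int, seed: int) -> list:
    """Generate k smooth, linearly independent displacement modes.

    Each mode is a random low-order (<= 2 half-cycles per axis) 2-D cosine
    series, favouring the lowest orders; the k vectorized fields are
    Gram-Schmidt orthogonalised (hence independent by construction) and
    rescaled so the peak per-pixel displacement magnitude is 2.5 px (< 3 px,
    keeping the warp invertible at unit amplitude).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if height < 16 or width < 16:
        raise ValueError("height and width must be >= 16")
    rng = np.random.default_rng(seed)
    ys = np.linspace(0.0, 1.0, height)[:, None]
    xs = np.linspace(0.0, 1.0, width)[None, :]
    orders = [(p, q) for p in range(3) for q in range(3)]
    raw = []
    for _ in range(k):
        f = np.zeros((height, width, 2))
        for (p, q) in orders:
            w = 1.0 / (1.0 + p + q)
            coef = rng.standard_normal(2) * w
            basis = np.cos(np.pi * p * ys) * np.cos(np.pi * q * xs)
            f[..., 0] += coef[0] * basis
            f[..., 1] += coef[1] * basis
        raw.append(f)

    # Orthogonalise the vectorized fields.
    modes = []
    for f in raw:
        v = f.ravel().copy()
        for m in modes:
            v -= (v @ m.ravel()) * m.ravel() / (m.ravel() @ m.ravel())
        f = v.reshape(height, width, 2)
        peak = np.hypot(f[..., 0], f[..., 1]).max()
        if peak < 1e-12:
            raise RuntimeError("degenerate mode draw; use a different seed")
        modes.append(f * (2.5 / peak))
    return modes


def make_base_image(height: int, width: int, seed: int) -> np.ndarray:
    """Smooth textured RGB base scene with a central face-like blob.

    Band-limited noise at two spatial scales gives the dense gradients the
    registration needs; a soft radial blob mimics a centred face against a
    plainer background.  Intensities lie in [0.1, 0.9].
    """
    rng = np.random.default_rng(seed)
    img = np.zeros((height, width, 3))
    for sigma, weight in ((2.0, 1.0), (6.0, 1.5)):
        noise = gaussian_filter(rng.standard_normal((height, width, 3)),
                                (sigma, sigma, 0))
        img += weight * noise / max(noise.std(), 1e-12)
    ys = (np.arange(height)[:, None] - height / 2) / (0.35 * height)
    xs = (np.arange(width)[None, :] - width / 2) / (0.35 * width)
    blob = np.exp(-(ys ** 2 + xs ** 2))
    img += 1.2 * blob[..., None] * np.array([1.0, 0.8, 0.6])
    lo, hi = img.min(), img.max()
    return 0.1 + 0.8 * (img - lo) / (hi - lo)


def _reference_envelope(ref_s: np.ndarray) -> np.ndarray:
    """Bump-train amplitude envelope on the reference timeline (s)."""
    env = np.zeros_like(ref_s)
    for t0 in BUMP_TIMES_S:
        env += np.exp(-0.5 * ((ref_s - t0) / BUMP_SIGMA_S) ** 2)
    return env / env.max()


def make_clip(base_image: np.ndarray,
              truth: SyntheticTruth) -> tuple[FrameSequence, AudioSignal]:
    """Render one synthetic clip and its audio from ground truth.

    Frame at clip time tau is the base image backward-warped by the planted
    displacement field at reference time g^{-1}(tau - onset), plus i.i.d.
    Gaussian pixel noise.  The audio is silent until the onset, then carries
    the time-warped bump-train envelope on a sine carrier.
    """
    base_image = np.asarray(base_image, dtype=np.float64)
    h, w = truth.mode_fields[0].shape[:2]
    if base_image.shape[:2] != (h, w):
        raise ValueError(
            f"base image {base_image.shape[:2]} does not match mode fields "
            f"({h}, {w})"
        )
    rng = np.random.default_rng(truth.seed)
    ref_end = float(truth.timewarp_ref_s[-1])
    duration = truth.audio_onset_s + float(truth.warp(ref_end))
    n_frames = max(2, int(np.floor(duration * truth.fps)) + 1)

    ref_times = truth.frame_ref_times(n_frames)
    frames = np.empty((n_frames, h, w, 3))
    for j, r in enumerate(ref_times):
        d = truth.displacement_at(min(r, ref_end))
        frame = apply_warp(base_image, d)
        if truth.noise_sd > 0:
            frame = frame + rng.normal(0.0, truth.noise_sd, frame.shape)
        frames[j] = np.clip(frame, 0.0, 1.0)

    n_samples = int(round(duration * truth.audio_rate))
    tau = np.arange(n_samples) / truth.audio_rate
    rel = tau - truth.audio_onset_s
    env = np.zeros(n_samples)
    voiced = rel >= 0
    env[voiced] = _reference_envelope(truth.warp_inv(rel[voiced]))
    samples = 0.8 * env * np.sin(2 * np.pi * CARRIER_HZ * tau)

    seq = FrameSequence(frames, fps=truth.fps, phrase_type="good_news")
    return seq, AudioSignal(samples, rate=truth.audio_rate)


def _draw_timewarp(rng: np.random.Generator,
                   config: FixtureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Smooth monotone warp with slope in [0.7, 1.4] (mean 1)."""
    grid = np.linspace(0.0, config.ref_duration_s, 81)
    c0 = rng.uniform(*config.slope_base_range)
    c1 = rng.uniform(0.0, config.slope_mod_max)
    phase = rng.uniform(0.0, 2 * np.pi)
    slope = c0 + c1 * np.cos(np.pi * grid / config.ref_duration_s + phase)
    clip_s = np.concatenate([[0.0], np.cumsum(
        0.5 * (slope[1:] + slope[:-1]) * np.diff(grid))])
    return grid, clip_s


def _draw_amplitudes(rng: np.random.Generator, config: FixtureConfig,
                     modes: list) -> np.ndarray:
    """Smooth random amplitude curves, tapered before the onset (unscaled)."""
    n_rows = int(round((PRE_ONSET_S + config.ref_duration_s) * config.fps)) + 1
    r = np.arange(n_rows) / config.fps - PRE_ONSET_S
    k = len(modes)
    curves = np.zeros((n_rows, k))
    for i in range(k):
        for h in range(1, 4):
            a, b = rng.standard_normal(2) / h
            arg = np.pi * h * (r + PRE_ONSET_S) / (PRE_ONSET_S + config.ref_duration_s)
            curves[:, i] += a * np.sin(arg) + b * (np.cos(arg) - 1.0)
    # Taper: little motion before the vocalisation onset.
    taper = np.clip((r + PRE_ONSET_S) / PRE_ONSET_S, 0.0, 1.0)
    curves *= (0.15 + 0.85 * taper[:, None]) ** 2
    return curves


def _peak_displacement(curves: np.ndarray, modes: list) -> float:
    """Peak per-pixel displacement magnitude over a clip's frames."""
    stack = np.stack(modes)  # (k, H, W, 2)
    disp = np.einsum("rk,khwc->rhwc", curves, stack)
    return float(np.hypot(disp[..., 0], disp[..., 1]).max())


def make_dataset(n_clips: int, config: FixtureConfig | None = None,
                 seed: int = 0) -> tuple[list, list]:
    """Generate a reproducible dataset of clips with ground truth.

    Returns ``(clips, truths)`` where ``clips[i]`` is a
    ``(FrameSequence, AudioSignal)`` pair.  Requires ``n_clips >= 3`` (the
    second-order PCA needs at least 3 samples for 2 components).
    """
    if n_clips < 3:
        raise ValueError("need at least 3 clips (second-order PCA minimum)")
    config = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    modes = make_modes(config.k_modes, config.height, config.width,
                       seed=int(rng.integers(2 ** 31)))
    base = make_base_image(config.height, config.width,
                           seed=int(rng.integers(2 ** 31)))

    # Draw all amplitude curves, then centre them across clips so the
    # dataset's average behaviour is the neutral base pose: clips are
    # idiosyncratic deviations around a static average, which is the regime
    # the caricature weighting manipulates.  A single global scale sets the
    # largest clip's peak displacement to the configured target.
    warps = [_draw_timewarp(rng, config) for _ in range(n_clips)]
    amp_raw = [_draw_amplitudes(rng, config, modes) for _ in range(n_clips)]
    onsets = [float(rng.uniform(*config.onset_range_s)) for _ in range(n_clips)]
    clip_seeds = [int(rng.integers(2 ** 31)) for _ in range(n_clips)]
    amp_mean = np.mean(amp_raw, axis=0)
    amplitudes = [a - amp_mean for a in amp_raw]
    peak = max(_peak_displacement(a, modes) for a in amplitudes)
    if peak > 1e-12:
        amplitudes = [a * (config.peak_displacement_px / peak)
                      for a in amplitudes]

    clips, truths = [], []
    for i in range(n_clips):
        ref_grid, clip_grid = warps[i]
        truth = SyntheticTruth(
            mode_fields=modes,
            amplitude_curves=amplitudes[i],
            timewarp_ref_s=ref_grid,
            timewarp_clip_s=clip_grid,
            audio_onset_s=onsets[i],
            noise_sd=config.noise_sd,
            seed=clip_seeds[i],
            fps=config.fps,
            audio_rate=config.audio_rate,
            base_image=base,
        )
        seq, audio = make_clip(base, truth)
        seq.clip_id = f"clip_{i:04d}"
        clips.append((seq, audio))
        truths.append(truth)
    return clips, truths


def write_dataset(path, clips: list, truths: list) -> None:
    """Write clips as per-clip directories (PNG frames, WAV, truth JSON)."""
    path = Path(path)
    for (seq, audio), truth in zip(clips, truths):
        clip_dir = path / seq.clip_id
        media_io.save_clip(clip_dir, seq, audio)
        payload = {
            "amplitude_curves": truth.amplitude_curves.tolist(),
            "timewarp_ref_s": truth.timewarp_ref_s.tolist(),
            "timewarp_clip_s": truth.timewarp_clip_s.tolist(),
            "audio_onset_s": truth.audio_onset_s,
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
            "fps": truth.fps,
            "audio_rate": truth.audio_rate,
        }
        (clip_dir / "truth.json").write_text(json.dumps(payload))
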