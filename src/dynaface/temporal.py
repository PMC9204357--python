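"""Audio-envelope temporal alignment and warping-curve arithmetic.

Clips of the same phrase differ in vocalisation onset and speaking rate, so
their first-order PCA timeseries cannot be averaged or compared frame by
frame.  Alignment is driven by the audio: the Hilbert amplitude envelope of
each (mono) track is re-cut at the detected vocalisation onset, decimated by
a factor of 10 (48 kHz -> 4.8 kHz) for tractability, and aligned to a common
reference envelope by dynamic time warping.  The reference starts as the
clip closest to the median duration and is replaced by the mean of the
aligned envelopes on each of (by default) three iterations; every envelope,
including the reference, is rescaled to unit L2 norm per iteration so global
loudness differences do not drive the alignment.

The DTW uses an asymmetric step pattern with the reference as the query —
every reference sample is matched to exactly one clip sample, so all aligned
series share the reference length — and open beginnings/ends, so neither
extremity of the clip needs to be matched.

The audio-rate warping curves are down-sampled to the video rate (25 fps) by
linear interpolation and extended at a 45 degree angle (slope exactly 1) for
four video frames (160 ms) before the vocalisation onset, to include facial
movements that precede the voice.  Curve gradients (forward differences) are
the representation appended to the second-order PCA input; a curve is
recovered from its gradients by cumulative summation, a bijection given the
anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert, resample_poly

from .media_io import AudioSignal

__all__ = [
    "Envelope",
    "WarpCurve",
    "AlignmentInfo",
    "hilbert_envelope",
    "detect_onset",
    "cut_envelope",
    "decimate_envelope",
    "align_envelopes",
    "audio_to_video_curve",
    "warp_timeseries",
    "unwarp_timeseries",
    "curve_gradients",
    "gradients_to_curve",
]


@dataclass
class Envelope:
    """Non-negative amplitude envelope at a given sample rate.

    ``onset_index`` records where the envelope was re-cut in the original
    sample stream (0 if uncut).
    """

    values: np.ndarray
    rate: float
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("envelope values must be non-negative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class WarpCurve:
    """Monotone mapping from reference timeline to clip timeline.

    ``mapping[t]`` is the (possibly fractional) clip-time coordinate matched
    to reference index ``t``; ``rate`` is Hz for audio-rate curves or fps for
    video-rate curves.
    """

    mapping: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=np.float64).ravel()
        if self.mapping.size < 2:
            raise ValueError("a warp curve needs at least 2 points")
        if not np.all(np.isfinite(self.mapping)):
            raise ValueError("warp curve contains non-finite values")
        if np.any(np.diff(self.mapping) < -1e-9):
            raise ValueError("warp curve must be non-decreasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.mapping.size

    @property
    def gradients(self) -> np.ndarray:
        return curve_gradients(self)


@dataclass
class AlignmentInfo:
    """Bookkeeping from :func:`align_envelopes`.

    ``reference_index`` is the clip chosen to seed the reference timeline
    (closest to median duration); ``objective_history`` is the mean squared
    distance of aligned unit-norm envelopes to the reference used on each
    iteration.
    """

    reference_index: int
    objective_history: list = field(default_factory=list)


def hilbert_envelope(audio: AudioSignal) -> Envelope:
    """Amplitude envelope = magnitude of the analytic signal."""
    if audio.samples.size < 64:
        raise ValueError("audio too short for envelope extraction (< 64 samples)")
    env = np.abs(hilbert(audio.samples))
    return Envelope(env, rate=audio.rate)


def detect_onset(env: Envelope, fps: float = 25.0,
                 threshold_frac: float = 0.1, sustain_s: float = 0.03,
                 smooth_s: float = 0.02, override: float | None = None) -> float:
    """Detect the vocalisation onset (seconds) from an amplitude envelope.

    The initial rise is the first sample where the smoothed envelope (20 ms
    moving average) exceeds ``threshold_frac`` of its maximum for at least
    ``sustain_s``.  The returned onset is 80 ms (two video frames) before the
    rise, clamped at zero and rounded to the nearest video-frame time
    (1/fps).  A manual ``override`` wins unconditionally, mirroring
    hand-corrected onsets.
    """
    if override is not None:
        return float(override)
    if fps <= 0:
        raise ValueError("fps must be positive")
    win = max(1, int(round(smooth_s * env.rate)))
    smoothed = uniform_filter1d(env.values, size=win)
    peak = smoothed.max()
    if peak <= 0:
        raise RuntimeError("silent clip: cannot detect a vocalisation onset")
    above = smoothed > threshold_frac * peak
    sustain = max(1, int(round(sustain_s * env.rate)))
    runs = np.convolve(above.astype(np.float64), np.ones(sustain), mode="valid")
    idx = np.flatnonzero(runs >= sustain - 1e-9)
    if idx.size == 0:
        raise RuntimeError("no sustained rise found in envelope")
    rise_s = idx[0] / env.rate
    onset = max(0.0, rise_s - 0.080)
    return round(onset * fps) / fps


def cut_envelope(env: Envelope, onset_s: float) -> Envelope:
    """Re-cut an envelope to start at ``onset_s``."""
    i0 = int(round(onset_s * env.rate))
    i0 = int(np.clip(i0, 0, env.values.size - 1))
    return Envelope(env.values[i0:], rate=env.rate, onset_index=i0)


def decimate_envelope(env: Envelope, factor: int = 10) -> Envelope:
    """Anti-aliased decimation (zero-phase low-pass, then stride).

    The rate is divided by ``factor``; DC content is preserved.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("decimation factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return Envelope(env.values.copy(), rate=env.rate,
                        onset_index=env.onset_index)
    # Polyphase FIR decimation: zero-phase low-pass then stride, with edge
    # padding so boundary transients do not distort the envelope.
    values = resample_poly(env.values, 1, factor, padtype="line")
    return Envelope(np.clip(values, 0.0, None), rate=env.rate / factor,
                    onset_index=env.onset_index)


def _dtw_curve(reference: np.ndarray, clip: np.ndarray) -> np.ndarray:
    """Asymmetric-step DTW with open begin/end; reference is the query.

    Steps from (i-1, j-k), k in {0, 1, 2}, each adding the local squared
    distance d(i, j) — exactly one clip coordinate per reference sample.
    Open begin: the first reference sample may match any clip sample at no
    prior cost; open end: the path may stop at any clip sample.  Returns the
    (integer, non-decreasing) clip index matched to each reference index.
    """
    n, m = reference.size, clip.size
    d = (reference[:, None] - clip[None, :]) ** 2
    prev = d[0].copy()
    choice = np.zeros((n, m), dtype=np.uint8)
    c1 = np.empty(m)
    c2 = np.empty(m)
    c1[0] = np.inf
    c2[:2] = np.inf
    for i in range(1, n):
        c1[1:] = prev[:-1]
        c2[2:] = prev[:-2]
        best = np.minimum(np.minimum(prev, c1), c2)
        row = choice[i]
        row[c2 == best] = 2
        row[c1 == best] = 1
        row[prev == best] = 0  # ties prefer the smallest step
        prev = d[i] + best
    path = np.empty(n, dtype=np.int64)
    j = int(np.argmin(prev))
    path[-1] = j
    for i in range(n - 1, 0, -1):
        j -= int(choice[i, j])
        path[i - 1] = j
    return path


def align_envelopes(envs: list, n_iterations: int = 3
                    ) -> tuple[list, Envelope, AlignmentInfo]:
    """Iteratively align envelopes to a common reference by DTW.

    Per iteration, all envelopes and the reference are rescaled to unit L2
    norm, each clip is warped onto the reference timeline by asymmetric
    open-ended DTW, and the reference is replaced by the mean of the aligned
    envelopes.  Returns one :class:`WarpCurve` per clip (reference timeline
    -> clip timeline, at the envelope rate), the final reference envelope,
    and an :class:`AlignmentInfo`.
    """
    if len(envs) < 2:
        raise ValueError("need at least 2 envelopes to align")
    rates = {e.rate for e in envs}
    if len(rates) > 1:
        raise ValueError(f"envelope rates differ: {rates}")
    rate = envs[0].rate

    def unit(v):
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v

    flat = [e.values.max() - e.values.min() < 1e-12 for e in envs]
    if any(flat):
        warnings.warn("degenerate flat envelope(s): using identity curves")

    lengths = np.array([e.values.size for e in envs])
    ref_idx = int(np.argmin(np.abs(lengths - np.median(lengths))))
    reference = envs[ref_idx].values.copy()

    info = AlignmentInfo(reference_index=ref_idx)
    curves = None
    for _ in range(n_iterations):
        ref_u = unit(reference)
        curves = []
        aligned = []
        sq = 0.0
        for e, is_flat in zip(envs, flat):
            if is_flat:
                path = np.clip(np.arange(ref_u.size), 0, e.values.size - 1)
            else:
                path = _dtw_curve(ref_u, unit(e.values))
            curves.append(path)
            aligned.append(unit(e.values)[path])
            sq += float(np.mean((aligned[-1] - ref_u) ** 2))
        info.objective_history.append(sq / len(envs))
        reference = np.mean(aligned, axis=0)

    warp_curves = [WarpCurve(np.asarray(p, dtype=np.float64), rate=rate)
                   for p in curves]
    return warp_curves, Envelope(np.clip(reference, 0.0, None), rate=rate), info


def audio_to_video_curve(curve: WarpCurve, fps: float = 25.0,
                         pre_frames: int = 4,
                         clip_onset_frames: float = 0.0) -> WarpCurve:
    """Down-sample an audio-rate warping curve to video rate.

    The audio-rate mapping is linearly interpolated at video-frame times and
    converted to clip frame indices (offset by ``clip_onset_frames``, the
    clip frame at which the aligned audio segment starts).  ``pre_frames``
    points are then prepended, continuing backwards at gradient exactly 1
    (45 degrees), to cover facial motion just before the vocalisation onset.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if pre_frames < 0:
        raise ValueError("pre_frames must be >= 0")
    spf = curve.rate / fps  # audio samples per video frame
    n_video = int(np.floor((len(curve) - 1) / spf)) + 1
    t_audio = np.arange(n_video) * spf
    mapped = np.interp(t_audio, np.arange(len(curve)), curve.mapping)
    mapped = mapped / spf + clip_onset_frames
    head = mapped[0] - np.arange(pre_frames, 0, -1)
    return WarpCurve(np.concatenate([head, mapped]), rate=fps)


def warp_timeseries(scores: np.ndarray, curve: WarpCurve) -> np.ndarray:
    """Resample a (T, K) timeseries onto the reference timeline.

    Row ``t`` of the output is the linear interpolation of ``scores`` at the
    fractional frame index ``curve.mapping[t]``; coordinates outside
    [0, T-1] are clamped with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if scores.size == 0:
        raise ValueError("empty timeseries")
    T = scores.shape[0]
    w = curve.mapping
    if w.min() < -1e-9 or w.max() > T - 1 + 1e-9:
        warnings.warn(
            f"warp curve range [{w.min():.2f}, {w.max():.2f}] exceeds clip "
            f"frames [0, {T - 1}]; clamping"
        )
    w = np.clip(w, 0.0, T - 1)
    i0 = np.floor(w).astype(np.int64)
    i1 = np.minimum(i0 + 1, T - 1)
    frac = (w - i0)[:, None]
    return scores[i0] * (1.0 - frac) + scores[i1] * frac


def unwarp_timeseries(aligned: np.ndarray, curve: WarpCurve) -> np.ndarray:
    """Map an aligned (T_ref, K) timeseries back to the clip timescale.

    The curve is re-based to start at 0; the output has
    ``floor(final clip coordinate) + 1`` rows, each obtained by inverting the
    monotone mapping and interpolating the aligned series there.
    """
    aligned = np.atleast_2d(np.asarray(aligned, dtype=np.float64))
    if aligned.size == 0:
        raise ValueError("empty timeseries")
    rel = curve.mapping - curve.mapping[0]
    # Strictify flats so the inverse interpolation is well defined.
    rel = rel + np.arange(rel.size) * 1e-9
    n_out = int(np.floor(rel[-1] + 1e-9)) + 1
    t_ref = np.interp(np.arange(n_out), rel, np.arange(rel.size))
    i0 = np.floor(t_ref).astype(np.int64)
    i1 = np.minimum(i0 + 1, aligned.shape[0] - 1)
    frac = (t_ref - i0)[:, None]
    return aligned[i0] * (1.0 - frac) + aligned[i1] * frac


def curve_gradients(curve: WarpCurve) -> np.ndarray:
    """Forward-difference gradients of the mapping, last value repeated.

    Length equals the curve length, so curve <-> gradients is a bijection
    given the anchor (first mapping value).
    """
    g = np.diff(curve.mapping)
    return np.concatenate([g, g[-1:]])


def gradients_to_curve(gradients: np.ndarray, anchor: float = 0.0,
                       rate: float = 25.0) -> WarpCurve:
    """Reconstruct a warping curve from its gradients by cumulative summation.

    Negative gradients (possible for extreme caricature weights) are clipped
    to 1e-3 with a warning, keeping the curve monotone.  Exact inverse of
    :func:`curve_gradients` when ``anchor`` is the original first value.
    """
    g = np.asarray(gradients, dtype=np.float64).ravel()
    if not np.all(np.isfinite(g)):
        raise ValueError("gradients contain non-finite values")
    if np.any(g < 0):
        warnings.warn(
            f"{int((g < 0).sum())} negative warp gradients clipped to 1e-3"
        )
        g = np.clip(g, 1e-3, None)
    mapping = anchor + np.concatenate([[0.0], np.cumsum(g[:-1])])
    return WarpCurve(mapping, rate=rate)
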