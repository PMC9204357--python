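"""Clip I/O, face-region cropping and anti-aliased down-sampling.

Clips are stored as plain directories: 8-bit PNG frames (``frame_%04d.png``),
a 16-bit PCM WAV for the audio track, and an optional ``clip.json`` sidecar
carrying frame rate, phrase type, word-onset timestamps and a crop
specification.  Inside the package everything is float in [0, 1]; the 8-bit
representation exists only at the file boundary.

Face detection is deliberately not implemented here: the crop region comes
from the sidecar, from configuration, or from a user-supplied detector
callable that honours the "average face position over frames plus a small
border" rule.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.io import wavfile
from skimage.transform import resize

logger = logging.getLogger("dynaface")

PHRASE_TYPES = ("good_news", "sorry_to_say", "other")

__all__ = [
    "FrameSequence",
    "AudioSignal",
    "CropSpec",
    "load_clip",
    "save_clip",
    "crop_and_downsample",
]


@dataclass
class FrameSequence:
    """Ordered RGB frames of one clip.

    frames: (T, H, W, 3) float array in [0, 1]; fps defaults to 25.
    """

    frames: np.ndarray
    fps: float = 25.0
    clip_id: str = ""
    phrase_type: str = "other"
    word_onsets: list | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must be (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a clip needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.phrase_type not in PHRASE_TYPES:
            raise ValueError(f"unknown phrase_type {self.phrase_type!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:3]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class AudioSignal:
    """Mono audio track; rate defaults to 48 kHz."""

    samples: np.ndarray
    rate: float = 48000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples contain non-finite values")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class CropSpec:
    """Square crop (row, col, side) in source pixels plus a border fraction.

    The border expands the square on every side by ``border_frac * side``
    and is clamped to the image bounds before use.
    """

    row: int
    col: int
    side: int
    border_frac: float = 0.1

    def expanded(self, height: int, width: int) -> tuple[int, int, int]:
        """Return (row, col, side) after border expansion and clamping."""
        if self.side <= 0:
            raise ValueError("crop side must be positive")
        if self.border_frac < 0:
            raise ValueError("border_frac must be >= 0")
        border = int(round(self.border_frac * self.side))
        r0 = self.row - border
        c0 = self.col - border
        side = self.side + 2 * border
        side = min(side, height, width)
        r0 = int(np.clip(r0, 0, height - side))
        c0 = int(np.clip(c0, 0, width - side))
        return r0, c0, side


_FRAME_RE = re.compile(r"frame_(\d+)\.png$")


def load_clip(path, word_onsets: list | None = None) -> tuple[FrameSequence, AudioSignal]:
    """Load a clip directory (PNG frames + WAV audio + optional sidecar).

    Stereo audio is averaged over channels to mono.  If word-onset
    timestamps are available (argument or sidecar), the clip is cut to start
    200 ms before the first word onset, rounded down to a frame boundary, so
    facial movements commencing just before the vocalisation are kept.
    """
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"clip path is not a directory: {path}")

    meta = {}
    sidecar = path / "clip.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    fps = float(meta.get("fps", 25.0))
    clip_id = str(meta.get("clip_id", path.name))
    phrase_type = str(meta.get("phrase_type", "other"))
    if word_onsets is None:
        word_onsets = meta.get("word_onsets")

    frame_files = sorted(
        (p for p in path.iterdir() if _FRAME_RE.search(p.name)),
        key=lambda p: int(_FRAME_RE.search(p.name).group(1)),
    )
    if not frame_files:
        raise IOError(f"no frames found in {path}")
    frames = np.stack([iio.imread(p) for p in frame_files]).astype(np.float64)
    if frames.ndim == 3:  # grayscale PNGs
        frames = np.repeat(frames[..., None], 3, axis=-1)
    frames = frames[..., :3] / 255.0

    wavs = sorted(path.glob("*.wav"))
    if not wavs:
        raise IOError(f"no WAV audio found in {path}")
    rate, raw = wavfile.read(wavs[0])
    samples = np.asarray(raw, dtype=np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        samples = samples / float(np.iinfo(raw.dtype).max)  # PCM -> [-1, 1]
    if samples.ndim == 2:
        samples = samples.mean(axis=1)

    seq = FrameSequence(frames, fps=fps, clip_id=clip_id,
                        phrase_type=phrase_type, word_onsets=word_onsets)
    audio = AudioSignal(samples, rate=float(rate))

    mismatch = abs(seq.duration_s - audio.duration_s)
    if mismatch > 1.0 / fps:
        logger.warning(
            "clip %s: audio/video duration mismatch of %.3f s", clip_id, mismatch
        )

    if word_onsets:
        start_s = max(0.0, float(word_onsets[0]) - 0.200)
        start_frame = int(np.floor(start_s * fps + 1e-9))
        if start_frame > 0 and seq.n_frames - start_frame >= 2:
            frames = seq.frames[start_frame:]
            samples = audio.samples[int(round(start_frame / fps * audio.rate)):]
            seq = FrameSequence(frames, fps=fps, clip_id=clip_id,
                                phrase_type=phrase_type, word_onsets=word_onsets)
            audio = AudioSignal(samples, rate=audio.rate)

    return seq, audio


def save_clip(path, seq: FrameSequence, audio: AudioSignal) -> None:
    """Write a clip directory: 8-bit PNG frames, 16-bit PCM WAV, sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / f"frame_{i:04d}.png",
                    np.round(frame * 255.0).astype(np.uint8))
    pcm = np.round(np.clip(audio.samples, -1.0, 1.0) * 32767.0).astype(np.int16)
    wavfile.write(path / "audio.wav", int(audio.rate), pcm)
    meta = {
        "fps": seq.fps,
        "clip_id": seq.clip_id,
        "phrase_type": seq.phrase_type,
    }
    if seq.word_onsets is not None:
        meta["word_onsets"] = list(seq.word_onsets)
    (path / "clip.json").write_text(json.dumps(meta, indent=2))


def crop_and_downsample(seq: FrameSequence, crop: CropSpec,
                        out_size: int = 128) -> FrameSequence:
    """Crop to the (border-expanded) square region and resize with anti-aliasing.

    The resize low-passes before decimation so frequencies above the output
    Nyquist are suppressed rather than aliased; a constant input comes out
    constant and the mean intensity is preserved.
    """
    height, width = seq.shape
    r0, c0, side = crop.expanded(height, width)
    if r0 < 0 or c0 < 0 or r0 + side > height or c0 + side > width:
        raise ValueError("crop region lies outside the frame")
    if out_size <= 0:
        raise ValueError("out_size must be positive")
    cropped = seq.frames[:, r0:r0 + side, c0:c0 + side, :]
    out = np.empty((seq.n_frames, out_size, out_size, 3))
    for i, frame in enumerate(cropped):
        out[i] = resize(frame, (out_size, out_size), order=1,
                        anti_aliasing=side > out_size, mode="reflect",
                        preserve_range=True)
    out = np.clip(out, 0.0, 1.0)
    return FrameSequence(out, fps=seq.fps, clip_id=seq.clip_id,
                         phrase_type=seq.phrase_type,
                         word_onsets=seq.word_onsets)
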