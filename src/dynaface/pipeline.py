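"""End-to-end orchestration: ingest -> register -> PCA1 -> align -> PCA2.

`run_pipeline` consumes a dataset directory of clip folders, groups clips by
phrase type (each type is modelled separately), and produces one fitted
:class:`~dynaface.spatiotemporal.AppearanceModel` per type plus a report of
explained variances, timeline length and round-trip reconstruction errors.
Runs are fully determined by the configuration and inputs — no randomness is
used anywhere in the fitting chain.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import media_io, pca_core, temporal
from .mcgm import RegistrationConfig, build_reference, vectorize
from .media_io import CropSpec
from .spatiotemporal import (AppearanceModel, build_clip_vectors,
                             fit_second_order)

logger = logging.getLogger("dynaface")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "fit_appearance_model",
    "save_model",
    "load_model",
    "rating_trial_count",
]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable to/from YAML.

    Defaults mirror the standard protocol: 128 px working resolution, 25 fps
    video, three reference-refinement passes, three DTW iterations, x10
    envelope decimation (48 kHz -> 4.8 kHz), 80 ms onset back-off, 200 ms
    pre-vocalisation prefix, four 45-degree pre-onset frames.
    """

    out_size: int = 128
    fps: float = 25.0
    mcgm_iterations: int = 3
    dtw_iterations: int = 3
    decimate_factor: int = 10
    onset_offset_s: float = 0.080
    prefix_s: float = 0.200
    pre_frames: int = 4
    channel_scale: float = 1.0
    unsharp_sigma: float = 2.0
    unsharp_amount: float = 1.0
    seed: int = 0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def __post_init__(self) -> None:
        for name in ("out_size", "fps", "mcgm_iterations", "dtw_iterations",
                     "decimate_factor", "unsharp_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.registration, dict):
            self.registration = RegistrationConfig(**self.registration)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Fitted models (one per phrase type) and the run report."""

    models: dict
    report: dict


def fit_appearance_model(sequences: list, audios: list,
                         config: PipelineConfig | None = None,
                         clip_ids: list | None = None
                         ) -> tuple[AppearanceModel, dict]:
    """Fit the two-level appearance model on one group of clips.

    Stages: (optional) resize to the working resolution; iterative-reference
    registration to 5-channel features; lossless first-order PCA over all
    frames; audio-envelope extraction, onset re-cut, decimation and
    iterative DTW alignment; score-timeseries warping; clip-vector assembly
    (scores + curve gradients); lossless second-order PCA.
    """
    config = config or PipelineConfig()
    if len(sequences) < 3:
        raise ValueError("need at least 3 clips to fit the model")
    clip_ids = clip_ids or [s.clip_id or f"clip_{i:04d}"
                            for i, s in enumerate(sequences)]

    # Stage: ingest / resize.
    seqs = []
    for seq in sequences:
        h, w = seq.shape
        if (h, w) != (config.out_size, config.out_size):
            side = min(h, w)
            crop = CropSpec(row=(h - side) // 2, col=(w - side) // 2,
                            side=side, border_frac=0.0)
            seq = media_io.crop_and_downsample(seq, crop, config.out_size)
        seqs.append(seq)

    # Stage: registration to the iteratively refined reference.
    reference, features = build_reference(seqs, config.mcgm_iterations,
                                          config.registration)
    reference.channel_scale = config.channel_scale

    # Stage: first-order lossless PCA over all frames of all clips.
    X1 = np.stack([vectorize(f, config.channel_scale)
                   for clip in features for f in clip])
    pca1 = pca_core.fit_lossless(X1)
    all_scores = pca_core.transform(pca1, X1)
    clip_scores, pos = [], 0
    for seq in seqs:
        clip_scores.append(all_scores[pos:pos + seq.n_frames])
        pos += seq.n_frames

    # Stage: audio envelopes, onsets, decimation, iterative DTW.
    onsets, envs = [], []
    for audio in audios:
        env = temporal.hilbert_envelope(audio)
        onset = temporal.detect_onset(env, fps=config.fps)
        envs.append(temporal.decimate_envelope(
            temporal.cut_envelope(env, onset), config.decimate_factor))
        onsets.append(onset)
    audio_curves, ref_env, align_info = temporal.align_envelopes(
        envs, n_iterations=config.dtw_iterations)

    # Stage: video-rate curves and timeseries alignment.
    video_curves, aligned = [], []
    for curve, onset, scores in zip(audio_curves, onsets, clip_scores):
        vcurve = temporal.audio_to_video_curve(
            curve, fps=config.fps, pre_frames=config.pre_frames,
            clip_onset_frames=round(onset * config.fps))
        video_curves.append(vcurve)
        aligned.append(temporal.warp_timeseries(scores, vcurve))

    # Stage: clip vectors and second-order lossless PCA.
    t_ref, k1 = aligned[0].shape
    vectors = build_clip_vectors(aligned, video_curves, clip_ids)
    pca2 = fit_second_order(vectors)
    embeddings = pca_core.transform(pca2, np.stack([v.values for v in vectors]))

    model = AppearanceModel(
        pca1=pca1, pca2=pca2, reference=reference, clip_ids=list(clip_ids),
        curves=video_curves, aligned_scores=aligned, embeddings=embeddings,
        t_ref=t_ref, k1=k1, height=config.out_size, width=config.out_size,
        fps=config.fps, channel_scale=config.channel_scale,
        unsharp_sigma=config.unsharp_sigma,
        unsharp_amount=config.unsharp_amount,
    )

    # Round-trip diagnostics on a few training samples.
    probe = X1[:: max(1, X1.shape[0] // 8)]
    rt1 = float(np.abs(pca_core.inverse_transform(
        pca1, pca_core.transform(pca1, probe)) - probe).max())
    V = np.stack([v.values for v in vectors])
    rt2 = float(np.abs(pca_core.inverse_transform(pca2, embeddings) - V).max())

    report = {
        "n_clips": len(seqs),
        "n_frames_total": int(X1.shape[0]),
        "t_ref": int(t_ref),
        "pca1_components": pca1.m,
        "pca1_explained_ratio": _explained_ratio(X1, pca1),
        "pca1_roundtrip_max_err": rt1,
        "pca2_components": pca2.m,
        "pca2_explained_ratio": _explained_ratio(V, pca2),
        "pca2_roundtrip_max_err": rt2,
        "registration_objective": list(reference.objective_history),
        "alignment_objective": list(align_info.objective_history),
        "alignment_reference_clip": align_info.reference_index,
        "onsets_s": [float(o) for o in onsets],
    }
    return model, report


def _explained_ratio(X: np.ndarray, model) -> float:
    total = float(np.var(X, axis=0, ddof=1).sum())
    if total == 0:
        return 1.0
    return float(model.explained_variance.sum() / total)


def run_pipeline(dataset_dir, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the full pipeline on a dataset directory of clip folders.

    Clips are grouped by phrase type and each group (>= 3 clips) is fitted
    independently.  Any stage failure aborts with the stage and clip named.
    """
    config = config or PipelineConfig()
    dataset_dir = Path(dataset_dir)
    clip_dirs = sorted(p for p in dataset_dir.iterdir() if p.is_dir())
    if not clip_dirs:
        raise IOError(f"no clip directories under {dataset_dir}")

    groups: dict = {}
    for d in clip_dirs:
        try:
            seq, audio = media_io.load_clip(d)
        except Exception as exc:
            raise RuntimeError(f"ingest failed for clip {d.name}: {exc}") from exc
        groups.setdefault(seq.phrase_type, []).append((seq, audio))

    models, report = {}, {"config": config.to_dict(), "groups": {}}
    for ptype, items in groups.items():
        if len(items) < 3:
            raise ValueError(
                f"phrase type {ptype!r} has {len(items)} clips; "
                "second-order PCA needs at least 3"
            )
        seqs = [s for s, _ in items]
        auds = [a for _, a in items]
        logger.info("fitting phrase type %r (%d clips)", ptype, len(seqs))
        model, group_report = fit_appearance_model(
            seqs, auds, config, clip_ids=[s.clip_id for s in seqs])
        models[ptype] = model
        report["groups"][ptype] = group_report
    return PipelineResult(models=models, report=report)


def save_model(model: AppearanceModel, path) -> None:
    """Serialize a fitted model to a directory (npz arrays + JSON manifest)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path / "arrays.npz",
        pca1_mean=model.pca1.mean, pca1_components=model.pca1.components,
        pca1_ev=model.pca1.explained_variance,
        pca2_mean=model.pca2.mean, pca2_components=model.pca2.components,
        pca2_ev=model.pca2.explained_variance,
        reference=model.reference.reference_image,
        embeddings=model.embeddings,
        curves=np.stack([c.mapping for c in model.curves]),
        aligned=np.stack(model.aligned_scores),
    )
    manifest = {
        "clip_ids": model.clip_ids,
        "t_ref": model.t_ref, "k1": model.k1,
        "height": model.height, "width": model.width,
        "fps": model.fps, "channel_scale": model.channel_scale,
        "unsharp_sigma": model.unsharp_sigma,
        "unsharp_amount": model.unsharp_amount,
        "reference_iterations": model.reference.n_iterations,
        "reference_objective": list(model.reference.objective_history),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> AppearanceModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    with np.load(path / "arrays.npz") as z:
        pca1 = pca_core.PcaModel(z["pca1_mean"], z["pca1_components"],
                                 z["pca1_ev"])
        pca2 = pca_core.PcaModel(z["pca2_mean"], z["pca2_components"],
                                 z["pca2_ev"])
        from .mcgm import ReferenceModel
        reference = ReferenceModel(
            z["reference"], n_iterations=manifest["reference_iterations"],
            channel_scale=manifest["channel_scale"],
            objective_history=manifest["reference_objective"])
        curves = [temporal.WarpCurve(m, rate=manifest["fps"])
                  for m in z["curves"]]
        aligned = [a for a in z["aligned"]]
        embeddings = z["embeddings"]
    return AppearanceModel(
        pca1=pca1, pca2=pca2, reference=reference,
        clip_ids=list(manifest["clip_ids"]), curves=curves,
        aligned_scores=aligned, embeddings=embeddings,
        t_ref=manifest["t_ref"], k1=manifest["k1"],
        height=manifest["height"], width=manifest["width"],
        fps=manifest["fps"], channel_scale=manifest["channel_scale"],
        unsharp_sigma=manifest["unsharp_sigma"],
        unsharp_amount=manifest["unsharp_amount"],
    )


def rating_trial_count(n_levels: int = 5,
                       clips_per_rater=(15, 15, 16)) -> int:
    """Trials per rater in a caricature-rating design: levels x clips.

    With 5 weight levels and 15 + 15 + 16 unique clips across three
    recording subjects this is 230 trials.
    """
    if n_levels < 1 or any(c < 0 for c in clips_per_rater):
        raise ValueError("invalid design")
    return int(n_levels) * int(sum(clips_per_rater))
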