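"""Second-order PCA, caricature linearity, rendering and motion metric."""

import numpy as np
import pytest

from dynaface import pca_core, spatiotemporal, temporal
from dynaface.mcgm import McgmFrame, WarpField
from dynaface.spatiotemporal import (CaricatureRequest, build_clip_vectors,
                                     fit_second_order, split_clip_vector)
from dynaface.temporal import WarpCurve


def _random_clip_set(n_clips=10, t_ref=50, k1=99, seed=0):
    rng = np.random.default_rng(seed)
    aligned = [rng.normal(size=(t_ref, k1)) for _ in range(n_clips)]
    curves = [WarpCurve(np.cumsum(rng.uniform(0.5, 1.5, t_ref)), rate=25.0)
              for _ in range(n_clips)]
    return aligned, curves


class TestClipVectors:
    def test_length_and_roundtrip(self):
        aligned, curves = _random_clip_set(3)
        vectors = build_clip_vectors(aligned, curves)
        assert all(v.values.size == 50 * 99 + 50 for v in vectors)
        s, g = split_clip_vector(vectors[1].values, 50, 99)
        assert np.array_equal(s, aligned[1])
        assert np.array_equal(g, temporal.curve_gradients(curves[1]))

    def test_mismatched_lengths_rejected(self):
        aligned, curves = _random_clip_set(3)
        aligned[1] = aligned[1][:-1]
        with pytest.raises(ValueError):
            build_clip_vectors(aligned, curves)

    def test_frame_major_ordering(self):
        aligned, curves = _random_clip_set(1, t_ref=4, k1=3)
        v = build_clip_vectors(aligned, curves)[0]
        assert np.array_equal(v.values[:3], aligned[0][0])


class TestSecondOrderPca:
    def test_component_count_and_roundtrip(self):
        aligned, curves = _random_clip_set(10, t_ref=20, k1=8)
        vectors = build_clip_vectors(aligned, curves)
        model = fit_second_order(vectors)
        assert model.m == 9
        X = np.stack([v.values for v in vectors])
        Xh = pca_core.inverse_transform(model, pca_core.transform(model, X))
        assert np.abs(Xh - X).max() < 1e-6

    def test_identical_clips_zero_variance(self):
        aligned, curves = _random_clip_set(1, t_ref=10, k1=4)
        vecs = build_clip_vectors(aligned * 4, curves * 4)
        model = fit_second_order(vecs)
        assert np.allclose(model.explained_variance, 0.0)

    def test_too_few_clips_rejected(self):
        aligned, curves = _random_clip_set(2, t_ref=10, k1=4)
        with pytest.raises(ValueError):
            fit_second_order(build_clip_vectors(aligned, curves))


class TestCaricatureLinearity:
    def test_weight_one_reproduces_clip(self, fitted):
        model, _ = fitted
        for i, cid in enumerate(model.clip_ids[:3]):
            vec = spatiotemporal.reconstruct_clip_vector(
                model, CaricatureRequest(cid, 1.0))
            orig = np.concatenate([
                model.aligned_scores[i].ravel(),
                temporal.curve_gradients(model.curves[i])])
            assert np.abs(vec - orig).max() < 1e-6

    def test_weight_zero_reproduces_mean(self, fitted):
        model, _ = fitted
        vec = spatiotemporal.reconstruct_clip_vector(
            model, CaricatureRequest(model.clip_ids[0], 0.0))
        assert np.abs(vec - model.pca2.mean).max() < 1e-6

    @pytest.mark.parametrize("w", [0.5, 1.7, -1.0])
    def test_any_weight_is_affine_mix(self, fitted, w):
        """Representation at weight w equals w*x + (1-w)*mean exactly,
        including caricatures (w > 1) and anti-faces (w < 0)."""
        model, _ = fitted
        i, cid = 1, fitted[0].clip_ids[1]
        vec = spatiotemporal.reconstruct_clip_vector(
            model, CaricatureRequest(cid, w))
        orig = np.concatenate([
            model.aligned_scores[i].ravel(),
            temporal.curve_gradients(model.curves[i])])
        expect = w * orig + (1 - w) * model.pca2.mean
        assert np.abs(vec - expect).max() < 1e-6

    def test_unknown_clip_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError, match="unknown clip"):
            spatiotemporal.reconstruct_clip_vector(
                model, CaricatureRequest("nope", 1.0))


class TestRendering:
    def test_caricature_renders_valid_sequence(self, fitted):
        model, _ = fitted
        seq = spatiotemporal.caricature(
            CaricatureRequest(model.clip_ids[0], 0.5), model)
        assert seq.frames.shape[1:] == (48, 48, 3)
        assert seq.frames.min() >= 0.0 and seq.frames.max() <= 1.0
        frames, curve = spatiotemporal.backproject_mcgm(
            model, CaricatureRequest(model.clip_ids[0], 0.5))
        expect_len = int(np.floor(curve.mapping[-1] - curve.mapping[0] + 1e-9)) + 1
        assert seq.n_frames == expect_len

    def test_duration_interpolates_between_mean_and_original(self, fitted):
        model, _ = fitted
        for cid in model.clip_ids:
            durs = []
            for w in (0.0, 0.25, 0.5, 0.75, 1.0):
                frames, _ = spatiotemporal.backproject_mcgm(
                    model, CaricatureRequest(cid, w))
                durs.append(len(frames))
            lo, hi = min(durs[0], durs[-1]), max(durs[0], durs[-1])
            assert all(lo <= d <= hi for d in durs)
            diffs = np.diff(durs)
            assert np.all(diffs >= 0) or np.all(diffs <= 0)


class TestUnsharpMask:
    def test_identity_cases(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.2, 0.8, (24, 24, 3))
        assert np.allclose(spatiotemporal.unsharp_mask(img, amount=0.0), img)
        flat = np.full((24, 24, 3), 0.5)
        assert np.allclose(spatiotemporal.unsharp_mask(flat), flat)

    def test_step_edge_contrast_increases(self):
        img = np.zeros((24, 24, 3))
        img[:, 12:] = 0.8
        img += 0.1
        out = spatiotemporal.unsharp_mask(img, sigma=2.0, amount=1.0)
        grad_in = np.abs(np.diff(img[12, :, 0])).max()
        grad_out = np.abs(np.diff(out[12, :, 0])).max()
        assert grad_out > grad_in

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            spatiotemporal.unsharp_mask(np.zeros((8, 8, 3)), sigma=0.0)


class TestMotionMagnitudes:
    def test_zero_and_pythagorean(self):
        z = McgmFrame(WarpField(np.zeros((8, 8)), np.zeros((8, 8))),
                      np.zeros((8, 8, 3)))
        per_frame, pooled = spatiotemporal.motion_magnitudes([z])
        assert np.all(per_frame == 0) and np.all(pooled == 0)
        c = McgmFrame(WarpField(np.full((8, 8), 3.0), np.full((8, 8), 4.0)),
                      np.zeros((8, 8, 3)))
        per_frame, pooled = spatiotemporal.motion_magnitudes([z, c])
        assert per_frame[1] == pytest.approx(5.0)
        assert pooled.size == 2 * 64

    def test_pooled_mean_motion_non_decreasing_in_weight(self, fitted):
        """Objective caricature check: pooled over all clips and frames, the
        mean warp magnitude grows with the caricature level."""
        model, _ = fitted
        pooled_means = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            mags = []
            for cid in model.clip_ids:
                frames, _ = spatiotemporal.backproject_mcgm(
                    model, CaricatureRequest(cid, w))
                per_frame, _ = spatiotemporal.motion_magnitudes(frames)
                mags.append(per_frame.mean())
            pooled_means.append(np.mean(mags))
        assert np.all(np.diff(pooled_means) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spatiotemporal.motion_magnitudes([])


class TestVisualizeComponent:
    def test_grid_shape_mean_and_reflection(self):
        rng = np.random.default_rng(6)
        model = pca_core.fit_lossless(rng.normal(size=(8, 30)))
        recon = spatiotemporal.visualize_component(model, 1)
        assert recon.shape == (7, 30)
        assert np.allclose(recon[3], model.mean)
        # +/- c multiples reflect about the mean
        assert np.abs(recon[0] + recon[6] - 2 * model.mean).max() < 1e-6

    def test_bad_index_rejected(self):
        model = pca_core.fit_lossless(
            np.random.default_rng(7).normal(size=(5, 12)))
        with pytest.raises(ValueError):
            spatiotemporal.visualize_component(model, 99)
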