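"""Lossless principal component analysis.

Both levels of the appearance model use the same PCA machinery.  The data
matrices are extremely "wide" (many more feature dimensions than samples), so
an n-sample dataset carries at most n - 1 directions of variance around its
mean.  Retaining all n - 1 components therefore loses nothing: every training
sample is reconstructed exactly (up to floating point) from its scores.  This
is what makes the whole pipeline reversible — a frame, a clip, or a weighted
caricature can be pushed back through both PCAs to pixel space.

Implementation is an economy-size SVD of the centred data matrix, which is
numerically stable in the d >> n regime and gives the exact rank-(n-1) basis
directly.  Scores are plain ``ndarray``s; the model is a small frozen
dataclass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PcaModel", "fit_lossless", "transform", "inverse_transform"]


@dataclass(frozen=True)
class PcaModel:
    """Mean + orthonormal component basis + per-component variance.

    Attributes
    ----------
    mean : (d,) ndarray
        Mean of the training samples; the origin of the score space.
    components : (m, d) ndarray
        Orthonormal rows, ordered by decreasing explained variance.
    explained_variance : (m,) ndarray
        Sample variance (normalised by n - 1) along each component.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def m(self) -> int:
        return self.components.shape[0]

    @property
    def d(self) -> int:
        return self.components.shape[1]


def fit_lossless(X: np.ndarray) -> PcaModel:
    """Fit a lossless PCA retaining all n - 1 components.

    Parameters
    ----------
    X : (n, d) array
        Data matrix with samples as rows.  Requires ``n >= 2`` and
        ``d >= n - 1`` (wide/tall data), all entries finite.

    Returns
    -------
    PcaModel
        Model with exactly ``n - 1`` components; cumulative explained
        variance ratio equals 1 to machine precision, and every training row
        round-trips through ``transform``/``inverse_transform`` exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D data matrix, got shape {X.shape}")
    n, d = X.shape
    if n < 2:
        raise ValueError(f"lossless PCA needs at least 2 samples, got {n}")
    if d < n - 1:
        raise ValueError(
            f"lossless PCA expects d >= n - 1 (wide data); got n={n}, d={d}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")

    mean = X.mean(axis=0)
    Xc = X - mean
    # Economy SVD: Vt rows span the sample subspace; rank <= n - 1 after
    # centring, so the first n - 1 right singular vectors are lossless.
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    m = n - 1
    components = Vt[:m].copy()
    explained_variance = (S[:m] ** 2) / (n - 1)

    # Deterministic sign convention: largest-|.| element of each component
    # is made positive.
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0

    return PcaModel(mean=mean, components=components,
                    explained_variance=explained_variance)


def transform(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project samples into score space: ``(X - mean) @ components.T``."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != model.d:
        raise ValueError(
            f"dimension mismatch: model d={model.d}, data d={X2.shape[1]}"
        )
    scores = (X2 - model.mean) @ model.components.T
    return scores[0] if single else scores


def inverse_transform(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    """Back-project scores to feature space: ``scores @ components + mean``.

    Exact inverse of :func:`transform` on the training span; zero scores map
    to the mean.
    """
    scores = np.asarray(scores, dtype=np.float64)
    single = scores.ndim == 1
    S2 = np.atleast_2d(scores)
    if S2.shape[1] != model.m:
        raise ValueError(
            f"dimension mismatch: model m={model.m}, scores m={S2.shape[1]}"
        )
    X = S2 @ model.components + model.mean
    return X[0] if single else X
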