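"""PCA feature extraction for pixel spectra.

Pixel spectra live in an m-band space; the classifier and the downstream
t-test operate on the first few principal components Z = (X - mean) W,
where W's columns are eigenvectors of the sample covariance (1/(n-1)
estimator).  The decomposition is made deterministic by sorting
eigenvalues nonincreasing and fixing each loading column's sign so its
largest-magnitude entry is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, InsufficientDataError

__all__ = ["PCAModel", "pca_fit", "pca_transform", "pca_reconstruct"]

#: default retained variance fraction when neither k nor a fraction is given
DEFAULT_VARIANCE_FRACTION = 0.95


@dataclass
class PCAModel:
    """Fitted PCA: column mean, m x k orthonormal loadings W, top-k eigenvalues.

    ``total_variance`` (sum of all m eigenvalues = total column variance of
    the centered training data) is kept so reconstruction error can be
    accounted exactly: sum of squared residuals = (n-1) * (discarded
    eigenvalue mass).
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        m, k = self.loadings.shape
        if not 1 <= k <= m:
            raise ValueError(f"retained components k={k} must satisfy 1 <= k <= m={m}")
        if self.eigenvalues.shape != (k,):
            raise ValueError("eigenvalues must have one entry per retained component")
        if np.any(np.diff(self.eigenvalues) > 1e-10) or np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonincreasing and nonnegative")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("loadings must be column-orthonormal")

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "loadings": self.loadings.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "total_variance": self.total_variance,
                "k": self.k,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PCAModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["mean"]),
            np.asarray(d["loadings"]),
            np.asarray(d["eigenvalues"]),
            float(d["total_variance"]),
        )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pca_fit(
    X: np.ndarray, k: int | None = None, variance_fraction: float | None = None
) -> PCAModel:
    """Fit PCA by dense eigendecomposition of the sample covariance.

    Exactly one of ``k`` (component count) or ``variance_fraction``
    (smallest k whose eigenvalue mass reaches that fraction of the total)
    may be given; with neither, ``variance_fraction`` defaults to 0.95.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, m = X.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 rows")
    if k is not None and variance_fraction is not None:
        raise ValueError("give either k or variance_fraction, not both")
    if k is not None and not 1 <= k <= m:
        raise ValueError(f"k={k} must satisfy 1 <= k <= {m}")
    if variance_fraction is not None and not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must lie in (0, 1]")
    if k is None and variance_fraction is None:
        variance_fraction = DEFAULT_VARIANCE_FRACTION

    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1).reshape(m, m)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals, kind="stable")[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = float(evals.sum())

    if k is None:
        if variance_fraction == 1.0:
            # keep the numerical rank of the covariance
            tol = max(total, 1.0) * 1e-12
            k = max(1, int(np.sum(evals > tol)))
        else:
            k = int(np.searchsorted(np.cumsum(evals), variance_fraction * total) + 1)
            k = min(k, m)
    return PCAModel(mean, evecs[:, :k], evals[:k], total)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project onto the retained components: Z = (X - mean) W."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise DimensionError(f"X has {X.shape[1]} columns, model expects {model.n_features}")
    return (X - model.mean) @ model.loadings


def pca_reconstruct(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Map scores back to band space: X_hat = Z W^T + mean."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.k:
        raise DimensionError(f"Z has {Z.shape[1]} columns, model retains k={model.k}")
    return Z @ model.loadings.T + model.mean
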