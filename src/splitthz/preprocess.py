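"""Spectral preprocessing: sampling guard, min-max normalization, FIR smoothing.

The acquisition chain samples a continuous reflectance signal x(t) at
interval T_s (x[n] = x(nT_s)); the Nyquist-Shannon condition
T_s <= 1/(2 f_max) guards against aliasing.  Pixel spectra are then
min-max normalized per band, x_norm = (x - min) / (max - min), and
low-pass filtered by discrete convolution with a short FIR kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateFeatureError, DimensionError, KernelError

__all__ = [
    "SampledSignal",
    "NormalizationParams",
    "FilterKernel",
    "check_nyquist",
    "resample",
    "minmax_fit_apply",
    "minmax_apply",
    "minmax_invert",
    "lowpass",
]


@dataclass
class SampledSignal:
    """A uniformly sampled signal: values x[n] at interval ``sample_interval``."""

    values: np.ndarray
    sample_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")


@dataclass
class NormalizationParams:
    """Per-feature min/max captured at fit time; the affine map is invertible."""

    per_feature_min: np.ndarray
    per_feature_max: np.ndarray

    def __post_init__(self) -> None:
        self.per_feature_min = np.asarray(self.per_feature_min, dtype=float)
        self.per_feature_max = np.asarray(self.per_feature_max, dtype=float)
        if np.any(self.per_feature_max < self.per_feature_min):
            raise ValueError("per-feature max must be >= min")

    @property
    def n_features(self) -> int:
        return self.per_feature_min.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {"per_feature_min": self.per_feature_min.tolist(), "per_feature_max": self.per_feature_max.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        return cls(np.asarray(d["per_feature_min"]), np.asarray(d["per_feature_max"]))


@dataclass
class FilterKernel:
    """FIR taps h[k]; ``normalized`` means the taps sum to 1 (unit DC gain)."""

    taps: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.taps.ndim != 1 or self.taps.size < 1:
            raise KernelError("kernel needs at least one tap")
        if not np.all(np.isfinite(self.taps)):
            raise KernelError("kernel taps must be finite")
        self.normalized = bool(abs(self.taps.sum() - 1.0) < 1e-12)

    def to_json(self) -> str:
        return json.dumps({"taps": self.taps.tolist(), "normalized": self.normalized})

    @classmethod
    def from_json(cls, text: str) -> "FilterKernel":
        return cls(np.asarray(json.loads(text)["taps"]))


#: 3-tap binomial smoother used by default throughout the pipeline.
DEFAULT_KERNEL = FilterKernel(np.array([0.25, 0.5, 0.25]))


def check_nyquist(sample_interval: float, max_frequency: float) -> bool:
    """True iff T_s <= 1 / (2 f_max), i.e. sampling is alias-free."""
    if sample_interval <= 0 or max_frequency <= 0:
        raise ValueError("sample_interval and max_frequency must be positive")
    return sample_interval <= 1.0 / (2.0 * max_frequency)


def resample(signal: SampledSignal, factor: int) -> SampledSignal:
    """Decimate by keeping every ``factor``-th sample starting at index 0."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"resample factor must be an integer >= 1, got {factor}")
    return SampledSignal(signal.values[:: int(factor)], signal.sample_interval * int(factor))


def minmax_fit_apply(X: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Fit per-column min/max on X and return the normalized matrix with the params.

    Each output column spans exactly [0, 1] on the fitted data.  Constant
    columns make the map undefined and raise
    :class:`DegenerateFeatureError` naming the offending columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("need at least one row")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    lo, hi = X.min(axis=0), X.max(axis=0)
    constant = np.flatnonzero(hi == lo)
    if constant.size:
        raise DegenerateFeatureError(
            f"constant feature column(s) {constant.tolist()}: min == max, normalization undefined"
        )
    params = NormalizationParams(lo, hi)
    return (X - lo) / (hi - lo), params


def minmax_apply(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Apply a previously fitted normalization (e.g. to validation data)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.n_features:
        raise DimensionError(f"X has {X.shape[1]} columns, params expect {params.n_features}")
    return (X - params.per_feature_min) / (params.per_feature_max - params.per_feature_min)


def minmax_invert(params: NormalizationParams, X_normalized: np.ndarray) -> np.ndarray:
    """Undo the normalization: x = x_norm * (max - min) + min."""
    Xn = np.atleast_2d(np.asarray(X_normalized, dtype=float))
    if Xn.shape[1] != params.n_features:
        raise DimensionError(f"X has {Xn.shape[1]} columns, params expect {params.n_features}")
    return Xn * (params.per_feature_max - params.per_feature_min) + params.per_feature_min


def lowpass(X: np.ndarray, kernel: FilterKernel = DEFAULT_KERNEL) -> np.ndarray:
    """Convolve each row (pixel spectrum) with the FIR taps, same-length output.

    Boundaries use edge replication (nearest padding) so normalized kernels
    leave constant spectra untouched end to end.  The kernel origin is its
    centre tap (index ``len(taps) // 2``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if kernel.taps.size > X.shape[1]:
        raise KernelError(f"kernel ({kernel.taps.size} taps) longer than spectrum ({X.shape[1]} bands)")
    return ndimage.convolve1d(X, kernel.taps, axis=1, mode="nearest")
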