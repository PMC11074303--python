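"""EM-based reliability filtering of training pixels.

Corrupted training spectra (e.g. FFPE-fixed tissue standing in for fresh
tissue) form a displaced cluster within each class.  Per class we fit a
two-component isotropic Gaussian mixture in PCA feature space by EM; the
majority component is designated *reliable* and each pixel's reliability
score is the posterior responsibility of that component.  Pixels whose
score exceeds a threshold tau (default 0.8) are kept for training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InsufficientDataError, LabelError

__all__ = ["ClassMixture", "ReliabilityModel", "em_fit", "reliability_scores", "select_reliable"]

DEFAULT_TAU = 0.8
_VAR_FLOOR_FRACTION = 1e-6  # of the class's total variance, guards collapse


@dataclass
class ClassMixture:
    """Two isotropic Gaussian components in k-dim feature space for one class."""

    mean_reliable: np.ndarray
    mean_unreliable: np.ndarray
    var_reliable: float
    var_unreliable: float
    pi_reliable: float
    log_likelihood: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_reliable < 1.0:
            raise ValueError("pi_reliable must lie strictly inside (0, 1)")
        if self.var_reliable <= 0 or self.var_unreliable <= 0:
            raise ValueError("component variances must be positive")


@dataclass
class ReliabilityModel:
    """Per-class mixtures plus the selection threshold tau."""

    mixtures: dict[int, ClassMixture]
    tau: float = DEFAULT_TAU
    n_features: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "tau": self.tau,
                "n_features": self.n_features,
                "mixtures": {
                    str(c): {
                        "mean_reliable": m.mean_reliable.tolist(),
                        "mean_unreliable": m.mean_unreliable.tolist(),
                        "var_reliable": m.var_reliable,
                        "var_unreliable": m.var_unreliable,
                        "pi_reliable": m.pi_reliable,
                        "log_likelihood": m.log_likelihood,
                    }
                    for c, m in self.mixtures.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReliabilityModel":
        d = json.loads(text)
        mixtures = {
            int(c): ClassMixture(
                np.asarray(m["mean_reliable"]),
                np.asarray(m["mean_unreliable"]),
                m["var_reliable"],
                m["var_unreliable"],
                m["pi_reliable"],
                m["log_likelihood"],
            )
            for c, m in d["mixtures"].items()
        }
        return cls(mixtures, d["tau"], d["n_features"])


def _log_iso_gauss(Z: np.ndarray, mean: np.ndarray, var: float) -> np.ndarray:
    k = Z.shape[1]
    sq = np.sum((Z - mean) ** 2, axis=1)
    return -0.5 * (k * np.log(2.0 * np.pi * var) + sq / var)


def _em_one_class(Z: np.ndarray, max_iter: int, tol: float) -> ClassMixture:
    n, k = Z.shape
    total_var = float(np.mean(np.var(Z, axis=0, ddof=0)))
    var_floor = max(_VAR_FLOOR_FRACTION * max(total_var, 1e-12), 1e-12)

    # deterministic init: reliable component at the class median, unreliable at
    # the point farthest from it; majority prior on the reliable component
    med = np.median(Z, axis=0)
    far = Z[np.argmax(np.sum((Z - med) ** 2, axis=1))]
    mu = np.vstack([med, far])
    var = np.array([max(total_var, var_floor)] * 2)
    pi = np.array([0.8, 0.2])

    trace: list[float] = []
    for _ in range(max_iter):
        log_joint = np.stack(
            [np.log(pi[j]) + _log_iso_gauss(Z, mu[j], var[j]) for j in range(2)], axis=1
        )
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])

        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp.T @ Z) / nk[:, None]
        for j in range(2):
            sq = np.sum((Z - mu[j]) ** 2, axis=1)
            var[j] = max(float((resp[:, j] @ sq) / (k * nk[j])), var_floor)
        pi = np.clip(nk / n, 1e-9, 1 - 1e-9)

        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * max(abs(trace[-2]), 1.0):
            break

    reliable = int(np.argmax(pi))  # larger mixing weight -> reliable
    other = 1 - reliable
    return ClassMixture(
        mean_reliable=mu[reliable].copy(),
        mean_unreliable=mu[other].copy(),
        var_reliable=float(var[reliable]),
        var_unreliable=float(var[other]),
        pi_reliable=float(pi[reliable]),
        log_likelihood=trace,
    )


def em_fit(
    Z: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    tau: float = DEFAULT_TAU,
) -> ReliabilityModel:
    """Fit a per-class 2-component isotropic Gaussian mixture by EM.

    ``seed`` is accepted for interface uniformity; initialization is
    deterministic (class median / farthest point) so it is unused.  Every
    class must contribute at least 4 rows.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    mixtures: dict[int, ClassMixture] = {}
    for c in np.unique(labels):
        Zc = Z[labels == c]
        if Zc.shape[0] < 4:
            raise InsufficientDataError(f"class {c} has {Zc.shape[0]} rows; need >= 4 for the mixture fit")
        mixtures[int(c)] = _em_one_class(Zc, max_iter, tol)
    return ReliabilityModel(mixtures, tau=tau, n_features=Z.shape[1])


def reliability_scores(model: ReliabilityModel, Z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Posterior responsibility of each row's class-specific reliable component."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    if Z.shape[1] != model.n_features:
        raise LabelError(f"features have {Z.shape[1]} dims, model fitted on {model.n_features}")
    scores = np.empty(Z.shape[0], dtype=float)
    for c in np.unique(labels):
        if int(c) not in model.mixtures:
            raise LabelError(f"label {c} was not seen at fit time")
        m = model.mixtures[int(c)]
        idx = labels == c
        lr = np.log(m.pi_reliable) + _log_iso_gauss(Z[idx], m.mean_reliable, m.var_reliable)
        lu = np.log1p(-m.pi_reliable) + _log_iso_gauss(Z[idx], m.mean_unreliable, m.var_unreliable)
        scores[idx] = np.exp(lr - logsumexp(np.stack([lr, lu], axis=1), axis=1))
    return scores


def select_reliable(
    scores: np.ndarray, tau: float, labels: np.ndarray | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Indices of rows with score > tau, plus a per-class retention summary.

    An empty selection for some class is a warning recorded in the summary,
    not an error — callers decide whether training can proceed.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    keep = np.flatnonzero(scores > tau)
    if labels is None:
        labels = np.zeros(scores.shape[0], dtype=int)
    labels = np.asarray(labels)
    rows = []
    for c in np.unique(labels):
        idx = labels == c
        n_before = int(idx.sum())
        n_after = int((idx & (scores > tau)).sum())
        rows.append({"class": int(c), "n_before": n_before, "n_after": n_after, "tau": tau})
        if n_before > 0 and n_after == 0:
            warnings.warn(f"reliability selection at tau={tau} removed every row of class {c}", stacklevel=2)
    return keep, pd.DataFrame(rows)
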