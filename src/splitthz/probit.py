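"""Bayesian ordinal probit regression over ordered tissue classes.

Model: a latent index u = beta' z + eps, eps ~ N(0, 1), is cut into C
ordered intervals by cutpoints gamma_1 < ... < gamma_{C-1}; the observed
class is c iff gamma_{c-1} < u <= gamma_c (gamma_0 = -inf, gamma_C =
+inf).  Class probabilities are differences of standard-normal CDFs,

    P(y = c | z) = Phi(gamma_c - beta' z) - Phi(gamma_{c-1} - beta' z).

The class order is fat < muscle < cancer.  The model is deliberately
small: d weights plus C-1 cutpoints (5 free parameters for 3 classes on
3 PCA features).  Fitting is either MAP by gradient descent with a
N(0, 10^2) prior on beta (flat on ordered cutpoints), or full Bayes by a
latent-variable Gibbs sampler (truncated-normal data augmentation,
conjugate normal update for beta, uniform conditional for cutpoints
bounded by the adjacent classes' latent order statistics).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import norm, truncnorm

from .errors import DivergenceError, LabelError, ParameterError
from .phantom import CLASS_CODES

__all__ = [
    "OrdinalProbitParams",
    "PosteriorDraws",
    "class_probs",
    "nll_grad",
    "nll_grad_full",
    "fit_map_centralized",
    "gibbs_fit",
]

_PROB_FLOOR = 1e-300
DEFAULT_PRIOR_SD = 10.0


@dataclass
class OrdinalProbitParams:
    """Weights beta, ordered cutpoints gamma, and the fixed class order (codes)."""

    beta: np.ndarray
    cutpoints: np.ndarray
    class_order: tuple = CLASS_CODES

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.cutpoints = np.asarray(self.cutpoints, dtype=float).ravel()
        if len(self.class_order) != self.cutpoints.size + 1:
            raise ParameterError(
                f"{len(self.class_order)} classes need {len(self.class_order) - 1} cutpoints, got {self.cutpoints.size}"
            )
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ParameterError(f"cutpoints must be strictly increasing, got {self.cutpoints}")

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def n_params(self) -> int:
        return self.beta.size + self.cutpoints.size

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.beta, self.cutpoints])

    def replace_vector(self, vec: np.ndarray) -> "OrdinalProbitParams":
        d = self.beta.size
        return OrdinalProbitParams(vec[:d], vec[d:], self.class_order)

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "cutpoints": self.cutpoints.tolist(),
                "class_order": list(self.class_order),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "OrdinalProbitParams":
        d = json.loads(text)
        return cls(np.asarray(d["beta"]), np.asarray(d["cutpoints"]), tuple(d["class_order"]))


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws, one row per draw: [beta..., cutpoints...]."""

    draws: np.ndarray
    burn_in: int
    seed: int
    n_features: int
    class_order: tuple = CLASS_CODES

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def posterior_mean(self) -> OrdinalProbitParams:
        mean = self.draws.mean(axis=0)
        return OrdinalProbitParams(mean[: self.n_features], mean[self.n_features :], self.class_order)


def _ordinal_index(y: np.ndarray, class_order: tuple) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(class_order)}
    try:
        return np.asarray([lookup[v] for v in np.asarray(y).tolist()], dtype=int)
    except KeyError as exc:
        raise LabelError(f"label {exc.args[0]!r} not in class order {class_order}") from exc


def _bounds(params: OrdinalProbitParams, ci: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper latent cutpoints (gamma_{c-1}, gamma_c) per observation."""
    gamma = np.concatenate([[-np.inf], params.cutpoints, [np.inf]])
    return gamma[ci], gamma[ci + 1]


def class_probs(params: OrdinalProbitParams, z: np.ndarray) -> np.ndarray:
    """Class probability vector(s); accepts a single feature vector or an n x d matrix."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Z = np.atleast_2d(z)
    eta = Z @ params.beta
    gamma = np.concatenate([[-np.inf], params.cutpoints, [np.inf]])
    cdf = norm.cdf(gamma[None, :] - eta[:, None])
    probs = np.diff(cdf, axis=1)
    return probs[0] if single else probs


def _per_obs_pieces(params: OrdinalProbitParams, Z: np.ndarray, ci: np.ndarray):
    eta = Z @ params.beta
    lo, hi = _bounds(params, ci)
    a, b = lo - eta, hi - eta
    p = norm.cdf(b) - norm.cdf(a)
    floored = p < _PROB_FLOOR
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} observation(s) had likelihood below {_PROB_FLOOR}; floored",
            stacklevel=3,
        )
        p = np.maximum(p, _PROB_FLOOR)
    return eta, a, b, p


def nll_grad_full(
    params: OrdinalProbitParams, Z: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL, gradient w.r.t. (beta, cutpoints), and gradient w.r.t. the rows of Z.

    The input gradient is what a split-learning server sends back to the
    client; it never references raw inputs beyond the representations Z.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    ci = _ordinal_index(y, params.class_order)
    _, a, b, p = _per_obs_pieces(params, Z, ci)

    nll = -float(np.sum(np.log(p)))
    phi_a = np.where(np.isfinite(a), norm.pdf(a), 0.0)
    phi_b = np.where(np.isfinite(b), norm.pdf(b), 0.0)
    g_eta = (phi_b - phi_a) / p  # d NLL / d eta_i

    grad_beta = Z.T @ g_eta
    grad_gamma = np.zeros(params.cutpoints.size)
    # cutpoint j is the upper bound where ci == j and the lower bound where ci == j+1
    np.add.at(grad_gamma, ci[ci < params.cutpoints.size], -(phi_b / p)[ci < params.cutpoints.size])
    np.add.at(grad_gamma, ci[ci > 0] - 1, (phi_a / p)[ci > 0])

    grad_Z = g_eta[:, None] * params.beta[None, :]
    return nll, np.concatenate([grad_beta, grad_gamma]), grad_Z


def nll_grad(params: OrdinalProbitParams, Z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient w.r.t. (beta, cutpoints)."""
    nll, grad, _ = nll_grad_full(params, Z, y)
    return nll, grad


def _project_cutpoints(cutpoints: np.ndarray, min_gap: float = 1e-6) -> np.ndarray:
    """Restore strict ordering after a raw gradient step, preserving the mean."""
    if np.all(np.diff(cutpoints) > 0):
        return cutpoints
    fixed = np.sort(cutpoints)
    for j in range(1, fixed.size):
        if fixed[j] - fixed[j - 1] < min_gap:
            fixed[j] = fixed[j - 1] + min_gap
    return fixed


def _init_cutpoints(ci: np.ndarray, n_classes: int) -> np.ndarray:
    """Normal quantiles of the empirical class frequencies (guarded off 0/1)."""
    freq = np.bincount(ci, minlength=n_classes) / ci.size
    cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
    return _project_cutpoints(norm.ppf(cum))


def fit_map_centralized(
    Z: np.ndarray,
    y: np.ndarray,
    learning_rate: float = 1e-4,
    max_iter: int = 2000,
    tol: float = 1e-10,
    seed: int = 0,
    prior_sd: float = DEFAULT_PRIOR_SD,
    class_order: tuple = CLASS_CODES,
) -> tuple[OrdinalProbitParams, list[float]]:
    """MAP fit by gradient descent on NLL + ||beta||^2 / (2 prior_sd^2).

    Initialization is deterministic (beta = 0, cutpoints at normal
    quantiles of the class frequencies); ``seed`` is accepted for
    interface uniformity.  Stops when the relative loss change drops
    below ``tol``; a loss above 1e10 raises :class:`DivergenceError`.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    ci = _ordinal_index(y, class_order)
    if np.unique(ci).size < 2:
        raise LabelError("need at least 2 distinct classes to fit")
    params = OrdinalProbitParams(np.zeros(Z.shape[1]), _init_cutpoints(ci, len(class_order)), class_order)

    d = Z.shape[1]
    trace: list[float] = []
    for _ in range(max_iter):
        nll, grad = nll_grad(params, Z, y)
        loss = nll + float(np.sum(params.beta**2)) / (2.0 * prior_sd**2)
        grad = grad.copy()
        grad[:d] += params.beta / prior_sd**2
        if not np.isfinite(loss) or loss > 1e10:
            raise DivergenceError(
                f"loss diverged to {loss:.3g}; try a smaller learning rate than {learning_rate}"
            )
        trace.append(loss)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * max(abs(trace[-2]), 1.0):
            break
        vec = params.as_vector() - learning_rate * grad
        params = OrdinalProbitParams(vec[:d], _project_cutpoints(vec[d:]), class_order)
    return params, trace


def gibbs_fit(
    Z: np.ndarray,
    y: np.ndarray,
    n_draws: int = 1500,
    burn_in: int = 500,
    seed: int = 0,
    prior_sd: float = DEFAULT_PRIOR_SD,
    class_order: tuple = CLASS_CODES,
) -> PosteriorDraws:
    """Latent-variable Gibbs sampler (data augmentation) for the ordinal probit.

    Per sweep: latents u_i ~ N(beta' z_i, 1) truncated to their class
    interval; beta from its conjugate normal conditional under the
    N(0, prior_sd^2 I) prior; each cutpoint uniform between the largest
    latent of the class below and the smallest latent of the class above.
    Requires every class in ``class_order`` to be present (the cutpoint
    conditionals are bounded by adjacent-class order statistics).
    """
    if n_draws <= burn_in:
        raise ValueError(f"n_draws ({n_draws}) must exceed burn_in ({burn_in})")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    ci = _ordinal_index(y, class_order)
    n_classes = len(class_order)
    if np.unique(ci).size < n_classes:
        raise LabelError("Gibbs sampler needs every class present to bound the cutpoints")

    rng = np.random.default_rng(seed)
    d = Z.shape[1]
    beta = np.zeros(d)
    cutpoints = _init_cutpoints(ci, n_classes)

    prec = Z.T @ Z + np.eye(d) / prior_sd**2
    chol_prec = linalg.cho_factor(prec)
    cov = linalg.cho_solve(chol_prec, np.eye(d))
    cov_chol = linalg.cholesky(cov, lower=True)

    class_masks = [ci == c for c in range(n_classes)]
    draws = np.empty((n_draws, d + n_classes - 1))
    for s in range(n_draws):
        eta = Z @ beta
        gamma = np.concatenate([[-np.inf], cutpoints, [np.inf]])
        a, b = gamma[ci] - eta, gamma[ci + 1] - eta
        u = truncnorm.rvs(a, b, loc=eta, scale=1.0, random_state=rng)

        mean = linalg.cho_solve(chol_prec, Z.T @ u)
        beta = mean + cov_chol @ rng.standard_normal(d)

        for j in range(n_classes - 1):
            lo = float(u[class_masks[j]].max())
            hi = float(u[class_masks[j + 1]].min())
            if j > 0:
                lo = max(lo, cutpoints[j - 1])
            if hi <= lo:  # numerically degenerate interval; keep previous value
                continue
            cutpoints[j] = rng.uniform(lo, hi)

        draws[s, :d] = beta
        draws[s, d:] = cutpoints
    return PosteriorDraws(draws[burn_in:], burn_in, seed, d, class_order)
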