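"""Client/server split learning for the hyperspectral classifier.

A client-side feature map F_c(X; theta_c) — a single linear (optionally
tanh) layer — produces representations X^t ("smashed data") which travel
to the server; the server-side head F_s(X^t; theta_s), an ordinal probit,
computes predictions and the loss L and returns only the gradient of L
with respect to the representations.  Both halves take gradient steps

    theta_s <- theta_s - alpha * dL/d theta_s
    theta_c <- theta_c - alpha * (chain-rule pullback of dL/dX^t)

computed from the same round's forward pass (server first).  Because the
exchange is exactly the chain rule, single-client full-batch training is
algebraically identical to joint gradient descent on the composed model —
a property the tests exploit as an oracle.  Raw feature rows never cross
the boundary; :func:`audit_transcript` verifies this on the recorded
protocol transcript.  Labels do travel to the server (label-sharing
variant): the confidentiality claim audited here is for the raw spectra.

Multi-client mode is sequential round-robin with hand-off of theta_c,
the classic split-learning schedule, over a disjoint row partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import probit
from .errors import ConfigError, DimensionError, PrivacyViolationError
from .phantom import CLASS_CODES
from .probit import OrdinalProbitParams

__all__ = [
    "ClientModel",
    "ServerModel",
    "TrainConfig",
    "SplitSession",
    "client_forward",
    "server_step",
    "split_round",
    "train_split",
    "audit_transcript",
]


@dataclass
class ClientModel:
    """Client half: X^t = activation(X W^T + b), with identity or tanh activation."""

    weights: np.ndarray  # d_out x m
    bias: np.ndarray  # d_out
    activation: str = "identity"

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.bias = np.asarray(self.bias, dtype=float).ravel()
        if self.activation not in ("identity", "tanh"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        if self.bias.shape[0] != self.weights.shape[0]:
            raise DimensionError("bias length must equal the number of output units")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ConfigError("client parameters must be finite")

    @property
    def d_out(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {"weights": self.weights.tolist(), "bias": self.bias.tolist(), "activation": self.activation}
        )

    @classmethod
    def from_json(cls, text: str) -> "ClientModel":
        d = json.loads(text)
        return cls(np.asarray(d["weights"]), np.asarray(d["bias"]), d["activation"])


@dataclass
class ServerModel:
    """Server half: the ordinal probit head over the client representations."""

    params: OrdinalProbitParams

    def to_json(self) -> str:
        return self.params.to_json()

    @classmethod
    def from_json(cls, text: str) -> "ServerModel":
        return cls(OrdinalProbitParams.from_json(text))


@dataclass
class TrainConfig:
    """Knobs of the split training loop."""

    learning_rate: float = 1e-3
    max_rounds: int = 500
    tol: float = 1e-6
    seed: int = 0
    d_out: int = 3
    activation: str = "identity"
    mode: str = "single"  # single | round_robin
    n_clients: int = 1
    client_partition: list | None = None  # explicit row-index arrays, optional
    class_order: tuple = CLASS_CODES

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.tol <= 0:
            raise ConfigError("learning_rate and tol must be positive")
        if self.mode not in ("single", "round_robin"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "single":
            self.n_clients = 1


@dataclass
class TranscriptEntry:
    """One payload crossing the client/server boundary."""

    round_index: int
    client: int
    direction: str  # 'client->server' | 'server->client'
    kind: str  # 'representations' | 'labels' | 'grad_representations' | 'loss'
    payload: np.ndarray

    @property
    def n_bytes(self) -> int:
        return int(np.asarray(self.payload).nbytes)


@dataclass
class SplitSession:
    """Round log plus the full boundary transcript of a training run."""

    round_log: list[dict] = field(default_factory=list)
    transcript: list[TranscriptEntry] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len({e["round"] for e in self.round_log})

    def log_jsonl(self) -> str:
        return "\n".join(json.dumps(e) for e in self.round_log)


def client_forward(client: ClientModel, X: np.ndarray) -> np.ndarray:
    """Compute the representations X^t = activation(X W^T + b)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != client.n_inputs:
        raise DimensionError(f"X has {X.shape[1]} columns, client expects {client.n_inputs}")
    pre = X @ client.weights.T + client.bias
    return np.tanh(pre) if client.activation == "tanh" else pre


def server_step(
    server: ServerModel, Xt: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Server forward/backward: predictions, loss, parameter grads, representation grads."""
    probs = probit.class_probs(server.params, Xt)
    loss, grad_theta_s, grad_Xt = probit.nll_grad_full(server.params, Xt, y)
    return probs, loss, grad_theta_s, grad_Xt


def _client_backward(client: ClientModel, X: np.ndarray, Xt: np.ndarray, grad_Xt: np.ndarray):
    """Chain-rule pullback of the representation gradient onto (W, b)."""
    d_pre = grad_Xt * (1.0 - Xt**2) if client.activation == "tanh" else grad_Xt
    return d_pre.T @ X, d_pre.sum(axis=0)


def split_round(
    client: ClientModel,
    server: ServerModel,
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    round_index: int = 0,
    client_index: int = 0,
    session: SplitSession | None = None,
) -> tuple[ClientModel, ServerModel, dict]:
    """One communication round: forward up, gradients down, both halves step.

    Updates use the gradients of the same round's loss; the server applies
    its step first but both gradients were computed at the pre-update
    parameters, so the round equals one simultaneous joint GD step.
    """
    if alpha < 0:
        raise ConfigError("learning rate must be nonnegative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xt = client_forward(client, X)

    # client -> server: smashed data + labels (label-sharing variant)
    if session is not None:
        session.transcript.append(TranscriptEntry(round_index, client_index, "client->server", "representations", Xt.copy()))
        session.transcript.append(TranscriptEntry(round_index, client_index, "client->server", "labels", np.asarray(y).copy()))

    _, loss, grad_theta_s, grad_Xt = server_step(server, Xt, y)
    if not (np.isfinite(loss) and np.all(np.isfinite(grad_theta_s)) and np.all(np.isfinite(grad_Xt))):
        raise FloatingPointError(f"non-finite gradients at round {round_index}")

    # server -> client: loss scalar + gradient w.r.t. representations
    if session is not None:
        session.transcript.append(TranscriptEntry(round_index, client_index, "server->client", "loss", np.asarray([loss])))
        session.transcript.append(TranscriptEntry(round_index, client_index, "server->client", "grad_representations", grad_Xt.copy()))

    d = server.params.beta.size
    vec = server.params.as_vector() - alpha * grad_theta_s
    new_server = ServerModel(
        OrdinalProbitParams(vec[:d], probit._project_cutpoints(vec[d:]), server.params.class_order)
    )

    grad_W, grad_b = _client_backward(client, X, Xt, grad_Xt)
    new_client = ClientModel(client.weights - alpha * grad_W, client.bias - alpha * grad_b, client.activation)

    record = {
        "round": round_index,
        "client": client_index,
        "loss": float(loss),
        "grad_norm_server": float(np.linalg.norm(grad_theta_s)),
        "grad_norm_client": float(np.linalg.norm(grad_W)),
    }
    if session is not None:
        session.round_log.append(record)
    return new_client, new_server, record


def _full_loss(client: ClientModel, server: ServerModel, X: np.ndarray, y: np.ndarray) -> float:
    Xt = client_forward(client, X)
    loss, _, _ = probit.nll_grad_full(server.params, Xt, y)
    return loss


def _accuracy(client: ClientModel, server: ServerModel, X: np.ndarray, y: np.ndarray, class_order) -> float:
    probs = probit.class_probs(server.params, client_forward(client, X))
    pred = np.asarray(class_order)[np.argmax(probs, axis=1)]
    return float(np.mean(pred == np.asarray(y)))


def init_models(n_features: int, config: TrainConfig) -> tuple[ClientModel, ServerModel]:
    """Seeded initialization: client weights ~ N(0, 0.01), probit head at zero."""
    rng = np.random.default_rng(config.seed)
    client = ClientModel(
        0.01 * rng.standard_normal((config.d_out, n_features)),
        np.zeros(config.d_out),
        config.activation,
    )
    n_cut = len(config.class_order) - 1
    server = ServerModel(
        OrdinalProbitParams(np.zeros(config.d_out), np.linspace(-0.5, 0.5, n_cut), config.class_order)
    )
    return client, server


def _partition_rows(n: int, config: TrainConfig) -> list[np.ndarray]:
    if config.client_partition is not None:
        parts = [np.asarray(p, dtype=int) for p in config.client_partition]
        flat = np.concatenate(parts) if parts else np.array([], dtype=int)
        if len(parts) == 0 or any(p.size == 0 for p in parts):
            raise ConfigError("every client partition must be non-empty")
        if np.sort(flat).tolist() != list(range(n)):
            raise ConfigError("client partition must cover all rows disjointly")
        return parts
    if config.n_clients < 1 or config.n_clients > n:
        raise ConfigError(f"cannot split {n} rows over {config.n_clients} clients")
    rng = np.random.default_rng(config.seed + 1)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, config.n_clients)]


def train_split(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[ClientModel, ServerModel, SplitSession]:
    """Run the split training loop to convergence or ``max_rounds``.

    Convergence is a relative change in the full-data loss below
    ``config.tol``.  When a validation set is supplied, per-round
    validation loss and accuracy are appended to the round log (computed
    outside the protocol; they do not enter the transcript).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ConfigError("training set is empty")
    client, server = init_models(X.shape[1], config)
    parts = [np.arange(X.shape[0])] if config.mode == "single" else _partition_rows(X.shape[0], config)

    session = SplitSession()
    prev_loss = _full_loss(client, server, X, y)
    for r in range(1, config.max_rounds + 1):
        round_records = []
        for ci_idx, rows in enumerate(parts):
            client, server, rec = split_round(
                client, server, X[rows], y[rows], config.learning_rate, r, ci_idx, session
            )
            round_records.append(rec)
        full = _full_loss(client, server, X, y)
        extra = {"full_loss": full, "train_acc": _accuracy(client, server, X, y, config.class_order)}
        if X_val is not None and y_val is not None:
            extra["val_loss"] = _full_loss(client, server, X_val, y_val)
            extra["val_acc"] = _accuracy(client, server, X_val, y_val, config.class_order)
        for rec in round_records:
            rec.update(extra)
        if abs(prev_loss - full) < config.tol * max(abs(prev_loss), 1.0):
            break
        prev_loss = full
    return client, server, session


def audit_transcript(session: SplitSession, X_raw: np.ndarray) -> dict:
    """Verify no transcript payload contains a raw feature row; summarize traffic.

    Checks every 2-D payload wide enough to hold a raw row for exact
    (bitwise float) equality with any row of ``X_raw``, including as a
    contiguous horizontal sub-block.  Raises
    :class:`PrivacyViolationError` naming the round on a hit.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    m = X_raw.shape[1]
    raw_rows = {row.tobytes() for row in X_raw}

    kinds: dict[str, int] = {}
    bytes_per_round: dict[int, int] = {}
    for entry in session.transcript:
        kinds[entry.kind] = kinds.get(entry.kind, 0) + 1
        bytes_per_round[entry.round_index] = bytes_per_round.get(entry.round_index, 0) + entry.n_bytes
        payload = np.atleast_2d(np.asarray(entry.payload, dtype=float))
        if payload.shape[1] < m:
            continue
        for prow in payload:
            for off in range(payload.shape[1] - m + 1):
                if prow[off : off + m].tobytes() in raw_rows:
                    raise PrivacyViolationError(
                        f"transcript payload ({entry.kind}) at round {entry.round_index} "
                        "contains a raw feature row",
                        round_index=entry.round_index,
                    )
    return {
        "n_rounds": len(bytes_per_round),
        "payload_counts": kinds,
        "bytes_per_round": bytes_per_round,
        "total_bytes": int(sum(bytes_per_round.values())),
        "violations": 0,
    }
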