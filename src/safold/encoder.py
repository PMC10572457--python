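"""Rotation-aware encoder-decoder over structure graphs.

The encoder is a small GVP-style message-passing network implemented in
NumPy.  Node state is split into scalar channels (rotation-invariant) and
3-vector channels (rotation-equivariant); messages combine neighbour scalars,
edge features, vector norms and vector/edge-direction inner products — all
invariants — while vector channels are updated only by channel mixing,
invariant gating and scaled edge directions, so equivariance holds by
construction rather than by training.

The trunk weights are drawn once from the model seed and kept frozen (a
random-features design); the decoder heads — a 23-way structural-alphabet
classifier over 5-residue windows and an 8-way secondary-structure classifier
per residue — are trained by negative log-likelihood with Adam and early
stopping on validation accuracy.  Per-residue embeddings (the scalar channels
of the trunk output) feed the localization step of the search pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .alphabet import GAP, LETTERS, SARecord
from .featurize import FeaturizeConfig, StructureGraph, build_knn_graph
from .fixtures import SS_ALPHABET
from .pdb_io import Chain

__all__ = [
    "ModelConfig",
    "Model",
    "Predictions",
    "init_model",
    "encode",
    "decode",
    "train",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters (all seed-deterministic)."""

    scalar_dim: int = 64  # embedding width d
    vector_dim: int = 16
    n_layers: int = 2
    hidden_dim: int = 64
    edge_dim: int = 32  # rbf_centers + pe_dims of the featurizer
    node_scalar_dim: int = 25
    node_vector_dim: int = 5
    n_letters: int = 23
    n_ss: int = len(SS_ALPHABET)
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 60
    patience: int = 5
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scalar_dim", "vector_dim", "n_layers", "hidden_dim",
                     "edge_dim", "batch_size", "max_epochs", "n_letters", "n_ss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class Predictions:
    """Per-window SA logits ((L-4) x 23) and per-residue SS logits (L x 8)."""

    sa_logits: np.ndarray
    ss_logits: np.ndarray

    @property
    def sa_probs(self) -> np.ndarray:
        return _softmax(self.sa_logits)

    @property
    def ss_probs(self) -> np.ndarray:
        return _softmax(self.ss_logits)

    def sa_string(self, letters: str = LETTERS) -> str:
        if self.sa_logits.shape[0] == 0:
            return ""
        return "".join(letters[i] for i in self.sa_logits.argmax(axis=1))

    def ss_string(self) -> str:
        return "".join(SS_ALPHABET[i] for i in self.ss_logits.argmax(axis=1))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Model:
    """Frozen equivariant trunk + trainable classifier heads."""

    def __init__(self, config: ModelConfig, featurize_config: FeaturizeConfig | None = None):
        self.config = config
        self.featurize_config = featurize_config or FeaturizeConfig()
        expected_edge = self.featurize_config.rbf_centers + self.featurize_config.pe_dims
        if config.edge_dim != expected_edge:
            raise ValueError(
                f"edge_dim={config.edge_dim} does not match featurizer ({expected_edge})"
            )
        rng = np.random.default_rng(config.seed)
        S, V, E = config.scalar_dim, config.vector_dim, config.edge_dim
        ds, dv, H = config.node_scalar_dim, config.node_vector_dim, config.hidden_dim

        def g(*shape):
            fan = shape[0]
            return rng.normal(scale=1.0 / np.sqrt(fan), size=shape)

        self.trunk = {"W_s0": g(ds, S), "b_s0": np.zeros(S), "W_v0": g(dv, V)}
        msg_in = S + E + 2 * V
        for l in range(config.n_layers):
            self.trunk.update({
                f"W_msg{l}": g(msg_in, S), f"b_msg{l}": np.zeros(S),
                f"W_upd{l}": g(S, S), f"b_upd{l}": np.zeros(S),
                f"W_vmix{l}": g(V, V), f"W_edir{l}": g(S, V),
                f"W_vself{l}": g(V, V),
                f"W_gate{l}": g(S, V), f"b_gate{l}": np.zeros(V),
            })
        # heads: final layers start at zero so an untrained model predicts the
        # uniform distribution exactly
        self.heads = {
            "sa_W1": g(5 * S, H), "sa_b1": np.zeros(H),
            "sa_W2": np.zeros((H, config.n_letters)), "sa_b2": np.zeros(config.n_letters),
            "ss_W1": g(S, H), "ss_b1": np.zeros(H),
            "ss_W2": np.zeros((H, config.n_ss)), "ss_b2": np.zeros(config.n_ss),
        }

    # -- trunk ------------------------------------------------------------

    def forward_trunk(self, graph: StructureGraph) -> tuple[np.ndarray, np.ndarray]:
        """Return (scalar channels (L, S), vector channels (L, V, 3))."""
        cfg = self.config
        t = self.trunk
        L = graph.length
        k = graph.edges.shape[0] // L

        h = np.tanh(graph.node_scalars @ t["W_s0"] + t["b_s0"])
        Vm = graph.node_vectors * graph.node_vector_mask[..., None]
        U = np.einsum("lvi,vc->lci", Vm, t["W_v0"])

        dst = graph.edges[:, 1]
        e_vec = graph.edge_vectors
        e_sca = graph.edge_scalars
        for l in range(cfg.n_layers):
            Uj = U[dst]
            norms = np.linalg.norm(Uj, axis=2)
            dots = np.einsum("eci,ei->ec", Uj, e_vec)
            msg_in = np.concatenate([h[dst], e_sca, norms, dots], axis=1)
            m = np.tanh(msg_in @ t[f"W_msg{l}"] + t[f"b_msg{l}"])
            agg = m.reshape(L, k, -1).mean(axis=1)
            h = np.tanh(h + agg @ t[f"W_upd{l}"] + t[f"b_upd{l}"])

            mv = np.einsum("eci,cd->edi", Uj, t[f"W_vmix{l}"])
            mv = mv + (m @ t[f"W_edir{l}"])[..., None] * e_vec[:, None, :]
            aggv = mv.reshape(L, k, cfg.vector_dim, 3).mean(axis=1)
            U = U + np.einsum("lci,cd->ldi", aggv, t[f"W_vself{l}"])
            gate = 1.0 / (1.0 + np.exp(-(h @ t[f"W_gate{l}"] + t[f"b_gate{l}"])))
            U = U * gate[..., None]
        return h, U

    # -- heads ------------------------------------------------------------

    def _sa_inputs(self, h: np.ndarray) -> np.ndarray:
        L, S = h.shape
        if L < 5:
            return np.zeros((0, 5 * S))
        return np.stack([h[i : i + 5].reshape(-1) for i in range(L - 4)])

    def head_logits(self, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.heads
        xs = self._sa_inputs(h)
        sa = np.maximum(xs @ p["sa_W1"] + p["sa_b1"], 0.0) @ p["sa_W2"] + p["sa_b2"]
        ss = np.maximum(h @ p["ss_W1"] + p["ss_b1"], 0.0) @ p["ss_W2"] + p["ss_b2"]
        return sa, ss


def init_model(
    config: ModelConfig | None = None, featurize_config: FeaturizeConfig | None = None
) -> Model:
    """Deterministically initialise a model from its config seed."""
    return Model(config or ModelConfig(), featurize_config)


def encode(model: Model, graph: StructureGraph) -> np.ndarray:
    """Per-residue embedding matrix (L x scalar_dim), rotation-invariant."""
    h, _ = model.forward_trunk(graph)
    return h


def decode(model: Model, graph: StructureGraph) -> Predictions:
    """SA-letter and secondary-structure logits for a graph."""
    h, _ = model.forward_trunk(graph)
    sa, ss = model.head_logits(h)
    return Predictions(sa_logits=sa, ss_logits=ss)


# ---------------------------------------------------------------------------
# training


def _head_forward_backward(X, y, W1, b1, W2, b2, want_grad=True, drop_mask=None):
    """Two-layer ReLU softmax classifier: mean NLL + gradients."""
    z1 = X @ W1 + b1
    a1 = np.maximum(z1, 0.0)
    if drop_mask is not None:
        a1 = a1 * drop_mask
    logits = a1 @ W2 + b2
    p = _softmax(logits)
    n = X.shape[0]
    nll = float(-np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean())
    if not want_grad:
        return nll, None
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    d /= n
    gW2 = a1.T @ d
    gb2 = d.sum(axis=0)
    da1 = d @ W2.T
    if drop_mask is not None:
        da1 = da1 * drop_mask
    dz1 = da1 * (z1 > 0)
    gW1 = X.T @ dz1
    gb1 = dz1.sum(axis=0)
    return nll, {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, gr in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gr
            self.v[k] = b2 * self.v[k] + (1 - b2) * gr**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _prepare(model: Model, labelled: list[tuple[Chain, SARecord]]):
    """Precompute trunk embeddings and targets for every labelled chain
    (the trunk is frozen, so this is done once)."""
    data = []
    for chain, record in labelled:
        graph = build_knn_graph(chain, model.featurize_config)
        h, _ = model.forward_trunk(graph)
        X_sa = model._sa_inputs(h)
        y_sa = np.array(
            [LETTERS.index(c) if c != GAP else -1 for c in record.sa_seq], dtype=int
        )
        keep = y_sa >= 0
        ss = record.ss_seq or (chain.ss or "")
        if len(ss) != len(chain):
            raise ValueError(f"chain {record.id}: missing or mismatched SS labels")
        y_ss = np.array([SS_ALPHABET.index(c) for c in ss], dtype=int)
        data.append((X_sa[keep], y_sa[keep], h, y_ss))
    return data


def _evaluate(model: Model, data) -> tuple[float, float, float]:
    """(mean NLL, SA accuracy, SS accuracy) over a prepared dataset."""
    p = model.heads
    losses, sa_hit, sa_n, ss_hit, ss_n = [], 0, 0, 0, 0
    for X_sa, y_sa, h, y_ss in data:
        total = 0.0
        if len(y_sa):
            nll, _ = _head_forward_backward(
                X_sa, y_sa, p["sa_W1"], p["sa_b1"], p["sa_W2"], p["sa_b2"], want_grad=False
            )
            total += nll
            pred = (np.maximum(X_sa @ p["sa_W1"] + p["sa_b1"], 0) @ p["sa_W2"] + p["sa_b2"]).argmax(1)
            sa_hit += int((pred == y_sa).sum())
            sa_n += len(y_sa)
        nll, _ = _head_forward_backward(
            h, y_ss, p["ss_W1"], p["ss_b1"], p["ss_W2"], p["ss_b2"], want_grad=False
        )
        total += nll
        pred = (np.maximum(h @ p["ss_W1"] + p["ss_b1"], 0) @ p["ss_W2"] + p["ss_b2"]).argmax(1)
        ss_hit += int((pred == y_ss).sum())
        ss_n += len(y_ss)
        losses.append(total)
    return (
        float(np.mean(losses)),
        sa_hit / sa_n if sa_n else 0.0,
        ss_hit / ss_n if ss_n else 0.0,
    )


def train(
    model: Model,
    labelled: list[tuple[Chain, SARecord]],
    config: ModelConfig | None = None,
) -> tuple[Model, list[dict]]:
    """Train the decoder heads on geometric-oracle labels.

    Loss is the sum of the mean window NLL (SA head) and the mean residue NLL
    (SS head), equally weighted.  Training stops early when the validation
    accuracy (mean of SA and SS accuracy) has not improved by more than 1e-4
    for more than ``patience`` epochs; the best-validation parameters are
    restored.  Fully deterministic given the config seed.
    """
    cfg = config or model.config
    if not labelled:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(labelled))
    n_val = max(1, int(round(cfg.validation_fraction * len(labelled)))) if len(labelled) > 1 else 0
    val_idx = set(order[:n_val].tolist())
    train_data = _prepare(model, [labelled[i] for i in range(len(labelled)) if i not in val_idx])
    val_data = _prepare(model, [labelled[i] for i in sorted(val_idx)]) if n_val else None

    opt = _Adam(model.heads, cfg.learning_rate)
    history: list[dict] = []
    init_loss, _, _ = _evaluate(model, train_data)
    best_acc = -np.inf
    best_params = {k: v.copy() for k, v in model.heads.items()}
    stale = 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(train_data))
        for start in range(0, len(perm), cfg.batch_size):
            batch = [train_data[i] for i in perm[start : start + cfg.batch_size]]
            X_sa = np.concatenate([b[0] for b in batch])
            y_sa = np.concatenate([b[1] for b in batch])
            X_ss = np.concatenate([b[2] for b in batch])
            y_ss = np.concatenate([b[3] for b in batch])
            p = model.heads
            grads: dict[str, np.ndarray] = {}
            if len(y_sa):
                dm = None
                if cfg.dropout > 0:
                    dm = (rng.random((len(y_sa), cfg.hidden_dim)) >= cfg.dropout) / (1 - cfg.dropout)
                _, g = _head_forward_backward(
                    X_sa, y_sa, p["sa_W1"], p["sa_b1"], p["sa_W2"], p["sa_b2"], drop_mask=dm
                )
                grads.update({f"sa_{k}": v for k, v in g.items()})
            dm = None
            if cfg.dropout > 0:
                dm = (rng.random((len(y_ss), cfg.hidden_dim)) >= cfg.dropout) / (1 - cfg.dropout)
            _, g = _head_forward_backward(
                X_ss, y_ss, p["ss_W1"], p["ss_b1"], p["ss_W2"], p["ss_b2"], drop_mask=dm
            )
            grads.update({f"ss_{k}": v for k, v in g.items()})
            opt.step(model.heads, grads)

        train_loss, train_sa, train_ss = _evaluate(model, train_data)
        if val_data:
            val_loss, val_sa, val_ss = _evaluate(model, val_data)
        else:
            val_loss, val_sa, val_ss = train_loss, train_sa, train_ss
        val_acc = (val_sa + val_ss) / 2.0
        history.append({
            "epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
            "val_acc_sa": val_sa, "val_acc_ss": val_ss, "val_acc": val_acc,
            "init_loss": init_loss,
        })
        if val_acc > best_acc + 1e-4:
            best_acc = val_acc
            best_params = {k: v.copy() for k, v in model.heads.items()}
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break

    model.heads = best_params
    return model, history


# ---------------------------------------------------------------------------
# checkpointing: versioned JSON header + parameter blob in a single .npz


def save_model(model: Model, path: str) -> None:
    header = json.dumps({
        "format": "safold-model",
        "version": 1,
        "config": asdict(model.config),
        "featurize": asdict(model.featurize_config),
    })
    arrays = {f"trunk/{k}": v for k, v in model.trunk.items()}
    arrays.update({f"heads/{k}": v for k, v in model.heads.items()})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> Model:
    blob = np.load(path)
    header = json.loads(bytes(blob["__header__"]).decode())
    if header.get("format") != "safold-model":
        raise ValueError(f"{path!r} is not a safold model checkpoint")
    model = Model(ModelConfig(**header["config"]), FeaturizeConfig(**header["featurize"]))
    for k in model.trunk:
        model.trunk[k] = blob[f"trunk/{k}"]
    for k in model.heads:
        model.heads[k] = blob[f"heads/{k}"]
    return model
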