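"""The forward model and its losses.

Architecture: encoded sequence (L x 25) -> two stacked bidirectional LSTM
layers (concatenated width 180) -> multi-head self-attention
A = softmax(Ws2 tanh(Ws1 H^T)) with the softmax over unmasked positions
-> embedding M = A H -> flatten (41 x 180 = 7380) -> dense 80 logits ->
sigmoid -> 8 x 10 score matrix -> per-column max gives the 10 organelle
scores.

Three losses are provided. For fully annotated samples the loss is binary
cross-entropy averaged over the 80 matrix cells (Lost1) plus binary
cross-entropy averaged over the 10 organelle scores taken after max-pooling
(Lost2). For organelle-only samples only Lost2 applies. Both add an
attention-orthogonality penalty ||A A^T - I||_F^2 scaled by a regularizer
weight, which pushes the heads to attend to different sequence parts. A
single-label variant uses categorical cross-entropy over 10 logits.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import Adam, Tensor

__all__ = [
    "ModelConfig",
    "Model",
    "ScoreMatrix",
    "forward",
    "attention_penalty",
    "loss_lv2",
    "loss_lv1",
    "loss_variant",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the full-scale configuration."""

    n_organelles: int = 10
    n_slots: int = 8
    encode_length: int = 1000
    feature_dim: int = 25
    lstm_layers: int = 2
    hidden_total: int = 180  # concatenated bidirectional width (2u)
    heads: int = 41
    attn_inner: int = 369  # d_a, rows of Ws1
    attention_reg_weight: float = 1e-3
    dropout_lstm: float = 0.1
    dropout_dense: float = 0.1
    lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    @property
    def dense_out(self) -> int:
        return self.n_slots * self.n_organelles

    @property
    def flatten_length(self) -> int:
        return self.hidden_total * self.heads

    def __post_init__(self):
        if self.hidden_total % 2:
            raise ValueError("hidden_total must be even (two LSTM directions)")


@dataclass
class ScoreMatrix:
    """Per-protein prediction: suborganelle cell scores and organelle scores."""

    sub_scores: np.ndarray  # (n_slots, n_organelles), in (0, 1)
    org_scores: np.ndarray  # (n_organelles,), column maxima of sub_scores

    @classmethod
    def from_sub(cls, sub_scores: np.ndarray) -> "ScoreMatrix":
        sub = np.asarray(sub_scores, dtype=float)
        return cls(sub_scores=sub, org_scores=sub.max(axis=0))


class Model:
    """Parameter container + forward pass for one sub-model."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.history: list = []  # (phase, epoch, mean loss) tuples from training
        rng = np.random.default_rng(cfg.seed)
        u = cfg.hidden_total // 2
        self.params: dict = {}

        def par(name, shape, scale):
            t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
            self.params[name] = t
            return t

        d_in = cfg.feature_dim
        for layer in range(cfg.lstm_layers):
            for direction in ("f", "b"):
                k = f"l{layer}{direction}"
                par(f"Wx_{k}", (d_in, 4 * u), 1.0 / np.sqrt(d_in))
                par(f"Wh_{k}", (u, 4 * u), 1.0 / np.sqrt(u))
                b = par(f"b_{k}", (4 * u,), 0.0)
                b.value[u : 2 * u] = 1.0  # forget-gate bias
            d_in = cfg.hidden_total
        par("Ws1", (cfg.attn_inner, cfg.hidden_total), 1.0 / np.sqrt(cfg.hidden_total))
        par("Ws2", (cfg.heads, cfg.attn_inner), 1.0 / np.sqrt(cfg.attn_inner))
        par("Wd", (cfg.flatten_length, cfg.dense_out), 1.0 / np.sqrt(cfg.flatten_length))
        par("bd", (cfg.dense_out,), 0.0)

    def parameters(self) -> list:
        return list(self.params.values())

    def forward_graph(self, x: np.ndarray, mask: np.ndarray, train=False, rng=None):
        """Differentiable forward pass on a batch.

        x: (B, L, 25), mask: (B, L). Returns a dict of graph Tensors:
        H (B, L, hidden), A (B, heads, L), M (B, heads, hidden),
        sub (B, n_slots, n_org) post-sigmoid, org (B, n_org).
        """
        cfg = self.cfg
        if not mask.any(axis=1).all():
            raise ValueError("all-masked input sequence")
        drop_rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        h = Tensor(x)
        for layer in range(cfg.lstm_layers):
            fw = h.lstm(
                self.params[f"Wx_l{layer}f"],
                self.params[f"Wh_l{layer}f"],
                self.params[f"b_l{layer}f"],
                mask,
            )
            bw = (
                h.flip_time()
                .lstm(
                    self.params[f"Wx_l{layer}b"],
                    self.params[f"Wh_l{layer}b"],
                    self.params[f"b_l{layer}b"],
                    mask[:, ::-1],
                )
                .flip_time()
            )
            h = fw.concat_last(bw)
            if train and cfg.dropout_lstm > 0:
                h = h.dropout(cfg.dropout_lstm, drop_rng)
        H = h  # (B, L, hidden_total); masked rows are zero by construction

        s = H.linear(self.params["Ws1"].swap()).tanh()  # (B, L, d_a)
        logits = s.linear(self.params["Ws2"].swap()).swap()  # (B, heads, L)
        A = logits.masked_softmax(mask[:, None, :])
        M = A.bmm(H)  # (B, heads, hidden_total)
        flat = M.reshape(M.shape[0], cfg.flatten_length)
        if train and cfg.dropout_dense > 0:
            flat = flat.dropout(cfg.dropout_dense, drop_rng)
        dense = flat.linear(self.params["Wd"], self.params["bd"])
        sub = dense.sigmoid().reshape(-1, cfg.n_slots, cfg.n_organelles)
        org = sub.max(axis=1)
        return {"H": H, "A": A, "M": M, "logits": dense, "sub": sub, "org": org}

    def predict(self, x: np.ndarray, mask: np.ndarray):
        """Inference on a batch: (ScoreMatrix list, attention (B, heads, L))."""
        out = self.forward_graph(x, mask, train=False)
        subs = out["sub"].value
        return [ScoreMatrix.from_sub(s) for s in subs], out["A"].value

    def make_optimizer(self) -> Adam:
        return Adam(self.parameters(), lr=self.cfg.lr)


def forward(x, cfg_or_model, params=None):
    """Run the forward model on a single encoded protein.

    Accepts an EncodedProtein (or a (features, mask) pair) and a Model, or a
    ModelConfig (a fresh seeded Model is built). Returns
    (ScoreMatrix, attention matrix (heads, L)).
    """
    model = cfg_or_model if isinstance(cfg_or_model, Model) else Model(cfg_or_model)
    feats, mask = (
        (x.features, x.mask) if hasattr(x, "features") else (x[0], x[1])
    )
    scores, A = model.predict(feats[None], np.asarray(mask)[None])
    return scores[0], A[0]


# ---------------------------------------------------------------------------
# losses (NumPy formulas; the training loop builds the same expressions on the
# autodiff graph, and the test suite checks the two routes agree)
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    """Binary cross-entropy averaged over all elements."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def attention_penalty(A: np.ndarray) -> float:
    """Orthogonality penalty ||A A^T - I||_F^2; zero iff rows are orthonormal."""
    A = np.asarray(A, dtype=float)
    G = A @ A.T - np.eye(A.shape[0])
    return float(np.sum(G * G))


def loss_lv2(pred: ScoreMatrix, target: np.ndarray, org_target: np.ndarray,
             cfg: ModelConfig | None = None, penalty: float = 0.0,
             cell_mask: np.ndarray | None = None) -> float:
    """Full loss for a suborganelle-annotated sample: Lost1 + Lost2 + reg.

    By default every matrix cell, including EMPTY hierarchy slots (whose
    target is 0), contributes to Lost1. Passing a binary `cell_mask`
    restricts the Lost1 average to occupied cells (the mask-out mode).
    """
    w = cfg.attention_reg_weight if cfg is not None else 0.0
    if cell_mask is None:
        lost1 = _bce(target, pred.sub_scores)
    else:
        m = np.asarray(cell_mask, dtype=bool)
        lost1 = _bce(np.asarray(target)[m], pred.sub_scores[m])
    lost2 = _bce(org_target, pred.org_scores)
    return lost1 + lost2 + w * penalty


def loss_lv1(pred: ScoreMatrix, org_target: np.ndarray,
             cfg: ModelConfig | None = None, penalty: float = 0.0) -> float:
    """Loss for an organelle-only sample: Lost2 (after max-pooling) + reg."""
    w = cfg.attention_reg_weight if cfg is not None else 0.0
    return _bce(org_target, pred.org_scores) + w * penalty


def loss_variant(pred_logits: np.ndarray, one_hot_target: np.ndarray) -> float:
    """Single-label categorical cross-entropy: -sum t_i log softmax(logits)_i."""
    t = np.asarray(one_hot_target, dtype=float)
    if not (np.all((t == 0) | (t == 1)) and t.sum() == 1):
        raise ValueError("target must be one-hot")
    z = np.asarray(pred_logits, dtype=float)
    z = z - z.max()
    logp = z - np.log(np.exp(z).sum())
    return float(-(t * logp).sum())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

ARCHIVE_VERSION = 1


def save_model(model: Model, path) -> None:
    """Write one sub-model to a versioned .npz archive (config embedded)."""
    arrays = {name: t.value for name, t in model.params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps({"version": ARCHIVE_VERSION, "config": asdict(model.cfg)}).encode(),
        dtype=np.uint8,
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> Model:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__config__"].tobytes()).decode())
        if meta["version"] != ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {meta['version']}")
        model = Model(ModelConfig(**meta["config"]))
        for name, t in model.params.items():
            t.value = npz[name].astype(np.float64)
    return model
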