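"""The hybrid attention/LSTM risk network and its ablation variants.

Architecture (full model, variant ``caal``):

1.  scalar feature tokenization: token_i = value_i * w_i + b_i, width d;
2.  multi-head self-attention over the 10 feature tokens (residual +
    feed-forward sublayers, stacked), giving token matrix A_T;
3.  positional-psychological encoding added to the tokens feeding the LSTM
    (a per-position scalar addend sin(i / 10^(2i/d)));
4.  an LSTM reading the ordered, position-encoded tokens, final hidden
    state h_T;
5.  a cross-attention attribution layer scoring each feature token against
    h_T and softmax-normalizing over features (the attribution map A_C),
    producing an attention-weighted context vector per head;
6.  a softmax risk head over {Low, Medium, High}.

The ablation ladder removes pieces of this design: ``lstm`` (E1) is the
bare sequence model, ``lstm_attn`` (E2) adds additive temporal attention
pooling, ``transformer`` (E3) is the attention branch alone with mean
pooling, ``early_fusion`` (E4) concatenates pooled branches, ``dual_attn``
(E5) pools each branch with its own additive attention, and ``caal`` (E6)
is the full model.

Training minimizes categorical cross-entropy plus an attribution-sharpness
regularizer: lambda_xai times the mean Shannon entropy (bits) of the A_C
heads.  With lambda_xai = 0 the loss is plain cross-entropy.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, parameter

N_FEATURES = 10
N_CLASSES = 3

VARIANTS = {
    "E1": "lstm",
    "E2": "lstm_attn",
    "E3": "transformer",
    "E4": "early_fusion",
    "E5": "dual_attn",
    "E6": "caal",
}
VARIANT_NAMES = tuple(VARIANTS.values())

#: residual-branch-style down-scaling of the CAAL projection init
CAAL_INIT_SCALE = 0.25

#: hyperparameter search grid for the full model
SEARCH_SPACE = {
    "n_heads": (4, 8),
    "n_layers": (2, 4),
    "ffn_dim": (256, 512),
    "lstm_units": (64, 128),
    "attention_dim": (32, 64),
    "caal_heads": (2, 4),
    "fusion": ("add", "concat"),
    "dropout": (0.1, 0.3),
    "lambda_xai": (0.1, 0.2),
    "learning_rate": (5e-5, 1e-4),
    "batch_size": (64, 128),
}


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are desk-scale: several widths sit below the published search
    grid so CPU training stays fast; :meth:`off_grid` lists them.
    """

    d_token: int = 32
    n_heads: int = 4
    n_layers: int = 2
    ffn_dim: int = 64
    lstm_units: int = 64
    attention_dim: int = 32
    caal_heads: int = 2
    fusion: str = "concat"
    dropout: float = 0.1
    lambda_xai: float = 0.1
    learning_rate: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 10
    optimizer: str = "sgd"
    seed: int = 0
    #: use the canonical 10000-base sine/cosine positional encoding instead
    #: of the model's own single-sine form
    canonical_pe: bool = False

    def __post_init__(self) -> None:
        if self.d_token % 2:
            raise ValueError("d_token must be even (sinusoidal encoding pairs)")
        if self.d_token % self.n_heads:
            raise ValueError(
                f"d_token={self.d_token} not divisible by n_heads={self.n_heads}"
            )
        if self.fusion not in ("add", "concat"):
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def off_grid(self) -> list[str]:
        """Names of hyperparameters set outside the published search grid."""
        out = []
        for name, grid in SEARCH_SPACE.items():
            if getattr(self, name) not in grid:
                out.append(name)
        return out


def positional_addend(m: int, d: int) -> np.ndarray:
    """Per-position scalar addend sin(i / 10^(2i/d)), i 0-based."""
    i = np.arange(m, dtype=np.float64)
    return np.sin(i / np.power(10.0, 2.0 * i / d))


def canonical_positional_encoding(m: int, d: int) -> np.ndarray:
    """Standard transformer sine/cosine positional encoding, shape (m, d)."""
    pos = np.arange(m, dtype=np.float64)[:, None]
    j = np.arange(0, d, 2, dtype=np.float64)
    angle = pos / np.power(10000.0, j / d)
    pe = np.zeros((m, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


# ---------------------------------------------------------------------------
# parameter initialization


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return parameter(rng.uniform(-limit, limit, size=shape))


def init_params(config: ModelConfig, variant: str = "caal") -> dict[str, Tensor]:
    """Seeded Glorot-style initialization of every matrix the variant uses."""
    variant = VARIANTS.get(variant, variant)
    if variant not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(config.seed)
    d, u, a = config.d_token, config.lstm_units, config.attention_dim
    p: dict[str, Tensor] = {}
    if variant not in ("lstm", "lstm_attn"):  # baselines skip the tokenizer
        p["W_tok"] = _glorot(rng, 1, d, (N_FEATURES, d))
        p["b_tok"] = parameter(np.zeros((N_FEATURES, d)))
    has_transformer = variant in ("transformer", "early_fusion", "dual_attn", "caal")
    has_lstm = variant != "transformer"
    if has_transformer:
        for layer in range(config.n_layers):
            for name in ("W_Q", "W_K", "W_V", "W_attn_out"):
                p[f"{name}_{layer}"] = _glorot(rng, d, d)
            p[f"W_ffn1_{layer}"] = _glorot(rng, d, config.ffn_dim)
            p[f"b_ffn1_{layer}"] = parameter(np.zeros(config.ffn_dim))
            p[f"W_ffn2_{layer}"] = _glorot(rng, config.ffn_dim, d)
            p[f"b_ffn2_{layer}"] = parameter(np.zeros(d))
    if has_lstm:
        # the recurrent baselines read the raw ordered scalars (one value
        # per step); only the hybrid variants feed the LSTM tokenized,
        # position-encoded features
        lstm_in = 1 if variant in ("lstm", "lstm_attn") else d
        p["W_lstm_x"] = _glorot(rng, lstm_in, 4 * u)
        p["W_lstm_h"] = _glorot(rng, u, 4 * u)
        p["b_lstm"] = parameter(np.zeros(4 * u))
    if variant == "lstm_attn":
        p["W_tattn"] = _glorot(rng, u, a)
        p["v_tattn"] = _glorot(rng, a, 1, (a,))
    if variant == "dual_attn":
        p["W_tattn"] = _glorot(rng, u, a)
        p["v_tattn"] = _glorot(rng, a, 1, (a,))
        p["W_fattn"] = _glorot(rng, d, a)
        p["v_fattn"] = _glorot(rng, a, 1, (a,))
    if variant == "caal":
        # small init on the attribution projections: the recurrent path
        # establishes the fit first and the cross-attention context refines
        # it, which both stabilizes training and keeps A_C faithful
        for head in range(config.caal_heads):
            p[f"W_F_{head}"] = _glorot(rng, d, a)
            p[f"W_L_{head}"] = _glorot(rng, u, a)
            p[f"W_F_{head}"].data *= CAAL_INIT_SCALE
            p[f"W_L_{head}"].data *= CAAL_INIT_SCALE
        if config.fusion == "add":
            p["W_proj"] = _glorot(rng, u, a * config.caal_heads)
    fused_dim = {
        "lstm": u,
        "lstm_attn": u,
        "transformer": d,
        "early_fusion": d + u,
        "dual_attn": d + u,
        "caal": a * config.caal_heads + (u if config.fusion == "concat" else 0),
    }[variant]
    p["W_O"] = _glorot(rng, fused_dim, N_CLASSES)
    p["b_O"] = parameter(np.zeros(N_CLASSES))
    return p


def param_count(params: dict[str, Tensor]) -> int:
    return int(sum(t.data.size for t in params.values()))


# ---------------------------------------------------------------------------
# forward pass


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def tokenize(X: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Scalar tokenization: (B, m) values -> (B, m, d) tokens."""
    B, m = X.shape
    return X.reshape(B, m, 1) * params["W_tok"] + params["b_tok"]


def feature_attention(
    tokens: Tensor,
    params: dict[str, Tensor],
    config: ModelConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, list[np.ndarray]]:
    """Stacked multi-head self-attention over feature tokens.

    Returns the transformed token matrix A_T (B, m, d) and the per-layer
    attention weights (each (B, heads, m, m), rows summing to 1).
    """
    B, m, d = tokens.shape
    H = config.n_heads
    dh = d // H
    weights: list[np.ndarray] = []
    x = tokens
    for layer in range(config.n_layers):
        def split(t: Tensor) -> Tensor:
            return t.reshape(B, m, H, dh).swapaxes(1, 2)

        q = split(x @ params[f"W_Q_{layer}"])
        k = split(x @ params[f"W_K_{layer}"])
        v = split(x @ params[f"W_V_{layer}"])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        attn = scores.softmax(axis=-1)
        weights.append(attn.data)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, m, d) @ params[f"W_attn_out_{layer}"]
        x = x + _dropout(ctx, config.dropout, rng)
        ffn = (x @ params[f"W_ffn1_{layer}"] + params[f"b_ffn1_{layer}"]).relu()
        ffn = ffn @ params[f"W_ffn2_{layer}"] + params[f"b_ffn2_{layer}"]
        x = x + _dropout(ffn, config.dropout, rng)
    return x, weights


def lstm_sequence(x_pe: Tensor, params: dict[str, Tensor], units: int) -> list[Tensor]:
    """Unroll the LSTM over the m ordered positions; zero initial state.

    Returns the list of hidden states [h_1 ... h_m]; the last entry is h_T.
    """
    B, m, _ = x_pe.shape
    u = units
    h = Tensor(np.zeros((B, u)))
    c = Tensor(np.zeros((B, u)))
    hs: list[Tensor] = []
    for t in range(m):
        x_t = x_pe[:, t, :]
        z = x_t @ params["W_lstm_x"] + h @ params["W_lstm_h"] + params["b_lstm"]
        i = z[:, 0 * u : 1 * u].sigmoid()
        f = z[:, 1 * u : 2 * u].sigmoid()
        g = z[:, 2 * u : 3 * u].tanh()
        o = z[:, 3 * u : 4 * u].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        hs.append(h)
    return hs


def _additive_pool(
    seq: list[Tensor], W: Tensor, v: Tensor
) -> tuple[Tensor, np.ndarray]:
    """Additive attention pooling: softmax(v . tanh(W h_t)) weighted sum."""
    B = seq[0].shape[0]
    a = W.shape[1]
    scores = concat(
        [((h @ W).tanh() * v.reshape(1, a)).sum(axis=1, keepdims=True) for h in seq],
        axis=1,
    )
    alpha = scores.softmax(axis=1)
    stacked = concat([h.reshape(B, 1, -1) for h in seq], axis=1)
    ctx = (alpha.reshape(B, len(seq), 1) * stacked).sum(axis=1)
    return ctx, alpha.data


def caal_fuse(
    A_T: Tensor,
    h_T: Tensor,
    params: dict[str, Tensor],
    config: ModelConfig,
    tokens: Tensor | None = None,
) -> tuple[Tensor, Tensor]:
    """Cross-attention attribution: score each feature token against h_T.

    Per head: scores_i = (A_T W_F)_i . (h_T W_L); A_C = softmax over the m
    features (a simplex attribution vector).  The context aggregates the
    *raw* feature tokens, c = sum_i A_C[i] (tokens W_F)_i: the attended
    representations steer where attention goes, while the aggregated values
    stay feature-identifiable (post-attention tokens are mixtures of all
    features, so aggregating them would let A_C drift onto arbitrary
    positions without hurting the loss).  With ``tokens=None`` the attended
    tokens serve as the value path too.  Head contexts are concatenated;
    fusion with h_T is ``concat`` or ``add`` (through a projection).
    Returns (A_C, fused) with A_C of shape (B, heads, m).
    """
    B, m, _ = A_T.shape
    a = config.attention_dim
    if tokens is None:
        tokens = A_T
    acs, ctxs = [], []
    for head in range(config.caal_heads):
        F = A_T @ params[f"W_F_{head}"]  # (B, m, a)
        V = tokens @ params[f"W_F_{head}"]  # value path, feature-aligned
        g = h_T @ params[f"W_L_{head}"]  # (B, a)
        scores = (F * g.reshape(B, 1, a)).sum(axis=2)  # (B, m)
        ac = scores.softmax(axis=1)
        acs.append(ac.reshape(B, 1, m))
        ctxs.append((ac.reshape(B, m, 1) * V).sum(axis=1))
    A_C = concat(acs, axis=1)
    context = concat(ctxs, axis=1) if len(ctxs) > 1 else ctxs[0]
    if config.fusion == "concat":
        fused = concat([context, h_T], axis=1)
    else:
        fused = context + h_T @ params["W_proj"]
    return A_C, fused


def classify(fused: Tensor, params: dict[str, Tensor]) -> Tensor:
    """Softmax risk head over {Low, Medium, High}."""
    return (fused @ params["W_O"] + params["b_O"]).softmax(axis=-1)


def forward(
    X: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
    variant: str = "caal",
    rng: np.random.Generator | None = None,
) -> dict:
    """Full forward pass; returns a trace of intermediate tensors.

    ``X`` is (B, m) of normalized feature values in the active ordering.
    ``rng`` enables dropout (training mode); None means evaluation mode.
    Trace keys: tokens, A_T, attn_weights, x_PE, h_T, A_C, fused, y_hat
    (absent branches are None).
    """
    variant = VARIANTS.get(variant, variant)
    X = np.asarray(X, dtype=np.float64)
    if np.any(np.abs(X) > 20):
        warnings.warn("input looks unnormalized (|z| > 20)", stacklevel=2)
    B, m = X.shape
    d = config.d_token
    tokens = (
        tokenize(Tensor(X), params)
        if variant not in ("lstm", "lstm_attn")
        else None
    )
    trace: dict = {
        "tokens": tokens,
        "A_T": None,
        "attn_weights": None,
        "x_PE": None,
        "h_T": None,
        "A_C": None,
    }

    A_T = None
    if variant in ("transformer", "early_fusion", "dual_attn", "caal"):
        A_T, attn_w = feature_attention(tokens, params, config, rng)
        trace["A_T"], trace["attn_weights"] = A_T, attn_w

    h_seq = None
    if variant in ("lstm", "lstm_attn"):
        # standalone recurrent baseline: raw ordered scalars, no tokens/PE
        x_seq = Tensor(X.reshape(B, m, 1))
        h_seq = lstm_sequence(x_seq, params, config.lstm_units)
        trace["h_T"] = h_seq[-1]
    elif variant != "transformer":
        if config.canonical_pe:
            pe = canonical_positional_encoding(m, d).reshape(1, m, d)
        else:
            pe = positional_addend(m, d).reshape(1, m, 1)
        x_pe = tokens + Tensor(pe)
        trace["x_PE"] = x_pe
        h_seq = lstm_sequence(x_pe, params, config.lstm_units)
        trace["h_T"] = h_seq[-1]

    if variant == "lstm":
        fused = h_seq[-1]
    elif variant == "lstm_attn":
        fused, _ = _additive_pool(h_seq, params["W_tattn"], params["v_tattn"])
    elif variant == "transformer":
        fused = A_T.mean(axis=1)
    elif variant == "early_fusion":
        fused = concat([A_T.mean(axis=1), h_seq[-1]], axis=1)
    elif variant == "dual_attn":
        tok_seq = [A_T[:, t, :] for t in range(m)]
        f_ctx, _ = _additive_pool(tok_seq, params["W_fattn"], params["v_fattn"])
        t_ctx, _ = _additive_pool(h_seq, params["W_tattn"], params["v_tattn"])
        fused = concat([f_ctx, t_ctx], axis=1)
    else:  # caal
        A_C, fused = caal_fuse(A_T, h_seq[-1], params, config, tokens=tokens)
        trace["A_C"] = A_C
    trace["fused"] = fused
    trace["y_hat"] = classify(fused, params)
    return trace


# ---------------------------------------------------------------------------
# loss and training


def attribution_entropy(A_C: Tensor) -> Tensor:
    """Mean Shannon entropy (bits) of the attribution heads."""
    p = A_C.clamp_min(1e-12)
    return -(p * p.log()).sum(axis=-1).mean() * (1.0 / math.log(2.0))


def loss_fn(
    y_hat: Tensor, y: np.ndarray, A_C: Tensor | None, lambda_xai: float
) -> Tensor:
    """Cross-entropy plus the attribution-sharpness regularizer.

    CE is in nats; the regularizer is lambda_xai times the mean A_C entropy
    in bits.  Zero probability at the true class is clamped at 1e-12.
    """
    B = y_hat.shape[0]
    onehot = np.zeros((B, N_CLASSES))
    onehot[np.arange(B), np.asarray(y, dtype=int)] = 1.0
    p_true = (y_hat * Tensor(onehot)).sum(axis=-1)
    ce = -(p_true.clamp_min(1e-12).log()).mean()
    if A_C is not None and lambda_xai != 0.0:
        return ce + lambda_xai * attribution_entropy(A_C)
    return ce


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, params: dict[str, Tensor]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in params.items():
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainState:
    """Per-epoch training curves and the best-epoch checkpoint."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    mean_entropy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0

    def curves_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
                "mean_prediction_entropy": self.mean_entropy,
            }
        )


def predict_proba(
    X: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
    variant: str = "caal",
    batch_size: int = 512,
) -> np.ndarray:
    """Class probabilities in evaluation mode (no dropout)."""
    outs = []
    for start in range(0, len(X), batch_size):
        trace = forward(X[start : start + batch_size], params, config, variant)
        outs.append(trace["y_hat"].data)
    return np.concatenate(outs, axis=0)


def _eval_loss_acc(X, y, params, config, variant):
    proba = predict_proba(X, params, config, variant)
    ll = -np.mean(np.log(np.maximum(proba[np.arange(len(y)), y], 1e-12)))
    acc = float(np.mean(proba.argmax(axis=1) == y))
    ent = float(
        np.mean(-np.sum(proba * np.log2(np.maximum(proba, 1e-12)), axis=1))
    )
    return float(ll), acc, ent


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None,
    y_val: np.ndarray | None,
    config: ModelConfig,
    variant: str = "caal",
) -> tuple[dict[str, Tensor], TrainState]:
    """Mini-batch training with best-validation-accuracy checkpointing.

    Deterministic given ``config.seed`` (initialization, shuffling and
    dropout all draw from one seeded generator).  Early stopping after
    ``config.patience`` epochs without validation improvement; with no
    validation set the final parameters are returned.
    """
    variant = VARIANTS.get(variant, variant)
    params = init_params(config, variant)
    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(params, config.learning_rate) if config.optimizer == "adam" else None
    state = TrainState()
    best_params = None
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=int)
    n = len(X_train)
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = X_train[idx], y_train[idx]
            drop_rng = rng if config.dropout > 0 else None
            trace = forward(Xb, params, config, variant, rng=drop_rng)
            loss = loss_fn(trace["y_hat"], yb, trace["A_C"], config.lambda_xai)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch rows {idx[:5]}..."
                )
            for p in params.values():
                p.zero_grad()
            loss.backward()
            if opt is not None:
                opt.step(params)
            else:
                for p in params.values():
                    p.data -= config.learning_rate * p.grad
            epoch_loss += float(loss.data) * len(idx)
            epoch_correct += int((trace["y_hat"].data.argmax(axis=1) == yb).sum())
        state.train_loss.append(epoch_loss / n)
        state.train_acc.append(epoch_correct / n)
        if X_val is not None and len(X_val):
            vl, va, ve = _eval_loss_acc(
                np.asarray(X_val, float), np.asarray(y_val, int), params, config, variant
            )
            state.val_loss.append(vl)
            state.val_acc.append(va)
            state.mean_entropy.append(ve)
            if va > state.best_val_acc:
                state.best_val_acc = va
                state.best_epoch = epoch
                best_params = {k: copy.deepcopy(p.data) for k, p in params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        else:
            state.val_loss.append(float("nan"))
            state.val_acc.append(float("nan"))
            _, _, ve = _eval_loss_acc(X_train, y_train, params, config, variant)
            state.mean_entropy.append(ve)
    if best_params is not None:
        for k, p in params.items():
            p.data = best_params[k]
    return params, state


def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig, variant: str, extra: dict | None = None) -> None:
    """Persist parameters (npz) alongside the config (JSON in the archive)."""
    import json

    arrays = {k: p.data for k, p in params.items()}
    meta = json.dumps(
        {"config": asdict(config), "variant": variant, "extra": extra or {}}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig, str, dict]:
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {
            k: parameter(archive[k]) for k in archive.files if k != "__meta__"
        }
    return params, ModelConfig(**meta["config"]), meta["variant"], meta["extra"]
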