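"""BiLSTM sequence classifier (written out from the gate equations) and an
SVM baseline.

Each feature sample is treated as a 62-step sequence: one step per
electrode in montage order, with that electrode's 31 features as the step
input.  A forward LSTM reads the sequence front to back, a backward LSTM
back to front; their final hidden states are concatenated and mapped by a
sigmoid readout to P(class = MA).

The LSTM cell is the standard gated recurrence

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        forget gate
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        input gate
    c~_t = tanh  (W_C [h_{t-1}, x_t] + b_C)        candidate memory
    C_t = f_t * C_{t-1} + i_t * c~_t               memory state
    o_t = sigmoid(W_O [h_{t-1}, x_t] + b_O)        output gate
    h_t = o_t * tanh(C_t)                          hidden state

implemented directly in NumPy with analytic backpropagation through time,
so each piece is inspectable and numerically checkable against a
finite-difference oracle.  Training minimises binary cross-entropy with
Adam, early-stops on validation balanced accuracy, and is deterministic
given the seed.

The baseline is a soft-margin SVM with sigmoid kernel (scikit-learn).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "LSTMParams",
    "LSTMState",
    "BiLSTMModel",
    "TrainConfig",
    "lstm_step",
    "bilstm_forward",
    "predict_proba",
    "train_bilstm",
    "train_svm_baseline",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMParams:
    """Gate weights over the concatenation [h_{t-1}, x_t], plus biases."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_O: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_O: np.ndarray

    def __post_init__(self) -> None:
        h = self.hidden_size
        for name in ("W_f", "W_i", "W_C", "W_O"):
            if getattr(self, name).shape != self.W_f.shape:
                raise ValueError("all gate weight matrices must share one shape")
        for name in ("b_f", "b_i", "b_C", "b_O"):
            if getattr(self, name).shape != (h,):
                raise ValueError("bias length must equal hidden size")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]


@dataclass
class LSTMState:
    """One cell state with the gate activations exposed for inspection."""

    h: np.ndarray
    C: np.ndarray
    f: np.ndarray | None = None
    i: np.ndarray | None = None
    o: np.ndarray | None = None
    C_tilde: np.ndarray | None = None

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(h=np.zeros(hidden_size), C=np.zeros(hidden_size))


def lstm_step(p: LSTMParams, prev: LSTMState, x_t: np.ndarray) -> LSTMState:
    """One application of the gate equations to a single input vector."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (p.input_size,):
        raise ValueError(f"input shape {x_t.shape} != ({p.input_size},)")
    z = np.concatenate([prev.h, x_t])
    f = _sigmoid(p.W_f @ z + p.b_f)
    i = _sigmoid(p.W_i @ z + p.b_i)
    c_tilde = np.tanh(p.W_C @ z + p.b_C)
    o = _sigmoid(p.W_O @ z + p.b_O)
    C = f * prev.C + i * c_tilde
    h = o * np.tanh(C)
    return LSTMState(h=h, C=C, f=f, i=i, o=o, C_tilde=c_tilde)


@dataclass
class BiLSTMModel:
    forward_cell: LSTMParams
    backward_cell: LSTMParams
    readout_w: np.ndarray  # (2 * hidden_size,)
    readout_b: float
    train_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.readout_w.shape != (2 * self.forward_cell.hidden_size,):
            raise ValueError("readout input size must be 2 x hidden size")


def bilstm_forward(m: BiLSTMModel, seq: np.ndarray) -> float:
    """P(positive class) for one (T, D) sequence."""
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be a nonempty (T, D) matrix")
    h = m.forward_cell.hidden_size
    sf = LSTMState.zeros(h)
    for t in range(seq.shape[0]):
        sf = lstm_step(m.forward_cell, sf, seq[t])
    sb = LSTMState.zeros(m.backward_cell.hidden_size)
    for t in range(seq.shape[0] - 1, -1, -1):
        sb = lstm_step(m.backward_cell, sb, seq[t])
    logit = m.readout_w @ np.concatenate([sf.h, sb.h]) + m.readout_b
    return float(_sigmoid(np.asarray([logit]))[0])


# ---------------------------------------------------------------------------
# batched forward / backward used by training


def _forward_batch(p: LSTMParams, X: np.ndarray):
    """Run the cell over (B, T, D); returns final h and per-step caches."""
    B, T, _ = X.shape
    H = p.hidden_size
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    cache = []
    for t in range(T):
        z = np.concatenate([h, X[:, t, :]], axis=1)
        f = _sigmoid(z @ p.W_f.T + p.b_f)
        i = _sigmoid(z @ p.W_i.T + p.b_i)
        g = np.tanh(z @ p.W_C.T + p.b_C)
        o = _sigmoid(z @ p.W_O.T + p.b_O)
        C_prev = C
        C = f * C_prev + i * g
        h = o * np.tanh(C)
        cache.append((z, f, i, g, o, C, C_prev))
    return h, cache


def _backward_batch(p: LSTMParams, cache, d_h_final: np.ndarray):
    """BPTT through the cached steps given the gradient at the final h."""
    H = p.hidden_size
    grads = {k: np.zeros_like(getattr(p, k))
             for k in ("W_f", "W_i", "W_C", "W_O", "b_f", "b_i", "b_C", "b_O")}
    dh = d_h_final
    dC = np.zeros_like(d_h_final)
    for z, f, i, g, o, C, C_prev in reversed(cache):
        tC = np.tanh(C)
        do = dh * tC
        dC = dC + dh * o * (1.0 - tC**2)
        df = dC * C_prev
        di = dC * g
        dg = dC * i
        dC_prev = dC * f
        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_g = dg * (1.0 - g**2)
        da_o = do * o * (1.0 - o)
        grads["W_f"] += da_f.T @ z
        grads["W_i"] += da_i.T @ z
        grads["W_C"] += da_g.T @ z
        grads["W_O"] += da_o.T @ z
        grads["b_f"] += da_f.sum(axis=0)
        grads["b_i"] += da_i.sum(axis=0)
        grads["b_C"] += da_g.sum(axis=0)
        grads["b_O"] += da_o.sum(axis=0)
        dz = da_f @ p.W_f + da_i @ p.W_i + da_g @ p.W_C + da_o @ p.W_O
        dh = dz[:, :H]
        dC = dC_prev
    return grads


def _model_forward_batch(m: BiLSTMModel, X: np.ndarray):
    hf, cf = _forward_batch(m.forward_cell, X)
    hb, cb = _forward_batch(m.backward_cell, X[:, ::-1, :])
    logits = np.concatenate([hf, hb], axis=1) @ m.readout_w + m.readout_b
    return _sigmoid(logits), (hf, cf, hb, cb)


def predict_proba(m: BiLSTMModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for (B, T, D) sequences."""
    p, _ = _model_forward_batch(m, np.asarray(X, dtype=float))
    return p


def loss_and_gradients(m: BiLSTMModel, X: np.ndarray, y: np.ndarray, l2: float = 0.0):
    """Mean binary cross-entropy (+ L2 on weights) and all parameter gradients."""
    B = X.shape[0]
    p, (hf, cf, hb, cb) = _model_forward_batch(m, X)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dlogit = (p - y) / B
    H = m.forward_cell.hidden_size
    d_read_w = np.concatenate([hf, hb], axis=1).T @ dlogit
    d_read_b = dlogit.sum()
    dhf = np.outer(dlogit, m.readout_w[:H])
    dhb = np.outer(dlogit, m.readout_w[H:])
    gf = _backward_batch(m.forward_cell, cf, dhf)
    gb = _backward_batch(m.backward_cell, cb, dhb)
    grads = {"fwd": gf, "bwd": gb, "readout_w": d_read_w, "readout_b": d_read_b}
    if l2 > 0:
        for cell, g in (("fwd", gf), ("bwd", gb)):
            params = m.forward_cell if cell == "fwd" else m.backward_cell
            for k in ("W_f", "W_i", "W_C", "W_O"):
                W = getattr(params, k)
                loss += 0.5 * l2 * np.sum(W**2)
                g[k] += l2 * W
        loss += 0.5 * l2 * np.sum(m.readout_w**2)
        grads["readout_w"] += l2 * m.readout_w
    return loss, grads


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Optimiser settings; the gate equations themselves have no knobs.

    Defaults favour fast, stable convergence at the cohort scale this
    package targets (a few hundred samples): hidden size 32, Adam at
    1e-2 on minibatches of 64, at most 80 epochs with early stopping
    after 10 epochs without validation improvement.
    """

    hidden_size: int = 32
    learning_rate: float = 1e-2
    max_epochs: int = 80
    batch_size: int = 64
    patience: int = 10
    l2: float = 1e-4
    init_scale: float = 0.08
    forget_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_size", "learning_rate", "max_epochs", "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def init_params(input_size: int, cfg: TrainConfig, rng: np.random.Generator) -> LSTMParams:
    H, D = cfg.hidden_size, input_size
    u = lambda: rng.uniform(-cfg.init_scale, cfg.init_scale, size=(H, H + D))
    return LSTMParams(
        W_f=u(), W_i=u(), W_C=u(), W_O=u(),
        b_f=np.full(H, cfg.forget_bias, dtype=float),
        b_i=np.zeros(H), b_C=np.zeros(H), b_O=np.zeros(H),
    )


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flatten(m: BiLSTMModel) -> dict:
    out = {}
    for tag, cell in (("f", m.forward_cell), ("b", m.backward_cell)):
        for k in ("W_f", "W_i", "W_C", "W_O", "b_f", "b_i", "b_C", "b_O"):
            out[f"{tag}.{k}"] = getattr(cell, k)
    out["readout_w"] = m.readout_w
    return out


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    sen = np.mean(y_pred[pos] == 1) if pos.any() else np.nan
    spe = np.mean(y_pred[~pos] == 0) if (~pos).any() else np.nan
    return 100.0 * (sen + spe) / 2.0


def train_bilstm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
) -> BiLSTMModel:
    """Fit a BiLSTM on (B, T, D) sequences with 0/1 labels.

    Keeps the parameters from the epoch with the best validation balanced
    accuracy (training accuracy when no validation set is given) and
    early-stops after ``cfg.patience`` epochs without improvement.
    Deterministic for fixed data, config and seed.
    """
    cfg = cfg or TrainConfig()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    D = X_train.shape[2]
    model = BiLSTMModel(
        forward_cell=init_params(D, cfg, rng),
        backward_cell=init_params(D, cfg, rng),
        readout_w=rng.uniform(-cfg.init_scale, cfg.init_scale, size=2 * cfg.hidden_size),
        readout_b=0.0,
    )
    if X_val is None:
        X_val, y_val = X_train, y_train
    opt = _Adam(cfg.learning_rate)
    best_bva, best_state, since_best = -np.inf, None, 0
    n = X_train.shape[0]
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            loss, grads = loss_and_gradients(model, X_train[idx], y_train[idx], cfg.l2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss!r} "
                    f"(lr={cfg.learning_rate}, hidden={cfg.hidden_size})"
                )
            flat_grads = {}
            for tag, g in (("f", grads["fwd"]), ("b", grads["bwd"])):
                for k, v in g.items():
                    flat_grads[f"{tag}.{k}"] = v
            flat_grads["readout_w"] = grads["readout_w"]
            opt.step(_flatten(model), flat_grads)
            model.readout_b -= cfg.learning_rate * grads["readout_b"]
            epoch_loss += loss * len(idx)
        val_pred = (predict_proba(model, X_val) >= 0.5).astype(int)
        bva = _balanced_accuracy(np.asarray(y_val, int), val_pred)
        model.train_log.append({"epoch": epoch, "loss": epoch_loss / n, "val_bva": bva})
        if bva > best_bva:
            best_bva, since_best = bva, 0
            best_state = copy.deepcopy(
                (model.forward_cell, model.backward_cell, model.readout_w, model.readout_b)
            )
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.forward_cell, model.backward_cell, model.readout_w, model.readout_b = best_state
    return model


def train_svm_baseline(
    X_train: np.ndarray, y_train: np.ndarray, kernel: str = "sigmoid", C: float = 1.0
) -> SVC:
    """Soft-margin SVM comparator on flat feature vectors."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(kernel=kernel, C=C, gamma="scale")
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    return clf
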