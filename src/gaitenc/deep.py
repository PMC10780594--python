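"""Compact CNN and LSTM classifiers for raw windowed sensor data.

Both networks are implemented directly in NumPy — forward pass, manual
backpropagation and an Adam optimizer — sized for the small windowed
datasets this package targets.

CNN (fixed stack, valid padding, ReLU):

    input (T, C, 1)
    -> conv 32 filters (3, 2) -> maxpool (2, 1)
    -> conv 64 filters (2, 1) -> maxpool (2, 1)
    -> conv 128 filters (2, 1)
    -> flatten -> dense(n_classes) -> softmax

LSTM: each input step x_t (n_features, default 3) passes through a ReLU
projection onto the hidden width, then two stacked recurrent cells of 50
units implementing the standard gate equations

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f + forget_bias)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
    g_t = tanh   (W_c [h_{t-1}, x_t] + b_c)
    c_t = f_t * c_{t-1} + i_t * g_t
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(c_t)

with the last time step's hidden state feeding a linear softmax layer.
The forget-gate bias offset defaults to 1.0 (gates start open, helping
gradient flow early in training).

Training minimizes cross-entropy with Adam, monitors a held-out
validation split, stops early when validation loss stops improving and
restores the best-seen weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def lstm_cell_step(
    x: np.ndarray, h: np.ndarray, c: np.ndarray,
    W: np.ndarray, b: np.ndarray, forget_bias: float = 1.0,
):
    """One LSTM time step on a batch; returns (h_new, c_new, cache).

    ``W`` is ((n_in + n_hidden), 4 * n_hidden) with gate blocks ordered
    [f, i, g, o]; ``b`` is (4 * n_hidden,).  ``forget_bias`` is added to
    the forget-gate preactivation.
    """
    H = h.shape[1]
    z = np.concatenate([h, x], axis=1) @ W + b
    f = _sigmoid(z[:, :H] + forget_bias)
    i = _sigmoid(z[:, H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = _sigmoid(z[:, 3 * H:])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new, (x, h, c, f, i, g, o, c_new)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# --------------------------------------------------------------------------
# CNN
# --------------------------------------------------------------------------

@dataclass
class CNNConfig:
    input_shape: tuple[int, int, int] = (128, 9, 1)   # (time, channels, 1)
    n_classes: int = 6
    conv_filters: tuple[int, ...] = (32, 64, 128)
    conv_kernels: tuple[tuple[int, int], ...] = ((3, 2), (2, 1), (2, 1))
    pool_sizes: tuple[tuple[int, int], ...] = ((2, 1), (2, 1))
    epochs: int = 27
    batch_size: int = 5
    lr: float = 1e-3
    clip_norm: float | None = None
    seed: int = 0


class _Conv2D:
    """Valid 2-D convolution via im2col + matmul; NHWC layout."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kh * kw * c_in))      # He init for ReLU
        self.W = rng.normal(0.0, scale, size=(kh, kw, c_in, c_out))
        self.b = np.zeros(c_out)
        self.kh, self.kw = kh, kw

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return h - self.kh + 1, w - self.kw + 1

    def forward(self, X: np.ndarray) -> np.ndarray:
        kh, kw = self.kh, self.kw
        # (N, Ho, Wo, C, kh, kw) -> (N, Ho, Wo, kh, kw, C)
        patches = sliding_window_view(X, (kh, kw), axis=(1, 2))
        patches = patches.transpose(0, 1, 2, 4, 5, 3)
        N, Ho, Wo = patches.shape[:3]
        cols = patches.reshape(N, Ho, Wo, -1)
        # cols' last axis flattens (kh, kw, C_in) in the same order as
        # W's leading axes, so a single matmul performs the convolution
        Wm = self.W.reshape(-1, self.W.shape[3])
        out = cols @ Wm + self.b
        self._cache = (X.shape, cols)
        return out

    def backward(self, dY: np.ndarray):
        x_shape, cols = self._cache
        kh, kw = self.kh, self.kw
        c_out = self.W.shape[3]
        dYf = dY.reshape(-1, c_out)
        colsf = cols.reshape(-1, cols.shape[-1])
        self.dW = (colsf.T @ dYf).reshape(self.W.shape)
        self.db = dYf.sum(axis=0)
        dcols = (dYf @ self.W.reshape(-1, c_out).T).reshape(
            dY.shape[0], dY.shape[1], dY.shape[2], kh, kw, x_shape[3]
        )
        dX = np.zeros(x_shape)
        for i in range(kh):
            for j in range(kw):
                dX[:, i:i + dY.shape[1], j:j + dY.shape[2], :] += \
                    dcols[:, :, :, i, j, :]
        return dX


class _MaxPool:
    """Non-overlapping max pooling with stride = pool size, valid padding."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw

    def forward(self, X: np.ndarray) -> np.ndarray:
        N, H, W, C = X.shape
        Ho, Wo = H // self.ph, W // self.pw
        Xc = X[:, :Ho * self.ph, :Wo * self.pw, :]
        blocks = Xc.reshape(N, Ho, self.ph, Wo, self.pw, C)
        out = blocks.max(axis=(2, 4))
        self._cache = (X.shape, blocks, out)
        return out

    def backward(self, dY: np.ndarray):
        x_shape, blocks, out = self._cache
        mask = blocks == out[:, :, None, :, None, :]
        # split ties evenly so gradient mass is conserved
        mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        dblocks = mask * dY[:, :, None, :, None, :]
        N, Ho, ph, Wo, pw, C = dblocks.shape
        dX = np.zeros(x_shape)
        dX[:, :Ho * ph, :Wo * pw, :] = dblocks.reshape(N, Ho * ph, Wo * pw, C)
        return dX


class CNNModel:
    """The fixed conv/pool/dense stack with manual backprop."""

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        t, c, _ = cfg.input_shape
        self.layers: list = []
        self.shape_report: list[tuple[str, tuple[int, ...], int]] = []
        c_in = cfg.input_shape[2]
        h, w = t, c
        for li, (n_f, (kh, kw)) in enumerate(
            zip(cfg.conv_filters, cfg.conv_kernels)
        ):
            conv = _Conv2D(kh, kw, c_in, n_f, rng)
            h2, w2 = conv.out_shape(h, w)
            if h2 < 1 or w2 < 1:
                raise ValueError(
                    f"input too small at conv{li + 1}: ({h}, {w}) with "
                    f"kernel ({kh}, {kw})"
                )
            self.layers.append(("conv", conv))
            self.shape_report.append(
                (f"conv{li + 1}", (h2, w2, n_f),
                 kh * kw * c_in * n_f + n_f)
            )
            h, w, c_in = h2, w2, n_f
            if li < len(cfg.pool_sizes):
                ph, pw = cfg.pool_sizes[li]
                pool = _MaxPool(ph, pw)
                h, w = h // ph, w // pw
                if h < 1 or w < 1:
                    raise ValueError(f"input too small at pool{li + 1}")
                self.layers.append(("pool", pool))
                self.shape_report.append((f"pool{li + 1}", (h, w, c_in), 0))
        self.flat_dim = h * w * c_in
        scale = np.sqrt(2.0 / self.flat_dim)
        self.Wd = rng.normal(0.0, scale, size=(self.flat_dim, cfg.n_classes))
        self.bd = np.zeros(cfg.n_classes)
        self.shape_report.append(("flatten", (self.flat_dim,), 0))
        self.shape_report.append(
            ("dense", (cfg.n_classes,),
             self.flat_dim * cfg.n_classes + cfg.n_classes)
        )

    @property
    def n_params(self) -> int:
        return sum(p for _, _, p in self.shape_report)

    def parameters(self) -> list[np.ndarray]:
        ps = []
        for kind, layer in self.layers:
            if kind == "conv":
                ps += [layer.W, layer.b]
        ps += [self.Wd, self.bd]
        return ps

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, T, C, 1)."""
        out = X
        self._relu_masks = []
        for kind, layer in self.layers:
            out = layer.forward(out)
            if kind == "conv":
                mask = out > 0
                out = out * mask
                self._relu_masks.append(mask)
        self._flat_in = out
        flat = out.reshape(out.shape[0], -1)
        self._flat = flat
        return flat @ self.Wd + self.bd

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        self.dWd = self._flat.T @ dlogits
        self.dbd = dlogits.sum(axis=0)
        d = (dlogits @ self.Wd.T).reshape(self._flat_in.shape)
        grads_rev = [self.dbd, self.dWd]
        mask_i = len(self._relu_masks) - 1
        for kind, layer in reversed(self.layers):
            if kind == "conv":
                d = d * self._relu_masks[mask_i]
                mask_i -= 1
                d = layer.backward(d)
                grads_rev += [layer.db, layer.dW]
            else:
                d = layer.backward(d)
        return list(reversed(grads_rev))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward(X))


def build_cnn(cfg: CNNConfig) -> CNNModel:
    """Build the CNN and log its per-layer shape/parameter report."""
    model = CNNModel(cfg)
    for name, shape, n_par in model.shape_report:
        logger.info("%-8s out=%s params=%d", name, shape, n_par)
    logger.info("total parameters: %d", model.n_params)
    return model


# --------------------------------------------------------------------------
# LSTM
# --------------------------------------------------------------------------

@dataclass
class LSTMConfig:
    segment_time_size: int = 200
    n_features: int = 3
    n_classes: int = 6
    hidden_size: int = 50
    n_layers: int = 2
    forget_bias: float = 1.0
    epochs: int = 27
    batch_size: int = 32
    lr: float = 1e-3
    #: global gradient-norm clip; recurrent nets are prone to exploding
    #: gradients, so the LSTM clips by default
    clip_norm: float | None = 1.0
    seed: int = 0


class _LSTMLayer:
    def __init__(self, n_in: int, n_hidden: int, forget_bias: float,
                 rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in + n_hidden)
        self.W = rng.normal(0.0, scale, size=(n_in + n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.n_hidden = n_hidden
        self.forget_bias = forget_bias

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X: (N, T, n_in) -> hidden states (N, T, n_hidden)."""
        N, T, _ = X.shape
        H = self.n_hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._caches = []
        out = np.empty((N, T, H))
        for t in range(T):
            h, c, cache = lstm_cell_step(
                X[:, t], h, c, self.W, self.b, self.forget_bias
            )
            self._caches.append(cache)
            out[:, t] = h
        return out

    def backward(self, dH: np.ndarray):
        """dH: gradient w.r.t. every hidden state (N, T, n_hidden)."""
        N, T, H = dH.shape
        n_in = self.W.shape[0] - H
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        dX = np.empty((N, T, n_in))
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, f, i, g, o, c_new = self._caches[t]
            dh = dH[:, t] + dh_next
            tc = np.tanh(c_new)
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [df * f * (1 - f), di * i * (1 - i),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1
            )
            inp = np.concatenate([h_prev, x], axis=1)
            self.dW += inp.T @ dz
            self.db += dz.sum(axis=0)
            dinp = dz @ self.W.T
            dh_next = dinp[:, :H]
            dX[:, t] = dinp[:, H:]
            dc_next = dc * f
        return dX


class LSTMModel:
    """ReLU input projection -> stacked LSTM cells -> linear softmax head."""

    def __init__(self, cfg: LSTMConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden_size
        self.Wp = rng.normal(0.0, 1.0 / np.sqrt(cfg.n_features),
                             size=(cfg.n_features, H))
        self.bp = np.zeros(H)
        self.cells = []
        n_in = H
        for _ in range(cfg.n_layers):
            self.cells.append(_LSTMLayer(n_in, H, cfg.forget_bias, rng))
            n_in = H
        self.Wo = rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, cfg.n_classes))
        self.bo = np.zeros(cfg.n_classes)

    def parameters(self) -> list[np.ndarray]:
        ps = [self.Wp, self.bp]
        for cell in self.cells:
            ps += [cell.W, cell.b]
        ps += [self.Wo, self.bo]
        return ps

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, T, n_features)."""
        proj = X @ self.Wp + self.bp
        self._proj_mask = proj > 0
        out = proj * self._proj_mask
        self._X = X
        for cell in self.cells:
            out = cell.forward(out)
        self._last_h = out[:, -1]
        return self._last_h @ self.Wo + self.bo

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        self.dWo = self._last_h.T @ dlogits
        self.dbo = dlogits.sum(axis=0)
        N, T = self._X.shape[:2]
        H = self.cfg.hidden_size
        dH = np.zeros((N, T, H))
        dH[:, -1] = dlogits @ self.Wo.T
        d = dH
        for cell in reversed(self.cells):
            d = cell.backward(d)
        d = d * self._proj_mask
        dWp = self._X.reshape(-1, self._X.shape[2]).T @ d.reshape(-1, H)
        dbp = d.sum(axis=(0, 1))
        grads = [dWp, dbp]
        for cell in self.cells:
            grads += [cell.dW, cell.db]
        grads += [self.dWo, self.dbo]
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.forward(X))


def build_lstm(cfg: LSTMConfig) -> LSTMModel:
    model = LSTMModel(cfg)
    n = sum(p.size for p in model.parameters())
    logger.info("LSTM: %d layers x %d units, %d parameters",
                cfg.n_layers, cfg.hidden_size, n)
    return model


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _xent_and_grad(logits: np.ndarray, y: np.ndarray):
    N = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(N), y] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(N), y] -= 1.0
    dlogits /= N
    return loss, dlogits


def train_deep(
    model,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int | None = None,
    batch_size: int | None = None,
    lr: float | None = None,
    val_fraction: float = 0.2,
    patience: int | None = None,
    monitor: str = "val_accuracy",
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> TrainHistory:
    """Train a CNN/LSTM model with Adam, early stopping and weight restore.

    ``y`` holds integer class indices.  A seeded ``val_fraction`` of the
    rows is held out; the weights of the best validation epoch are
    restored at the end.  With ``patience`` set, training additionally
    stops once the monitored metric has not improved for that many
    consecutive epochs; by default the full ``epochs`` budget is used,
    because epoch selection from a small validation set is noisy enough
    that stopping early forfeits later, better epochs.  ``monitor`` is ``"val_accuracy"`` (default) or
    ``"val_loss"``: with small validation sets the cross-entropy loss is
    dominated by a few confidently-wrong items and can select
    under-trained epochs, so accuracy is the more robust default here.
    When ``groups`` (e.g. recording ids) are given, whole groups are held
    out, so overlapping windows of one recording never straddle the
    train/validation boundary and the monitored metric tracks
    generalization to unseen recordings.  A NaN loss aborts with
    diagnostics rather than continuing.
    """
    if monitor not in ("val_accuracy", "val_loss"):
        raise ValueError(f"unknown monitor {monitor!r}")
    cfg = model.cfg
    epochs = epochs if epochs is not None else cfg.epochs
    batch_size = batch_size if batch_size is not None else cfg.batch_size
    lr = lr if lr is not None else cfg.lr
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        logger.warning("training labels contain a single class")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if groups is not None:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        n_val_groups = max(1, int(round(val_fraction * len(uniq))))
        val_mask = np.isin(groups, uniq[:n_val_groups])
        val_idx = np.flatnonzero(val_mask)
        tr_idx = np.flatnonzero(~val_mask)
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    params = model.parameters()
    opt = _Adam(params, lr=lr)
    hist = TrainHistory()
    best_metric = -np.inf
    best_weights = None
    since_best = 0

    for epoch in range(epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(Xtr[idx], train=True)
            loss, dlogits = _xent_and_grad(logits, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}, "
                    f"batch {start // batch_size}"
                )
            grads = model.backward(dlogits)
            clip = getattr(cfg, "clip_norm", None)
            if clip is not None:
                norm = math.sqrt(sum(float((g * g).sum()) for g in grads))
                if norm > clip:
                    grads = [g * (clip / norm) for g in grads]
            opt.step(grads)
            losses.append(loss)
        val_logits = _batched_forward(model, Xval)
        val_loss, _ = _xent_and_grad(val_logits, yval)
        val_acc = float(np.mean(val_logits.argmax(axis=1) == yval))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        logger.info("epoch %d: train loss %.4f, val loss %.4f, val acc %.3f",
                    epoch, hist.train_loss[-1], val_loss, val_acc)
        # ties resolve toward the later epoch: among epochs the validation
        # set cannot distinguish, prefer the one trained longest
        metric = val_acc if monitor == "val_accuracy" else -val_loss
        if metric >= best_metric:
            best_metric = metric
            best_weights = [p.copy() for p in params]
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                logger.info("early stop at epoch %d", epoch)
                break
    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p[...] = w
    return hist


def _batched_forward(model, X: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [model.forward(X[i:i + batch]) for i in range(0, X.shape[0], batch)]
    return np.concatenate(outs) if outs else np.empty((0, model.cfg.n_classes))


def predict_classes(model, X: np.ndarray) -> np.ndarray:
    return _batched_forward(model, X).argmax(axis=1)
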