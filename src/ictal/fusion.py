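"""Two-input CNN-LSTM fusion classifier, implemented in numpy.

One input takes the raw analysis window as a sequence of short overlapping
sub-windows (33 x 50 samples for Bonn geometry); each sub-window passes
through three 1-D convolution layers (32 filters, kernel 3, relu) with one
max-pool (size 2) after the second, is flattened into a per-step feature
vector, and the sequence of step vectors feeds an LSTM with 64 units.  The
other input takes the handcrafted feature vector.  The LSTM state and the
handcrafted vector are concatenated and classified by two relu dense layers
of 128 units and a softmax output of 2 or 3 units.  Training uses the Adam
optimizer on the categorical cross-entropy, mini-batches, and a fixed seed
for weight initialisation and shuffling.

Forward and backward passes are hand-written (im2col convolutions,
max-pool argmax caching, full backpropagation through time for the LSTM)
and verified against numerical gradients in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ConfusionMatrix, MetricsReport, metrics_from_confusion

__all__ = ["FusionModelSpec", "FusionModel", "build_fusion_model",
           "train_fusion", "scale_raw_windows"]


@dataclass(frozen=True)
class FusionModelSpec:
    """Topology and training hyper-parameters of the fusion network."""

    conv_filters: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    lstm_units: int = 64
    dense_units: tuple[int, int] = (128, 128)
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 1-D convolution over the last-but-one axis.

    x: (B, S, L, Cin); w: (K, Cin, Cout); returns (B, S, L-K+1, Cout).
    """
    k = w.shape[0]
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    # cols: (B, S, Lout, Cin, K) -> (B, S, Lout, K*Cin)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 3))
    B, S, Lout = cols.shape[:3]
    cols2 = cols.reshape(B, S, Lout, -1)
    y = cols2 @ w.reshape(-1, w.shape[2]) + b
    return y, (cols2, x.shape, w.shape)


def _conv_backward(dy: np.ndarray, w: np.ndarray, cache):
    cols2, x_shape, w_shape = cache
    k, cin, cout = w_shape
    dw = np.tensordot(cols2, dy, axes=([0, 1, 2], [0, 1, 2]))
    dw = dw.reshape(k, cin, cout)
    db = dy.sum(axis=(0, 1, 2))
    dcols = dy @ w.reshape(-1, cout).T  # (B,S,Lout,K*Cin)
    B, S, Lout = dcols.shape[:3]
    dcols = dcols.reshape(B, S, Lout, k, cin)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    for kk in range(k):
        dx[:, :, kk:kk + Lout, :] += dcols[:, :, :, kk, :]
    return dx, dw, db


def _pool_forward(x: np.ndarray, size: int):
    B, S, L, C = x.shape
    Lp = L // size
    blocks = x[:, :, :Lp * size, :].reshape(B, S, Lp, size, C)
    arg = blocks.argmax(axis=3)
    y = np.take_along_axis(blocks, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, (arg, x.shape, size)


def _pool_backward(dy: np.ndarray, cache):
    arg, x_shape, size = cache
    B, S, L, C = x_shape
    Lp = dy.shape[2]
    dblocks = np.zeros((B, S, Lp, size, C), dtype=dy.dtype)
    np.put_along_axis(dblocks, arg[:, :, :, None, :], dy[:, :, :, None, :],
                      axis=3)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, :Lp * size, :] = dblocks.reshape(B, S, Lp * size, C)
    return dx


class FusionModel:
    """Trainable two-input CNN-LSTM; see the module docstring for topology."""

    def __init__(self, spec: FusionModelSpec, sub_window_shape: tuple[int, int],
                 n_handcrafted: int, n_classes: int, seed: int = 0,
                 dtype=np.float32):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.spec = spec
        self.S, self.L = sub_window_shape
        self.n_handcrafted = int(n_handcrafted)
        self.n_classes = n_classes
        self.dtype = dtype
        k, f = spec.kernel_size, spec.conv_filters
        L1 = self.L - k + 1
        L2 = L1 - k + 1
        if L2 < spec.pool_size:
            raise ValueError("sub-window too short for the conv/pool stack")
        Lp = L2 // spec.pool_size
        L3 = Lp - k + 1
        if L3 < 1:
            raise ValueError("sub-window too short for the third conv layer")
        self.step_dim = L3 * f
        rng = np.random.default_rng(seed)
        H = spec.lstm_units
        d1, d2 = spec.dense_units
        cat = H + self.n_handcrafted
        p = {}
        p["Wc1"] = _glorot(rng, (k, 1, f), k, f, dtype)
        p["bc1"] = np.zeros(f, dtype)
        p["Wc2"] = _glorot(rng, (k, f, f), k * f, f, dtype)
        p["bc2"] = np.zeros(f, dtype)
        p["Wc3"] = _glorot(rng, (k, f, f), k * f, f, dtype)
        p["bc3"] = np.zeros(f, dtype)
        p["Wx"] = _glorot(rng, (self.step_dim, 4 * H), self.step_dim, 4 * H, dtype)
        p["Wh"] = _glorot(rng, (H, 4 * H), H, 4 * H, dtype)
        p["bh"] = np.zeros(4 * H, dtype)
        p["bh"][H:2 * H] = 1.0  # forget-gate bias
        p["W1"] = _glorot(rng, (cat, d1), cat, d1, dtype)
        p["b1"] = np.zeros(d1, dtype)
        p["W2"] = _glorot(rng, (d1, d2), d1, d2, dtype)
        p["b2"] = np.zeros(d2, dtype)
        p["W3"] = _glorot(rng, (d2, n_classes), d2, n_classes, dtype)
        p["b3"] = np.zeros(n_classes, dtype)
        self.params = p
        self._adam_m = {k_: np.zeros_like(v) for k_, v in p.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in p.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------ fwd

    def forward(self, x_raw: np.ndarray, x_hand: np.ndarray | None,
                train: bool = False):
        """Class probabilities for a batch.

        x_raw: (B, S, L); x_hand: (B, F) or None when the handcrafted branch
        has zero width (ablation path).
        """
        p = self.params
        H = self.spec.lstm_units
        x = np.asarray(x_raw, self.dtype)[..., None]  # (B,S,L,1)
        B = x.shape[0]

        a1, c1 = _conv_forward(x, p["Wc1"], p["bc1"])
        r1 = np.maximum(a1, 0)
        a2, c2 = _conv_forward(r1, p["Wc2"], p["bc2"])
        r2 = np.maximum(a2, 0)
        pl, cp = _pool_forward(r2, self.spec.pool_size)
        a3, c3 = _conv_forward(pl, p["Wc3"], p["bc3"])
        r3 = np.maximum(a3, 0)
        steps = r3.reshape(B, self.S, self.step_dim)

        h = np.zeros((B, H), self.dtype)
        c = np.zeros((B, H), self.dtype)
        lstm_cache = []
        for t in range(self.S):
            z = steps[:, t, :] @ p["Wx"] + h @ p["Wh"] + p["bh"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            lstm_cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new

        if self.n_handcrafted:
            cat = np.concatenate([h, np.asarray(x_hand, self.dtype)], axis=1)
        else:
            cat = h
        z1 = cat @ p["W1"] + p["b1"]
        r_1 = np.maximum(z1, 0)
        z2 = r_1 @ p["W2"] + p["b2"]
        r_2 = np.maximum(z2, 0)
        logits = r_2 @ p["W3"] + p["b3"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        if not train:
            return probs
        cache = dict(x=x, c1=c1, a1=a1, c2=c2, a2=a2, cp=cp, c3=c3, a3=a3,
                     steps=steps, lstm=lstm_cache, h_last=h, cat=cat,
                     z1=z1, r1d=r_1, z2=z2, r2d=r_2)
        return probs, cache

    # ------------------------------------------------------------------ bwd

    def loss_and_grads(self, x_raw, x_hand, y_onehot):
        p = self.params
        H = self.spec.lstm_units
        probs, cache = self.forward(x_raw, x_hand, train=True)
        B = probs.shape[0]
        eps = np.finfo(self.dtype).tiny
        loss = float(-np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1)))

        g = {}
        dlogits = (probs - y_onehot).astype(self.dtype) / B
        g["W3"] = cache["r2d"].T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        dr2 = dlogits @ p["W3"].T
        dz2 = dr2 * (cache["z2"] > 0)
        g["W2"] = cache["r1d"].T @ dz2
        g["b2"] = dz2.sum(axis=0)
        dr1 = dz2 @ p["W2"].T
        dz1 = dr1 * (cache["z1"] > 0)
        g["W1"] = cache["cat"].T @ dz1
        g["b1"] = dz1.sum(axis=0)
        dcat = dz1 @ p["W1"].T
        dh = dcat[:, :H].copy()

        # backpropagation through time
        g["Wx"] = np.zeros_like(p["Wx"])
        g["Wh"] = np.zeros_like(p["Wh"])
        g["bh"] = np.zeros_like(p["bh"])
        dsteps = np.zeros_like(cache["steps"])
        dc = np.zeros_like(dh)
        for t in range(self.S - 1, -1, -1):
            h_prev, c_prev, i, f, gg, o, tc = cache["lstm"][t]
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * gg
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - gg * gg), do * o * (1 - o)], axis=1)
            g["Wx"] += cache["steps"][:, t, :].T @ dz
            g["Wh"] += h_prev.T @ dz
            g["bh"] += dz.sum(axis=0)
            dsteps[:, t, :] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T
            dc = dc * f

        dr3 = dsteps.reshape(cache["a3"].shape)
        da3 = dr3 * (cache["a3"] > 0)
        dpl, g["Wc3"], g["bc3"] = _conv_backward(da3, p["Wc3"], cache["c3"])
        dr2c = _pool_backward(dpl, cache["cp"])
        da2 = dr2c * (cache["a2"] > 0)
        dr1c, g["Wc2"], g["bc2"] = _conv_backward(da2, p["Wc2"], cache["c2"])
        da1 = dr1c * (cache["a1"] > 0)
        _, g["Wc1"], g["bc1"] = _conv_backward(da1, p["Wc1"], cache["c1"])
        return loss, g

    # ----------------------------------------------------------------- train

    def _adam_step(self, grads: dict) -> None:
        s = self.spec
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk * gk
            mhat = self._adam_m[k] / (1 - b1**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2**self._adam_t)
            self.params[k] -= (s.learning_rate * mhat
                               / (np.sqrt(vhat) + eps)).astype(self.dtype)

    def fit(self, x_raw, x_hand, y, epochs: int | None = None,
            seed: int = 0, verbose: bool = False) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss."""
        classes = np.unique(y)
        onehot = (np.asarray(y)[:, None] == classes[None, :]).astype(self.dtype)
        self.classes_ = classes
        n = onehot.shape[0]
        rng = np.random.default_rng(seed)
        history = []
        for epoch in range(epochs or self.spec.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.spec.batch_size):
                idx = order[start:start + self.spec.batch_size]
                xb = x_raw[idx]
                hb = x_hand[idx] if self.n_handcrafted else None
                loss, grads = self.loss_and_grads(xb, hb, onehot[idx])
                self._adam_step(grads)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}: loss {history[-1]:.4f}")
        return history

    def predict(self, x_raw, x_hand, batch_size: int = 256) -> np.ndarray:
        preds = []
        for start in range(0, x_raw.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            hb = x_hand[sl] if self.n_handcrafted else None
            probs = self.forward(x_raw[sl], hb)
            preds.append(self.classes_[np.argmax(probs, axis=1)])
        return np.concatenate(preds)


def build_fusion_model(spec: FusionModelSpec, sub_window_shape: tuple[int, int],
                       n_handcrafted: int, n_classes: int,
                       seed: int = 0) -> FusionModel:
    return FusionModel(spec, sub_window_shape, n_handcrafted, n_classes,
                       seed=seed)


def scale_raw_windows(x_raw: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-window amplitude scaling: each window divided by its own std."""
    sd = x_raw.std(axis=(1, 2), keepdims=True)
    return x_raw / (sd + eps)


def train_fusion(raw_subwindows: np.ndarray, handcrafted: np.ndarray | None,
                 labels: np.ndarray, spec: FusionModelSpec = FusionModelSpec(),
                 cv=None, epochs: int | None = None,
                 seed: int = 0) -> MetricsReport:
    """K-fold cross-validated training of the fusion network.

    raw_subwindows: (n, S, L) per-window sub-window stacks; handcrafted:
    (n, F) feature matrix or None for the raw-only ablation.  The raw branch
    is per-window amplitude scaled; the handcrafted branch is z-scored with
    training-fold statistics.  Returns pooled metrics with per-fold values.
    """
    from .classify import CVConfig, kfold_split  # local import avoids cycle

    cv = cv or CVConfig(seed=seed)
    labels = np.asarray(labels)
    n = labels.size
    if n < cv.k:
        raise ValueError("fewer rows than folds")
    x_raw = scale_raw_windows(np.asarray(raw_subwindows, float))
    n_hand = 0 if handcrafted is None else np.asarray(handcrafted).shape[1]
    classes = np.unique(labels)
    pooled = None
    per_fold = []
    for fold, (tr, te) in enumerate(kfold_split(labels, cv)):
        if n_hand:
            hand = np.asarray(handcrafted, float)
            mu = hand[tr].mean(axis=0)
            sd = hand[tr].std(axis=0)
            sd[sd == 0] = 1.0
            hz = (hand - mu) / sd
        else:
            hz = None
        model = FusionModel(spec, x_raw.shape[1:], n_hand, classes.size,
                            seed=cv.seed + fold)
        model.fit(x_raw[tr], None if hz is None else hz[tr], labels[tr],
                  epochs=epochs, seed=cv.seed + fold)
        pred = model.predict(x_raw[te], None if hz is None else hz[te])
        cm = ConfusionMatrix.from_labels(labels[te], pred, classes=classes)
        pooled = cm if pooled is None else pooled + cm
        mv = metrics_from_confusion(cm)
        per_fold.append({"acc": mv.acc, "sens": mv.sens, "spec": mv.spec,
                         "prec": mv.prec, "f1": mv.f1})
    report = metrics_from_confusion(pooled)
    report.per_fold = per_fold
    return report
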