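"""Minimal seeded neural-network engine (numpy, CPU, deterministic).

Implements exactly the two compact architectures the pipeline needs — a
shallow spectral-spatial CNN and a single/multi-layer LSTM — with manual
reverse-mode gradients and an Adam optimizer.  Everything is plain numpy
(float32 by default for speed, float64 available for gradient checks),
single-threaded and fully determined by the seed, which makes training
runs bit-reproducible (a contract the pipeline's determinism tests rely
on).

Gradient correctness is established by finite-difference checks in the
test suite rather than trusted by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Adam:
    """Standard Adam; state keyed like the parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# shallow spectral-spatial CNN
# ---------------------------------------------------------------------------

class ShallowCNN:
    """Temporal conv -> spatial conv -> square -> average-pool -> dense softmax.

    Input ``(batch, channels, samples)``.  The temporal convolution acts as
    a learned band-pass filter bank shared across channels; the spatial
    convolution spans the full montage; squaring + average pooling computes
    band power over time windows, which is precisely the ERD/ERS feature
    family.  Inputs are expected spatially whitened (see the training
    routine): with isotropic background noise the class-modulated source
    direction dominates the quadratic feature gradients, which is what
    makes the spatial filters learnable from a few hundred trials.

    Both convolutions are evaluated as im2col + GEMM so that training a
    full 118-channel montage stays fast on one CPU; ``dtype=float32`` is
    the training default, ``float64`` is used by the gradient-check tests.
    """

    def __init__(self, n_channels: int, n_samples: int, *,
                 temporal_kernel: int = 11, n_temporal_filters: int = 8,
                 n_spatial_filters: int = 16, pool_factor: int = 4,
                 n_classes: int = 2, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        k, f1, f2, p = temporal_kernel, n_temporal_filters, n_spatial_filters, pool_factor
        if n_samples < k:
            raise ValueError("trial shorter than temporal kernel")
        self.k, self.f1, self.f2, self.p = k, f1, f2, p
        self.dtype = np.dtype(dtype)
        self.n_channels, self.n_samples = n_channels, n_samples
        t_conv = n_samples - k + 1
        self.t_pool = t_conv // p
        self.t_conv = t_conv
        if self.t_pool < 1:
            raise ValueError("pool_factor too large for this trial length")
        n_feat = f2 * self.t_pool
        d = self.dtype
        self.params = {
            "Wt": rng.normal(0, 1.0 / np.sqrt(k), size=(f1, k)).astype(d),
            "bt": np.zeros(f1, dtype=d),
            "Ws": rng.normal(0, 1.0 / np.sqrt(f1 * n_channels),
                             size=(f2, f1, n_channels)).astype(d),
            "bs": np.zeros(f2, dtype=d),
            "Wd": rng.normal(0, 1.0 / np.sqrt(n_feat), size=(n_feat, n_classes)).astype(d),
            "bd": np.zeros(n_classes, dtype=d),
        }

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, C, T) -> contiguous (B*T', C*k), rows ordered (b, t)."""
        xs = sliding_window_view(np.asarray(x), self.k, axis=2)  # (B,C,T',k)
        xs = np.ascontiguousarray(xs.transpose(0, 2, 1, 3), dtype=self.dtype)
        return xs.reshape(-1, self.n_channels * self.k)

    def _combined_kernel(self):
        """The two stacked linear convolutions collapse into one space-time
        kernel W2[g,c,k] = sum_f Ws[g,f,c] * Wt[f,k] (and an effective bias),
        which avoids materialising the (B,T',F1,C) intermediate."""
        P = self.params
        W2 = np.einsum("gfc,fk->gck", P["Ws"], P["Wt"])
        beff = np.einsum("gfc,f->g", P["Ws"], P["bt"]) + P["bs"]
        return W2, beff

    def forward(self, x: np.ndarray, want_cache: bool = False):
        P = self.params
        batch = len(x)
        f2 = self.f2
        xcol = self._im2col(x)
        W2, beff = self._combined_kernel()
        h2 = xcol @ W2.reshape(f2, -1).T + beff               # (B*T', F2)
        s = (h2 * h2).reshape(batch, self.t_conv, f2)
        t_used = self.t_pool * self.p
        pooled = s[:, :t_used].reshape(batch, self.t_pool, self.p, f2).mean(axis=2)
        zf = pooled.reshape(batch, -1)
        logits = zf @ P["Wd"] + P["bd"]
        if not want_cache:
            return logits
        return logits, (xcol, h2, pooled, zf)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        P = self.params
        C, f1, f2, k = self.n_channels, self.f1, self.f2, self.k
        logits, (xcol, h2, pooled, zf) = self.forward(x, want_cache=True)
        loss, dlogits = cross_entropy(logits, y)
        dlogits = dlogits.astype(self.dtype)

        grads = {}
        grads["Wd"] = zf.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dpooled = (dlogits @ P["Wd"].T).reshape(len(x), self.t_pool, f2)
        t_used = self.t_pool * self.p
        ds = np.zeros((len(x), self.t_conv, f2), dtype=self.dtype)
        ds[:, :t_used] = np.repeat(dpooled / self.p, self.p, axis=1)
        dh2 = (2.0 * h2.reshape(len(x), self.t_conv, f2) * ds).reshape(-1, f2)

        # grads flow through the combined kernel back to the two factors
        dW2 = (dh2.T @ xcol).reshape(f2, C, k)
        dbeff = dh2.sum(axis=0)
        grads["Ws"] = (
            np.einsum("gck,fk->gfc", dW2, P["Wt"])
            + dbeff[:, None, None] * P["bt"][None, :, None]
        )
        grads["Wt"] = np.einsum("gck,gfc->fk", dW2, P["Ws"])
        grads["bs"] = dbeff
        grads["bt"] = np.einsum("g,gfc->f", dbeff, P["Ws"])
        return loss, grads


# ---------------------------------------------------------------------------
# LSTM sequence classifier
# ---------------------------------------------------------------------------

def _lstm_layer_forward(x: np.ndarray, Wx, Wh, b):
    """x: (B, T, D) -> hidden sequence (B, T, H) plus BPTT cache."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    hs = np.empty((B, T, H), dtype=x.dtype)
    cache = []
    for t in range(T):
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev_cache = h
        h = o * tc
        hs[:, t] = h
        cache.append((i, f, g, o, c_prev, tc, h_prev_cache))
    return hs, cache


def _lstm_layer_backward(x, hs, cache, dhs, Wx, Wh):
    """dhs: (B, T, H) upstream grads on the hidden sequence.

    Returns (dx, dWx, dWh, db)."""
    B, T, D = x.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=x.dtype)
    dx = np.empty_like(x)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dc_next = np.zeros((B, H), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate([
            di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o),
        ], axis=1)
        dWx += x[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dx, dWx, dWh, db


class LSTMClassifier:
    """(Stacked) LSTM over channel vectors per timestep; mean hidden state
    over time feeds a dense softmax layer."""

    def __init__(self, n_inputs: int, *, hidden_units: int = 64, n_layers: int = 1,
                 n_classes: int = 2, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.H, self.n_layers = hidden_units, n_layers
        self.dtype = np.dtype(dtype)
        self.params = {}
        d = n_inputs
        for l in range(n_layers):
            scale_x = 1.0 / np.sqrt(d)
            scale_h = 1.0 / np.sqrt(hidden_units)
            self.params[f"Wx{l}"] = rng.normal(
                0, scale_x, size=(d, 4 * hidden_units)).astype(self.dtype)
            self.params[f"Wh{l}"] = rng.normal(
                0, scale_h, size=(hidden_units, 4 * hidden_units)).astype(self.dtype)
            b = np.zeros(4 * hidden_units, dtype=self.dtype)
            b[hidden_units:2 * hidden_units] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
            d = hidden_units
        self.params["Wd"] = rng.normal(0, 1.0 / np.sqrt(hidden_units),
                                       size=(hidden_units, n_classes)).astype(self.dtype)
        self.params["bd"] = np.zeros(n_classes, dtype=self.dtype)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        P = self.params
        seqs = [np.ascontiguousarray(x, dtype=self.dtype)]
        caches = []
        for l in range(self.n_layers):
            hs, cache = _lstm_layer_forward(seqs[-1], P[f"Wx{l}"], P[f"Wh{l}"], P[f"b{l}"])
            seqs.append(hs)
            caches.append(cache)
        hbar = seqs[-1].mean(axis=1)
        logits = hbar @ P["Wd"] + P["bd"]
        if not want_cache:
            return logits
        return logits, (seqs, caches, hbar)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        P = self.params
        logits, (seqs, caches, hbar) = self.forward(x, want_cache=True)
        loss, dlogits = cross_entropy(logits, y)
        dlogits = dlogits.astype(self.dtype)
        grads = {"Wd": hbar.T @ dlogits, "bd": dlogits.sum(axis=0)}
        T = x.shape[1]
        dhs = np.broadcast_to(
            (dlogits @ P["Wd"].T)[:, None, :] / T, seqs[-1].shape
        ).copy()
        for l in range(self.n_layers - 1, -1, -1):
            dx, dWx, dWh, db = _lstm_layer_backward(
                seqs[l], seqs[l + 1], caches[l], dhs, P[f"Wx{l}"], P[f"Wh{l}"]
            )
            grads[f"Wx{l}"] = dWx
            grads[f"Wh{l}"] = dWh
            grads[f"b{l}"] = db
            dhs = dx
        return loss, grads


# ---------------------------------------------------------------------------
# seeded mini-batch training with early stopping
# ---------------------------------------------------------------------------

@dataclass
class FitHistory:
    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    best_epoch: int
    n_epochs_run: int


def fit(model, X: np.ndarray, y: np.ndarray, X_val: np.ndarray, y_val: np.ndarray, *,
        batch_size: int = 32, max_epochs: int = 100, patience: int = 10,
        min_epochs: int = 40, learning_rate: float = 1e-3,
        weight_decay: float = 0.0, rng: np.random.Generator) -> FitHistory:
    """Mini-batch Adam with L2 weight penalty and early stopping on
    validation loss.

    The L2 term applies to weight matrices only (not biases).  Early
    stopping is suspended for the first ``min_epochs`` epochs: with small
    validation sets the loss is noisy early on and a lucky minimum in the
    first epochs would otherwise freeze the model before the spatial
    filters are learned.  Restores the best-validation parameters before
    returning.  Deterministic given the rng state.
    """
    opt = Adam(model.params, lr=learning_rate)
    best = {k: v.copy() for k, v in model.params.items()}
    best_loss = np.inf
    best_epoch = -1
    hist = FitHistory([], [], [], -1, 0)
    since_best = 0
    n = len(X)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = model.loss_and_grads(X[idx], y[idx])
            if weight_decay:
                for k, v in model.params.items():
                    if v.ndim >= 2:
                        grads[k] = grads[k] + weight_decay * v
            opt.step(model.params, grads)
            losses.append(loss)
        vlogits = model.forward(X_val)
        vloss, _ = cross_entropy(vlogits, y_val)
        vacc = float(np.mean(vlogits.argmax(axis=1) == y_val))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(vloss))
        hist.val_accuracy.append(vacc)
        hist.n_epochs_run = epoch + 1
        if vloss < best_loss - 1e-6:
            best_loss = vloss
            best = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if epoch + 1 >= min_epochs and since_best >= patience:
                break
    model.params.update(best)
    hist.best_epoch = best_epoch
    return hist
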