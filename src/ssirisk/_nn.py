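"""NumPy building blocks for the deep risk models.

Implements exactly the two fusion architectures used by the package —
a convolutional text network and a Bi-LSTM self-attention network, each
concatenating its text representation with the structured feature vector
before a GELU dense layer and a sigmoid output — with hand-written
forward/backward passes and an AdamW optimizer (decoupled weight decay).

Conventions shared by both networks:

* sequences are left-padded token-id matrices; the id ``V`` (one past the
  vocabulary) is the pad row of the embedding matrix and is pinned to the
  zero vector;
* pad positions are masked out of convolutional max-pooling (a window is
  valid when it contains at least one real token) and out of the
  attention softmax (probability mass lives on real positions only);
* GELU is the exact Gaussian-CDF form x * Phi(x);
* dropout is inverted dropout, active only during training.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

F32 = np.float32


def gelu(x):
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def dgelu(x):
    phi = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * phi


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def softmax_masked(scores, mask):
    """Softmax over the last axis restricted to mask==1 positions.

    Rows with no valid position come back all-zero.
    """
    neg = np.where(mask > 0, scores, -np.inf)
    mx = np.max(neg, axis=-1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    e = np.exp(neg - mx) * (mask > 0)
    s = e.sum(axis=-1, keepdims=True)
    return np.divide(e, s, out=np.zeros_like(e), where=s > 0)


def _dropout(x, rate, rng, train):
    if not train or rate <= 0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


class AdamW:
    """AdamW over a dict of parameter arrays; decay skips listed names."""

    def __init__(self, params: dict, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, no_decay=()):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.no_decay = set(no_decay)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict):
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            if self.weight_decay and k not in self.no_decay:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_bce_grad(logits, y, pos_weight):
    """Class-weighted cross-entropy (mean over batch) and d loss / d logit."""
    p = sigmoid(logits)
    eps = 1e-12
    w = np.where(y == 1, pos_weight, 1.0)
    loss = -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).mean()
    dlogit = w * (p - y) / len(y)
    return float(loss), dlogit


def _glorot(rng, shape):
    lim = math.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-lim, lim, size=shape).astype(F32)


# ---------------------------------------------------------------------------
# convolutional text network
# ---------------------------------------------------------------------------

class CNNNet:
    """Text CNN + structured fusion.

    Per filter-window size h: a sliding dot product over h consecutive
    embedding rows per channel with GELU activation, max-pooled over valid
    window positions; the pooled vectors for all window sizes are
    concatenated with the structured features, passed through a GELU dense
    layer and a sigmoid output unit.
    """

    def __init__(self, emb_init: np.ndarray, n_struct: int,
                 windows=(3, 4, 5), channels=256, dense_units=128,
                 dropout_emb=0.0, dropout_conv=0.35, dropout_dense=0.5,
                 seed=0):
        rng = np.random.default_rng(seed)
        self.windows = tuple(windows)
        self.channels = channels
        self.dropout_emb, self.dropout_conv, self.dropout_dense = \
            dropout_emb, dropout_conv, dropout_dense
        V1, d = emb_init.shape  # includes pad row (last)
        self.d = d
        self.pad_id = V1 - 1
        p = {"E": emb_init.astype(F32).copy()}
        for h in self.windows:
            p[f"Wc{h}"] = _glorot(rng, (h * d, channels))
            p[f"bc{h}"] = np.zeros(channels, dtype=F32)
        fused = len(self.windows) * channels + n_struct
        p["W1"] = _glorot(rng, (fused, dense_units))
        p["b1"] = np.zeros(dense_units, dtype=F32)
        p["w2"] = _glorot(rng, (dense_units, 1))[:, 0]
        p["b2"] = np.zeros(1, dtype=F32)
        p["E"][self.pad_id] = 0.0
        self.params = p
        self.no_decay = {"bc%d" % h for h in self.windows} | {"b1", "b2"}

    def forward(self, ids, lengths, Xs, train=False, rng=None):
        p = self.params
        B, n = ids.shape
        emb = p["E"][ids]                                   # (B, n, d)
        emb, kemb = _dropout(emb, self.dropout_emb, rng, train)
        pooled_list, cache_conv = [], []
        for h in self.windows:
            npos = n - h + 1
            if npos < 1:
                raise ValueError(f"filter window {h} exceeds padded length {n}")
            sw = np.lib.stride_tricks.sliding_window_view(emb, h, axis=1)
            Xcol = np.ascontiguousarray(sw.transpose(0, 1, 3, 2)).reshape(B, npos, h * self.d)
            pre = Xcol @ p[f"Wc{h}"] + p[f"bc{h}"]           # (B, npos, m)
            act = gelu(pre)
            # window valid iff it contains >= 1 real token: i + h - 1 >= n - len
            pos = np.arange(npos)[None, :]
            valid = pos >= (n - lengths[:, None] - h + 1)
            neg = np.where(valid[:, :, None], act, -np.inf)
            arg = neg.argmax(axis=1)                         # (B, m)
            pooled = np.take_along_axis(act, arg[:, None, :], axis=1)[:, 0, :]
            pooled = np.where(valid.any(axis=1)[:, None], pooled, 0.0)
            pooled_list.append(pooled)
            cache_conv.append((Xcol, pre, arg, valid))
        pooled_all = np.concatenate(pooled_list, axis=1)
        pooled_all, kconv = _dropout(pooled_all, self.dropout_conv, rng, train)
        fused = np.concatenate([pooled_all, Xs], axis=1)
        z1 = fused @ p["W1"] + p["b1"]
        a1 = gelu(z1)
        a1d, kdense = _dropout(a1, self.dropout_dense, rng, train)
        logit = a1d @ p["w2"] + p["b2"][0]
        cache = (ids, emb, kemb, cache_conv, kconv, fused, z1, a1, a1d, kdense, lengths)
        return logit, cache

    def backward(self, cache, dlogit):
        p = self.params
        ids, emb, kemb, cache_conv, kconv, fused, z1, a1, a1d, kdense, lengths = cache
        B, n, d = emb.shape
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["w2"] = a1d.T @ dlogit
        g["b2"] = np.array([dlogit.sum()], dtype=F32)
        da1 = np.outer(dlogit, p["w2"])
        if kdense is not None:
            da1 = da1 * kdense
        dz1 = da1 * dgelu(z1)
        g["W1"] = fused.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        dfused = dz1 @ p["W1"].T
        m = self.channels
        dpooled_all = dfused[:, :len(self.windows) * m]
        if kconv is not None:
            dpooled_all = dpooled_all * kconv
        demb = np.zeros_like(emb)
        for wi, h in enumerate(self.windows):
            Xcol, pre, arg, valid = cache_conv[wi]
            npos = pre.shape[1]
            dpool = dpooled_all[:, wi * m:(wi + 1) * m]
            dpool = dpool * valid.any(axis=1)[:, None]
            dact = np.zeros_like(pre)
            np.put_along_axis(dact, arg[:, None, :], dpool[:, None, :], axis=1)
            dpre = dact * dgelu(pre)
            g[f"Wc{h}"] = np.einsum("bpf,bpm->fm", Xcol, dpre)
            g[f"bc{h}"] = dpre.sum(axis=(0, 1))
            dXcol = dpre @ p[f"Wc{h}"].T                     # (B, npos, h*d)
            dXcol = dXcol.reshape(B, npos, h, d)
            for i in range(h):
                demb[:, i:i + npos] += dXcol[:, :, i]
        if kemb is not None:
            demb = demb * kemb
        np.add.at(g["E"], ids, demb)
        g["E"][self.pad_id] = 0.0
        return g


# ---------------------------------------------------------------------------
# Bi-LSTM self-attention network
# ---------------------------------------------------------------------------

def _lstm_forward(x, mask, Wx, Wh, b, reverse=False):
    """Single-direction LSTM over (B, n, d) with position mask (B, n).

    Returns hidden states (B, n, m) and caches for backprop.  Masked
    positions keep zero state, which is exact for left padding.
    """
    B, n, d = x.shape
    m = Wh.shape[0]
    dt = np.result_type(x.dtype, Wx.dtype)
    h = np.zeros((B, m), dtype=dt)
    c = np.zeros((B, m), dtype=dt)
    order = range(n - 1, -1, -1) if reverse else range(n)
    H = np.zeros((B, n, m), dtype=dt)
    caches = {}
    for t in order:
        z = x[:, t] @ Wx + h @ Wh + b
        zi, zf, zg, zo = np.split(z, 4, axis=1)
        i, f, o = sigmoid(zi), sigmoid(zf), sigmoid(zo)
        gt = np.tanh(zg)
        c_raw = f * c + i * gt
        h_raw = o * np.tanh(c_raw)
        mt = mask[:, t:t + 1]
        caches[t] = (x[:, t], h.copy(), c.copy(), i, f, gt, o, c_raw, mt)
        c = mt * c_raw
        h = mt * h_raw
        H[:, t] = h
    return H, caches


def _lstm_backward(dH, caches, x_shape, Wx, Wh, reverse=False):
    B, n, d = x_shape
    m = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * m, dtype=Wx.dtype)
    dx = np.zeros(x_shape, dtype=Wx.dtype)
    dh_next = np.zeros((B, m), dtype=Wx.dtype)
    dc_next = np.zeros((B, m), dtype=Wx.dtype)
    order = range(n) if reverse else range(n - 1, -1, -1)
    for t in order:
        xt, h_prev, c_prev, i, f, gt, o, c_raw, mt = caches[t]
        dh = dH[:, t] + dh_next
        dh_raw = dh * mt
        tc = np.tanh(c_raw)
        dc_raw = dc_next * mt + dh_raw * o * (1 - tc * tc)
        do = dh_raw * tc
        df = dc_raw * c_prev
        di = dc_raw * gt
        dg = dc_raw * i
        dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - gt * gt), do * o * (1 - o)], axis=1)
        dWx += xt.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc_raw * f
    return dx, dWx, dWh, db


class AttnNet:
    """Bi-LSTM with structured self-attention + structured fusion.

    The padded embedding sequence runs through forward and backward LSTMs
    (hidden size m each), giving H of shape (n, 2m) per note.  Attention
    weights A = softmax(W1 . tanh(W2 . H^T)) are d2 distributions over the
    real positions; the sentence embedding M = A . H is flattened, fused
    with the structured features, and passed through a GELU dense layer
    and a sigmoid output unit.  W1 and W2 are bias-free.
    """

    def __init__(self, emb_init: np.ndarray, n_struct: int, m=256,
                 d1=256, d2=64, dense_units=128,
                 dropout_emb=0.5, dropout_lstm=0.45, dropout_dense=0.0,
                 seed=0):
        rng = np.random.default_rng(seed)
        V1, d = emb_init.shape
        self.d, self.m, self.d1, self.d2 = d, m, d1, d2
        self.pad_id = V1 - 1
        self.dropout_emb, self.dropout_lstm, self.dropout_dense = \
            dropout_emb, dropout_lstm, dropout_dense
        p = {"E": emb_init.astype(F32).copy()}
        for tag in ("f", "b"):
            p[f"Wx_{tag}"] = _glorot(rng, (d, 4 * m))
            p[f"Wh_{tag}"] = _glorot(rng, (m, 4 * m))
            bias = np.zeros(4 * m, dtype=F32)
            bias[m:2 * m] = 1.0  # forget-gate bias
            p[f"b_{tag}"] = bias
        p["W2"] = _glorot(rng, (d1, 2 * m))
        p["W1"] = _glorot(rng, (d2, d1))
        fused = d2 * 2 * m + n_struct
        p["Wd"] = _glorot(rng, (fused, dense_units))
        p["bd"] = np.zeros(dense_units, dtype=F32)
        p["w_out"] = _glorot(rng, (dense_units, 1))[:, 0]
        p["b_out"] = np.zeros(1, dtype=F32)
        p["E"][self.pad_id] = 0.0
        self.params = p
        self.no_decay = {"b_f", "b_b", "bd", "b_out"}

    def forward(self, ids, lengths, Xs, train=False, rng=None):
        p = self.params
        B, n = ids.shape
        mask = (np.arange(n)[None, :] >= (n - lengths[:, None])).astype(F32)
        emb = p["E"][ids]
        emb, kemb = _dropout(emb, self.dropout_emb, rng, train)
        Hf, cf = _lstm_forward(emb, mask, p["Wx_f"], p["Wh_f"], p["b_f"])
        Hb, cb = _lstm_forward(emb, mask, p["Wx_b"], p["Wh_b"], p["b_b"], reverse=True)
        H = np.concatenate([Hf, Hb], axis=2)                # (B, n, 2m)
        Hd, klstm = _dropout(H, self.dropout_lstm, rng, train)
        U = np.tanh(Hd @ p["W2"].T)                         # (B, n, d1)
        S = (U @ p["W1"].T).transpose(0, 2, 1)              # (B, d2, n)
        A = softmax_masked(S, mask[:, None, :])             # (B, d2, n)
        M = A @ Hd                                          # (B, d2, 2m)
        flat = M.reshape(B, -1)
        fused = np.concatenate([flat, Xs], axis=1)
        z1 = fused @ p["Wd"] + p["bd"]
        a1 = gelu(z1)
        a1d, kdense = _dropout(a1, self.dropout_dense, rng, train)
        logit = a1d @ p["w_out"] + p["b_out"][0]
        cache = (ids, emb, kemb, mask, Hf, cf, Hb, cb, Hd, klstm, U, A,
                 fused, z1, a1, a1d, kdense)
        return logit, cache, A

    def backward(self, cache, dlogit):
        p = self.params
        (ids, emb, kemb, mask, Hf, cf, Hb, cb, Hd, klstm, U, A,
         fused, z1, a1, a1d, kdense) = cache
        B, n, _ = emb.shape
        m = self.m
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["w_out"] = a1d.T @ dlogit
        g["b_out"] = np.array([dlogit.sum()], dtype=F32)
        da1 = np.outer(dlogit, p["w_out"])
        if kdense is not None:
            da1 = da1 * kdense
        dz1 = da1 * dgelu(z1)
        g["Wd"] = fused.T @ dz1
        g["bd"] = dz1.sum(axis=0)
        dfused = dz1 @ p["Wd"].T
        dM = dfused[:, :self.d2 * 2 * m].reshape(B, self.d2, 2 * m)
        dA = np.einsum("bqm,bnm->bqn", dM, Hd)
        dHd = np.einsum("bqn,bqm->bnm", A, dM)
        # softmax backward (per attention row, over positions)
        dS = A * (dA - (dA * A).sum(axis=2, keepdims=True))  # (B, d2, n)
        dU = np.einsum("bqn,qk->bnk", dS, p["W1"])
        g["W1"] = np.einsum("bqn,bnk->qk", dS, U)
        dpre = dU * (1 - U * U)                              # (B, n, d1)
        g["W2"] = np.einsum("bnk,bnm->km", dpre, Hd)
        dHd += dpre @ p["W2"]
        if klstm is not None:
            dHd = dHd * klstm
        dHf = dHd[:, :, :m]
        dHb = dHd[:, :, m:]
        dx_f, dWxf, dWhf, dbf = _lstm_backward(dHf, cf, emb.shape, p["Wx_f"], p["Wh_f"])
        dx_b, dWxb, dWhb, dbb = _lstm_backward(dHb, cb, emb.shape, p["Wx_b"],
                                               p["Wh_b"], reverse=True)
        g["Wx_f"], g["Wh_f"], g["b_f"] = dWxf, dWhf, dbf
        g["Wx_b"], g["Wh_b"], g["b_b"] = dWxb, dWhb, dbb
        demb = dx_f + dx_b
        if kemb is not None:
            demb = demb * kemb
        np.add.at(g["E"], ids, demb)
        g["E"][self.pad_id] = 0.0
        return g
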