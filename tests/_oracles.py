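"""Independent straight-line oracle implementations used by the tests.

Everything here is deliberately written as plain loops over scalars /
small vectors, independent of the package's vectorized implementations,
so agreement between the two is meaningful.
"""

import math

import numpy as np


def phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def gelu_scalar(x: float) -> float:
    return x * phi(x)


def sigmoid_scalar(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def cnn_oracle(padded, structured, length, windows, conv_w, conv_b,
               W1, b1, w2, b2):
    """Loop CNN: conv windows, GELU, masked max-pool, dense, sigmoid.

    conv_w[h] has shape (h, d, m); conv_b[h] has shape (m,).
    A pooling window is valid when it touches >= 1 real (non-pad) token.
    """
    padded = np.asarray(padded, dtype=float)
    n, d = padded.shape
    pooled_all = []
    maps = {}
    for h in windows:
        m = conv_b[h].shape[0]
        fmap = np.zeros((n - h + 1, m))
        for i in range(n - h + 1):
            for j in range(m):
                s = conv_b[h][j]
                for a in range(h):
                    for k in range(d):
                        s += conv_w[h][a, k, j] * padded[i + a, k]
                fmap[i, j] = gelu_scalar(s)
        maps[h] = fmap
        pooled = np.zeros(m)
        first_valid = n - length - h + 1  # i >= this touches a real token
        valid = [i for i in range(n - h + 1) if i >= first_valid]
        for j in range(m):
            pooled[j] = max(fmap[i, j] for i in valid) if valid else 0.0
        pooled_all.append(pooled)
    fused = np.concatenate(pooled_all + [np.asarray(structured, dtype=float)])
    a1 = np.array([gelu_scalar(z) for z in fused @ W1 + b1])
    return sigmoid_scalar(float(a1 @ w2 + b2)), maps


def lstm_oracle(x, length, Wx, Wh, b, reverse=False):
    """Loop LSTM over one left-padded sequence (n, d) -> (n, m)."""
    n, d = x.shape
    m = Wh.shape[0]
    h = np.zeros(m)
    c = np.zeros(m)
    H = np.zeros((n, m))
    order = range(n - 1, -1, -1) if reverse else range(n)
    for t in order:
        real = t >= n - length
        z = x[t] @ Wx + h @ Wh + b
        i = 1 / (1 + np.exp(-z[:m]))
        f = 1 / (1 + np.exp(-z[m:2 * m]))
        g = np.tanh(z[2 * m:3 * m])
        o = 1 / (1 + np.exp(-z[3 * m:]))
        c_raw = f * c + i * g
        h_raw = o * np.tanh(c_raw)
        c = c_raw if real else np.zeros(m)
        h = h_raw if real else np.zeros(m)
        H[t] = h
    return H


def attention_oracle(padded, structured, length, Wx_f, Wh_f, b_f,
                     Wx_b, Wh_b, b_b, W2, W1, Wd, bd, w_out, b_out):
    """Loop Bi-LSTM + self-attention + fusion for one sequence."""
    padded = np.asarray(padded, dtype=float)
    n, d = padded.shape
    m = Wh_f.shape[0]
    Hf = lstm_oracle(padded, length, Wx_f, Wh_f, b_f)
    Hb = lstm_oracle(padded, length, Wx_b, Wh_b, b_b, reverse=True)
    H = np.concatenate([Hf, Hb], axis=1)                 # (n, 2m)
    d1 = W2.shape[0]
    d2 = W1.shape[0]
    S = np.zeros((d2, n))
    for q in range(d2):
        for t in range(n):
            u = np.array([math.tanh(W2[k] @ H[t]) for k in range(d1)])
            S[q, t] = W1[q] @ u
    A = np.zeros((d2, n))
    for q in range(d2):
        real = [t for t in range(n) if t >= n - length]
        mx = max(S[q, t] for t in real)
        Z = sum(math.exp(S[q, t] - mx) for t in real)
        for t in real:
            A[q, t] = math.exp(S[q, t] - mx) / Z
    M = A @ H                                            # (d2, 2m)
    fused = np.concatenate([M.reshape(-1), np.asarray(structured, dtype=float)])
    a1 = np.array([gelu_scalar(z) for z in fused @ Wd + bd])
    return sigmoid_scalar(float(a1 @ w_out + b_out)), A


def auroc_allpairs(scores, labels) -> float:
    """All-pairs counting AUROC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Best (threshold, sens, spec, J); ties -> lowest threshold."""
    best = None
    n_pos = sum(1 for y in labels if y == 1)
    n_neg = sum(1 for y in labels if y == 0)
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= t)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < t)
        sens, spec = tp / n_pos, tn / n_neg
        j = sens + spec - 1
        if best is None or j > best[3] + 1e-12:
            best = (t, sens, spec, j)
    return best


def max_pool_loops(matrix):
    n, d = matrix.shape
    out = [max(matrix[i][j] for i in range(n)) for j in range(d)]
    return np.array(out)
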