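"""Subword-aware skipgram embeddings, sequence embedding and padding rules.

Words are represented by character n-grams (default sizes 2-5) of the
boundary-marked word plus a whole-word vector; a word's vector is the
mean of its subword-gram vectors plus its whole-word vector, which lets
out-of-vocabulary words be composed from their grams.  Training is
skipgram with negative sampling, implemented as vectorized NumPy updates
over (center, context) pairs; it is deterministic under a fixed seed.

The padding rule for the sequence encoders comes from the development
split: pad length = ceil(Q3 + 1.5 * IQR) of the note-length distribution;
shorter notes are zero-padded on the left, longer notes keep their
rightmost tokens.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

__all__ = [
    "extract_subwords", "EmbeddingTable", "SubwordSkipgram", "train_embeddings",
    "lookup", "embed_sequence", "compute_padding_length", "pad_or_truncate",
]

BOW, EOW = "<", ">"


def extract_subwords(word: str, min_n: int = 2, max_n: int = 5,
                     include_word: bool = True) -> list[str]:
    """Character n-grams of the boundary-marked word, with multiplicity.

    The word is wrapped as ``<word>`` and all contiguous n-grams with
    ``min_n <= len <= max_n`` are listed; when *include_word* is true the
    whole marked word is appended as a final special gram (it lives in a
    separate vector namespace even if it coincides with a char n-gram).
    """
    if not word:
        raise ValueError("word must be non-empty")
    marked = BOW + word + EOW
    grams = []
    for n in range(min_n, max_n + 1):
        for i in range(len(marked) - n + 1):
            grams.append(marked[i:i + n])
    if include_word:
        grams.append(marked)
    return grams


def _fnv1a(s: str) -> int:
    h = 0x811C9DC5
    for b in s.encode("utf-8"):
        h = ((h ^ b) * 0x01000193) & 0xFFFFFFFF
    return h


class EmbeddingTable:
    """Word -> d-vector map with subword-gram composition for OOV words.

    ``vector(word)`` returns, for an in-vocabulary word, the stored vector
    (mean of its subword-gram vectors plus its whole-word vector); for an
    OOV word, the mean of its known gram vectors; and the zero vector when
    no gram is known.
    """

    def __init__(self, words: list[str], word_vecs: np.ndarray,
                 gram_vecs: np.ndarray, gram_index: dict[str, int] | None,
                 n_buckets: int | None, min_n: int = 2, max_n: int = 5):
        self.words = list(words)
        self.word_index = {w: i for i, w in enumerate(self.words)}
        self.word_vecs = np.asarray(word_vecs, dtype=np.float32)
        self.gram_vecs = np.asarray(gram_vecs, dtype=np.float32)
        self.gram_index = gram_index  # None in hashed-bucket mode
        self.n_buckets = n_buckets
        self.min_n, self.max_n = min_n, max_n
        self.d = self.word_vecs.shape[1]
        self._stored = None
        self._cache: dict[str, np.ndarray] = {}

    # -- gram id resolution -------------------------------------------------
    def _gram_ids(self, word: str) -> list[int]:
        grams = extract_subwords(word, self.min_n, self.max_n, include_word=False)
        if self.gram_index is not None:
            return [self.gram_index[g] for g in grams if g in self.gram_index]
        return [_fnv1a(g) % self.n_buckets for g in grams]

    def _compose(self, word: str) -> np.ndarray:
        ids = self._gram_ids(word)
        sub = (self.gram_vecs[ids].mean(axis=0) if ids
               else np.zeros(self.d, dtype=np.float32))
        if word in self.word_index:
            return sub + self.word_vecs[self.word_index[word]]
        return sub

    @property
    def stored_vectors(self) -> np.ndarray:
        """Exported per-word vectors (lazy; one row per vocabulary word)."""
        if self._stored is None:
            self._stored = np.stack([self._compose(w) for w in self.words]) \
                if self.words else np.zeros((0, self.d), dtype=np.float32)
        return self._stored

    def vector(self, word: str) -> np.ndarray:
        if word in self.word_index:
            return self.stored_vectors[self.word_index[word]]
        if word not in self._cache:  # memoize OOV composition
            self._cache[word] = self._compose(word)
        return self._cache[word]

    def __contains__(self, word: str) -> bool:
        return word in self.word_index

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Word vectors in the standard text format ('n d' header, one word
        per line) plus an .npz sidecar with gram vectors and metadata."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.d}\n")
            for w, v in zip(self.words, self.stored_vectors):
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in v) + "\n")
        meta = {"min_n": self.min_n, "max_n": self.max_n,
                "n_buckets": self.n_buckets,
                "grams": list(self.gram_index) if self.gram_index is not None else None}
        np.savez(path.with_suffix(path.suffix + ".grams.npz"),
                 word_vecs=self.word_vecs, gram_vecs=self.gram_vecs,
                 meta=json.dumps(meta), words=json.dumps(self.words))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        path = Path(path)
        z = np.load(path.with_suffix(path.suffix + ".grams.npz"))
        meta = json.loads(str(z["meta"]))
        words = json.loads(str(z["words"]))
        gram_index = ({g: i for i, g in enumerate(meta["grams"])}
                      if meta["grams"] is not None else None)
        return cls(words, z["word_vecs"], z["gram_vecs"], gram_index,
                   meta["n_buckets"], meta["min_n"], meta["max_n"])


class SubwordSkipgram:
    """Skipgram-with-negative-sampling trainer over subword representations.

    sklearn-style estimator: construct with hyperparameters, ``fit`` on a
    corpus (list of token lists), read ``table_`` afterwards.  The center
    word's representation is the mean of its subword-gram vectors plus its
    whole-word vector; gradients flow to grams, whole-word and context
    vectors.  Gram vectors live either in a fixed hashed bucket table
    (default 2e5 buckets, bounded memory) or, with ``exact_grams=True``,
    in an exact gram vocabulary (used by composition-identity tests).
    """

    def __init__(self, d: int = 128, window: int = 5, negative: int = 5,
                 epochs: int = 5, lr: float = 0.1, min_count: int = 1,
                 subsample: float = 0.0,
                 min_n: int = 2, max_n: int = 5, n_buckets: int = 200_000,
                 exact_grams: bool = False, batch_pairs: int = 256,
                 seed: int = 0):
        self.d = d
        self.window = window
        self.negative = negative
        self.epochs = epochs
        self.lr = lr
        self.min_count = min_count
        self.subsample = subsample
        self.min_n = min_n
        self.max_n = max_n
        self.n_buckets = n_buckets
        self.exact_grams = exact_grams
        self.batch_pairs = batch_pairs
        self.seed = seed

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "d", "window", "negative", "epochs", "lr", "min_count",
            "subsample", "min_n", "max_n", "n_buckets", "exact_grams",
            "batch_pairs", "seed")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, corpus: list[list[str]]) -> "SubwordSkipgram":
        if not corpus or not any(corpus):
            raise ValueError("empty corpus")
        rng = np.random.default_rng(self.seed)

        # vocabulary
        counts: dict[str, int] = {}
        for sent in corpus:
            for w in sent:
                counts[w] = counts.get(w, 0) + 1
        words = sorted(w for w, c in counts.items() if c >= self.min_count)
        V = len(words)
        if V == 0:
            raise ValueError("no word reaches min_count")
        w2i = {w: i for i, w in enumerate(words)}

        # gram ids per word (padded matrix for vectorized gather)
        gram_index: dict[str, int] | None = {} if self.exact_grams else None
        gram_ids_per_word: list[list[int]] = []
        for w in words:
            grams = extract_subwords(w, self.min_n, self.max_n, include_word=False)
            if self.exact_grams:
                ids = []
                for g in grams:
                    if g not in gram_index:
                        gram_index[g] = len(gram_index)
                    ids.append(gram_index[g])
            else:
                ids = [_fnv1a(g) % self.n_buckets for g in grams]
            gram_ids_per_word.append(ids)
        n_gram_rows = len(gram_index) if self.exact_grams else self.n_buckets
        gmax = max(len(g) for g in gram_ids_per_word)
        # pad with a dummy row (index n_gram_rows) whose gradient is discarded
        GI = np.full((V, gmax), n_gram_rows, dtype=np.int64)
        gcnt = np.zeros(V, dtype=np.float32)
        for i, ids in enumerate(gram_ids_per_word):
            GI[i, :len(ids)] = ids
            gcnt[i] = max(len(ids), 1)

        # parameters (float32): input word vecs, gram vecs (+dummy), output vecs
        scale = 0.5 / self.d
        Wword = rng.uniform(-scale, scale, size=(V, self.d)).astype(np.float32)
        Wgram = rng.uniform(-scale, scale, size=(n_gram_rows + 1, self.d)).astype(np.float32)
        Wgram[n_gram_rows] = 0.0
        Cout = np.zeros((V, self.d), dtype=np.float32)

        # negative-sampling table: unigram^0.75
        freq = np.array([counts[w] for w in words], dtype=np.float64) ** 0.75
        neg_p = freq / freq.sum()

        sents = [np.array([w2i[w] for w in sent if w in w2i], dtype=np.int64)
                 for sent in corpus]
        sents = [s for s in sents if len(s) >= 2]

        # frequent-word subsampling: keep probability sqrt(t/f) + t/f
        n_tokens = sum(len(s) for s in sents)
        word_f = np.array([counts[w] for w in words], dtype=np.float64) / n_tokens
        if self.subsample > 0:
            ratio = self.subsample / np.maximum(word_f, 1e-12)
            keep_p = np.minimum(1.0, np.sqrt(ratio) + ratio)
        else:
            keep_p = np.ones(V)

        # total batches for linear lr decay
        approx_pairs = sum(len(s) for s in sents) * (self.window + 1)
        total_batches = max(1, self.epochs * math.ceil(approx_pairs / self.batch_pairs))
        batch_no = 0

        for _epoch in range(self.epochs):
            centers, contexts = [], []
            for s0 in sents:
                s = s0[rng.random(len(s0)) < keep_p[s0]] \
                    if self.subsample > 0 else s0
                L = len(s)
                if L < 2:
                    continue
                b = rng.integers(1, self.window + 1, size=L)
                for delta in range(1, self.window + 1):
                    if delta >= L:
                        break
                    m = b[delta:] >= delta        # center right of context
                    centers.append(s[delta:][m]); contexts.append(s[:-delta][m])
                    m = b[:-delta] >= delta       # center left of context
                    centers.append(s[:-delta][m]); contexts.append(s[delta:][m])
            if not centers:
                continue  # subsampling can empty a tiny epoch
            centers = np.concatenate(centers)
            contexts = np.concatenate(contexts)
            order = rng.permutation(len(centers))
            centers, contexts = centers[order], contexts[order]

            for start in range(0, len(centers), self.batch_pairs):
                c = centers[start:start + self.batch_pairs]
                o = contexts[start:start + self.batch_pairs]
                B = len(c)
                lr_t = self.lr * max(1e-4, 1.0 - batch_no / total_batches)
                batch_no += 1
                negs = rng.choice(V, size=(B, self.negative), p=neg_p)

                gi = GI[c]                                  # (B, gmax)
                mask = (gi != n_gram_rows).astype(np.float32)[:, :, None]
                vsub = (Wgram[gi] * mask).sum(axis=1) / gcnt[c][:, None]
                v = Wword[c] + vsub                         # (B, d)

                u_pos = Cout[o]                             # (B, d)
                u_neg = Cout[negs]                          # (B, k, d)
                g_pos = _sigmoid32((v * u_pos).sum(1)) - 1.0          # (B,)
                g_neg = _sigmoid32(np.einsum("bd,bkd->bk", v, u_neg))  # (B, k)
                g_neg *= (negs != o[:, None]) & (negs != c[:, None])  # skip accidental hits

                dv = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
                ctx_idx = np.concatenate([o, negs.reshape(-1)])
                ctx_grad = np.concatenate(
                    [g_pos[:, None] * v,
                     (g_neg[:, :, None] * v[:, None, :]).reshape(-1, self.d)])
                _scatter_mean_update(Cout, ctx_idx, ctx_grad, lr_t)
                _scatter_mean_update(Wword, c, dv, lr_t)
                dg = ((dv / gcnt[c][:, None])[:, None, :] * mask).reshape(-1, self.d)
                _scatter_mean_update(Wgram, gi.reshape(-1), dg, lr_t)
                Wgram[n_gram_rows] = 0.0

        self.table_ = EmbeddingTable(
            words, Wword, Wgram[:n_gram_rows], gram_index,
            None if self.exact_grams else self.n_buckets, self.min_n, self.max_n)
        return self


def _scatter_mean_update(W, idx, grad, lr):
    """SGD step averaging duplicate-row gradients inside the batch.

    Averaging (rather than summing) gradients that hit the same row keeps
    the per-row step bounded when the vocabulary is small relative to the
    batch, which would otherwise destabilize training.
    """
    u, inv = np.unique(idx, return_inverse=True)
    acc = np.zeros((len(u), grad.shape[-1]), dtype=W.dtype)
    np.add.at(acc, inv, grad.astype(W.dtype, copy=False))
    cnt = np.bincount(inv, minlength=len(u)).astype(W.dtype)
    W[u] -= lr * acc / cnt[:, None]


def _sigmoid32(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30), dtype=np.float32))


def train_embeddings(corpus: list[list[str]], d: int = 128, window: int = 5,
                     negatives: int = 5, epochs: int = 5, seed: int = 0,
                     **kwargs) -> EmbeddingTable:
    """Train a :class:`SubwordSkipgram` and return its embedding table."""
    model = SubwordSkipgram(d=d, window=window, negative=negatives,
                            epochs=epochs, seed=seed, **kwargs)
    return model.fit(corpus).table_


def lookup(table: EmbeddingTable, word: str) -> np.ndarray:
    """Vector for a word; OOV words are composed from their known grams."""
    return table.vector(word)


def embed_sequence(tokens: list[str], table: EmbeddingTable) -> np.ndarray:
    """n x d embedding matrix T with row i the vector of token i."""
    if not tokens:
        raise ValueError("empty token sequence")
    return np.stack([table.vector(t) for t in tokens])


def compute_padding_length(dev_lengths) -> int:
    """Pad length from the development note lengths: ceil(Q3 + 1.5 * IQR).

    Quantiles use linear interpolation.  Computed on the development split
    only; the same length is applied unchanged to held-out notes.
    """
    lengths = np.asarray(list(dev_lengths), dtype=float)
    if lengths.size < 4:
        raise ValueError("need at least 4 development lengths")
    q1, q3 = np.quantile(lengths, [0.25, 0.75], method="linear")
    return max(1, int(math.ceil(q3 + 1.5 * (q3 - q1))))


def pad_or_truncate(matrix: np.ndarray, n_pad: int) -> np.ndarray:
    """Left-pad with zero rows, or keep the rightmost ``n_pad`` rows."""
    if n_pad < 1:
        raise ValueError("n_pad must be >= 1")
    matrix = np.asarray(matrix)
    n, d = matrix.shape
    if n >= n_pad:
        return matrix[n - n_pad:]
    out = np.zeros((n_pad, d), dtype=matrix.dtype)
    out[n_pad - n:] = matrix
    return out
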