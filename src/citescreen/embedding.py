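"""Word and document embeddings and the sentence-word feature matrix.

The screening engine represents each article (title + abstract) by a row of
the DW matrix: the product of a document-embedding matrix ``D`` (m x k,
PV-DBOW paragraph vectors) and the transposed word-embedding matrix ``W``
(n x k, skip-gram with negative sampling), giving an m x n "sentence-word"
matrix whose columns are the n most common corpus words. Similar articles
have nearby rows; because the map is linear, additive structure in the
embedding space survives the multiplication. No dimensionality reduction is
applied to DW: the column count stays at the vocabulary size.

Both matrices are trained jointly by a single negative-sampling objective:
skip-gram pairs (center word -> context word) train ``W`` and PV-DBOW pairs
(document -> each of its words) train ``D`` against a shared output layer.
The trainer is a vectorized minibatch SGD implementation with the standard
word2vec recipe: uniform(-0.5/k, 0.5/k) input initialization, zero output
initialization, unigram^0.75 negative-sampling distribution, dynamically
shrunk context windows, and a linearly decaying learning rate.
"""

from __future__ import annotations

import json
import re
import zipfile
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import LabeledCorpus

__all__ = [
    "tokenize",
    "Vocabulary",
    "EmbeddingConfig",
    "EmbeddingModel",
    "FeatureMatrix",
    "build_vocabulary",
    "train_embeddings",
    "compute_feature_matrix",
    "cosine_similarity",
]

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase a text and split it on any non-alphanumeric character.

    Empty fragments are dropped; stopwords and numerals are retained.
    This is the English degenerate case of morphological analysis: English
    orthography already separates words, so morpheme segmentation reduces
    to word tokenization.
    """
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


@dataclass(frozen=True)
class Vocabulary:
    """The n most common corpus words, descending frequency, ties lexicographic."""

    words: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        return self._index[word]

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        """Map tokens to vocabulary indices, dropping out-of-vocabulary tokens."""
        idx = self._index
        return np.asarray([idx[t] for t in tokens if t in idx], dtype=np.int64)


def build_vocabulary(corpus: LabeledCorpus, max_vocab: int = 1000) -> Vocabulary:
    """Select the ``max_vocab`` most frequent words over all titles+abstracts.

    No stopword removal is performed: the engine embeds the raw most-common
    words, stopwords included. Ties in frequency break lexicographically, so
    the vocabulary is invariant to article order.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for article in corpus:
        counts.update(tokenize(article.text))
    if not counts:
        raise ValueError("corpus contains no tokens")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:max_vocab]
    words, freqs = zip(*ranked)
    return Vocabulary(words=words, counts=freqs)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the joint skip-gram / PV-DBOW trainer.

    ``k`` is the embedding dimension and ``negative`` the number of noise
    samples per positive pair; both default to the published settings
    (k=300, 5 negatives, 1000-word vocabulary). ``epochs``, ``window``,
    ``subsample`` (frequent-word downsampling threshold, word2vec's t) and
    the learning-rate bounds are declared defaults of this implementation.
    ``joint=False`` switches to the two-stage alternative (train W by
    skip-gram alone, then fit D against the frozen output layer).
    """

    k: int = 300
    negative: int = 5
    max_vocab: int = 1000
    epochs: int = 40
    window: int = 5
    subsample: float = 1e-3
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0
    deterministic: bool = True
    joint: bool = True
    batch_size: int = 2048

    def __post_init__(self) -> None:
        if self.k < 1 or self.negative < 1 or self.max_vocab < 2 or self.epochs < 1:
            raise ValueError("invalid embedding configuration")


@dataclass(frozen=True)
class EmbeddingModel:
    """Trained word (W, n x k) and document (D, m x k) vectors."""

    W: np.ndarray
    D: np.ndarray
    vocab: Vocabulary
    article_ids: tuple[str, ...]
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        n, m = len(self.vocab), len(self.article_ids)
        if self.W.shape != (n, self.config.k) or self.D.shape != (m, self.config.k):
            raise ValueError("embedding matrix shapes do not match vocab/corpus sizes")
        if not (np.isfinite(self.W).all() and np.isfinite(self.D).all()):
            raise ValueError("embedding matrices contain non-finite entries")


@dataclass(frozen=True)
class FeatureMatrix:
    """The m x n DW sentence-word matrix; row i is article i's feature vector."""

    F: np.ndarray
    article_ids: tuple[str, ...]
    vocab: Vocabulary

    def __post_init__(self) -> None:
        if self.F.shape != (len(self.article_ids), len(self.vocab)):
            raise ValueError("feature matrix shape does not match labels")
        object.__setattr__(
            self, "_row", {a: i for i, a in enumerate(self.article_ids)}
        )

    def row(self, article_id: str) -> np.ndarray:
        return self.F[self._row[article_id]]

    def row_index(self, article_id: str) -> int:
        return self._row[article_id]

    @property
    def m(self) -> int:
        return self.F.shape[0]

    @property
    def n(self) -> int:
        return self.F.shape[1]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.F, index=list(self.article_ids), columns=list(self.vocab.words)
        ).to_csv(path, index_label="id")

    def to_mtx(self, path: str | Path) -> None:
        """MatrixMarket export; row/column label manifests go in sidecar files."""
        from scipy import io as spio, sparse

        path = Path(path)
        spio.mmwrite(path, sparse.csr_matrix(self.F))
        path.with_suffix(".rows.txt").write_text("\n".join(self.article_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(self.vocab.words) + "\n")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _skipgram_pairs(
    doc: np.ndarray, window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Center/context index pairs with word2vec-style shrunk windows."""
    L = doc.size
    if L < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    b = rng.integers(1, window + 1, size=L)
    centers, contexts = [], []
    for off in range(1, window + 1):
        use = b >= off
        idx = np.nonzero(use)[0]
        left = idx[idx - off >= 0]
        right = idx[idx + off < L]
        centers.append(doc[left])
        contexts.append(doc[left - off])
        centers.append(doc[right])
        contexts.append(doc[right + off])
    return np.concatenate(centers), np.concatenate(contexts)


def _train_pairs(
    inputs: np.ndarray,
    outputs: np.ndarray,
    V: np.ndarray,
    C: np.ndarray,
    noise_cdf: np.ndarray,
    negative: int,
    lr0: float,
    lr1: float,
    batch_size: int,
    rng: np.random.Generator,
    update_outputs: bool = True,
) -> None:
    """One pass of minibatch SGD over (input row, output word) pairs.

    ``V`` holds input vectors (word rows followed by document rows), ``C``
    the shared output layer. The learning rate decays linearly from ``lr0``
    to ``lr1`` over the pass. Within a batch, gradients hitting the same
    embedding row are averaged (not summed), so a frequent word's effective
    step stays bounded by the learning rate — the batched update would
    otherwise diverge for Zipf-distributed vocabularies.
    """
    n_pairs = inputs.size
    order = rng.permutation(n_pairs)
    inputs, outputs = inputs[order], outputs[order]
    for start in range(0, n_pairs, batch_size):
        stop = min(start + batch_size, n_pairs)
        lr = lr0 + (lr1 - lr0) * (start / max(n_pairs - 1, 1))
        inp = inputs[start:stop]
        B = inp.size
        # column 0 is the positive word, the rest are noise words
        out = np.empty((B, 1 + negative), dtype=np.int64)
        out[:, 0] = outputs[start:stop]
        out[:, 1:] = np.searchsorted(
            noise_cdf, rng.random((B, negative)), side="right"
        )
        vin = V[inp]  # (B, k)
        cout = C[out]  # (B, 1+neg, k)
        score = np.einsum("bk,bnk->bn", vin, cout)
        grad = _sigmoid(score)
        grad[:, 0] -= 1.0
        grad *= lr
        gin = np.einsum("bn,bnk->bk", grad, cout)
        _scatter_mean(V, inp, gin)
        if update_outputs:
            gout = (grad[:, :, None] * vin[:, None, :]).reshape(-1, C.shape[1])
            _scatter_mean(C, out.ravel(), gout)


def _scatter_mean(M: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    """Apply ``M[i] -= mean of grads rows with idx == i`` for each unique i.

    Sort-and-segment-sum formulation: orders of magnitude faster than
    ``np.add.at`` for the many-duplicate index vectors seen here.
    """
    if idx.size == 0:
        return
    order = np.argsort(idx, kind="stable")
    sidx = idx[order]
    sgrads = grads[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(sidx)) + 1))
    uniq = sidx[starts]
    gsum = np.add.reduceat(sgrads, starts, axis=0)
    counts = np.diff(np.concatenate((starts, [sidx.size])))
    M[uniq] -= gsum / counts[:, None]


def train_embeddings(
    corpus: LabeledCorpus,
    vocab: Vocabulary,
    config: EmbeddingConfig | None = None,
) -> EmbeddingModel:
    """Train W and D on a corpus restricted to the given vocabulary.

    Out-of-vocabulary tokens are removed before training; an article whose
    encoded token sequence is empty still receives a row in D (the zero
    vector). With ``deterministic=True`` (single stream of seeded
    randomness, no threading) identical inputs yield bit-identical matrices.
    """
    config = config or EmbeddingConfig()
    docs = [vocab.encode(tokenize(a.text)) for a in corpus]
    nonempty = [i for i, d in enumerate(docs) if d.size > 0]
    if len(nonempty) < 2:
        raise ValueError(
            "training requires at least 2 articles with in-vocabulary tokens"
        )
    n, m, k = len(vocab), len(corpus), config.k
    rng = np.random.default_rng(config.seed)

    # input matrix: word rows [0, n), document rows [n, n+m); float32 keeps
    # the bandwidth-bound batch updates fast
    V = rng.uniform(-0.5 / k, 0.5 / k, size=(n + m, k)).astype(np.float32)
    C = np.zeros((n, k), dtype=np.float32)

    counts = np.asarray(vocab.counts, dtype=np.float64)
    freqs = counts ** 0.75
    noise_cdf = np.cumsum(freqs / freqs.sum())
    noise_cdf[-1] = 1.0

    # word2vec frequent-word downsampling: keeps the minibatch scatter-add
    # stable (few duplicate indices per batch) and improves the signal from
    # rarer, more topical words
    if config.subsample > 0:
        rel_freq = counts / counts.sum()
        keep_prob = np.minimum(1.0, np.sqrt(config.subsample / rel_freq))
    else:
        keep_prob = np.ones(n)

    def downsample(doc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if config.subsample <= 0:
            return doc
        return doc[rng.random(doc.size) < keep_prob[doc]]

    def run_epochs(pair_builder, epochs: int, update_outputs: bool = True) -> None:
        for epoch in range(epochs):
            inputs, outputs = pair_builder(rng)
            frac0 = epoch / epochs
            frac1 = (epoch + 1) / epochs
            lr0 = config.alpha + (config.min_alpha - config.alpha) * frac0
            lr1 = config.alpha + (config.min_alpha - config.alpha) * frac1
            _train_pairs(
                inputs, outputs, V, C, noise_cdf, config.negative,
                lr0, lr1, config.batch_size, rng, update_outputs=update_outputs,
            )

    def joint_pairs(rng: np.random.Generator):
        ins, outs = [], []
        for i in nonempty:
            doc = downsample(docs[i], rng)
            c, t = _skipgram_pairs(doc, config.window, rng)
            ins.append(c)
            outs.append(t)
            ins.append(np.full(doc.size, n + i, dtype=np.int64))  # PV-DBOW pairs
            outs.append(doc)
        return np.concatenate(ins), np.concatenate(outs)

    def word_pairs(rng: np.random.Generator):
        ins, outs = [], []
        for i in nonempty:
            c, t = _skipgram_pairs(downsample(docs[i], rng), config.window, rng)
            ins.append(c)
            outs.append(t)
        return np.concatenate(ins), np.concatenate(outs)

    def doc_pairs(rng: np.random.Generator):
        ins, outs = [], []
        for i in nonempty:
            doc = downsample(docs[i], rng)
            ins.append(np.full(doc.size, n + i, dtype=np.int64))
            outs.append(doc)
        return np.concatenate(ins), np.concatenate(outs)

    if config.joint:
        run_epochs(joint_pairs, config.epochs)
    else:
        run_epochs(word_pairs, config.epochs)
        # document vectors fitted against the frozen output layer
        run_epochs(doc_pairs, config.epochs, update_outputs=False)

    W = V[:n].astype(np.float64)
    D = V[n:].astype(np.float64)
    for i, d in enumerate(docs):
        if d.size == 0:
            D[i] = 0.0
    return EmbeddingModel(
        W=W, D=D, vocab=vocab, article_ids=corpus.ids, config=config
    )


def compute_feature_matrix(model: EmbeddingModel) -> FeatureMatrix:
    """Form the DW sentence-word matrix F = D @ W.T (m x n, no reduction)."""
    if model.D.shape[1] != model.W.shape[1]:
        raise ValueError("D and W embedding dimensions disagree")
    F = model.D @ model.W.T
    if not np.isfinite(F).all():
        raise ValueError("feature matrix contains non-finite entries")
    return FeatureMatrix(F=F, article_ids=model.article_ids, vocab=model.vocab)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float | None:
    """Cosine similarity in [-1, 1], or None when either vector has zero norm.

    Rankings treat None ("undefined") as below every defined score.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return None
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Serialize a trained model (W, D, vocabulary, config) to one .npz-style archive."""
    path = Path(path)
    manifest = {
        "article_ids": list(model.article_ids),
        "vocab_words": list(model.vocab.words),
        "vocab_counts": list(model.vocab.counts),
        "config": asdict(model.config),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest))
        import io

        for name, arr in (("W", model.W), ("D", model.D)):
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"{name}.npy", buf.getvalue())


def load_model(path: str | Path) -> EmbeddingModel:
    """Inverse of :func:`save_model`."""
    import io

    with zipfile.ZipFile(Path(path)) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        W = np.load(io.BytesIO(zf.read("W.npy")))
        D = np.load(io.BytesIO(zf.read("D.npy")))
    vocab = Vocabulary(
        words=tuple(manifest["vocab_words"]), counts=tuple(manifest["vocab_counts"])
    )
    return EmbeddingModel(
        W=W,
        D=D,
        vocab=vocab,
        article_ids=tuple(manifest["article_ids"]),
        config=EmbeddingConfig(**manifest["config"]),
    )
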