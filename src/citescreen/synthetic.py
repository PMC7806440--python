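"""Synthetic labeled screening corpora with a tunable topical signal.

Real screening datasets for this task are PubMed search results labeled by
which records a published systematic review actually included: a few
thousand records at most, of which only a handful (roughly 5-20) are
relevant. This generator emulates that structure with the simplest model
whose relevant/irrelevant separation is a single interpretable knob:

* a Zipf-distributed background vocabulary shared by every article (so a
  most-common-words vocabulary cap is actually exercised), and
* a disjoint set of topic words; each token of a relevant article is drawn
  from the topic distribution with probability ``delta`` and from the
  background otherwise, while irrelevant articles draw from the background
  only.

``delta=0`` makes labels statistically independent of the text (a null
corpus); ``delta=1`` makes every relevant-article token a topic word. Token
counts per article follow a positive-truncated normal; the first 8 tokens
of each article become its title and the rest its abstract, so titles and
abstracts share the topic signal. Sentence structure, bigrams and semantic
realism are deliberately not modelled.

Ids are zero-padded decimals, so lexicographic order equals numeric order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus import Article, Label, LabeledCorpus

__all__ = ["SynthConfig", "generate_corpus", "paper_like_configs"]

_TITLE_TOKENS = 8
_MIN_TOKENS = _TITLE_TOKENS + 4


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``m``: total articles; ``n_relevant``: relevant count; ``vocab_size``:
    distinct words overall (background + topic); ``topic_size``: words
    reserved for the relevant topic; ``delta``: topic weight in relevant
    articles, in [0, 1]; ``len_mean``/``len_sd``: token-count distribution.
    """

    m: int = 200
    n_relevant: int = 10
    vocab_size: int = 1200
    topic_size: int = 100
    delta: float = 0.8
    len_mean: float = 120.0
    len_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_relevant <= self.m:
            raise ValueError(f"need 2 <= n_relevant <= m, got P={self.n_relevant}, m={self.m}")
        if not 0 < self.topic_size < self.vocab_size:
            raise ValueError("topic_size must be in (0, vocab_size)")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.len_mean <= 0:
            raise ValueError("len_mean must be positive")


def _zipf_probs(n: int, exponent: float = 1.0) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=np.float64)
    p = ranks ** -exponent
    return p / p.sum()


def generate_corpus(config: SynthConfig) -> LabeledCorpus:
    """Draw one labeled corpus; deterministic given ``config.seed``.

    The first ``n_relevant`` ids are the relevant articles (the screening
    loop never sees ids in a meaningful order, only scores, so placement is
    immaterial).
    """
    rng = np.random.default_rng(config.seed)
    n_bg = config.vocab_size - config.topic_size
    bg_words = np.array([f"bg{i:05d}" for i in range(n_bg)])
    topic_words = np.array([f"topic{i:04d}" for i in range(config.topic_size)])
    bg_probs = _zipf_probs(n_bg)
    topic_probs = _zipf_probs(config.topic_size)

    width = len(str(config.m))
    articles = []
    for i in range(config.m):
        relevant = i < config.n_relevant
        length = max(_MIN_TOKENS, int(round(rng.normal(config.len_mean, config.len_sd))))
        if relevant and config.delta > 0:
            from_topic = rng.random(length) < config.delta
            n_topic = int(from_topic.sum())
            tokens = np.empty(length, dtype=object)
            tokens[from_topic] = rng.choice(topic_words, size=n_topic, p=topic_probs)
            tokens[~from_topic] = rng.choice(bg_words, size=length - n_topic, p=bg_probs)
        else:
            tokens = rng.choice(bg_words, size=length, p=bg_probs)
        articles.append(
            Article(
                id=f"{i:0{width}d}",
                title=" ".join(tokens[:_TITLE_TOKENS]),
                abstract=" ".join(tokens[_TITLE_TOKENS:]),
                label=Label.RELEVANT if relevant else Label.IRRELEVANT,
            )
        )
    return LabeledCorpus.from_articles(articles)


# (P, m) shapes of the eight reproduced review datasets.
_REVIEW_SHAPES = [
    (6, 410),
    (12, 560),
    (17, 5644),
    (20, 6935),
    (11, 830),
    (5, 5839),
    (5, 138),
    (5, 2389),
]


def paper_like_configs(delta: float = 0.8, base_seed: int = 1000) -> list[SynthConfig]:
    """Eight configs mirroring the sizes of the reproduced review datasets.

    Each pairs a small relevant count (5-20) with a total size between 138
    and 6935 articles, with a fixed per-config seed.
    """
    return [
        SynthConfig(m=m, n_relevant=p, delta=delta, seed=base_seed + i)
        for i, (p, m) in enumerate(_REVIEW_SHAPES)
    ]
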