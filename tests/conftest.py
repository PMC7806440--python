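import numpy as np
import pytest

from citescreen import Article, FeatureMatrix, Label, LabeledCorpus, Vocabulary


def make_corpus(labels: dict[str, Label], titles: dict[str, str] | None = None,
                abstracts: dict[str, str] | None = None) -> LabeledCorpus:
    titles = titles or {}
    abstracts = abstracts or {}
    return LabeledCorpus.from_articles(
        Article(id=aid, title=titles.get(aid, f"title {aid}"),
                abstract=abstracts.get(aid, f"abstract {aid}"), label=lab)
        for aid, lab in labels.items()
    )


def make_features(ids: list[str], rows: np.ndarray) -> FeatureMatrix:
    rows = np.asarray(rows, dtype=np.float64)
    vocab = Vocabulary(
        words=tuple(f"w{j:03d}" for j in range(rows.shape[1])),
        counts=tuple([1] * rows.shape[1]),
    )
    return FeatureMatrix(F=rows, article_ids=tuple(ids), vocab=vocab)


def random_labeled_problem(rng: np.random.Generator, m: int, n: int, p: int):
    """Random feature matrix + fully labeled corpus with exactly p relevant."""
    ids = [f"{i:03d}" for i in range(m)]
    rel = set(rng.choice(m, size=p, replace=False).tolist())
    corpus = make_corpus(
        {aid: (Label.RELEVANT if i in rel else Label.IRRELEVANT)
         for i, aid in enumerate(ids)}
    )
    F = make_features(ids, rng.standard_normal((m, n)))
    return F, corpus


@pytest.fixture
def tiny_corpus() -> LabeledCorpus:
    """Five articles, two relevant, deterministic contents."""
    return make_corpus(
        {
            "a1": Label.RELEVANT,
            "a2": Label.RELEVANT,
            "b1": Label.IRRELEVANT,
            "b2": Label.IRRELEVANT,
            "b3": Label.IRRELEVANT,
        }
    )
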