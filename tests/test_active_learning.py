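"""The relevance-feedback screening loop and its determinism guarantees."""

import numpy as np
import pytest

from citescreen import (
    CorpusValidationError,
    Label,
    ScreeningState,
    StopReason,
    enumerate_seed_pairs,
    init_query,
    run_screening,
    score_unscreened,
    select_next,
    update_query,
)

from conftest import make_corpus, make_features, random_labeled_problem


def naive_reference_run(F, corpus, seed_pair):
    """From-scratch reference loop: recomputes means and every cosine each
    step with no caching or vectorized ranking. Returns [(id, label), ...]."""
    labels = {a.id: a.label for a in corpus}
    P = sum(1 for v in labels.values() if v is Label.RELEVANT)
    row = {aid: F.row(aid) for aid in corpus.ids}
    unscreened = set(corpus.ids)
    rel, irr, reads = [], [], []
    for sid in seed_pair:
        unscreened.remove(sid)
        rel.append(sid)
        reads.append((sid, Label.RELEVANT))
    while len(rel) < P:
        q = np.mean([row[a] for a in rel], axis=0)
        if irr:
            q = q - np.mean([row[a] for a in irr], axis=0)
        qn = np.linalg.norm(q)
        scores = {}
        for aid in unscreened:
            rn = np.linalg.norm(row[aid])
            if qn == 0.0 or rn == 0.0:
                scores[aid] = None
            else:
                scores[aid] = float(np.dot(q, row[aid]) / (qn * rn))
        defined = {a: s for a, s in scores.items() if s is not None}
        if defined:
            best = max(defined.values())
            chosen = min(a for a, s in defined.items() if s == best)
        else:
            chosen = min(unscreened)
        unscreened.remove(chosen)
        (rel if labels[chosen] is Label.RELEVANT else irr).append(chosen)
        reads.append((chosen, labels[chosen]))
    return reads


class TestQueryVector:
    def test_init_is_mean_of_seed_rows(self):
        F = make_features(["a", "b"], [[1.0, 0.0], [0.0, 1.0]])
        assert np.allclose(init_query(F, ("a", "b")), [0.5, 0.5])

    def test_init_identical_rows_idempotent(self):
        F = make_features(["a", "b"], [[2.0, 3.0], [2.0, 3.0]])
        assert np.allclose(init_query(F, ("a", "b")), [2.0, 3.0])

    def test_init_rejects_duplicate_seed(self):
        F = make_features(["a", "b"], [[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(CorpusValidationError):
            init_query(F, ("a", "a"))

    def test_update_subtracts_irrelevant_mean(self):
        F = make_features(["r", "i"], [[2.0, 0.0], [0.0, 2.0]])
        state = ScreeningState(
            screened_relevant=["r"], screened_irrelevant=["i"], unscreened=set()
        )
        assert np.allclose(update_query(F, state), [2.0, -2.0])

    def test_update_mean_only_without_irrelevant(self):
        F = make_features(["r1", "r2"], [[2.0, 0.0], [0.0, 2.0]])
        state = ScreeningState(screened_relevant=["r1", "r2"], unscreened=set())
        assert np.allclose(update_query(F, state), [1.0, 1.0])

    def test_update_can_cancel_to_zero(self):
        F = make_features(["r", "i"], [[1.0, 1.0], [1.0, 1.0]])
        state = ScreeningState(
            screened_relevant=["r"], screened_irrelevant=["i"], unscreened=set()
        )
        assert np.array_equal(update_query(F, state), [0.0, 0.0])

    def test_update_requires_a_relevant_article(self):
        F = make_features(["i"], [[1.0]])
        with pytest.raises(CorpusValidationError):
            update_query(F, ScreeningState(screened_irrelevant=["i"], unscreened=set()))


class TestScoring:
    def test_cosine_scores(self):
        F = make_features(["a", "b"], [[2.0, 0.0], [0.0, 3.0]])
        scores = score_unscreened(F, np.array([1.0, 0.0]),
                                  ScreeningState(unscreened={"a", "b"}))
        assert scores["a"] == pytest.approx(1.0)
        assert scores["b"] == pytest.approx(0.0)

    def test_all_screened_gives_empty_map(self):
        F = make_features(["a"], [[1.0]])
        assert score_unscreened(F, np.array([1.0]), ScreeningState(unscreened=set())) == {}

    def test_zero_row_scores_undefined(self):
        F = make_features(["a"], [[0.0, 0.0]])
        scores = score_unscreened(F, np.array([1.0, 0.0]),
                                  ScreeningState(unscreened={"a"}))
        assert scores["a"] is None

    def test_select_breaks_ties_to_smallest_id(self):
        assert select_next({"a": 0.9, "b": 0.9, "c": 0.1}) == "a"

    def test_select_singleton(self):
        assert select_next({"z": 0.2}) == "z"

    def test_select_empty_is_error(self):
        with pytest.raises(ValueError):
            select_next({})

    def test_select_all_undefined_falls_back_to_id_order(self):
        assert select_next({"b": None, "a": None}) == "a"

    def test_undefined_never_outranks_defined(self):
        assert select_next({"a": None, "z": -0.99}) == "z"


class TestRunScreening:
    def rel_corpus(self):
        return make_corpus(
            {
                "r1": Label.RELEVANT,
                "r2": Label.RELEVANT,
                "r3": Label.RELEVANT,
                "x1": Label.IRRELEVANT,
                "x2": Label.IRRELEVANT,
            }
        )

    def toy_features(self):
        # relevant rows near [1, 0], irrelevant near [0, 1]
        return make_features(
            ["r1", "r2", "r3", "x1", "x2"],
            [[1.0, 0.0], [0.95, 0.05], [0.9, 0.1], [0.1, 1.0], [0.0, 1.0]],
        )

    def test_separable_toy_stops_after_three_reads(self):
        trace = run_screening(self.toy_features(), self.rel_corpus(), ("r1", "r2"))
        assert trace.read_ids() == ("r1", "r2", "r3")
        assert trace.reads == 3
        assert trace.stop_reason is StopReason.ALL_RELEVANT_FOUND

    def test_all_relevant_corpus_reads_everything(self):
        corpus = make_corpus({f"a{i}": Label.RELEVANT for i in range(5)})
        F = make_features(sorted(corpus.ids), np.eye(5))
        trace = run_screening(F, corpus, ("a0", "a1"))
        assert trace.reads == 5
        assert trace.stop_reason is StopReason.ALL_RELEVANT_FOUND

    def test_budget_stops_early(self):
        corpus = make_corpus({f"a{i}": Label.RELEVANT for i in range(5)})
        F = make_features(sorted(corpus.ids), np.eye(5))
        trace = run_screening(F, corpus, ("a0", "a1"), budget=3)
        assert trace.reads == 3
        assert trace.stop_reason is StopReason.BUDGET_EXHAUSTED

    def test_unknown_labels_rejected(self):
        corpus = make_corpus(
            {"r1": Label.RELEVANT, "r2": Label.RELEVANT, "u": Label.UNKNOWN}
        )
        F = make_features(sorted(corpus.ids), np.eye(3))
        with pytest.raises(CorpusValidationError, match="label"):
            run_screening(F, corpus, ("r1", "r2"))

    def test_seed_must_be_relevant(self):
        with pytest.raises(CorpusValidationError, match="x1"):
            run_screening(self.toy_features(), self.rel_corpus(), ("r1", "x1"))

    def test_trace_is_deterministic(self):
        rng = np.random.default_rng(12)
        F, corpus = random_labeled_problem(rng, m=15, n=6, p=4)
        pair = tuple(sorted(corpus.relevant_ids())[:2])
        t1 = run_screening(F, corpus, pair)
        t2 = run_screening(F, corpus, pair)
        assert t1.read_ids() == t2.read_ids()
        assert [s.score for s in t1.steps] == [s.score for s in t2.steps]

    def test_no_article_read_twice_and_steps_consecutive(self):
        rng = np.random.default_rng(3)
        F, corpus = random_labeled_problem(rng, m=18, n=5, p=5)
        pair = tuple(sorted(corpus.relevant_ids())[:2])
        trace = run_screening(F, corpus, pair)
        ids = trace.read_ids()
        assert len(set(ids)) == len(ids)
        assert [s.step for s in trace.steps] == list(range(1, trace.reads + 1))

    def test_monotone_recall_reaches_all_relevant(self):
        rng = np.random.default_rng(7)
        F, corpus = random_labeled_problem(rng, m=20, n=4, p=6)
        pair = tuple(sorted(corpus.relevant_ids())[:2])
        trace = run_screening(F, corpus, pair)
        found = np.cumsum([s.label is Label.RELEVANT for s in trace.steps])
        assert (np.diff(found) >= 0).all()
        assert found[-1] == corpus.n_relevant

    def test_matches_naive_reference_on_random_problems(self):
        """Spot check against the from-scratch loop; the full 25-corpus
        equivalence sweep lives in the acceptance suite."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            F, corpus = random_labeled_problem(
                rng, m=int(rng.integers(6, 15)), n=4, p=3
            )
            for pair in enumerate_seed_pairs(corpus):
                trace = run_screening(F, corpus, pair)
                expected = naive_reference_run(F, corpus, pair)
                assert [(s.article_id, s.label) for s in trace.steps] == expected


class TestSeedPairs:
    @pytest.mark.parametrize("p,count", [(2, 1), (5, 10), (20, 190)])
    def test_pair_counts(self, p, count):
        corpus = make_corpus(
            {
                **{f"r{i:02d}": Label.RELEVANT for i in range(p)},
                "x": Label.IRRELEVANT,
            }
        )
        pairs = enumerate_seed_pairs(corpus)
        assert len(pairs) == count
        assert pairs == sorted(pairs)  # deterministic lexicographic order

    def test_requires_two_relevant(self):
        corpus = make_corpus({"r": Label.RELEVANT, "x": Label.IRRELEVANT})
        with pytest.raises(CorpusValidationError):
            enumerate_seed_pairs(corpus)
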