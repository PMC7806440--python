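"""The relevance-feedback screening loop.

The simulated workflow mirrors retrospective screening: a researcher seeds
the engine with 2 known-relevant articles; the engine scores every
unscreened article by the cosine similarity between its DW feature row and
the current query vector; the researcher reads the top-ranked article and
reveals its true label; the query is recomputed as

    q = mean(feature rows of screened relevant)
      - mean(feature rows of screened irrelevant)

(the second term omitted until an irrelevant article has been read) and the
loop repeats until every relevant article has been found, or an optional
reading budget runs out. No classifier is trained on top of the feature
vectors: the query vector itself is the model of relevance.

Scores of zero-norm rows (e.g. articles with no in-vocabulary tokens) are
undefined and rank below every defined score; any remaining ties, and the
all-undefined degenerate case, fall back to lexicographically smallest id,
so the whole loop is deterministic given the feature matrix and seed pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import CorpusValidationError, Label, LabeledCorpus
from .embedding import FeatureMatrix

__all__ = [
    "StopReason",
    "StepRecord",
    "RunTrace",
    "ScreeningState",
    "init_query",
    "update_query",
    "score_unscreened",
    "select_next",
    "run_screening",
    "enumerate_seed_pairs",
]


class StopReason(str, Enum):
    ALL_RELEVANT_FOUND = "all_relevant_found"
    BUDGET_EXHAUSTED = "budget_exhausted"


@dataclass(frozen=True)
class StepRecord:
    """One read: which article, its true label, and its score at selection.

    Seed articles carry ``score=None`` (they were chosen, not ranked); an
    undefined cosine at selection is also ``None``.
    """

    step: int
    article_id: str
    label: Label
    score: float | None
    is_seed: bool = False


@dataclass
class ScreeningState:
    """Partition of article ids into screened-relevant / screened-irrelevant / unscreened."""

    screened_relevant: list[str] = field(default_factory=list)
    screened_irrelevant: list[str] = field(default_factory=list)
    unscreened: set[str] = field(default_factory=set)

    def mark(self, article_id: str, label: Label) -> None:
        self.unscreened.remove(article_id)
        if label is Label.RELEVANT:
            self.screened_relevant.append(article_id)
        else:
            self.screened_irrelevant.append(article_id)


@dataclass(frozen=True)
class RunTrace:
    """Ordered record of one simulated screening run.

    ``score_snapshots[s]`` holds the score map over unscreened articles that
    was used to pick the article read at step ``s`` (absent for seed steps);
    these snapshots feed the per-step AUROC trace.
    """

    seed_pair: tuple[str, str]
    steps: tuple[StepRecord, ...]
    stop_reason: StopReason
    score_snapshots: dict[int, dict[str, float | None]] = field(default_factory=dict)

    @property
    def reads(self) -> int:
        return len(self.steps)

    def read_ids(self) -> tuple[str, ...]:
        return tuple(s.article_id for s in self.steps)

    def to_frame(self, corpus: LabeledCorpus):
        """Per-step table: cumulative counts, recall and fraction read."""
        import pandas as pd

        P = corpus.n_relevant
        m = corpus.m
        rows = []
        cum_rel = 0
        for rec in self.steps:
            cum_rel += rec.label is Label.RELEVANT
            rows.append(
                {
                    "step": rec.step,
                    "article_id": rec.article_id,
                    "true_label": rec.label.value,
                    "score": rec.score,
                    "cum_relevant": cum_rel,
                    "cum_read": rec.step,
                    "recall": cum_rel / P if P else float("nan"),
                    "fraction_read": rec.step / m,
                }
            )
        return pd.DataFrame(rows)


def init_query(F: FeatureMatrix, seed_ids: tuple[str, str]) -> np.ndarray:
    """Mean of the two seed articles' feature rows."""
    a, b = seed_ids
    if a == b:
        raise CorpusValidationError(f"seed pair must be two distinct articles, got {a!r} twice")
    return (F.row(a) + F.row(b)) / 2.0


def update_query(F: FeatureMatrix, state: ScreeningState) -> np.ndarray:
    """Mean of screened-relevant rows minus mean of screened-irrelevant rows."""
    if not state.screened_relevant:
        raise CorpusValidationError("query update requires at least one screened relevant article")
    rel = np.mean([F.row(i) for i in state.screened_relevant], axis=0)
    if not state.screened_irrelevant:
        return rel
    irr = np.mean([F.row(i) for i in state.screened_irrelevant], axis=0)
    return rel - irr


def score_unscreened(
    F: FeatureMatrix, q: np.ndarray, state: ScreeningState
) -> dict[str, float | None]:
    """Cosine similarity of the query against every unscreened feature row.

    Returns ``None`` for undefined scores (zero-norm query or row).
    """
    if q.shape != (F.n,):
        raise ValueError(f"query length {q.shape} does not match feature columns {F.n}")
    ids = sorted(state.unscreened)
    if not ids:
        return {}
    rows = np.stack([F.row(i) for i in ids])
    row_norms = np.linalg.norm(rows, axis=1)
    q_norm = np.linalg.norm(q)
    scores: dict[str, float | None] = {}
    if q_norm == 0.0:
        return {i: None for i in ids}
    sims = rows @ q / np.where(row_norms == 0.0, 1.0, row_norms) / q_norm
    for i, aid in enumerate(ids):
        scores[aid] = None if row_norms[i] == 0.0 else float(np.clip(sims[i], -1, 1))
    return scores


def select_next(scores: Mapping[str, float | None]) -> str:
    """Highest-scoring id; ties and the all-undefined case break to smallest id."""
    if not scores:
        raise ValueError("cannot select from an empty score map")
    defined = [(aid, s) for aid, s in scores.items() if s is not None]
    if not defined:
        return min(scores)
    best = max(s for _, s in defined)
    return min(aid for aid, s in defined if s == best)


def run_screening(
    F: FeatureMatrix,
    corpus: LabeledCorpus,
    seed_pair: tuple[str, str],
    budget: int | None = None,
    record_scores: bool = True,
) -> RunTrace:
    """Simulate one full screening run from a seed pair.

    Requires a fully labeled corpus (the labels are the oracle the simulated
    researcher consults). Stops when all relevant articles are screened, or
    when ``budget`` total reads (seeds included) have been spent.
    """
    if not corpus.fully_labeled():
        raise CorpusValidationError(
            "screening simulation requires a fully labeled corpus (no unknown labels)"
        )
    labels = corpus.labels()
    P = corpus.n_relevant
    if P < 2:
        raise CorpusValidationError(f"need at least 2 relevant articles, got {P}")
    for sid in seed_pair:
        if labels.get(sid) is not Label.RELEVANT:
            raise CorpusValidationError(f"seed article {sid!r} is not labeled relevant")
    if seed_pair[0] == seed_pair[1]:
        raise CorpusValidationError("seed pair must contain two distinct articles")

    # vectorized equivalent of composing update_query / score_unscreened /
    # select_next each step: articles live at sorted-id positions, so argmax
    # over an exact-equality tie lands on the lexicographically smallest id
    ids_sorted = sorted(corpus.ids)
    R = F.F
    rows_sorted = np.fromiter(
        (F.row_index(a) for a in ids_sorted), dtype=np.int64, count=len(ids_sorted)
    )
    norms_sorted = np.linalg.norm(R[rows_sorted], axis=1)
    pos_of = {aid: i for i, aid in enumerate(ids_sorted)}
    unscreened = np.ones(len(ids_sorted), dtype=bool)
    rel_rows: list[int] = []
    irr_rows: list[int] = []

    steps: list[StepRecord] = []
    snapshots: dict[int, dict[str, float | None]] = {}

    def mark(aid: str) -> None:
        unscreened[pos_of[aid]] = False
        (rel_rows if labels[aid] is Label.RELEVANT else irr_rows).append(
            int(rows_sorted[pos_of[aid]])
        )

    for sid in seed_pair:
        mark(sid)
        steps.append(
            StepRecord(step=len(steps) + 1, article_id=sid, label=Label.RELEVANT,
                       score=None, is_seed=True)
        )

    stop_reason = StopReason.ALL_RELEVANT_FOUND
    while len(rel_rows) < P:
        if budget is not None and len(steps) >= budget:
            stop_reason = StopReason.BUDGET_EXHAUSTED
            break
        q = np.mean(R[rel_rows], axis=0)
        if irr_rows:
            q = q - np.mean(R[irr_rows], axis=0)
        qn = np.linalg.norm(q)
        un_pos = np.flatnonzero(unscreened)
        sub_rows = rows_sorted[un_pos]
        nsub = norms_sorted[un_pos]
        defined = nsub != 0.0
        if qn == 0.0 or not defined.any():
            sims = None
            chosen_j = 0  # all scores undefined: smallest unscreened id
            chosen_score = None
        else:
            sims = np.clip(R[sub_rows] @ q / np.where(nsub == 0.0, 1.0, nsub) / qn, -1, 1)
            chosen_j = int(np.argmax(np.where(defined, sims, -np.inf)))
            chosen_score = float(sims[chosen_j])
        chosen = ids_sorted[un_pos[chosen_j]]
        step_no = len(steps) + 1
        if record_scores:
            if sims is None:
                snapshots[step_no] = {ids_sorted[p]: None for p in un_pos}
            else:
                vals = sims.tolist()
                snapshots[step_no] = {
                    ids_sorted[p]: (vals[j] if defined[j] else None)
                    for j, p in enumerate(un_pos)
                }
        mark(chosen)
        steps.append(
            StepRecord(step=step_no, article_id=chosen, label=labels[chosen],
                       score=chosen_score)
        )

    return RunTrace(
        seed_pair=seed_pair,
        steps=tuple(steps),
        stop_reason=stop_reason,
        score_snapshots=snapshots,
    )


def enumerate_seed_pairs(corpus: LabeledCorpus) -> list[tuple[str, str]]:
    """All C(P,2) unordered pairs of relevant-article ids, in lexicographic order.

    Sweeping every pair measures how sensitive performance is to the
    researcher's choice of the two starting articles.
    """
    rel = sorted(corpus.relevant_ids())
    if len(rel) < 2:
        raise CorpusValidationError(
            f"need at least 2 relevant articles to form seed pairs, got {len(rel)}"
        )
    return [(a, b) for i, a in enumerate(rel) for b in rel[i + 1 :]]
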