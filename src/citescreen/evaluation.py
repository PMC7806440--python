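"""Retrospective performance metrics for screening runs.

Work saved over sampling at R% recall,

    WSS@R = (N - n_read)/N - (1 - R/100),

compares the number of articles actually read when R% of the relevant
articles have been found (``n_read``) against the expected reading effort of
random-order screening; the required relevant count is ``ceil(R/100 * P)``
with no interpolation between steps. At R=100 with a run that stops when the
last relevant article is found, WSS@100 reduces exactly to
``1 - reading_ratio``.

Per-step discrimination is the AUROC of the selection scores over the
articles still unscreened at that step: the Mann-Whitney probability that a
randomly chosen relevant article outscores a randomly chosen irrelevant
one (ties counted one half). Steps where the unscreened pool is
single-class, or where fewer than one relevant and one irrelevant article
have defined scores, have undefined AUROC and are omitted from aggregates
rather than imputed.

``sweep`` repeats a full run for every possible seed pair and aggregates
WSS@95, WSS@100 and final AUROC as mean, SD (sample), min and max — the
shape of a per-review results table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .active_learning import RunTrace, StopReason, enumerate_seed_pairs, run_screening
from .corpus import Label, LabeledCorpus
from .embedding import FeatureMatrix

__all__ = [
    "RecallCurve",
    "WSSResult",
    "AUROCTrace",
    "SweepSummary",
    "recall_curve",
    "reading_ratio",
    "wss_at",
    "auroc",
    "auroc_trace",
    "sweep",
]


@dataclass(frozen=True)
class RecallCurve:
    """(reads, recall) after each step; recall is non-decreasing."""

    points: tuple[tuple[int, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["reads", "recall"])


@dataclass(frozen=True)
class WSSResult:
    """Work saved over sampling at recall level R.

    ``attained`` is False when the trace never reaches R% recall (possible
    under a reading budget); ``n_read`` and ``wss`` are then None.
    """

    R: float
    n_read: int | None
    wss: float | None
    attained: bool


@dataclass(frozen=True)
class AUROCTrace:
    """Per-step AUROC over unscreened articles; None where undefined."""

    points: tuple[tuple[int, float | None], ...]

    def defined(self) -> tuple[tuple[int, float], ...]:
        return tuple((s, a) for s, a in self.points if a is not None)

    def final(self) -> float | None:
        d = self.defined()
        return d[-1][1] if d else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["step", "auroc"])


def recall_curve(trace: RunTrace, corpus: LabeledCorpus) -> RecallCurve:
    P = corpus.n_relevant
    if P == 0:
        raise ValueError("recall undefined for a corpus with no relevant articles")
    pts = []
    found = 0
    for rec in trace.steps:
        found += rec.label is Label.RELEVANT
        pts.append((rec.step, found / P))
    return RecallCurve(points=tuple(pts))


def reading_ratio(trace: RunTrace, corpus: LabeledCorpus) -> float:
    """Articles read at stop divided by corpus size."""
    if corpus.m == 0:
        raise ValueError("reading ratio undefined for an empty corpus")
    return trace.reads / corpus.m


def wss_at(trace: RunTrace, corpus: LabeledCorpus, R: float = 95.0) -> WSSResult:
    if not 0.0 < R <= 100.0:
        raise ValueError(f"recall level R must be in (0, 100], got {R}")
    P = corpus.n_relevant
    N = corpus.m
    if P == 0:
        raise ValueError("WSS undefined for a corpus with no relevant articles")
    needed = math.ceil(R / 100.0 * P)
    found = 0
    for rec in trace.steps:
        found += rec.label is Label.RELEVANT
        if found >= needed:
            n_read = rec.step
            # R/100 - n_read/N, the same quantity as (N-n_read)/N - (1-R/100)
            # but rounded identically to 1 - reading_ratio at R=100
            return WSSResult(
                R=R, n_read=n_read,
                wss=R / 100.0 - n_read / N,
                attained=True,
            )
    return WSSResult(R=R, n_read=None, wss=None, attained=False)


def auroc(
    scores: Mapping[str, float | None], labels: Mapping[str, Label]
) -> float | None:
    """Probability a random relevant article outscores a random irrelevant one.

    Articles with undefined scores are excluded; returns None unless at
    least one relevant and one irrelevant article have defined scores.
    """
    y, s = [], []
    for aid, score in scores.items():
        if score is None:
            continue
        lab = labels[aid]
        if lab is Label.UNKNOWN:
            continue
        y.append(1 if lab is Label.RELEVANT else 0)
        s.append(score)
    if len(set(y)) < 2:
        return None
    return float(roc_auc_score(y, s))


def auroc_trace(trace: RunTrace, corpus: LabeledCorpus) -> AUROCTrace:
    """AUROC of the selection scores at every ranked step of a run.

    Requires the per-step score snapshots retained by ``run_screening``;
    seed steps (no ranking happened) are not part of the trace.
    """
    if not trace.score_snapshots and trace.reads > 2:
        raise ValueError("trace carries no score snapshots (record_scores=False?)")
    labels = corpus.labels()
    pts = []
    for step in sorted(trace.score_snapshots):
        pts.append((step, auroc(trace.score_snapshots[step], labels)))
    return AUROCTrace(points=tuple(pts))


def _final_auroc(trace: RunTrace, labels: Mapping[str, Label]) -> float | None:
    """AUROC at the last step where it is defined (walked from the end)."""
    for step in sorted(trace.score_snapshots, reverse=True):
        val = auroc(trace.score_snapshots[step], labels)
        if val is not None:
            return val
    return None


def _aggregate(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=np.float64)
    if arr.size == 0:
        return {"mean": float("nan"), "sd": float("nan"),
                "min": float("nan"), "max": float("nan")}
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd,
            "min": float(arr.min()), "max": float(arr.max())}


@dataclass(frozen=True)
class SweepSummary:
    """Seed-pair sweep results: one row per pair plus mean/SD/min/max aggregates."""

    per_pair: pd.DataFrame
    wss95: dict[str, float]
    wss100: dict[str, float]
    auroc_final: dict[str, float]

    @property
    def pair_count(self) -> int:
        return len(self.per_pair)

    def to_dict(self) -> dict:
        return {
            "pair_count": self.pair_count,
            "wss95": self.wss95,
            "wss100": self.wss100,
            "auroc_final": self.auroc_final,
        }


def sweep(
    F: FeatureMatrix,
    corpus: LabeledCorpus,
    budget: int | None = None,
    keep_traces: bool = False,
) -> SweepSummary | tuple[SweepSummary, list[RunTrace]]:
    """Run the screening simulation once per possible seed pair and aggregate.

    Deterministic given the feature matrix. Errors inside a run are
    re-raised annotated with the offending seed pair.
    """
    pairs = enumerate_seed_pairs(corpus)
    labels = corpus.labels()
    rows = []
    traces = []
    for pair in pairs:
        try:
            trace = run_screening(F, corpus, pair, budget=budget)
            w95 = wss_at(trace, corpus, 95.0)
            w100 = wss_at(trace, corpus, 100.0)
            final_auroc = _final_auroc(trace, labels)
        except Exception as exc:
            raise RuntimeError(f"sweep failed for seed pair {pair}") from exc
        rows.append(
            {
                "seed_a": pair[0],
                "seed_b": pair[1],
                "reads": trace.reads,
                "reading_ratio": reading_ratio(trace, corpus),
                "wss95": w95.wss,
                "wss100": w100.wss,
                "auroc_final": final_auroc,
                "stop_reason": trace.stop_reason.value,
            }
        )
        if keep_traces:
            traces.append(trace)
    per_pair = pd.DataFrame(rows)
    summary = SweepSummary(
        per_pair=per_pair,
        wss95=_aggregate(per_pair["wss95"].tolist()),
        wss100=_aggregate(per_pair["wss100"].tolist()),
        auroc_final=_aggregate(per_pair["auroc_final"].tolist()),
    )
    return (summary, traces) if keep_traces else summary


def mean_recall_curve(traces: Sequence[RunTrace], corpus: LabeledCorpus) -> pd.DataFrame:
    """Average cumulative recall over runs, per read count.

    Runs that stopped before a given read count contribute recall 1.0 there
    (all relevant had been found), so the curve reflects the average recall
    a reviewer following the ranking would have attained.
    """
    max_reads = max(t.reads for t in traces)
    acc = np.zeros(max_reads)
    for t in traces:
        rc = recall_curve(t, corpus)
        vals = np.asarray([r for _, r in rc.points])
        padded = np.concatenate([vals, np.full(max_reads - vals.size, vals[-1])])
        acc += padded
    acc /= len(traces)
    return pd.DataFrame({"reads": np.arange(1, max_reads + 1), "mean_recall": acc})


def mean_auroc_trace(traces: Sequence[RunTrace], corpus: LabeledCorpus) -> pd.DataFrame:
    """Across-run mean and SD of the per-step AUROC (undefined steps omitted)."""
    per_step: dict[int, list[float]] = {}
    for t in traces:
        for step, val in auroc_trace(t, corpus).defined():
            per_step.setdefault(step, []).append(val)
    rows = [
        {
            "step": step,
            "mean_auroc": float(np.mean(vals)),
            "sd_auroc": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_runs": len(vals),
        }
        for step, vals in sorted(per_step.items())
    ]
    return pd.DataFrame(rows)
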