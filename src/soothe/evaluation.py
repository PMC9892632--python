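"""Ranking metrics, controller accuracy, survey arithmetic, and the
seeded recovery experiments that validate the whole stack end to end.

Survey summaries reproduce count-table arithmetic: proportions are
100 * count / n_total rounded half-up to one decimal, rendered without
a trailing ".0" (the style survey tables typically print).

The two experiment drivers are the package's study conditions:

* ``planted_recovery_experiment`` — generate a cohort with block
  structure, hold out part of each patient's history, and compare
  item-CF recall@K on held-out in-block likes against an empirical
  random-recommender baseline over many seeds;
* ``state_recovery_experiment`` — generate heart-rate traces from a
  known state schedule and score the threshold controller's per-sample
  state classification accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .biofeedback import ThresholdConfig, classify_heart_rate
from .collaborative import (
    build_interaction_store,
    build_item_similarity_matrix,
    build_user_similarity_matrix,
)
from .hybrid import HybridConfig, recommend
from .synthetic import (
    SynthConfig,
    generate_cohort_interactions,
    generate_corpus,
    generate_heart_rate_trace,
    schedule_states,
)


def precision_recall_at_k(
    recommended: Sequence[str], relevant: set[str] | frozenset[str], k: int
) -> tuple[float, float]:
    """Precision and recall of the top-K of a ranked list.

    precision = hits / K, recall = hits / |relevant|.  An empty
    relevant set leaves recall undefined: NaN is returned so callers
    must handle the degenerate case explicitly.
    """
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    top = list(recommended)[:k]
    hits = sum(1 for tid in top if tid in relevant)
    precision = hits / k
    recall = hits / len(relevant) if relevant else float("nan")
    return precision, recall


@dataclass(frozen=True)
class SatisfactionCounts:
    """One survey row: counts of the three satisfaction levels."""

    group: str
    very_satisfied: int
    satisfied: int
    dissatisfied: int
    n_total: int

    def __post_init__(self) -> None:
        counts = (self.very_satisfied, self.satisfied, self.dissatisfied)
        if any(c < 0 for c in counts) or self.n_total < 1:
            raise ValueError(f"negative count or empty group in {self.group!r}")
        if sum(counts) != self.n_total:
            raise ValueError(
                f"counts {counts} sum to {sum(counts)}, not n_total={self.n_total} "
                f"({self.group!r})"
            )


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def satisfaction_summary(
    counts: SatisfactionCounts,
) -> tuple[float, float, float]:
    """Proportions (%) of the three levels, half-up to one decimal."""
    return tuple(
        _round_half_up_1dp(100.0 * c / counts.n_total)
        for c in (counts.very_satisfied, counts.satisfied, counts.dissatisfied)
    )


def format_proportion(p: float) -> str:
    """Render a proportion the way survey tables print it: 12 not 12.0."""
    return f"{p:.1f}".rstrip("0").rstrip(".")


def state_accuracy(
    classified: Sequence[str], truth: Sequence[str]
) -> float:
    """Fraction of samples whose classified state matches the schedule."""
    if len(classified) != len(truth):
        raise ValueError(
            f"time-grid mismatch: {len(classified)} classified vs {len(truth)} truth samples"
        )
    if not truth:
        raise ValueError("empty state sequences")
    return sum(1 for a, b in zip(classified, truth) if a == b) / len(truth)


# --------------------------------------------------------------------------
# seeded recovery experiments


@dataclass(frozen=True)
class RecoveryResult:
    """Aggregate of the planted-block recovery experiment."""

    mean_recall: float  # item-CF recall@K, averaged over seeds and patients
    mean_baseline: float  # random-recommender recall@K, same protocol
    factor: float  # mean_recall / mean_baseline
    z_score: float  # (mean_recall - mean_baseline) / MC standard error
    n_seeds: int
    k: int


def _holdout_split(
    liked: list[str], rng: np.random.Generator, holdout_frac: float
) -> tuple[list[str], list[str]]:
    """Split a history into train/held-out; at least one item on each side."""
    if len(liked) < 2:
        return liked, []
    n_hold = max(1, int(round(holdout_frac * len(liked))))
    n_hold = min(n_hold, len(liked) - 1)
    held_idx = set(rng.choice(len(liked), size=n_hold, replace=False).tolist())
    train = [t for i, t in enumerate(liked) if i not in held_idx]
    held = [t for i, t in enumerate(liked) if i in held_idx]
    return train, held


_ENGINES = {
    "item": HybridConfig(beta=0.0, cf_variant="item"),
    "user": HybridConfig(beta=0.0, cf_variant="user"),
    "content": HybridConfig(beta=1.0),
    "hybrid": HybridConfig(beta=0.5, cf_variant="item"),
}


def planted_recovery_experiment(
    config: SynthConfig,
    *,
    engine: str = "item",
    n_seeds: int = 20,
    k: int = 10,
    holdout_frac: float = 0.3,
) -> RecoveryResult:
    """Can item-CF recover held-out in-block likes from a planted cohort?

    For each seed: generate the library and cohort, hold out
    ``holdout_frac`` of each patient's likes, recommend top-K with the
    pure item-CF engine (beta = 0) from the training store, and score
    recall against the held-out in-block likes.  The baseline draws a
    uniformly random K-subset of the same candidate pool (catalog minus
    training history) through the same scorer.  Means are paired over
    the same patients and seeds; the z-score uses the Monte-Carlo
    standard error of the per-seed recall difference.
    """
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {sorted(_ENGINES)}")
    per_seed_recall: list[float] = []
    per_seed_baseline: list[float] = []
    base = _ENGINES[engine]
    hconfig = replace(base, k=k, neighborhood_k=k)
    for s in range(n_seeds):
        cfg = replace(config, seed=(config.seed + 1000 * (s + 1)) % (2**31))
        corpus = generate_corpus(cfg)
        records, blocks = generate_cohort_interactions(cfg, corpus)
        rng = np.random.default_rng([cfg.seed % (2**31), 77])

        by_user: dict[str, list[str]] = {}
        for u, y in records:
            by_user.setdefault(u, []).append(y)

        train_records: list[tuple[str, str]] = []
        held_by_user: dict[str, list[str]] = {}
        for u in sorted(by_user):
            train, held = _holdout_split(sorted(by_user[u]), rng, holdout_frac)
            train_records.extend((u, y) for y in train)
            held_by_user[u] = held

        store = build_interaction_store(train_records)
        sims = None
        if hconfig.beta < 1.0 and hconfig.cf_variant == "item":
            sims = build_item_similarity_matrix(
                store, items=corpus.track_ids, penalized=True
            )
        elif hconfig.beta < 1.0:
            sims = build_user_similarity_matrix(store, penalized=True)
        cat_of = {t.track_id: t.category for t in corpus.tracks}

        recalls, baselines = [], []
        for u in sorted(held_by_user):
            relevant = {
                y for y in held_by_user[u] if cat_of[y] == blocks[u]
            }
            if not relevant or u not in store.user_items:
                continue
            rec = recommend(u, corpus, store, hconfig, sims=sims)
            _, r = precision_recall_at_k(rec.track_ids, relevant, k)
            recalls.append(r)
            candidates = [
                t for t in corpus.track_ids if t not in store.user_items[u]
            ]
            pick = rng.choice(
                len(candidates), size=min(k, len(candidates)), replace=False
            )
            random_top = [candidates[i] for i in pick.tolist()]
            _, rb = precision_recall_at_k(random_top, relevant, k)
            baselines.append(rb)
        if recalls:
            per_seed_recall.append(float(np.mean(recalls)))
            per_seed_baseline.append(float(np.mean(baselines)))

    mean_r = float(np.mean(per_seed_recall))
    mean_b = float(np.mean(per_seed_baseline))
    diffs = np.array(per_seed_recall) - np.array(per_seed_baseline)
    se = float(np.std(diffs, ddof=1) / math.sqrt(len(diffs))) if len(diffs) > 1 else float("nan")
    z = (mean_r - mean_b) / se if se and se > 0 else float("inf")
    factor = mean_r / mean_b if mean_b > 0 else float("inf")
    return RecoveryResult(mean_r, mean_b, factor, z, n_seeds, k)


def state_recovery_experiment(
    config: SynthConfig,
    thresholds: ThresholdConfig,
    schedule: Sequence[tuple[str, float]],
    *,
    n_seeds: int = 20,
) -> float:
    """Mean per-sample state-classification accuracy over seeds.

    Each seed generates a fresh trace from the schedule; the controller
    classifies every sample and accuracy is scored against the known
    schedule labels.
    """
    truth = schedule_states(schedule, config.sampling_hz)
    accs = []
    for s in range(n_seeds):
        cfg = replace(config, seed=(config.seed + 1000 * (s + 1)) % (2**31))
        trace = generate_heart_rate_trace(schedule, cfg)
        classified = [
            classify_heart_rate(x.hr_bpm, thresholds)[0] for x in trace
        ]
        accs.append(state_accuracy(classified, truth))
    return float(np.mean(accs))
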