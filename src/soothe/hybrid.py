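"""Weighted fusion of the content and collaborative engines.

The fused preference is the convex combination
``G = beta * content + (1 - beta) * cf`` with beta in [0, 1]: beta = 1
recovers the pure content ranking, beta = 0 the pure collaborative
ranking.  Because the two engines score on different scales (cosines in
[0, 1] vs unbounded similarity sums), both candidate score sets are
min-max normalized before fusion by default; without a shared scale
beta is uninterpretable.

Candidates are all corpus tracks outside the patient's history,
optionally restricted to one soothing level when the biofeedback
controller drives the session.  The top-K list is deterministic: score
descending, ties by ascending track id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .collaborative import (
    InteractionStore,
    SimilarityMatrix,
    build_item_similarity_matrix,
    build_user_similarity_matrix,
    item_cf_score,
    user_cf_score,
)
from .corpus import (
    Corpus,
    PreferenceMatrix,
    build_preference_matrix,
    content_score,
    neutral_profile,
    patient_profile,
)


@dataclass(frozen=True)
class HybridConfig:
    """Fusion settings.

    beta            weight of the content engine, in [0, 1]
    k               recommendation list length
    cf_variant      "user" or "item" collaborative engine
    normalization   "minmax" (default) or "none"
    neighborhood_k  K of the CF neighborhoods (defaults to k)
    """

    beta: float = 0.5
    k: int = 10
    cf_variant: str = "item"
    normalization: str = "minmax"
    neighborhood_k: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.cf_variant not in ("user", "item"):
            raise ValueError(f"cf_variant must be 'user' or 'item', got {self.cf_variant!r}")
        if self.normalization not in ("minmax", "none"):
            raise ValueError(f"normalization must be 'minmax' or 'none', got {self.normalization!r}")

    @property
    def cf_k(self) -> int:
        return self.neighborhood_k if self.neighborhood_k is not None else self.k


@dataclass(frozen=True)
class RecommendationList:
    """Ranked playlist for one patient with the config that produced it."""

    patient: str
    items: tuple[tuple[str, float], ...]
    config: HybridConfig
    cold_start: bool = False
    category: str | None = None

    @property
    def track_ids(self) -> tuple[str, ...]:
        return tuple(tid for tid, _ in self.items)


def normalize_scores(
    scores: Mapping[str, float], method: str = "minmax"
) -> dict[str, float]:
    """Rescale candidate scores to [0, 1].

    minmax maps (s - min) / (max - min); a constant score set maps to
    0.5 everywhere (no information either way).  "none" is the
    identity.  Empty input is an error.
    """
    if not scores:
        raise ValueError("cannot normalize an empty candidate score set")
    if method == "none":
        return dict(scores)
    if method != "minmax":
        raise ValueError(f"unknown normalization method {method!r}")
    lo = min(scores.values())
    hi = max(scores.values())
    if hi == lo:
        return {k: 0.5 for k in scores}
    span = hi - lo
    return {k: (v - lo) / span for k, v in scores.items()}


def hybrid_score(content: float, cf: float, beta: float) -> float:
    """Convex combination beta * content + (1 - beta) * cf."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    return beta * content + (1 - beta) * cf


def recommend(
    patient: str,
    corpus: Corpus,
    store: InteractionStore,
    config: HybridConfig,
    *,
    category: str | None = None,
    matrix: PreferenceMatrix | None = None,
    sims: SimilarityMatrix | None = None,
) -> RecommendationList:
    """Produce the top-K fused playlist for one patient.

    Candidates are corpus tracks outside the patient's history,
    restricted to ``category`` (a soothing level) when given.  A
    cold-start patient — absent from the store or with an empty
    history — is ranked purely by content against a neutral uniform
    profile and the list is flagged.
    """
    if matrix is None:
        matrix = build_preference_matrix(corpus)

    history = frozenset(store.user_items.get(patient, frozenset()))
    cold = len(history) == 0

    candidates = [
        t.track_id
        for t in corpus.tracks
        if t.track_id not in history
        and (category is None or t.soothing_level == category)
    ]
    if not candidates:
        raise ValueError(
            f"no candidate tracks for patient {patient!r}"
            + (f" at soothing level {category!r}" if category else "")
        )

    if cold:
        profile = neutral_profile(matrix)
        beta = 1.0
    else:
        profile = patient_profile(sorted(history), matrix)
        beta = config.beta

    content_raw = {
        tid: content_score(profile, matrix.track_vector(tid))
        for tid in candidates
    }

    if cold or beta == 1.0:
        cf_raw = {tid: 0.0 for tid in candidates}
    elif config.cf_variant == "user":
        if sims is None:
            sims = build_user_similarity_matrix(store, penalized=True)
        cf_raw = {
            tid: user_cf_score(patient, tid, store, sims, config.cf_k)
            for tid in candidates
        }
    else:
        if sims is None:
            sims = build_item_similarity_matrix(
                store, items=corpus.track_ids, penalized=True
            )
        cf_raw = {
            tid: item_cf_score(patient, tid, store, sims, config.cf_k)
            for tid in candidates
        }

    c_scores = normalize_scores(content_raw, config.normalization)
    cf_scores = normalize_scores(cf_raw, config.normalization)
    fused = {
        tid: hybrid_score(c_scores[tid], cf_scores[tid], beta)
        for tid in candidates
    }
    ranked = sorted(fused.items(), key=lambda kv: (-kv[1], kv[0]))
    return RecommendationList(
        patient,
        tuple(ranked[: config.k]),
        replace(config, beta=beta) if cold else config,
        cold_start=cold,
        category=category,
    )
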