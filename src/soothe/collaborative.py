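"""User- and item-based collaborative filtering over implicit feedback.

The behavior history is a set Q(u) of tracks each patient liked, with
its inverted index Q(y) — the audience of each track.  Ratings default
to binary implicit feedback (R = 1 for every stored pair) and may be
overridden with explicit values in [0, 5].

User-user similarity is set cosine |Q(u) ∩ Q(v)| / sqrt(|Q(u)||Q(v)|),
optionally replacing each co-liked item's unit contribution by the
popularity penalty 1 / log10(1 + |Q(a)|) so that ubiquitous tracks
carry less evidence of shared taste.  The penalty factor exceeds 1 when
an item's audience is below 9 (there log10(1 + n) < 1), so penalized
user similarity is bounded by 1 only in the large-audience regime the
penalty is designed for.  Item-item similarity comes in an
asymmetric conditional form |Q(h) ∩ Q(y)| / |Q(h)| and the symmetric
penalized form |Q(h) ∩ Q(y)| / sqrt(|Q(h)||Q(y)|); the co-occurrence
path accumulates shared-audience counts user by user from the inverted
index and must agree exactly with the direct pairwise computation.

Neighborhood scores sum similarity x rating over the K nearest
neighbors, in ascending neighbor-id order so every float is exactly
reproducible by an independent recomputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class InteractionError(ValueError):
    """Unknown user/item id or malformed interaction data."""


@dataclass
class InteractionStore:
    """Forward and inverted maps of the liked-track history.

    Invariant: u in item_users[y] iff y in user_items[u]; ratings exist
    exactly for stored (user, item) pairs.
    """

    user_items: dict[str, frozenset[str]]
    item_users: dict[str, frozenset[str]]
    ratings: dict[tuple[str, str], float]
    n_rejected: int = 0

    @property
    def users(self) -> tuple[str, ...]:
        return tuple(sorted(self.user_items))

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(sorted(self.item_users))

    def liked(self, user: str) -> frozenset[str]:
        if user not in self.user_items:
            raise InteractionError(f"unknown user {user!r}")
        return self.user_items[user]

    def audience(self, item: str) -> frozenset[str]:
        return self.item_users.get(item, frozenset())

    def rating(self, user: str, item: str) -> float:
        return self.ratings.get((user, item), 0.0)


def build_interaction_store(
    records: Iterable[Sequence],
) -> InteractionStore:
    """Deduplicate interaction records into a consistent store.

    Each record is (user_id, item_id) or (user_id, item_id, rating);
    a later duplicate overwrites the rating.  Records with a missing id
    are rejected and counted in ``n_rejected`` rather than raising.
    """
    user_items: dict[str, set[str]] = {}
    item_users: dict[str, set[str]] = {}
    ratings: dict[tuple[str, str], float] = {}
    rejected = 0
    for rec in records:
        if len(rec) < 2 or not rec[0] or not rec[1]:
            rejected += 1
            continue
        u, y = str(rec[0]), str(rec[1])
        r = 1.0
        if len(rec) >= 3 and rec[2] is not None and rec[2] == rec[2]:
            r = float(rec[2])
            if not 0.0 <= r <= 5.0:
                rejected += 1
                continue
        user_items.setdefault(u, set()).add(y)
        item_users.setdefault(y, set()).add(u)
        ratings[(u, y)] = r
    return InteractionStore(
        {u: frozenset(s) for u, s in user_items.items()},
        {y: frozenset(s) for y, s in item_users.items()},
        ratings,
        rejected,
    )


def user_similarity(
    u: str,
    v: str,
    store: InteractionStore,
    *,
    penalized: bool = False,
    sqrt_denominator: bool = True,
) -> float:
    """Taste similarity of two patients from their liked-track sets.

    Unpenalized: |Q(u) ∩ Q(v)| over the (root of the) product of set
    sizes.  Penalized: each co-liked item a contributes
    1 / log10(1 + |Q(a)|) instead of 1, down-weighting popular tracks.
    ``sqrt_denominator=False`` selects the plain product denominator
    (the non-cosine variant) instead of the default cosine form.
    Symmetric in (u, v); zero when either history is empty.
    """
    qu, qv = store.liked(u), store.liked(v)
    if not qu or not qv:
        return 0.0
    denom = len(qu) * len(qv)
    if sqrt_denominator:
        denom = math.sqrt(denom)
    if not penalized:
        return len(qu & qv) / denom
    num = 0.0
    for a in sorted(qu & qv):
        num += 1.0 / math.log10(1 + len(store.audience(a)))
    return num / denom


@dataclass
class SimilarityMatrix:
    """Pairwise similarities among users or among items.

    Values lie in [0, 1] (penalized user similarities only when
    co-liked audiences are >= 9; see the module docstring) and the
    matrix is symmetric, except the item matrix built from the
    asymmetric conditional form, which is marked ``symmetric=False``.
    The diagonal is stored as 1 but never enters a neighborhood.
    """

    kind: str  # "user" | "item"
    labels: tuple[str, ...]
    values: np.ndarray
    penalized: bool = False
    symmetric: bool = True
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def sim(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as e:
            raise InteractionError(f"unknown {self.kind} id {e.args[0]!r}") from None


def build_user_similarity_matrix(
    store: InteractionStore,
    *,
    penalized: bool = True,
    sqrt_denominator: bool = True,
) -> SimilarityMatrix:
    users = store.users
    n = len(users)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            z = user_similarity(
                users[i], users[j], store,
                penalized=penalized, sqrt_denominator=sqrt_denominator,
            )
            values[i, j] = values[j, i] = z
    return SimilarityMatrix("user", users, values, penalized=penalized)


def item_similarity(
    h: str,
    y: str,
    store: InteractionStore,
    *,
    penalized: bool = True,
) -> float:
    """Audience overlap of two tracks.

    Penalized (symmetric): |Q(h) ∩ Q(y)| / sqrt(|Q(h)||Q(y)|), which
    caps the similarity any track can have to a very popular one.
    Unpenalized (asymmetric conditional): |Q(h) ∩ Q(y)| / |Q(h)|.
    Zero when either audience is empty.
    """
    qh, qy = store.audience(h), store.audience(y)
    if not qh or not qy:
        return 0.0
    shared = len(qh & qy)
    if penalized:
        return shared / math.sqrt(len(qh) * len(qy))
    return shared / len(qh)


def build_item_similarity_matrix(
    store: InteractionStore,
    items: Sequence[str] | None = None,
    *,
    penalized: bool = True,
) -> SimilarityMatrix:
    """Direct pairwise item similarity over ``items`` (default: stored items)."""
    labels = tuple(sorted(items)) if items is not None else store.items
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            values[i, j] = item_similarity(
                labels[i], labels[j], store, penalized=penalized
            )
    return SimilarityMatrix(
        "item", labels, values, penalized=penalized, symmetric=penalized
    )


def build_cooccurrence_matrix(
    store: InteractionStore,
    items: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Symmetric item similarity via the co-occurrence path.

    Shared-audience counts are accumulated user by user from the
    forward histories (the dual of walking the inverted index), then
    normalized by sqrt(|Q(h)||Q(y)|).  Counts are integers, so this
    equals the direct pairwise computation exactly, not just to
    tolerance.
    """
    labels = tuple(sorted(items)) if items is not None else store.items
    index = {y: i for i, y in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=np.int64)
    for u in store.users:
        liked = sorted(y for y in store.user_items[u] if y in index)
        for a in range(len(liked)):
            ia = index[liked[a]]
            for b in range(a + 1, len(liked)):
                ib = index[liked[b]]
                counts[ia, ib] += 1
                counts[ib, ia] += 1
    values = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nh = len(store.audience(labels[i]))
            ny = len(store.audience(labels[j]))
            if nh == 0 or ny == 0:
                values[i, j] = 0.0
            else:
                values[i, j] = int(counts[i, j]) / math.sqrt(nh * ny)
    return SimilarityMatrix("item", labels, values, penalized=True)


@dataclass(frozen=True)
class Neighborhood:
    """The K nearest neighbors of an entity, similarity-descending.

    Ties are broken by ascending entity id so neighborhoods are
    deterministic across runs; the entity itself is excluded.
    """

    entity: str
    neighbors: tuple[tuple[str, float], ...]
    k: int

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(nid for nid, _ in self.neighbors)


def top_k_neighbors(entity: str, sims: SimilarityMatrix, k: int) -> Neighborhood:
    """Select the K most similar entities, excluding the entity itself."""
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    if entity not in sims._index:
        raise InteractionError(f"unknown {sims.kind} id {entity!r}")
    cand = [
        (lab, sims.sim(entity, lab)) for lab in sims.labels if lab != entity
    ]
    cand.sort(key=lambda t: (-t[1], t[0]))
    return Neighborhood(entity, tuple(cand[:k]), k)


def user_cf_score(
    u: str,
    y: str,
    store: InteractionStore,
    sims: SimilarityMatrix,
    k: int,
) -> float:
    """User-based preference of patient u for track y.

    Sum of similarity x rating over the K nearest neighbors of u that
    have y in their history; 0 when none do.  Accumulated in ascending
    neighbor-id order.
    """
    store.liked(u)  # raises on unknown user; an audience-less track scores 0
    hood = top_k_neighbors(u, sims, k)
    score = 0.0
    for v, z in sorted(hood.neighbors):
        if y in store.user_items.get(v, frozenset()):
            score += z * store.rating(v, y)
    return score


def item_cf_score(
    u: str,
    y: str,
    store: InteractionStore,
    sims: SimilarityMatrix,
    k: int,
) -> float:
    """Item-based preference of patient u for track y.

    Sum over tracks h the patient liked that fall in the K-neighborhood
    of y, of similarity(h, y) x rating(u, h); 0 when the history misses
    the neighborhood entirely.  Accumulated in ascending h order.
    """
    liked = store.liked(u)
    hood_ids = set(top_k_neighbors(y, sims, k).ids)
    score = 0.0
    for h in sorted(liked & hood_ids):
        score += sims.sim(h, y) * store.rating(u, h)
    return score
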