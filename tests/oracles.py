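"""Independent brute-force oracles used by the test suite.

These reimplement every scored quantity with plain Python set/loop
arithmetic, independent of the library's code paths, accumulating sums
in the same documented order (vocabulary order, ascending ids) so that
agreement can be asserted bit-for-bit, not merely to tolerance.
"""

from __future__ import annotations

import math
from collections import Counter


def oracle_tokenize(text: str) -> Counter:
    out: Counter = Counter()
    word = []
    for ch in text.lower():
        if ch.isalnum():
            word.append(ch)
        else:
            if word:
                out["".join(word)] += 1
            word = []
    if word:
        out["".join(word)] += 1
    return out


def oracle_tf(term: str, tokens: Counter) -> float:
    total = sum(tokens.values())
    return tokens.get(term, 0) / total if total else 0.0


def oracle_idf(term: str, docs: dict[str, Counter]) -> float:
    q_total = len(docs)
    q = sum(1 for c in docs.values() if term in c)
    if q == 0:
        return math.log10(q_total / (1 + q))
    return math.log10(q_total / q)


def oracle_preference_matrix(
    docs: dict[str, Counter], track_order: list[str], vocab: list[str]
) -> list[list[float]]:
    """Row-wise TF-IDF with L2 normalization, cell by cell."""
    rows = []
    for tid in track_order:
        raw = [oracle_tf(x, docs[tid]) * oracle_idf(x, docs) for x in vocab]
        sq = 0.0
        for w in raw:
            sq += w * w
        if sq == 0.0:
            rows.append(raw)
        else:
            norm = math.sqrt(sq)
            rows.append([w / norm for w in raw])
    return rows


def oracle_profile(rows: dict[str, list[float]], liked: list[str]) -> list[float]:
    m = len(next(iter(rows.values()))) if rows else 0
    total = [0.0] * m
    for tid in sorted(liked):
        total = [a + b for a, b in zip(total, rows[tid])]
    sq = 0.0
    for w in total:
        sq += w * w
    if sq == 0.0:
        return total
    norm = math.sqrt(sq)
    return [w / norm for w in total]


def oracle_dot(a: list[float], b: list[float]) -> float:
    s = 0.0
    for x, y in zip(a, b):
        s += x * y
    return s


# ------------------------------------------------------------ collaborative


def oracle_user_sim(
    likes: dict[str, set[str]], u: str, v: str, *, penalized: bool,
    sqrt_denominator: bool = True,
) -> float:
    qu, qv = likes[u], likes[v]
    if not qu or not qv:
        return 0.0
    denom = len(qu) * len(qv)
    if sqrt_denominator:
        denom = math.sqrt(denom)
    if not penalized:
        return len(qu & qv) / denom
    audiences = {
        y: {w for w, s in likes.items() if y in s}
        for y in set.union(*likes.values())
    }
    num = 0.0
    for a in sorted(qu & qv):
        num += 1.0 / math.log10(1 + len(audiences[a]))
    return num / denom


def oracle_item_sim(
    likes: dict[str, set[str]], h: str, y: str, *, penalized: bool
) -> float:
    qh = {u for u, s in likes.items() if h in s}
    qy = {u for u, s in likes.items() if y in s}
    if not qh or not qy:
        return 0.0
    shared = len(qh & qy)
    if penalized:
        return shared / math.sqrt(len(qh) * len(qy))
    return shared / len(qh)


def oracle_top_k(entity: str, all_sims: dict[tuple[str, str], float],
                 labels: list[str], k: int) -> list[tuple[str, float]]:
    cand = [(lab, all_sims[(entity, lab)]) for lab in labels if lab != entity]
    cand.sort(key=lambda t: (-t[1], t[0]))
    return cand[:k]


def oracle_user_cf(
    likes: dict[str, set[str]], ratings: dict[tuple[str, str], float],
    u: str, y: str, k: int,
) -> float:
    labels = sorted(likes)
    sims = {
        (a, b): oracle_user_sim(likes, a, b, penalized=True)
        for a in labels for b in labels if a != b
    }
    hood = oracle_top_k(u, sims, labels, k)
    score = 0.0
    for v, z in sorted(hood):
        if y in likes[v]:
            score += z * ratings.get((v, y), 0.0)
    return score


def oracle_item_cf(
    likes: dict[str, set[str]], ratings: dict[tuple[str, str], float],
    items: list[str], u: str, y: str, k: int,
) -> float:
    labels = sorted(items)
    sims = {
        (a, b): oracle_item_sim(likes, a, b, penalized=True)
        for a in labels for b in labels if a != b
    }
    hood_ids = {h for h, _ in oracle_top_k(y, sims, labels, k)}
    score = 0.0
    for h in sorted(likes[u] & hood_ids):
        score += oracle_item_sim(likes, h, y, penalized=True) * ratings.get((u, h), 0.0)
    return score


# ------------------------------------------------------------------ hybrid


def oracle_minmax(scores: dict[str, float]) -> dict[str, float]:
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        return {k: 0.5 for k in scores}
    return {k: (v - lo) / (hi - lo) for k, v in scores.items()}


def oracle_fuse(content: dict[str, float], cf: dict[str, float],
                beta: float) -> dict[str, float]:
    c = oracle_minmax(content)
    f = oracle_minmax(cf)
    return {k: beta * c[k] + (1 - beta) * f[k] for k in content}
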