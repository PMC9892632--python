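"""Content model for the music library.

Each track carries free-text features (title, lyrics fragments, tags).
The model is classical TF-IDF over that text: term frequency within a
track, inverse document frequency across the library (base-10 logarithm,
unsmoothed for corpus-derived vocabularies), L2 row normalization, and a
tracks x terms preference matrix whose rows are the normalized weight
vectors.  A patient's content profile is the L2-normalized sum of the
vectors of the tracks in their listening history, and the content score
of a candidate track is the cosine (dot product of two unit vectors).

Sums over vocabulary terms are accumulated in vocabulary order with
scalar arithmetic so that results are exactly reproducible: a per-cell
recomputation in the same order yields bit-identical floats.
"""

from __future__ import annotations

import math
import re
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The three-level emotion taxonomy used throughout: library categories ...
CATEGORIES = ("relaxed", "normal", "excited")
#: ... and the matching soothing-level prescription of the controller.
SOOTHING_LEVELS = ("gentle", "moderate", "high")

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})
_WS = re.compile(r"\s+")


class CorpusError(ValueError):
    """Invalid corpus construction (duplicate ids, empty corpus, ...)."""


@dataclass(frozen=True)
class MusicTrack:
    """A music item with therapy metadata.

    ``category`` is the emotion level the piece targets (relaxed /
    normal / excited) and ``soothing_level`` the controller-facing
    prescription strength (gentle / moderate / high).  Audio descriptors
    such as melody speed, rhythm or timbre are out of scope and only
    representable through ``text_features`` tags.
    """

    track_id: str
    category: str
    soothing_level: str
    text_features: str = ""
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.track_id:
            raise CorpusError("track_id must be non-empty")
        if self.category not in CATEGORIES:
            raise CorpusError(
                f"unknown category {self.category!r} for track {self.track_id!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.soothing_level not in SOOTHING_LEVELS:
            raise CorpusError(
                f"unknown soothing_level {self.soothing_level!r} for track "
                f"{self.track_id!r}; expected one of {SOOTHING_LEVELS}"
            )


def tokenize(
    text: str,
    *,
    lowercase: bool = True,
    strip_punctuation: bool = True,
    stop_words: frozenset[str] = frozenset(),
) -> Counter:
    """Split raw text into a term multiset.

    Whitespace split after optional lowercasing and punctuation
    stripping; no stemming.  Deterministic for fixed settings; empty
    text yields an empty multiset.
    """
    if lowercase:
        text = text.lower()
    if strip_punctuation:
        text = text.translate(_PUNCT_TABLE)
    terms = [t for t in _WS.split(text) if t and t not in stop_words]
    return Counter(terms)


class Corpus:
    """A fixed collection of tracks with a reproducible vocabulary.

    The vocabulary is the sorted union of all track terms; document
    frequency q(x) counts the tracks containing term x at least once.
    """

    def __init__(
        self,
        tracks: Iterable[MusicTrack],
        *,
        stop_words: frozenset[str] = frozenset(),
    ) -> None:
        self.tracks: tuple[MusicTrack, ...] = tuple(tracks)
        if not self.tracks:
            raise CorpusError("corpus must contain at least one track")
        seen: set[str] = set()
        for t in self.tracks:
            if t.track_id in seen:
                raise CorpusError(f"duplicate track_id {t.track_id!r}")
            seen.add(t.track_id)
        self.tokens: dict[str, Counter] = {
            t.track_id: tokenize(t.text_features, stop_words=stop_words)
            for t in self.tracks
        }
        vocab: set[str] = set()
        for counts in self.tokens.values():
            vocab.update(counts)
        self.vocabulary: tuple[str, ...] = tuple(sorted(vocab))
        self.doc_freq: dict[str, int] = {
            term: sum(1 for c in self.tokens.values() if term in c)
            for term in self.vocabulary
        }

    @property
    def track_count(self) -> int:
        return len(self.tracks)

    @property
    def track_ids(self) -> tuple[str, ...]:
        return tuple(t.track_id for t in self.tracks)

    def track(self, track_id: str) -> MusicTrack:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(f"unknown track_id {track_id!r}")


def term_frequency(term: str, track_tokens: Mapping[str, int]) -> float:
    """Within-track relative frequency f(x,y) / sum_k f(k,y).

    Zero for an absent term; an empty track is degenerate and yields 0
    for every term.
    """
    total = sum(track_tokens.values())
    if total == 0:
        return 0.0
    return track_tokens.get(term, 0) / total


def inverse_document_frequency(term: str, corpus: Corpus) -> float:
    """Corpus-level rarity weight log10(Q / q(x)).

    For a corpus-derived vocabulary q(x) >= 1 always holds and the
    weight is 0 exactly when the term appears in every track.  A term
    the corpus has never seen (externally supplied vocabulary) takes the
    smoothed value log10(Q / (1 + q(x))) = log10(Q) so the function is
    total without ever dividing by zero.
    """
    q = corpus.doc_freq.get(term, 0)
    if q == 0:
        return math.log10(corpus.track_count / (1 + q))
    return math.log10(corpus.track_count / q)


def tfidf_weight(term: str, track_id: str, corpus: Corpus) -> float:
    """Combined weight: term frequency times inverse document frequency."""
    tf = term_frequency(term, corpus.tokens[track_id])
    return tf * inverse_document_frequency(term, corpus)


@dataclass(frozen=True)
class TrackVector:
    """Per-term weights of one track: raw TF-IDF and its L2 normalization.

    ``degenerate`` marks an all-zero raw vector (empty text, or every
    term ubiquitous); such a vector is left all-zero rather than raising.
    """

    track_id: str
    raw: np.ndarray
    weights: np.ndarray
    degenerate: bool = False


def normalize_track_vector(track_id: str, raw: np.ndarray) -> TrackVector:
    """Divide a non-negative weight vector by its Euclidean norm.

    The norm is accumulated in index order so independent recomputation
    reproduces the exact float.  An all-zero vector is returned
    unchanged with the degenerate flag set.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size and raw.min() < 0:
        raise ValueError("raw TF-IDF weights must be non-negative")
    sq = 0.0
    for w in raw.tolist():
        sq += w * w
    if sq == 0.0:
        return TrackVector(track_id, raw, raw.copy(), degenerate=True)
    norm = math.sqrt(sq)
    out = np.array([w / norm for w in raw.tolist()])
    return TrackVector(track_id, raw, out, degenerate=False)


@dataclass
class PreferenceMatrix:
    """Tracks x vocabulary matrix of normalized TF-IDF weights.

    Row y is the unit-norm weight vector of track y (all-zero when
    degenerate); the content side of the recommender works entirely in
    this matrix.
    """

    track_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]
    values: np.ndarray
    degenerate_tracks: frozenset[str] = field(default_factory=frozenset)

    def row(self, track_id: str) -> np.ndarray:
        return self.values[self.track_ids.index(track_id)]

    def track_vector(self, track_id: str) -> TrackVector:
        i = self.track_ids.index(track_id)
        return TrackVector(
            track_id,
            raw=self.values[i].copy(),
            weights=self.values[i].copy(),
            degenerate=track_id in self.degenerate_tracks,
        )


def build_preference_matrix(corpus: Corpus) -> PreferenceMatrix:
    """Assemble the preference matrix row by row.

    Each row is the track's raw TF-IDF vector over the corpus
    vocabulary, L2-normalized.  Deterministic: rows follow corpus track
    order, columns follow the sorted vocabulary.
    """
    vocab = corpus.vocabulary
    rows = []
    degenerate = set()
    for t in corpus.tracks:
        raw = np.array([tfidf_weight(x, t.track_id, corpus) for x in vocab])
        vec = normalize_track_vector(t.track_id, raw)
        if vec.degenerate:
            degenerate.add(t.track_id)
        rows.append(vec.weights)
    values = (
        np.vstack(rows) if vocab else np.zeros((corpus.track_count, 0))
    )
    return PreferenceMatrix(
        corpus.track_ids, vocab, values, frozenset(degenerate)
    )


def patient_profile(
    liked_track_ids: Sequence[str], matrix: PreferenceMatrix
) -> np.ndarray:
    """Content profile of a patient: L2-normalized sum of liked-track rows.

    An empty or all-degenerate history yields the all-zero profile
    (callers treat it as cold start).
    """
    m = len(matrix.vocabulary)
    total = np.zeros(m)
    for tid in sorted(liked_track_ids):
        total = total + matrix.row(tid)
    return normalize_track_vector("<profile>", total).weights


def neutral_profile(matrix: PreferenceMatrix) -> np.ndarray:
    """Uniform unit-norm profile used for cold-start patients."""
    m = len(matrix.vocabulary)
    if m == 0:
        return np.zeros(0)
    return np.full(m, 1.0 / math.sqrt(m))


def content_score(profile: np.ndarray, track_vector: TrackVector) -> float:
    """Cosine preference of a profile for a track, in [0, 1].

    Both vectors are non-negative and unit-norm (or all-zero when
    degenerate), so the dot product is bounded by Cauchy-Schwarz.  The
    sum runs in vocabulary order for exact reproducibility.
    """
    p = np.asarray(profile, dtype=float)
    w = track_vector.weights
    if p.shape != w.shape:
        raise ValueError(
            f"profile and track vector cover different vocabularies "
            f"({p.shape[0]} vs {w.shape[0]} terms)"
        )
    s = 0.0
    for a, b in zip(p.tolist(), w.tolist()):
        s += a * b
    return s
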