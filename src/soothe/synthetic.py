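"""Synthetic cohorts, music libraries, and heart-rate traces.

No public dataset exists for this closed-loop setting, so every other
module is exercised on generated data with planted, known structure:

* a music library whose tracks belong to one of three categories
  (relaxed / normal / excited), each category with its own token
  vocabulary, so that within-category content similarity exceeds
  cross-category similarity;
* a patient cohort with latent block preferences — each patient favors
  one category ("block") and likes in-block tracks with probability
  ``block_affinity`` and out-block tracks with probability
  ``(1 - block_affinity) * out_block_scale`` — giving collaborative
  filtering a recoverable signal (none at affinity 0.5 with symmetric
  scaling);
* heart-rate traces sampled at 1 Hz around state-dependent means with
  i.i.d. Gaussian within-state noise (an AR(1) option exists for
  smoothing-window experiments), clipped to the physiologic 30-220 bpm.

All generators are bit-reproducible given (config, seed); independent
substreams are derived per generator so adding tracks never perturbs
the interaction draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .biofeedback import HeartRateSample
from .corpus import CATEGORIES, SOOTHING_LEVELS, Corpus, MusicTrack

_CAT_LEVEL = dict(zip(CATEGORIES, SOOTHING_LEVELS))

# substream tags: keep every derived seed entry below 2**31
_CORPUS_STREAM = 1
_INTERACTION_STREAM = 2
_TRACE_STREAM = 3


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs for all generators.

    Defaults describe the reference desk-scale cohort: 40 patients and
    a 30-track library split evenly over the three categories, strong
    block preference (0.9), and well-separated heart-rate state means
    (65 / 80 / 110 bpm, within-state sd 3).
    """

    n_patients: int = 40
    n_tracks: int = 30
    n_categories: int = 3
    tokens_per_category: int = 12
    shared_tokens: int = 8
    tokens_per_track: int = 40
    in_category_token_prob: float = 0.7
    block_affinity: float = 0.9
    out_block_scale: float = 1.0
    hr_means: tuple[float, float, float] = (65.0, 80.0, 110.0)
    hr_sd: float = 3.0
    hr_ar1: float = 0.0  # autocorrelation of within-state noise; 0 = i.i.d.
    sampling_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_categories <= len(CATEGORIES):
            raise ValueError(
                f"n_categories must be in [1, {len(CATEGORIES)}], got {self.n_categories}"
            )
        if self.n_tracks < self.n_categories:
            raise ValueError(
                f"need n_tracks >= n_categories, got {self.n_tracks} < {self.n_categories}"
            )
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("in_category_token_prob", "block_affinity", "out_block_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (self.hr_means[0] < self.hr_means[1] < self.hr_means[2]):
            raise ValueError(
                f"hr_means must be strictly increasing relaxed < normal < excited, "
                f"got {self.hr_means}"
            )
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be >= 0")
        if not 0.0 <= self.hr_ar1 < 1.0:
            raise ValueError("hr_ar1 must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def categories(self) -> tuple[str, ...]:
        return CATEGORIES[: self.n_categories]

    @property
    def state_means(self) -> dict[str, float]:
        return dict(zip(CATEGORIES, self.hr_means))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def category_vocabulary(config: SynthConfig) -> dict[str, list[str]]:
    """Token pools: one per category plus a shared pool every track draws from."""
    pools = {
        cat: [f"{cat}_tok{j:02d}" for j in range(config.tokens_per_category)]
        for cat in config.categories
    }
    pools["shared"] = [f"common_tok{j:02d}" for j in range(config.shared_tokens)]
    return pools


def generate_corpus(config: SynthConfig) -> Corpus:
    """A library with category-specific token distributions.

    Tracks are assigned round-robin to categories; each track's text is
    ``tokens_per_track`` draws, from its own category pool with
    probability ``in_category_token_prob`` and from the shared pool
    otherwise.  Soothing level follows the category (relaxed -> gentle,
    normal -> moderate, excited -> high).
    """
    rng = config._rng(_CORPUS_STREAM)
    pools = category_vocabulary(config)
    tracks = []
    for i in range(config.n_tracks):
        cat = config.categories[i % config.n_categories]
        own = pools[cat]
        shared = pools["shared"]
        words = []
        for _ in range(config.tokens_per_track):
            if shared and rng.random() >= config.in_category_token_prob:
                words.append(shared[rng.integers(len(shared))])
            else:
                words.append(own[rng.integers(len(own))])
        tracks.append(
            MusicTrack(
                track_id=f"t{i:03d}",
                category=cat,
                soothing_level=_CAT_LEVEL[cat],
                text_features=" ".join(words),
                duration_s=float(rng.integers(120, 360)),
            )
        )
    return Corpus(tracks)


def generate_cohort_interactions(
    config: SynthConfig, corpus: Corpus
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Implicit-feedback likes with planted block structure.

    Patients are assigned preferred blocks (categories) round-robin.
    Each (patient, track) like is an independent Bernoulli draw:
    probability ``block_affinity`` in-block, ``(1 - block_affinity) *
    out_block_scale`` out-of-block.  Returns the like records together
    with the ground-truth block labels.
    """
    rng = config._rng(_INTERACTION_STREAM)
    blocks = {
        f"p{i:03d}": config.categories[i % config.n_categories]
        for i in range(config.n_patients)
    }
    records = []
    out_prob = (1.0 - config.block_affinity) * config.out_block_scale
    for patient in sorted(blocks):
        block = blocks[patient]
        for track in corpus.tracks:
            p = config.block_affinity if track.category == block else out_prob
            if rng.random() < p:
                records.append((patient, track.track_id))
    return records, blocks


def generate_heart_rate_trace(
    state_schedule: Sequence[tuple[str, float]],
    config: SynthConfig,
) -> list[HeartRateSample]:
    """Sample a trace that follows an emotional-state schedule.

    Each (state, duration_s) segment contributes ``duration_s *
    sampling_hz`` samples at the state's mean plus Gaussian noise
    (sd ``hr_sd``; AR(1) with coefficient ``hr_ar1`` when non-zero),
    clipped to 30-220 bpm.
    """
    if not state_schedule:
        raise ValueError("state schedule is empty")
    means = config.state_means
    for state, _ in state_schedule:
        if state not in means:
            raise ValueError(
                f"unknown emotion state {state!r}; expected one of {CATEGORIES}"
            )
    rng = config._rng(_TRACE_STREAM)
    dt = 1.0 / config.sampling_hz
    samples: list[HeartRateSample] = []
    t = 0.0
    noise_prev = 0.0
    innovation_sd = (
        config.hr_sd * float(np.sqrt(1.0 - config.hr_ar1**2))
        if config.hr_ar1 > 0
        else config.hr_sd
    )
    for state, duration_s in state_schedule:
        n = int(round(duration_s * config.sampling_hz))
        for _ in range(n):
            eps = rng.normal(0.0, innovation_sd) if innovation_sd > 0 else 0.0
            noise = config.hr_ar1 * noise_prev + eps if config.hr_ar1 > 0 else eps
            noise_prev = noise
            hr = float(np.clip(means[state] + noise, 30.0, 220.0))
            samples.append(HeartRateSample(time_s=t, hr_bpm=hr))
            t += dt
    return samples


def schedule_states(
    state_schedule: Sequence[tuple[str, float]], sampling_hz: float = 1.0
) -> list[str]:
    """Ground-truth per-sample state labels for a schedule (same grid)."""
    labels: list[str] = []
    for state, duration_s in state_schedule:
        labels.extend([state] * int(round(duration_s * sampling_hz)))
    return labels
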