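"""Two-threshold heart-rate controller and closed-loop session driver.

Heart rate is used as a proxy for the patient's emotional state on a
three-level taxonomy (relaxed / normal / excited).  The controller is a
memoryless step function of instantaneous heart rate with two
thresholds theta_low < theta_high:

    hr >  theta_high  ->  excited  ->  play highly soothing music
    hr <  theta_low   ->  relaxed  ->  play gently soothing music
    otherwise (closed middle band)  ->  normal -> moderate soothing

The closed middle band [theta_low, theta_high] maps to normal so the
classifier is total; the soothing-level index (gentle < moderate <
high) is non-decreasing in heart rate.  An optional trailing-mean
smoothing window is available but off by default (window = 1 sample).

``run_session`` replays a heart-rate trace: each sample is classified,
the recommender is asked for a playlist restricted to the dictated
soothing level, and the decision is logged.  Other affect sensors can
replace the heart-rate classifier through the ``StateProvider``
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

from .collaborative import InteractionStore
from .corpus import CATEGORIES, SOOTHING_LEVELS, Corpus, PreferenceMatrix
from .hybrid import HybridConfig, RecommendationList, recommend

#: emotion state -> soothing level prescription
STATE_TO_LEVEL = dict(zip(CATEGORIES, SOOTHING_LEVELS))


@dataclass(frozen=True)
class ThresholdConfig:
    """Heart-rate band edges in beats per minute."""

    theta_low: float = 60.0
    theta_high: float = 100.0

    def __post_init__(self) -> None:
        if not self.theta_low < self.theta_high:
            raise ValueError(
                f"theta_low must be < theta_high, got "
                f"({self.theta_low}, {self.theta_high})"
            )
        for name, v in (("theta_low", self.theta_low), ("theta_high", self.theta_high)):
            if not 30.0 <= v <= 220.0:
                raise ValueError(f"{name}={v} outside the physiologic range 30-220 bpm")


@dataclass(frozen=True)
class HeartRateSample:
    time_s: float
    hr_bpm: float

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError(f"non-positive heart rate {self.hr_bpm} at t={self.time_s}")


class StateProvider(Protocol):
    """Anything that maps a sample to (emotion state, soothing level)."""

    def __call__(self, sample: HeartRateSample) -> tuple[str, str]: ...


def classify_heart_rate(
    hr_bpm: float, thresholds: ThresholdConfig
) -> tuple[str, str]:
    """Map a heart rate to (emotion state, soothing level).

    Total on hr > 0; the middle band is closed on both ends.
    """
    if hr_bpm <= 0:
        raise ValueError(f"non-positive heart rate {hr_bpm}")
    if hr_bpm > thresholds.theta_high:
        return "excited", "high"
    if hr_bpm < thresholds.theta_low:
        return "relaxed", "gentle"
    return "normal", "moderate"


def heart_rate_provider(thresholds: ThresholdConfig) -> StateProvider:
    """The reference state provider: threshold the instantaneous heart rate."""

    def provide(sample: HeartRateSample) -> tuple[str, str]:
        return classify_heart_rate(sample.hr_bpm, thresholds)

    return provide


@dataclass(frozen=True)
class SessionStep:
    """One logged controller decision."""

    time_s: float
    hr_bpm: float
    state: str
    soothing_level: str
    track_id: str | None
    level_available: bool  # False when the library lacked the level


@dataclass(frozen=True)
class SessionLog:
    patient: str
    steps: tuple[SessionStep, ...]

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(s.soothing_level for s in self.steps)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s.state for s in self.steps)


def _validate_trace(trace: Sequence[HeartRateSample]) -> None:
    if not trace:
        raise ValueError("heart-rate trace is empty")
    for a, b in zip(trace, trace[1:]):
        if b.time_s < a.time_s:
            raise ValueError(
                f"trace not time-ordered at t={b.time_s} (after t={a.time_s})"
            )


def smooth_trace(
    trace: Sequence[HeartRateSample], window: int
) -> list[HeartRateSample]:
    """Trailing-mean smoothing over the last ``window`` samples (1 = none)."""
    if window < 1:
        raise ValueError(f"smoothing window must be >= 1, got {window}")
    if window == 1:
        return list(trace)
    out = []
    for i, s in enumerate(trace):
        lo = max(0, i - window + 1)
        vals = [t.hr_bpm for t in trace[lo : i + 1]]
        out.append(HeartRateSample(s.time_s, sum(vals) / len(vals)))
    return out


def run_session(
    patient: str,
    trace: Sequence[HeartRateSample],
    thresholds: ThresholdConfig,
    corpus: Corpus,
    store: InteractionStore,
    config: HybridConfig,
    *,
    matrix: PreferenceMatrix | None = None,
    smoothing_window: int = 1,
    state_provider: StateProvider | None = None,
) -> SessionLog:
    """Replay a heart-rate trace through the closed loop.

    Each (optionally smoothed) sample is classified, and the
    recommender is asked for a playlist restricted to the dictated
    soothing level; the top track is logged.  If the library offers no
    track at that level (or the patient has heard them all), the gap is
    logged and the unrestricted pool is used instead.  The store is
    static within a session, so playlists are computed once per
    soothing level; the per-step decision is identical to classifying
    each sample independently.
    """
    _validate_trace(trace)
    samples = smooth_trace(trace, smoothing_window)
    provider = state_provider or heart_rate_provider(thresholds)

    playlist_cache: dict[str | None, RecommendationList | None] = {}

    def playlist_for(level: str | None) -> RecommendationList | None:
        if level not in playlist_cache:
            try:
                playlist_cache[level] = recommend(
                    patient, corpus, store, config,
                    category=level, matrix=matrix,
                )
            except ValueError:
                playlist_cache[level] = None
        return playlist_cache[level]

    steps = []
    for s in samples:
        state, level = provider(s)
        rec = playlist_for(level)
        available = rec is not None
        if rec is None:
            rec = playlist_for(None)
        track = rec.track_ids[0] if rec is not None and rec.items else None
        steps.append(
            SessionStep(s.time_s, s.hr_bpm, state, level, track, available)
        )
    return SessionLog(patient, tuple(steps))


@dataclass(frozen=True)
class SessionSummary:
    dwell_fractions: dict[str, float]  # soothing level -> fraction of steps
    switch_count: int
    n_steps: int


def session_summary(log: SessionLog) -> SessionSummary:
    """Per-level dwell fractions (summing to 1) and level-switch count."""
    if not log.steps:
        raise ValueError("session log is empty")
    n = len(log.steps)
    levels = log.levels
    fractions = {
        lvl: sum(1 for x in levels if x == lvl) / n for lvl in SOOTHING_LEVELS
    }
    switches = sum(1 for a, b in zip(levels, levels[1:]) if a != b)
    return SessionSummary(fractions, switches, n)
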