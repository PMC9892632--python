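"""Readers and writers for the interchange formats, plus run configuration.

Formats:

* tracks — JSON array of ``{track_id, category, soothing_level,
  text_features, duration_s}``;
* interactions — CSV with header ``user_id,item_id[,rating,timestamp]``;
* heart-rate trace — CSV with header ``time_s,hr_bpm``;
* playlist — JSON ``{patient, items: [{track_id, score}], ...}``;
* session log — JSON lines, one record per step;
* survey counts — CSV ``group,very_satisfied,satisfied,dissatisfied,n_total``;
* metrics / ground truth — plain JSON objects.

Every file this package writes embeds the tool version, the seed, and a
hash of the effective configuration, so identical inputs reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .biofeedback import HeartRateSample, SessionLog, ThresholdConfig
from .corpus import CATEGORIES, SOOTHING_LEVELS, MusicTrack
from .evaluation import SatisfactionCounts
from .hybrid import HybridConfig, RecommendationList
from .synthetic import SynthConfig


class SchemaError(ValueError):
    """Input file violates its documented schema."""


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(seed: int | None, config: Any) -> dict[str, Any]:
    return {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
    }


# ---------------------------------------------------------------- tracks


def load_tracks(path: str | Path) -> list[MusicTrack]:
    """Parse and validate a tracks JSON file."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except UnicodeDecodeError as e:
        raise SchemaError(f"{path}: not valid UTF-8 ({e})") from e
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: invalid JSON ({e})") from e
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a JSON array of track objects")
    tracks: list[MusicTrack] = []
    seen: set[str] = set()
    for i, obj in enumerate(data):
        for key in ("track_id", "category", "soothing_level"):
            if key not in obj:
                raise SchemaError(f"{path}: track #{i} missing field {key!r}")
        tid = str(obj["track_id"])
        if tid in seen:
            raise SchemaError(f"{path}: duplicate track_id {tid!r}")
        seen.add(tid)
        if obj["category"] not in CATEGORIES:
            raise SchemaError(
                f"{path}: track {tid!r} has unknown category {obj['category']!r}"
            )
        if obj["soothing_level"] not in SOOTHING_LEVELS:
            raise SchemaError(
                f"{path}: track {tid!r} has unknown soothing_level "
                f"{obj['soothing_level']!r}"
            )
        tracks.append(
            MusicTrack(
                track_id=tid,
                category=obj["category"],
                soothing_level=obj["soothing_level"],
                text_features=str(obj.get("text_features", "")),
                duration_s=float(obj.get("duration_s", 0.0)),
            )
        )
    return tracks


def write_tracks(tracks: Sequence[MusicTrack], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([asdict(t) for t in tracks], indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# ----------------------------------------------------------- interactions


def load_interactions(path: str | Path) -> list[tuple]:
    """Parse an interactions CSV into (user_id, item_id[, rating]) records."""
    try:
        df = pd.read_csv(path, dtype={"user_id": str, "item_id": str})
    except UnicodeDecodeError as e:
        raise SchemaError(f"{path}: not valid UTF-8 ({e})") from e
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"{path}: empty interactions file") from e
    for col in ("user_id", "item_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no interaction rows")
    records = []
    has_rating = "rating" in df.columns
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        u, y = getattr(row, "user_id"), getattr(row, "item_id")
        if pd.isna(u) or pd.isna(y) or not str(u) or not str(y):
            raise SchemaError(f"{path}: row {row_no}: missing user_id or item_id")
        if has_rating and not pd.isna(getattr(row, "rating")):
            r = float(getattr(row, "rating"))
            if not 0.0 <= r <= 5.0:
                raise SchemaError(
                    f"{path}: row {row_no}: rating {r} outside [0, 5]"
                )
            records.append((str(u), str(y), r))
        else:
            records.append((str(u), str(y)))
    return records


def write_interactions(records: Sequence[Sequence], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        has_rating = any(len(r) >= 3 for r in records)
        w.writerow(["user_id", "item_id"] + (["rating"] if has_rating else []))
        for rec in records:
            row = list(rec[:2]) + ([rec[2]] if has_rating and len(rec) >= 3 else
                                   ([""] if has_rating else []))
            w.writerow(row)


# ------------------------------------------------------------------ trace


def load_heart_rate_trace(path: str | Path) -> list[HeartRateSample]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"{path}: empty trace file") from e
    for col in ("time_s", "hr_bpm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no samples")
    return [
        HeartRateSample(float(t), float(h))
        for t, h in zip(df["time_s"], df["hr_bpm"])
    ]


def write_heart_rate_trace(
    trace: Sequence[HeartRateSample], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "hr_bpm"])
        for s in trace:
            w.writerow([s.time_s, s.hr_bpm])


# ------------------------------------------------------- playlists & logs


def write_playlist(
    rec: RecommendationList, path: str | Path, *, seed: int | None = None
) -> None:
    payload = {
        "patient": rec.patient,
        "items": [{"track_id": t, "score": s} for t, s in rec.items],
        "cold_start": rec.cold_start,
        "category": rec.category,
        "provenance": provenance(seed, asdict(rec.config)),
    }
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def write_session_log(
    log: SessionLog, path: str | Path, *, seed: int | None = None,
    config: Any = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        header = {"patient": log.patient, **provenance(seed, config)}
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for step in log.steps:
            fh.write(json.dumps(asdict(step), sort_keys=True) + "\n")


def write_metrics(metrics: dict, path: str | Path, *, seed: int | None = None,
                  config: Any = None) -> None:
    payload = {**metrics, "provenance": provenance(seed, config)}
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


# ------------------------------------------------------------ survey CSV


def load_survey_counts(path: str | Path) -> list[SatisfactionCounts]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"{path}: empty survey file") from e
    required = ("group", "very_satisfied", "satisfied", "dissatisfied", "n_total")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                SatisfactionCounts(
                    group=str(row.group),
                    very_satisfied=int(row.very_satisfied),
                    satisfied=int(row.satisfied),
                    dissatisfied=int(row.dissatisfied),
                    n_total=int(row.n_total),
                )
            )
        except ValueError as e:
            raise SchemaError(f"{path}: row {row_no}: {e}") from e
    return out


# ------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Effective configuration: built-in defaults, overridden by a YAML
    config file, overridden by CLI flags (documented precedence)."""

    hybrid: HybridConfig = field(default_factory=HybridConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return {
            "hybrid": asdict(self.hybrid),
            "thresholds": asdict(self.thresholds),
            "synth": asdict(self.synth),
            "seed": self.seed,
            "log_level": self.log_level,
        }


def load_run_config(path: str | Path | None, **overrides: Any) -> RunConfig:
    """Assemble the effective RunConfig.

    ``overrides`` are flat dotted keys from CLI flags, e.g.
    ``hybrid_beta=0.7``; None values are ignored.
    """
    sections: dict[str, dict] = {"hybrid": {}, "thresholds": {}, "synth": {}}
    top: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        for key, val in raw.items():
            if key in sections:
                if not isinstance(val, dict):
                    raise SchemaError(f"{path}: section {key!r} must be a mapping")
                sections[key].update(val)
            elif key in ("seed", "log_level"):
                top[key] = val
            else:
                raise SchemaError(f"{path}: unknown config section {key!r}")
    for key, val in overrides.items():
        if val is None:
            continue
        if "_" in key and key.split("_", 1)[0] in sections:
            section, name = key.split("_", 1)
            sections[section][name] = val
        else:
            top[key] = val
    seed = int(top.get("seed", 0))
    if "seed" not in sections["synth"]:
        sections["synth"]["seed"] = seed
    hr = sections["synth"].pop("hr_means", None)
    if hr is not None:
        sections["synth"]["hr_means"] = tuple(float(x) for x in hr)
    try:
        return RunConfig(
            hybrid=HybridConfig(**sections["hybrid"]),
            thresholds=ThresholdConfig(**sections["thresholds"]),
            synth=SynthConfig(**sections["synth"]),
            seed=seed,
            log_level=str(top.get("log_level", "INFO")),
        )
    except (TypeError, ValueError) as e:
        raise SchemaError(f"invalid configuration: {e}") from e
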