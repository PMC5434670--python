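"""Heartbeat-counting (mental tracking) interoceptive accuracy.

One trial: the participant silently counts felt heartbeats over an
unannounced interval (25, 35, 45 or 100 s in the standard task) while the
ECG supplies the recorded reference count.  The per-interval score is
``1 - |recorded - counted| / recorded`` and the subject's interoceptive
accuracy (IA) is the mean over the four intervals, lying in [0, 1].

The raw formula goes negative if a participant reports more than twice
the recorded beats; since the score is defined on [0, 1], such scores are
clamped to 0 and a warning is emitted rather than silently dropping the
trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import RRSeries

__all__ = [
    "STANDARD_INTERVALS_S",
    "CountingTrial",
    "interval_score",
    "ia_score",
    "recorded_beats_from_rr",
    "score_counting_table",
]

STANDARD_INTERVALS_S = (25, 35, 45, 100)


@dataclass(frozen=True)
class CountingTrial:
    """One heartbeat-counting interval."""

    interval_s: float
    recorded_beats: int
    counted_beats: int

    def __post_init__(self) -> None:
        if self.recorded_beats < 1:
            raise ValueError("no reference beats: recorded_beats must be >= 1")
        if self.counted_beats < 0:
            raise ValueError("counted_beats must be >= 0")
        if self.interval_s <= 0:
            raise ValueError("interval_s must be positive")


def interval_score(trial: CountingTrial) -> float:
    """Unit accuracy score for one interval, clamped into [0, 1]."""
    raw = 1.0 - abs(trial.recorded_beats - trial.counted_beats) / trial.recorded_beats
    if raw < 0:
        warnings.warn(
            f"counting score {raw:.3f} clamped to 0 "
            f"(counted {trial.counted_beats} vs recorded {trial.recorded_beats})",
            stacklevel=2,
        )
        return 0.0
    return raw


def ia_score(trials: Sequence[CountingTrial], expected: int = 4) -> float:
    """Interoceptive accuracy: mean interval score over the task's trials."""
    if len(trials) != expected:
        raise ValueError(f"expected {expected} intervals, got {len(trials)}")
    return float(np.mean([interval_score(t) for t in trials]))


def recorded_beats_from_rr(rr: RRSeries, onset_ms: float, duration_ms: float) -> int:
    """Count beat onsets inside the half-open window [onset, onset+duration).

    The RR series must cover the window.
    """
    if duration_ms < 0:
        raise ValueError("duration must be non-negative")
    beats = rr.beat_times
    if onset_ms < beats[0] or onset_ms + duration_ms > beats[-1]:
        raise ValueError("interval not covered by the RR series")
    return int(np.sum((beats >= onset_ms) & (beats < onset_ms + duration_ms)))


def score_counting_table(df: pd.DataFrame, expected: int = 4) -> pd.DataFrame:
    """Score a tidy counting table (subject, interval_s, recorded_beats,
    counted_beats): appends ``interval_score`` per row and ``ia_score``
    per subject."""
    required = ["subject", "interval_s", "recorded_beats", "counted_beats"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"counting table: missing column(s) {missing}")
    out = df.copy()
    out["interval_score"] = [
        interval_score(
            CountingTrial(r.interval_s, int(r.recorded_beats), int(r.counted_beats))
        )
        for r in out.itertuples()
    ]
    ia = (
        out.groupby("subject")["interval_score"]
        .agg(lambda s: ia_score_from_scores(s, expected))
        .rename("ia_score")
    )
    return out.merge(ia, on="subject")


def ia_score_from_scores(scores: Iterable[float], expected: int = 4) -> float:
    scores = list(scores)
    if len(scores) != expected:
        raise ValueError(f"expected {expected} intervals, got {len(scores)}")
    return float(np.mean(scores))
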