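"""Record types: released score rows, normative-table rows, and session logs.

The released score schema is one CSV row per subtest score, 11 columns
(identifier, demographics, battery/subtest ids, hour of day, raw score,
composite Grand Index).  ``gender``, ``education_level`` and ``grand_index``
may be missing; the other fields never are.

Session logs are a richer, per-assessment record carrying per-subtest
timestamps, trial events and a pre-test gameplay count.  The released score
schema cannot express the time-based exclusion filters (24-hour pause,
interleaved tests, slow trail making) nor the gameplay filter, so those
filters consume :class:`SessionLog` objects — in practice produced by the
cohort simulator, or by whoever holds the raw platform logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Optional

from .registry import EDUCATION_LEVELS

__all__ = ["ScoreRecord", "NormRow", "TrialEvent", "SubtestSession", "SessionLog",
           "SCORE_COLUMNS", "NORMS_COLUMNS"]

#: Released score schema, in column order.
SCORE_COLUMNS = (
    "user_id",
    "age",
    "gender",
    "education_level",
    "country",
    "test_run_id",
    "battery_id",
    "specific_subtest_id",
    "time_of_day",
    "raw_score",
    "grand_index",
)

#: Released normative-table schema, in column order.
NORMS_COLUMNS = (
    "subtest_name",
    "specific_subtest_id",
    "age",
    "education_level",
    "gender",
    "N",
    "mean",
    "SD",
    "10th_perc",
    "25th_perc",
    "50th_perc",
    "75th_perc",
    "90th_perc",
)


def _is_missing(x: Any) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return False


@dataclass
class ScoreRecord:
    """One subtest score with the participant's demographics.

    Mirrors one row of the released 11-column score schema.  ``gender``,
    ``education_level`` and ``grand_index`` use ``None`` for missing values;
    a missing ``grand_index`` means the participant did not complete the
    entire test battery.
    """

    user_id: str
    age: int
    gender: Optional[str]
    education_level: Optional[int]
    country: str
    test_run_id: str
    battery_id: int
    specific_subtest_id: int
    time_of_day: int
    raw_score: float
    grand_index: Optional[float] = None

    @property
    def education_description(self) -> Optional[str]:
        """Verbal description of the numeric education code, if reported."""
        if self.education_level is None:
            return None
        return EDUCATION_LEVELS[self.education_level]

    def is_missing(self, name: str) -> bool:
        return _is_missing(getattr(self, name))


@dataclass
class NormRow:
    """One normative-table row: a subtest (or the Grand Index) crossed with an
    age bin, an education bin, and a gender.

    All summary statistics are computed on raw scores.  For time-scored
    subtests the percentile columns follow the performance convention: a
    higher percentile always indicates better performance, so e.g. the
    90th percentile of a trail making subtest is a *fast* (low) raw time.
    """

    subtest_name: str
    specific_subtest_id: Optional[int]  # None for the Grand Index row
    age: str            # age-bin label, e.g. "18-29"
    education_level: str  # education-bin label
    gender: str
    N: int
    mean: float
    SD: float
    perc_10: float
    perc_25: float
    perc_50: float
    perc_75: float
    perc_90: float

    def as_row(self) -> list:
        return [
            self.subtest_name,
            "" if self.specific_subtest_id is None else self.specific_subtest_id,
            self.age,
            self.education_level,
            self.gender,
            self.N,
            self.mean,
            self.SD,
            self.perc_10,
            self.perc_25,
            self.perc_50,
            self.perc_75,
            self.perc_90,
        ]


@dataclass
class TrialEvent:
    """One trial of a simulated subtest session.

    ``stimulus`` is a small free-form descriptor (span level, go/no-go trial
    type, cue validity, item difficulty...); ``rt`` is the response time in
    seconds.
    """

    trial: int
    stimulus: dict
    response: Any
    correct: bool
    rt: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubtestSession:
    """One subtest within an assessment: timestamps, trials, raw score.

    Timestamps are seconds on an absolute clock (e.g. Unix time).  A missing
    ``raw_score`` marks a subtest the participant failed or abandoned.
    """

    subtest_id: int
    start_time: float
    end_time: float
    raw_score: Optional[float] = None
    trials: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class SessionLog:
    """One full assessment (test run) by one participant.

    Subtest entries are kept in administration (start-time) order.
    ``pre_test_gameplays`` counts the participant's training-game plays
    logged before taking the assessment; the norm sample excludes
    participants with more than 25.
    """

    user_id: str
    test_run_id: str
    battery_id: int
    age: int
    gender: Optional[str]
    education_level: Optional[int]
    country: str
    pre_test_gameplays: int = 0
    entries: list[SubtestSession] = field(default_factory=list)

    @property
    def first_start(self) -> float:
        return min(e.start_time for e in self.entries)

    @property
    def last_end(self) -> float:
        return max(e.end_time for e in self.entries)

    def sorted_entries(self) -> list[SubtestSession]:
        return sorted(self.entries, key=lambda e: e.start_time)

    # -- JSON plumbing (sessions are exchanged as JSON lines) ---------------
    def to_dict(self, with_trials: bool = False) -> dict:
        d = {
            "user_id": self.user_id,
            "test_run_id": self.test_run_id,
            "battery_id": self.battery_id,
            "age": self.age,
            "gender": self.gender,
            "education_level": self.education_level,
            "country": self.country,
            "pre_test_gameplays": self.pre_test_gameplays,
            "entries": [
                {
                    "subtest_id": e.subtest_id,
                    "start_time": e.start_time,
                    "end_time": e.end_time,
                    "raw_score": e.raw_score,
                    "trials": [t.to_dict() for t in e.trials] if with_trials else [],
                }
                for e in self.entries
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionLog":
        entries = [
            SubtestSession(
                subtest_id=int(e["subtest_id"]),
                start_time=float(e["start_time"]),
                end_time=float(e["end_time"]),
                raw_score=None if e.get("raw_score") is None else float(e["raw_score"]),
                trials=[TrialEvent(**t) for t in e.get("trials", [])],
            )
            for e in d["entries"]
        ]
        return cls(
            user_id=str(d["user_id"]),
            test_run_id=str(d["test_run_id"]),
            battery_id=int(d["battery_id"]),
            age=int(d["age"]),
            gender=d.get("gender"),
            education_level=None if d.get("education_level") is None else int(d["education_level"]),
            country=str(d.get("country", "")),
            pre_test_gameplays=int(d.get("pre_test_gameplays", 0)),
            entries=entries,
        )
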