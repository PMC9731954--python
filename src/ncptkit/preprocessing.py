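"""Inclusion/exclusion filters and de-identification preprocessing.

The filters reproduce the dataset's inclusion criteria:

* only each participant's first assessment is kept;
* participants who paused for more than 24 hours between successive
  subtests of a battery are excluded;
* participants who started one test, started a different test mid-way, then
  returned to and completed the first are excluded;
* participants who took longer than 15 minutes on a trail making subtest
  (ids 39, 40) lose *all* of their data.

All time-based filters need per-subtest timestamps and therefore consume
:class:`~ncptkit.records.SessionLog` objects; the released score schema
carries no timestamps, so a pipeline fed bare score rows skips them with a
warning.  Ages above 89 are top-coded to 90 (Safe-Harbor de-identification).

Thresholds are strict: a pause of exactly 24 hours or a trail making
duration of exactly 15 minutes is kept ("more than" / "longer than").
Gaps are measured from the end of one subtest to the start of the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .norming import completeness_flags  # noqa: F401  (part of this surface)
from .records import SessionLog

__all__ = [
    "PAUSE_LIMIT_S",
    "TRAILS_LIMIT_S",
    "ExclusionReport",
    "select_first_assessment",
    "filter_pauses",
    "filter_interleaved",
    "filter_slow_trails",
    "topcode_age",
    "completeness_flags",
    "run_filters",
]

PAUSE_LIMIT_S = 24 * 3600.0     # "more than 24 h" between successive subtests
TRAILS_LIMIT_S = 15 * 60.0      # "longer than 15 minutes" on a trail making subtest
TRAIL_SUBTESTS = (39, 40)

REASONS = (
    "pause_gt_24h",
    "interleaved_tests",
    "slow_trails",
    "not_first_assessment",
    "missing_required_demographics",
)


@dataclass
class ExclusionReport:
    """Per-reason exclusion lists; one user may appear under several reasons."""

    excluded: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in REASONS}
    )

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(v) for r, v in self.excluded.items()}

    def add(self, reason: str, user_id: str) -> None:
        if reason not in self.excluded:
            raise KeyError(f"unknown exclusion reason: {reason}")
        if user_id not in self.excluded[reason]:
            self.excluded[reason].append(user_id)

    def merge(self, other: "ExclusionReport") -> "ExclusionReport":
        for reason, users in other.excluded.items():
            for u in users:
                self.add(reason, u)
        return self

    def all_excluded_users(self) -> set[str]:
        return {u for users in self.excluded.values() for u in users}

    def to_dict(self) -> dict:
        return {"counts": self.counts, "excluded": {r: sorted(v) for r, v in self.excluded.items()}}


def _check_timestamps(logs: Iterable[SessionLog]) -> None:
    for log in logs:
        if not log.entries:
            raise ValueError(f"session {log.test_run_id!r} has no subtest entries")
        for e in log.entries:
            if e.start_time is None or e.end_time is None:
                raise ValueError(
                    f"session {log.test_run_id!r} lacks timestamps; time-based "
                    "filters require session logs, not bare score rows"
                )


def select_first_assessment(
    logs: Sequence[SessionLog],
    report: ExclusionReport | None = None,
) -> tuple[list[SessionLog], ExclusionReport]:
    """Keep only each participant's first assessment.

    The first assessment is the run whose earliest subtest start time is
    minimal; ties break deterministically on the lexicographically smaller
    test_run_id, so the result is invariant to input order.  Later runs are
    reported under ``not_first_assessment``.
    """
    _check_timestamps(logs)
    report = report if report is not None else ExclusionReport()
    best: dict[str, SessionLog] = {}
    for log in logs:
        cur = best.get(log.user_id)
        key = (log.first_start, str(log.test_run_id))
        if cur is None or key < (cur.first_start, str(cur.test_run_id)):
            best[log.user_id] = log
    kept = []
    for log in logs:
        if best[log.user_id] is log:
            kept.append(log)
        else:
            report.add("not_first_assessment", log.user_id)
    return kept, report


def filter_pauses(
    logs: Sequence[SessionLog],
    report: ExclusionReport | None = None,
    limit_s: float = PAUSE_LIMIT_S,
) -> tuple[list[SessionLog], ExclusionReport]:
    """Drop runs containing an inter-subtest pause of more than 24 hours.

    The pause is the gap from one subtest's end to the next subtest's start,
    taken over the run's entries in start-time order.  Exactly 24 hours is
    kept (strict inequality).
    """
    _check_timestamps(logs)
    report = report if report is not None else ExclusionReport()
    kept = []
    for log in logs:
        entries = log.sorted_entries()
        gaps = [b.start_time - a.end_time for a, b in zip(entries, entries[1:])]
        if gaps and max(gaps) > limit_s:
            report.add("pause_gt_24h", log.user_id)
        else:
            kept.append(log)
    return kept, report


def filter_interleaved(
    logs: Sequence[SessionLog],
    report: ExclusionReport | None = None,
) -> tuple[list[SessionLog], ExclusionReport]:
    """Drop users who interleaved two assessments.

    A user is excluded when some run B begins strictly inside another run
    A's [first start, last end] interval — i.e. the user started A, started
    B part-way through, then returned to finish A.  A run B starting exactly
    at A's last end is sequential, not interleaved.
    """
    _check_timestamps(logs)
    report = report if report is not None else ExclusionReport()
    by_user: dict[str, list[SessionLog]] = {}
    for log in logs:
        by_user.setdefault(log.user_id, []).append(log)
    bad_users = set()
    for user, runs in by_user.items():
        for a in runs:
            for b in runs:
                if a is b:
                    continue
                if a.first_start < b.first_start < a.last_end:
                    bad_users.add(user)
    for u in sorted(bad_users):
        report.add("interleaved_tests", u)
    kept = [log for log in logs if log.user_id not in bad_users]
    return kept, report


def filter_slow_trails(
    logs: Sequence[SessionLog],
    report: ExclusionReport | None = None,
    limit_s: float = TRAILS_LIMIT_S,
) -> tuple[list[SessionLog], ExclusionReport]:
    """Drop *all* data of users with a trail making subtest over 15 minutes.

    Applies to subtests 39 and 40 where present; batteries without trail
    making subtests are unaffected.  Exactly 15 minutes is kept.
    """
    _check_timestamps(logs)
    report = report if report is not None else ExclusionReport()
    bad_users = set()
    for log in logs:
        for e in log.entries:
            if e.subtest_id in TRAIL_SUBTESTS and e.duration > limit_s:
                bad_users.add(log.user_id)
    for u in sorted(bad_users):
        report.add("slow_trails", u)
    kept = [log for log in logs if log.user_id not in bad_users]
    return kept, report


def topcode_age(age: int) -> int:
    """Safe-Harbor top-coding: ages over 89 become 90.

    Ages below 18 are outside the data's domain and raise ``ValueError``.
    """
    age = int(age)
    if age < 18:
        raise ValueError(f"age below the supported range [18, 99]: {age}")
    return 90 if age > 89 else age


def run_filters(
    logs: Sequence[SessionLog],
) -> tuple[list[SessionLog], ExclusionReport]:
    """Apply the full exclusion chain and top-code ages.

    Order: interleaving (needs all of a user's runs), first-assessment
    selection, the 24-hour pause rule, then the trail making duration rule.
    The filters target disjoint defects, so the kept set does not depend on
    this order; it only determines which reason a doubly-contaminated user
    is reported under first.
    """
    report = ExclusionReport()
    kept, report = filter_interleaved(logs, report)
    kept, report = select_first_assessment(kept, report)
    kept, report = filter_pauses(kept, report)
    kept, report = filter_slow_trails(kept, report)
    for log in kept:
        if log.age is None:
            # upstream release guarantees age; flag rather than silently drop
            report.add("missing_required_demographics", log.user_id)
        else:
            log.age = topcode_age(log.age)
    return kept, report
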