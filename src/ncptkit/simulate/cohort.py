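"""Cohort-level simulation: released-schema scores, session logs, truth table.

``simulate_cohort`` administers the configured battery to every agent in
administration order, assembles per-subtest timestamps into session logs,
and injects contamination that triggers each exclusion filter:

* *pause*: a gap of more than 24 h between two successive subtests;
* *interleave*: a second assessment started strictly inside the first one;
* *slow trails*: a trail making subtest stretched past 15 minutes;
* *dropout*: the battery abandoned part-way (incomplete, not excluded).

Contamination categories are assigned mutually exclusively (one stacked
uniform draw per participant) so the truth table induces exactly one
exclusion reason per contaminated user; dropout is drawn independently
among uncontaminated users.  The truth table records every participant's
latent ability, speed, gameplay count and injected defect, which the tests
use as an oracle for exact filter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from ..binning import ReferenceComposition, assign_bins
from ..records import SCORE_COLUMNS, SessionLog, SubtestSession
from ..registry import get_battery
from .agents import AgentProfile, sample_cohort
from .config import CohortConfig, DEFAULT_CENSUS_REFERENCE
from .tasks import simulate_subtest

__all__ = ["SimulatedCohort", "simulate_cohort", "make_reference"]

_EPOCH = 1_577_836_800.0  # an arbitrary session-clock origin (2020-01-01 UTC)
_TRAILS = (39, 40)


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces."""

    scores: pd.DataFrame          # released 11-column schema (grand_index empty)
    logs: list[SessionLog]        # all runs, contamination included
    truth: pd.DataFrame           # per-participant ground truth
    config: CohortConfig
    seed: int

    @property
    def gameplay_counts(self) -> dict[str, int]:
        return dict(zip(self.truth["user_id"], self.truth["pre_test_gameplays"]))


def _assign_contamination(config: CohortConfig, rng: np.random.Generator,
                          n: int, has_trails: bool) -> np.ndarray:
    u = rng.random(n)
    out = np.full(n, "none", dtype=object)
    lo = 0.0
    for name, rate in (("pause", config.pause_rate),
                       ("interleave", config.interleave_rate),
                       ("slow_trails", config.slow_trails_rate if has_trails else 0.0)):
        out[(u >= lo) & (u < lo + rate)] = name
        lo += rate
    if lo > 1.0:
        raise ValueError("contamination rates sum to more than 1")
    return out


def simulate_cohort(config: CohortConfig, seed: int) -> SimulatedCohort:
    """Simulate a full cohort at trial level.

    Returns released-schema score rows for each participant's first run
    (administration order preserved, ``grand_index`` left missing — it is a
    pipeline output), the session logs of *all* runs, and the truth table.
    Fully deterministic under (config, seed).
    """
    config.validate()
    battery = get_battery(config.battery_id)
    has_trails = any(s in battery for s in _TRAILS)
    profiles = sample_cohort(config, seed)
    rng = np.random.default_rng((int(seed), 1))

    contamination = _assign_contamination(config, rng, config.n, has_trails)
    dropout = (rng.random(config.n) < config.dropout_rate) & (contamination == "none")

    score_rows: list[dict] = []
    logs: list[SessionLog] = []
    truth_rows: list[dict] = []

    for i, prof in enumerate(profiles):
        defect = contamination[i]
        start0 = _EPOCH + float(rng.uniform(0, 365 * 86400))
        time_of_day = int((start0 % 86400) // 3600)
        n_sub = len(battery.subtest_ids)
        n_admin = n_sub
        if dropout[i]:
            n_admin = int(rng.integers(1, n_sub))

        # per-subtest gaps; one contaminated gap for 'pause', one ~2 h gap
        # (still under the 24 h limit) to host the interleaved run
        gaps = rng.uniform(5.0, 30.0, size=n_sub)
        special_gap_idx = None
        if n_admin > 1 and defect == "pause":
            special_gap_idx = int(rng.integers(1, n_admin))
            gaps[special_gap_idx] = 24 * 3600 + float(rng.uniform(3600, 21600))
        elif n_admin > 1 and defect == "interleave":
            special_gap_idx = int(rng.integers(1, n_admin))
            gaps[special_gap_idx] = float(rng.uniform(5400, 9000))

        slow_target = None
        if defect == "slow_trails":
            present = [s for s in battery.subtest_ids[:n_admin] if s in _TRAILS]
            if not present:  # ensure the defect is expressible
                n_admin = n_sub
                present = [s for s in battery.subtest_ids if s in _TRAILS]
            slow_target = int(present[int(rng.integers(len(present)))])

        entries = []
        clock = start0
        for j, sid in enumerate(battery.subtest_ids[:n_admin]):
            if j > 0:
                clock += gaps[j]
            trials, raw = simulate_subtest(prof, sid, rng=rng)
            duration = sum(t.rt for t in trials) + float(rng.uniform(10, 30))
            if sid == slow_target:
                duration = 15 * 60 + float(rng.uniform(60, 600))
                raw = duration  # trail making scores are completion times
            entries.append(SubtestSession(
                subtest_id=sid, start_time=clock, end_time=clock + duration,
                raw_score=raw, trials=trials))
            clock = entries[-1].end_time

        run_id = f"r{i:07d}a"
        log = SessionLog(
            user_id=prof.user_id, test_run_id=run_id,
            battery_id=config.battery_id, age=prof.age, gender=prof.gender,
            education_level=prof.education_level, country=prof.country,
            pre_test_gameplays=prof.pre_test_gameplays, entries=entries)
        logs.append(log)

        if defect == "interleave" and special_gap_idx is not None:
            host = entries[special_gap_idx - 1]
            b_start = host.end_time + gaps[special_gap_idx] * 0.3
            b_trials, b_raw = simulate_subtest(prof, battery.subtest_ids[0], rng=rng)
            b_dur = min(sum(t.rt for t in b_trials) + 20.0,
                        gaps[special_gap_idx] * 0.3)
            logs.append(SessionLog(
                user_id=prof.user_id, test_run_id=f"r{i:07d}b",
                battery_id=config.battery_id, age=prof.age, gender=prof.gender,
                education_level=prof.education_level, country=prof.country,
                pre_test_gameplays=prof.pre_test_gameplays,
                entries=[SubtestSession(
                    subtest_id=battery.subtest_ids[0], start_time=b_start,
                    end_time=b_start + b_dur, raw_score=b_raw, trials=b_trials)]))

        for e in entries:
            if e.raw_score is None:
                continue
            score_rows.append({
                "user_id": prof.user_id, "age": prof.age, "gender": prof.gender,
                "education_level": prof.education_level, "country": prof.country,
                "test_run_id": run_id, "battery_id": config.battery_id,
                "specific_subtest_id": e.subtest_id, "time_of_day": time_of_day,
                "raw_score": float(e.raw_score), "grand_index": np.nan,
            })

        truth_rows.append({
            "user_id": prof.user_id, "test_run_id": run_id,
            "g": prof.g, "speed": prof.speed,
            "pre_test_gameplays": prof.pre_test_gameplays,
            "violation": defect, "dropout": bool(dropout[i]),
        })

    scores = pd.DataFrame(score_rows, columns=list(SCORE_COLUMNS))
    for c in ("age", "education_level", "battery_id", "specific_subtest_id",
              "time_of_day"):
        scores[c] = scores[c].astype("Int64")
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(scores=scores, logs=logs, truth=truth,
                           config=config, seed=int(seed))


def make_reference(
    kind: str = "census",
    cohort: Optional[Union[SimulatedCohort, pd.DataFrame]] = None,
    explicit=None,
    strict: bool = True,
) -> ReferenceComposition:
    """Build an 18-bin reference composition.

    ``kind`` is one of:

    * ``"census"`` — the shipped census-like default;
    * ``"uniform"`` — all 18 bins equal;
    * ``"match_cohort"`` — the empirical composition of ``cohort``
      (one contribution per participant);
    * ``"explicit"`` — the supplied vector; with ``strict=False`` a vector
      not summing to 1 is renormalized with a warning instead of rejected.
    """
    if kind == "census":
        return ReferenceComposition(DEFAULT_CENSUS_REFERENCE.copy())
    if kind == "uniform":
        return ReferenceComposition.uniform()
    if kind == "match_cohort":
        if cohort is None:
            raise ValueError("match_cohort requires a cohort")
        frame = cohort.scores if isinstance(cohort, SimulatedCohort) else cohort
        per_user = frame.groupby("user_id", sort=False).agg(
            age=("age", "first"), education_level=("education_level", "first"))
        k = assign_bins(per_user["age"], per_user["education_level"])
        return ReferenceComposition.from_counts(k)
    if kind == "explicit":
        if explicit is None:
            raise ValueError("explicit reference requires a vector")
        return ReferenceComposition(explicit, strict=strict)
    raise ValueError(f"unknown reference kind: {kind!r}")
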