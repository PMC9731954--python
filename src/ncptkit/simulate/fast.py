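"""Vectorized score-level cohort simulation.

For large calibration cohorts (10^5+ participants) the trial-level
simulators are unnecessarily detailed: the normalization and Grand Index
machinery only consumes (raw score, demographics) pairs.  This module draws
raw scores directly from per-subtest marginal models that mirror the
trial-level simulators — binomial counts for fixed-trial tasks, rate-style
counts for timed tasks, lognormal times for speeded tasks — driven by the
same latent one-factor ability model, so the correlation structure and
demographic effects match the trial-level path.  No session logs or
contamination are produced: every run is complete and clean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from ..records import SCORE_COLUMNS
from ..registry import get_battery
from .agents import ability_matrix, sample_demographics
from .config import CohortConfig

__all__ = ["simulate_scores_fast"]


def _fast_raw_score(sid: int, a: np.ndarray, spd: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    n = a.size
    z = rng.standard_normal
    if sid in (26, 32):      # mean correct-go RT, ms
        return np.clip(450.0 * np.exp(-0.12 * a - 0.10 * spd + 0.18 * z(n)), 150, 1450)
    if sid == 39:            # trail making A completion time, s
        return 35.0 * np.exp(-0.20 * a - 0.10 * spd + 0.15 * z(n))
    if sid == 40:            # trail making B completion time, s
        return 65.0 * np.exp(-0.20 * a - 0.10 * spd + 0.15 * z(n))
    if sid in (28, 33):      # max span reached
        return np.clip(np.round(5.5 + 1.3 * a + 0.6 * z(n)), 0, 10)
    if sid in (43, 44):      # total correct span trials
        return np.clip(np.round(8.0 + 2.5 * a + 1.2 * z(n)), 0, None)
    if sid == 53:            # complex span, total correct
        return np.clip(np.round(5.0 + 2.0 * a + 1.0 * z(n)), 0, None)
    fixed = {27: (12, 0.5), 31: (17, 0.3), 51: (25, 0.6), 52: (100, 3.2),
             54: (40, 0.8), 55: (50, 0.5), 36: (12, 0.6), 37: (12, 0.3)}
    if sid in fixed:
        trials, base = fixed[sid]
        return rng.binomial(trials, expit(a + base)).astype(float)
    if sid in (29, 30):      # 45-second item streams
        attempts = np.floor(45.0 / (3.2 * np.exp(-0.15 * spd))).astype(int)
        correct = rng.binomial(attempts, expit(a + 1.0))
        if sid == 29:
            return correct.astype(float)
        return np.maximum(2 * correct - attempts, 0).astype(float)
    if sid in (38, 45):      # 90-second digit symbol stream
        attempts = np.floor(90.0 / (1.6 * np.exp(-0.15 * spd))).astype(int)
        return rng.binomial(attempts, expit(a + 2.0)).astype(float)
    raise KeyError(f"no fast score model for subtest {sid}")


def simulate_scores_fast(config: CohortConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a clean, complete cohort of released-schema score rows.

    Returns ``(scores, truth)`` where truth carries each participant's
    latent ability, speed and gameplay count.  Deterministic under
    (config, seed); contamination and dropout settings are ignored.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    demo = sample_demographics(config, rng)
    battery = get_battery(config.battery_id)
    sids = list(battery.subtest_ids)
    g, speed, abil = ability_matrix(config, demo, rng, sids)
    n = config.n
    plays = np.round(config.gameplay_median
                     * np.exp(config.gameplay_sigma * rng.standard_normal(n))).astype(int)
    tod = rng.integers(0, 24, size=n)

    user_ids = np.array([f"u{i:07d}" for i in range(n)])
    run_ids = np.array([f"r{i:07d}a" for i in range(n)])

    s = len(sids)
    raw = np.empty((n, s))
    for j, sid in enumerate(sids):
        raw[:, j] = _fast_raw_score(sid, abil[:, j], speed, rng)

    # participant-major row order = administration order within each run
    rep = np.repeat(np.arange(n), s)
    scores = pd.DataFrame({
        "user_id": user_ids[rep],
        "age": pd.array(demo["age"].to_numpy()[rep], dtype="Int64"),
        "gender": demo["gender"].to_numpy()[rep],
        "education_level": demo["education_level"].to_numpy(dtype=object)[rep],
        "country": config.country,
        "test_run_id": run_ids[rep],
        "battery_id": pd.array(np.full(n * s, config.battery_id), dtype="Int64"),
        "specific_subtest_id": pd.array(np.tile(np.array(sids), n), dtype="Int64"),
        "time_of_day": pd.array(tod[rep], dtype="Int64"),
        "raw_score": raw.ravel(),
        "grand_index": np.nan,
    }, columns=list(SCORE_COLUMNS))
    scores["education_level"] = scores["education_level"].astype("Int64")

    truth = pd.DataFrame({
        "user_id": user_ids, "test_run_id": run_ids, "g": g, "speed": speed,
        "pre_test_gameplays": plays,
        "violation": "none", "dropout": False,
    })
    return scores, truth
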