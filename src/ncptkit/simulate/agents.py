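"""Latent-ability agent sampling.

Each agent carries a general ability g ~ N(0, 1); the subtest-specific
ability is

    a_s = lambda_s * g + sqrt(1 - lambda_s^2) * eps_s + demographic effect,

where the demographic effect is a linear age slope (per decade, centered at
45), an education-bin offset, and a gender offset, all on the ability (SD)
scale.  With all loadings positive, any two subtest abilities are positively
correlated — the positive manifold is built in.  A response-speed parameter,
partially loaded on g, drives the response-time distributions of the timed
simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..binning import AGE_BIN_EDGES, EDU_CODE_TO_BIN, K_BINS
from .config import CohortConfig

__all__ = ["AgentProfile", "sample_demographics", "sample_cohort", "ability_matrix"]

#: Education codes per attainment bin, with within-bin draw weights.
_EDU_DRAW = {
    0: ([1, 2], [0.2, 0.8]),
    1: ([3, 4, 8], [0.40, 0.50, 0.10]),
    2: ([5, 6, 7], [0.25, 0.62, 0.13]),
}


@dataclass
class AgentProfile:
    """One simulated participant: demographics, latent abilities, speed."""

    user_id: str
    age: int
    gender: Optional[str]
    education_level: Optional[int]
    country: str
    g: float
    speed: float
    abilities: dict[int, float] = field(default_factory=dict)
    pre_test_gameplays: int = 0

    def ability(self, subtest_id: int) -> float:
        return self.abilities[subtest_id]


def sample_demographics(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized draw of n participants' demographics from the composition.

    Returns a frame with ``age``, ``gender``, ``education_level`` (nullable)
    and the hidden ``_edu_bin`` (-1 when missing/other) used for ability
    offsets.
    """
    config.validate()
    n = config.n
    comp = np.asarray(config.composition, dtype=float)
    comp = comp / comp.sum()
    k = rng.choice(K_BINS, size=n, p=comp)
    age_bin, edu_bin = k // 3, k % 3

    lo = np.array([e[0] for e in AGE_BIN_EDGES])
    hi = np.array([e[1] for e in AGE_BIN_EDGES])
    age = rng.integers(lo[age_bin], hi[age_bin] + 1)

    edu = np.empty(n, dtype=object)
    for b, (codes, wts) in _EDU_DRAW.items():
        m = edu_bin == b
        edu[m] = rng.choice(codes, size=int(m.sum()), p=wts)
    u = rng.random(n)
    other = u < config.p_education_other
    missing = (u >= config.p_education_other) & (
        u < config.p_education_other + config.p_education_missing)
    edu[other] = 99
    edu[missing] = None
    edu_bin = edu_bin.copy()
    edu_bin[other | missing] = -1

    tokens = list(config.gender_probs)
    probs = np.array([config.gender_probs[t] for t in tokens], dtype=float)
    gender = rng.choice(np.array(tokens, dtype=object), size=n, p=probs / probs.sum())

    return pd.DataFrame({
        "age": age.astype(int),
        "gender": gender,
        "education_level": pd.array([None if e is None else int(e) for e in edu],
                                    dtype="Int64"),
        "_edu_bin": edu_bin,
    })


def ability_matrix(config: CohortConfig, demo: pd.DataFrame,
                   rng: np.random.Generator,
                   subtest_ids: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(g, speed, abilities[n x s]) for the given subtests."""
    n = len(demo)
    g = rng.standard_normal(n)
    speed = config.speed_loading * g + np.sqrt(
        max(0.0, 1 - config.speed_loading ** 2)) * rng.standard_normal(n)

    age_eff = config.age_slope_per_decade * (demo["age"].to_numpy(dtype=float) - 45.0) / 10.0
    edu_bin = demo["_edu_bin"].to_numpy(dtype=int)
    offsets = np.asarray(config.edu_bin_offsets, dtype=float)
    edu_eff = np.where(edu_bin >= 0, offsets[np.clip(edu_bin, 0, 2)], 0.0)
    gender_eff = np.array([config.gender_offsets.get(t, 0.0) for t in demo["gender"]])
    demo_eff = age_eff + edu_eff + gender_eff

    abil = np.empty((n, len(subtest_ids)))
    for j, sid in enumerate(subtest_ids):
        lam = float(config.loadings.get(sid, 0.6))
        uniq = np.sqrt(max(0.0, 1 - lam ** 2))
        abil[:, j] = lam * g + uniq * rng.standard_normal(n) + demo_eff
    return g, speed, abil


def sample_cohort(config: CohortConfig, seed: int) -> list[AgentProfile]:
    """Sample a reproducible cohort of :class:`AgentProfile` objects."""
    from ..registry import get_battery

    rng = np.random.default_rng(seed)
    demo = sample_demographics(config, rng)
    sids = list(get_battery(config.battery_id).subtest_ids)
    g, speed, abil = ability_matrix(config, demo, rng, sids)
    plays = np.round(
        config.gameplay_median * np.exp(config.gameplay_sigma * rng.standard_normal(config.n))
    ).astype(int)

    profiles = []
    for i in range(config.n):
        edu = demo["education_level"].iloc[i]
        profiles.append(AgentProfile(
            user_id=f"u{i:07d}",
            age=int(demo["age"].iloc[i]),
            gender=None if demo["gender"].iloc[i] is None else str(demo["gender"].iloc[i]),
            education_level=None if pd.isna(edu) else int(edu),
            country=config.country,
            g=float(g[i]),
            speed=float(speed[i]),
            abilities={sid: float(abil[i, j]) for j, sid in enumerate(sids)},
            pre_test_gameplays=int(plays[i]),
        ))
    return profiles
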