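"""Cohort configuration and default demographic compositions.

Defaults emulate the structure of large web-based assessment cohorts: a
composition skewed toward college-and-above education relative to the
general population, a modest female majority, a few percent missing gender
and education, and a gameplay-count distribution with median 25 (the median
number of pre-assessment training gameplays in the released data).

The latent model is a single general-ability factor g ~ N(0, 1) with
per-subtest loadings lambda_s (default 0.6 everywhere, giving residual
subtest-subtest correlations near 0.36) plus demographic main effects on
the ability scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from ..binning import K_BINS
from ..registry import subtest_registry

__all__ = ["CohortConfig", "DEFAULT_LOADING", "DEFAULT_COHORT_COMPOSITION",
           "DEFAULT_CENSUS_REFERENCE", "joint_from_marginals"]

DEFAULT_LOADING = 0.6


def joint_from_marginals(age_marginals, edu_marginals) -> np.ndarray:
    """Independent joint over the 18 bins from 6 age and 3 education margins."""
    age = np.asarray(age_marginals, dtype=float)
    edu = np.asarray(edu_marginals, dtype=float)
    if age.shape != (6,) or edu.shape != (3,):
        raise ValueError("expected 6 age and 3 education marginal proportions")
    joint = np.outer(age / age.sum(), edu / edu.sum()).ravel()
    assert joint.shape == (K_BINS,)
    return joint


#: Assessment-cohort-like joint composition (skews younger / more educated
#: than the census: heavier college and post-college mass).
DEFAULT_COHORT_COMPOSITION = joint_from_marginals(
    [0.18, 0.17, 0.19, 0.19, 0.15, 0.12],
    [0.11, 0.61, 0.28],
)

#: Census-like joint composition (older, much heavier high-school-or-less
#: mass), the shipped plausible default for the reweighting reference.
DEFAULT_CENSUS_REFERENCE = joint_from_marginals(
    [0.170, 0.158, 0.159, 0.159, 0.155, 0.199],
    [0.353, 0.519, 0.128],
)


@dataclass
class CohortConfig:
    """Everything the cohort generator needs.

    Attributes
    ----------
    n : number of participants.
    battery_id : which battery they take.
    composition : joint probabilities over the 18 age x education bins
        (ages uniform within bin, codes drawn within their education bin).
    gender_probs : probabilities for gender tokens; ``None`` key = missing.
    p_education_missing, p_education_other : probabilities that the
        education field is missing / coded 99, overriding the binned draw.
    loadings : per-subtest factor loading lambda_s (default 0.6).
    age_slope_per_decade : ability change (SD units) per decade of age.
    edu_bin_offsets : ability offsets for the three education bins.
    gender_offsets : ability offsets per gender token.
    speed_loading : loading of response speed on g.
    gameplay_median, gameplay_sigma : lognormal pre-test gameplay counts.
    pause_rate, interleave_rate, slow_trails_rate, dropout_rate :
        contamination probabilities per participant.
    """

    n: int = 1000
    battery_id: int = 39
    composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_COHORT_COMPOSITION.copy())
    gender_probs: Mapping[Optional[str], float] = field(
        default_factory=lambda: {"m": 0.40, "f": 0.55, None: 0.05})
    p_education_missing: float = 0.06
    p_education_other: float = 0.02
    country: str = "United States"

    loadings: Mapping[int, float] = field(
        default_factory=lambda: {sid: DEFAULT_LOADING for sid in subtest_registry()})
    age_slope_per_decade: float = -0.20
    edu_bin_offsets: tuple[float, float, float] = (-0.15, 0.0, 0.15)
    gender_offsets: Mapping[Optional[str], float] = field(
        default_factory=lambda: {"m": 0.0, "f": 0.0, None: 0.0})
    speed_loading: float = 0.3

    gameplay_median: float = 25.0
    gameplay_sigma: float = 1.0

    pause_rate: float = 0.0
    interleave_rate: float = 0.0
    slow_trails_rate: float = 0.0
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (K_BINS,):
            raise ValueError(f"composition must have {K_BINS} cells")
        if (comp < 0).any() or comp.sum() <= 0:
            raise ValueError("composition must be a non-negative, non-empty measure")
        for rate in (self.pause_rate, self.interleave_rate,
                     self.slow_trails_rate, self.dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("contamination rates must lie in [0, 1]")
        for lam in self.loadings.values():
            if not np.isfinite(lam):
                raise ValueError("loadings must be finite")
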