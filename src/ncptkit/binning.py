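"""Demographic bins and reference-population compositions.

Scores are post-stratified over K = 18 demographic bins: six age bins
([18-29], [30-39], [40-49], [50-59], [60-69], [70-99], every bin including
both boundaries) crossed with three educational-attainment bins
({some high school, high school diploma/GED}, {some college, college degree,
associate's degree}, {professional degree, master's degree, Ph.D.}).

A :class:`ReferenceComposition` holds target proportions f*_k over these 18
bins — in the intended use, the composition of the general population from
census microdata.  Participants with missing education or the "Other"
education code fall in no bin and are excluded from reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .registry import EDUCATION_LEVELS

__all__ = [
    "K_BINS",
    "AGE_BIN_EDGES",
    "AGE_BIN_LABELS",
    "EDU_BIN_LABELS",
    "EDU_CODE_TO_BIN",
    "DemographicBin",
    "assign_bin",
    "assign_bins",
    "ReferenceComposition",
]

K_BINS = 18

#: (low, high) of each age bin, both boundaries included.
AGE_BIN_EDGES: tuple[tuple[int, int], ...] = (
    (18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 99),
)
AGE_BIN_LABELS: tuple[str, ...] = tuple(f"{lo}-{hi}" for lo, hi in AGE_BIN_EDGES)

#: Education codes grouped into three attainment bins; 99 ("Other") is in none.
EDU_CODE_TO_BIN: dict[int, int] = {1: 0, 2: 0, 3: 1, 4: 1, 8: 1, 5: 2, 6: 2, 7: 2}
EDU_BIN_LABELS: tuple[str, ...] = ("high_school", "college", "post_college")


@dataclass(frozen=True)
class DemographicBin:
    """One of the 18 age x education cells; ``k = 3*age_bin + edu_bin``."""

    age_bin: int
    edu_bin: int

    @property
    def k(self) -> int:
        return 3 * self.age_bin + self.edu_bin

    @property
    def age_label(self) -> str:
        return AGE_BIN_LABELS[self.age_bin]

    @property
    def edu_label(self) -> str:
        return EDU_BIN_LABELS[self.edu_bin]

    @classmethod
    def from_k(cls, k: int) -> "DemographicBin":
        if not 0 <= k < K_BINS:
            raise ValueError(f"bin index out of range: {k}")
        return cls(age_bin=k // 3, edu_bin=k % 3)


def _age_bin(age: int) -> int:
    for i, (lo, hi) in enumerate(AGE_BIN_EDGES):
        if lo <= age <= hi:
            return i
    raise ValueError(f"age outside [18, 99]: {age}")


def assign_bin(age: int, education_level: Optional[int]) -> Optional[DemographicBin]:
    """Assign a participant to one of the 18 demographic bins.

    Returns ``None`` when education is missing or coded 99 ("Other"), which
    belongs to none of the three attainment bins.  Raises ``ValueError`` for
    an age outside [18, 99] or an unknown education code.
    """
    a = _age_bin(int(age))
    if education_level is None or (isinstance(education_level, float) and np.isnan(education_level)):
        return None
    code = int(education_level)
    if code not in EDUCATION_LEVELS:
        raise ValueError(f"unknown education code: {code}")
    if code not in EDU_CODE_TO_BIN:  # 99 = "Other"
        return None
    return DemographicBin(age_bin=a, edu_bin=EDU_CODE_TO_BIN[code])


def assign_bins(age: Sequence, education_level: Sequence) -> np.ndarray:
    """Vectorized flat bin index k for arrays of ages and education codes.

    Returns an integer array with -1 for unbinnable participants.
    """
    age = np.asarray(pd.array(age, dtype="Int64").to_numpy(dtype=float))
    edu = np.asarray(pd.array(education_level, dtype="Int64").to_numpy(dtype=float))
    if np.isnan(age).any():
        raise ValueError("age must not be missing")
    if ((age < 18) | (age > 99)).any():
        raise ValueError("age outside [18, 99]")
    known = ~np.isnan(edu)
    bad = known & ~np.isin(edu, list(EDUCATION_LEVELS))
    if bad.any():
        raise ValueError(f"unknown education code: {edu[bad][0]}")
    edges = np.array([lo for lo, _ in AGE_BIN_EDGES] + [100])
    a = np.digitize(age, edges) - 1
    e = np.full(age.shape, -1)
    for code, b in EDU_CODE_TO_BIN.items():
        e[known & (edu == code)] = b
    k = np.where(e >= 0, 3 * a + e, -1)
    return k.astype(int)


class ReferenceComposition:
    """Target proportions f*_k over the 18 demographic bins.

    The proportions must be non-negative and sum to 1 (within 1e-12); with
    ``strict=False`` a positive vector is renormalized instead of rejected.
    """

    def __init__(self, proportions: Union[Sequence[float], Mapping[int, float]],
                 strict: bool = True):
        if isinstance(proportions, Mapping):
            vec = np.zeros(K_BINS)
            for k, v in proportions.items():
                if not 0 <= int(k) < K_BINS:
                    raise ValueError(f"bin index out of range: {k}")
                vec[int(k)] = float(v)
        else:
            vec = np.asarray(proportions, dtype=float)
            if vec.shape != (K_BINS,):
                raise ValueError(f"expected {K_BINS} proportions, got shape {vec.shape}")
        if (vec < 0).any():
            raise ValueError("negative reference mass")
        total = vec.sum()
        if total <= 0:
            raise ValueError("reference composition has zero total mass")
        if abs(total - 1.0) > 1e-12:
            if strict:
                raise ValueError(f"reference proportions sum to {total!r}, not 1")
            import warnings

            warnings.warn(
                f"reference proportions sum to {total:.6g}; renormalizing",
                stacklevel=2,
            )
            vec = vec / total
        self.proportions = vec

    def __getitem__(self, k: int) -> float:
        return float(self.proportions[int(k)])

    def __len__(self) -> int:
        return K_BINS

    @classmethod
    def uniform(cls) -> "ReferenceComposition":
        return cls(np.full(K_BINS, 1.0 / K_BINS))

    @classmethod
    def from_counts(cls, bin_indices: Sequence[int]) -> "ReferenceComposition":
        """Empirical composition of a sample of flat bin indices (-1 ignored)."""
        k = np.asarray(bin_indices, dtype=int)
        k = k[k >= 0]
        if k.size == 0:
            raise ValueError("no binnable observations")
        counts = np.bincount(k, minlength=K_BINS).astype(float)
        return cls(counts / counts.sum())

    def as_mapping(self) -> dict[int, float]:
        return {k: float(v) for k, v in enumerate(self.proportions)}
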