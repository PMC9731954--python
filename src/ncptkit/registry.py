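"""Fixed registries for the NCPT subtests, test batteries, and education codes.

The NeuroCognitive Performance Test (NCPT) is a self-administered, web-based
cognitive assessment composed of brief subtests (go/no-go, memory span,
progressive matrices, ...).  Eight standardized batteries exist, each a fixed,
ordered set of 5-11 subtests.  Several cognitive tasks have two scored
versions, released under distinct subtest identifiers; aggregating over
versions there are 17 distinct tasks.

Everything in this module is a fixed constant of the released data schema:
the 21 subtest definitions, the 8 battery compositions (in administration
order), and the 9 numeric education codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "SubtestDefinition",
    "BatteryDefinition",
    "subtest_registry",
    "battery_registry",
    "education_levels",
    "NEGATED_SUBTESTS",
    "UnknownSubtestError",
    "UnknownBatteryError",
]

#: Subtests whose raw score decreases as performance improves (response times):
#: the go/no-go subtests (26, 32) and the trail making subtests (39, 40).
#: These are negated before rank-based normalization, never in released files.
NEGATED_SUBTESTS = frozenset({26, 32, 39, 40})


class UnknownSubtestError(KeyError):
    """Raised when a subtest id is not one of the 21 registered subtests."""


class UnknownBatteryError(KeyError):
    """Raised when a battery id is not one of the 8 registered batteries."""


@dataclass(frozen=True)
class SubtestDefinition:
    """One scored subtest version.

    Attributes
    ----------
    subtest_id : int
        Released numeric identifier.
    task : str
        Cognitive task name (shared across versions of the same task).
    short_name : str
        Compact label used in tables.
    version : str
        ``"v1"`` or ``"v2"``.
    sibling_id : int or None
        The other version's identifier, if the task has two versions.
    negate_for_norms : bool
        True when a lower raw score means better performance.
    score_units : str
        One of ``count``, ``milliseconds``, ``seconds``, ``span``, ``net-count``.
    """

    subtest_id: int
    task: str
    short_name: str
    version: str
    sibling_id: Optional[int]
    negate_for_norms: bool
    score_units: str


def _st(sid, task, short, ver, sib, units):
    return SubtestDefinition(
        subtest_id=sid,
        task=task,
        short_name=short,
        version=ver,
        sibling_id=sib,
        negate_for_norms=sid in NEGATED_SUBTESTS,
        score_units=units,
    )


_SUBTESTS: dict[int, SubtestDefinition] = {
    d.subtest_id: d
    for d in [
        _st(26, "Go/no-go", "Go/no-go", "v1", 32, "milliseconds"),
        _st(27, "Divided visual attention", "DVA", "v1", None, "count"),
        _st(28, "Forward memory span", "Forward mem.", "v1", 43, "span"),
        _st(29, "Arithmetic reasoning", "Arithmetic", "v1", None, "count"),
        _st(30, "Grammatical reasoning", "Grammar", "v1", None, "net-count"),
        _st(31, "Progressive matrices", "Matrices", "v1", None, "count"),
        _st(32, "Go/no-go", "Go/no-go", "v2", 26, "milliseconds"),
        _st(33, "Reverse memory span", "Reverse mem.", "v1", 44, "span"),
        _st(36, "Verbal list learning", "Lists", "v1", None, "count"),
        _st(37, "Delayed verbal list learning", "Delayed lists", "v1", None, "count"),
        _st(38, "Digit symbol coding", "Digit symbol", "v1", 45, "count"),
        _st(39, "Trail making part A", "Trails A", "v1", None, "seconds"),
        _st(40, "Trail making part B", "Trails B", "v1", None, "seconds"),
        _st(43, "Forward memory span", "Forward mem.", "v2", 28, "count"),
        _st(44, "Reverse memory span", "Reverse mem.", "v2", 33, "count"),
        _st(45, "Digit symbol coding", "Digit symbol", "v2", 38, "count"),
        _st(51, "Scale balance", "Scale balance", "v1", None, "count"),
        _st(52, "Posner cueing", "Posner", "v1", None, "count"),
        _st(53, "Complex memory span", "Complex mem.", "v1", None, "count"),
        _st(54, "Object recognition", "Object recog.", "v1", None, "count"),
        _st(55, "Dual search", "Dual search", "v1", None, "count"),
    ]
}


@dataclass(frozen=True)
class BatteryDefinition:
    """A test battery: an ordered set of subtests administered together."""

    battery_id: int
    subtest_ids: tuple[int, ...]

    def __contains__(self, subtest_id: int) -> bool:
        return subtest_id in self.subtest_ids

    def __len__(self) -> int:
        return len(self.subtest_ids)


_BATTERIES: dict[int, BatteryDefinition] = {
    bid: BatteryDefinition(bid, tuple(ids))
    for bid, ids in {
        14: [29, 28, 30, 27, 26],
        17: [29, 28, 30, 27, 32, 31],
        25: [29, 28, 33, 30, 27, 32, 31],
        26: [36, 39, 40, 29, 28, 33, 30, 27, 32, 38, 37],
        32: [29, 38, 28, 33, 39, 40, 30, 27, 31],
        39: [29, 38, 28, 33, 39, 40, 30, 31],
        50: [29, 45, 43, 44, 39, 40, 30, 31],
        60: [54, 52, 53, 55, 51],
    }.items()
}

#: Numeric coding of self-reported educational attainment (99 = "Other").
EDUCATION_LEVELS: dict[int, str] = {
    1: "Some high school",
    2: "High school diploma/GED",
    3: "Some college",
    4: "College degree",
    5: "Professional degree",
    6: "Master's degree",
    7: "Ph.D.",
    8: "Associate's degree",
    99: "Other",
}


def subtest_registry() -> dict[int, SubtestDefinition]:
    """Return the fixed map subtest_id -> :class:`SubtestDefinition`."""
    return dict(_SUBTESTS)


def battery_registry() -> dict[int, BatteryDefinition]:
    """Return the fixed map battery_id -> :class:`BatteryDefinition`."""
    return dict(_BATTERIES)


def education_levels() -> dict[int, str]:
    """Return the fixed map education code -> description."""
    return dict(EDUCATION_LEVELS)


def get_subtest(subtest_id: int) -> SubtestDefinition:
    try:
        return _SUBTESTS[int(subtest_id)]
    except (KeyError, ValueError, TypeError):
        raise UnknownSubtestError(f"unknown subtest id: {subtest_id!r}") from None


def get_battery(battery_id: int) -> BatteryDefinition:
    try:
        return _BATTERIES[int(battery_id)]
    except (KeyError, ValueError, TypeError):
        raise UnknownBatteryError(f"unknown battery id: {battery_id!r}") from None
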