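"""GHS-derived hazard indicators and their point scoring.

Nine toxicity endpoints are scored from GHS hazard-class assignments.
The three CMR endpoints (germ cell mutagenicity, reproductive toxicity,
carcinogenicity) carry the heaviest weights (20 points each); the six
"other toxicity" endpoints share the remaining 40 points, so a chemical
classified in the top class for every endpoint scores exactly 100.

A chemical with *no data* for an endpoint scores as if it were in the top
class (precautionary scoring); a chemical positively *not classified* for
an endpoint, or for which the endpoint is *not applicable*, scores 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "HazardIndicator",
    "HazardClass",
    "HazardProfile",
    "HazardScoringTable",
    "CMR_INDICATORS",
    "score_hazard_indicator",
    "merge_classifications",
    "raw_hazard_score",
    "cmr_subscore",
    "other_toxicity_subscore",
]


class HazardIndicator(enum.Enum):
    """The nine scored toxicity endpoints."""

    T1 = "acute toxicity (oral, dermal)"
    T2 = "acute toxicity (inhalation)"
    T3 = "irritation (skin, eyes)"
    T4 = "sensitization (skin, respiratory)"
    T5 = "aspiration hazard"
    T6 = "germ cell mutagenicity"
    T7 = "reproductive toxicity"
    T8 = "carcinogenicity"
    T9 = "target organ toxicity (repeated)"

    @property
    def is_cmr(self) -> bool:
        return self in CMR_INDICATORS


CMR_INDICATORS = frozenset(
    {HazardIndicator.T6, HazardIndicator.T7, HazardIndicator.T8}
)


class HazardClass(enum.Enum):
    """A GHS hazard-class label, or one of the three non-class states.

    ``C1A``/``C1B`` exist only for the CMR endpoints (whose class 1 is
    subdivided); the undivided ``C1`` exists only for the others.
    """

    C1 = "1"
    C1A = "1A"
    C1B = "1B"
    C2 = "2"
    C3 = "3"
    C4 = "4"
    NO_DATA = "ND"
    NOT_CLASSIFIED = "NC"
    NOT_APPLICABLE = "NA"

    @property
    def is_definite(self) -> bool:
        """True for an actual GHS class (not ND/NC/NA)."""
        return self not in (
            HazardClass.NO_DATA,
            HazardClass.NOT_CLASSIFIED,
            HazardClass.NOT_APPLICABLE,
        )


# Severity order used to break point ties in conservative merging:
# a definite class beats No Data beats Not Classified beats Not Applicable,
# and among definite classes a lower class number (A before B) is more severe.
_SEVERITY_ORDER = (
    HazardClass.C1,
    HazardClass.C1A,
    HazardClass.C1B,
    HazardClass.C2,
    HazardClass.C3,
    HazardClass.C4,
    HazardClass.NO_DATA,
    HazardClass.NOT_CLASSIFIED,
    HazardClass.NOT_APPLICABLE,
)
_SEVERITY_RANK = {cls: i for i, cls in enumerate(_SEVERITY_ORDER)}

_NON_CLASS = (
    HazardClass.NO_DATA,
    HazardClass.NOT_CLASSIFIED,
    HazardClass.NOT_APPLICABLE,
)

# Valid labels per indicator. Grid cells that do not exist for an endpoint
# (class 4 irritation, class 3 CMR, ...) are invalid inputs, not zero.
VALID_CLASSES: dict[HazardIndicator, frozenset[HazardClass]] = {
    HazardIndicator.T1: frozenset(
        (HazardClass.C1, HazardClass.C2, HazardClass.C3, HazardClass.C4) + _NON_CLASS
    ),
    HazardIndicator.T2: frozenset(
        (HazardClass.C1, HazardClass.C2, HazardClass.C3, HazardClass.C4) + _NON_CLASS
    ),
    HazardIndicator.T3: frozenset((HazardClass.C1, HazardClass.C2) + _NON_CLASS),
    HazardIndicator.T4: frozenset((HazardClass.C1,) + _NON_CLASS),
    HazardIndicator.T5: frozenset((HazardClass.C1, HazardClass.C2) + _NON_CLASS),
    HazardIndicator.T6: frozenset(
        (HazardClass.C1A, HazardClass.C1B, HazardClass.C2) + _NON_CLASS
    ),
    HazardIndicator.T7: frozenset(
        (HazardClass.C1A, HazardClass.C1B, HazardClass.C2) + _NON_CLASS
    ),
    HazardIndicator.T8: frozenset(
        (HazardClass.C1A, HazardClass.C1B, HazardClass.C2) + _NON_CLASS
    ),
    HazardIndicator.T9: frozenset((HazardClass.C1, HazardClass.C2) + _NON_CLASS),
}


def _default_points() -> dict[HazardIndicator, dict[HazardClass, int]]:
    T = HazardIndicator
    C = HazardClass
    pts: dict[HazardIndicator, dict[HazardClass, int]] = {
        T.T1: {C.C1: 6, C.C2: 4, C.C3: 2, C.C4: 1, C.NO_DATA: 6},
        T.T2: {C.C1: 5, C.C2: 3, C.C3: 2, C.C4: 1, C.NO_DATA: 5},
        T.T3: {C.C1: 6, C.C2: 4, C.NO_DATA: 6},
        T.T4: {C.C1: 9, C.NO_DATA: 9},
        T.T5: {C.C1: 5, C.C2: 3, C.NO_DATA: 5},
        T.T6: {C.C1A: 20, C.C1B: 16, C.C2: 12, C.NO_DATA: 20},
        T.T7: {C.C1A: 20, C.C1B: 16, C.C2: 12, C.NO_DATA: 20},
        T.T8: {C.C1A: 20, C.C1B: 16, C.C2: 12, C.NO_DATA: 20},
        T.T9: {C.C1: 9, C.C2: 7, C.NO_DATA: 9},
    }
    for ind in T:
        pts[ind][C.NOT_CLASSIFIED] = 0
        pts[ind][C.NOT_APPLICABLE] = 0
    return pts


@dataclass(frozen=True)
class HazardScoringTable:
    """Points per (indicator, class) cell; defaults are the published grid.

    The maxima over classes sum to 100 across the nine indicators
    (20 + 20 + 20 for CMR, 6 + 5 + 6 + 9 + 5 + 9 for the rest).
    """

    points: Mapping[HazardIndicator, Mapping[HazardClass, int]] = field(
        default_factory=_default_points
    )

    def __post_init__(self) -> None:
        for ind in HazardIndicator:
            if ind not in self.points:
                raise ValueError(f"scoring table missing indicator {ind.name}")
            for cls, pts in self.points[ind].items():
                if cls not in VALID_CLASSES[ind]:
                    raise ValueError(
                        f"class {cls.value!r} is not a valid label for {ind.name}"
                    )
                if pts < 0:
                    raise ValueError(
                        f"negative points for ({ind.name}, {cls.value})"
                    )

    def lookup(self, indicator: HazardIndicator, cls: HazardClass) -> int:
        if cls not in VALID_CLASSES[indicator]:
            raise ValueError(
                f"hazard class {cls.value!r} is not a valid label for "
                f"indicator {indicator.name} ({indicator.value})"
            )
        return int(self.points[indicator].get(cls, 0))

    def max_points(self, indicator: HazardIndicator) -> int:
        return max(self.points[indicator].values())


DEFAULT_HAZARD_TABLE = HazardScoringTable()


@dataclass(frozen=True)
class HazardProfile:
    """One resolved hazard class per indicator, for a single chemical."""

    assignments: Mapping[HazardIndicator, HazardClass]

    def __post_init__(self) -> None:
        missing = [i.name for i in HazardIndicator if i not in self.assignments]
        if missing:
            raise ValueError(f"profile missing indicators: {', '.join(missing)}")
        for ind, cls in self.assignments.items():
            if cls not in VALID_CLASSES[ind]:
                raise ValueError(
                    f"hazard class {cls.value!r} is not a valid label for "
                    f"indicator {ind.name} ({ind.value})"
                )

    @classmethod
    def not_classified(cls) -> "HazardProfile":
        return cls({i: HazardClass.NOT_CLASSIFIED for i in HazardIndicator})


def score_hazard_indicator(
    indicator: HazardIndicator,
    cls: HazardClass,
    table: HazardScoringTable = DEFAULT_HAZARD_TABLE,
) -> int:
    """Points for one (indicator, class) cell.

    Raises ``ValueError`` if the class label does not exist for the
    indicator (e.g. class 4 irritation).
    """
    return table.lookup(indicator, cls)


def merge_classifications(
    candidates: Iterable[HazardClass],
    indicator: HazardIndicator,
    table: HazardScoringTable = DEFAULT_HAZARD_TABLE,
) -> HazardClass:
    """Resolve multi-source assignments to the most conservative class.

    The winner is the candidate with the highest point value; point ties go
    to the more severe label (definite class > No Data > Not Classified >
    Not Applicable, and among definite classes 1/1A before 1B before 2...).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError(f"no candidate classes supplied for {indicator.name}")
    for cls in candidates:
        if cls not in VALID_CLASSES[indicator]:
            raise ValueError(
                f"hazard class {cls.value!r} is not a valid label for "
                f"indicator {indicator.name} ({indicator.value})"
            )
    return max(
        candidates,
        key=lambda c: (table.lookup(indicator, c), -_SEVERITY_RANK[c]),
    )


def raw_hazard_score(
    profile: HazardProfile, table: HazardScoringTable = DEFAULT_HAZARD_TABLE
) -> int:
    """Sum of the nine indicator points; 0–100 under the default table."""
    return sum(
        table.lookup(ind, profile.assignments[ind]) for ind in HazardIndicator
    )


def cmr_subscore(
    profile: HazardProfile, table: HazardScoringTable = DEFAULT_HAZARD_TABLE
) -> int:
    """Points from the CMR endpoints only (0–60 under the default table)."""
    return sum(
        table.lookup(ind, profile.assignments[ind])
        for ind in HazardIndicator
        if ind.is_cmr
    )


def other_toxicity_subscore(
    profile: HazardProfile, table: HazardScoringTable = DEFAULT_HAZARD_TABLE
) -> int:
    """Points from the six non-CMR endpoints (0–40 under the default table)."""
    return sum(
        table.lookup(ind, profile.assignments[ind])
        for ind in HazardIndicator
        if not ind.is_cmr
    )
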