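"""Min–max normalization, multiplicative total scores, and ranking.

Raw hazard and exposure scores (each 0–100) are rescaled to 0–10 by
min–max normalization over the evaluated set,

    hv_i = (HV_i - HV_min) / (HV_max - HV_min) × 10,

so the set maximum maps to 10 and the set minimum to 0. The total score is
the product of the two normalized scores (0–100); chemicals are ranked by
descending total. Normalization is set-relative by default — scores are
comparable only within one evaluated inventory — with an option to
normalize against the fixed theoretical 0–100 range instead for
cross-inventory comparability.

The central object is :class:`CrirsRanker`, a scikit-learn style
transformer: ``fit`` learns the normalization bounds from an inventory,
``transform`` emits the scored and ranked table. :func:`rank_chemicals` is
the one-call wrapper.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import exposure as _exp
from . import hazard as _haz
from .exposure import DEFAULT_EXPOSURE_TABLE, ExposureScoringTable
from .hazard import DEFAULT_HAZARD_TABLE, HazardScoringTable
from .records import ChemicalRecord

__all__ = ["normalize", "total_score", "CrirsRanker", "rank_chemicals", "SCORE_COLUMNS"]

logger = logging.getLogger(__name__)

#: Columns of the scored table, in output order.
SCORE_COLUMNS = [
    "rank",
    "name",
    "cas",
    "raw_hazard",
    "raw_exposure",
    "cmr",
    "other_toxicity",
    "handling",
    "distribution",
    "measured",
    "hazard_score",
    "exposure_score",
    "total_score",
]


def normalize(
    values: Sequence[float],
    scale: float = 10.0,
    bounds: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Min–max rescale ``values`` onto [0, scale].

    With ``bounds=None`` (the default) the observed minimum and maximum of
    the set are used, so the set maximum maps exactly to ``scale``. Pass
    explicit ``bounds`` (e.g. ``(0, 100)``) to normalize against a fixed
    reference range instead.

    A degenerate set (max == min) maps to all zeros, with a logged warning:
    with no spread there is no information to rank on, and the division by
    zero must not occur.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty value set")
    lo, hi = bounds if bounds is not None else (arr.min(), arr.max())
    if hi <= lo:
        logger.warning(
            "degenerate normalization range [%s, %s]: all values map to 0", lo, hi
        )
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo) * scale


def total_score(hazard_norm: float, exposure_norm: float) -> float:
    """Product of the two normalized scores; range 0–100."""
    for label, v in (("hazard", hazard_norm), ("exposure", exposure_norm)):
        if not 0.0 <= v <= 10.0:
            raise ValueError(f"normalized {label} score out of [0, 10]: {v}")
    return hazard_norm * exposure_norm


def _raw_score_frame(
    records: Sequence[ChemicalRecord],
    hazard_table: HazardScoringTable,
    exposure_table: ExposureScoringTable,
) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "name": rec.name,
                "cas": rec.cas,
                "raw_hazard": _haz.raw_hazard_score(rec.hazard, hazard_table),
                "raw_exposure": _exp.raw_exposure_score(rec.exposure, exposure_table),
                "cmr": _haz.cmr_subscore(rec.hazard, hazard_table),
                "other_toxicity": _haz.other_toxicity_subscore(rec.hazard, hazard_table),
                "handling": _exp.handling_subscore(rec.exposure, exposure_table),
                "distribution": _exp.distribution_subscore(rec.exposure, exposure_table),
                "measured": _exp.measured_subscore(rec.exposure, exposure_table),
            }
        )
    return pd.DataFrame(rows)


class CrirsRanker(BaseEstimator, TransformerMixin):
    """Score and rank a chemical inventory.

    Parameters
    ----------
    fixed_range : bool, default False
        If True, normalize raw scores against the theoretical [0, 100]
        range instead of the evaluated set's own min/max. Set-relative
        normalization is the default; fixed-range scores are comparable
        across inventories.
    hazard_table, exposure_table : scoring tables or None
        Override the default point grids (e.g. loaded from a config file).

    Attributes
    ----------
    hazard_bounds_, exposure_bounds_ : tuple of (min, max)
        Normalization bounds learned by ``fit``.
    n_chemicals_ : int
        Inventory size seen at fit time.

    Examples
    --------
    >>> scored = CrirsRanker().fit_transform(records)   # doctest: +SKIP
    >>> scored.loc[scored["rank"] == 1, "name"]         # doctest: +SKIP
    """

    def __init__(
        self,
        fixed_range: bool = False,
        hazard_table: Optional[HazardScoringTable] = None,
        exposure_table: Optional[ExposureScoringTable] = None,
    ) -> None:
        self.fixed_range = fixed_range
        self.hazard_table = hazard_table
        self.exposure_table = exposure_table

    def _tables(self) -> tuple[HazardScoringTable, ExposureScoringTable]:
        return (
            self.hazard_table if self.hazard_table is not None else DEFAULT_HAZARD_TABLE,
            self.exposure_table
            if self.exposure_table is not None
            else DEFAULT_EXPOSURE_TABLE,
        )

    @staticmethod
    def _validate_records(records: Iterable[ChemicalRecord]) -> list[ChemicalRecord]:
        records = list(records)
        if not records:
            raise ValueError("inventory is empty")
        seen: dict[str, str] = {}
        for rec in records:
            if rec.cas in seen:
                raise ValueError(
                    f"duplicate CAS number {rec.cas!r} "
                    f"({seen[rec.cas]!r} vs {rec.name!r}): ambiguous identity"
                )
            seen[rec.cas] = rec.name
        return records

    def fit(self, X: Iterable[ChemicalRecord], y=None) -> "CrirsRanker":
        """Learn normalization bounds from an inventory."""
        records = self._validate_records(X)
        ht, et = self._tables()
        raw = _raw_score_frame(records, ht, et)
        if self.fixed_range:
            self.hazard_bounds_ = (0.0, 100.0)
            self.exposure_bounds_ = (0.0, 100.0)
        else:
            self.hazard_bounds_ = (
                float(raw["raw_hazard"].min()),
                float(raw["raw_hazard"].max()),
            )
            self.exposure_bounds_ = (
                float(raw["raw_exposure"].min()),
                float(raw["raw_exposure"].max()),
            )
        self.n_chemicals_ = len(records)
        return self

    def transform(self, X: Iterable[ChemicalRecord]) -> pd.DataFrame:
        """Score and rank an inventory using the fitted bounds.

        Returns a DataFrame with one row per chemical, sorted by rank
        (descending total score; ties broken by higher normalized hazard
        score, then CAS string ascending).
        """
        if not hasattr(self, "hazard_bounds_"):
            raise NotFittedError("CrirsRanker must be fitted before transform")
        records = self._validate_records(X)
        ht, et = self._tables()
        df = _raw_score_frame(records, ht, et)
        df["hazard_score"] = normalize(df["raw_hazard"], bounds=self.hazard_bounds_)
        df["exposure_score"] = normalize(df["raw_exposure"], bounds=self.exposure_bounds_)
        df["total_score"] = df["hazard_score"] * df["exposure_score"]
        df = df.sort_values(
            by=["total_score", "hazard_score", "cas"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df[SCORE_COLUMNS]


def rank_chemicals(
    records: Sequence[ChemicalRecord],
    fixed_range: bool = False,
    hazard_table: Optional[HazardScoringTable] = None,
    exposure_table: Optional[ExposureScoringTable] = None,
) -> pd.DataFrame:
    """Score and rank an inventory in one call (set-relative by default)."""
    ranker = CrirsRanker(
        fixed_range=fixed_range,
        hazard_table=hazard_table,
        exposure_table=exposure_table,
    )
    return ranker.fit_transform(records)
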