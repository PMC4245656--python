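"""Correlation structure of indicator sub-scores versus composite scores.

For a scored inventory this module reports, with two-sided p-values from
the t distribution on n − 2 degrees of freedom:

* ``r1`` — Pearson r between each of the five indicator sub-scores
  (CMR, other toxicity, handling volume, distribution, measured exposure)
  and the total score;
* ``r2`` — Pearson r between each sub-score and its parent composite
  (normalized hazard score for the two hazard sub-scores, normalized
  exposure score for the three exposure sub-scores);
* a symmetric 5 × 5 pairwise matrix among the sub-scores;
* the hazard-vs-exposure composite correlation.

Undefined correlations (a constant column) are reported as missing with a
reason code rather than as a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUBSCORE_NAMES",
    "UndefinedCorrelationError",
    "CorrelationEntry",
    "CorrelationReport",
    "pearson_r",
    "correlation_report",
]

#: The five indicator sub-scores, in report order.
SUBSCORE_NAMES = ("cmr", "other_toxicity", "handling", "distribution", "measured")

#: Parent composite column of each sub-score.
PARENT_COMPOSITE = {
    "cmr": "hazard_score",
    "other_toxicity": "hazard_score",
    "handling": "exposure_score",
    "distribution": "exposure_score",
    "measured": "exposure_score",
}


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson r is undefined (zero variance or n < 3)."""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value.

    The p-value comes from the t statistic r·sqrt((n−2)/(1−r²)) on n − 2
    degrees of freedom — identical to the slope test of the corresponding
    simple linear regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need at least 3 observations, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: at least one input has zero variance"
        )
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationEntry:
    """One correlation cell: r, p, a significance flag, or a reason it is missing."""

    r: Optional[float]
    p: Optional[float]
    significant: Optional[bool]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.r is not None


def _entry(x, y, alpha: float) -> CorrelationEntry:
    try:
        r, p = pearson_r(x, y)
    except UndefinedCorrelationError as exc:
        return CorrelationEntry(None, None, None, reason=str(exc))
    return CorrelationEntry(r, p, p < alpha)


@dataclass(frozen=True)
class CorrelationReport:
    """All correlation blocks for one scored inventory."""

    r1: dict[str, CorrelationEntry]
    r2: dict[str, CorrelationEntry]
    pairwise: pd.DataFrame
    pairwise_p: pd.DataFrame
    hazard_vs_exposure: CorrelationEntry
    alpha: float = 0.05
    n: int = 0

    def to_long_frame(self) -> pd.DataFrame:
        """Flatten every reported correlation to (var1, var2, r, p, sig) rows."""
        rows = []

        def add(var1: str, var2: str, e: CorrelationEntry) -> None:
            rows.append(
                {
                    "var1": var1,
                    "var2": var2,
                    "r": e.r,
                    "p": e.p,
                    "sig": e.significant,
                    "reason": e.reason,
                }
            )

        for name, e in self.r1.items():
            add(name, "total_score", e)
        for name, e in self.r2.items():
            add(name, PARENT_COMPOSITE[name], e)
        for i, a in enumerate(SUBSCORE_NAMES):
            for b in SUBSCORE_NAMES[i + 1 :]:
                r = self.pairwise.loc[a, b]
                p = self.pairwise_p.loc[a, b]
                e = CorrelationEntry(
                    None if pd.isna(r) else float(r),
                    None if pd.isna(p) else float(p),
                    None if pd.isna(p) else bool(p < self.alpha),
                    reason="zero variance" if pd.isna(r) else None,
                )
                add(a, b, e)
        add("hazard_score", "exposure_score", self.hazard_vs_exposure)
        return pd.DataFrame(rows)


def correlation_report(scored: pd.DataFrame, alpha: float = 0.05) -> CorrelationReport:
    """Build the full correlation report from a scored inventory table.

    ``scored`` must carry the sub-score columns (``cmr``, ``other_toxicity``,
    ``handling``, ``distribution``, ``measured``), the normalized composites
    (``hazard_score``, ``exposure_score``) and ``total_score`` — i.e. the
    output of :func:`crirs.scoring.rank_chemicals`.
    """
    required = set(SUBSCORE_NAMES) | {"hazard_score", "exposure_score", "total_score"}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored table missing columns: {sorted(missing)}")
    n = len(scored)
    if n < 3:
        raise ValueError(f"need at least 3 chemicals for correlations, got {n}")

    r1 = {s: _entry(scored[s], scored["total_score"], alpha) for s in SUBSCORE_NAMES}
    r2 = {
        s: _entry(scored[s], scored[PARENT_COMPOSITE[s]], alpha)
        for s in SUBSCORE_NAMES
    }

    k = len(SUBSCORE_NAMES)
    rmat = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i, a in enumerate(SUBSCORE_NAMES):
        if np.ptp(scored[a].to_numpy(dtype=float)) > 0:
            rmat[i, i] = 1.0
            pmat[i, i] = 0.0
        for j in range(i + 1, k):
            b = SUBSCORE_NAMES[j]
            e = _entry(scored[a], scored[b], alpha)
            if e.defined:
                rmat[i, j] = rmat[j, i] = e.r
                pmat[i, j] = pmat[j, i] = e.p
    pairwise = pd.DataFrame(rmat, index=SUBSCORE_NAMES, columns=SUBSCORE_NAMES)
    pairwise_p = pd.DataFrame(pmat, index=SUBSCORE_NAMES, columns=SUBSCORE_NAMES)

    hve = _entry(scored["hazard_score"], scored["exposure_score"], alpha)
    return CorrelationReport(
        r1=r1,
        r2=r2,
        pairwise=pairwise,
        pairwise_p=pairwise_p,
        hazard_vs_exposure=hve,
        alpha=alpha,
        n=n,
    )
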