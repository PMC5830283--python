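"""Classical-test-theory statistics: internal consistency and sample description.

Cronbach's alpha is computed on complete cases (listwise deletion, matching
the exclusion of incompletely filled questionnaires at data collection),
with sample variances on the N - 1 denominator:

    alpha = k / (k - 1) * (1 - sum(var_i) / var(total score)).

Demographic summaries turn stratum counts into percentages at two decimals,
with a round-half-up default and an optional truncation mode (published
tables occasionally truncate, which shows up as a 0.01 discrepancy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .responses import ResponseMatrix

__all__ = ["ReliabilityResult", "DemographicsTable", "cronbach_alpha", "demographics_summary"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    n_items: int
    n_complete: int
    item_total_correlations: np.ndarray  # corrected (item vs rest-score)
    alpha_if_deleted: np.ndarray
    item_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": list(self.item_ids),
                "item_rest_correlation": self.item_total_correlations,
                "alpha_if_deleted": self.alpha_if_deleted,
            }
        )


def _alpha_from_matrix(X: np.ndarray) -> float:
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def cronbach_alpha(rm: ResponseMatrix, drop_zero_variance: bool = False) -> ReliabilityResult:
    """Cronbach's alpha with per-item diagnostics on complete cases."""
    complete = rm.complete_cases()
    X = complete.values
    item_ids = list(rm.item_ids)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 complete cases")
    variances = X.var(axis=0, ddof=1)
    zero_var = variances == 0
    if zero_var.any():
        names = [item_ids[j] for j in np.flatnonzero(zero_var)]
        if drop_zero_variance:
            logger.warning("dropping zero-variance items: %s", names)
            X = X[:, ~zero_var]
            item_ids = [i for i, z in zip(item_ids, zero_var) if not z]
        else:
            raise ValueError(f"zero-variance items: {names} (set drop_zero_variance to exclude)")
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least 2 items")
    alpha = _alpha_from_matrix(X)
    total = X.sum(axis=1)
    itc = np.empty(k)
    aid = np.empty(k)
    for j in range(k):
        rest = total - X[:, j]
        sd_j = X[:, j].std(ddof=1)
        sd_rest = rest.std(ddof=1)
        itc[j] = (
            np.nan
            if sd_j == 0 or sd_rest == 0
            else np.corrcoef(X[:, j], rest)[0, 1]
        )
        aid[j] = _alpha_from_matrix(np.delete(X, j, axis=1)) if k > 2 else np.nan
    return ReliabilityResult(
        alpha=float(alpha),
        n_items=k,
        n_complete=X.shape[0],
        item_total_correlations=itc,
        alpha_if_deleted=aid,
        item_ids=tuple(item_ids),
    )


def _percent(count: int, total: int, mode: str) -> float:
    raw = Decimal(count) * Decimal(100) / Decimal(total)
    rounding = ROUND_HALF_UP if mode == "round" else ROUND_DOWN
    return float(raw.quantize(Decimal("0.01"), rounding=rounding))


@dataclass(frozen=True)
class DemographicsTable:
    counts: dict[str, dict[str, int]]  # variable -> stratum -> count
    percentages: dict[str, dict[str, float]]
    total: int
    mode: str
    flags: tuple[str, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, strata in self.counts.items():
            for stratum, count in strata.items():
                rows.append(
                    {
                        "variable": var,
                        "stratum": stratum,
                        "count": count,
                        "percentage": self.percentages[var][stratum],
                    }
                )
        return pd.DataFrame(rows)


def demographics_summary(
    counts: dict[str, dict[str, int]] | dict[str, int],
    total: int,
    mode: str = "round",
) -> DemographicsTable:
    """Percentages (2 dp) from stratum counts.

    ``counts`` maps variable -> stratum -> count, or stratum -> count for a
    single unnamed variable.  Any variable whose counts do not sum to
    ``total`` is flagged, not rejected (published strata occasionally omit
    a residual category).  ``mode`` is "round" (half-up, default) or
    "truncate"; when the two disagree for a cell, the disagreement is
    logged so truncated source tables can be reconciled.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if mode not in ("round", "truncate"):
        raise ValueError("mode must be 'round' or 'truncate'")
    if counts and not isinstance(next(iter(counts.values())), dict):
        counts = {"": counts}  # type: ignore[assignment]
    flags: list[str] = []
    percentages: dict[str, dict[str, float]] = {}
    for var, strata in counts.items():  # type: ignore[union-attr]
        percentages[var] = {}
        for stratum, count in strata.items():
            if count < 0:
                raise ValueError(f"negative count for {var}/{stratum}")
            pct = _percent(count, total, mode)
            other = _percent(count, total, "truncate" if mode == "round" else "round")
            if pct != other:
                msg = (
                    f"{var}/{stratum}: rounding modes disagree "
                    f"(round {max(pct, other):.2f} vs truncate {min(pct, other):.2f})"
                )
                flags.append(msg)
                logger.warning(msg)
            percentages[var][stratum] = pct
        ssum = sum(strata.values())
        if ssum != total:
            msg = f"{var}: stratum counts sum to {ssum}, not {total}"
            flags.append(msg)
            logger.warning(msg)
    return DemographicsTable(
        counts={k: dict(v) for k, v in counts.items()},  # type: ignore[union-attr]
        percentages=percentages,
        total=total,
        mode=mode,
        flags=tuple(flags),
    )
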