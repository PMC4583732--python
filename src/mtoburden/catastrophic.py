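"""Catastrophic health expenditure statistics.

A household's health budget share is its monthly out-of-pocket health
spending over its total monthly expenditure. With threshold z (default
10 %):

* headcount  H  = fraction of households whose share exceeds z,
* overshoot  O  = mean over all households of max(share - z, 0),
* mean positive overshoot MPO = O / H, the average excess among
  exceeders, so z + MPO is their mean budget share.

Exceedance is strict (share > z) by default, matching "payments in excess
of a threshold budget share"; weak exceedance is available for sensitivity
analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_data import HouseholdBudget, TravelerRecord, bin_income_quintiles, categorize


class ShareUndefinedError(ValueError):
    """Budget share requested for a household with zero total expenditure."""


class UndefinedStatisticError(ValueError):
    """MPO requested when no household exceeds the threshold."""


@dataclass(frozen=True)
class CatastrophicConfig:
    z: float = 0.10
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.z < 1:
            raise ValueError(f"threshold z must be in (0,1), got {self.z}")


@dataclass
class CatastrophicResult:
    n: int
    H: float
    O: float = 0.0
    MPO: float | None = None  # None when H == 0
    exceeders: list[str] = field(default_factory=list)


def health_share(budget: HouseholdBudget, household_id: str = "?") -> float:
    if budget.total_month == 0:
        raise ShareUndefinedError(f"household {household_id}: total monthly expenditure is zero")
    return budget.health_month / budget.total_month


def _exceed(shares: np.ndarray, config: CatastrophicConfig) -> np.ndarray:
    return shares > config.z if config.strict else shares >= config.z


def incidence(shares: Sequence[float], config: CatastrophicConfig = CatastrophicConfig(),
              ids: Sequence[str] | None = None) -> CatastrophicResult:
    s = np.asarray(shares, dtype=float)
    if s.size == 0:
        raise ValueError("incidence of an empty collection")
    mask = _exceed(s, config)
    exceeders = [ids[i] for i in np.flatnonzero(mask)] if ids is not None else []
    return CatastrophicResult(n=s.size, H=float(mask.mean()), exceeders=exceeders)


def overshoot(shares: Sequence[float], config: CatastrophicConfig = CatastrophicConfig(),
              ids: Sequence[str] | None = None) -> CatastrophicResult:
    """Fill O and MPO on top of the headcount."""
    res = incidence(shares, config, ids)
    s = np.asarray(shares, dtype=float)
    res.O = float(np.maximum(s - config.z, 0.0).mean())
    res.MPO = res.O / res.H if res.H > 0 else None
    return res


def mean_positive_overshoot(result: CatastrophicResult) -> float:
    if result.MPO is None:
        raise UndefinedStatisticError("MPO undefined: no household exceeds the threshold")
    return result.MPO


_GROUPINGS = ("stratum", "region", "household_size_class", "income_quintile")


def subgroup_table(records: Sequence[TravelerRecord], grouping: str,
                   config: CatastrophicConfig = CatastrophicConfig()) -> tuple[pd.DataFrame, float | None]:
    """Households below/above the threshold per subgroup, with row
    percentages and a chi-square independence p-value.

    Returns ``(table, p_value)``; the p-value is None for a single group.
    """
    from .stats_report import chi_square_test

    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}")
    if grouping == "income_quintile":
        q = bin_income_quintiles(records)
        labels = [f"Q{q[r.id]}" for r in records]
    elif grouping == "stratum":
        labels = [r.stratum for r in records]
    else:
        labels = [categorize(r)[grouping] for r in records]

    shares = np.array([health_share(r.household_budget, r.id) for r in records])
    above = _exceed(shares, config)

    rows = []
    for g in sorted(set(labels)):
        mask = np.array([lab == g for lab in labels])
        n_above = int(above[mask].sum())
        n_below = int(mask.sum()) - n_above
        if n_above + n_below == 0:
            warnings.warn(f"dropping empty group {g!r}", stacklevel=2)
            continue
        rows.append({
            "group": g, "n_below": n_below, "n_above": n_above,
            "pct_below": 100.0 * n_below / (n_below + n_above),
            "pct_above": 100.0 * n_above / (n_below + n_above),
            "n": n_below + n_above,
        })
    table = pd.DataFrame(rows)
    p_value = None
    if len(table) > 1:
        counts = table[["n_below", "n_above"]].to_numpy()
        p_value = chi_square_test(counts).p_value
    return table, p_value
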