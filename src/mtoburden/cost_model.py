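"""Per-visit cost aggregation: payer split, per-capita allocation between
the patient and the caretakers, productivity loss, and component shares.

Conventions
-----------
* "Total cost" of a visit always excludes productivity loss, which is a
  loss rather than a payment and is reported in its own column.
* Non-medical costs are shared equally across the travel party (patient +
  caretakers); medical costs belong to the patient alone.
* Productivity loss converts hours lost per day into a fraction of a
  working day (default 8 h) before multiplying by days abroad and the
  daily income.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._money import cents_to_usd, round_half_up
from .survey_data import (COMPONENTS, TRAVEL_COMPONENTS, CostBreakdown,
                          ProductivityInput, TravelerRecord)

WORKDAY_HOURS = 8.0


@dataclass(frozen=True)
class PayerSplit:
    subsidy_total: int  # cents
    oop_total: int  # cents
    subsidy_share: float
    zero_total: bool = False


@dataclass(frozen=True)
class PerCapitaCost:
    """Episode cost per member of the travel party, USD.

    ``patient_pc`` carries the full medical cost plus one equal share of
    the non-medical cost; ``caretaker_pc`` is that equal share alone.
    """

    patient_pc: float
    caretaker_pc: float


def visit_total_cost(costs: CostBreakdown) -> int:
    """Episode total over all components and both payers, cents.
    Productivity loss is never part of this sum."""
    return costs.total()


def payer_split(costs: CostBreakdown) -> PayerSplit:
    s, o = costs.subsidy_total(), costs.oop_total()
    total = s + o
    if total == 0:
        return PayerSplit(0, 0, 0.0, zero_total=True)
    return PayerSplit(s, o, s / total)


def per_capita_costs(costs: CostBreakdown, n_caretakers: int) -> PerCapitaCost:
    if n_caretakers < 0:
        raise ValueError("n_caretakers must be >= 0")
    medical = costs.component_total("direct_medical")
    nonmedical = costs.total() - medical
    share = cents_to_usd(nonmedical) / (n_caretakers + 1)
    return PerCapitaCost(patient_pc=cents_to_usd(medical) + share, caretaker_pc=share)


def productivity_loss(p: ProductivityInput, workday_hours: float = WORKDAY_HOURS) -> int:
    """Lost earnings in cents: (hours lost / working day) x days abroad x
    daily income."""
    frac = p.hours_lost_per_day / workday_hours
    return round_half_up(frac * p.days_abroad * p.income_per_day)


def component_shares(records: Sequence[TravelerRecord]) -> dict[str, float]:
    """Mean over travelers of each component's share of that traveler's
    total (mean of ratios, so scale-free). Travelers with zero total are
    excluded from the mean; if none have a positive total this is an error."""
    sums = {c: 0.0 for c in COMPONENTS}
    n = 0
    for r in records:
        total = r.costs.total()
        if total == 0:
            continue
        n += 1
        for c in COMPONENTS:
            sums[c] += r.costs.component_total(c) / total
    if n == 0:
        raise ValueError("component shares undefined: no traveler with positive total")
    return {c: sums[c] / n for c in COMPONENTS}


def travel_share(shares: dict[str, float]) -> float:
    """Aggregate the three travel components of a share table."""
    return sum(shares[c] for c in TRAVEL_COMPONENTS)


def per_traveler_cost_table(records: Sequence[TravelerRecord]):
    """Per-traveler costs as a DataFrame (USD): totals, payer split,
    per-capita allocation and productivity loss."""
    import pandas as pd

    rows = []
    for r in records:
        split = payer_split(r.costs)
        pc = per_capita_costs(r.costs, r.n_caretakers)
        rows.append({
            "id": r.id,
            "stratum": r.stratum,
            "total": cents_to_usd(r.costs.total()),
            "subsidy_total": cents_to_usd(split.subsidy_total),
            "oop_total": cents_to_usd(split.oop_total),
            "patient_pc": pc.patient_pc,
            "caretaker_pc": pc.caretaker_pc,
            "productivity_loss": cents_to_usd(productivity_loss(r.productivity)),
        })
    return pd.DataFrame(rows)


def median_iqr_by_component(records: Sequence[TravelerRecord]) -> dict[str, tuple[float, float, float]]:
    """Median (q1, q3) in USD of each component's combined-payer spend."""
    out = {}
    for c in COMPONENTS:
        vals = np.array([r.costs.component_total(c) / 100.0 for r in records])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[c] = (float(med), float(q1), float(q3))
    return out
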