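"""National economic-cost extrapolation with bootstrap uncertainty.

The national annual cost of overseas medical treatment is built from four
strata — patients and caretakers within the subsidized and the privately
funded groups. For each stratum the annual cost is

    c = a x b

where a is the median per-capita episode cost from the survey and b the
estimated number of annual visits. Patient visit counts come from
secondary data and are treated as fixed; caretaker visits are derived as
round(mean caretakers x patient visits). Standard errors follow the
median through a nonparametric bootstrap (resample the per-capita sample,
recompute median x visits, take the SD across replicates).

Productivity loss is summarized separately and never added to the annual
cost totals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._money import round_half_up, to_cents

STRATUM_LABELS = ("subsidized-patients", "subsidized-caretakers",
                  "private-patients", "private-caretakers")


@dataclass(frozen=True)
class EconomyContext:
    """2013 national aggregates used as denominators."""

    gdp: float = 1_431_000_000.0  # USD
    population: int = 336_224

    def __post_init__(self) -> None:
        if self.gdp <= 0 or self.population <= 0:
            raise ValueError("gdp and population must be positive")


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")


@dataclass
class StratumEstimate:
    label: str
    median_pc: float  # (a) USD
    visits: int  # (b)
    annual_cost: float  # (c) = a x b, USD (exact product in cents)
    se: float = 0.0
    gdp_share: float = 0.0  # percent


@dataclass
class NationalTotals:
    total_visits: int
    total_cost: float  # USD
    gdp_share_pct: float
    per_capita_usd: float
    se: float = 0.0


def caretaker_visits(mean_caretakers: float, patient_visits: int) -> int:
    """Annual caretaker journeys implied by the average party size."""
    if mean_caretakers < 0 or patient_visits < 0:
        raise ValueError("inputs must be non-negative")
    return round_half_up(mean_caretakers * patient_visits)


def stratum_annual_cost(median_pc: float, visits: int) -> float:
    """Exact product a x b computed in integer cents, returned as USD."""
    if median_pc < 0 or visits < 0:
        raise ValueError("inputs must be non-negative")
    return to_cents(median_pc) * visits / 100.0


def make_stratum_estimate(label: str, median_pc: float, visits: int,
                          economy: EconomyContext = EconomyContext()) -> StratumEstimate:
    c = stratum_annual_cost(median_pc, visits)
    return StratumEstimate(label=label, median_pc=median_pc, visits=visits,
                           annual_cost=c, gdp_share=100.0 * c / economy.gdp)


def national_totals(strata: Sequence[StratumEstimate],
                    economy: EconomyContext = EconomyContext()) -> NationalTotals:
    labels = {s.label for s in strata}
    missing = set(STRATUM_LABELS) - labels
    if missing:
        raise ValueError(f"missing stratum estimate(s): {', '.join(sorted(missing))}")
    total_visits = sum(s.visits for s in strata)
    total_cost = sum(s.annual_cost for s in strata)
    se = float(np.sqrt(sum(s.se ** 2 for s in strata)))
    return NationalTotals(
        total_visits=total_visits,
        total_cost=total_cost,
        gdp_share_pct=100.0 * total_cost / economy.gdp,
        per_capita_usd=total_cost / economy.population,
        se=se,
    )


def bootstrap_annual_costs(per_capita_sample: Sequence[float], visits: int,
                           config: BootstrapConfig) -> np.ndarray:
    """Annual-cost replicates: median of a size-n resample times visits."""
    x = np.asarray(per_capita_sample, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap needs a sample of size >= 2")
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, x.size, size=(config.replicates, x.size))
    return np.median(x[idx], axis=1) * visits


def bootstrap_se(per_capita_sample: Sequence[float], visits: int,
                 config: BootstrapConfig) -> float:
    """Bootstrap SE of the stratum annual cost (median x visits)."""
    return float(bootstrap_annual_costs(per_capita_sample, visits, config).std(ddof=1))


def productivity_loss_summary(losses_usd: Sequence[float],
                              config: BootstrapConfig) -> tuple[float, float]:
    """Median productivity loss and its bootstrap SE (per traveler, USD).
    Reported beside — never inside — the annual cost totals."""
    x = np.asarray(losses_usd, dtype=float)
    if x.size == 0:
        raise ValueError("no productivity losses supplied")
    med = float(np.median(x))
    if x.size < 2 or np.all(x == x[0]):
        return med, 0.0
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, x.size, size=(config.replicates, x.size))
    return med, float(np.median(x[idx], axis=1).std(ddof=1))


def estimate_strata(records, visits_subsidized: int, visits_private: int,
                    economy: EconomyContext = EconomyContext(),
                    bootstrap: BootstrapConfig | None = None) -> list[StratumEstimate]:
    """Survey records -> the four stratum estimates.

    Patient visit counts are required inputs (secondary data); caretaker
    visits derive from each stratum's observed mean party size.
    """
    from .cost_model import per_capita_costs

    out = []
    for stratum, patient_visits in (("subsidized", visits_subsidized),
                                    ("private", visits_private)):
        grp = [r for r in records if r.stratum == stratum]
        if not grp:
            raise ValueError(f"no records in stratum {stratum!r}")
        pcs = [per_capita_costs(r.costs, r.n_caretakers) for r in grp]
        patient_pc = [p.patient_pc for p in pcs]
        caretaker_pc = [p.caretaker_pc for p in pcs]
        mean_caretakers = float(np.mean([r.n_caretakers for r in grp]))
        ct_visits = caretaker_visits(mean_caretakers, patient_visits)
        for kind, sample, visits in (("patients", patient_pc, patient_visits),
                                     ("caretakers", caretaker_pc, ct_visits)):
            est = make_stratum_estimate(f"{stratum}-{kind}",
                                        float(np.median(sample)), visits, economy)
            if bootstrap is not None:
                # one independent stream per stratum, derived from the root seed
                cfg = BootstrapConfig(bootstrap.replicates,
                                      (bootstrap.seed + len(out)) % 2**31)
                est.se = bootstrap_se(sample, visits, cfg)
            out.append(est)
    return out
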