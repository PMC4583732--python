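"""Synthetic traveler-survey generator.

Produces traveler-level microdata with the statistical structure the
downstream analysis assumes: two funding strata, right-skewed itemized
costs (log-normal, calibrated so each component reproduces a target
median and IQR), zero-inflated components, caretaker party sizes from a
shifted Poisson, and household budgets whose health share follows a
two-component Beta mixture solved to hit a target catastrophic-payment
incidence at threshold z.

All randomness flows from a single root seed through named independent
streams, one per field, so adding a field never perturbs the others.
"""
from __future__ import annotations

import csv
import math
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats as _st

from ._money import to_cents
from .survey_data import (CSV_COLUMNS, CostBreakdown, HouseholdBudget,
                          LoadResult, ProductivityInput, TravelerRecord,
                          load_survey, record_to_row)

#: Standard normal upper quartile; a log-normal's quartiles are
#: median * exp(+-PHI_75 * sigma).
PHI_75 = 0.6744897501960817


class ConfigError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class LogNormalParams:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise CalibrationError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> LogNormalParams:
    """Log-normal parameters matching a (median, q1, q3) summary.

    mu = ln median and sigma = ln(q3/q1) / (2 * 0.67449), the spread that
    puts the quartiles of the fitted distribution at q1 and q3 when the
    summary is quartile-symmetric on the log scale.
    """
    if q1 == 0:
        raise CalibrationError(
            "q1 = 0: use the zero-inflated path (p_zero > 0) for this component")
    if not 0 < q1 <= median <= q3:
        raise CalibrationError(f"need 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})")
    return LogNormalParams(mu=math.log(median), sigma=math.log(q3 / q1) / (2 * PHI_75))


def zero_inflated_from_median_q3(median: float, q3: float, p_zero: float) -> LogNormalParams:
    """Positive-part log-normal of a zero-inflated component, solved so the
    overall (mixture) median and upper quartile hit the targets. Requires
    p_zero < 0.5 so the overall median is positive."""
    if not 0 < p_zero < 0.5:
        raise CalibrationError("zero-inflated path needs 0 < p_zero < 0.5")
    if not 0 < median < q3:
        raise CalibrationError(f"need 0 < median < q3, got ({median}, {q3})")
    z1 = _st.norm.ppf((0.5 - p_zero) / (1 - p_zero))
    z2 = _st.norm.ppf((0.75 - p_zero) / (1 - p_zero))
    sigma = (math.log(q3) - math.log(median)) / (z2 - z1)
    return LogNormalParams(mu=math.log(median) - sigma * z1, sigma=sigma)


@dataclass
class ComponentDist:
    """One cost component's target summary and sampling law."""

    median: float
    q1: float
    q3: float
    p_zero: float = 0.0
    tail_median: float = 100.0  # positive tail of all-zero components

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.median == 0 and self.q3 == 0:
            # "0 (0-0)" component: rare positives only
            x = rng.lognormal(math.log(self.tail_median), 1.0, n)
            x[rng.random(n) < self.p_zero] = 0.0
            return x
        if self.p_zero > 0:
            p = zero_inflated_from_median_q3(self.median, self.q3, self.p_zero)
            x = rng.lognormal(p.mu, p.sigma, n)
            x[rng.random(n) < self.p_zero] = 0.0
            return x
        p = lognormal_from_median_iqr(self.median, self.q1, self.q3)
        return rng.lognormal(p.mu, p.sigma, n)


def _norm_weights(d: dict) -> tuple[list, np.ndarray]:
    keys = list(d.keys())
    w = np.array([float(d[k]) for k in keys])
    if w.sum() <= 0:
        raise ConfigError("categorical weights sum to zero")
    return keys, w / w.sum()


@dataclass
class SurveyConfig:
    """Full parameterization of the generator; see the default YAML for
    every field with its provenance."""

    raw: dict

    def __post_init__(self) -> None:
        r = self.raw
        if r["n_subsidized"] < 1 or r["n_private"] < 1:
            raise ConfigError("stratum sizes must be >= 1")
        if not 0 < r["catastrophic_target"] < 1:
            raise ConfigError("catastrophic_target must be in (0,1)")
        if not 0 < r["z"] < 1:
            raise ConfigError("z must be in (0,1)")
        for stratum, comps in r["components"].items():
            for name, c in comps.items():
                if not c["q1"] <= c["median"] <= c["q3"]:
                    raise ConfigError(f"{stratum}.{name}: need q1 <= median <= q3")
        # the mixture weight must be solvable now, not at generate() time
        self.high_weight()

    @classmethod
    def default(cls) -> "SurveyConfig":
        text = resources.files("mtoburden.resources").joinpath("default_survey.yaml").read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def component_dists(self, stratum: str) -> dict[str, ComponentDist]:
        return {name: ComponentDist(**c) for name, c in self.raw["components"][stratum].items()}

    def high_weight(self) -> float:
        """Mixture weight on the high budget-share component, solved so the
        exceedance probability at z equals the catastrophic target."""
        r = self.raw
        lo, hi = r["share_mixture"]["low"], r["share_mixture"]["high"]
        p_lo = _st.beta.sf(r["z"], lo["a"], lo["b"])
        p_hi = _st.beta.sf(r["z"], hi["a"], hi["b"])
        w = (r["catastrophic_target"] - p_lo) / (p_hi - p_lo)
        if not 0 <= w <= 1:
            raise ConfigError(
                f"catastrophic_target {r['catastrophic_target']} not reachable by the "
                f"share mixture (component exceedances {p_lo:.3f}, {p_hi:.3f})")
        return float(w)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator keyed by (root seed, stream name)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


def _ln_draw(rng: np.random.Generator, n: int, summary: dict) -> np.ndarray:
    p = lognormal_from_median_iqr(summary["median"], summary["q1"], summary["q3"])
    return rng.lognormal(p.mu, p.sigma, n)


_COST_FIELDS = {
    "medical_subsidy": "medical_subsidy", "medical_oop": "medical_oop",
    "travel_home_oop": "travel_home_oop", "airfare_subsidy": "airfare_subsidy",
    "airfare_oop": "airfare_oop", "travel_dest_oop": "travel_dest_oop",
    "entertainment_oop": "entertainment_oop", "lodging_oop": "lodging_oop",
    "food_oop": "food_oop", "visa_oop": "visa_oop", "fx_oop": "fx_oop",
    "other_oop": "other_oop",
}


def _generate_stratum(cfg: SurveyConfig, stratum: str, n: int, seed: int,
                      prefix: str) -> list[TravelerRecord]:
    r = cfg.raw
    key = stratum  # "subsidized" | "private"

    def stream(name: str) -> np.random.Generator:
        return _stream(seed, f"{key}/{name}")

    sexes, sw = _norm_weights(r["sex_weights"][key])
    sex = np.array(sexes)[stream("sex").choice(len(sexes), n, p=sw)]

    bands = [(0, 9), (10, 19), (20, 29), (30, 59), (60, 90)]
    aw = np.array(r["age_weights"][key], dtype=float)
    band_idx = stream("age_band").choice(len(bands), n, p=aw / aw.sum())
    age_rng = stream("age_within")
    age = np.array([age_rng.integers(bands[i][0], bands[i][1] + 1) for i in band_idx])

    regions, rw = _norm_weights(r["region_weights"][key])
    region = np.array(regions)[stream("region").choice(len(regions), n, p=rw)]

    occs, ow = _norm_weights(r["occupation_weights"][key])
    occupation = np.array(occs)[stream("occupation").choice(len(occs), n, p=ow)]

    size_classes = [(1, 5), (6, 10), (11, 15)]
    hw = np.array(r["household_size_weights"][key], dtype=float)
    size_idx = stream("hh_size_class").choice(len(size_classes), n, p=hw / hw.sum())
    size_rng = stream("hh_size_within")
    hh_size = np.array([size_rng.integers(size_classes[i][0], size_classes[i][1] + 1)
                        for i in size_idx])

    dests, dw = _norm_weights(r["destination_weights"][key])
    destination = np.array(dests)[stream("destination").choice(len(dests), n, p=dw)]

    chapters, cw = _norm_weights(r["chapter_weights"][key])
    icd = np.array(chapters, dtype=object)[stream("chapter").choice(len(chapters), n, p=cw)]

    income = _ln_draw(stream("income"), n, r["income_month"])

    los = np.maximum(1, np.round(_ln_draw(stream("los"), n, r["los_days"][key]))).astype(int)
    caretakers = 1 + stream("caretakers").poisson(r["caretaker_mean"][key] - 1.0, n)
    visits = 1 + stream("visits").poisson(r["visits_extra_mean"], n)

    comps = cfg.component_dists(key)
    cost_draws = {name: dist.sample(stream(f"cost/{name}"), n) for name, dist in comps.items()}

    # productivity loss inputs
    prod = r["productivity"]
    prng = stream("productivity")
    hours = prng.uniform(*prod["hours_range"], n)
    hours[prng.random(n) < prod["p_zero"]] = 0.0
    income_day = _ln_draw(stream("income_day"), n, prod["income_per_day"])

    # household budget: health share from the calibrated Beta mixture
    w_hi = cfg.high_weight()
    brng = stream("budget_share")
    lo, hi = r["share_mixture"]["low"], r["share_mixture"]["high"]
    is_hi = brng.random(n) < w_hi
    share = np.where(is_hi, brng.beta(hi["a"], hi["b"], n), brng.beta(lo["a"], lo["b"], n))
    total_month = _ln_draw(stream("budget_total"), n, r["household_total_month"])
    health = share * total_month
    ff = r["food_frac_beta"]
    food_frac = stream("food_frac").beta(ff["a"], ff["b"], n)
    food = food_frac * (total_month - health)
    other = total_month - health - food

    records = []
    for i in range(n):
        kwargs = {field: to_cents(round(cost_draws[name][i], 2)) if name in cost_draws else 0
                  for name, field in _COST_FIELDS.items()}
        costs = CostBreakdown(**kwargs)
        records.append(TravelerRecord(
            id=f"{prefix}{i + 1:04d}",
            stratum=stratum,
            sex=str(sex[i]),
            age=int(age[i]),
            region=str(region[i]),
            occupation=str(occupation[i]),
            household_size=int(hh_size[i]),
            household_income_month=to_cents(round(income[i], 2)),
            icd_code=str(icd[i]) or None,
            destination=str(destination[i]),
            los_days=float(los[i]),
            n_caretakers=int(caretakers[i]),
            visits_per_year=int(visits[i]),
            costs=costs,
            productivity=ProductivityInput(
                hours_lost_per_day=float(round(hours[i], 2)),
                days_abroad=float(los[i]),
                income_per_day=to_cents(round(income_day[i], 2)),
            ),
            household_budget=HouseholdBudget(
                health_month=to_cents(round(health[i], 2)),
                food_month=to_cents(round(food[i], 2)),
                other_month=to_cents(round(other[i], 2)),
            ),
        ))
    return records


def generate(config: SurveyConfig | None = None, seed: int | None = None,
             n_subsidized: int | None = None, n_private: int | None = None) -> list[TravelerRecord]:
    """Generate the synthetic survey; a pure function of (config, seed)."""
    cfg = config or SurveyConfig.default()
    seed = cfg.seed if seed is None else int(seed)
    n_sub = n_subsidized if n_subsidized is not None else int(cfg.raw["n_subsidized"])
    n_priv = n_private if n_private is not None else int(cfg.raw["n_private"])
    return (_generate_stratum(cfg, "subsidized", n_sub, seed, "S")
            + _generate_stratum(cfg, "private", n_priv, seed, "P"))


def write_survey(records: Sequence[TravelerRecord], path) -> None:
    """Write records as a schema-conformant CSV that round-trips through
    :func:`mtoburden.survey_data.load_survey`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for r in records:
            writer.writerow(record_to_row(r))


def roundtrip(records: Sequence[TravelerRecord], path) -> LoadResult:
    write_survey(records, path)
    return load_survey(path)
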