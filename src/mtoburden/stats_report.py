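"""Descriptive statistics, hypothesis tests, and report-table generation.

The survey's cost outcomes are heavily right-skewed, so all comparisons
are nonparametric: a rank-sum test between two groups (mid-ranks, normal
approximation with continuity correction), Pearson's chi-square for
categorical independence, and Cuzick's rank test for trend across ordered
groups. All p-values are two-sided; quantiles use the linear-interpolation
convention throughout.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from . import __version__
from .survey_data import (AGE_LABELS, LOS_LABELS, SIZE_LABELS, TravelerRecord,
                          assign_icd_chapter, bin_income_quintiles, categorize,
                          filter_disease_profile)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order statistics."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median of an empty collection")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Mid-ranks for ties; the exact conditional permutation distribution for
    small untied samples, otherwise the tie-corrected normal approximation
    with continuity correction (the two agree to within the approximation
    error, and survey-sized groups always take the asymptotic path).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "rank-sum (exact for small untied samples, else normal approximation)",
                      (a.size, b.size))


def chi_square_test(contingency) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table,
    df = (r-1)(c-1), upper-tail p. No continuity correction."""
    table = np.asarray(contingency, dtype=float)
    expected = _st.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("zero expected count; merge sparse categories first")
    chi2, p, dof, _ = _st.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p), f"Pearson chi-square (df={dof})",
                      tuple(int(x) for x in table.sum(axis=1)))


def trend_test(values: Sequence[float], group_labels: Sequence,
               order: Sequence | None = None) -> TestResult:
    """Cuzick's nonparametric test for trend across ordered groups.

    Groups are scored 1..k in the given (or sorted) order; the statistic is
    the score-weighted rank sum T = sum_j l_j S_j, standardized by its
    exact null mean and variance (mid-ranks; no tie correction beyond the
    mid-ranks themselves) and referred to the normal distribution,
    two-sided. With two groups the z-statistic agrees in direction with
    the rank-sum test.
    """
    x = np.asarray(values, dtype=float)
    labels = list(group_labels)
    if len(labels) != x.size:
        raise ValueError("values and group labels differ in length")
    groups = list(order) if order is not None else sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("trend test needs at least 2 ordered groups")
    score = {g: i + 1 for i, g in enumerate(groups)}
    l = np.array([score[g] for g in labels], dtype=float)
    ranks = _st.rankdata(x)  # mid-ranks
    N = x.size
    T = float(np.sum(l * ranks))
    sum_l = float(np.sum(l))
    sum_l2 = float(np.sum(l ** 2))
    e_t = (N + 1) / 2 * sum_l
    var_t = (N + 1) / 12 * (N * sum_l2 - sum_l ** 2)
    if var_t <= 0:
        raise ValueError("degenerate trend test: all observations in one group")
    z = (T - e_t) / np.sqrt(var_t)
    p = 2 * _st.norm.sf(abs(z))
    sizes = tuple(int(np.sum(np.array(labels, dtype=object) == g)) for g in groups)
    return TestResult(float(z), float(min(p, 1.0)), "Cuzick trend test", sizes)


# ---------------------------------------------------------------------------
# Report bundle


def _pct(n: int, total: int) -> float:
    return round(100.0 * n / total, 1) if total else 0.0


def _crosstab(records, label_fn, order) -> pd.DataFrame:
    rows = []
    strata = ("subsidized", "private")
    by = {s: [label_fn(r) for r in records if r.stratum == s] for s in strata}
    totals = {s: len(by[s]) for s in strata}
    for lab in order:
        row = {"label": lab}
        for s in strata:
            k = by[s].count(lab)
            row[f"n_{s}"] = k
            row[f"pct_{s}"] = _pct(k, totals[s])
        row["n_total"] = row["n_subsidized"] + row["n_private"]
        row["pct_total"] = _pct(row["n_total"], len(records))
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(records: Sequence[TravelerRecord], out_dir, seed: int | None = None,
                 config_hash_source: str | None = None,
                 visits_subsidized: int = 3546, visits_private: int = 15462,
                 bootstrap_replicates: int = 1000) -> dict:
    """Emit the full table bundle (CSV) plus a JSON summary and metadata.

    Tables mirror the survey write-up: demographics and utilization,
    disease profile (profile-ineligible chapters omitted and counted),
    per-visit costs, the subsidized payer breakdown, catastrophic
    expenditure by subgroup, and the national extrapolation.
    """
    from .catastrophic import CatastrophicConfig, health_share, overshoot, subgroup_table
    from .cost_model import component_shares, per_traveler_cost_table, travel_share
    from .extrapolation import BootstrapConfig, EconomyContext, estimate_strata, national_totals

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = list(records)

    # demographics / utilization
    quint = bin_income_quintiles(records)
    demo = pd.concat([
        _crosstab(records, lambda r: r.sex, ("female", "male")),
        _crosstab(records, lambda r: categorize(r)["age_group"], AGE_LABELS),
        _crosstab(records, lambda r: r.region, ("North", "Central", "South")),
        _crosstab(records, lambda r: categorize(r)["household_size_class"], SIZE_LABELS),
        _crosstab(records, lambda r: f"Q{quint[r.id]}", tuple(f"Q{i}" for i in range(1, 6))),
        _crosstab(records, lambda r: categorize(r)["los_class"], LOS_LABELS),
    ], ignore_index=True)
    demo.to_csv(out / "table_demographics.csv", index=False)

    # disease profile
    profiled, n_omitted = filter_disease_profile(records)
    chap_labels = sorted({assign_icd_chapter(r.icd_code).label for r in profiled})
    disease = _crosstab(profiled, lambda r: assign_icd_chapter(r.icd_code).label, chap_labels)
    disease.to_csv(out / "table_disease_profile.csv", index=False)

    # costs
    cost_table = per_traveler_cost_table(records)
    cost_table.to_csv(out / "costs_per_traveler.csv", index=False)
    shares = component_shares(records)
    pd.DataFrame([{"component": c, "mean_share_pct": round(100 * v, 1)}
                  for c, v in shares.items()]).to_csv(out / "table_cost_shares.csv", index=False)

    # catastrophic
    cfg = CatastrophicConfig()
    shares_h = [health_share(r.household_budget, r.id) for r in records]
    cat = overshoot(shares_h, cfg, ids=[r.id for r in records])
    cat_rows = []
    for grouping in ("stratum", "region", "household_size_class", "income_quintile"):
        tbl, p = subgroup_table(records, grouping, cfg)
        tbl.insert(0, "grouping", grouping)
        tbl["p_value"] = p
        cat_rows.append(tbl)
    pd.concat(cat_rows, ignore_index=True).to_csv(out / "table_catastrophic.csv", index=False)

    # extrapolation
    boot = BootstrapConfig(replicates=bootstrap_replicates, seed=(seed or 0))
    economy = EconomyContext()
    strata = estimate_strata(records, visits_subsidized, visits_private, economy, boot)
    totals = national_totals(strata, economy)
    pd.DataFrame([vars(s) for s in strata]).to_csv(out / "table_extrapolation.csv", index=False)

    summary = {
        "n_records": len(records),
        "n_subsidized": sum(r.stratum == "subsidized" for r in records),
        "n_private": sum(r.stratum == "private" for r in records),
        "disease_profile_omitted": n_omitted,
        "mean_share_travel_pct": round(100 * travel_share(shares), 1),
        "mean_share_medical_pct": round(100 * shares["direct_medical"], 1),
        "catastrophic": {"z": cfg.z, "H_pct": round(100 * cat.H, 1),
                         "O_points": round(100 * cat.O, 2),
                         "MPO_points": None if cat.MPO is None else round(100 * cat.MPO, 1)},
        "national": {"total_visits": totals.total_visits,
                     "total_cost_usd": round(totals.total_cost, 2),
                     "gdp_share_pct": round(totals.gdp_share_pct, 2),
                     "per_capita_usd": round(totals.per_capita_usd, 2),
                     "se_usd": round(totals.se, 2)},
    }
    meta = {
        "version": __version__,
        "seed": seed,
        "config_sha256": (hashlib.sha256(config_hash_source.encode()).hexdigest()
                          if config_hash_source else None),
        "visits": {"subsidized": visits_subsidized, "private": visits_private},
        "bootstrap_replicates": bootstrap_replicates,
        "trend_test": "Cuzick rank test",
        "quantile_convention": "linear interpolation",
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return summary
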