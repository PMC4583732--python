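"""Per-visit cost analysis: component medians/IQRs by stratum, mean cost
shares, the payer split among subsidized travelers, and the rank-sum
comparison of direct medical costs between strata.

Reads results/survey.csv; writes the cost tables under results/.
"""
from pathlib import Path

import pandas as pd

from mtoburden.cost_model import (component_shares, median_iqr_by_component,
                                  payer_split, per_traveler_cost_table,
                                  travel_share)
from mtoburden.stats_report import median_iqr, rank_sum_test
from mtoburden.survey_data import load_survey

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records = load_survey(ROOT / "results" / "survey.csv").records
    sub = [r for r in records if r.stratum == "subsidized"]
    priv = [r for r in records if r.stratum == "private"]

    rows = []
    for label, grp in (("total", records), ("subsidized", sub), ("private", priv)):
        for comp, (med, q1, q3) in median_iqr_by_component(grp).items():
            rows.append({"group": label, "component": comp,
                         "median": med, "q1": q1, "q3": q3})
    pd.DataFrame(rows).to_csv(ROOT / "results" / "table_cost_components.csv", index=False)

    per_traveler = per_traveler_cost_table(records)
    per_traveler.to_csv(ROOT / "results" / "costs_per_traveler.csv", index=False)

    shares = component_shares(records)
    pd.DataFrame([{"component": c, "mean_share_pct": round(100 * v, 1)}
                  for c, v in shares.items()]
                 ).to_csv(ROOT / "results" / "table_cost_shares.csv", index=False)

    med_sub = [r.costs.component_total("direct_medical") / 100 for r in sub]
    med_priv = [r.costs.component_total("direct_medical") / 100 for r in priv]
    test = rank_sum_test(med_sub, med_priv)

    sub_split_share = sum(payer_split(r.costs).subsidy_total for r in sub) / \
        sum(r.costs.total() for r in sub)
    m, q1, q3 = median_iqr(per_traveler["patient_pc"])

    print(f"mean cost shares: travel {100 * travel_share(shares):.1f} %, "
          f"medical {100 * shares['direct_medical']:.1f} %")
    print(f"median per-capita (patient) total cost: ${m:,.1f} (IQR {q1:,.1f}-{q3:,.1f})")
    print(f"direct medical cost, subsidized vs private: "
          f"median ${float(pd.Series(med_sub).median()):,.0f} vs "
          f"${float(pd.Series(med_priv).median()):,.0f}, rank-sum p = {test.p_value:.2g}")
    print(f"government share of subsidized travelers' total cost: {100 * sub_split_share:.0f} %")


if __name__ == "__main__":
    main()
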