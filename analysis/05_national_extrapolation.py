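"""Extrapolate the survey to the national annual cost of overseas medical
treatment: four strata (patients/caretakers x subsidized/private), each
c = median per-capita cost x annual visits, with bootstrap standard
errors, GDP share and national per-capita spending.

Patient visit counts are secondary-data inputs (3546 subsidized visits
from the universal-coverage program; 15462 private). Reads
results/survey.csv; writes results/table_extrapolation.csv.
"""
from pathlib import Path

import pandas as pd

from mtoburden.extrapolation import (BootstrapConfig, EconomyContext,
                                     estimate_strata, national_totals,
                                     productivity_loss_summary)
from mtoburden.cost_model import productivity_loss
from mtoburden.survey_data import load_survey

ROOT = Path(__file__).resolve().parents[1]
VISITS_SUBSIDIZED = 3546
VISITS_PRIVATE = 15462
SEED = 1


def main() -> None:
    records = load_survey(ROOT / "results" / "survey.csv").records
    economy = EconomyContext()
    boot = BootstrapConfig(replicates=1000, seed=SEED)
    strata = estimate_strata(records, VISITS_SUBSIDIZED, VISITS_PRIVATE, economy, boot)
    totals = national_totals(strata, economy)

    table = pd.DataFrame([vars(s) for s in strata])
    table.to_csv(ROOT / "results" / "table_extrapolation.csv", index=False)

    losses = [productivity_loss(r.productivity) / 100 for r in records]
    loss_med, loss_se = productivity_loss_summary(losses, boot)

    for s in strata:
        print(f"{s.label:22s} a=${s.median_pc:10,.2f}  b={s.visits:6d}  "
              f"c=${s.annual_cost:14,.2f} (se {s.se:,.0f})  {s.gdp_share:.2f} % GDP")
    print(f"{'total':22s} visits {totals.total_visits:,}  "
          f"cost ${totals.total_cost:,.0f} (se {totals.se:,.0f})")
    print(f"GDP share {totals.gdp_share_pct:.2f} %; "
          f"${totals.per_capita_usd:,.0f} per capita (population {economy.population:,})")
    print(f"productivity loss: median ${loss_med:,.2f} per traveler "
          f"(bootstrap se {loss_se:,.2f}); reported separately, not in totals")


if __name__ == "__main__":
    main()
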