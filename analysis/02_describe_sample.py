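"""Describe the simulated sample: demographics and utilization by funding
stratum, and the disease profile with ineligible chapters omitted.

Reads results/survey.csv (run 01 first); writes the demographic and
disease-profile tables under results/ and prints the headline counts.
"""
from pathlib import Path

import pandas as pd

from mtoburden.stats_report import _crosstab  # table helper shared with build_report
from mtoburden.survey_data import (AGE_LABELS, LOS_LABELS, SIZE_LABELS,
                                   assign_icd_chapter, categorize,
                                   filter_disease_profile, load_survey)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records = load_survey(ROOT / "results" / "survey.csv").records
    demo = pd.concat([
        _crosstab(records, lambda r: r.sex, ("female", "male")),
        _crosstab(records, lambda r: categorize(r)["age_group"], AGE_LABELS),
        _crosstab(records, lambda r: r.region, ("North", "Central", "South")),
        _crosstab(records, lambda r: categorize(r)["household_size_class"], SIZE_LABELS),
        _crosstab(records, lambda r: categorize(r)["los_class"], LOS_LABELS),
    ], ignore_index=True)
    demo.to_csv(ROOT / "results" / "table_demographics.csv", index=False)

    profiled, omitted = filter_disease_profile(records)
    labels = sorted({assign_icd_chapter(r.icd_code).label for r in profiled})
    disease = _crosstab(profiled, lambda r: assign_icd_chapter(r.icd_code).label, labels)
    disease = disease.sort_values("n_total", ascending=False)
    disease.to_csv(ROOT / "results" / "table_disease_profile.csv", index=False)

    print(f"{len(records)} travelers; {omitted} omitted from the disease profile "
          "(health-service-contact chapter or missing code)")
    top = disease.head(3)[["label", "n_total"]].to_records(index=False)
    print("most common disease groups:", ", ".join(f"{l} ({n})" for l, n in top))


if __name__ == "__main__":
    main()
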