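"""Descriptive tables: obesity filtering, sample construction, composition.

Reads results/cohort/panel.csv, applies the BMI ≥ 30 filter and monotone
disease coding, builds the independent and longitudinal samples, and
writes stratified summaries plus the comorbidity-band composition at
first and last follow-up under results/descriptives/.
"""
from pathlib import Path

from morbiditrail.panel import (
    build_independent_sample,
    build_longitudinal_sample,
    carry_forward_diseases,
    comorbidity_distribution,
    filter_obese,
    load_panel,
    summarize_cohort,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "descriptives"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = filter_obese(carry_forward_diseases(load_panel(ROOT / "cohort" / "panel.csv")))
    independent = build_independent_sample(panel)
    longitudinal = build_longitudinal_sample(panel)

    summarize_cohort(independent).to_csv(OUT / "independent_by_band.csv", index=False)
    first = longitudinal.groupby("participant_id", sort=False).head(1)
    last = longitudinal.groupby("participant_id", sort=False).tail(1)
    d_first = comorbidity_distribution(first)
    d_last = comorbidity_distribution(last)
    d_first.to_csv(OUT / "first_followup_composition.csv")
    d_last.to_csv(OUT / "last_followup_composition.csv")

    print(f"independent sample: {len(independent)}; "
          f"longitudinal: {longitudinal['participant_id'].nunique()} participants, "
          f"{len(longitudinal)} person-observations")
    print("comorbidity-band % at first follow-up:",
          [f"{p:.1f}" for p in d_first['pct']])
    print("comorbidity-band % at last follow-up: ",
          [f"{p:.1f}" for p in d_last['pct']])


if __name__ == "__main__":
    main()
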