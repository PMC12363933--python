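"""Health burden by onset disease type.

Identifies each participant's first-acquired trio disease, tabulates
depression, work limitation, adverse sleep and adverse self-rated health
by onset group, and tests the differences with Pearson chi-square.
Writes results/burden/.
"""
from pathlib import Path

from morbiditrail.burden import burden_by_onset, identify_onset
from morbiditrail.panel import (
    build_longitudinal_sample,
    carry_forward_diseases,
    filter_obese,
    load_panel,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "burden"
TRIO = ("CVD", "MTD", "SMD")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = filter_obese(carry_forward_diseases(load_panel(ROOT / "cohort" / "panel.csv")))
    longit = build_longitudinal_sample(panel)

    onsets = identify_onset(longit, TRIO)
    print(onsets["onset_type"].value_counts().to_string())

    table = burden_by_onset(panel, onsets)
    table.prevalences.to_csv(OUT / "prevalences.csv", index=False)
    table.tests.to_csv(OUT / "tests.csv", index=False)

    wide = table.prevalences.pivot(index="measure", columns="onset_type", values="prevalence")
    print("\nburden prevalence by onset type:")
    print((100 * wide).round(1).to_string())
    print("\ntests:")
    for _, r in table.tests.iterrows():
        print(f"  {r['measure']}: chi2 = {r['statistic']:.2f} (df {r['df']}), p = {r['p']:.4g}")


if __name__ == "__main__":
    main()
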