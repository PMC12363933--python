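"""Simulate the synthetic obese cohort used by all later steps.

Writes the longitudinal panel (with burden outcomes attached at each
participant's last wave), the cross-sectional transaction sample, and
the ground-truth sidecar (true intensities, onset labels) under
results/cohort/.
"""
import json
from pathlib import Path

from morbiditrail.synthetic import (
    SyntheticConfig,
    generate_burden,
    generate_cross_section,
    generate_panel,
)
from morbiditrail.panel import save_panel

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20260918


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED, n_participants=3_000, n_cross_section=20_000)

    panel, truth = generate_panel(cfg)
    panel = generate_burden(cfg, panel, truth["onset"])
    save_panel(panel, OUT / "panel.csv")
    truth["onset"].to_csv(OUT / "true_onsets.csv", index=False)
    with open(OUT / "true_rates.json", "w") as fh:
        json.dump({f"{i}->{j}": r for (i, j), r in cfg.true_rates.items()}, fh, indent=2)

    cross = generate_cross_section(cfg)
    cross.to_csv(OUT / "cross_section.csv", index=False)

    print(f"panel: {panel['participant_id'].nunique()} participants, "
          f"{len(panel)} person-observations -> {OUT / 'panel.csv'}")
    print(f"cross-section: {len(cross)} transactions -> {OUT / 'cross_section.csv'}")


if __name__ == "__main__":
    main()
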