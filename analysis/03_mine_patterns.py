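"""Association-rule mining of disease-system co-occurrence patterns.

Apriori at min support 0.005 and min confidence 0.07, overall and
stratified by sex and age band; selects the modelling trio (highest-
support frequent 3-itemset).  Writes ranked tables and rules under
results/arm/.
"""
from pathlib import Path

import pandas as pd

from morbiditrail.arm import (
    generate_rules,
    mine_frequent_itemsets,
    rules_to_frame,
    select_trio,
    stratified_patterns,
)
from morbiditrail.conditions import DISEASE_GROUPS

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "arm"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cross = pd.read_csv(ROOT / "cohort" / "cross_section.csv")
    items = cross[list(DISEASE_GROUPS)].astype(bool)

    itemsets = mine_frequent_itemsets(items, 0.005)
    rules_to_frame(generate_rules(itemsets, 0.07)).to_csv(OUT / "rules.csv", index=False)
    stratified_patterns(items, None).to_csv(OUT / "patterns_overall.csv", index=False)
    for stratum in ("sex", "age_band"):
        stratified_patterns(
            pd.concat([items, cross[stratum]], axis=1).dropna(subset=[stratum]),
            stratum,
        ).to_csv(OUT / f"patterns_by_{stratum}.csv", index=False)

    trio = sorted(select_trio(itemsets))
    supports = {fs.items: fs.support for fs in itemsets}
    print(f"selected trio: {trio} "
          f"(support {supports[frozenset(trio)]:.3f})")


if __name__ == "__main__":
    main()
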