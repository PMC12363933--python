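"""Health-burden comparison by onset disease type.

A participant's onset disease is the first trio component observed to
appear during follow-up.  Burden measures (depression, work limitation,
sleep quality, self-rated health) are compared across CVD/MTD/SMD-onset
groups with Pearson chi-square tests (no continuity correction) for
categorical measures and one-way ANOVA for continuous ones.  The
five-level ordinals are collapsed to adverse = {fair, poor} for
prevalence reporting; the collapse rule is configurable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ID_COL, WAVE_COL

logger = logging.getLogger(__name__)

ONSET_LABELS = ("CVD", "MTD", "SMD", "none", "ambiguous")

#: ordinal levels collapsed to "adverse" by default
DEFAULT_ADVERSE_LEVELS = ("fair", "poor")

BINARY_MEASURES = ("depressed", "work_limited")
ORDINAL_MEASURES = ("sleep_quality", "self_rated_health")


def identify_onset(panel: pd.DataFrame, trio=("CVD", "MTD", "SMD")) -> pd.DataFrame:
    """Onset disease per participant from monotone-coded trio indicators.

    The onset is the single trio disease present at the first wave where
    any trio disease appears, provided an earlier trio-free wave was
    observed.  Participants already holding a trio disease at first
    observation, or acquiring two or more simultaneously, are
    'ambiguous'; participants never holding one are 'none'.
    Returns columns (participant_id, onset_type, onset_wave).
    """
    trio = tuple(str(t).upper() for t in trio)
    cols = [t.lower() for t in trio]
    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    rows = []
    for pid, g in panel.groupby(ID_COL, sort=False):
        flags = g[cols].to_numpy(dtype=np.int64)
        any_trio = flags.sum(axis=1)
        hit = np.flatnonzero(any_trio > 0)
        if len(hit) == 0:
            rows.append({ID_COL: pid, "onset_type": "none", "onset_wave": pd.NA})
            continue
        first = hit[0]
        wave = g[WAVE_COL].iloc[first]
        if first == 0 or any_trio[first] > 1:
            rows.append({ID_COL: pid, "onset_type": "ambiguous", "onset_wave": wave})
        else:
            rows.append({
                ID_COL: pid,
                "onset_type": trio[int(np.flatnonzero(flags[first])[0])],
                "onset_wave": wave,
            })
    return pd.DataFrame(rows)


@dataclass
class BurdenTable:
    """Per-onset-group prevalences and the tests comparing them."""

    prevalences: pd.DataFrame  # onset_type, n, measure, prevalence
    tests: pd.DataFrame        # measure, test, statistic, df, p, low_expected_flag
    n_analyzed: int
    assessment: str


def chi_square_test(table) -> tuple[float, int, float, bool]:
    """Pearson chi-square on an r×c count table, no continuity correction.

    Returns (statistic, df, p, low_expected_flag); the flag marks any
    expected cell below 1.
    """
    table = np.asarray(table, dtype=float)
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p), bool((expected < 1).any())


def anova_oneway(*groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA F test; returns (F, (df_between, df_within), p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    F, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(F), (df1, df2), float(p)


def burden_by_onset(
    panel: pd.DataFrame,
    onsets: pd.DataFrame,
    adverse_levels=DEFAULT_ADVERSE_LEVELS,
    assessment: str = "last",
    onset_groups=("CVD", "MTD", "SMD"),
) -> BurdenTable:
    """Tabulate and test burden measures by onset-disease group.

    Burden is read at each participant's last observed wave (or the
    onset wave with ``assessment="onset"``).  Participants with 'none'
    or 'ambiguous' onset are excluded.  Binary measures and collapsed
    ordinals (adverse = ``adverse_levels``) are compared across groups
    with Pearson chi-square.
    """
    if assessment not in ("last", "onset"):
        raise ValueError("assessment must be 'last' or 'onset'")
    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    if assessment == "last":
        at = panel.groupby(ID_COL, sort=False).tail(1)
    else:
        merged = panel.merge(
            onsets[[ID_COL, "onset_wave"]].dropna(), on=ID_COL, how="inner"
        )
        at = merged[merged[WAVE_COL] == merged["onset_wave"]]
    data = at.merge(onsets[[ID_COL, "onset_type"]], on=ID_COL, how="inner")
    data = data[data["onset_type"].isin(onset_groups)]

    adverse = set(adverse_levels)
    measures: dict[str, pd.Series] = {}
    for m in BINARY_MEASURES:
        if m in data:
            measures[m] = pd.to_numeric(data[m], errors="coerce")
    for m in ORDINAL_MEASURES:
        if m in data:
            vals = data[m].astype("string").str.lower()
            measures[f"{m}_adverse"] = vals.map(
                lambda v: np.nan if pd.isna(v) else float(v in adverse)
            )

    prev_rows, test_rows = [], []
    groups_present = [
        g for g in onset_groups if (data["onset_type"] == g).sum() > 0
    ]
    dropped = set(onset_groups) - set(groups_present)
    if dropped:
        logger.warning("empty onset groups dropped from tests: %s", sorted(dropped))
    for name, series in measures.items():
        sub = pd.DataFrame({"g": data["onset_type"], "y": series}).dropna()
        for g in groups_present:
            gi = sub[sub["g"] == g]
            prev_rows.append({
                "onset_type": g, "measure": name,
                "n": len(gi), "prevalence": gi["y"].mean() if len(gi) else np.nan,
            })
        tab = pd.crosstab(sub["g"], sub["y"])
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            stat, df, p, low = chi_square_test(tab.to_numpy())
            test_rows.append({
                "measure": name, "test": "chi-square", "statistic": stat,
                "df": df, "p": p, "low_expected_flag": low,
            })
    return BurdenTable(
        prevalences=pd.DataFrame(prev_rows),
        tests=pd.DataFrame(test_rows),
        n_analyzed=int(data[ID_COL].nunique()),
        assessment=assessment,
    )
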