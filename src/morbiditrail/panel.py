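"""Long-format longitudinal panel handling.

The in-memory panel is a pandas DataFrame with one row per participant per
survey wave: identifiers, interview timing, demographics, BMI, the seven
binary disease-system indicators and (optionally) four health-burden
measures.  Functions here validate panels, apply the obesity filter,
carry disease indicators forward (the survey asks "ever diagnosed", and
the progression model has no backward arrows), and construct the two
analysis samples: the cross-sectional "independent" sample (last
observation per participant) and the longitudinal sample (participants
with at least two complete observations).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .conditions import DISEASE_COLUMNS

logger = logging.getLogger(__name__)

ID_COL = "participant_id"
WAVE_COL = "wave"
TIME_COL = "time_years"

#: five-level ordinal used by self-rated health and sleep quality
ORDINAL_LEVELS = ("excellent", "very good", "good", "fair", "poor")

BURDEN_COLUMNS = ("self_rated_health", "work_limited", "sleep_quality", "depressed")

REQUIRED_COLUMNS = (ID_COL, WAVE_COL, TIME_COL, "age", "sex", "race", "bmi") + DISEASE_COLUMNS

#: comorbidity-count bands used throughout descriptive tables
COMORBIDITY_BANDS = ("0", "1", "2", "3+")


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel structure; returns the panel sorted by (id, wave).

    Raises ``ValueError`` on missing columns, non-binary disease flags,
    non-positive BMI, or wave/time indices that do not strictly increase
    within a participant.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")
    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort").reset_index(drop=True)
    for c in DISEASE_COLUMNS:
        vals = panel[c].dropna()
        if not vals.isin([0, 1]).all():
            raise ValueError(f"disease indicator {c!r} must be 0/1")
    bmi = panel["bmi"].dropna()
    if (bmi <= 0).any():
        raise ValueError("bmi must be positive where present")
    grouped = panel.groupby(ID_COL, sort=False)
    if (grouped[WAVE_COL].diff().dropna() <= 0).any():
        raise ValueError("wave indices must strictly increase within participant")
    if (grouped[TIME_COL].diff().dropna() <= 0).any():
        raise ValueError("time_years must strictly increase within participant")
    return panel


def load_panel(path, validate: bool = True) -> pd.DataFrame:
    """Read a long-format panel CSV (UTF-8, header row, '' or 'NA' missing)."""
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    return validate_panel(df) if validate else df


def save_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, na_rep="")


def carry_forward_diseases(panel: pd.DataFrame, columns=DISEASE_COLUMNS) -> pd.DataFrame:
    """Once a disease group is reported, keep it present at all later waves.

    Apparent remission is possible in raw self-report data but is not
    representable in the progressive model, so indicators are made
    monotone within participant by a running maximum over waves.
    """
    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort").reset_index(drop=True)
    out = panel.copy()
    grouped = out.groupby(ID_COL, sort=False)
    for c in columns:
        out[c] = grouped[c].cummax()
    return out


def filter_obese(panel: pd.DataFrame, threshold: float = 30.0, rule: str = "first") -> pd.DataFrame:
    """Retain participants who qualify as obese (BMI ≥ threshold).

    ``rule="first"`` classifies on the first non-missing BMI per
    participant (classification at cohort entry); ``rule="any"`` keeps
    anyone with any wave at or above the threshold.  All waves of a
    qualifying participant are retained.  Participants with no BMI at any
    wave are excluded and logged.
    """
    if threshold <= 0:
        raise ValueError("BMI threshold must be positive")
    if rule not in ("first", "any"):
        raise ValueError("rule must be 'first' or 'any'")
    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    grouped = panel.groupby(ID_COL, sort=False)["bmi"]
    if rule == "first":
        qual = grouped.apply(lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan)
    else:
        qual = grouped.max()
    no_bmi = qual.index[qual.isna()]
    if len(no_bmi):
        logger.warning("excluding %d participants with no BMI at any wave", len(no_bmi))
    keep = qual.index[qual >= threshold]
    return panel[panel[ID_COL].isin(keep)].reset_index(drop=True)


def build_independent_sample(panel: pd.DataFrame) -> pd.DataFrame:
    """Cross-sectional sample: the last available wave per participant."""
    if panel.empty:
        return panel.copy()
    panel = panel.sort_values([ID_COL, WAVE_COL], kind="mergesort")
    return panel.groupby(ID_COL, sort=False).tail(1).reset_index(drop=True)


def build_longitudinal_sample(
    panel: pd.DataFrame, required_fields=REQUIRED_COLUMNS
) -> pd.DataFrame:
    """Participants with ≥ 2 records complete on ``required_fields``.

    Rows with missing values on any required field are dropped first;
    participants left with fewer than two rows are then excluded.  The
    result's row count is the person-observation count.
    """
    required_fields = list(required_fields)
    complete = panel.dropna(subset=required_fields)
    counts = complete[ID_COL].value_counts()
    keep = counts.index[counts >= 2]
    out = complete[complete[ID_COL].isin(keep)]
    return out.sort_values([ID_COL, WAVE_COL], kind="mergesort").reset_index(drop=True)


def comorbidity_band(records: pd.DataFrame) -> pd.Series:
    """Band each record by its disease-system count: 0, 1, 2 or 3+."""
    count = records[list(DISEASE_COLUMNS)].sum(axis=1)
    return pd.Series(
        np.select([count == 0, count == 1, count == 2], ["0", "1", "2"], "3+"),
        index=records.index,
        name="comorbidity_band",
    ).astype(pd.CategoricalDtype(COMORBIDITY_BANDS, ordered=True))


def comorbidity_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of records in each comorbidity band.

    Percentages use the full record count as denominator, the convention
    for follow-up composition tables.
    """
    band = comorbidity_band(records)
    counts = band.value_counts().reindex(COMORBIDITY_BANDS, fill_value=0)
    return pd.DataFrame(
        {"count": counts, "pct": 100.0 * counts / len(records)}
    ).rename_axis("comorbidity_band")


def summarize_cohort(
    records: pd.DataFrame,
    stratify_by: str = "comorbidity_band",
    continuous=("age", "bmi"),
    categorical=("sex", "race") + DISEASE_COLUMNS,
) -> pd.DataFrame:
    """Stratified descriptive summary: mean (SD) and n (%) per stratum.

    ``stratify_by`` is ``"comorbidity_band"`` or any column of
    ``records``.  Percentages for categorical variables use the stratum n
    as denominator.  Empty strata are reported with n=0 and no
    percentages.  Returns a tidy frame with columns (stratum, variable,
    level, n, mean, sd, count, pct).
    """
    if records.empty:
        raise ValueError("summarize_cohort requires non-empty records")
    records = records.copy()
    if stratify_by == "comorbidity_band" and "comorbidity_band" not in records:
        records["comorbidity_band"] = comorbidity_band(records)
    rows = []
    grouped = records.groupby(stratify_by, observed=False)
    for stratum, g in grouped:
        n = len(g)
        rows.append({"stratum": stratum, "variable": "n", "level": "", "n": n})
        if n == 0:
            continue
        for var in continuous:
            vals = g[var].dropna()
            rows.append({
                "stratum": stratum, "variable": var, "level": "", "n": n,
                "mean": vals.mean(), "sd": vals.std(ddof=1),
            })
        for var in categorical:
            counts = g[var].value_counts(dropna=True)
            denom = counts.sum()
            for level, cnt in counts.items():
                rows.append({
                    "stratum": stratum, "variable": var, "level": str(level),
                    "n": n, "count": int(cnt), "pct": 100.0 * cnt / denom,
                })
    return pd.DataFrame(rows)
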