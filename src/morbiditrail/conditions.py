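"""Disease-system vocabulary and mapping from raw condition reports.

Self-reported chronic conditions are grouped into seven body-system
categories (ICD-11 style): cardiovascular (CVD), metabolic (MTD),
respiratory (RPD), skeletal-muscular (SMD), neurological (NRD), mental
disorders (MD) and cancer (CC).  A group flag is set as soon as any member
condition is reported, and survey questions ask about "ever diagnosed", so
group indicators are treated as monotone over time downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

#: canonical upper-case group labels, in fixed display order
DISEASE_GROUPS: tuple[str, ...] = ("CVD", "MTD", "RPD", "SMD", "NRD", "MD", "CC")

#: lower-case column names used in panel DataFrames, same order
DISEASE_COLUMNS: tuple[str, ...] = tuple(g.lower() for g in DISEASE_GROUPS)

#: default raw-condition → group mapping (condition labels are matched
#: case-insensitively after stripping whitespace)
DEFAULT_CONDITION_MAP: dict[str, str] = {
    # cardiovascular
    "heart disease": "CVD",
    "angina": "CVD",
    "hypertension": "CVD",
    "high blood pressure": "CVD",
    "varicose veins": "CVD",
    "thrombosis": "CVD",
    "heart failure": "CVD",
    "heart murmur": "CVD",
    "arrhythmia": "CVD",
    # metabolic
    "high cholesterol": "MTD",
    "high blood glucose": "MTD",
    "diabetes": "MTD",
    "abnormal endocrine metabolism": "MTD",
    # respiratory
    "bronchitis": "RPD",
    "emphysema": "RPD",
    "asthma": "RPD",
    "hay fever": "RPD",
    "lung disease": "RPD",
    "respiratory ailment": "RPD",
    # skeletal-muscular
    "arthritis": "SMD",
    "rheumatism": "SMD",
    "fibromyalgia": "SMD",
    "slipped disc": "SMD",
    "gout": "SMD",
    "back problem": "SMD",
    "joint problem": "SMD",
    "muscle problem": "SMD",
    "neck problem": "SMD",
    "spine problem": "SMD",
    # neurological
    "epilepsy": "NRD",
    "migraine": "NRD",
    "stroke": "NRD",
    "cerebral hemorrhage": "NRD",
    "parkinson's disease": "NRD",
    "alzheimer's disease": "NRD",
    "dementia": "NRD",
    "multiple sclerosis": "NRD",
    "motor neuron disease": "NRD",
    # mental disorders
    "mental illness": "MD",
    "psychiatric disorder": "MD",
    "anxiety": "MD",
    # cancer
    "cancer": "CC",
}


@dataclass(frozen=True)
class DiseaseProfile:
    """Presence flags (0/1) for the seven disease systems at one observation."""

    cvd: int = 0
    mtd: int = 0
    rpd: int = 0
    smd: int = 0
    nrd: int = 0
    md: int = 0
    cc: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1):
                raise ValueError(f"{f.name} must be 0 or 1, got {v!r}")

    @property
    def comorbidity_count(self) -> int:
        return sum(getattr(self, c) for c in DISEASE_COLUMNS)

    def present_groups(self) -> frozenset[str]:
        """Upper-case labels of the groups flagged present."""
        return frozenset(
            g for g, c in zip(DISEASE_GROUPS, DISEASE_COLUMNS) if getattr(self, c)
        )

    @classmethod
    def from_groups(cls, groups) -> "DiseaseProfile":
        groups = {str(g).upper() for g in groups}
        unknown = groups - set(DISEASE_GROUPS)
        if unknown:
            raise ValueError(f"unknown disease groups: {sorted(unknown)}")
        return cls(**{g.lower(): 1 for g in groups})


def map_conditions_to_profile(
    condition_labels,
    mapping: dict[str, str] | None = None,
    *,
    on_unknown: str = "warn",
) -> DiseaseProfile:
    """Map a set of raw condition strings to a :class:`DiseaseProfile`.

    A group flag is 1 iff at least one member condition is reported.
    Unknown labels are dropped with a warning (``on_unknown="warn"``),
    silently (``"ignore"``) or raise (``"error"``).
    """
    if mapping is None:
        mapping = DEFAULT_CONDITION_MAP
    norm = {k.strip().lower(): v.upper() for k, v in mapping.items()}
    groups: set[str] = set()
    for label in condition_labels:
        key = str(label).strip().lower()
        if key in norm:
            groups.add(norm[key])
        elif on_unknown == "error":
            raise KeyError(f"unknown condition label: {label!r}")
        elif on_unknown == "warn":
            warnings.warn(f"unknown condition label excluded: {label!r}", stacklevel=2)
    return DiseaseProfile.from_groups(groups)


def load_condition_map(path) -> dict[str, str]:
    """Read a two-column (condition,group) CSV into a mapping dict."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("condition map CSV needs columns (condition, group)")
    cond, grp = df.columns[:2]
    out = dict(zip(df[cond].astype(str), df[grp].astype(str).str.upper()))
    bad = set(out.values()) - set(DISEASE_GROUPS)
    if bad:
        raise ValueError(f"condition map contains unknown groups: {sorted(bad)}")
    return out
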