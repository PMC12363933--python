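"""Panel construction, filtering and descriptive summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morbiditrail.conditions import (
    DEFAULT_CONDITION_MAP,
    DISEASE_COLUMNS,
    DiseaseProfile,
    map_conditions_to_profile,
)
from morbiditrail.panel import (
    build_independent_sample,
    build_longitudinal_sample,
    carry_forward_diseases,
    comorbidity_band,
    comorbidity_distribution,
    filter_obese,
    summarize_cohort,
    validate_panel,
)

from conftest import make_panel


class TestDiseaseProfile:
    def test_flags_must_be_binary(self):
        with pytest.raises(ValueError):
            DiseaseProfile(cvd=2)

    def test_comorbidity_count(self):
        assert DiseaseProfile().comorbidity_count == 0
        assert DiseaseProfile(cvd=1, mtd=1, cc=1).comorbidity_count == 3


class TestConditionMapping:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ({"angina", "diabetes"}, {"cvd": 1, "mtd": 1}),
            (set(), {}),
            ({"gout", "migraine", "asthma"}, {"smd": 1, "nrd": 1, "rpd": 1}),
        ],
    )
    def test_group_flag_set_iff_member_reported(self, labels, expected):
        profile = map_conditions_to_profile(labels)
        for c in DISEASE_COLUMNS:
            assert getattr(profile, c) == expected.get(c, 0)

    def test_unknown_label_warns_then_excludes(self):
        with pytest.warns(UserWarning, match="unknown condition"):
            profile = map_conditions_to_profile({"angina", "scurvy"})
        assert profile.present_groups() == {"CVD"}

    def test_unknown_label_hard_error(self):
        with pytest.raises(KeyError):
            map_conditions_to_profile({"scurvy"}, on_unknown="error")

    @settings(max_examples=50, deadline=None)
    @given(
        base=st.sets(st.sampled_from(sorted(DEFAULT_CONDITION_MAP))),
        extra=st.sampled_from(sorted(DEFAULT_CONDITION_MAP)),
    )
    def test_monotone_adding_condition_never_clears_flag(self, base, extra):
        before = map_conditions_to_profile(base)
        after = map_conditions_to_profile(base | {extra})
        for c in DISEASE_COLUMNS:
            assert getattr(after, c) >= getattr(before, c)


class TestObesityFilter:
    def test_threshold_is_inclusive(self):
        panel = make_panel([
        {"participant_id": "a", "wave": 0, "bmi": 31.2},
            {"participant_id": "b", "wave": 0, "bmi": 30.0},
            {"participant_id": "c", "wave": 0, "bmi": 29.9},
        ])
        kept = filter_obese(panel, 30.0)
        assert set(kept["participant_id"]) == {"a", "b"}

    def test_first_bmi_classifies_and_all_waves_kept(self):
        panel = make_panel([
            {"participant_id": "a", "wave": 0, "bmi": 31.0},
            {"participant_id": "a", "wave": 1, "bmi": 27.0},
            {"participant_id": "b", "wave": 0, "bmi": 28.0},
            {"participant_id": "b", "wave": 1, "bmi": 33.0},
        ])
        assert len(filter_obese(panel, 30.0, rule="first")) == 2  # both waves of a
        assert set(filter_obese(panel, 30.0, rule="any")["participant_id"]) == {"a", "b"}

    def test_no_bmi_anywhere_excluded(self):
        panel = make_panel([
            {"participant_id": "a", "wave": 0, "bmi": np.nan},
            {"participant_id": "a", "wave": 1, "bmi": np.nan},
            {"participant_id": "b", "wave": 0, "bmi": 35.0},
        ])
        assert set(filter_obese(panel, 30.0)["participant_id"]) == {"b"}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_obese(make_panel([{"participant_id": "a", "wave": 0}]), 0.0)


class TestSampleConstruction:
    def test_independent_sample_takes_last_wave(self):
        panel = make_panel([
            {"participant_id": "a", "wave": 2, "cvd": 0},
            {"participant_id": "a", "wave": 4, "cvd": 0},
            {"participant_id": "a", "wave": 6, "cvd": 1},
            {"participant_id": "b", "wave": 1, "mtd": 1},
        ])
        ind = build_independent_sample(panel)
        assert len(ind) == 2
        a = ind[ind["participant_id"] == "a"].iloc[0]
        assert a["wave"] == 6 and a["cvd"] == 1

    def test_independent_sample_empty_panel(self):
        assert build_independent_sample(make_panel([])).empty

    def test_one_record_per_distinct_participant(self, rng):
        panel = make_panel([
            {"participant_id": f"p{i}", "wave": int(w)}
            for i in range(20)
            for w in sorted(rng.choice(10, size=rng.integers(1, 6), replace=False))
        ])
        ind = build_independent_sample(panel)
        assert len(ind) == panel["participant_id"].nunique()

    def test_longitudinal_sample_counts(self):
        rows = []
        for pid, nw in [("a", 1), ("b", 2), ("c", 5)]:
            rows += [{"participant_id": pid, "wave": w} for w in range(nw)]
        longit = build_longitudinal_sample(make_panel(rows))
        assert longit["participant_id"].nunique() == 2
        assert len(longit) == 7  # person-observations

    def test_all_single_wave_gives_empty(self):
        panel = make_panel([{"participant_id": p, "wave": 0} for p in "abc"])
        assert build_longitudinal_sample(panel).empty

    def test_missing_key_variable_drops_record_then_participant(self):
        panel = make_panel([
            {"participant_id": "a", "wave": 0, "bmi": np.nan},
            {"participant_id": "a", "wave": 1},
            {"participant_id": "b", "wave": 0},
            {"participant_id": "b", "wave": 1},
        ])
        longit = build_longitudinal_sample(panel)
        # a has only one complete record left
        assert set(longit["participant_id"]) == {"b"}
        # conservation: rows equal sum of retained per-participant counts
        assert len(longit) == longit.groupby("participant_id").size().sum()


class TestValidation:
    def test_waves_must_increase(self):
        panel = make_panel([
            {"participant_id": "a", "wave": 1, "time_years": 2.0},
            {"participant_id": "a", "wave": 1, "time_years": 4.0},
        ])
        with pytest.raises(ValueError, match="wave"):
            validate_panel(panel)

    def test_disease_flags_binary(self):
        panel = make_panel([{"participant_id": "a", "wave": 0, "cvd": 3}])
        with pytest.raises(ValueError, match="cvd"):
            validate_panel(panel)

    def test_carry_forward_is_monotone(self):
        panel = make_panel([
            {"participant_id": "a", "wave": 0, "cvd": 1},
            {"participant_id": "a", "wave": 1, "cvd": 0},
            {"participant_id": "a", "wave": 2, "cvd": 0},
        ])
        out = carry_forward_diseases(panel)
        assert out["cvd"].tolist() == [1, 1, 1]


class TestSummaries:
    def test_percentages_sum_to_100_within_rounding(self, rng):
        panel = make_panel([
            {"participant_id": f"p{i}", "wave": 0,
             **{c: int(rng.random() < 0.3) for c in DISEASE_COLUMNS},
             "sex": rng.choice(["female", "male"])}
            for i in range(200)
        ])
        summary = summarize_cohort(panel)
        for (stratum, var), g in summary.dropna(subset=["pct"]).groupby(["stratum", "variable"]):
            assert g["pct"].sum() == pytest.approx(100.0, abs=0.05)
            n_in_stratum = (comorbidity_band(panel) == stratum).sum()
            assert g[g["variable"] == "sex"]["count"].sum() <= n_in_stratum

    def test_matches_brute_force_groupby(self, rng):
        panel = make_panel([
            {"participant_id": f"p{i}", "wave": 0,
             **{c: int(rng.random() < 0.4) for c in DISEASE_COLUMNS}}
            for i in range(300)
        ])
        summary = summarize_cohort(panel)
        band = comorbidity_band(panel)
        for stratum in band.cat.categories:
            expected_n = int((band == stratum).sum())
            got = summary[(summary["stratum"] == stratum) & (summary["variable"] == "n")]
            assert int(got["n"].iloc[0]) == expected_n

    def test_single_stratum_percentages_normalise(self):
        panel = make_panel([
            {"participant_id": f"p{i}", "wave": 0, "sex": s}
            for i, s in enumerate(["female"] * 3 + ["male"] * 7)
        ])
        dist = comorbidity_distribution(panel)
        assert dist["pct"].sum() == pytest.approx(100.0)
        assert dist.loc["0", "count"] == 10

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(make_panel([]))
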