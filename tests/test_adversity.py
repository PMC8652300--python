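import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdnfnet.adversity import (AdversityScore, PrenatalRecord, compute_adversity,
                               score_cohort, split_adversity_groups)


def record(benign, **overrides):
    return PrenatalRecord(**{**benign, **overrides})


class TestRubricBoundaries:
    def test_benign_record_scores_zero(self, benign_record_fields):
        s = compute_adversity(record(benign_record_fields))
        assert s.total == 0 and s.n_missing == 0

    @pytest.mark.parametrize("field,value,point", [
        ("gestational_age", 37.0, 1),    # <= 37 weeks: boundary counts
        ("gestational_age", 37.5, 0),
        ("cesd", 22.0, 0),               # "above 22" is strict
        ("cesd", 22.5, 1),
        ("money_hassles", 9.0, 0),       # "above 9" is strict
        ("money_hassles", 9.5, 1),
        ("stai", 1.95, 0),               # "above 1.95" is strict
        ("stai", 2.0, 1),
        ("marital_strain", 2.9, 0),      # "less than 2.9" is strict
        ("marital_strain", 2.8, 1),
        ("birth_percentile", 10.0, 0),   # strictly outside the 10th-90th band
        ("birth_percentile", 9.9, 1),
        ("birth_percentile", 90.0, 0),
        ("birth_percentile", 90.5, 1),
        ("income", 30_000.0, 0),         # "less than $30,000" is strict
        ("income", 29_999.0, 1),
        ("smoking", True, 1),
        ("abuse_present", True, 1),
    ])
    def test_single_indicator_boundary(self, benign_record_fields, field, value, point):
        s = compute_adversity(record(benign_record_fields, **{field: value}))
        assert s.total == point

    def test_any_health_condition_scores_one_point(self, benign_record_fields):
        one = compute_adversity(record(benign_record_fields,
                                       health_conditions=frozenset({"asthma"})))
        several = compute_adversity(record(
            benign_record_fields,
            health_conditions=frozenset({"diabetes", "hypertension", "bleeding"})))
        assert one.total == 1 and several.total == 1

    def test_worked_example_three_points(self, benign_record_fields):
        s = compute_adversity(record(benign_record_fields, smoking=True,
                                     income=25_000.0, cesd=25.0))
        assert s.total == 3


class TestMissingHandling:
    def test_missing_field_scores_zero_and_is_counted(self, benign_record_fields):
        s = compute_adversity(record(benign_record_fields, cesd=None))
        assert s.total == 0 and s.n_missing == 1

    def test_all_missing_is_an_error(self):
        rec = PrenatalRecord(health_known=False)
        with pytest.raises(ValueError, match="uninformative"):
            compute_adversity(rec)

    def test_total_bounded_by_ten_minus_missing(self, benign_record_fields):
        s = compute_adversity(record(benign_record_fields, stai=None, smoking=True))
        assert s.total <= 10 - s.n_missing


class TestMonotonicity:
    def test_crossing_any_threshold_never_decreases_total(self, benign_record_fields):
        worst = dict(money_hassles=15.0, cesd=30.0, stai=3.0, abuse_present=True,
                     marital_strain=1.0,
                     health_conditions=frozenset({"diabetes"}), smoking=True,
                     gestational_age=35.0, birth_percentile=5.0, income=10_000.0)
        base = compute_adversity(record(benign_record_fields)).total
        running = dict(benign_record_fields)
        for field, bad in worst.items():
            running[field] = bad
            new = compute_adversity(record(benign_record_fields, **{field: bad})).total
            assert new >= base
            base_cum = compute_adversity(PrenatalRecord(**running)).total
            assert 0 <= base_cum <= 10
        assert compute_adversity(PrenatalRecord(**worst)).total == 10


class TestScoreInvariants:
    @settings(derandomize=True, max_examples=60)
    @given(
        money=st.one_of(st.none(), st.floats(0, 30)),
        cesd=st.one_of(st.none(), st.floats(0, 60)),
        stai=st.one_of(st.none(), st.floats(1, 4)),
        strain=st.one_of(st.none(), st.floats(1, 4)),
        ga=st.one_of(st.none(), st.floats(25, 42)),
        pct=st.one_of(st.none(), st.floats(0, 100)),
        income=st.one_of(st.none(), st.floats(0, 200_000)),
        smoking=st.booleans(),
        abuse=st.booleans(),
    )
    def test_total_in_range_and_equals_indicator_sum(
            self, money, cesd, stai, strain, ga, pct, income, smoking, abuse):
        rec = PrenatalRecord(money_hassles=money, cesd=cesd, stai=stai,
                             abuse_present=abuse, marital_strain=strain,
                             smoking=smoking, gestational_age=ga,
                             birth_percentile=pct, income=income)
        s = compute_adversity(rec)
        assert 0 <= s.total <= 10
        assert s.total == sum(s.indicators.values())
        assert s.total <= 10 - s.n_missing


class TestCohortScoring:
    def test_validation_rejects_implausible_values(self):
        with pytest.raises(ValueError):
            PrenatalRecord(gestational_age=50)
        with pytest.raises(ValueError):
            PrenatalRecord(birth_percentile=101)

    def test_percentile_mode_flags_top_15_percent(self):
        n = 100
        tab = pd.DataFrame({
            "subject_id": range(n),
            "money_hassles": np.linspace(0, 8, n),  # all below absolute cut
            "cesd": np.linspace(0, 20, n),
            "stai": np.linspace(1.0, 1.9, n),
            "marital_strain": np.linspace(3.0, 4.0, n),
        })
        absolute = score_cohort(tab)
        relative = score_cohort(tab, percentile_mode=True)
        assert absolute["adversity"].sum() == 0
        # each scale flags roughly its top 15% under the percentile rule
        assert relative["ind_depression"].sum() == pytest.approx(15, abs=2)
        assert relative["ind_marital_strain"].sum() == pytest.approx(15, abs=2)


class TestGroupSplit:
    def test_worked_median_split(self):
        labels, rep = split_adversity_groups([0, 0, 1, 2, 2, 3])
        assert labels.tolist() == ["low", "low", "low", "high", "high", "high"]
        assert rep["n_low"] == 3 and rep["n_high"] == 3

    def test_distinct_scores_even_n_split_in_half(self):
        labels, rep = split_adversity_groups(np.arange(10))
        assert rep["n_low"] == 5 and rep["n_high"] == 5

    def test_47_distinct_scores_split_23_high_24_low(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal(47)
        labels, rep = split_adversity_groups(scores)
        assert (rep["n_low"], rep["n_high"]) == (24, 23)

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_adversity_groups([2, 2, 2])
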