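"""Family expansion/contraction: filtering, outlier replacement, scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbio.families import (
    DynamicsParams,
    FamilyCountMatrix,
    core_accessory,
    filter_families,
    replace_outliers,
    score_families,
)

GROUPS4 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


def fcm(rows: dict, groups=None) -> FamilyCountMatrix:
    groups = groups or GROUPS4
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))
    return FamilyCountMatrix(counts=df, groups=dict(groups))


class TestFilter:
    def test_taxon_specific_flagged(self):
        m = filter_families(fcm({"f": [0, 0, 0, 4]}))
        assert m.exclusions["f"] == "taxon_specific"

    def test_zero_group_median_flagged(self):
        g6 = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        m = filter_families(fcm({"f": [3, 3, 3, 0, 0, 1]}, g6))
        assert m.exclusions["f"] == "zero_group_median"

    def test_group_exclusive_flagged(self):
        m = filter_families(fcm({"f": [2, 3, 0, 0]}))
        assert m.exclusions["f"] == "group_exclusive"

    def test_balanced_family_retained(self):
        m = filter_families(fcm({"f": [2, 3, 2, 3]}))
        assert "f" not in m.exclusions

    def test_flagged_not_deleted(self):
        m = filter_families(fcm({"f": [0, 0, 0, 4], "g": [1, 1, 1, 1]}))
        assert list(m.counts.index) == ["f", "g"]
        assert list(m.included().index) == ["g"]

    def test_user_exclusion_list(self):
        m = filter_families(
            fcm({"f": [2, 3, 2, 3]}), extra_exclusions={"f": "expanded_in_naegleria"}
        )
        assert m.exclusions["f"] == "expanded_in_naegleria"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            filter_families(fcm({"f": [1, 1]}, groups={"a1": "A", "a2": "A"}))


class TestReplaceOutliers:
    G6 = {"a1": "A", "a2": "A", "a3": "A", "a4": "A", "b1": "B", "b2": "B"}

    def test_gross_outlier_replaced_by_group_median(self):
        # (2,2,2,100): population sd ~42.43, z(100) ~1.73 > 1.5 -> median 2
        m = replace_outliers(fcm({"f": [2, 2, 2, 100, 3, 3]}, self.G6))
        assert list(m.counts.loc["f", ["a1", "a2", "a3", "a4"]]) == [2, 2, 2, 2]
        assert list(m.counts.loc["f", ["b1", "b2"]]) == [3, 3]

    def test_mild_deviation_untouched(self):
        # (1,1,10): z(10) = 6/sqrt(18) ~1.41 < 1.5 -> unchanged
        g3 = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        m = replace_outliers(fcm({"f": [1, 1, 10, 2, 2]}, g3))
        assert list(m.counts.loc["f", ["a1", "a2", "a3"]]) == [1, 1, 10]

    def test_constant_vector_untouched(self):
        m = replace_outliers(fcm({"f": [5, 5, 5, 5, 1, 1]}, self.G6))
        assert list(m.counts.loc["f"]) == [5, 5, 5, 5, 1, 1]

    def test_single_member_group_warns(self):
        g = {"a1": "A", "a2": "A", "b1": "B"}
        with pytest.warns(UserWarning, match="single member"):
            m = replace_outliers(fcm({"f": [1, 1, 99]}, g))
        assert m.counts.loc["f", "b1"] == 99

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.2, size=(200, 6)),
            index=[f"F{i}" for i in range(200)],
            columns=list(self.G6),
        )
        m = FamilyCountMatrix(counts=counts, groups=self.G6)
        once = replace_outliers(m)
        twice = replace_outliers(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_idempotent_on_cascading_case(self):
        # (2,2,3,100): the first pass exposes 3 as a second-round outlier
        m = fcm({"f": [2, 2, 3, 100, 1, 1]}, self.G6)
        once = replace_outliers(m)
        twice = replace_outliers(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestScore:
    def test_worked_example_log2fc_3(self):
        # A (40,40) vs B (5,5): family median 22.5, group medians 40/22.5 and
        # 5/22.5 -> log2FC = 3 -> flagged at the 2.35 threshold
        scores = score_families(fcm({"f": [40, 40, 5, 5]}))
        row = scores.iloc[0]
        assert row.log2fc == pytest.approx(3.0)
        assert row.flag == "expanded"

    def test_identical_groups_zero(self):
        scores = score_families(fcm({"f": [7, 9, 7, 9]}))
        assert scores.iloc[0].log2fc == 0.0
        assert scores.iloc[0].flag == "none"

    def test_family_scale_invariance(self):
        s1 = score_families(fcm({"f": [4, 4, 1, 1]}))
        s2 = score_families(fcm({"f": [40, 40, 10, 10]}))
        assert s1.iloc[0].log2fc == s2.iloc[0].log2fc

    def test_antisymmetry_exact(self):
        m = fcm({"f": [40, 41, 5, 6], "g": [3, 5, 17, 19]})
        ab = score_families(m, group_pairs=[("A", "B")])
        ba = score_families(m, group_pairs=[("B", "A")])
        assert (ab["log2fc"].to_numpy() == -ba["log2fc"].to_numpy()).all()

    def test_contraction_flag(self):
        scores = score_families(fcm({"f": [1, 1, 40, 40]}))
        assert scores.iloc[0].flag == "contracted"

    def test_zero_median_reaching_scoring_is_internal_error(self):
        m = fcm({"f": [0, 0, 5, 5]})  # unfiltered on purpose
        with pytest.raises(RuntimeError, match="filter"):
            score_families(m)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.lists(st.integers(1, 50), min_size=2, max_size=4),
        b=st.lists(st.integers(1, 50), min_size=2, max_size=4),
        scale=st.integers(2, 20),
    )
    def test_scale_invariance_property(self, a, b, scale):
        groups = {f"a{i}": "A" for i in range(len(a))}
        groups.update({f"b{i}": "B" for i in range(len(b))})
        m1 = fcm({"f": a + b}, groups)
        m2 = fcm({"f": [x * scale for x in a + b]}, groups)
        s1, s2 = score_families(m1), score_families(m2)
        assert s1.iloc[0].log2fc == pytest.approx(s2.iloc[0].log2fc, abs=1e-12)


class TestCoreAccessory:
    def test_labels(self):
        m = fcm({"core": [1, 2, 1, 5], "acc": [0, 2, 1, 5]})
        labels = core_accessory(m)
        assert labels["core"] == "core"
        assert labels["acc"] == "accessory"

    def test_all_zero_warns_accessory(self):
        with pytest.warns(UserWarning, match="zero counts"):
            labels = core_accessory(fcm({"z": [0, 0, 0, 0]}))
        assert labels["z"] == "accessory"


class TestParams:
    def test_defaults_match_published_thresholds(self):
        p = DynamicsParams()
        assert p.z_threshold == 1.5
        assert p.log2fc_threshold == 2.35
        assert p.fold_equivalent == 5.0

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            DynamicsParams(z_threshold=0)
        with pytest.raises(ValueError):
            DynamicsParams(group_agg="mode")
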