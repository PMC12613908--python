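"""Scale scoring, composite risk and descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psynet.scales import DEFAULT_SCALE_MAP
from psynet.scoring import (
    ScaleScorer,
    composite_risk,
    descriptives,
    prevalence_pct,
    split_by_age,
)


def make_items(**overrides) -> pd.DataFrame:
    """One participant with every item at its scale minimum."""
    row = {}
    for scale in DEFAULT_SCALE_MAP.scales.values():
        for col in scale.items:
            row[col] = scale.item_range[0]
    row.update(overrides)
    return pd.DataFrame([row])


class TestScaleTotals:
    def test_phq_ceiling(self):
        df = make_items(**{f"PHQ{i}": 3 for i in range(1, 10)})
        totals = ScaleScorer().fit(df).scale_totals(df)
        assert totals.loc[0, "PHQ_total"] == 27

    def test_rses_ceiling_with_reverse_coding(self):
        # maximum self-esteem: positive items at 3, negative items at 0
        vals = {f"RSES{i}": 3 for i in range(1, 11)}
        for neg in ("RSES3", "RSES5", "RSES8", "RSES9", "RSES10"):
            vals[neg] = 0
        df = make_items(**vals)
        totals = ScaleScorer().fit(df).scale_totals(df)
        assert totals.loc[0, "RSES_total"] == 30

    @pytest.mark.parametrize("value,expected", [(1, 3), (3, 9)])
    def test_ucla_range(self, value, expected):
        df = make_items(**{f"UCLA{i}": value for i in (1, 2, 3)})
        totals = ScaleScorer().fit(df).scale_totals(df)
        assert totals.loc[0, "UCLA_total"] == expected

    def test_mspss_subscale_is_item_mean(self):
        df = make_items(MSPSS3=7, MSPSS4=7, MSPSS8=7, MSPSS11=7)
        totals = ScaleScorer().fit(df).scale_totals(df)
        assert totals.loc[0, "MSPSS_FAM"] == 7.0

    def test_soi_reverse_codes_item6(self):
        # SOI6 is reverse-keyed: raw 1 counts as 5 on the aligned scale
        df = make_items(SOI4=5, SOI5=5, SOI6=1)
        totals = ScaleScorer().fit(df).scale_totals(df)
        assert totals.loc[0, "SOI_ATT"] == 5.0

    def test_soi_sum_is_affine_in_mean(self):
        df = make_items(SOI7=2, SOI8=4, SOI9=3)
        t_mean = ScaleScorer(soi_score="mean").fit(df).scale_totals(df)
        t_sum = ScaleScorer(soi_score="sum").fit(df).scale_totals(df)
        assert t_sum.loc[0, "SOI_DES"] == 3 * t_mean.loc[0, "SOI_DES"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=9, max_size=9))
    def test_phq_scoring_is_linear(self, base):
        df0 = make_items(**{f"PHQ{i+1}": v for i, v in enumerate(base)})
        df1 = make_items(**{f"PHQ{i+1}": v + 1 for i, v in enumerate(base)})
        scorer = ScaleScorer().fit(df0)
        assert (
            scorer.scale_totals(df1).loc[0, "PHQ_total"]
            == scorer.scale_totals(df0).loc[0, "PHQ_total"] + 9
        )


class TestNodeMatrix:
    def test_has_37_nodes(self, default_nodes):
        assert default_nodes.shape[1] == 37

    def test_item_polarity_alignment_flips_negative_items(self):
        df = make_items(RSES10=3)  # "no good" endorsed fully
        aligned = ScaleScorer(item_polarity="aligned").fit(df).transform(df)
        raw = ScaleScorer(item_polarity="raw").fit(df).transform(df)
        assert aligned.loc[0, "RSES10"] == 0  # low self-esteem on aligned scale
        assert raw.loc[0, "RSES10"] == 3

    def test_missing_values_rejected(self):
        df = make_items()
        df.loc[0, "GAD3"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ScaleScorer().fit(df).transform(df)


class TestCompositeRisk:
    @pytest.mark.parametrize(
        "c,m,score,uai,msp",
        [
            (4, 5, 9, True, True),
            (1, 1, 2, False, False),
            (2, 3, 5, False, True),  # MSP boundary: 2-3 partners
            (3, 2, 5, True, False),  # UAI boundary: sometimes used condoms
        ],
    )
    def test_examples(self, c, m, score, uai, msp):
        df = pd.DataFrame({"condom_use": [c], "partner_count": [m]})
        out = composite_risk(df)
        assert out.loc[0, "risk_score"] == score
        assert out.loc[0, "uai"] == uai
        assert out.loc[0, "msp"] == msp

    def test_monotone_in_each_code(self):
        grid = pd.DataFrame(
            [(c, m) for c in range(1, 5) for m in range(1, 6)],
            columns=["condom_use", "partner_count"],
        )
        s = composite_risk(grid)["risk_score"].to_numpy().reshape(4, 5)
        assert (np.diff(s, axis=0) > 0).all() and (np.diff(s, axis=1) > 0).all()

    def test_out_of_range_code_rejected(self):
        df = pd.DataFrame({"condom_use": [5], "partner_count": [1]})
        with pytest.raises(ValueError, match="condom"):
            composite_risk(df)


class TestAgeSplit:
    def test_boundary_belongs_to_older_group(self):
        young, old = split_by_age([32, 33, 34])
        assert young.tolist() == [True, False, False]
        assert old.tolist() == [False, True, True]

    def test_degenerate_split_warns(self):
        with pytest.warns(UserWarning, match="empty group"):
            split_by_age([20, 21, 22])


class TestDescriptives:
    def test_prevalence_percentages(self):
        # 50/405 is 12.3457% -> 12.3 at one decimal (the source table's
        # 12.4 does not follow from 50/405 under any rounding rule)
        assert prevalence_pct(50, 405) == 12.3
        assert prevalence_pct(41, 405) == 10.1
        assert prevalence_pct(27, 405) == 6.7
        assert prevalence_pct(269, 405) == 66.4

    def test_group_sizes_sum_to_total(self, default_sim):
        rep = descriptives(default_sim.cohort)
        assert rep["n"]["young"] + rep["n"]["old"] == rep["n"]["total"]

    def test_categorical_percentages_sum_to_100(self, default_sim):
        rep = descriptives(default_sim.cohort)
        for var in rep["categorical"].values():
            for g in var["counts"].values():
                assert sum(c["pct"] for c in g.values()) == pytest.approx(100, abs=0.2)

    def test_group_mean_shift_detected(self, default_sim):
        # planting a 1-SD depression shift in the older group must give
        # an overwhelming two-sample t-test at n ~ 200/group
        df = default_sim.cohort.copy()
        old = df["age"] >= 33
        for i in range(1, 10):
            df.loc[old, f"PHQ{i}"] = np.minimum(df.loc[old, f"PHQ{i}"] + 1, 3)
        rep = descriptives(df)
        assert rep["continuous"]["PHQ_total"]["p"] < 1e-3
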