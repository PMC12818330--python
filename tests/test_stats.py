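"""Closed-form risk ratios, MH heterogeneity, chi-squared, stratified tables."""

import math

import numpy as np
import pandas as pd
import pytest

from rtiepi.stats import (TwoByTwo, UndefinedRRError,
                          mh_heterogeneity, mh_pooled_rr, pearson_chi2,
                          risk_ratio, round_half_away, stratified_rr_table,
                          two_by_two_from_printed)


class TestRiskRatio:
    def test_closed_form_example(self):
        # pre: 10/50 = 0.2; pandemic: 10/100 = 0.1 -> RR 0.5
        r = risk_ratio(TwoByTwo(n_pre=50, x_pre=10, n_pand=100, x_pand=10))
        assert r.rr == pytest.approx(0.5)
        se = math.sqrt((1 - 0.1) / 10 + (1 - 0.2) / 10)
        assert r.log_se == pytest.approx(se)
        assert r.ci_low == pytest.approx(0.5 * math.exp(-1.96 * se))
        assert r.ci_high == pytest.approx(0.5 * math.exp(1.96 * se))

    def test_equal_risks_give_unity(self):
        r = risk_ratio(TwoByTwo(200, 50, 400, 100))
        assert r.rr == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_zero_treated_cell_is_error(self):
        with pytest.raises(UndefinedRRError):
            risk_ratio(TwoByTwo(50, 0, 100, 10))
        with pytest.raises(UndefinedRRError):
            risk_ratio(TwoByTwo(50, 10, 0, 0))

    def test_scale_invariance_shrinks_ci(self):
        t1 = TwoByTwo(50, 10, 100, 10)
        t10 = TwoByTwo(500, 100, 1000, 100)
        r1, r10 = risk_ratio(t1), risk_ratio(t10)
        assert r1.rr == pytest.approx(r10.rr)
        assert (r10.ci_high - r10.ci_low) < (r1.ci_high - r1.ci_low)

    def test_period_swap_inverts(self):
        t = TwoByTwo(50, 10, 100, 15)
        swapped = TwoByTwo(100, 15, 50, 10)
        r, rs = risk_ratio(t), risk_ratio(swapped)
        assert rs.rr == pytest.approx(1 / r.rr)
        assert rs.ci_low == pytest.approx(1 / r.ci_high)
        assert rs.ci_high == pytest.approx(1 / r.ci_low)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            TwoByTwo(10, 11, 5, 1)


def test_round_half_away():
    assert round_half_away(0.515, 2) == 0.52
    assert round_half_away(2.5) == 3.0
    assert round_half_away(-2.5) == -3.0
    assert round_half_away(26.05, 1) == 26.1


def test_two_by_two_from_printed_reconstruction():
    t = two_by_two_from_printed(2_024_067, 26.1, 1_845_645, 13.5)
    assert t.x_pre == 528_281  # round(2024067 * 0.261)
    assert t.x_pand == 249_162


class TestHeterogeneity:
    def test_identical_risks_give_zero_statistic(self):
        strata = [TwoByTwo(100, 20, 100, 10), TwoByTwo(200, 40, 200, 20)]
        h = mh_heterogeneity(strata)
        assert h.statistic == pytest.approx(0.0, abs=1e-12)
        assert h.p_value == pytest.approx(1.0)
        assert h.df == 1

    def test_stratum_order_invariance(self):
        strata = [TwoByTwo(120, 30, 110, 12), TwoByTwo(300, 60, 280, 40),
                  TwoByTwo(90, 25, 95, 20)]
        h1 = mh_heterogeneity(strata)
        h2 = mh_heterogeneity(strata[::-1])
        assert h1.statistic == pytest.approx(h2.statistic)
        assert h1.p_value == pytest.approx(h2.p_value)

    def test_undefined_stratum_reported(self):
        with pytest.raises(UndefinedRRError, match="1"):
            mh_heterogeneity([TwoByTwo(100, 20, 100, 10), TwoByTwo(50, 0, 50, 5)])

    def test_needs_two_strata(self):
        with pytest.raises(ValueError):
            mh_heterogeneity([TwoByTwo(100, 20, 100, 10)])

    def test_pooled_rr_matches_single_stratum(self):
        t = TwoByTwo(100, 20, 200, 30)
        assert mh_pooled_rr([t]) == pytest.approx(risk_ratio(t).rr)


class TestPearsonChi2:
    def test_independent_table_gives_zero(self):
        stat, df, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_direct_arithmetic(self):
        obs = np.array([[20, 10], [10, 20]])
        stat, df, p = pearson_chi2(obs)
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2([[0, 0], [10, 20]])


def _episode_frame(n_pre, x_pre, n_pand, x_pand, **labels):
    base = {"age_group": "25-34", "service_label": "DGP", "mode_label": "in_person",
            "count_class": "one", "contains_covid_code": False, "all_covid": False}
    base.update(labels)
    rows = []
    for period, n, x in (("pre", n_pre, x_pre), ("pandemic", n_pand, x_pand)):
        for i in range(n):
            rows.append({"period": period, "treated": i < x, **base})
    return pd.DataFrame(rows)


class TestStratifiedTable:
    def test_single_stratum_reduces_to_risk_ratio(self):
        df = _episode_frame(50, 10, 100, 10)
        table = stratified_rr_table(df, "age_group")
        row = table.loc["25-34"]
        direct = risk_ratio(TwoByTwo(50, 10, 100, 10))
        assert row["rr"] == pytest.approx(direct.rr)
        assert table.loc["Total", "rr"] == pytest.approx(direct.rr)

    def test_empty_strata_emitted_blank(self):
        df = _episode_frame(50, 10, 100, 10)
        table = stratified_rr_table(df, "age_group")
        assert len(table) == 11  # 10 bands + total
        assert np.isnan(table.loc["0-4", "rr"])

    def test_neither_period_episodes_ignored(self):
        df = _episode_frame(50, 10, 100, 10)
        extra = df.iloc[:5].assign(period="neither")
        table = stratified_rr_table(pd.concat([df, extra]), "age_group")
        assert table.loc["Total", "n_pre"] == 50

    def test_covid_filter_modes(self):
        df = _episode_frame(50, 10, 100, 10)
        covid = _episode_frame(10, 1, 20, 2, contains_covid_code=True)
        covid_only = covid.copy()
        covid_only["all_covid"] = True
        both = pd.concat([df, covid_only], ignore_index=True)
        t_off = stratified_rr_table(both, "age_group", covid_filter="off")
        t_any = stratified_rr_table(both, "age_group", covid_filter="any")
        t_all = stratified_rr_table(both, "age_group", covid_filter="all")
        assert t_off.loc["Total", "n_pre"] == 60
        assert t_any.loc["Total", "n_pre"] == 50
        assert t_all.loc["Total", "n_pre"] == 50
        mixed_covid = pd.concat([df, covid], ignore_index=True)  # all_covid False
        t_all2 = stratified_rr_table(mixed_covid, "age_group", covid_filter="all")
        assert t_all2.loc["Total", "n_pre"] == 60

    def test_heterogeneity_attached_for_multiple_strata(self):
        a = _episode_frame(100, 30, 100, 10, age_group="0-4")
        b = _episode_frame(200, 30, 200, 25, age_group="5-14")
        table = stratified_rr_table(pd.concat([a, b], ignore_index=True), "age_group")
        assert "heterogeneity_p" in table.attrs
        assert 0 <= table.attrs["heterogeneity_p"] <= 1
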