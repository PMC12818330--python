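"""Episode construction: chain rule, labelling, trimming, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from rtiepi.episodes import (LabelError, assign_period, build_episodes,
                             flag_rti_consultations, label_episodes,
                             trim_boundary_months)
from conftest import make_consultations, make_persons

BASE = pd.Timestamp("2019-01-01")


def consults_at(days, patient="P1", service="DGP", mode="2ad", diag="R74"):
    rows = [(patient, BASE + pd.Timedelta(days=d), service, mode, diag) for d in days]
    df = make_consultations(rows)
    df["is_covid_specific"] = False
    df["has_noncovid_rti"] = True
    df["mode"] = "in_person"
    return df


def oracle_components(dates, window=30):
    """Independent oracle: connected components of the <=window-day link graph."""
    d = np.asarray(dates)
    adj = np.abs(d[:, None] - d[None, :]) <= window
    n, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


class TestChainRule:
    @pytest.mark.parametrize("days,expected_sizes", [
        ([0, 20, 45], [3]),       # 45-20=25 chains through the follow-up
        ([0, 31], [1, 1]),        # gap 31 > 30 starts a new episode
        ([0, 30], [2]),           # gap of exactly 30 days chains (inclusive)
        ([0], [1]),
        ([0, 0, 10], [3]),        # same-day repeats stay in one episode
    ])
    def test_examples(self, days, expected_sizes):
        episodes, cmap = build_episodes(consults_at(days))
        assert sorted(episodes["n_consultations"].tolist()) == sorted(expected_sizes)

    def test_empty_input(self):
        episodes, cmap = build_episodes(consults_at([]).iloc[0:0])
        assert len(episodes) == 0 and len(cmap) == 0

    def test_gap_between_consecutive_episodes_exceeds_window(self):
        days = [0, 10, 45, 50, 95]
        episodes, _ = build_episodes(consults_at(days))
        ep = episodes.sort_values("index_date")
        gaps = (ep["index_date"].values[1:] - ep["last_date"].values[:-1]
                ).astype("timedelta64[D]").astype(int)
        assert (gaps > 30).all()

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(min_value=0, max_value=400), min_size=1, max_size=40))
    def test_matches_transitive_chaining_oracle(self, days):
        df = consults_at(days)
        episodes, cmap = build_episodes(df)
        got = cmap.sort_values("date")["episode_id"].values
        want = oracle_components(sorted(days))
        # same partition: equal label boundaries
        assert len(set(got)) == len(set(want))
        remap = {}
        for g, w in zip(got, want):
            assert remap.setdefault(g, w) == w

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=25),
           st.randoms(use_true_random=False))
    def test_order_independence(self, days, rnd):
        df = consults_at(days)
        shuffled = df.sample(frac=1.0, random_state=rnd.randint(0, 10**6))
        e1, _ = build_episodes(df)
        e2, _ = build_episodes(shuffled)
        cols = ["index_date", "last_date", "n_consultations"]
        pd.testing.assert_frame_equal(
            e1[cols].sort_values(cols).reset_index(drop=True),
            e2[cols].sort_values(cols).reset_index(drop=True))

    def test_partition_invariant_multi_patient(self):
        rng = np.random.default_rng(5)
        frames = [consults_at(sorted(rng.integers(0, 300, size=rng.integers(1, 20))),
                              patient=f"P{i}") for i in range(30)]
        df = pd.concat(frames, ignore_index=True)
        episodes, cmap = build_episodes(df)
        assert episodes["n_consultations"].sum() == len(df)
        assert cmap.groupby("episode_id").size().sum() == len(df)
        # each consultation in exactly one episode
        assert cmap["episode_id"].notna().all()


class TestFlagging:
    def test_rti_code_retained_non_rti_dropped(self, codelist):
        df = make_consultations([
            ("P1", "2020-01-05", "DGP", "2ad", "R74"),
            ("P2", "2020-01-06", "DGP", "2ad", "K86"),
            ("P3", "2020-01-07", "DGP", "2ad", "R83;R991"),
        ])
        rti, rejected = flag_rti_consultations(df, codelist)
        assert rti["patient_id"].tolist() == ["P1", "P3"]
        assert rti["is_covid_specific"].tolist() == [False, True]

    def test_mode_derivation(self, codelist):
        df = make_consultations([
            ("P1", "2020-01-05", "DGP", "2ae", "R74"),       # all electronic
            ("P2", "2020-01-06", "DGP", "2ad;2ae", "R74"),   # mixed claim -> in person
            ("P3", "2020-01-07", "DGP", "2ad", "R74"),
        ])
        rti, _ = flag_rti_consultations(df, codelist)
        assert rti["mode"].tolist() == ["electronic", "in_person", "in_person"]

    def test_unknown_procedure_code_policy(self, codelist):
        df = make_consultations([("P1", "2020-01-05", "DGP", "9zz", "R74")])
        rti, rejected = flag_rti_consultations(df, codelist)
        assert len(rti) == 0 and len(rejected) == 1
        lenient = codelist.__class__(unknown_procedure_policy="in_person")
        rti, rejected = flag_rti_consultations(df, lenient)
        assert rti["mode"].tolist() == ["in_person"] and len(rejected) == 0


class TestLabels:
    def test_service_and_mode_labels(self, perioddef):
        df = consults_at([0, 5])
        df.loc[1, "service_type"] = "OOH"
        episodes, _ = build_episodes(df)
        episodes = label_episodes(episodes, make_persons(["P1"]), perioddef)
        assert episodes["service_label"].tolist() == ["mixed"]
        assert episodes["mode_label"].tolist() == ["in_person"]
        assert episodes["count_class"].tolist() == ["two_plus"]

    @pytest.mark.parametrize("day,expected", [
        ("2020-03-12", "pandemic"), ("2021-11-30", "pandemic"),
        ("2019-12-15", "neither"), ("2018-03-12", "pre"),
        ("2019-11-30", "pre"), ("2020-03-11", "neither"),
    ])
    def test_period_assignment(self, day, expected, perioddef):
        s = pd.Series([pd.Timestamp(day)])
        assert assign_period(s, perioddef).tolist() == [expected]

    def test_age_group_at_index_date(self, perioddef):
        df = consults_at([0])
        episodes, _ = build_episodes(df)
        # born 2014-01-02: still 4 years old on 2019-01-01
        persons = make_persons(["P1"], birth="2014-01-02")
        labelled = label_episodes(episodes, persons, perioddef)
        assert labelled["age_group"].tolist() == ["0-4"]
        persons = make_persons(["P1"], birth="2014-01-01")  # 5 on index day
        labelled = label_episodes(episodes, persons, perioddef)
        assert labelled["age_group"].tolist() == ["5-14"]

    def test_unknown_patient_raises(self, perioddef):
        episodes, _ = build_episodes(consults_at([0]))
        with pytest.raises(LabelError, match="P1"):
            label_episodes(episodes, make_persons(["P9"]), perioddef)


class TestTrim:
    def test_boundary_months_removed(self, perioddef):
        df = make_consultations([
            ("P1", "2018-01-15", "DGP", "2ad", "R74"),
            ("P2", "2018-02-01", "DGP", "2ad", "R74"),
            ("P3", "2021-12-31", "DGP", "2ad", "R74"),
        ])
        out = trim_boundary_months(df, perioddef)
        assert out["patient_id"].tolist() == ["P2"]
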