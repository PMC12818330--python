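"""Synthetic registry generator: determinism, rate structure, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rtiepi import ScenarioConfig, default_codelist
from rtiepi.episodes import build_episodes, flag_rti_consultations, label_episodes
from rtiepi.linkage import link_treatments
from rtiepi.simulate import (NOISE_ATC, generate_consultations,
                             generate_dispensings, generate_population,
                             scenario_truth, simulate_registry)


class TestPopulation:
    def test_empty_population(self):
        persons = generate_population(ScenarioConfig(n_persons=0))
        assert len(persons) == 0

    def test_degenerate_age_mix_puts_everyone_in_band(self):
        cfg = ScenarioConfig(n_persons=1000, seed=1,
                             age_mix=(1.0,) + (0.0,) * 9)
        persons = generate_population(cfg)
        ages = (pd.Timestamp(cfg.date_start) - persons["birth_date"]).dt.days
        assert (ages < 5 * 365.25).all() and (ages >= 0).all()

    def test_unique_ids_and_sex_balance(self):
        persons = generate_population(ScenarioConfig(n_persons=4000, seed=2))
        assert persons["patient_id"].is_unique
        frac_male = (persons["sex"] == "male").mean()
        assert abs(frac_male - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_determinism(self):
        cfg = ScenarioConfig(n_persons=2000, seed=1)
        pd.testing.assert_frame_equal(generate_population(cfg),
                                      generate_population(cfg))


class TestConsultations:
    def test_flat_rate_limit_monthly_counts_uniform(self):
        cfg = ScenarioConfig(n_persons=50_000, seed=4, seasonal_amplitude=0.0,
                             spike_multiplier=1.0, suppression_multiplier=1.0,
                             p_followup=0.0, death_rate_per_year=0.0)
        persons = generate_population(cfg)
        cons = generate_consultations(persons, cfg)
        months = cons["date"].dt.to_period("M")
        counts = months.value_counts().sort_index()
        days = counts.index.days_in_month.values
        expected = counts.sum() * days / days.sum()
        stat = ((counts.values - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(stat, len(counts) - 1)
        assert p > 0.01

    def test_spike_multiplier_realized(self):
        cfg = ScenarioConfig(n_persons=30_000, seed=5, seasonal_amplitude=0.0,
                             spike_multiplier=3.0, spike_days=30,
                             suppression_multiplier=1.0, p_followup=0.0,
                             death_rate_per_year=0.0)
        persons = generate_population(cfg)
        cons = generate_consultations(persons, cfg)
        pstart = pd.Timestamp(cfg.pandemic_start)
        pre = cons.loc[cons["date"] < pstart]
        spike = cons.loc[(cons["date"] >= pstart) &
                         (cons["date"] < pstart + pd.Timedelta(days=30))]
        pre_days = (pstart - pd.Timestamp(cfg.date_start)).days
        pre_daily = len(pre) / pre_days
        spike_daily = len(spike) / 30
        se = np.sqrt(len(spike) / 30**2 + 9 * len(pre) / pre_days**2)
        assert abs(spike_daily - 3.0 * pre_daily) < 3 * se

    def test_no_followups_means_all_index(self):
        cfg = ScenarioConfig(n_persons=5000, seed=6, p_followup=0.0)
        persons = generate_population(cfg)
        cons = generate_consultations(persons, cfg)
        assert cons["is_index"].all()

    def test_followups_within_30_days_of_parent(self):
        cfg = ScenarioConfig(n_persons=3000, seed=7, p_followup=0.5)
        persons = generate_population(cfg)
        cons = generate_consultations(persons, cfg)
        # brute-force: every follow-up has some same-person consultation
        # 1-30 days before it
        follows = cons.loc[~cons["is_index"]]
        by_patient = {p: g["date"].values for p, g in cons.groupby("patient_id")}
        for _, row in follows.head(300).iterrows():
            dates = by_patient[row["patient_id"]]
            gaps = (row["date"].to_datetime64() - dates).astype(
                "timedelta64[D]").astype(int)
            assert ((gaps >= 1) & (gaps <= 30)).any()

    def test_events_bounded_by_window_and_death(self):
        cfg = ScenarioConfig(n_persons=4000, seed=8, death_rate_per_year=0.1)
        persons, cons, disp, _ = simulate_registry(cfg)
        start, end = pd.Timestamp(cfg.date_start), pd.Timestamp(cfg.date_end)
        for df in (cons, disp):
            assert (df["date"] >= start).all() and (df["date"] <= end).all()
            death = df["patient_id"].map(persons.set_index("patient_id")["death_date"])
            alive = death.isna() | (df["date"] <= death)
            assert alive.all()

    def test_missing_person_columns_is_schema_error(self):
        from rtiepi.io import SchemaError
        cfg = ScenarioConfig(n_persons=10)
        with pytest.raises(SchemaError, match="birth_date"):
            generate_consultations(pd.DataFrame({"patient_id": ["P1"]}), cfg)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = ScenarioConfig(n_persons=2000, seed=9)
        persons = generate_population(cfg)
        a = generate_consultations(persons, cfg)
        b = generate_consultations(persons, cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()


class TestDispensings:
    def test_zero_propensity_emits_only_noise(self):
        cfg = ScenarioConfig(n_persons=3000, seed=10, p_treat_pre=0.0,
                             p_treat_pandemic=0.0)
        persons = generate_population(cfg)
        cons = generate_consultations(persons, cfg)
        disp = generate_dispensings(cons, cfg, persons)
        assert disp["atc_code"].isin(NOISE_ATC).all()

    def test_degenerate_type_mix_all_phenoxymethylpenicillin(self):
        mix = {"azithromycin": 0.0, "other_macrolides": 0.0,
               "phenoxymethylpenicillin": 1.0, "other_penicillins": 0.0,
               "tetracyclines": 0.0, "other": 0.0}
        cfg = ScenarioConfig(n_persons=2000, seed=11, type_mix=mix,
                             noise_dispensing_rate=0.0)
        persons = generate_population(cfg)
        cons = generate_consultations(persons, cfg)
        disp = generate_dispensings(cons, cfg, persons)
        assert (disp["atc_code"] == "J01CE01").all() and len(disp) > 0

    def test_zero_lag_no_noise_linkage_recovers_emitted_fraction(self, perioddef):
        """With all dispensings on the consultation day and no noise, the
        linked treated-episode count equals the emitted treatment count at
        episode level exactly."""
        cfg = ScenarioConfig(n_persons=4000, seed=12, delay_mix={0: 1.0},
                             noise_dispensing_rate=0.0, p_followup=0.0,
                             death_rate_per_year=0.0)
        persons, cons, disp, _ = simulate_registry(cfg)
        codelist = default_codelist()
        rti, _ = flag_rti_consultations(cons.drop(columns=["is_index"]), codelist)
        episodes, cmap = build_episodes(rti)
        episodes = label_episodes(episodes, persons, perioddef)
        episodes, links = link_treatments(episodes, cmap, disp, codelist)
        assert len(links) == len(disp)  # every emitted treatment links
        # episodes with >=1 emitted treatment == treated episodes
        emitted = disp.merge(cmap, on=["patient_id", "date"], how="left")
        assert emitted["episode_id"].notna().all()
        assert int(episodes["treated"].sum()) == emitted["episode_id"].nunique()


class TestTruth:
    def test_true_rr_is_propensity_ratio(self):
        cfg = ScenarioConfig(n_persons=100, p_treat_pre=0.26,
                             p_treat_pandemic=0.135, seed=0)
        persons, cons, disp, truth = simulate_registry(cfg)
        assert truth.true_rr == pytest.approx(0.135 / 0.26)
        assert truth.true_rr == pytest.approx(0.519, abs=5e-4)

    def test_equal_propensities_give_unit_rr(self):
        cfg = ScenarioConfig(n_persons=10, p_treat_pre=0.2, p_treat_pandemic=0.2)
        truth = scenario_truth(cfg, generate_consultations(
            generate_population(cfg), cfg))
        assert truth.true_rr == pytest.approx(1.0)

    def test_empty_tables_give_zero_counts(self):
        cfg = ScenarioConfig(n_persons=0)
        persons, cons, disp, truth = simulate_registry(cfg)
        assert truth.n_episodes_pre == 0 and truth.n_episodes_pandemic == 0
        assert truth.n_episodes_total == 0
        assert truth.monthly_index_counts == {}

    def test_realized_counts_match_emitted_index_consultations(self, small_registry,
                                                               perioddef):
        _, cons, _, truth = small_registry
        idx = cons.loc[cons["is_index"], "date"]
        pre = ((idx >= pd.Timestamp(perioddef.pre_start)) &
               (idx <= pd.Timestamp(perioddef.pre_end))).sum()
        assert truth.n_episodes_pre == pre
        assert truth.n_episodes_total == cons["is_index"].sum()
        assert sum(truth.monthly_index_counts.values()) == truth.n_episodes_total
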