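"""Synthetic primary-care registry generator.

Emulates the joint structure of the linked Norwegian registries the analysis
expects: a person table with demographics and deaths, per-person consultation
streams with winter-peaking seasonality, a consultation spike immediately
after the pandemic start followed by suppression, a pandemic shift from
in-person to electronic consultations, per-episode antibiotic-treatment
propensities that drop in the pandemic period, and dispensing dates lagged
0 days to beyond a week after the consultation (so some true treatments fall
outside the 7-day linkage window). A ground-truth sidecar supports
parameter-recovery tests.

Index consultations arise from an inhomogeneous Poisson process with daily
rate

    lambda(d) = baseline/30.4375 * (1 + A*cos(2*pi*(doy(d)-peak)/365.25)) * m(d)

where m(d) is the spike multiplier for ``spike_days`` after the pandemic
start, the suppression multiplier thereafter, and 1 before. Each
consultation spawns a follow-up 1-30 days later with probability
``p_followup`` (a geometric chain, uncapped). Treatment propensity attaches
to the index consultation, so episode-level treated fractions match the
configured propensities. All output is deterministic given the scenario
seed; no event is dated outside the study window or after its person's
death.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AGE_EDGES, PeriodDefinition, ScenarioConfig
from .io import SchemaError

__all__ = [
    "ScenarioTruth",
    "generate_population", "generate_consultations", "generate_dispensings",
    "scenario_truth", "simulate_registry",
]

DAYS_PER_MONTH = 30.4375

#: representative full ATC code per simulated antibiotic class
CLASS_ATC = {
    "azithromycin": "J01FA10",
    "other_macrolides": "J01FA01",       # erythromycin
    "phenoxymethylpenicillin": "J01CE01",
    "other_penicillins": "J01CA04",      # amoxicillin
    "tetracyclines": "J01AA02",          # doxycycline
    "other": "J01EE01",                  # sulfamethoxazole-trimethoprim
}

#: urinary-tract agents used as unrelated noise dispensings
NOISE_ATC = ("J01EA01", "J01XE01", "J01CA08")

_BASE_RTI_CODE = "R74"
_COVID_CODE = "R991"


def _rng(config: ScenarioConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


@dataclass
class ScenarioTruth:
    """Ground truth of one scenario realisation, for recovery assertions."""

    true_rr: float
    n_episodes_pre: int
    n_episodes_pandemic: int
    n_episodes_total: int
    monthly_index_counts: dict[str, int]

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the person table.

    Ages at the study start follow ``age_mix`` over the ten bands (the open
    top band is truncated at 100 years); sex is an even coin; a small
    constant mortality hazard places optional death dates inside the window;
    residency spans the whole study window.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_persons
    start = pd.Timestamp(config.date_start)
    end = pd.Timestamp(config.date_end)
    window_days = (end - start).days + 1

    band = rng.choice(len(config.age_mix), size=n, p=list(config.age_mix))
    edges = np.array(list(AGE_EDGES) + [100], dtype=float) * 365.25
    lo, hi = edges[band], edges[band + 1]
    age_days = lo + rng.random(n) * (hi - lo)
    birth = start - pd.to_timedelta(np.floor(age_days), unit="D")

    sex = np.where(rng.random(n) < 0.5, "male", "female")

    p_death = 1.0 - np.exp(-config.death_rate_per_year * window_days / 365.25)
    dies = rng.random(n) < p_death
    death_offset = rng.integers(0, window_days, size=n)
    death = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death[dies] = start + pd.to_timedelta(death_offset[dies], unit="D")

    return pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "birth_date": pd.Series(birth, dtype="datetime64[ns]"),
        "sex": sex,
        "death_date": death,
        "residency_start": pd.Series([start] * n, dtype="datetime64[ns]"),
        "residency_end": pd.Series([pd.NaT] * n, dtype="datetime64[ns]"),
    })


def _daily_rate(config: ScenarioConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    dates = pd.date_range(config.date_start, config.date_end, freq="D")
    doy = dates.dayofyear.values
    peak_doy = (config.seasonal_peak_month - 1) * DAYS_PER_MONTH + 15
    seasonal = 1.0 + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - peak_doy) / 365.25)
    pstart = pd.Timestamp(config.pandemic_start)
    spike_end = pstart + pd.Timedelta(days=config.spike_days)
    mult = np.ones(len(dates))
    mult[(dates >= pstart) & (dates < spike_end)] = config.spike_multiplier
    mult[dates >= spike_end] = config.suppression_multiplier
    lam = config.baseline_monthly_rti_rate / DAYS_PER_MONTH * seasonal * mult
    return dates, lam


def generate_consultations(persons: pd.DataFrame,
                           config: ScenarioConfig) -> pd.DataFrame:
    """Generate the consultation table from a person table.

    Index consultations are drawn day by day at the population level and
    assigned to random persons (consultations landing after a person's death
    are discarded, which thins the process to the per-alive-person rate).
    Output carries an ``is_index`` column distinguishing index consultations
    from follow-ups; the analysis never uses it, the dispensing generator and
    truth sidecar do.
    """
    config.validate()
    required = {"patient_id", "birth_date", "death_date"}
    missing = required - set(persons.columns)
    if missing:
        raise SchemaError(f"person table missing column(s): {sorted(missing)}")
    rng = _rng(config, 1)
    n = len(persons)
    empty = pd.DataFrame({
        "patient_id": pd.Series(dtype=str),
        "date": pd.Series(dtype="datetime64[ns]"),
        "service_type": pd.Series(dtype=str),
        "mode_codes": pd.Series(dtype=str),
        "diagnosis_codes": pd.Series(dtype=str),
        "is_index": pd.Series(dtype=bool),
    })
    if n == 0:
        return empty

    dates, lam = _daily_rate(config)
    counts = rng.poisson(n * lam)
    k = int(counts.sum())
    if k == 0:
        return empty
    day_idx = np.repeat(np.arange(len(dates)), counts)
    person_idx = rng.integers(0, n, size=k)

    df = pd.DataFrame({
        "person_idx": person_idx,
        "date": dates.values[day_idx],
        "is_index": True,
    })

    # geometric follow-up chains, 1-30 days after the previous consultation
    frontier = df
    chains = [df]
    end = pd.Timestamp(config.date_end)
    while len(frontier):
        follow = frontier.loc[rng.random(len(frontier)) < config.p_followup].copy()
        if not len(follow):
            break
        follow["date"] = follow["date"] + pd.to_timedelta(
            rng.integers(1, 31, size=len(follow)), unit="D")
        follow = follow.loc[follow["date"] <= end]
        follow["is_index"] = False
        chains.append(follow)
        frontier = follow
    df = pd.concat(chains, ignore_index=True)

    death = persons["death_date"].values[df["person_idx"].values]
    alive = pd.isna(death) | (df["date"].values <= death)
    df = df.loc[alive].reset_index(drop=True)
    m = len(df)
    if m == 0:
        return empty

    pandemic = df["date"] >= pd.Timestamp(config.pandemic_start)
    service = np.where(rng.random(m) < config.p_ooh, "OOH", "DGP")
    p_elec = np.where(pandemic, config.p_electronic_pandemic, config.p_electronic_pre)
    electronic = rng.random(m) < p_elec
    mode_codes = np.where(electronic, "2ae", "2ad")

    covid = pandemic.values & (rng.random(m) < config.p_covid_code_pandemic)
    only_covid = covid & (rng.random(m) < 0.5)
    diagnosis = np.full(m, _BASE_RTI_CODE, dtype=object)
    diagnosis[covid] = f"{_BASE_RTI_CODE};{_COVID_CODE}"
    diagnosis[only_covid] = _COVID_CODE

    out = pd.DataFrame({
        "patient_id": persons["patient_id"].values[df["person_idx"].values],
        "date": df["date"],
        "service_type": service,
        "mode_codes": mode_codes,
        "diagnosis_codes": diagnosis,
        "is_index": df["is_index"],
    })
    return out.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def generate_dispensings(consultations: pd.DataFrame, config: ScenarioConfig,
                         persons: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Generate the dispensing table from the consultation stream.

    Each index consultation emits one antibiotic dispensing with the
    period-appropriate propensity, lagged by a draw from ``delay_mix`` and
    typed by a draw from ``type_mix``. Unrelated urinary-tract-agent
    dispensings are added as noise at ``noise_dispensing_rate`` per
    person-year. Dispensings after the study end or after the person's death
    (when a person table is supplied) are discarded.
    """
    config.validate()
    if "is_index" not in consultations.columns:
        raise SchemaError("consultation table lacks 'is_index' "
                          "(not produced by generate_consultations?)")
    rng = _rng(config, 2)
    end = pd.Timestamp(config.date_end)

    idx = consultations.loc[consultations["is_index"]]
    pandemic = idx["date"] >= pd.Timestamp(config.pandemic_start)
    p = np.where(pandemic, config.p_treat_pandemic, config.p_treat_pre)
    treated = idx.loc[rng.random(len(idx)) < p]

    lag_days = np.array(list(config.delay_mix.keys()))
    lag_p = np.array(list(config.delay_mix.values()))
    lags = rng.choice(lag_days, size=len(treated), p=lag_p)
    classes = list(config.type_mix.keys())
    class_p = list(config.type_mix.values())
    drawn = rng.choice(len(classes), size=len(treated), p=class_p)

    disp = pd.DataFrame({
        "patient_id": treated["patient_id"].values,
        "date": treated["date"].values + pd.to_timedelta(lags, unit="D"),
        "atc_code": [CLASS_ATC[classes[i]] for i in drawn],
    })

    if persons is not None and len(persons):
        n = len(persons)
        window_days = (end - pd.Timestamp(config.date_start)).days + 1
        n_noise = rng.poisson(n * config.noise_dispensing_rate * window_days / 365.25)
        noise_person = rng.integers(0, n, size=n_noise)
        noise = pd.DataFrame({
            "patient_id": persons["patient_id"].values[noise_person],
            "date": pd.Timestamp(config.date_start) + pd.to_timedelta(
                rng.integers(0, window_days, size=n_noise), unit="D"),
            "atc_code": rng.choice(NOISE_ATC, size=n_noise),
        })
        noise_death = persons["death_date"].values[noise_person]
        noise = noise.loc[pd.isna(noise_death) | (noise["date"].values <= noise_death)]
        disp = pd.concat([disp, noise], ignore_index=True)

    disp = disp.loc[disp["date"] <= end]
    if persons is not None and len(persons):
        death = persons.set_index("patient_id")["death_date"]
        d = disp["patient_id"].map(death)
        disp = disp.loc[d.isna() | (disp["date"] <= d)]
    return disp.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def scenario_truth(config: ScenarioConfig, consultations: pd.DataFrame,
                   perioddef: Optional[PeriodDefinition] = None) -> ScenarioTruth:
    """Ground truth of a realisation: true RR and realized episode counts.

    The true RR is the ratio of configured treatment propensities; realized
    episode counts are index consultations per comparison period; the
    monthly curve counts index consultations per calendar month.
    """
    perioddef = perioddef or PeriodDefinition()
    true_rr = (config.p_treat_pandemic / config.p_treat_pre
               if config.p_treat_pre > 0 else float("nan"))
    if len(consultations):
        idx = consultations.loc[consultations["is_index"], "date"]
        pre = ((idx >= pd.Timestamp(perioddef.pre_start)) &
               (idx <= pd.Timestamp(perioddef.pre_end))).sum()
        pand = ((idx >= pd.Timestamp(perioddef.pandemic_start)) &
                (idx <= pd.Timestamp(perioddef.pandemic_end))).sum()
        monthly = idx.dt.strftime("%Y-%m").value_counts().sort_index()
        monthly_counts = {k: int(v) for k, v in monthly.items()}
        total = int(consultations["is_index"].sum())
    else:
        pre = pand = total = 0
        monthly_counts = {}
    return ScenarioTruth(true_rr=float(true_rr), n_episodes_pre=int(pre),
                         n_episodes_pandemic=int(pand), n_episodes_total=total,
                         monthly_index_counts=monthly_counts)


def simulate_registry(config: ScenarioConfig,
                      perioddef: Optional[PeriodDefinition] = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, ScenarioTruth]:
    """Run the full generator: persons, consultations, dispensings, truth."""
    persons = generate_population(config)
    consultations = generate_consultations(persons, config)
    dispensings = generate_dispensings(consultations, config, persons=persons)
    truth = scenario_truth(config, consultations, perioddef)
    return persons, consultations, dispensings, truth
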