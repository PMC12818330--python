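"""RTI consultation flagging and episode construction.

An episode of care is a chain of RTI consultations for one patient: a
consultation starts a new episode iff there is no RTI consultation for that
patient in the preceding 30 days (strictly more than 30 days since the
previous one); otherwise it joins the current episode, regardless of whether
the previous consultation was the index or a follow-up. There is no cap on
episode length or consultation count. "Within 30 days" is read inclusively:
a gap of exactly 30 days chains, 31 starts a new episode. Same-day repeat
consultations stay in the same episode as separate consultations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codelists import CodeListConfig
from .config import AGE_EDGES, AGE_GROUPS, PeriodDefinition

__all__ = [
    "LabelError",
    "flag_rti_consultations", "build_episodes", "label_episodes",
    "trim_boundary_months", "assign_period",
]


class LabelError(KeyError):
    """Episode labelling failed (e.g. patient absent from the person table)."""


def _split_codes(series: pd.Series, delim: str) -> pd.Series:
    return series.fillna("").str.split(delim)


def flag_rti_consultations(consultations: pd.DataFrame, codelist: CodeListConfig,
                           code_delim: str = ";") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain consultations carrying at least one RTI diagnosis code.

    Returns ``(rti, rejected)``. The retained table gains:

    - ``mode``: 'electronic' iff every recognised procedure code on the claim
      is electronic-type, 'in_person' otherwise (a claim mixing both kinds of
      code bills as in-person);
    - ``is_covid_specific``: any diagnosis code is COVID-specific;
    - ``has_noncovid_rti``: at least one RTI diagnosis code is not
      COVID-specific (used by the strict COVID exclusion mode).

    Consultations with no recognised procedure code follow
    ``codelist.unknown_procedure_policy``: rejected (default) or assumed
    in-person.
    """
    df = consultations.reset_index(drop=True)
    diag = _split_codes(df["diagnosis_codes"], code_delim)

    rti_set = codelist.rti_icpc2_codes
    covid_set = codelist.covid_icpc2_codes
    noncovid_rti = rti_set - covid_set

    has_rti = diag.map(lambda cs: any(c in rti_set for c in cs))
    is_covid = diag.map(lambda cs: any(c in covid_set for c in cs))
    has_noncovid = diag.map(lambda cs: any(c in noncovid_rti for c in cs))

    proc = _split_codes(df["mode_codes"], code_delim)
    known = codelist.consultation_procedure_codes
    n_known = proc.map(lambda cs: sum(c in known for c in cs))
    n_elec = proc.map(lambda cs: sum(known.get(c) == "electronic" for c in cs))

    rti = df.loc[has_rti].copy()
    rti["is_covid_specific"] = is_covid[has_rti]
    rti["has_noncovid_rti"] = has_noncovid[has_rti]
    nk, ne = n_known[has_rti], n_elec[has_rti]
    rti["mode"] = np.where((nk > 0) & (ne == nk), "electronic", "in_person")

    unknown = nk == 0
    if codelist.unknown_procedure_policy == "reject":
        rejected = rti.loc[unknown].copy()
        rejected["reason"] = "no recognised procedure code"
        rti = rti.loc[~unknown]
    else:
        rejected = rti.iloc[0:0].copy()
        rejected["reason"] = pd.Series(dtype=str)
        rti.loc[unknown, "mode"] = "in_person"
    return rti.reset_index(drop=True), rejected.reset_index(drop=True)


def build_episodes(rti: pd.DataFrame,
                   chain_window_days: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group RTI consultations into episodes with the chain rule.

    Returns ``(episodes, consult_map)``: one row per episode, and the input
    consultations annotated with ``episode_id``. The episodes partition the
    input; output is independent of input row order (sorting is canonical).
    """
    if rti.empty:
        episodes = pd.DataFrame(columns=[
            "episode_id", "patient_id", "index_date", "last_date", "n_consultations",
            "service_label", "mode_label", "count_class",
            "contains_covid_code", "all_covid"])
        consult_map = rti.copy()
        consult_map["episode_id"] = pd.Series(dtype=int)
        return episodes, consult_map

    df = rti.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    same_patient = df["patient_id"].eq(df["patient_id"].shift())
    gap = df["date"].diff().dt.days
    new_episode = ~(same_patient & (gap <= chain_window_days))
    df["episode_id"] = new_episode.cumsum() - 1

    g = df.groupby("episode_id", sort=True)
    episodes = g.agg(
        patient_id=("patient_id", "first"),
        index_date=("date", "min"),
        last_date=("date", "max"),
        n_consultations=("date", "size"),
        n_service=("service_type", "nunique"),
        first_service=("service_type", "first"),
        n_mode=("mode", "nunique"),
        first_mode=("mode", "first"),
        contains_covid_code=("is_covid_specific", "any"),
        any_noncovid=("has_noncovid_rti", "any"),
    ).reset_index()
    episodes["service_label"] = np.where(
        episodes["n_service"] == 1, episodes["first_service"], "mixed")
    episodes["mode_label"] = np.where(
        episodes["n_mode"] == 1, episodes["first_mode"], "mixed")
    episodes["count_class"] = np.where(
        episodes["n_consultations"] >= 2, "two_plus", "one")
    episodes["all_covid"] = episodes["contains_covid_code"] & ~episodes["any_noncovid"]
    episodes = episodes.drop(columns=["n_service", "first_service", "n_mode",
                                      "first_mode", "any_noncovid"])
    return episodes, df


def _age_years(index_date: pd.Series, birth_date: pd.Series) -> np.ndarray:
    """Completed years of age at index_date."""
    idx, birth = pd.to_datetime(index_date), pd.to_datetime(birth_date)
    before_birthday = (idx.dt.month.values * 100 + idx.dt.day.values) < (
        birth.dt.month.values * 100 + birth.dt.day.values)
    return idx.dt.year.values - birth.dt.year.values - before_birthday


def age_group_of(index_date: pd.Series, birth_date: pd.Series) -> pd.Series:
    years = _age_years(index_date, birth_date)
    edges = list(AGE_EDGES) + [np.inf]
    return pd.cut(years, bins=edges, labels=AGE_GROUPS, right=False).astype(str)


def assign_period(dates: pd.Series, perioddef: PeriodDefinition) -> pd.Series:
    d = pd.to_datetime(dates)
    pre = (d >= pd.Timestamp(perioddef.pre_start)) & (d <= pd.Timestamp(perioddef.pre_end))
    pand = (d >= pd.Timestamp(perioddef.pandemic_start)) & (
        d <= pd.Timestamp(perioddef.pandemic_end))
    return pd.Series(np.select([pre, pand], ["pre", "pandemic"], default="neither"),
                     index=dates.index)


def label_episodes(episodes: pd.DataFrame, persons: pd.DataFrame,
                   perioddef: PeriodDefinition) -> pd.DataFrame:
    """Attach age group, sex and analysis period to built episodes.

    Age is completed years at the index consultation; the period is assigned
    from the index date, so an episode extending past a window boundary stays
    in the window of its index.
    """
    if episodes.empty:
        out = episodes.copy()
        for c in ("age_group", "sex", "period"):
            out[c] = pd.Series(dtype=str)
        return out
    merged = episodes.merge(persons[["patient_id", "birth_date", "sex"]],
                            on="patient_id", how="left")
    missing = merged["birth_date"].isna()
    if missing.any():
        ids = sorted(merged.loc[missing, "patient_id"].unique())
        raise LabelError(f"patient_id(s) absent from person table: {ids[:5]}")
    merged["age_group"] = age_group_of(merged["index_date"], merged["birth_date"])
    merged["period"] = assign_period(merged["index_date"], perioddef)
    return merged.drop(columns=["birth_date"])


def trim_boundary_months(consultations: pd.DataFrame,
                         perioddef: PeriodDefinition) -> pd.DataFrame:
    """Drop consultations dated in the trimmed boundary months.

    Applied before episode building on the comparative-analysis path; the
    monthly-rate reporting path keeps all months.
    """
    months = pd.to_datetime(consultations["date"]).dt.strftime("%Y-%m")
    return consultations.loc[~months.isin(perioddef.trim_months)].reset_index(drop=True)
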