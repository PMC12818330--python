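"""Monthly population denominators and episode rates per 1000 inhabitants.

Denominators are first-day-of-month snapshots: a person contributes to a
month iff alive and resident on the first day of that month, with age group
taken in completed years on that day. A person who dies mid-month therefore
still counts in that month; a person born mid-month counts from the next.
An optional frozen-cohort mode excludes persons whose residency begins after
a cutoff date, mirroring registries whose final study year lacks updates for
newborns and migrants.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AGE_GROUPS
from .episodes import age_group_of

__all__ = ["monthly_population", "episode_rate", "yearly_characteristics"]


def _month_starts(months: Iterable[str]) -> pd.DatetimeIndex:
    return pd.DatetimeIndex([pd.Timestamp(m + "-01") for m in months])


def month_range(start: date, end: date) -> list[str]:
    """All 'YYYY-MM' labels from the month of start to the month of end."""
    return [str(p) for p in pd.period_range(pd.Timestamp(start), pd.Timestamp(end),
                                            freq="M")]


def monthly_population(persons: pd.DataFrame, months: str | Sequence[str],
                       freeze_entries_after: Optional[date] = None) -> pd.DataFrame:
    """Population counts by month, age group and sex.

    ``months`` is one 'YYYY-MM' label or a sequence of them. Returns one row
    per (month, age_group, sex) cell, zero-filled so cells partition the
    population for each month.
    """
    if isinstance(months, str):
        months = [months]
    persons = persons.copy()
    if freeze_entries_after is not None:
        cutoff = pd.Timestamp(freeze_entries_after)
        entered_late = persons["residency_start"].notna() & (
            persons["residency_start"] > cutoff)
        persons = persons.loc[~entered_late]

    frames = []
    for m, start in zip(months, _month_starts(months)):
        alive = (persons["birth_date"] <= start) & (
            persons["death_date"].isna() | (persons["death_date"] >= start))
        resident = (persons["residency_start"].isna() |
                    (persons["residency_start"] <= start)) & (
            persons["residency_end"].isna() | (persons["residency_end"] >= start))
        sub = persons.loc[alive & resident]
        if len(sub):
            ag = age_group_of(pd.Series([start] * len(sub), index=sub.index),
                              sub["birth_date"])
            counts = (pd.DataFrame({"age_group": ag, "sex": sub["sex"].values})
                      .value_counts().rename("count").reset_index())
        else:
            counts = pd.DataFrame({"age_group": pd.Series(dtype=str),
                                   "sex": pd.Series(dtype=str),
                                   "count": pd.Series(dtype=int)})
        full = pd.MultiIndex.from_product([AGE_GROUPS, ["male", "female"]],
                                          names=["age_group", "sex"]).to_frame(index=False)
        merged = full.merge(counts, on=["age_group", "sex"], how="left")
        merged["count"] = merged["count"].fillna(0).infer_objects(copy=False).astype(int)
        merged.insert(0, "month", m)
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def episode_rate(episodes: pd.DataFrame, population_cells: pd.DataFrame,
                 grouping: Optional[list[str]] = None) -> pd.DataFrame:
    """Episode rates per 1000 inhabitants per month (optionally stratified).

    Episodes are assigned to months by index date. ``grouping`` may contain
    ``'age_group'`` and/or ``'sex'``; the matching population cells form the
    denominator. A month with episodes but no covering population is a
    denominator misconfiguration and raises ``ValueError``.
    """
    grouping = grouping or []
    bad = set(grouping) - {"age_group", "sex"}
    if bad:
        raise ValueError(f"grouping only supports age_group/sex, got {bad}")
    ep = episodes.copy()
    ep["month"] = pd.to_datetime(ep["index_date"]).dt.strftime("%Y-%m")
    keys = ["month"] + grouping
    counts = ep.groupby(keys, observed=True).size().rename("episodes").reset_index()
    pop = (population_cells.groupby(keys, observed=True)["count"].sum()
           .rename("population").reset_index())
    merged = counts.merge(pop, on=keys, how="left")
    uncovered = merged["population"].isna() | (merged["population"] == 0)
    if uncovered.any():
        rows = merged.loc[uncovered, keys].to_dict("records")
        raise ValueError(f"episodes with zero/missing population denominator: {rows[:5]}")
    # carry months with population but no episodes as zero rates
    merged = pop.merge(counts, on=keys, how="left")
    merged["episodes"] = merged["episodes"].fillna(0).astype(int)
    merged = merged.loc[merged["population"] > 0].reset_index(drop=True)
    merged["rate_per_1000"] = 1000.0 * merged["episodes"] / merged["population"]
    return merged


_BLOCKS = {
    "treated": ("treated", {True: "Yes", False: "No"}),
    "age_group": ("age_group", None),
    "sex": ("sex", {"male": "Male", "female": "Female"}),
    "service_type": ("service_label", {"DGP": "DGP", "OOH": "OOH", "mixed": "Mixed"}),
    "mode": ("mode_label", {"in_person": "In-person", "electronic": "Electronic",
                            "mixed": "Mixed"}),
}


def yearly_characteristics(episodes: pd.DataFrame,
                           persons: pd.DataFrame) -> pd.DataFrame:
    """Yearly episode rates per 1000 inhabitants with characteristic breakdowns.

    For each calendar year of the index consultation: the overall rate per
    1000 inhabitants, then within-year breakdowns by treatment status, age
    group, sex, service type and consultation mode. Each row reports the
    episode count, its percentage of the year's episodes, and the rate per
    1000 of the stratum population (the whole population except for the age
    and sex blocks, which use the matching stratum denominator). The year
    denominator is the mean of the twelve monthly snapshots.
    """
    ep = episodes.copy()
    ep["year"] = pd.to_datetime(ep["index_date"]).dt.year
    records = []
    for year, sub in ep.groupby("year"):
        months = [f"{year}-{m:02d}" for m in range(1, 13)]
        cells = monthly_population(persons, months)
        n_months = cells["month"].nunique()
        pop_total = cells["count"].sum() / n_months
        n_year = len(sub)
        records.append({"year": year, "block": "N", "level": "Total",
                        "episodes": n_year, "population": pop_total,
                        "rate_per_1000": 1000.0 * n_year / pop_total if pop_total else np.nan,
                        "pct_of_episodes": 100.0})
        for block, (col, labels) in _BLOCKS.items():
            for value, group in sub.groupby(col, observed=True):
                if block == "age_group":
                    denom = cells.loc[cells["age_group"] == value, "count"].sum() / n_months
                elif block == "sex":
                    denom = cells.loc[cells["sex"] == value, "count"].sum() / n_months
                else:
                    denom = pop_total
                records.append({
                    "year": year, "block": block,
                    "level": labels.get(value, str(value)) if labels else str(value),
                    "episodes": len(group), "population": denom,
                    "rate_per_1000": 1000.0 * len(group) / denom if denom else np.nan,
                    "pct_of_episodes": 100.0 * len(group) / n_year if n_year else np.nan,
                })
    return pd.DataFrame.from_records(records)
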