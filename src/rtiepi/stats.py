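"""Risk ratios, Mantel-Haenszel heterogeneity and contingency chi-squared.

The comparison of interest is the treated proportion of episodes in the
pandemic period against the pre-pandemic period. With a single binary
exposure the log-binomial maximum-likelihood risk ratio is the plain ratio
of proportions, so the RR is computed in closed form:

    RR = (x1/n1) / (x0/n0)
    95% CI = exp(log RR ± z * sqrt((1-p1)/x1 + (1-p0)/x0))

with z = 1.96 (the difference from the exact normal quantile is invisible at
two printed decimals). Heterogeneity of stratum RRs is tested against the
Mantel-Haenszel pooled RR with an inverse-variance-weighted Q statistic on
the log scale, referred to chi-squared with (strata - 1) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AGE_GROUPS, PeriodDefinition

__all__ = [
    "TwoByTwo", "RRResult", "HeterogeneityResult", "UndefinedRRError",
    "risk_ratio", "mh_pooled_rr", "mh_heterogeneity", "pearson_chi2",
    "two_by_two_from_printed", "stratified_rr_table", "round_half_away",
]

Z95 = 1.96


class UndefinedRRError(ZeroDivisionError):
    """A risk ratio is undefined (a zero treated count or empty period)."""


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention of printed report tables)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class TwoByTwo:
    """Treated/total episode counts in the pre and pandemic periods."""

    n_pre: int
    x_pre: int
    n_pand: int
    x_pand: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_pre <= self.n_pre and 0 <= self.x_pand <= self.n_pand):
            raise ValueError("counts must satisfy 0 <= x <= n in both periods")


@dataclass(frozen=True)
class RRResult:
    rr: float
    ci_low: float
    ci_high: float
    log_se: float

    def round(self, decimals: int = 2) -> tuple[float, float, float]:
        return tuple(round_half_away(v, decimals)
                     for v in (self.rr, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class HeterogeneityResult:
    statistic: float
    df: int
    p_value: float


def two_by_two_from_printed(n_pre: int, pct_pre: float,
                            n_pand: int, pct_pand: float) -> TwoByTwo:
    """Reconstruct counts from a printed (N, % treated) pair per period.

    Treated counts are recovered as round(N * % / 100), half away from zero —
    the inverse of how the percentages were printed.
    """
    return TwoByTwo(
        n_pre=n_pre, x_pre=int(round_half_away(n_pre * pct_pre / 100.0)),
        n_pand=n_pand, x_pand=int(round_half_away(n_pand * pct_pand / 100.0)))


def risk_ratio(t: TwoByTwo, z: float = Z95) -> RRResult:
    """Pandemic-vs-pre risk ratio with a Wald CI on the log scale."""
    if t.n_pre == 0 or t.n_pand == 0:
        raise UndefinedRRError("risk ratio undefined: empty period")
    if t.x_pre == 0 or t.x_pand == 0:
        raise UndefinedRRError(
            "risk ratio undefined: zero treated count "
            f"(x_pre={t.x_pre}, x_pand={t.x_pand})")
    p0 = t.x_pre / t.n_pre
    p1 = t.x_pand / t.n_pand
    rr = p1 / p0
    se = math.sqrt((1.0 - p1) / t.x_pand + (1.0 - p0) / t.x_pre)
    log_rr = math.log(rr)
    return RRResult(rr=rr, ci_low=math.exp(log_rr - z * se),
                    ci_high=math.exp(log_rr + z * se), log_se=se)


def mh_pooled_rr(strata: Sequence[TwoByTwo]) -> float:
    """Mantel-Haenszel pooled risk ratio across strata."""
    num = den = 0.0
    for t in strata:
        n_total = t.n_pre + t.n_pand
        if n_total == 0:
            continue
        num += t.x_pand * t.n_pre / n_total
        den += t.x_pre * t.n_pand / n_total
    if den == 0:
        raise UndefinedRRError("pooled risk ratio undefined")
    return num / den


def mh_heterogeneity(strata: Sequence[TwoByTwo]) -> HeterogeneityResult:
    """Test whether stratum risk ratios share a common value.

    Q = sum_i w_i (log RR_i - log RR_MH)^2 with w_i the inverse variance of
    log RR_i; under homogeneity Q ~ chi-squared(k - 1).
    """
    if len(strata) < 2:
        raise ValueError("heterogeneity test needs at least 2 strata")
    bad = []
    results = []
    for i, t in enumerate(strata):
        try:
            results.append(risk_ratio(t))
        except UndefinedRRError:
            bad.append(i)
    if bad:
        raise UndefinedRRError(f"strata with undefined RR: {bad}")
    log_mh = math.log(mh_pooled_rr(strata))
    q = sum((math.log(r.rr) - log_mh) ** 2 / r.log_se ** 2 for r in results)
    df = len(strata) - 1
    return HeterogeneityResult(statistic=q, df=df, p_value=float(sps.chi2.sf(q, df)))


def pearson_chi2(contingency) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a counts matrix."""
    table = np.asarray(contingency, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# stratified episode-level analysis

_STRATA_ORDERS = {
    "age_group": [(g,) for g in AGE_GROUPS],
    "service": [("DGP", "one"), ("OOH", "one"),
                ("DGP", "two_plus"), ("OOH", "two_plus"), ("mixed", "two_plus")],
    "mode": [("in_person", "one"), ("electronic", "one"),
             ("in_person", "two_plus"), ("electronic", "two_plus"),
             ("mixed", "two_plus")],
}
_STRATA_COLS = {
    "age_group": ["age_group"],
    "service": ["service_label", "count_class"],
    "mode": ["mode_label", "count_class"],
}


def _stratum_name(stratification: str, key: tuple) -> str:
    if stratification == "age_group":
        return key[0]
    label = {"one": "(1)", "two_plus": "(2+)"}[key[1]]
    head = {"DGP": "DGP", "OOH": "OOH", "mixed": "Mixed",
            "in_person": "In-person", "electronic": "Electronic"}[key[0]]
    return f"{head} {label}"


def apply_covid_filter(episodes: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Drop COVID-coded episodes for the non-COVID sensitivity analysis.

    mode 'any' drops episodes containing any COVID-specific diagnosis;
    'all' drops only episodes whose every RTI diagnosis is COVID-specific;
    'off' keeps everything.
    """
    if mode == "off":
        return episodes
    if mode == "any":
        return episodes.loc[~episodes["contains_covid_code"]]
    if mode == "all":
        return episodes.loc[~episodes["all_covid"]]
    raise ValueError(f"unknown covid filter mode: {mode!r}")


def _counts(sub: pd.DataFrame) -> tuple[int, int, int, int]:
    pre = sub["period"] == "pre"
    pand = sub["period"] == "pandemic"
    return (int(pre.sum()), int((pre & sub["treated"]).sum()),
            int(pand.sum()), int((pand & sub["treated"]).sum()))


def stratified_rr_table(episodes: pd.DataFrame, stratification: str,
                        perioddef: PeriodDefinition | None = None,
                        covid_filter: str = "off") -> pd.DataFrame:
    """Stratified risk-ratio table for one stratification.

    ``stratification`` is ``'age_group'``, ``'service'`` (service type by
    consultation count) or ``'mode'`` (consultation mode by count) — service
    and mode are crossed with episode consultation count because mixed
    episodes necessarily have two or more consultations. Episodes outside
    the two comparison periods are ignored. A total row is appended. Strata
    with undefined RRs are emitted with blank RR cells, not dropped.
    """
    if stratification not in _STRATA_ORDERS:
        raise ValueError(f"unknown stratification: {stratification!r}")
    df = apply_covid_filter(episodes, covid_filter)
    df = df.loc[df["period"].isin(["pre", "pandemic"])]

    rows = []
    strata_tables: list[TwoByTwo] = []
    cols = _STRATA_COLS[stratification]
    for key in _STRATA_ORDERS[stratification]:
        mask = np.ones(len(df), dtype=bool)
        for col, val in zip(cols, key):
            mask &= (df[col] == val).values
        t = TwoByTwo(*_counts(df.loc[mask]))
        rows.append((_stratum_name(stratification, key), t))
        strata_tables.append(t)
    rows.append(("Total", TwoByTwo(*_counts(df))))

    records = []
    for name, t in rows:
        rec = {"stratum": name, "n_pre": t.n_pre, "n_pandemic": t.n_pand,
               "pct_treated_pre": round_half_away(100 * t.x_pre / t.n_pre, 1)
               if t.n_pre else np.nan,
               "pct_treated_pandemic": round_half_away(100 * t.x_pand / t.n_pand, 1)
               if t.n_pand else np.nan}
        try:
            r = risk_ratio(t)
            rec.update(rr=r.rr, ci_low=r.ci_low, ci_high=r.ci_high)
        except UndefinedRRError:
            rec.update(rr=np.nan, ci_low=np.nan, ci_high=np.nan)
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("stratum")

    defined = [t for t in strata_tables
               if t.n_pre and t.n_pand and t.x_pre and t.x_pand]
    if len(defined) >= 2:
        het = mh_heterogeneity(defined)
        table.attrs["heterogeneity_q"] = het.statistic
        table.attrs["heterogeneity_df"] = het.df
        table.attrs["heterogeneity_p"] = het.p_value
    table.attrs["covid_filter"] = covid_filter
    table.attrs["stratification"] = stratification
    return table
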