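"""Model/Results facade over the episode pipeline.

:class:`RTIAntibioticModel` holds labelled, treatment-annotated episodes and
the analysis configuration; :meth:`RTIAntibioticModel.fit` produces an
:class:`RTIAntibioticResults` carrying the total and stratified risk ratios,
their Wald confidence intervals, the per-stratification Mantel-Haenszel
heterogeneity tests, and a printable summary. Construct the model either
from raw registry tables (``from_tables``) or by simulating a scenario
(``from_scenario``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .codelists import CodeListConfig, default_codelist
from .config import PeriodDefinition, ScenarioConfig
from .episodes import (build_episodes, flag_rti_consultations, label_episodes,
                       trim_boundary_months)
from .linkage import link_treatments
from .simulate import ScenarioTruth, simulate_registry
from .stats import (HeterogeneityResult, RRResult, TwoByTwo, apply_covid_filter,
                    risk_ratio, round_half_away, stratified_rr_table)

__all__ = ["RTIAntibioticModel", "RTIAntibioticResults"]


class RTIAntibioticModel:
    """Pandemic-vs-pre comparison of antibiotic treatment for RTI episodes.

    Parameters
    ----------
    episodes
        Labelled, treatment-annotated episode table (one row per episode with
        ``period``, ``treated`` and the stratification labels).
    perioddef
        The comparison windows the labels were derived from.
    covid_filter
        'off' (default) analyses all RTI episodes; 'any' drops episodes
        containing any COVID-specific diagnosis; 'all' drops only episodes
        whose every RTI diagnosis is COVID-specific.

    Examples
    --------
    >>> model = RTIAntibioticModel.from_scenario(ScenarioConfig(seed=7))
    >>> res = model.fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, episodes: pd.DataFrame,
                 perioddef: Optional[PeriodDefinition] = None,
                 covid_filter: str = "off") -> None:
        self.episodes = episodes
        self.perioddef = perioddef or PeriodDefinition()
        self.covid_filter = covid_filter

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_tables(cls, consultations: pd.DataFrame, dispensings: pd.DataFrame,
                    persons: pd.DataFrame,
                    codelist: Optional[CodeListConfig] = None,
                    perioddef: Optional[PeriodDefinition] = None,
                    chain_window_days: int = 30, link_window_days: int = 7,
                    covid_filter: str = "off",
                    trim_boundaries: bool = True) -> "RTIAntibioticModel":
        """Build the model from the three raw registry tables.

        Runs the full comparative path: boundary-month trimming, RTI
        flagging, episode construction, labelling and treatment linkage.
        """
        codelist = codelist or default_codelist()
        perioddef = perioddef or PeriodDefinition()
        if trim_boundaries:
            consultations = trim_boundary_months(consultations, perioddef)
        rti, _rejected = flag_rti_consultations(consultations, codelist)
        episodes, consult_map = build_episodes(rti, chain_window_days)
        episodes = label_episodes(episodes, persons, perioddef)
        episodes, links = link_treatments(episodes, consult_map, dispensings,
                                          codelist, link_window_days)
        model = cls(episodes, perioddef, covid_filter)
        model.links = links
        model.consult_map = consult_map
        return model

    @classmethod
    def from_scenario(cls, scenario: ScenarioConfig,
                      perioddef: Optional[PeriodDefinition] = None,
                      **kwargs) -> "RTIAntibioticModel":
        """Simulate a synthetic registry and build the model from it."""
        persons, consultations, dispensings, truth = simulate_registry(
            scenario, perioddef)
        model = cls.from_tables(consultations.drop(columns=["is_index"]),
                                dispensings, persons,
                                perioddef=perioddef, **kwargs)
        model.truth = truth
        return model

    # -- estimation --------------------------------------------------------

    def fit(self) -> "RTIAntibioticResults":
        """Estimate the total and stratified risk ratios."""
        tables = {
            s: stratified_rr_table(self.episodes, s, self.perioddef,
                                   covid_filter=self.covid_filter)
            for s in ("age_group", "service", "mode")
        }
        in_scope = self.episodes.loc[
            self.episodes["period"].isin(["pre", "pandemic"])]
        in_scope = apply_covid_filter(in_scope, self.covid_filter)
        pre = in_scope["period"] == "pre"
        pand = in_scope["period"] == "pandemic"
        total = TwoByTwo(int(pre.sum()), int((pre & in_scope["treated"]).sum()),
                         int(pand.sum()), int((pand & in_scope["treated"]).sum()))
        total_rr = risk_ratio(total)
        return RTIAntibioticResults(
            model=self, total_counts=total, total_rr=total_rr,
            stratified=tables,
            truth=getattr(self, "truth", None))


@dataclass
class RTIAntibioticResults:
    """Fitted pandemic-vs-pre treatment comparison.

    Attributes
    ----------
    total_counts : TwoByTwo
        Episode and treated-episode counts per period.
    total_rr : RRResult
        Overall risk ratio with 95% CI.
    stratified : dict
        Stratification name -> result table (with heterogeneity test
        results in ``.attrs``).
    truth : ScenarioTruth or None
        Present when the model came from a simulated scenario.
    """

    model: RTIAntibioticModel
    total_counts: TwoByTwo
    total_rr: RRResult
    stratified: dict[str, pd.DataFrame]
    truth: Optional[ScenarioTruth] = None

    @property
    def rr(self) -> float:
        return self.total_rr.rr

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.total_rr.ci_low, self.total_rr.ci_high)

    def covers_truth(self) -> bool:
        """Whether the 95% CI covers the scenario's true RR (simulated runs)."""
        if self.truth is None:
            raise ValueError("no scenario truth attached to this fit")
        return self.total_rr.ci_low <= self.truth.true_rr <= self.total_rr.ci_high

    def heterogeneity(self, stratification: str) -> HeterogeneityResult:
        t = self.stratified[stratification]
        return HeterogeneityResult(t.attrs["heterogeneity_q"],
                                   t.attrs["heterogeneity_df"],
                                   t.attrs["heterogeneity_p"])

    def summary(self) -> str:
        """Printable report: counts, treated fractions, RRs and heterogeneity."""
        t = self.total_counts
        p0 = 100.0 * t.x_pre / t.n_pre if t.n_pre else float("nan")
        p1 = 100.0 * t.x_pand / t.n_pand if t.n_pand else float("nan")
        rr, lo, hi = self.total_rr.round(2)
        lines = [
            "Antibiotic treatment for RTI episodes: pandemic vs pre-pandemic",
            "=" * 66,
            f"Pre-pandemic:  {t.n_pre:>9d} episodes, "
            f"{round_half_away(p0, 1):.1f}% treated",
            f"Pandemic:      {t.n_pand:>9d} episodes, "
            f"{round_half_away(p1, 1):.1f}% treated",
            f"Risk ratio:    {rr:.2f} (95% CI {lo:.2f}-{hi:.2f})",
            f"COVID filter:  {self.model.covid_filter}",
        ]
        if self.truth is not None:
            lines.append(f"Scenario true RR: {self.truth.true_rr:.3f} "
                         f"(CI covers truth: {self.covers_truth()})")
        for name, table in self.stratified.items():
            lines += ["", f"Stratified by {name}", "-" * 66]
            disp = table.copy()
            for c in ("rr", "ci_low", "ci_high"):
                disp[c] = disp[c].map(lambda v: round_half_away(v, 2))
            lines.append(disp.to_string(float_format=lambda v: f"{v:.2f}"))
            if "heterogeneity_p" in table.attrs:
                p = table.attrs["heterogeneity_p"]
                lines.append(f"MH heterogeneity: Q={table.attrs['heterogeneity_q']:.1f}, "
                             f"df={table.attrs['heterogeneity_df']}, "
                             f"p={'<0.0001' if p < 1e-4 else f'{p:.4f}'}")
        return "\n".join(lines)
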