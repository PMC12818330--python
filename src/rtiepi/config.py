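"""Configuration objects for the analysis pipeline and the registry simulator.

All windows are whole calendar days; dates are ``datetime.date``. Probability
vectors must sum to one and rates must be non-negative; violations raise
:class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Sequence

__all__ = [
    "AGE_GROUPS",
    "AGE_EDGES",
    "ANTIBIOTIC_CLASSES",
    "ConfigError",
    "PeriodDefinition",
    "ScenarioConfig",
    "PipelineConfig",
]

#: Ten age bands used for stratification, closed on the left (completed years).
AGE_GROUPS = (
    "0-4", "5-14", "15-24", "25-34", "35-44",
    "45-54", "55-64", "65-74", "75-84", "85+",
)
#: Left edges of the bands; the last band is open-ended.
AGE_EDGES = (0, 5, 15, 25, 35, 45, 55, 65, 75, 85)

#: Report-level antibiotic type labels, in the order they are tabulated.
ANTIBIOTIC_CLASSES = (
    "azithromycin",
    "other_macrolides",
    "phenoxymethylpenicillin",
    "other_penicillins",
    "tetracyclines",
    "other",
)


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_prob_vector(name: str, vec: Sequence[float], tol: float = 1e-9) -> None:
    if any(v < 0 for v in vec):
        raise ConfigError(f"{name} has negative entries")
    if abs(sum(vec) - 1.0) > tol:
        raise ConfigError(f"{name} must sum to 1 (got {sum(vec)!r})")


@dataclass(frozen=True)
class PeriodDefinition:
    """Equal-length pre-pandemic and pandemic comparison windows.

    The default windows run 12 March 2018 – 30 November 2019 and
    12 March 2020 – 30 November 2021 (both endpoints inclusive), with the
    first and last calendar months of the study horizon trimmed before
    episode construction on the comparative path, because episodes and
    treatment linkage look across day boundaries.
    """

    pre_start: date = date(2018, 3, 12)
    pre_end: date = date(2019, 11, 30)
    pandemic_start: date = date(2020, 3, 12)
    pandemic_end: date = date(2021, 11, 30)
    trim_months: tuple[str, ...] = ("2018-01", "2021-12")

    def __post_init__(self) -> None:
        if (self.pre_end - self.pre_start) != (self.pandemic_end - self.pandemic_start):
            raise ConfigError(
                "pre and pandemic windows must have equal length in days: "
                f"{(self.pre_end - self.pre_start).days} vs "
                f"{(self.pandemic_end - self.pandemic_start).days}"
            )
        if not (self.pre_start < self.pre_end < self.pandemic_start < self.pandemic_end):
            raise ConfigError("period windows must be ordered and non-overlapping")


#: Dispensing-lag distribution (days -> probability). Mass above 7 days is
#: deliberate: those treatments fall outside the linkage window.
DEFAULT_DELAY_MIX: Mapping[int, float] = {0: 0.55, 1: 0.20, 2: 0.10, 3: 0.05, 5: 0.05, 10: 0.05}

#: Antibiotic-type mix for simulated treatments, loosely matching the national
#: distribution (phenoxymethylpenicillin dominates).
DEFAULT_TYPE_MIX: Mapping[str, float] = {
    "azithromycin": 0.035,
    "other_macrolides": 0.118,
    "phenoxymethylpenicillin": 0.538,
    "other_penicillins": 0.134,
    "tetracyclines": 0.125,
    "other": 0.050,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic registry scenario.

    The defaults emulate the Norwegian primary-care setting of 2018–2021:
    winter-peaking RTI consultations, a consultation spike immediately after
    the 12 March 2020 lockdown followed by suppression, a pandemic shift to
    electronic consultations, and a drop in per-episode antibiotic
    treatment propensity from 0.26 to 0.135.
    """

    n_persons: int = 20_000
    date_start: date = date(2018, 1, 1)
    date_end: date = date(2021, 12, 31)
    age_mix: tuple[float, ...] = (0.055, 0.115, 0.12, 0.135, 0.125, 0.135, 0.125, 0.10, 0.06, 0.03)
    baseline_monthly_rti_rate: float = 0.019
    seasonal_amplitude: float = 0.45
    seasonal_peak_month: int = 1
    pandemic_start: date = date(2020, 3, 12)
    spike_multiplier: float = 2.5
    spike_days: int = 30
    suppression_multiplier: float = 0.75
    p_followup: float = 0.25
    p_treat_pre: float = 0.26
    p_treat_pandemic: float = 0.135
    type_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    p_electronic_pre: float = 0.005
    p_electronic_pandemic: float = 0.40
    p_ooh: float = 0.12
    p_covid_code_pandemic: float = 0.15
    delay_mix: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_DELAY_MIX))
    noise_dispensing_rate: float = 0.05  # unrelated (urinary-agent) dispensings per person-year
    death_rate_per_year: float = 0.008
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        if self.n_persons < 0:
            raise ConfigError(f"n_persons must be >= 0, got {self.n_persons}")
        if not self.date_start < self.pandemic_start < self.date_end:
            raise ConfigError("dates must satisfy date_start < pandemic_start < date_end")
        if len(self.age_mix) != len(AGE_GROUPS):
            raise ConfigError(f"age_mix must have {len(AGE_GROUPS)} entries")
        _check_prob_vector("age_mix", self.age_mix)
        _check_prob_vector("type_mix", list(self.type_mix.values()))
        if set(self.type_mix) != set(ANTIBIOTIC_CLASSES):
            raise ConfigError("type_mix keys must be the six antibiotic classes")
        _check_prob_vector("delay_mix", list(self.delay_mix.values()))
        if any(d < 0 for d in self.delay_mix):
            raise ConfigError("delay_mix days must be >= 0")
        if self.baseline_monthly_rti_rate < 0:
            raise ConfigError("baseline_monthly_rti_rate must be >= 0")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ConfigError("seasonal_amplitude must be in [0, 1)")
        if not 1 <= self.seasonal_peak_month <= 12:
            raise ConfigError("seasonal_peak_month must be in 1..12")
        if self.spike_multiplier < 1.0:
            raise ConfigError("spike_multiplier must be >= 1")
        if not 0.0 < self.suppression_multiplier <= 1.0:
            raise ConfigError("suppression_multiplier must be in (0, 1]")
        if self.spike_days < 0:
            raise ConfigError("spike_days must be >= 0")
        for name in ("p_followup", "p_treat_pre", "p_treat_pandemic",
                     "p_electronic_pre", "p_electronic_pandemic", "p_ooh",
                     "p_covid_code_pandemic"):
            _check_prob(name, getattr(self, name))
        if self.noise_dispensing_rate < 0:
            raise ConfigError("noise_dispensing_rate must be >= 0")
        if self.death_rate_per_year < 0:
            raise ConfigError("death_rate_per_year must be >= 0")
        return self

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: either three input paths or a scenario."""

    consultations_path: Optional[str] = None
    dispensings_path: Optional[str] = None
    persons_path: Optional[str] = None
    scenario: Optional[ScenarioConfig] = None
    codelist_path: Optional[str] = None
    period: PeriodDefinition = field(default_factory=PeriodDefinition)
    chain_window_days: int = 30
    link_window_days: int = 7
    covid_filter_mode: str = "any"  # "any" | "all" | "off"
    output_dir: str = "rtiepi_output"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        paths = [self.consultations_path, self.dispensings_path, self.persons_path]
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.scenario is not None and some_paths:
            raise ConfigError("provide either input paths or a scenario, not both")
        if self.scenario is None and not have_paths:
            raise ConfigError("provide all three input paths or a scenario")
        if self.chain_window_days < 1:
            raise ConfigError("chain_window_days must be >= 1")
        if self.link_window_days < 1:
            raise ConfigError("link_window_days must be >= 1")
        if self.covid_filter_mode not in ("any", "all", "off"):
            raise ConfigError("covid_filter_mode must be 'any', 'all' or 'off'")
        return self
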