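"""Diagnosis, procedure and ATC code lists, with a shipped editable default.

The RTI definition rests on ICPC-2 diagnosis codes; the default list below
covers the standard ICPC-2 respiratory-infection codes plus acute otitis
media and the COVID-19 codes, and is a starting point users must confirm
against their own extract. Consultation mode is derived from reimbursement
procedure codes (the defaults use the Norwegian tariff codes 2ad for
in-person and 2ae for electronic consultations). Antibiotics are classified
from ATC codes: J01 systemic antibacterials plus vancomycin (A07AA09) and
metronidazole (P01AB01), with urinary-tract-only agents excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .config import ConfigError

__all__ = ["CodeListConfig", "default_codelist", "load_codelist", "save_codelist", "ATC_PATTERN"]

#: Lexical pattern of a full 7-character ATC code: L NN LL NN.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

_DEFAULT_RTI_ICPC2 = frozenset({
    # ICPC-2 chapter R infections (upper and lower respiratory tract)
    "R72",   # strep throat
    "R74",   # upper respiratory infection, acute
    "R75",   # sinusitis acute/chronic
    "R76",   # tonsillitis, acute
    "R77",   # laryngitis/tracheitis, acute
    "R78",   # acute bronchitis/bronchiolitis
    "R80",   # influenza
    "R81",   # pneumonia
    "R82",   # pleurisy/pleural effusion
    "R83",   # respiratory infection, other
    "H71",   # acute otitis media
    "R991",  # COVID-19, confirmed
    "R992",  # COVID-19, suspected
})

_DEFAULT_COVID_ICPC2 = frozenset({"R991", "R992"})

# procedure code -> mode; Norwegian tariff: 2ad in-person, 2ae e-consultation
_DEFAULT_PROCEDURE_CODES = {
    "2ad": "in_person",
    "2ak": "in_person",   # out-of-hours in-person consultation
    "2ae": "electronic",
    "2aek": "electronic",
}

_DEFAULT_ATC_EXCLUDED = frozenset({
    "J01CA08",  # pivmecillinam
    "J01CA11",  # mecillinam
    "J01EA01",  # trimethoprim
    "J01XE01",  # nitrofurantoin
    "J01XX05",  # methenamine
})

# longest-prefix wins; "other" covers the rest of J01 plus the two named
# non-J01 antibiotics
_DEFAULT_ATC_CLASS_MAP = {
    "J01CE01": "phenoxymethylpenicillin",
    "J01C": "other_penicillins",
    "J01A": "tetracyclines",
    "J01FA": "macrolides",
    "J01": "other",
    "A07AA09": "other",  # vancomycin
    "P01AB01": "other",  # metronidazole
}


@dataclass(frozen=True)
class CodeListConfig:
    rti_icpc2_codes: frozenset[str] = _DEFAULT_RTI_ICPC2
    covid_icpc2_codes: frozenset[str] = _DEFAULT_COVID_ICPC2
    consultation_procedure_codes: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_PROCEDURE_CODES))
    atc_excluded_codes: frozenset[str] = _DEFAULT_ATC_EXCLUDED
    atc_class_map: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_ATC_CLASS_MAP))
    unknown_procedure_policy: str = "reject"  # "reject" | "in_person"

    def validate(self) -> "CodeListConfig":
        if not self.covid_icpc2_codes <= self.rti_icpc2_codes:
            raise ConfigError("covid_icpc2_codes must be a subset of rti_icpc2_codes")
        bad_modes = set(self.consultation_procedure_codes.values()) - {"in_person", "electronic"}
        if bad_modes:
            raise ConfigError(f"procedure-code modes must be in_person/electronic, got {bad_modes}")
        allowed = {"phenoxymethylpenicillin", "other_penicillins",
                   "tetracyclines", "macrolides", "other"}
        if not set(self.atc_class_map.values()) <= allowed:
            raise ConfigError(f"unknown class labels: {set(self.atc_class_map.values()) - allowed}")
        overlap = self.atc_excluded_codes & set(self.atc_class_map)
        if overlap:
            raise ConfigError(f"codes both excluded and class-mapped: {overlap}")
        if self.unknown_procedure_policy not in ("reject", "in_person"):
            raise ConfigError("unknown_procedure_policy must be 'reject' or 'in_person'")
        return self

    @property
    def electronic_procedure_codes(self) -> frozenset[str]:
        return frozenset(c for c, m in self.consultation_procedure_codes.items()
                         if m == "electronic")


def default_codelist() -> CodeListConfig:
    return CodeListConfig().validate()


def load_codelist(path: str) -> CodeListConfig:
    """Load a code-list configuration from a YAML file.

    Any omitted key falls back to the shipped default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = CodeListConfig()
    kwargs = {}
    for key in ("rti_icpc2_codes", "covid_icpc2_codes", "atc_excluded_codes"):
        if key in raw:
            kwargs[key] = frozenset(raw[key])
    for key in ("consultation_procedure_codes", "atc_class_map"):
        if key in raw:
            kwargs[key] = dict(raw[key])
    if "unknown_procedure_policy" in raw:
        kwargs["unknown_procedure_policy"] = raw["unknown_procedure_policy"]
    merged = CodeListConfig(
        rti_icpc2_codes=kwargs.get("rti_icpc2_codes", base.rti_icpc2_codes),
        covid_icpc2_codes=kwargs.get("covid_icpc2_codes", base.covid_icpc2_codes),
        consultation_procedure_codes=kwargs.get(
            "consultation_procedure_codes", dict(base.consultation_procedure_codes)),
        atc_excluded_codes=kwargs.get("atc_excluded_codes", base.atc_excluded_codes),
        atc_class_map=kwargs.get("atc_class_map", dict(base.atc_class_map)),
        unknown_procedure_policy=kwargs.get(
            "unknown_procedure_policy", base.unknown_procedure_policy),
    )
    return merged.validate()


def save_codelist(codelist: CodeListConfig, path: str) -> None:
    payload = {
        "rti_icpc2_codes": sorted(codelist.rti_icpc2_codes),
        "covid_icpc2_codes": sorted(codelist.covid_icpc2_codes),
        "consultation_procedure_codes": dict(codelist.consultation_procedure_codes),
        "atc_excluded_codes": sorted(codelist.atc_excluded_codes),
        "atc_class_map": dict(codelist.atc_class_map),
        "unknown_procedure_policy": codelist.unknown_procedure_policy,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
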