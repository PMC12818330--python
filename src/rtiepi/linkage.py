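"""ATC classification of dispensings and linkage to RTI consultations.

A consultation counts as treated when an included antibiotic is dispensed to
the same patient within 7 days after it (both endpoints inclusive: lag 0 and
lag 7 link; the week-long window absorbs pharmacy closures around holidays).
An episode is treated when any of its consultations is. Each dispensing is
attributed to at most one consultation — the nearest preceding one, with
same-day ties broken toward the earlier-entered consultation — so treatment
counts are never double-counted; the episode-level treated flag is unaffected
by this choice.

Antibiotic classes: phenoxymethylpenicillin (J01CE01), other penicillins
(other J01C), tetracyclines (J01A), macrolides (J01FA, with azithromycin
J01FA10 flagged separately), and other (other J01, vancomycin A07AA09,
metronidazole P01AB01). Agents indicated only for urinary tract infections
are excluded before any class is assigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codelists import ATC_PATTERN, CodeListConfig
from .config import ANTIBIOTIC_CLASSES

__all__ = [
    "ClassificationError",
    "classify_antibiotic", "classify_dispensings",
    "link_treatments", "treatment_type_table",
    "EXCLUDED", "NOT_ANTIBIOTIC",
]

EXCLUDED = "excluded"
NOT_ANTIBIOTIC = "not_antibiotic"
AZITHROMYCIN_ATC = "J01FA10"


class ClassificationError(ValueError):
    """The ATC code is lexically malformed."""


def classify_antibiotic(atc_code: str, codelist: CodeListConfig) -> tuple[str, bool]:
    """Classify one ATC code.

    Returns ``(label, azithromycin_flag)`` where label is one of the five
    antibiotic classes, ``'excluded'`` (urinary-tract-only agents) or
    ``'not_antibiotic'``. Exclusion is checked before class matching;
    class matching is longest-prefix over the configured map.
    """
    code = atc_code.strip().upper()
    if not ATC_PATTERN.fullmatch(code):
        raise ClassificationError(f"malformed ATC code: {atc_code!r}")
    if code in codelist.atc_excluded_codes:
        return EXCLUDED, False
    best = max((p for p in codelist.atc_class_map if code.startswith(p)),
               key=len, default=None)
    if best is None:
        return NOT_ANTIBIOTIC, False
    return codelist.atc_class_map[best], code == AZITHROMYCIN_ATC


def classify_dispensings(dispensings: pd.DataFrame,
                         codelist: CodeListConfig) -> pd.DataFrame:
    """Vectorised classification; adds ``atc_class`` and ``azithromycin`` columns."""
    out = dispensings.copy()
    uniq = out["atc_code"].unique()
    table = {c: classify_antibiotic(c, codelist) for c in uniq}
    out["atc_class"] = out["atc_code"].map(lambda c: table[c][0])
    out["azithromycin"] = out["atc_code"].map(lambda c: table[c][1])
    return out


def link_treatments(episodes: pd.DataFrame, consult_map: pd.DataFrame,
                    dispensings: pd.DataFrame, codelist: CodeListConfig,
                    link_window_days: int = 7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Link classified dispensings to consultations and lift to episodes.

    Parameters
    ----------
    episodes, consult_map
        Output of :func:`rtiepi.episodes.build_episodes` (the consultation
        map must carry ``episode_id``).
    dispensings
        Dispensing table; classified on the fly if ``atc_class`` is absent.

    Returns
    -------
    (episodes, links)
        Episodes with ``treated`` and ``n_treatments`` columns, and a link
        table with one row per attributed dispensing (consultation date,
        lag in days, ATC code, class, azithromycin flag).
    """
    if "atc_class" not in dispensings.columns:
        dispensings = classify_dispensings(dispensings, codelist)
    usable = dispensings.loc[
        ~dispensings["atc_class"].isin([EXCLUDED, NOT_ANTIBIOTIC])].copy()

    episodes = episodes.copy()
    if episodes.empty or usable.empty:
        episodes["treated"] = pd.Series(False, index=episodes.index, dtype=bool)
        episodes["n_treatments"] = 0
        links = pd.DataFrame(columns=["patient_id", "consult_date", "dispensing_date",
                                      "lag_days", "atc_code", "atc_class",
                                      "azithromycin", "episode_id"])
        return episodes, links

    consults = consult_map[["patient_id", "date", "episode_id"]].copy()
    consults["consult_seq"] = np.arange(len(consults))
    # merge_asof takes the last equal-key row; sorting same-day consultations
    # by descending entry order makes the earliest-entered one win ties
    consults = consults.sort_values(["date", "consult_seq"],
                                    ascending=[True, False], kind="stable")
    usable = usable.sort_values("date", kind="stable")
    usable["dispensing_date"] = usable["date"]

    linked = pd.merge_asof(
        usable, consults.rename(columns={"date": "consult_date"}),
        left_on="date", right_on="consult_date",
        by="patient_id", direction="backward",
        tolerance=pd.Timedelta(days=link_window_days),
        allow_exact_matches=True)
    linked = linked.dropna(subset=["consult_date"])
    links = pd.DataFrame({
        "patient_id": linked["patient_id"],
        "consult_date": linked["consult_date"],
        "dispensing_date": linked["dispensing_date"],
        "lag_days": (linked["dispensing_date"] - linked["consult_date"]).dt.days,
        "atc_code": linked["atc_code"],
        "atc_class": linked["atc_class"],
        "azithromycin": linked["azithromycin"],
        "episode_id": linked["episode_id"].astype(int),
    }).reset_index(drop=True)

    counts = links.groupby("episode_id").size()
    episodes["n_treatments"] = episodes["episode_id"].map(counts).fillna(0).astype(int)
    episodes["treated"] = episodes["n_treatments"] > 0
    return episodes, links


def report_class(links: pd.DataFrame) -> pd.Series:
    """Six-way reporting class: macrolides split into azithromycin / other."""
    cls = links["atc_class"].copy()
    cls = cls.mask(links["azithromycin"], "azithromycin")
    cls = cls.mask((links["atc_class"] == "macrolides") & ~links["azithromycin"],
                   "other_macrolides")
    return cls


def treatment_type_table(links: pd.DataFrame,
                         windows: dict[str, tuple] | list[tuple]) -> pd.DataFrame:
    """Counts and column percentages of antibiotic type per calendar window.

    ``windows`` maps a column label to an inclusive ``(start, end)`` date
    pair (a list of pairs gets positional labels). Treatments are assigned
    to windows by the linked consultation date. Returns a table with the six
    type rows plus a ``Total`` row, and per window a count column
    ``n <label>`` and a percentage column ``% <label>`` (one decimal; blank
    for an empty window).
    """
    if isinstance(windows, list):
        windows = {f"w{i}": w for i, w in enumerate(windows)}
    cls = report_class(links)
    dates = pd.to_datetime(links["consult_date"])
    out = pd.DataFrame(index=list(ANTIBIOTIC_CLASSES) + ["Total"])
    for label, (start, end) in windows.items():
        in_win = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
        counts = cls[in_win].value_counts().reindex(ANTIBIOTIC_CLASSES, fill_value=0)
        total = int(counts.sum())
        out[f"n {label}"] = list(counts) + [total]
        if total > 0:
            pct = (100.0 * counts / total).round(1)
            out[f"% {label}"] = list(pct) + [100.0]
        else:
            out[f"% {label}"] = np.nan
    return out
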