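"""Monthly rate charts: episode rates and antibiotic-type distributions."""

from __future__ import annotations

from typing import Optional

import matplotlib
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .config import ANTIBIOTIC_CLASSES  # noqa: E402
from .linkage import report_class  # noqa: E402

__all__ = ["plot_monthly_rates", "plot_type_rates"]


def _month_axis(ax, months) -> None:
    step = max(1, len(months) // 12)
    ax.set_xticks(range(0, len(months), step))
    ax.set_xticklabels(list(months)[::step], rotation=45, ha="right")


def plot_monthly_rates(total_rates: pd.DataFrame,
                       treated_rates: Optional[pd.DataFrame] = None,
                       ax=None, path: Optional[str] = None):
    """Monthly RTI episode rates per 1000 inhabitants (optionally with the
    treated-episode rate as a second line)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    months = total_rates["month"]
    ax.plot(range(len(months)), total_rates["rate_per_1000"],
            label="RTI episodes", color="tab:blue")
    if treated_rates is not None:
        aligned = treated_rates.set_index("month").reindex(months)["rate_per_1000"]
        ax.plot(range(len(months)), aligned.values,
                label="with antibiotic treatment", color="tab:red")
    ax.set_ylabel("episodes per 1000 inhabitants / month")
    ax.legend()
    _month_axis(ax, months)
    ax.figure.tight_layout()
    if path:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def plot_type_rates(links: pd.DataFrame, population_by_month: pd.DataFrame,
                    ax=None, path: Optional[str] = None):
    """Monthly antibiotic treatments per 1000 inhabitants by antibiotic type."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    df = links.copy()
    df["month"] = pd.to_datetime(df["consult_date"]).dt.strftime("%Y-%m")
    df["type"] = report_class(df)
    pop = population_by_month.groupby("month")["count"].sum()
    counts = df.groupby(["month", "type"], observed=True).size().unstack(fill_value=0)
    counts = counts.reindex(columns=list(ANTIBIOTIC_CLASSES), fill_value=0)
    rates = counts.div(pop.reindex(counts.index), axis=0) * 1000.0
    for cls in ANTIBIOTIC_CLASSES:
        ax.plot(range(len(rates)), rates[cls], label=cls)
    ax.set_ylabel("treatments per 1000 inhabitants / month")
    ax.legend(fontsize="small")
    _month_axis(ax, rates.index)
    ax.figure.tight_layout()
    if path:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
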