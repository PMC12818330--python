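"""End-to-end orchestration: simulate or read, build, link, analyse, report.

``run_pipeline`` ties the stages together and writes every intermediate and
result table to the output directory, along with a JSON run manifest (config
hash, seed, row counts at every stage, rejection counts). Stage failures
raise :class:`StageError` carrying the stage name and a machine-readable
error code, which the CLI maps to distinct exit codes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict
import pandas as pd

from . import io as rio
from .codelists import default_codelist, load_codelist
from .config import PipelineConfig
from .episodes import build_episodes, flag_rti_consultations, label_episodes, \
    trim_boundary_months
from .linkage import link_treatments, treatment_type_table
from .rates import episode_rate, month_range, monthly_population, \
    yearly_characteristics
from .simulate import simulate_registry
from .stats import stratified_rr_table

__all__ = ["StageError", "run_pipeline", "make_report", "STAGE_EXIT_CODES"]

log = logging.getLogger("rtiepi")

STAGE_EXIT_CODES = {"config": 2, "io": 3, "episodes": 4, "linkage": 5,
                    "rates": 6, "stats": 7, "report": 8}


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _config_hash(config: PipelineConfig) -> str:
    fields = {k: v for k, v in asdict(config).items() if k != "output_dir"}
    payload = json.dumps(fields, default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _kv(stage: str, **kw) -> None:
    log.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kw.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    try:
        config.validate()
    except Exception as exc:
        raise StageError("config", "invalid_config", str(exc)) from exc
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "covid_filter": config.covid_filter_mode, "counts": {}}
    counts = manifest["counts"]

    try:
        codelist = (load_codelist(config.codelist_path)
                    if config.codelist_path else default_codelist())
    except Exception as exc:
        raise StageError("config", "bad_codelist", str(exc)) from exc

    # --- inputs ---------------------------------------------------------
    try:
        if config.scenario is not None:
            scenario = config.scenario.replace(seed=config.seed)
            persons, consultations, dispensings, truth = simulate_registry(
                scenario, config.period)
            consultations = consultations.drop(columns=["is_index"])
            rio.write_population(persons, os.path.join(out, "persons.csv"))
            rio.write_consultations(consultations,
                                    os.path.join(out, "consultations.csv"))
            rio.write_dispensings(dispensings, os.path.join(out, "dispensings.csv"))
            truth.to_json(os.path.join(out, "scenario_truth.json"))
            counts["rejected_rows"] = 0
        else:
            consultations, rej_c = rio.read_consultations(config.consultations_path)
            dispensings, rej_d = rio.read_dispensings(config.dispensings_path)
            persons, rej_p = rio.read_population(config.persons_path)
            counts["rejected_rows"] = int(len(rej_c) + len(rej_d) + len(rej_p))
            for name, rej in (("consultations", rej_c), ("dispensings", rej_d),
                              ("persons", rej_p)):
                if len(rej):
                    rej.to_csv(os.path.join(out, f"rejections_{name}.csv"), index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("io", "read_failed", str(exc)) from exc
    counts["persons"] = len(persons)
    counts["consultations"] = len(consultations)
    counts["dispensings"] = len(dispensings)
    _kv("io", persons=len(persons), consultations=len(consultations),
        dispensings=len(dispensings))

    # --- comparative path: trim, flag, episodes, label, link -------------
    try:
        trimmed = trim_boundary_months(consultations, config.period)
        rti, rej_proc = flag_rti_consultations(trimmed, codelist)
        episodes, consult_map = build_episodes(rti, config.chain_window_days)
        episodes = label_episodes(episodes, persons, config.period)
    except Exception as exc:
        raise StageError("episodes", "episode_build_failed", str(exc)) from exc
    counts["rti_consultations"] = len(rti)
    counts["procedure_rejections"] = len(rej_proc)
    counts["episodes"] = len(episodes)
    _kv("episodes", rti=len(rti), episodes=len(episodes))

    try:
        episodes, links = link_treatments(episodes, consult_map, dispensings,
                                          codelist, config.link_window_days)
    except Exception as exc:
        raise StageError("linkage", "link_failed", str(exc)) from exc
    counts["treatment_links"] = len(links)
    counts["treated_episodes"] = int(episodes["treated"].sum())
    _kv("linkage", links=len(links), treated=counts["treated_episodes"])

    episodes_out = episodes.copy()
    for c in ("index_date", "last_date"):
        episodes_out[c] = pd.to_datetime(episodes_out[c]).dt.strftime("%Y-%m-%d")
    episodes_out.to_csv(os.path.join(out, "episodes.csv"), index=False)
    consult_map.assign(date=lambda d: d["date"].dt.strftime("%Y-%m-%d")) \
        .to_csv(os.path.join(out, "consultation_episode_map.csv"), index=False)
    links_out = links.copy()
    for c in ("consult_date", "dispensing_date"):
        links_out[c] = pd.to_datetime(links_out[c]).dt.strftime("%Y-%m-%d")
    links_out.to_csv(os.path.join(out, "treatment_links.csv"), index=False)

    # --- rates path (untrimmed) ------------------------------------------
    try:
        rti_all, _ = flag_rti_consultations(consultations, codelist)
        ep_all, map_all = build_episodes(rti_all, config.chain_window_days)
        ep_all = label_episodes(ep_all, persons, config.period)
        ep_all, links_all = link_treatments(ep_all, map_all, dispensings,
                                            codelist, config.link_window_days)
        if len(ep_all):
            months = month_range(ep_all["index_date"].min(),
                                 ep_all["index_date"].max())
            pop = monthly_population(persons, months)
            rates = episode_rate(ep_all, pop)
            treated_rates = episode_rate(ep_all.loc[ep_all["treated"]], pop)
            rates.to_csv(os.path.join(out, "monthly_rates.csv"), index=False)
            table1 = yearly_characteristics(ep_all, persons)
            table1.to_csv(os.path.join(out, "table1_yearly_characteristics.csv"),
                          index=False)
        else:
            pop = rates = treated_rates = table1 = None
    except Exception as exc:
        raise StageError("rates", "rate_computation_failed", str(exc)) from exc

    # --- comparative statistics ------------------------------------------
    try:
        strat_paths = {}
        for strat in ("age_group", "service", "mode"):
            table = stratified_rr_table(episodes, strat, config.period,
                                        covid_filter=config.covid_filter_mode
                                        if config.covid_filter_mode != "off"
                                        else "off")
            meta = {k: v for k, v in table.attrs.items()}
            path = os.path.join(out, f"table2_rr_by_{strat}.csv")
            table.round(6).to_csv(path)
            with open(path.replace(".csv", ".json"), "w", encoding="utf-8") as fh:
                json.dump(meta, fh, indent=2, default=float)
            strat_paths[strat] = path
        years = sorted(pd.to_datetime(links["consult_date"]).dt.year.unique()) \
            if len(links) else []
        windows = {str(y): (f"{y}-03-12", f"{y}-04-12") for y in years}
        table3 = treatment_type_table(links, windows) if windows else None
        if table3 is not None:
            table3.to_csv(os.path.join(out, "table3_type_distribution.csv"))
    except Exception as exc:
        raise StageError("stats", "stat_computation_failed", str(exc)) from exc

    # --- charts ------------------------------------------------------------
    try:
        if rates is not None:
            from .plotting import plot_monthly_rates, plot_type_rates
            plot_monthly_rates(rates, treated_rates,
                               path=os.path.join(out, "fig1_monthly_rates.png"))
            if len(links_all):
                plot_type_rates(links_all, pop,
                                path=os.path.join(out, "fig2_type_rates.png"))
    except Exception as exc:
        raise StageError("report", "chart_failed", str(exc)) from exc

    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def make_report(output_dir: str) -> str:
    """Assemble a human-readable markdown report from pipeline outputs.

    Missing tables are listed as absent; the report is produced regardless.
    """
    sections = ["# RTI antibiotic treatment report", ""]
    manifest_path = os.path.join(output_dir, "manifest.json")
    if os.path.exists(manifest_path):
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
        sections.append(f"COVID filter mode: {manifest.get('covid_filter', 'off')}; "
                        f"config hash {manifest.get('config_hash')}; "
                        f"seed {manifest.get('seed')}.")
        sections.append("")

    named = [("Yearly characteristics", "table1_yearly_characteristics.csv"),
             ("Risk ratios by age group", "table2_rr_by_age_group.csv"),
             ("Risk ratios by service type", "table2_rr_by_service.csv"),
             ("Risk ratios by consultation mode", "table2_rr_by_mode.csv"),
             ("Antibiotic type distribution (12 Mar-12 Apr)",
              "table3_type_distribution.csv")]
    for title, fname in named:
        path = os.path.join(output_dir, fname)
        sections.append(f"## {title}")
        if not os.path.exists(path):
            sections.append("*absent*")
        else:
            df = pd.read_csv(path)
            sections.append(df.to_string(index=False))
            meta_path = path.replace(".csv", ".json")
            if os.path.exists(meta_path):
                with open(meta_path, encoding="utf-8") as fh:
                    meta = json.load(fh)
                if "heterogeneity_p" in meta:
                    p = meta["heterogeneity_p"]
                    sections.append(f"MH heterogeneity p-value: "
                                    f"{'<0.0001' if p < 1e-4 else f'{p:.4f}'}")
        sections.append("")
    for title, fname in [("Monthly episode rates", "fig1_monthly_rates.png"),
                         ("Monthly treatment types", "fig2_type_rates.png")]:
        path = os.path.join(output_dir, fname)
        sections.append(f"## {title}")
        sections.append(f"![{title}]({fname})" if os.path.exists(path) else "*absent*")
        sections.append("")
    report = "\n".join(sections)
    with open(os.path.join(output_dir, "report.md"), "w", encoding="utf-8") as fh:
        fh.write(report)
    return report
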