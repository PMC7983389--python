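"""End-to-end pipeline: simulate/load -> DDI -> decay fit -> rare-disease
flagging -> incidence modelling -> consolidated report.

Every stage reads and writes documented delimited tables, so any later
stage can be re-run from the on-disk intermediates alone, and an
identical (config, seed) pair reproduces every numeric report field.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codes import normalize_icd_code
from .config import RunConfig, ScenarioConfig
from .decay import LogLogisticFit, fit_loglogistic
from .diversity import diagnosis_count_summary, explode_codes, region_ddi_table
from .errors import DdikitError, FitFailureError
from .incidence import fit_all_groups, group_fit_table, sir_table
from .io import (
    DDI_FILE, read_cases, read_mapping, read_regions, write_dataset, write_table,
)
from .rare import flag_cases, group_region_counts, load_mapping, rd_proportion
from .synthetic import generate_scenario

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Consolidated results of one pipeline run."""

    dataset_summary: dict
    decay_fit: Optional[dict]
    sir_summary: dict
    group_fits: List[dict]
    group_summary: dict
    provenance: dict
    rd_proportion: float = float("nan")
    rd_percent: int = -1

    def to_dict(self) -> dict:
        return {
            "dataset_summary": self.dataset_summary,
            "rd_proportion": self.rd_proportion,
            "rd_percent": self.rd_percent,
            "decay_fit": self.decay_fit,
            "sir_summary": self.sir_summary,
            "group_fits": self.group_fits,
            "group_summary": self.group_summary,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True, default=_jsonable)

    def to_text(self) -> str:
        d = self.dataset_summary
        lines = [
            "ddikit run report",
            "=================",
            f"cases: {d.get('n_cases')}  regions: {d.get('n_regions')}  "
            f"distinct codes: {d.get('n_distinct_codes')}",
            f"diagnoses per case: median {d.get('diag_median')} "
            f"(IQR {d.get('diag_q1')}-{d.get('diag_q3')})",
            f"rare-disease cases: {self.rd_percent}% of all cases",
        ]
        if self.decay_fit:
            f = self.decay_fit
            lines += [
                "",
                "DDI decay (4-parameter log-logistic):",
                f"  DDI_low={f['ddi_low']:.3f}  DDI_up={f['ddi_up']:.3f}  "
                f"tau={f['tau']:.4f}/min  T_half={f['t_half']:.1f} min",
                f"  tangent threshold t* = {f['tangent_threshold']:.1f} min"
                + ("  [DEGENERATE]" if f.get("degenerate") else ""),
            ]
        lines += ["", f"incidence: {self.group_summary.get('headline', 'n/a')}"]
        return "\n".join(lines)


def _jsonable(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def validate_inputs(cases_path, regions_path, mapping_path=None) -> List[dict]:
    """Schema / integrity / normalizability checks; returns violations.

    Each violation is a dict with ``table``, ``row`` (0-based, -1 when
    table-level) and ``problem``.
    """
    violations: List[dict] = []
    try:
        cases = read_cases(cases_path)
        regions = read_regions(regions_path)
    except DdikitError as exc:
        return [{"table": "schema", "row": -1, "problem": str(exc)}]

    bad_pop = regions.index[regions["population"] <= 0]
    for i in bad_pop:
        violations.append({"table": "regions", "row": int(i),
                           "problem": f"population {regions.loc[i, 'population']} <= 0"})
    bad_t = regions.index[regions["travel_time_min"] < 0]
    for i in bad_t:
        violations.append({"table": "regions", "row": int(i),
                           "problem": "negative travel time"})
    dup = regions.index[regions["region_id"].duplicated()]
    for i in dup:
        violations.append({"table": "regions", "row": int(i),
                           "problem": "duplicate region_id"})

    known = set(regions["region_id"])
    orphan_rows = cases.index[~cases["region_id"].isin(known)]
    for i in orphan_rows[:100]:
        violations.append({"table": "cases", "row": int(i),
                           "problem": f"unknown region_id {cases.loc[i, 'region_id']}"})

    raw_codes = set(cases["main_dx"].unique())
    for joined in cases.loc[cases["addl_dx"].str.len() > 0, "addl_dx"].unique():
        raw_codes.update(joined.split(";"))
    for code in sorted(raw_codes):
        try:
            normalize_icd_code(code)
        except DdikitError as exc:
            violations.append({"table": "cases", "row": -1, "problem": str(exc)})

    if mapping_path is not None:
        try:
            mapping = read_mapping(mapping_path)
            load_mapping(mapping)
        except DdikitError as exc:
            violations.append({"table": "mapping", "row": -1, "problem": str(exc)})
    return violations


def _config_hash(run: RunConfig) -> str:
    payload = {
        "outdir": None,  # location does not affect results
        "scenario": run.scenario.to_flat_dict() if run.scenario else None,
        "input_dir": run.input_dir,
        "min_cases": run.min_cases,
        "weight_by_cases": run.weight_by_cases,
        "bootstrap": run.bootstrap,
        "alpha": run.alpha,
        "seed": run.seed,
    }
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(run: RunConfig) -> RunReport:
    """Execute every stage in order and write all outputs to run.outdir."""
    outdir = run.outdir
    os.makedirs(outdir, exist_ok=True)
    stage = "inputs"
    try:
        if run.scenario is not None:
            scenario = run.scenario
            if scenario.seed != run.seed:
                scenario = ScenarioConfig.from_flat_dict(
                    {**scenario.to_flat_dict(), "seed": run.seed}
                )
            logger.info("[simulate] generating scenario (seed=%d)", scenario.seed)
            ds = generate_scenario(scenario)
            write_dataset(ds, outdir)
            cases, regions, mapping_tab = ds.cases, ds.regions, ds.mapping
        else:
            logger.info("[load] reading input tables from %s", run.input_dir)
            cases = read_cases(os.path.join(run.input_dir, "cases.csv"))
            regions = read_regions(os.path.join(run.input_dir, "regions.csv"))
            mapping_tab = read_mapping(os.path.join(run.input_dir, "mapping.csv"))

        stage = "ddi"
        logger.info("[ddi] computing per-region diversity")
        ddi = region_ddi_table(cases, regions, min_cases=run.min_cases)
        write_table(ddi, os.path.join(outdir, DDI_FILE))
        diag = diagnosis_count_summary(cases)
        long = explode_codes(cases)
        n_distinct = int(long["code"].nunique())

        stage = "decay_fit"
        logger.info("[decay] fitting log-logistic model")
        merged = ddi.merge(regions, on="region_id")
        pts = merged[["travel_time_min", "H"]].to_numpy()
        weights = merged["n_cases"].to_numpy(float) if run.weight_by_cases else None
        fit: Optional[LogLogisticFit]
        try:
            fit = fit_loglogistic(pts, weights=weights)
        except FitFailureError as exc:
            fit = exc.best
            logger.warning("[decay] fit did not converge; best attempt retained")
        fit_dict = fit.to_dict() if fit is not None else None
        if fit_dict is not None:
            with open(os.path.join(outdir, "decay_fit.json"), "w") as fh:
                json.dump(fit_dict, fh, indent=1, sort_keys=True, default=_jsonable)

        stage = "rare_disease"
        logger.info("[rd] flagging rare-disease cases")
        mapping = load_mapping(mapping_tab)
        flags = flag_cases(cases, mapping)
        frac, pct = rd_proportion(flags)
        counts = group_region_counts(flags, cases, regions, mapping)
        write_table(counts, os.path.join(outdir, "group_region_counts.csv"))

        stage = "incidence"
        logger.info("[incidence] SIR and Poisson travel-time models")
        sirs = sir_table(counts, regions)
        write_table(sirs, os.path.join(outdir, "sir.csv"))
        fits, gsummary = fit_all_groups(counts, regions, alpha=run.alpha)
        gtable = group_fit_table(fits)
        write_table(gtable, os.path.join(outdir, "group_fits.csv"))

        stage = "report"
        all_sir = sirs[sirs["group_label"] == "ALL"]["sir"]
        report = RunReport(
            dataset_summary={
                "n_cases": int(len(cases)),
                "n_regions": int(len(regions)),
                "n_regions_analyzed": int(len(ddi)),
                "n_distinct_codes": n_distinct,
                "diag_median": diag.median,
                "diag_q1": diag.q1,
                "diag_q3": diag.q3,
            },
            rd_proportion=frac,
            rd_percent=pct,
            decay_fit=fit_dict,
            sir_summary={
                "mean_sir_all": float(all_sir.mean()) if len(all_sir) else float("nan"),
                "n_rows": int(len(sirs)),
            },
            group_fits=[f.to_dict() for f in fits],
            group_summary=gsummary,
            provenance={
                "version": __version__,
                "seed": run.seed,
                "config_hash": _config_hash(run),
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "mapping_summary": mapping.summary(),
            },
        )
        report.to_json(os.path.join(outdir, "report.json"))
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(report.to_text() + "\n")

        if run.make_plots:
            stage = "plots"
            try:
                plot_outputs(report, merged, gtable, outdir)
            except Exception as exc:  # plotting is never fatal
                logger.warning("[plots] failed: %s", exc)
        return report
    except Exception as exc:
        raise DdikitError(f"pipeline aborted in stage {stage!r}: {exc}") from exc


def plot_outputs(report: RunReport, ddi_points: pd.DataFrame,
                 group_table: pd.DataFrame, outdir) -> List[str]:
    """DDI-vs-travel-time figure and per-group rate-ratio forest plot.

    Alongside each PNG a small CSV with the exact plotted values is
    written, so figure content is diffable across runs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    fit = report.decay_fit
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(ddi_points["travel_time_min"], ddi_points["H"], s=8, alpha=0.4,
               label="regions")
    curve_df = None
    if fit is not None:
        from .decay import LogLogisticParams, loglogistic_value
        params = LogLogisticParams(fit["ddi_low"], fit["ddi_up"], fit["tau"], fit["t_half"])
        tg = np.linspace(ddi_points["travel_time_min"].min(),
                         ddi_points["travel_time_min"].max(), 200)
        yg = loglogistic_value(tg, params)
        ax.plot(tg, yg, color="C1", label="log-logistic fit")
        thr = fit["tangent_threshold"]
        if np.isfinite(thr):
            ax.axvline(thr, color="C3", ls="--",
                       label=f"threshold t* = {thr:.1f} min")
        curve_df = pd.DataFrame({"t": tg, "ddi_fit": yg,
                                 "tangent_threshold": thr})
    ax.set_xlabel("travel time to nearest tertiary hospital (min)")
    ax.set_ylabel("diagnostic diversity index H (nats)")
    ax.legend()
    fig.tight_layout()
    p = os.path.join(outdir, "ddi_decay.png")
    fig.savefig(p, dpi=120)
    plt.close(fig)
    made.append(p)
    if curve_df is not None:
        curve_path = os.path.join(outdir, "ddi_decay_curve.csv")
        curve_df.to_csv(curve_path, index=False)
        made.append(curve_path)

    if group_table is not None and len(group_table):
        gt = group_table.sort_values("group_label")
        lo = np.exp(10 * (gt["beta1"] - 1.96 * gt["se_beta1"]))
        hi = np.exp(10 * (gt["beta1"] + 1.96 * gt["se_beta1"]))
        y = np.arange(len(gt))
        fig, ax = plt.subplots(figsize=(7, max(4, 0.22 * len(gt))))
        ax.hlines(y, lo, hi, color="0.6")
        ax.plot(gt["rate_ratio_per_10min"], y, "o", ms=4,
                color="C0")
        ax.axvline(1.0, color="C3", ls=":")
        ax.set_yticks(y)
        ax.set_yticklabels(gt["group_label"], fontsize=7)
        ax.set_xlabel("incidence rate ratio per 10 min travel time")
        fig.tight_layout()
        p = os.path.join(outdir, "group_rate_ratios.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
        forest = gt[["group_label", "rate_ratio_per_10min"]].copy()
        forest["ci_low"], forest["ci_high"] = lo.to_numpy(), hi.to_numpy()
        fp = os.path.join(outdir, "group_rate_ratios.csv")
        forest.to_csv(fp, index=False)
        made.append(fp)
    return made
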