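"""End-to-end analysis pipeline and report assembly.

Stage order mirrors a standard two-sample MR workflow: read both summary
tables, filter the exposure to genome-wide significance, harmonize to
the exposure effect allele (dropping palindromes), LD-clump when an LD
table is supplied, compute instrument QC and drop weak instruments,
exclude instruments with genome-wide-significant outcome associations,
then estimate (IVW, MR-Egger, weighted median), run heterogeneity and
sensitivity diagnostics (leave-one-out, MR-PRESSO), and finish with an
analytical power evaluation.  Every exclusion is counted in a
provenance trail so the final instrument count is fully auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import HeterogeneityResult, MrEstimate, egger, ivw, weighted_median
from .exceptions import PipelineAbort
from .power import PowerParams, mr_power_continuous
from .qc import compute_qc, filter_weak
from .sensitivity import LooResult, PressoResult, leave_one_out, presso
from .sumstats import (
    LdTable,
    exclude_outcome_associated,
    filter_significant,
    harmonize,
    ld_clump,
    read_sumstats,
)

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = ["method", "estimate", "se", "ci_low", "ci_high", "pval",
                    "n_snps", "residual_scale"]


@dataclass
class RunConfig:
    """All thresholds and inputs of one pipeline run."""

    exposure_path: str
    outcome_path: str
    outcome_label: str = "outcome"
    ld_path: str | None = None
    n_exposure: float = 9639
    n_outcome: float | None = None
    p_instrument: float = 5e-8
    r2_max: float = 0.3
    window: float = 10_000_000
    f_min: float = 10.0
    p_outcome_exclude: float = 5e-8
    alpha: float = 0.05
    palindrome_policy: str = "drop"
    wm_boot: int = 1000
    presso_sim: int = 1000
    seed: int = 42
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Everything one pipeline run produced, ready for serialization."""

    config: RunConfig
    qc: pd.DataFrame
    estimates: pd.DataFrame
    heterogeneity: HeterogeneityResult
    loo: LooResult
    presso: PressoResult
    power: dict | None
    provenance: dict


def _estimates_frame(results: list[MrEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=ESTIMATE_COLUMNS)


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis; deterministic given ``config.seed``."""
    prov: dict = {"version": __version__, "seed": config.seed,
                  "outcome_label": config.outcome_label, "stages": []}

    def stage(name: str, n_before: int, n_after: int) -> None:
        prov["stages"].append({"stage": name, "n_before": n_before, "n_after": n_after})
        logger.info("stage %s: %d -> %d instruments", name, n_before, n_after)

    def ensure(n: int, name: str) -> None:
        if n < 3:
            raise PipelineAbort(
                f"stage {name!r} left {n} instrument(s); at least 3 are needed"
            )

    exposure = read_sumstats(config.exposure_path, column_map=config.exposure_columns)
    outcome = read_sumstats(config.outcome_path, column_map=config.outcome_columns)
    stage("read_exposure", len(exposure), len(exposure))

    sig = filter_significant(exposure, config.p_instrument)
    stage("significance_filter", len(exposure), len(sig))
    ensure(len(sig), "significance_filter")

    if config.ld_path:
        ld = LdTable.from_tsv(config.ld_path)
        window = config.window if all(r.pos is not None for r in sig) else None
        clumped = ld_clump(sig, ld, r2_max=config.r2_max, window=window)
    else:
        clumped = sig
    stage("ld_clump", len(sig), len(clumped))
    ensure(len(clumped), "ld_clump")

    instruments = harmonize(clumped, outcome, palindrome_policy=config.palindrome_policy)
    stage("harmonize", len(clumped), len(instruments))
    ensure(len(instruments), "harmonize")

    qc = compute_qc(instruments, config.n_exposure, f_min=config.f_min)
    strong, weak = filter_weak(instruments, qc, f_min=config.f_min)
    stage("weak_instrument_filter", len(instruments), len(strong))
    ensure(len(strong), "weak_instrument_filter")

    kept, excluded = exclude_outcome_associated(strong, config.p_outcome_exclude)
    stage("outcome_association_filter", len(strong), len(kept))
    ensure(len(kept), "outcome_association_filter")
    prov["excluded_outcome_associated"] = list(excluded["snp_id"])
    prov["dropped_weak"] = list(weak["snp_id"])
    prov["analysis_snp_ids"] = list(kept["snp_id"])

    ivw_res, het = ivw(kept)
    slope, intercept = egger(kept)
    wm = weighted_median(kept, n_boot=config.wm_boot, seed=config.seed)
    estimates = _estimates_frame([ivw_res, slope, intercept, wm])

    loo = leave_one_out(kept, alpha=config.alpha)
    pr = presso(kept, n_sim=config.presso_sim, seed=config.seed)

    power = None
    if config.n_outcome:
        r2_total = float(qc.loc[qc["snp_id"].isin(kept["snp_id"]), "r2"].sum())
        power = {
            "n_outcome": config.n_outcome,
            "r2_total": r2_total,
            "beta_std": ivw_res.estimate,
            "power_at_ivw_estimate": mr_power_continuous(
                PowerParams(config.n_outcome, r2_total, ivw_res.estimate, config.alpha)
            ),
        }

    return AnalysisReport(config=config, qc=qc, estimates=estimates, heterogeneity=het,
                          loo=loo, presso=pr, power=power, provenance=prov)


def render_forest_data(report: AnalysisReport) -> pd.DataFrame:
    """Plot-ready (label, estimate, ci_low, ci_high) rows: one per causal
    estimator (intercept excluded) followed by one per leave-one-out fit."""
    rows = [
        {"label": r.method, "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in (MrEstimate(**rec) for rec in report.estimates.to_dict("records"))
        if r.method != "egger_intercept"
    ]
    rows += [
        {"label": f"loo:{rec.snp_id}", "estimate": rec.estimate,
         "ci_low": rec.ci_low, "ci_high": rec.ci_high}
        for rec in report.loo.table.itertuples(index=False)
    ]
    return pd.DataFrame(rows, columns=["label", "estimate", "ci_low", "ci_high"])


def format_value(x: float) -> str:
    """Report formatting: 4 significant figures, scientific below 1e-3."""
    if x == 0:
        return "0"
    return f"{x:.3e}" if abs(x) < 1e-3 else f"{x:.4g}"


def report_to_dict(report: AnalysisReport) -> dict:
    return {
        "config": dataclasses.asdict(report.config),
        "qc": report.qc.to_dict("records"),
        "estimates": report.estimates.to_dict("records"),
        "heterogeneity": dataclasses.asdict(report.heterogeneity),
        "leave_one_out": {
            "table": report.loo.table.to_dict("records"),
            "flags": report.loo.flags,
            "alpha": report.loo.alpha,
        },
        "presso": dataclasses.asdict(report.presso),
        "power": report.power,
        "provenance": report.provenance,
    }


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Write the report bundle: report.json plus estimates/qc/loo/forest TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.estimates.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    report.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    report.loo.table.to_csv(outdir / "loo.tsv", sep="\t", index=False)
    render_forest_data(report).to_csv(outdir / "forest.tsv", sep="\t", index=False)
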