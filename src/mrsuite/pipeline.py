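"""End-to-end two-sample MR pipeline with a human-readable report.

Stage order mirrors the standard workflow: significance filtering ->
LD clumping -> confounder-trait exclusion -> harmonization ->
outlier screening (MR-PRESSO) -> causal estimation -> sensitivity
diagnostics.  Every stage logs its in/out counts and every drop carries
a reason, so the report can account for each candidate instrument.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from .harmonize import harmonize_datasets
from .instruments import (
    TabularLDSource,
    clump,
    exclude_pleiotropic_traits,
    filter_significant,
    read_ld_tsv,
    read_trait_catalog,
)
from .presso import PressoResult, presso
from .simulate import ScenarioConfig, generate, make_trait_catalog
from .summary_io import instruments_to_frame, read_harmonized, read_summary

__all__ = ["PipelineError", "PipelineResult", "DEFAULT_CONFIG", "run_pipeline"]

ALL_METHODS = ["ivw", "egger", "simple-median", "weighted-median", "raps",
               "presso"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 6,
    "p_threshold": 5e-8,
    "clump": {"r2": 0.001, "kb": 10, "missing_ld": "remove"},
    "palindrome_maf": 0.3,
    "palindromic_action": "align",
    "trait_p_threshold": 5e-8,
    "methods": list(ALL_METHODS),
    "n_boot": 1000,
    "presso_n_sim": 1000,
    "presso_alpha": 0.05,
    "remove_presso_outliers": True,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: dict[str, Any]
    counts: dict[str, int]
    results: pd.DataFrame
    heterogeneity: pd.DataFrame
    egger_intercept: pd.DataFrame
    loo: pd.DataFrame
    funnel: pd.DataFrame
    scatter: pd.DataFrame
    drop_log: pd.DataFrame
    exclusion_log: pd.DataFrame
    presso_result: PressoResult | None = None
    instruments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def report(self) -> str:
        lines = ["# Two-sample MR report", "", "## Configuration", "",
                 "```yaml", yaml.safe_dump(self.config, sort_keys=True).rstrip(),
                 "```", "", "## Instrument accounting", ""]
        for stage, n in self.counts.items():
            lines.append(f"- {stage}: {n}")
        lines += ["", "## Causal estimates", "", "```",
                  self.results.to_string(index=False), "```", ""]
        if not self.egger_intercept.empty:
            lines += ["## Egger intercept (directional pleiotropy)", "", "```",
                      self.egger_intercept.to_string(index=False), "```", ""]
        lines += ["## Heterogeneity", "", "```",
                  self.heterogeneity.to_string(index=False), "```", ""]
        if self.presso_result is not None:
            pr = self.presso_result
            lines += [
                "## MR-PRESSO",
                "",
                f"- global test p = {pr.global_p:.4g} "
                f"(RSS = {pr.rss_observed:.6g}, {pr.n_sim} simulations, "
                f"seed {pr.seed})",
                f"- outliers: {', '.join(pr.outliers) if pr.outliers else 'none'}",
            ]
            if pr.distortion_pct is not None:
                lines.append(
                    f"- distortion: {pr.distortion_pct:.2f}% "
                    f"(p = {pr.distortion_p:.4g})"
                )
            lines.append("")
        if not self.loo.empty:
            flagged = self.loo[self.loo["influential"]]
            lines += ["## Leave-one-out", "",
                      f"- influential omissions: "
                      f"{', '.join(flagged['omitted']) if len(flagged) else 'none'}",
                      ""]
        if len(self.drop_log):
            lines += ["## Harmonization drops", "", "```",
                      self.drop_log.to_string(index=False), "```", ""]
        if len(self.exclusion_log):
            lines += ["## Trait-screen exclusions", "", "```",
                      self.exclusion_log.to_string(index=False), "```", ""]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outdir / "results.tsv", sep="\t", index=False)
        self.heterogeneity.to_csv(outdir / "heterogeneity.tsv", sep="\t",
                                  index=False)
        self.loo.to_csv(outdir / "loo.tsv", sep="\t", index=False)
        self.funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
        self.scatter.to_csv(outdir / "scatter.tsv", sep="\t", index=False)
        (outdir / "report.md").write_text(self.report())


def _merge_config(config: dict[str, Any] | None) -> dict[str, Any]:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _load_inputs(cfg):
    if "scenario" in cfg:
        scen_kwargs = dict(cfg["scenario"] or {})
        if "eaf_range" in scen_kwargs:
            scen_kwargs["eaf_range"] = tuple(scen_kwargs["eaf_range"])
        if scen_kwargs.get("ld_blocks") is not None:
            scen_kwargs["ld_blocks"] = tuple(scen_kwargs["ld_blocks"])
        scen_kwargs.setdefault("seed", cfg["seed"])
        study = generate(ScenarioConfig(**scen_kwargs))
        exposure, outcome, ld = study.exposure, study.outcome, study.ld
        catalog = None
        frac = cfg.get("confounder_fraction", 0.0)
        if frac:
            catalog = make_trait_catalog(exposure, frac, seed=cfg["seed"])
        return exposure, outcome, ld, catalog
    exposure = read_summary(cfg["exposure"], cfg.get("exposure_columns"))
    outcome = read_summary(cfg["outcome"], cfg.get("outcome_columns"))
    ld = read_ld_tsv(cfg["ld"]) if cfg.get("ld") else TabularLDSource()
    catalog = None
    if cfg.get("trait_catalog"):
        catalog = read_trait_catalog(cfg["trait_catalog"],
                                     cfg.get("excluded_traits", []))
    return exposure, outcome, ld, catalog


def _estimate_row(estimate: est.MREstimate) -> dict[str, Any]:
    return {
        "method": estimate.method,
        "n_snps": estimate.n_snps,
        "beta": estimate.beta,
        "se": estimate.se,
        "or": estimate.or_point,
        "ci_low": estimate.ci95[0],
        "ci_high": estimate.ci95[1],
        "pval": estimate.pval,
    }


def _het_row(label: str, het: est.HeterogeneityResult) -> dict[str, Any]:
    return {"stage": label, "Q": het.q, "df": het.df, "pval": het.pval,
            "I2": het.i2}


def run_pipeline(config: dict[str, Any] | None = None) -> PipelineResult:
    """Execute the full pipeline described by ``config``.

    ``config`` overrides :data:`DEFAULT_CONFIG`; inputs come either from
    a ``scenario`` block (synthetic generation) or from ``exposure`` /
    ``outcome`` file paths.  Any stage failure raises
    :class:`PipelineError` naming the stage; no partial outputs are
    written.
    """
    cfg = _merge_config(config)
    seed = cfg["seed"]
    methods = list(cfg["methods"])
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise PipelineError("config", ValueError(f"unknown methods {sorted(unknown)}"))

    counts: dict[str, int] = {}

    if cfg.get("harmonized"):
        try:
            harmonized = read_harmonized(cfg["harmonized"])
        except Exception as exc:
            raise PipelineError("load", exc) from exc
        drops = []
        exclusion_rows: list[tuple[str, str, float]] = []
        counts["harmonized"] = len(harmonized)
        if len(harmonized) < 3:
            raise PipelineError(
                "load",
                ValueError(f"only {len(harmonized)} instruments in input"))
        frame = instruments_to_frame(harmonized)
        return _run_analysis(cfg, seed, methods, counts, frame, drops,
                             exclusion_rows)

    try:
        exposure, outcome, ld, catalog = _load_inputs(cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", exc) from exc
    counts["exposure variants"] = len(exposure)

    try:
        selected = filter_significant(exposure, cfg["p_threshold"])
        counts["genome-wide significant"] = len(selected)
        selected = clump(selected, ld, r2_threshold=cfg["clump"]["r2"],
                         window_bp=int(cfg["clump"]["kb"] * 1000),
                         missing_ld=cfg["clump"].get("missing_ld", "remove"))
        counts["after LD clumping"] = len(selected)
        exclusion_rows: list[tuple[str, str, float]] = []
        if catalog is not None:
            selected, exclusion_rows = exclude_pleiotropic_traits(
                selected, catalog, cfg["trait_p_threshold"])
        counts["after trait screen"] = len(selected)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("select", exc) from exc

    try:
        harmonized, drops = harmonize_datasets(
            selected, outcome, maf_threshold=cfg["palindrome_maf"],
            palindromic_action=cfg["palindromic_action"])
        counts["harmonized"] = len(harmonized)
    except Exception as exc:
        raise PipelineError("harmonize", exc) from exc
    if len(harmonized) < 3:
        raise PipelineError(
            "harmonize",
            ValueError(f"only {len(harmonized)} instruments harmonized"))
    frame = instruments_to_frame(harmonized)
    return _run_analysis(cfg, seed, methods, counts, frame, drops,
                         exclusion_rows)


def _run_analysis(cfg, seed, methods, counts, frame, drops, exclusion_rows):
    """Shared back half: outlier screen, estimation, diagnostics."""
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(3).astype(np.int64) % (2**31)
    seed_simple, seed_weighted, seed_presso = (int(s) for s in sub)

    presso_result = None
    final = frame
    try:
        het_rows = [_het_row("pre-outlier-removal", est.heterogeneity(frame))]
        if "presso" in methods and len(frame) >= 4:
            presso_result = presso(frame, n_sim=cfg["presso_n_sim"],
                                   seed=seed_presso,
                                   outlier_alpha=cfg["presso_alpha"])
            if presso_result.outliers and cfg["remove_presso_outliers"]:
                final = frame[~frame["rsid"].isin(presso_result.outliers)]
                final = final.reset_index(drop=True)
        counts["after outlier removal"] = len(final)
        het_rows.append(_het_row("post-outlier-removal",
                                 est.heterogeneity(final)))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("presso", exc) from exc

    rows = []
    egger_rows = []
    try:
        for method in methods:
            if method == "ivw":
                estimate, _ = est.ivw_mre(final)
                rows.append(_estimate_row(estimate))
            elif method == "egger":
                result = est.egger(final)
                rows.append(_estimate_row(result.slope))
                egger_rows.append({
                    "intercept": result.intercept,
                    "se": result.intercept_se,
                    "ci_low": result.intercept_ci[0],
                    "ci_high": result.intercept_ci[1],
                    "pval": result.intercept_pval,
                })
            elif method == "simple-median":
                rows.append(_estimate_row(est.median_estimators(
                    final, kind="simple", n_boot=cfg["n_boot"],
                    seed=seed_simple)))
            elif method == "weighted-median":
                rows.append(_estimate_row(est.median_estimators(
                    final, kind="weighted", n_boot=cfg["n_boot"],
                    seed=seed_weighted)))
            elif method == "raps":
                rows.append(_estimate_row(est.raps(final)))
            elif method == "presso" and presso_result is not None:
                if presso_result.corrected is not None:
                    row = _estimate_row(presso_result.corrected)
                    row["method"] = "presso"
                    rows.append(row)
    except Exception as exc:
        raise PipelineError("estimate", exc) from exc

    try:
        loo = diag.leave_one_out(final).table
        funnel_points, funnel_lines = diag.funnel_data(final)
        funnel = funnel_points.merge(
            funnel_lines.rename(columns={"beta": "line_beta"}), how="cross")
        scatter_points, scatter_lines = diag.scatter_data(final)
        scatter = scatter_points.merge(scatter_lines, how="cross")
    except Exception as exc:
        raise PipelineError("diagnostics", exc) from exc

    return PipelineResult(
        config=cfg,
        counts=counts,
        results=pd.DataFrame(rows),
        heterogeneity=pd.DataFrame(het_rows),
        egger_intercept=pd.DataFrame(egger_rows),
        loo=loo,
        funnel=funnel,
        scatter=scatter,
        drop_log=pd.DataFrame(
            [(d.rsid, d.reason) for d in drops], columns=["rsid", "reason"]),
        exclusion_log=pd.DataFrame(
            exclusion_rows, columns=["rsid", "trait", "pval"]),
        presso_result=presso_result,
        instruments=final,
    )
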