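"""End-to-end orchestration of the two-stage causal screen.

Simulate (or load) inputs, QC the summary statistics, clump instruments
against the LD panel, run the cohort GRS scan, validate with the
two-sample MR estimator suite plus sensitivity analyses, fit the
multivariable MR model on the jointly significant metabolites, test
pathway enrichment, and write a consolidated, deterministic report bundle.
Every stage's output is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .grs_association import grs_scan
from .instruments import clump, harmonize, instrument_strength, qc_filter
from .io_formats import (PathwayLibrary, ValidationError, write_gmt,
                         write_results_table, write_summary_stats)
from .mr_core import run_all_methods
from .mr_sensitivity import leave_one_out, mr_presso, reverse_mr, threshold_grid
from .mvmr import build_multi_panel, mvmr_wls
from .pathway import enrich_report
from .synthetic_data import SimConfig, simulate_cohort, simulate_ld_panel, \
    simulate_two_sample_gwas

log = logging.getLogger("metabomr.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline run depends on, in one place.

    Defaults reproduce the selection thresholds of the study design:
    clumping at p < 1e-5, r² 0.1 within 500 kb; the reverse direction at
    the genome-wide 5e-8; GRS Bonferroni over 486 tests; pathway
    significance 0.10 on metabolites with p < 0.05.
    """

    n_metabolites: int = 4
    causal_betas: tuple[float, ...] = (0.2, -0.15, 0.0, 0.0)
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_snps=40, n_samples_cohort=5000, n_samples_panel=1000))
    clump_p: float = 1e-5
    clump_r2: float = 0.1
    clump_window_kb: float = 500.0
    reverse_p: float = 5e-8
    grs_alpha: float = 0.05
    grs_m_tests: int = 486
    mr_methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "mode")
    q_alpha: float = 0.05
    n_boot: int = 500
    presso_n_sim: int = 1000
    presso_sig: float = 0.05
    grid_p: tuple[float, ...] = (1e-5, 1e-4)
    grid_r2: tuple[float, ...] = (0.05, 0.1)
    pathway_p_cutoff: float = 0.05
    pathway_alpha: float = 0.10
    seed: int = 1
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if len(self.causal_betas) != self.n_metabolites:
            raise ValidationError("causal_betas length must equal n_metabolites")
        for p in (self.clump_p, self.reverse_p, self.grs_alpha,
                  self.pathway_p_cutoff, self.pathway_alpha, self.q_alpha):
            if not (0 < p <= 1):
                raise ValidationError(f"threshold {p} outside (0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("causal_betas", "mr_methods", "grid_p", "grid_r2"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "ld_blocks" in sim_raw and isinstance(sim_raw["ld_blocks"], list):
            sim_raw["ld_blocks"] = tuple(tuple(b) for b in sim_raw["ld_blocks"])
        if "maf_range" in sim_raw and isinstance(sim_raw["maf_range"], list):
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        return cls(sim=SimConfig(**sim_raw), **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _toy_library(metabolites: Sequence[str], causal_betas: Sequence[float]
                 ) -> PathwayLibrary:
    """Synthetic pathway library over the simulated metabolites.

    Groups causal and non-causal metabolites so that enrichment has signal
    to find; a real run would load an SMPDB/KEGG-style GMT instead.
    """
    causal = [m for m, b in zip(metabolites, causal_betas) if b != 0]
    null = [m for m, b in zip(metabolites, causal_betas) if b == 0]
    pathways: dict[str, frozenset[str]] = {}
    if causal:
        pathways["causal_module"] = frozenset(causal)
    if null:
        pathways["background_module"] = frozenset(null)
    pathways["all_measured"] = frozenset(metabolites)
    return PathwayLibrary(pathways=pathways,
                          descriptions={k: "synthetic" for k in pathways})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  Rerun
    with the same config and seed is byte-identical, which the manifest
    records as a SHA-256 over all written artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "metabomr", "version": __version__,
        "seed": config.seed, "config": config.to_jsonable(),
        "stages": {},
    }
    mets = [f"met{k + 1}" for k in range(config.n_metabolites)]
    stage = "simulate"
    try:
        sims = {}
        for k, met in enumerate(mets):
            cfg = dataclasses.replace(
                config.sim, true_beta=config.causal_betas[k],
                seed=config.seed * 1000 + k)
            exposure, outcome, truth = simulate_two_sample_gwas(cfg)
            sims[met] = (cfg, exposure, outcome, truth)
            write_summary_stats(exposure, out / f"exposure_{met}.tsv")
            write_summary_stats(outcome, out / f"outcome_{met}.tsv")
        panel_ids, panel_dosages = simulate_ld_panel(
            dataclasses.replace(config.sim, seed=config.seed))
        causal_idx = next((k for k, b in enumerate(config.causal_betas) if b != 0), 0)
        cohort_cfg, cohort_truth = sims[mets[causal_idx]][0], sims[mets[causal_idx]][3]
        cohort, _ = simulate_cohort(cohort_cfg, cohort_truth.gamma,
                                    mafs=cohort_truth.maf)
        manifest["stages"][stage] = {
            "n_metabolites": len(mets), "n_snps": config.sim.n_snps,
            "n_cohort": cohort.n_samples,
        }

        stage = "qc"
        qc_kept = {}
        for met in mets:
            _, exposure, outcome, _ = sims[met]
            kept_x, log_x = qc_filter(exposure)
            kept_y, log_y = qc_filter(outcome)
            qc_kept[met] = (kept_x, kept_y)
            for rule, n in {**log_x}.items():
                if n:
                    log.info("qc drop %s exposure %s: %d", met, rule, n)
        manifest["stages"][stage] = {
            met: {"exposure_kept": len(kx), "outcome_kept": len(ky)}
            for met, (kx, ky) in qc_kept.items()}

        stage = "clump"
        instruments = {}
        for met in mets:
            kept_x, _ = qc_kept[met]
            index_ids, clog = clump(kept_x, panel_dosages, panel_ids,
                                    p_thresh=config.clump_p,
                                    r2_thresh=config.clump_r2,
                                    window_kb=config.clump_window_kb)
            by_id = {r.snp_id: r for r in kept_x}
            instruments[met] = [by_id[s] for s in index_ids]
            log.info("clump %s: %d candidates -> %d index SNPs", met,
                     clog["n_candidates"], len(index_ids))
        manifest["stages"][stage] = {met: len(instruments[met]) for met in mets}
        strength_rows = []
        for met in mets:
            if instruments[met]:
                rep = instrument_strength(instruments[met],
                                          config.sim.n_samples_exposure)
                strength_rows.append({
                    "metabolite": met, "n_snp": len(rep.snp_ids),
                    "mean_f": rep.mean_f, "total_pve": rep.total_pve})
        write_results_table(strength_rows, out / "instrument_strength.tsv")

        stage = "grs_scan"
        weight_sets = {met: {r.snp_id: r.beta for r in instruments[met]}
                       for met in mets if instruments[met]}
        grs_results, grs_failures = grs_scan(
            cohort, weight_sets, alpha=config.grs_alpha,
            m_tests=config.grs_m_tests)
        write_results_table([r.as_dict() for r in grs_results],
                            out / "grs_results.tsv")
        manifest["stages"][stage] = {
            "n_results": len(grs_results), "n_failures": len(grs_failures)}

        stage = "mr"
        mr_rows, presso_rows, loo_frames = [], [], {}
        mr_ivw_by_met = {}
        for met in mets:
            if len(instruments[met]) < 2:
                continue
            _, _, outcome_recs = sims[met][0], sims[met][1], sims[met][2]
            kept_y = qc_kept[met][1]
            panel, _ = harmonize(instruments[met], kept_y)
            ests = run_all_methods(panel, q_alpha=config.q_alpha,
                                   n_boot=config.n_boot,
                                   seed=config.seed * 100 + 7,
                                   methods=config.mr_methods)
            for e in ests:
                mr_rows.append({"metabolite": met, **e.as_dict()})
                if e.method.startswith("ivw") or e.method == "wald":
                    mr_ivw_by_met[met] = e
            if panel.n_snp >= 4:
                pres = mr_presso(panel, n_sim=config.presso_n_sim,
                                 seed=config.seed * 100 + 11,
                                 sig_level=config.presso_sig)
                presso_rows.append({
                    "metabolite": met, "rss_obs": pres.rss_obs,
                    "global_pval": pres.global_pval,
                    "n_outliers": pres.n_outliers,
                    "distortion_pval": pres.distortion_pval,
                })
            if panel.n_snp >= 3:
                loo_frames[met] = leave_one_out(panel, q_alpha=config.q_alpha)
        write_results_table(mr_rows, out / "mr_results.tsv")
        write_results_table(presso_rows, out / "presso_results.tsv")
        for met, frame in loo_frames.items():
            write_results_table(frame.to_dict("records"),
                                out / f"loo_{met}.tsv")
        manifest["stages"][stage] = {"n_mr_rows": len(mr_rows),
                                     "n_presso": len(presso_rows)}

        stage = "threshold_grid"
        grid_rows = []
        for met in mets:
            kept_x, kept_y = qc_kept[met]
            grid = threshold_grid(kept_x, kept_y, panel_dosages, panel_ids,
                                  p_list=config.grid_p, r2_list=config.grid_r2,
                                  window_kb=config.clump_window_kb,
                                  q_alpha=config.q_alpha)
            for rec in grid.to_dict("records"):
                grid_rows.append({"metabolite": met, **rec})
        write_results_table(grid_rows, out / "threshold_grid.tsv")
        manifest["stages"][stage] = {"n_cells": len(grid_rows)}

        stage = "reverse_mr"
        reverse_rows = []
        for met in mets:
            kept_x, kept_y = qc_kept[met]
            try:
                rev = reverse_mr(kept_y, kept_x, panel_dosages, panel_ids,
                                 p_thresh=config.reverse_p,
                                 r2_thresh=config.clump_r2,
                                 window_kb=config.clump_window_kb,
                                 q_alpha=config.q_alpha)
                reverse_rows.append({"metabolite": met, **rev.as_dict()})
            except ValidationError as exc:
                reverse_rows.append({"metabolite": met, "method": "none",
                                     "beta": np.nan, "se": np.nan,
                                     "ci_lo": np.nan, "ci_hi": np.nan,
                                     "pval": np.nan, "n_snp": 0, "Q": np.nan,
                                     "Q_df": 0, "Q_pval": np.nan,
                                     "egger_intercept": np.nan,
                                     "egger_intercept_se": np.nan,
                                     "egger_intercept_pval": np.nan})
                log.info("reverse MR %s skipped: %s", met, exc)
        write_results_table(reverse_rows, out / "reverse_mr.tsv")
        manifest["stages"][stage] = {"n_rows": len(reverse_rows)}

        stage = "mvmr"
        # joint model over metabolites with any instruments, on the union of
        # their index SNPs (each metabolite's full table is dense over them)
        mv_mets = [m for m in mets if instruments[m]]
        manifest["stages"][stage] = {"n_exposures": len(mv_mets)}
        if len(mv_mets) >= 2:
            union_ids = sorted({r.snp_id for m in mv_mets for r in instruments[m]})
            exposure_sets = []
            for m in mv_mets:
                by_id = {r.snp_id: r for r in qc_kept[m][0]}
                exposure_sets.append([by_id[s] for s in union_ids if s in by_id])
            outcome_full = qc_kept[mv_mets[0]][1]
            try:
                mpanel, _ = build_multi_panel(exposure_sets, outcome_full,
                                              exposure_names=mv_mets)
                mv = mvmr_wls(mpanel)
                write_results_table(mv.as_rows(), out / "mvmr_results.tsv")
                manifest["stages"][stage]["n_snp"] = mv.n_snp
            except ValidationError as exc:
                log.info("mvmr skipped: %s", exc)
                manifest["stages"][stage]["skipped"] = str(exc)

        stage = "pathway"
        library = _toy_library(mets, config.causal_betas)
        write_gmt(library, out / "library.gmt")
        ebmd_rows = [r for r in grs_results if r.outcome == "ebmd"]
        report = enrich_report(ebmd_rows, library,
                               p_cutoff=config.pathway_p_cutoff,
                               alpha=config.pathway_alpha)
        write_results_table([r.as_dict() for r in report["rows"]],
                            out / "pathway_enrichment.tsv")
        manifest["stages"][stage] = {
            "query_size": report["query_size"],
            "n_pathways": len(report["rows"]),
            "warning": report["warning"]}

        stage = "report"
        validated = []
        grs_sig = {r.metabolite for r in grs_results
                   if r.outcome == "ebmd" and r.significant}
        for met, est in mr_ivw_by_met.items():
            grs_beta = next((r.beta for r in grs_results
                             if r.metabolite == met and r.outcome == "ebmd"), None)
            if (met in grs_sig and est.pval < 0.05 and grs_beta is not None
                    and np.sign(grs_beta) == np.sign(est.beta)):
                validated.append(met)
        manifest["validated_metabolites"] = sorted(validated)

        artifacts = sorted(p.name for p in out.iterdir()
                           if p.name not in ("manifest.json", "FAILED"))
        digest = hashlib.sha256()
        for name in artifacts:
            digest.update(name.encode())
            digest.update((out / name).read_bytes())
        manifest["artifacts"] = artifacts
        manifest["bundle_sha256"] = digest.hexdigest()
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n")
        failed = out / "FAILED"
        if failed.exists():
            failed.unlink()
        return manifest
    except Exception as exc:  # keep partial artifacts, mark the failure
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc
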