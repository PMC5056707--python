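"""End-to-end pipeline driver.

Runs the whole stock-identification workflow on a baseline: locus QC and
Hardy-Weinberg screening, outlier-site flagging on the D_A ordination,
hold-out split, F_ST locus ranking with accuracy-vs-panel-size curves,
regional k-means clustering, iterative assignment-unit definition, final
dual-method evaluation, and mixed-stock simulations.  Every stochastic
stage derives its seed deterministically from the pipeline seed, so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment, mixture, panel as panel_mod, qc, structure, units as units_mod
from .core import BaselineHierarchy, GenotypeMatrix, counts_by_group
from .simulate import SimConfig, simulate_baseline

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs for the full pipeline; defaults follow the standard workflow:
    call-rate 0.90, hold-out 6 fish/site, score cut-off 80, unit precision
    threshold 0.80, 10 CV repeats."""

    seed: int = 0
    call_rate_threshold: float = 0.90
    hwe_alpha: float = 0.05
    holdout_per_site: int = 6
    panel_sizes: tuple[int, ...] = panel_mod.DEFAULT_PANEL_SIZES
    eval_panel_size: int = 288
    cutoff: float = 80.0
    unit_threshold: float = 0.80
    unit_margin: float = 0.05
    cv_repeats: int = 10
    k_max: int = 12
    sim_B: int = 1000
    mix_size_100pct: int = 200
    mix_size_fishery: int = 1000
    neutral_only: bool = False
    outlier_fdr: float = 0.05
    max_iter: int = 20
    manual_outlier_sites: list[str] | None = None
    unit_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.call_rate_threshold <= 1):
            raise ValueError("call_rate_threshold outside [0, 1]")
        if not (0 < self.unit_threshold <= 1):
            raise ValueError("unit_threshold outside (0, 1]")
        if not (0 <= self.cutoff <= 100):
            raise ValueError("cutoff outside [0, 100]")


def _stage_seed(seed: int, stage: str) -> int:
    import zlib

    tag = zlib.crc32(stage.encode()) % (2 ** 31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0]
               % (2 ** 31))


STAGES = ("split", "units", "tfcv", "sim100", "fishery")


def run_pipeline(cfg: PipelineConfig, gm: GenotypeMatrix,
                 hierarchy: BaselineHierarchy,
                 outdir: str | Path | None = None) -> dict:
    """Execute the full workflow; returns a JSON-serializable report."""
    seeds = {s: _stage_seed(cfg.seed, s) for s in STAGES}
    report: dict = {"seed": cfg.seed, "stage_seeds": seeds}

    # --- QC ---------------------------------------------------------------
    gm = gm.with_call_rates()
    retained, removed = qc.filter_call_rate(gm.loci, cfg.call_rate_threshold)
    gm = gm.subset_loci([l.locus_id for l in retained])
    hwe = qc.hwe_site_scan(gm, hierarchy, cfg.hwe_alpha)
    hwe_flagged = [r.site_id for r in hwe if r.reject]
    report["qc"] = {
        "n_loci_retained": gm.n_loci,
        "n_loci_removed": len(removed),
        "hwe_flagged_sites": hwe_flagged,
    }

    # --- outlier sites on the D_A ordination --------------------------------
    site_counts = counts_by_group(gm, hierarchy, "site")
    dm = structure.da_distance_matrix(site_counts)
    coords, evals = structure.pcoa(dm, n_axes=2)
    outlier_sites = structure.flag_outlier_sites(
        coords, manual=cfg.manual_outlier_sites)
    report["outlier_sites"] = sorted(outlier_sites)

    # ranking stages exclude flagged sites (and HWE-rejected ones); they are
    # returned for the evaluation stages, which always use all fish
    excluded = set(outlier_sites) | set(hwe_flagged)
    core_idx = [i for i, ind in enumerate(gm.individuals)
                if hierarchy.site_of(ind) not in excluded]
    gm_core = gm.subset_individuals(core_idx) if excluded else gm

    # --- optional neutral-only variant --------------------------------------
    if cfg.neutral_only:
        theta_all = panel_mod.wc_theta_per_locus(
            counts_by_group(gm_core, hierarchy, "river"))
        screen = panel_mod.detect_outlier_loci(
            theta_all, n_groups=len(hierarchy.rivers()), fdr=cfg.outlier_fdr)
        keep = [l for l in gm.locus_ids if l not in set(screen.outliers)]
        report["outlier_loci"] = screen.outliers
        gm = gm.subset_loci(keep)
        gm_core = gm_core.subset_loci(keep)

    # --- hold-out split and ranking -----------------------------------------
    train, hold = assignment.holdout_split(gm, hierarchy,
                                           cfg.holdout_per_site, seeds["split"])
    train_core_idx = [i for i, ind in enumerate(train.individuals)
                      if hierarchy.site_of(ind) not in excluded]
    train_core = train.subset_individuals(train_core_idx) if excluded else train
    theta = panel_mod.wc_theta_per_locus(
        counts_by_group(train_core, hierarchy, "river"))
    ranked = panel_mod.rank_and_select(theta, cfg.panel_sizes)
    report["panel"] = {"n_ranked": len(ranked.table),
                       "sizes": list(ranked.sizes)}

    # --- accuracy vs panel size (river level) -------------------------------
    curve = []
    for size in ranked.sizes:
        ct = assignment.evaluate_holdout(train, hold, hierarchy,
                                         ranked.panel(size), cfg.cutoff)
        curve.append({
            "size": size,
            "accuracy_all": ct.overall_accuracy(filtered=False),
            "accuracy_cutoff": ct.overall_accuracy(filtered=True),
            "proportion_assigned": ct.proportion_assigned_overall(),
        })
    report["accuracy_curve"] = curve

    # --- regional clustering ------------------------------------------------
    scan = structure.kmeans_bic_scan(gm, k_max=min(cfg.k_max,
                                                   gm.n_individuals),
                                     seed=cfg.seed)
    report["clusters"] = {"chosen_k": scan.chosen_k,
                          "bic": [round(b, 3) for b in scan.bic]}

    # --- iterative unit definition ------------------------------------------
    unit_res = units_mod.iterate_units(
        gm, hierarchy, panel_size=cfg.eval_panel_size,
        sizes=cfg.panel_sizes, threshold=cfg.unit_threshold,
        margin=cfg.unit_margin, cutoff=cfg.cutoff,
        per_site_holdout=cfg.holdout_per_site, cv_repeats=cfg.cv_repeats,
        k_max=cfg.k_max, max_iter=cfg.max_iter, seed=seeds["units"],
        overrides=cfg.unit_overrides or None)
    final_hier = unit_res.hierarchy
    report["units"] = {
        "final": {u: final_hier.rivers_of_unit(u) for u in final_hier.units()},
        "n_iterations": len(unit_res.ledger),
        "converged": unit_res.converged,
        "ledger": [
            {"iteration": it.iteration,
             "decisions": [{k: v for k, v in asdict(d).items()}
                           for d in it.decisions]}
            for it in unit_res.ledger],
    }

    # --- final evaluation ---------------------------------------------------
    final_panel = unit_res.final_panel.panel(
        min(cfg.eval_panel_size, len(unit_res.final_panel.table)))
    ct_final = assignment.evaluate_holdout(train, hold, final_hier,
                                           final_panel, cfg.cutoff)
    report["final_holdout"] = _metrics_records(ct_final.metrics)
    report["final_tfcv"] = _metrics_records(
        unit_res.final_tfcv.per_unit.rename(
            columns={"mean": "proportion_correct"}))

    # --- mixed-stock simulations ---------------------------------------------
    unit_counts = counts_by_group(gm, final_hier, "unit").select_groups(
        sorted(final_hier.units()))
    jj = [unit_counts.locus_ids.index(l) for l in final_panel]
    unit_counts = type(unit_counts)(
        list(unit_counts.groups), list(final_panel),
        unit_counts.n_a[:, jj], unit_counts.n_b[:, jj],
        unit_counts.n_het[:, jj], unit_counts.n_ind[:, jj], "unit")
    sims100 = mixture.sim_100pct(unit_counts, B=cfg.sim_B,
                                 mix_size=cfg.mix_size_100pct,
                                 seed=seeds["sim100"])
    report["sim_100pct"] = {
        u: round(float(s.table.loc[u, "mean"]), 6) for u, s in sims100.items()}
    n_units = len(unit_counts.groups)
    equal_pi = {u: 1.0 / n_units for u in unit_counts.groups}
    fishery = mixture.sim_fishery(unit_counts, equal_pi, B=cfg.sim_B,
                                  mix_size=cfg.mix_size_fishery,
                                  seed=seeds["fishery"])
    report["sim_fishery_equal"] = {
        "table": fishery.table.round(6).reset_index().to_dict("records")}

    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _metrics_records(metrics: pd.DataFrame) -> list[dict]:
    out = metrics.copy()
    out.index.name = "unit"
    recs = out.round(6).reset_index().to_dict("records")
    for r in recs:
        for k, v in r.items():
            if isinstance(v, float) and np.isnan(v):
                r[k] = None
    return recs


def _write_report(report: dict, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    pd.DataFrame(report["accuracy_curve"]).to_csv(
        outdir / "accuracy_curve.tsv", sep="\t", index=False)
    pd.DataFrame(report["final_holdout"]).to_csv(
        outdir / "final_holdout.tsv", sep="\t", index=False)


def run_demo(cfg: PipelineConfig | None = None,
             sim: SimConfig | None = None, outdir=None) -> dict:
    """Simulate the demo baseline and run the pipeline on it."""
    cfg = cfg or PipelineConfig()
    sim = sim or SimConfig(seed=cfg.seed)
    gm, hierarchy, _ = simulate_baseline(sim)
    return run_pipeline(cfg, gm, hierarchy, outdir)
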