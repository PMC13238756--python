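"""End-to-end orchestration of the conservation-unit delineation analysis.

``run_pipeline`` wires the stages together on a simulated (or pre-built)
dataset: filters -> distances -> structure -> isolation -> scans -> WZA ->
consensus. Every stochastic stage derives its seed from the config seed, so
a fixed config reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import distances, io, isolation, scans_gea, simdata, structure, wza_consensus
from .containers import DistMatrix, ScanStats

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("filters", "distances", "structure", "isolation", "scans", "wza", "consensus")


@dataclass
class PipelineConfig:
    """Thresholds, permutation counts and stage toggles for one run."""

    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    maf_min: float = 0.01
    maf_min_scan: float = 0.05
    coverage_min: float = 0.75
    ld_window_bp: int = 500_000
    prune_max_bp: int = 200_000
    prune_r2_max: float = 0.1
    n_perm: int = 999
    pcadapt_k: int = 4
    min_snps_per_gene: int = 5
    p_max_candidates: float = 0.001
    wza_mode: str = "normal_tail"
    seed: int = 0
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5 or not 0 <= self.maf_min_scan < 0.5:
            raise ValueError("MAF thresholds must lie in [0, 0.5)")
        if not 0 <= self.coverage_min <= 1:
            raise ValueError("coverage_min must lie in [0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _require(report: dict, stage: str, needs: str) -> None:
    if needs not in report["stages"]:
        raise RuntimeError(f"stage {stage!r} requires stage {needs!r} which did not run")


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Run the configured stages on a freshly simulated dataset.

    Returns a report dict with one block per executed stage; when ``out_dir``
    is given, TSV outputs plus ``report.json`` are written there.
    """
    rng_seed = cfg.seed
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": rng_seed, "config": {"maf_min": cfg.maf_min,
                    "n_perm": cfg.n_perm, "sim_seed": cfg.sim.seed}, "stages": {}}
    art: dict = {}

    snp, truth = simdata.simulate_dataset(cfg.sim)
    sites, env = truth.sites, truth.env
    art.update(snp=snp, truth=truth)

    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        try:
            if stage == "filters":
                filtered = io.apply_filters(snp, cfg.maf_min, cfg.coverage_min,
                                            n_ind_total=cfg.sim.n_ind_per_pop)
                art["filtered"] = filtered
                report["stages"]["filters"] = {
                    "n_snps_in": snp.n_snps, "n_snps_out": filtered.n_snps,
                }
            elif stage == "distances":
                _require(report, stage, "filters")
                fst = distances.fst_matrix(art["filtered"], cfg.maf_min)
                afd = distances.afd_matrix(art["filtered"], cfg.maf_min)
                envd = distances.env_distance(env)
                anc = distances.ancestry_distance(sites)
                art.update(fst=fst, afd=afd, envd=envd, anc=anc)
                tri = fst.condensed()
                report["stages"]["distances"] = {
                    "fst_min": float(tri.min()), "fst_max": float(tri.max()),
                    "afd_min": float(afd.condensed().min()),
                    "afd_max": float(afd.condensed().max()),
                    "env_axes": envd.n_axes,
                }
                if out_dir:
                    fst.to_tsv(out_dir / "fst.tsv")
                    afd.to_tsv(out_dir / "afd.tsv")
            elif stage == "structure":
                _require(report, stage, "filters")
                scores, _, varfrac = structure.pca_freq(art["filtered"], n_axes=4)
                art["pca_scores"] = scores
                report["stages"]["structure"] = {
                    "pc1_var": float(varfrac[0]), "pc2_var": float(varfrac[1]),
                }
            elif stage == "isolation":
                _require(report, stage, "distances")
                res = isolation.residualize_genetic(art["afd"], art["anc"], sites)
                art["residual"] = res
                r_anc, p_anc = isolation.mantel(art["afd"], art["anc"],
                                                cfg.n_perm, seed=rng_seed + 11)
                r_env, p_env = isolation.partial_mantel(res, art["envd"],
                                                        art["marine"] if "marine" in art else truth.marine,
                                                        cfg.n_perm, seed=rng_seed + 12)
                r_mar, p_mar = isolation.partial_mantel(res, truth.marine, art["envd"],
                                                        cfg.n_perm, seed=rng_seed + 13)
                per_var = isolation.ibe_by_variable(res, env, truth.marine, sites,
                                                    "all", cfg.n_perm, seed=rng_seed + 14)
                art["ibe_by_variable"] = per_var
                report["stages"]["isolation"] = {
                    "mantel_r_ancestry": r_anc, "mantel_p_ancestry": p_anc,
                    "partial_r_env": r_env, "partial_p_env": p_env,
                    "partial_r_marine": r_mar, "partial_p_marine": p_mar,
                }
                if out_dir:
                    per_var.to_csv(out_dir / "ibe_by_variable.tsv", sep="\t", index=False)
            elif stage == "scans":
                _require(report, stage, "filters")
                scan_maf = art["filtered"].subset(
                    art["filtered"].snp_ids[art["filtered"].global_maf() > cfg.maf_min_scan])
                kept = scans_gea.vif_prune(env)
                rda = scans_gea.rda_fit(scan_maf, env[kept], n_perm=min(cfg.n_perm, 199),
                                        seed=rng_seed + 21)
                prda = scans_gea.rda_fit(scan_maf, env[kept],
                                         covariate=sites["q"],
                                         n_perm=min(cfg.n_perm, 199), seed=rng_seed + 22)
                uni = scans_gea.univariate_gea(scan_maf, env)
                stats_list: list[ScanStats] = rda.scan_stats() + prda.scan_stats() + uni
                art.update(scan_table=scan_maf, scan_stats=stats_list, rda=rda, prda=prda)
                report["stages"]["scans"] = {
                    "n_snps_scanned": scan_maf.n_snps,
                    "vif_retained": kept,
                    "rda_adj_r2": rda.adj_r2, "rda_axes": rda.n_retained,
                    "prda_adj_r2": prda.adj_r2, "prda_axes": prda.n_retained,
                    "n_scan_stats": len(stats_list),
                }
            elif stage == "wza":
                _require(report, stage, "scans")
                scan_tab = art["scan_table"]
                mapping, background = wza_consensus.assign_snps_to_genes(
                    scan_tab.meta, art["truth"].genes, cfg.min_snps_per_gene)
                maf = scan_tab.global_maf()
                weights = maf * (1 - maf)
                tables = {s.name: wza_consensus.wza(s, mapping, weights, cfg.wza_mode)
                          for s in art["scan_stats"]}
                art.update(wza_tables=tables, background=background, mapping=mapping)
                report["stages"]["wza"] = {
                    "n_background_genes": len(background),
                    "n_methods": len(tables),
                }
            elif stage == "consensus":
                _require(report, stage, "wza")
                cands = wza_consensus.top_candidates(art["wza_tables"],
                                                     cfg.p_max_candidates)
                pairwise, consensus, union = wza_consensus.overlap_consensus(cands)
                art.update(candidates=cands, consensus=consensus)
                report["stages"]["consensus"] = {
                    "n_union": len(union), "n_multi_method": len(consensus),
                    "pct_multi_method": 100.0 * len(consensus) / len(union) if union else 0.0,
                }
                if out_dir:
                    pairwise.to_csv(out_dir / "overlaps.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    report["_artifacts"] = art
    return report
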