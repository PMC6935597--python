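"""Structured configuration and end-to-end pipeline orchestration.

Stages run in the fixed order simulate -> qc -> stats -> assign -> capture
-> poolfreq -> afs, each logging its parameters, seeds and input/output
row counts in key=value form.  Identical configuration and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix
from . import io as cw_io
from .admixture import QMatrix, classify_individuals
from .afs import build_afs, mask_low_freq
from .cytonuclear import build_cp_haplotypes, detect_capture, map_haplotypes_to_lineages
from .diversity import amova_hierarchical, diversity_indices
from .poolseq import (
    PoolFilterRules,
    apply_detection_limit,
    classify_endemic,
    filter_pool_variants,
    fst_scan,
    one_vs_rest_fst,
    pairwise_fst_matrix,
    pool_fst,
)
from .qc import run_qc
from .sim import LineageSimSpec, simulate_lineages, simulate_pools, true_pool_frequencies

log = logging.getLogger("cottonwood")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters with their literature-standard defaults."""

    outdir: str = "cottonwood_out"
    seed: int = 0
    # simulate
    simulate: bool = True
    n_lineages: int = 3
    n_pops_per_lineage: int = 84
    n_ind_per_pop: int = 4
    n_loci: int = 93
    lineage_fst: Sequence[float] = (0.15, 0.15, 0.15)
    admix_fraction: float = 0.1
    capture_rate_forward: float = 0.05  # lineage 1 cp into lineage 0 nuclei
    capture_rate_reverse: float = 0.01
    clone_rate: float = 0.0
    missing_rate: float = 0.01
    # qc
    missing_threshold: float = 0.10
    clone_max_mismatch: int = 0
    hybrid_max_foreign_fraction: float = 0.1
    # stats
    min_pop_size: int = 3
    amova_permutations: int = 0
    # assign
    q_thresholds: Sequence[float] = (0.667, 0.9)
    # capture
    capture_nuclear_threshold: float = 0.667
    # poolfreq
    pool_mean_coverage: float = 300.0
    pool_coverage_dispersion: float = 20.0
    pool_error_rate: float = 0.001
    pool_size: int = 20
    detection_limit: float = 0.02
    min_cov: int = 150
    max_cov: int = 500
    merged_min_cov: int = 200
    min_qual: float = 20.0
    # scan / afs
    window_size_bp: int = 500_000
    scan_min_snps: int = 5
    peak_quantile: float = 0.99
    afs_mask_cutoff: float = 0.05

    def validate(self) -> None:
        if not (0.0 <= self.missing_threshold <= 1.0):
            raise ValueError("missing_threshold must lie in [0, 1]")
        if not (0.0 <= self.detection_limit < 0.5):
            raise ValueError("detection_limit must lie in [0, 0.5)")
        if not (0.0 <= self.afs_mask_cutoff < 0.5):
            raise ValueError("afs_mask_cutoff must lie in [0, 0.5)")
        if self.min_cov > self.max_cov:
            raise ValueError("min_cov exceeds max_cov")
        for t in self.q_thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError(f"q threshold {t} outside (0, 1]")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["lineage_fst"] = list(self.lineage_fst)
        data["q_thresholds"] = list(self.q_thresholds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in data.items()})
        cfg.validate()
        return cfg


def _log_stage(stage: str, **kv) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    log.info("stage=%s %s", stage, pairs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage on synthetic data; returns key results.

    Writes per-stage TSV reports under ``config.outdir`` and a run log;
    aborts with the failing stage's name, preserving earlier outputs.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    params.pop("outdir")  # provenance hash covers parameters, not paths
    results: dict = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "simulate"
    try:
        # --- simulate -------------------------------------------------
        K = config.n_lineages
        cr = np.zeros((K, K))
        cr[0, 1] = config.capture_rate_forward
        cr[1, 0] = config.capture_rate_reverse
        spec = LineageSimSpec(
            n_lineages=K,
            n_pops_per_lineage=config.n_pops_per_lineage,
            n_ind_per_pop=config.n_ind_per_pop,
            n_loci=config.n_loci,
            lineage_fst=tuple(config.lineage_fst),
            admix_fraction=config.admix_fraction,
            capture_rates=cr,
            missing_rate=config.missing_rate,
            clone_rate=config.clone_rate,
            seed=config.seed,
        )
        sim = simulate_lineages(spec)
        cw_io.write_genotypes(sim.genotypes, out / "genotypes.tsv", params)
        cw_io.write_table(sim.cp_genotypes, out / "cp_genotypes.tsv", params)
        cw_io.write_table(sim.ledger, out / "truth_ledger.tsv", params)
        cw_io.write_table(sim.q_true, out / "q_true.tsv", params)
        _log_stage(stage, seed=config.seed, n_ind=sim.genotypes.n_individuals,
                   n_loci=sim.genotypes.n_loci)
        results["sim"] = sim

        # --- qc -------------------------------------------------------
        stage = "qc"
        gm, reports = run_qc(
            sim.genotypes,
            max_mismatch=config.clone_max_mismatch,
            missing_threshold=config.missing_threshold,
        )
        rep_df = pd.DataFrame(
            [(r.step, r.n_input, r.n_removed, r.n_retained) for r in reports],
            columns=["step", "n_input", "n_removed", "n_retained"],
        )
        cw_io.write_table(rep_df, out / "qc_report.tsv", params, index=False)
        _log_stage(stage, n_in=sim.genotypes.n_individuals, n_out=gm.n_individuals)
        results["qc"] = (gm, reports)

        # --- assign ---------------------------------------------------
        stage = "assign"
        q = QMatrix(sim.q_true.loc[gm.calls.index])
        cls = classify_individuals(q, tuple(config.q_thresholds))
        cw_io.write_table(cls.table, out / "classification.tsv", params)
        _log_stage(stage, thresholds=tuple(config.q_thresholds),
                   n_pure=int(cls.pure_mask(config.q_thresholds[0]).sum()))
        results["classification"] = cls

        # --- stats ----------------------------------------------------
        stage = "stats"
        div = diversity_indices(gm, min_pop_size=config.min_pop_size)
        # populations must nest in groups: group = modal lineage of the pop
        lin = sim.ledger.loc[gm.calls.index, "lineage"]
        pop = gm.individuals["population"]
        pop_modal = lin.groupby(pop).agg(lambda s: s.mode().iloc[0])
        groups = pop.map(pop_modal).map(lambda k: f"lineage{k}")
        amova = amova_hierarchical(
            gm, groups, min_pop_size=config.min_pop_size,
            n_permutations=config.amova_permutations, seed=config.seed,
        )
        stats_df = pd.DataFrame(
            {
                "value": {
                    "Ho": div.Ho, "Hs": div.Hs, "Ht": div.Ht, "Fis": div.Fis,
                    "Fst_gst": div.Fst_gst, "Fst_theta": div.Fst_theta,
                    "Fct": amova.Fct, "Fsc": amova.Fsc, "Fst_amova": amova.Fst,
                }
            }
        )
        cw_io.write_table(stats_df, out / "diversity.tsv", params)
        _log_stage(stage, fst_gst=round(div.Fst_gst, 4), fct=round(amova.Fct, 4))
        results["diversity"] = div
        results["amova"] = amova

        # --- capture --------------------------------------------------
        stage = "capture"
        haps = build_cp_haplotypes(sim.cp_genotypes.loc[gm.calls.index])
        hmap = map_haplotypes_to_lineages(haps, cls)
        report = detect_capture(
            haps, cls, hmap, nuclear_threshold=config.capture_nuclear_threshold
        )
        cw_io.write_table(haps.catalogue, out / "haplotypes.tsv", params)
        cw_io.write_table(report.pair_counts, out / "capture_counts.tsv", params)
        cw_io.write_table(report.events, out / "capture_events.tsv", params)
        _log_stage(stage, n_discordant=report.n_discordant)
        results["capture"] = report

        # --- poolfreq -------------------------------------------------
        stage = "poolfreq"
        lineage_of = sim.ledger.loc[gm.calls.index, "lineage"]
        pools = {
            f"pool_lineage{k}": list(lineage_of.index[lineage_of == k])[: config.pool_size]
            for k in range(K)
        }
        pools = {k: v for k, v in pools.items() if v}
        tf = true_pool_frequencies(gm, pools)
        nuclear = [l for l in tf.index if not str(l).startswith("diag")]
        tf = tf.loc[nuclear]
        counts = simulate_pools(
            tf, config.pool_mean_coverage, config.pool_coverage_dispersion,
            config.pool_error_rate, pool_size=config.pool_size,
            snps=gm.loci.loc[nuclear, ["chrom", "pos"]], seed=config.seed + 1,
        )
        cw_io.write_pool_vcf(counts, out / "pool_counts.vcf")
        table = cw_io.pool_counts_to_variant_table(counts)
        rules = PoolFilterRules(
            min_cov=config.min_cov, max_cov=config.max_cov,
            merged_min_cov=config.merged_min_cov, min_qual=config.min_qual,
        )
        pf, rejected = filter_pool_variants(
            table, list(pools), config.pool_size, rules
        )
        pf = apply_detection_limit(pf, config.detection_limit)
        endemic = classify_endemic(pf)
        fst_mat = pairwise_fst_matrix(pf)
        ovr = one_vs_rest_fst(pf)
        cw_io.write_table(
            pd.concat([pf.snps[["chrom", "pos"]], pf.freqs], axis=1),
            out / "pool_freqs.tsv", params, index=False,
        )
        cw_io.write_table(endemic.summary, out / "endemic_summary.tsv", params)
        cw_io.write_table(fst_mat, out / "fst_matrix.tsv", params)
        cw_io.write_table(ovr.to_frame(), out / "fst_one_vs_rest.tsv", params)
        _log_stage(stage, n_snps=pf.n_snps, n_rejected=int(rejected.sum()))
        results["pool_freqs"] = pf
        results["endemic"] = endemic
        results["fst_matrix"] = fst_mat

        # --- scan -----------------------------------------------------
        stage = "scan"
        pool_names = list(pf.pools)
        if len(pool_names) >= 2 and pf.n_snps:
            fr = pool_fst(pf, (pool_names[0], pool_names[1]))
            scan = fst_scan(
                fr.track, config.window_size_bp, config.scan_min_snps,
                config.peak_quantile,
            )
            cw_io.write_table(fr.track, out / "fst_track.tsv", params)
            cw_io.write_table(scan.windows, out / "fst_windows.tsv", params, index=False)
            cw_io.write_bed(scan.peaks, out / "fst_peaks.bed")
            _log_stage(stage, n_windows=len(scan.windows), n_peaks=len(scan.peaks))
            results["scan"] = scan

        # --- afs ------------------------------------------------------
        stage = "afs"
        if len(pool_names) >= 2 and pf.n_snps:
            grid = build_afs(pf, pool_names[0], pool_names[1])
            grid = mask_low_freq(grid, config.afs_mask_cutoff)
            cw_io.write_table(grid.to_frame(), out / "afs_grid.tsv", params)
            _log_stage(stage, shape=grid.shape, n_snps=grid.n_snps)
            results["afs"] = grid
    except Exception as exc:
        log.error("stage=%s status=failed", stage)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    log.removeHandler(handler)
    handler.close()
    return results
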