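"""Configuration, orchestration and table writers for the command pipeline.

A :class:`ScanConfig` collects every tunable of the pipeline in one flat
namespace; defaults follow the conventional post-calling recipe (GQ >= 40,
MQ >= 25, > 3 SNPs / 10 bp cluster removal), 50 kb / 25 kb windows, top-5%
F_ST and top-1% log2 theta-pi-ratio cutoffs, ``--indep-pairwise 50 10 0.1``
pruning and 100-kb minimum ROH length.

All emitted tables are TSV with a commented ``#key=value`` provenance block
(config hash + seed), so a directory of mixed-config outputs is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diversity, linkage, roh as roh_mod, structure, sweep, variant_io
from .genotypes import GenotypeMatrix, PopulationMap


@dataclass
class ScanConfig:
    # paths
    vcf: str = ""
    popmap: str = ""
    genes: str = ""
    outdir: str = "results"
    # contrast (group or superset labels)
    group_a: str = "native"
    group_b: str = "commercial"
    # windows
    window_size: int = 50_000
    window_step: int = 25_000
    # outlier fractions
    fst_frac: float = 0.05
    ratio_frac: float = 0.01
    ratio_tail: str = "upper"
    fst_estimator: str = "ratio_of_sums"
    # site filters
    gq_min: float = 40.0
    mq_min: float = 25.0
    cluster_max_snps: int = 3
    cluster_span_bp: int = 10
    # LD
    ld_window_snps: int = 50
    ld_step_snps: int = 10
    ld_r2_max: float = 0.1
    ld_bin_edges_kb: tuple = (0.0, 1.0, 3.0, 5.0, 15.0, 60.0, 100.0)
    ld_max_pairs_per_bin: int = 50_000
    ld_mode: str = "dosage"
    # ROH
    roh_min_kb: float = 100.0
    roh_min_snps: int = 50
    roh_scan_window_snps: int = 50
    roh_max_het_per_window: int = 1
    roh_max_miss_per_window: int = 5
    roh_hit_frac: float = 0.05
    # PCA
    pca_components: int = 2
    # global seed for every stochastic step (LD subsampling)
    seed: int = 0

    def validate(self) -> None:
        for name in ("fst_frac", "ratio_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ratio_tail not in ("upper", "lower"):
            raise ValueError("ratio_tail must be 'upper' or 'lower'")

    def config_hash(self) -> str:
        # destination directory excluded: the same analysis written to two
        # places must be recognisably identical
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        text = ";".join(f"{k}={d[k]!r}" for k in sorted(d))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | None, overrides: dict | None = None
                  ) -> "ScanConfig":
        data = {}
        if path:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        if overrides:
            data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def provenance(cfg: ScanConfig, extra: dict | None = None) -> dict:
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    if extra:
        meta.update(extra)
    return meta


def write_table(df: pd.DataFrame, path: str, meta: dict) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"#{k}={meta[k]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_bed(regions: pd.DataFrame, path: str, meta: dict) -> None:
    """Regions (1-based inclusive) as 0-based half-open BED."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for k in sorted(meta):
            fh.write(f"#{k}={meta[k]}\n")
        for _, r in regions.iterrows():
            name = r.get("region_id", ".")
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}"
                     f"\t{name}\n")


def load_inputs(cfg: ScanConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    gm = variant_io.read_vcf(cfg.vcf)
    pm = variant_io.read_popmap(cfg.popmap)
    pm.check_samples(gm)
    return gm, pm


def apply_filters(gm: GenotypeMatrix, cfg: ScanConfig
                  ) -> tuple[GenotypeMatrix, list[str]]:
    gm1, c1 = variant_io.filter_quality(gm, cfg.gq_min, cfg.mq_min)
    gm2, c2 = variant_io.filter_biallelic_and_clusters(
        gm1, cfg.cluster_max_snps, cfg.cluster_span_bp)
    log = c1.as_log_lines("quality") + c2.as_log_lines("biallelic_cluster")
    return gm2, log


def run_scan(gm: GenotypeMatrix, pm: PopulationMap, cfg: ScanConfig,
             genes: pd.DataFrame | None = None) -> sweep.SweepReport:
    """Windowed F_ST + log2 pi-ratio outlier scan on a filtered matrix."""
    windows = diversity.make_windows(gm.effective_contig_lengths(),
                                     cfg.window_size, cfg.window_step)
    pi_a = diversity.windowed_pi(gm, pm, cfg.group_a, windows)
    pi_b = diversity.windowed_pi(gm, pm, cfg.group_b, windows)
    ratio = sweep.log2_pi_ratio(pi_a, pi_b)
    fst_df, genome_fst = sweep.windowed_weighted_fst(
        gm, pm, cfg.group_a, cfg.group_b, windows,
        estimator=cfg.fst_estimator)
    stats = fst_df.merge(
        ratio[["chrom", "start", "end", "index", "truncated",
               "pi_a", "pi_b", "log2_ratio", "zero_pi"]],
        on=["chrom", "start", "end", "index"], validate="one_to_one")
    report = sweep.call_candidate_regions(
        stats, genome_fst, cfg.fst_frac, cfg.ratio_frac, cfg.ratio_tail)
    if genes is not None:
        sweep.annotate_report(report, genes)
    return report


def write_scan_outputs(report: sweep.SweepReport, cfg: ScanConfig,
                       outdir: str, filter_log: list[str] | None = None
                       ) -> None:
    meta = provenance(cfg, {
        "genome_weighted_fst": f"{report.genome_fst:.6g}",
        "fst_threshold": f"{report.fst_threshold:.6g}",
        "ratio_threshold": f"{report.ratio_threshold:.6g}",
        "n_windows_usable_fst": report.n_windows_usable_fst,
        "n_windows_excluded_fst": report.n_excluded_fst,
        "n_windows_usable_ratio": report.n_windows_usable_ratio,
        "n_windows_excluded_ratio": report.n_excluded_ratio,
        "n_flagged_fst": report.n_flagged_fst,
        "n_flagged_ratio": report.n_flagged_ratio,
    })
    os.makedirs(outdir, exist_ok=True)
    write_table(report.window_stats, os.path.join(outdir, "windows.tsv"), meta)
    thr = pd.DataFrame({
        "statistic": ["fst", "log2_ratio"],
        "upper_frac": [cfg.fst_frac, cfg.ratio_frac],
        "threshold": [report.fst_threshold, report.ratio_threshold],
        "n_flagged": [report.n_flagged_fst, report.n_flagged_ratio],
        "n_usable": [report.n_windows_usable_fst,
                     report.n_windows_usable_ratio]})
    write_table(thr, os.path.join(outdir, "thresholds.tsv"), meta)
    write_bed(report.fst_regions, os.path.join(outdir, "regions_fst.bed"),
              meta)
    write_bed(report.ratio_regions,
              os.path.join(outdir, "regions_log2_ratio.bed"), meta)
    write_bed(report.intersection,
              os.path.join(outdir, "regions_intersection.bed"), meta)
    if report.gene_table is not None:
        write_table(report.gene_table,
                    os.path.join(outdir, "candidate_genes.tsv"), meta)
    log_lines = list(filter_log or [])
    with open(os.path.join(outdir, "run_log.txt"), "w") as fh:
        for k in sorted(meta):
            fh.write(f"{k}={meta[k]}\n")
        for line in log_lines:
            fh.write(line + "\n")
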