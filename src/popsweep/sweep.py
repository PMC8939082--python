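"""Two-statistic selective-sweep scan.

Per biallelic site the Weir–Cockerham variance components are computed from
per-group sample sizes ``n_i`` (non-missing diploids), alt-allele
frequencies ``p_i`` and observed heterozygote proportions ``h_i``:

    nbar = sum(n_i) / r
    n_c  = (r nbar - sum(n_i^2) / (r nbar)) / (r - 1)
    pbar = sum(n_i p_i) / (r nbar)
    s2   = sum(n_i (p_i - pbar)^2) / ((r - 1) nbar)
    hbar = sum(n_i h_i) / (r nbar)
    a = (nbar / n_c) (s2 - (pbar qbar - (r-1)/r s2 - hbar/4) / (nbar - 1))
    b = (nbar / (nbar - 1)) (pbar qbar - (r-1)/r s2 - (2 nbar - 1)/(4 nbar) hbar)
    c = hbar / 2

The windowed "weighted" F_ST is the ratio of sums ``sum(a) / sum(a+b+c)``
over the usable sites of each window (negative per-window values are kept,
not clamped; an unweighted mean-of-per-site-ratios variant is available).
The second statistic is ``log2(pi_a / pi_b)`` of the two contrasted groups'
windowed nucleotide diversity.  Outliers are flagged by empirical quantile
(top ``ceil(frac * N)`` usable windows), merged into regions
(overlapping or book-ended windows), intersected across the two statistics,
and annotated against gene intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import GenomicWindow, windowed_pi
from .genotypes import GenotypeMatrix, PopulationMap


@dataclass
class WCComponents:
    """Per-site Weir–Cockerham quantities (arrays over sites)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    nbar: np.ndarray
    nc: np.ndarray
    pbar: np.ndarray
    s2: np.ndarray
    hbar: np.ndarray
    usable: np.ndarray       # site enters the ratio-of-sums
    monomorphic: np.ndarray  # monomorphic across the contrast -> excluded
    r: int = 2


def wc_site_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                       ) -> WCComponents:
    """Variance components from per-group (n_i, p_i, h_i); arrays (r, S).

    Sites with ``nbar <= 1`` or any empty group are unusable and skipped;
    sites monomorphic across all groups get components (0, 0, 0) and are
    excluded from the sums.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")

    nsum = n.sum(axis=0)
    nbar = nsum / r
    ok = (nbar > 1.0) & np.all(n > 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        qbar = 1.0 - pbar
        inner = pbar * qbar - (r - 1) / r * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * qbar - (r - 1) / r * s2
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    mono = (pbar <= 0.0) | (pbar >= 1.0)
    for arr in (a, b, c):
        arr[~ok] = np.nan
        arr[ok & mono] = 0.0
    usable = ok & ~mono
    return WCComponents(a=a, b=b, c=c, nbar=nbar, nc=nc, pbar=pbar, s2=s2,
                        hbar=hbar, usable=usable, monomorphic=mono, r=r)


def group_site_stats(gm: GenotypeMatrix, idx: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_diploids, p_alt, h_obs) per site for one group's sample columns."""
    al = gm.alleles[:, idx, :]
    called = np.all(al != -1, axis=2)
    n = called.sum(axis=1).astype(float)
    c_alt = ((al > 0) & (al != -1)).sum(axis=(1, 2)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, c_alt / (2.0 * n), np.nan)
        het = ((al[:, :, 0] != al[:, :, 1]) & called).sum(axis=1)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def site_components(gm: GenotypeMatrix, pm: PopulationMap, group_a: str,
                    group_b: str) -> WCComponents:
    """WC components for a two-group contrast on all biallelic sites."""
    if group_a == group_b:
        raise ValueError("contrast groups must differ")
    ia = pm.indices_of(gm, group_a)
    ib = pm.indices_of(gm, group_b)
    if set(ia) & set(ib):
        raise ValueError("contrast groups share samples")
    na, pa, ha = group_site_stats(gm, ia)
    nb, pb, hb = group_site_stats(gm, ib)
    comp = wc_site_components(np.stack([na, nb]), np.stack([pa, pb]),
                              np.stack([ha, hb]))
    comp.usable &= gm.is_biallelic
    return comp


def windowed_weighted_fst(gm: GenotypeMatrix, pm: PopulationMap,
                          group_a: str, group_b: str,
                          windows: list[GenomicWindow],
                          estimator: str = "ratio_of_sums"
                          ) -> tuple[pd.DataFrame, float]:
    """Per-window F_ST plus the genome-wide weighted value.

    ``estimator='ratio_of_sums'`` (default) computes ``sum a / sum (a+b+c)``
    per window; ``'mean_of_ratios'`` averages per-site ratios instead.
    Windows with no usable site are flagged and excluded from ranking.
    """
    comp = site_components(gm, pm, group_a, group_b)
    a = np.where(comp.usable, comp.a, 0.0)
    abc = np.where(comp.usable, comp.a + comp.b + comp.c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        site_ratio = np.where(comp.usable & (abc != 0), a / np.where(abc != 0,
                                                                     abc, 1.0),
                              np.nan)
    usable = comp.usable.astype(np.int64)

    rows = []
    for chrom in gm.chrom_order():
        on_c = np.flatnonzero(gm.chrom == chrom)
        pos = gm.pos[on_c]
        cum_a = np.concatenate([[0.0], np.cumsum(a[on_c])])
        cum_abc = np.concatenate([[0.0], np.cumsum(abc[on_c])])
        cum_n = np.concatenate([[0], np.cumsum(usable[on_c])])
        ratio = site_ratio[on_c]
        cum_ratio = np.concatenate([[0.0], np.cumsum(np.nan_to_num(ratio))])
        cum_ratio_n = np.concatenate(
            [[0], np.cumsum((~np.isnan(ratio)).astype(np.int64))])
        for w in windows:
            if w.chrom != chrom:
                continue
            lo = np.searchsorted(pos, w.start, side="left")
            hi = np.searchsorted(pos, w.end, side="right")
            n_sites = int(cum_n[hi] - cum_n[lo])
            if estimator == "ratio_of_sums":
                denom = cum_abc[hi] - cum_abc[lo]
                fst = ((cum_a[hi] - cum_a[lo]) / denom
                       if n_sites > 0 and denom != 0 else np.nan)
            elif estimator == "mean_of_ratios":
                m = int(cum_ratio_n[hi] - cum_ratio_n[lo])
                fst = (cum_ratio[hi] - cum_ratio[lo]) / m if m else np.nan
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            rows.append((w.chrom, w.start, w.end, w.index, n_sites,
                         float(fst) if fst == fst else np.nan,
                         n_sites == 0))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "index",
                                     "n_sites_fst", "fst", "no_usable_sites"])
    denom = abc.sum()
    genome_fst = float(a.sum() / denom) if denom != 0 else float("nan")
    return df, genome_fst


def log2_pi_ratio(pi_a: pd.DataFrame, pi_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window ``log2(pi_a / pi_b)``; zero-diversity windows flagged.

    Both inputs must come from :func:`~popsweep.diversity.windowed_pi` on
    identical windows.
    """
    key = ["chrom", "start", "end", "index"]
    if not pi_a[key].reset_index(drop=True).equals(
            pi_b[key].reset_index(drop=True)):
        raise ValueError("window sets differ between the two pi tables")
    out = pi_a[key + ["truncated"]].copy()
    out["pi_a"] = pi_a["pi"].to_numpy()
    out["pi_b"] = pi_b["pi"].to_numpy()
    zero = (out["pi_a"] <= 0) | (out["pi_b"] <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_ratio"] = np.where(~zero,
                                     np.log2(out["pi_a"] / out["pi_b"]),
                                     np.nan)
    out["zero_pi"] = zero
    return out


def empirical_outliers(values: np.ndarray, upper_frac: float,
                       order: np.ndarray | None = None
                       ) -> tuple[float, np.ndarray]:
    """Flag the ``k = ceil(frac * N)`` largest values; nearest-rank convention.

    ``order`` supplies genomic tie-break keys (earlier window wins ties).
    Returns (threshold = smallest flagged value, boolean flag array).
    NaN entries are unusable and never flagged.
    """
    values = np.asarray(values, dtype=float)
    if not (0.0 < upper_frac < 1.0):
        raise ValueError("upper_frac must lie in (0, 1)")
    usable = np.flatnonzero(~np.isnan(values))
    if usable.size == 0:
        raise ValueError("no usable values")
    if order is None:
        order = np.arange(len(values))
    v = values[usable]
    if np.all(v == v[0]):
        warnings.warn("all values equal; flagging first k in genomic order")
    k = math.ceil(upper_frac * usable.size)
    rank = np.lexsort((order[usable], -v))  # by value desc, then genomic order
    chosen = usable[rank[:k]]
    flags = np.zeros(len(values), dtype=bool)
    flags[chosen] = True
    return float(values[chosen].min()), flags


def merge_windows(df: pd.DataFrame, flags: np.ndarray) -> pd.DataFrame:
    """Merge flagged windows that overlap or are book-ended into regions."""
    sub = df.loc[np.asarray(flags, dtype=bool),
                 ["chrom", "start", "end"]].sort_values(
        ["chrom", "start", "end"], kind="mergesort")
    regions = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                regions.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            regions.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    out["region_id"] = [f"{c}:{s}-{e}" for c, s, e in
                        zip(out["chrom"], out["start"], out["end"])]
    return out


def intersect_regions(ra: pd.DataFrame, rb: pd.DataFrame) -> pd.DataFrame:
    """Interval intersection of two region sets (1-based inclusive)."""
    rows = []
    for chrom in sorted(set(ra["chrom"]) & set(rb["chrom"])):
        A = ra[ra["chrom"] == chrom]
        B = rb[rb["chrom"] == chrom]
        for sa, ea in zip(A["start"], A["end"]):
            for sb, eb in zip(B["start"], B["end"]):
                s, e = max(sa, sb), min(ea, eb)
                if s <= e:
                    rows.append((chrom, s, e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if not out.empty:
        out = merge_windows(out, np.ones(len(out), dtype=bool))
    else:
        out["region_id"] = pd.Series(dtype=str)
    return out


@dataclass
class SweepReport:
    fst_threshold: float
    ratio_threshold: float
    window_stats: pd.DataFrame
    fst_regions: pd.DataFrame
    ratio_regions: pd.DataFrame
    intersection: pd.DataFrame
    n_windows_usable_fst: int
    n_windows_usable_ratio: int
    n_flagged_fst: int
    n_flagged_ratio: int
    n_excluded_fst: int
    n_excluded_ratio: int
    genome_fst: float
    gene_table: pd.DataFrame | None = None


def call_candidate_regions(window_stats: pd.DataFrame, genome_fst: float,
                           fst_frac: float = 0.05, ratio_frac: float = 0.01,
                           ratio_tail: str = "upper") -> SweepReport:
    """Quantile outliers per statistic, merged regions, and their intersection.

    ``window_stats`` must carry fst, log2_ratio, the degeneracy flags and a
    genomic ``index`` column.  ``ratio_tail='lower'`` ranks the most negative
    log2 ratios instead of the most positive.
    """
    df = window_stats.reset_index(drop=True)
    order = df["index"].to_numpy()
    fst_vals = df["fst"].to_numpy(dtype=float).copy()
    fst_vals[df["no_usable_sites"].to_numpy(dtype=bool)] = np.nan
    ratio_vals = df["log2_ratio"].to_numpy(dtype=float).copy()
    ratio_vals[df["zero_pi"].to_numpy(dtype=bool)] = np.nan
    if ratio_tail == "lower":
        rank_vals = -ratio_vals
    elif ratio_tail == "upper":
        rank_vals = ratio_vals
    else:
        raise ValueError(f"unknown ratio_tail {ratio_tail!r}")

    fst_thr, fst_flags = empirical_outliers(fst_vals, fst_frac, order)
    rank_thr, ratio_flags = empirical_outliers(rank_vals, ratio_frac, order)
    ratio_thr = -rank_thr if ratio_tail == "lower" else rank_thr

    df = df.copy()
    df["fst_outlier"] = fst_flags
    df["ratio_outlier"] = ratio_flags
    fst_regions = merge_windows(df, fst_flags)
    ratio_regions = merge_windows(df, ratio_flags)
    inter = intersect_regions(fst_regions, ratio_regions)
    return SweepReport(
        fst_threshold=fst_thr,
        ratio_threshold=float(ratio_thr),
        window_stats=df,
        fst_regions=fst_regions,
        ratio_regions=ratio_regions,
        intersection=inter,
        n_windows_usable_fst=int((~np.isnan(fst_vals)).sum()),
        n_windows_usable_ratio=int((~np.isnan(ratio_vals)).sum()),
        n_flagged_fst=int(fst_flags.sum()),
        n_flagged_ratio=int(ratio_flags.sum()),
        n_excluded_fst=int(np.isnan(fst_vals).sum()),
        n_excluded_ratio=int(np.isnan(ratio_vals).sum()),
        genome_fst=genome_fst,
    )


# ----------------------------------------------------------------------
# gene annotation
# ----------------------------------------------------------------------

def read_genes_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open; name column required).

    Returned coordinates are converted to 1-based inclusive.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start0", "end0", "gene"],
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "gene"])
    if df["gene"].isna().any():
        raise ValueError(f"BED gene file {path} lacks a name column")
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["start0"] + 1,
                        "end": df["end0"], "gene": df["gene"]})
    return out


def read_genes_gff3(path) -> pd.DataFrame:
    """Gene intervals from a minimal GFF3 (``gene`` feature lines only)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("gene_name") \
                or attrs.get("ID") or "."
            rows.append((f[0], int(f[3]), int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame,
                     statistic: str = "") -> pd.DataFrame:
    """Genes overlapping any region by >=1 bp; one row per gene.

    Regions on chromosomes absent from the annotation produce a warning and
    are reported unannotated (empty gene set).
    """
    gene_chroms = set(genes["chrom"]) if len(genes) else set()
    hits: dict[str, dict] = {}
    for _, reg in regions.iterrows():
        if reg["chrom"] not in gene_chroms:
            warnings.warn(f"no annotation for chromosome {reg['chrom']!r}; "
                          f"region {reg['region_id']} left unannotated")
            continue
        g = genes[genes["chrom"] == reg["chrom"]]
        ov = g[(g["start"] <= reg["end"]) & (g["end"] >= reg["start"])]
        for _, row in ov.iterrows():
            e = hits.setdefault(row["gene"], {
                "gene": row["gene"], "chrom": row["chrom"],
                "gene_start": int(row["start"]), "gene_end": int(row["end"]),
                "regions": [], "overlap_bp": 0, "statistics": set()})
            e["regions"].append(reg["region_id"])
            e["overlap_bp"] += int(min(reg["end"], row["end"])
                                   - max(reg["start"], row["start"]) + 1)
            if statistic:
                e["statistics"].add(statistic)
    rows = [{**e, "regions": ",".join(e["regions"]),
             "statistics": ",".join(sorted(e["statistics"]))}
            for e in hits.values()]
    return pd.DataFrame(rows, columns=["gene", "chrom", "gene_start",
                                       "gene_end", "regions", "overlap_bp",
                                       "statistics"])


def annotate_report(report: SweepReport, genes: pd.DataFrame) -> pd.DataFrame:
    """Candidate-gene table across both statistics and their intersection."""
    parts = []
    for name, regs in (("fst", report.fst_regions),
                       ("log2_ratio", report.ratio_regions),
                       ("intersection", report.intersection)):
        if len(regs):
            parts.append(annotate_regions(regs, genes, statistic=name))
    if not parts:
        report.gene_table = pd.DataFrame(columns=[
            "gene", "chrom", "gene_start", "gene_end", "regions",
            "overlap_bp", "statistics"])
        return report.gene_table
    merged: dict[str, dict] = {}
    for part in parts:
        for _, row in part.iterrows():
            if row["gene"] not in merged:
                merged[row["gene"]] = dict(row)
                continue
            e = merged[row["gene"]]
            regs = set(str(e["regions"]).split(",")) | \
                set(str(row["regions"]).split(","))
            stats = set(str(e["statistics"]).split(",")) | \
                set(str(row["statistics"]).split(","))
            e["regions"] = ",".join(sorted(r for r in regs if r))
            e["statistics"] = ",".join(sorted(s for s in stats if s))
    out = pd.DataFrame(list(merged.values()),
                       columns=["gene", "chrom", "gene_start", "gene_end",
                                "regions", "overlap_bp", "statistics"])
    report.gene_table = out.sort_values("gene").reset_index(drop=True)
    return report.gene_table
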