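"""VCF / population-map I/O and the post-calling site filters.

Reading uses cyvcf2 (htslib), so plain and bgzipped VCFs both work.  Writing
emits minimal VCF v4.2 text restricted to the fields the data model carries
(GT, optional GQ, optional INFO/MQ, ##contig header lines) and round-trips
through :func:`read_vcf`.

Two filters mirror a common post-calling recipe for WGS SNP panels:

* :func:`filter_quality` — genotypes below a GQ floor are set missing
  (default 40); sites below an MQ floor are dropped (default 25).
* :func:`filter_biallelic_and_clusters` — sites with more than two alleles
  are dropped, then every SNP that lies in any 10-bp interval holding more
  than 3 SNPs is dropped together with the rest of its cluster (a guard
  against alignment artefacts).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix, PopulationMap, PopmapError


class VcfParseError(ValueError):
    pass


@dataclass
class FilterCounts:
    """Bookkeeping for one filter pass; totals always reconcile."""

    n_sites_in: int = 0
    n_sites_removed: int = 0
    n_genotypes_masked: int = 0
    detail: dict = field(default_factory=dict)

    @property
    def n_sites_out(self) -> int:
        return self.n_sites_in - self.n_sites_removed

    def as_log_lines(self, name: str) -> list[str]:
        lines = [f"{name}.sites_in={self.n_sites_in}",
                 f"{name}.sites_removed={self.n_sites_removed}",
                 f"{name}.sites_out={self.n_sites_out}",
                 f"{name}.genotypes_masked={self.n_genotypes_masked}"]
        lines += [f"{name}.{k}={v}" for k, v in self.detail.items()]
        return lines


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def _validate_vcf_text(path: str | os.PathLike) -> None:
    """Cheap structural check with line numbers (htslib aborts unhelpfully)."""
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    n_cols = None
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                n_cols = len(fields)
                continue
            if len(fields) < 8 or (n_cols is not None
                                   and len(fields) != n_cols):
                raise VcfParseError(
                    f"malformed VCF line {ln} of {path}: wrong column count")
            try:
                int(fields[1])
            except ValueError:
                raise VcfParseError(
                    f"malformed VCF line {ln} of {path}: "
                    f"non-integer POS {fields[1]!r}") from None


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Load a VCF v4.x with GT into a :class:`GenotypeMatrix`.

    ``./.`` and ``.|.`` genotypes map to missing; GQ is read when present in
    FORMAT, MQ when present in INFO, contig lengths from ``##contig`` header
    lines when present.
    """
    _validate_vcf_text(path)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise VcfParseError(f"duplicate sample name in {path}")

    contig_lengths: dict[str, int] = {}
    try:
        seqlens = vcf.seqlens
    except Exception:
        seqlens = []
    for name, ln in zip(vcf.seqnames, seqlens or []):
        if ln and ln > 0:
            contig_lengths[name] = int(ln)

    chrom, pos, ref, alt = [], [], [], []
    alleles_rows, phased_rows, gq_rows, mq_vals = [], [], [], []
    any_gq = False
    i = 0
    try:
        for i, v in enumerate(vcf, start=1):
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(tuple(v.ALT))
            g = np.asarray(v.genotypes, dtype=np.int64)  # (n_samples, 3)
            al = g[:, :2].astype(np.int8)
            phased_rows.append(g[:, 2].astype(bool))
            alleles_rows.append(al)
            try:
                gq = v.format("GQ")
            except KeyError:
                gq = None
            if gq is not None:
                any_gq = True
                q = np.asarray(gq, dtype=np.float32).reshape(-1)
                q[q < 0] = np.nan  # htslib missing-value sentinel
                gq_rows.append(q)
            else:
                gq_rows.append(np.full(len(samples), np.nan, dtype=np.float32))
            mq = v.INFO.get("MQ")
            mq_vals.append(np.nan if mq is None else float(mq))
    except Exception as exc:  # htslib parse failures surface here
        if isinstance(exc, VcfParseError):
            raise
        raise VcfParseError(f"malformed VCF record near data line {i + 1} "
                            f"of {path}: {exc}") from exc

    n_sites = len(pos)
    alleles = (np.stack(alleles_rows) if n_sites
               else np.empty((0, len(samples), 2), dtype=np.int8))
    phased = (np.stack(phased_rows) if n_sites
              else np.empty((0, len(samples)), dtype=bool))
    gq_arr = np.stack(gq_rows) if (n_sites and any_gq) else None
    mq_arr = np.asarray(mq_vals, dtype=np.float32)
    if n_sites == 0 or np.all(np.isnan(mq_arr)):
        mq_arr = None
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=alt,
        alleles=alleles,
        phased=phased,
        gq=gq_arr,
        mq=mq_arr if mq_arr is not None else None,
        contig_lengths=contig_lengths or None,
    )


def _fmt_num(x: float) -> str:
    """Render a quality value without trailing zeros (42 not 42.0)."""
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(xf)


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Emit ``gm`` as VCF v4.2 text; ``read_vcf(write_vcf(gm))`` == ``gm``."""
    has_gq = gm.gq is not None
    has_mq = gm.mq is not None
    lines: list[str] = ["##fileformat=VCFv4.2"]
    for c, ln in (gm.contig_lengths or {}).items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    if has_mq:
        lines.append('##INFO=<ID=MQ,Number=1,Type=Float,'
                     'Description="RMS mapping quality">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_gq:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                     'Description="Genotype quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids))
    fmt = "GT:GQ" if has_gq else "GT"
    for i in range(gm.n_sites):
        info = "."
        if has_mq and not np.isnan(gm.mq[i]):
            info = f"MQ={_fmt_num(gm.mq[i])}"
        alt = ",".join(gm.alt[i]) if gm.alt[i] else "."
        cells = []
        for j in range(gm.n_samples):
            a0, a1 = gm.alleles[i, j]
            sep = "|" if gm.phased[i, j] else "/"
            gt = f"{'.' if a0 == MISSING else int(a0)}{sep}" \
                 f"{'.' if a1 == MISSING else int(a1)}"
            if has_gq:
                q = gm.gq[i, j]
                gt += ":." if np.isnan(q) else f":{_fmt_num(q)}"
            cells.append(gt)
        lines.append("\t".join([gm.chrom[i], str(int(gm.pos[i])), ".",
                                gm.ref[i], alt, ".", "PASS", info, fmt]
                               + cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# population map
# ----------------------------------------------------------------------

POPMAP_COLUMNS = ("sample", "group", "superset")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a sample/group/superset TSV (header required)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise PopmapError(f"empty population map: {path}") from None
    for col in POPMAP_COLUMNS:
        if col not in df.columns:
            raise PopmapError(f"population map {path} lacks column {col!r}")
    if df.empty:
        raise PopmapError(f"population map {path} has no rows")
    dup = df["sample"][df["sample"].duplicated()]
    if not dup.empty:
        raise PopmapError(f"sample listed twice in {path}: {dup.iloc[0]!r}")
    superset: dict[str, str] = {}
    for g, s in zip(df["group"], df["superset"]):
        if g in superset and superset[g] != s:
            raise PopmapError(f"group {g!r} mapped to two supersets")
        superset[g] = s
    return PopulationMap(assignment=dict(zip(df["sample"], df["group"])),
                         superset=superset)


def write_popmap(pm: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\tsuperset\n")
        for s, g in pm.assignment.items():
            fh.write(f"{s}\t{g}\t{pm.superset[g]}\n")


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------

def filter_quality(gm: GenotypeMatrix, gq_min: float = 40.0,
                   mq_min: float = 25.0) -> tuple[GenotypeMatrix, FilterCounts]:
    """Mask genotypes with GQ below ``gq_min``; drop sites with MQ below ``mq_min``.

    Genotypes and sites lacking the respective quality field pass unchanged.
    """
    if gq_min < 0 or mq_min < 0:
        raise ValueError("quality thresholds must be non-negative")
    counts = FilterCounts(n_sites_in=gm.n_sites)

    keep = np.ones(gm.n_sites, dtype=bool)
    if gm.mq is not None:
        keep = ~(gm.mq < mq_min)  # NaN (absent MQ) passes
    counts.n_sites_removed = int((~keep).sum())
    counts.detail["sites_removed_mq"] = counts.n_sites_removed

    out = gm.take_sites(keep)
    if out.gq is not None:
        mask = out.gq < gq_min  # NaN passes
        mask &= ~out.call_missing  # count only newly-masked calls
        counts.n_genotypes_masked = int(mask.sum())
        if counts.n_genotypes_masked:
            alleles = out.alleles.copy()
            phased = out.phased.copy()
            alleles[mask] = MISSING
            phased[mask] = False
            out = GenotypeMatrix(out.sample_ids, out.chrom, out.pos, out.ref,
                                 out.alt, alleles, phased, out.gq, out.mq,
                                 out.contig_lengths)
    return out, counts


def cluster_mask(chrom: np.ndarray, pos: np.ndarray, max_in_span: int = 3,
                 span: int = 10) -> np.ndarray:
    """True for every SNP belonging to some ``span``-bp interval with more
    than ``max_in_span`` SNPs (the whole offending cluster is marked)."""
    marked = np.zeros(len(pos), dtype=bool)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        # window anchored at each SNP: [p_i, p_i + span - 1]
        hi = np.searchsorted(p, p + span - 1, side="right")
        for i in range(len(p)):
            if hi[i] - i > max_in_span:
                marked[idx[i:hi[i]]] = True
    return marked


def filter_biallelic_and_clusters(
        gm: GenotypeMatrix, max_in_span: int = 3,
        span: int = 10) -> tuple[GenotypeMatrix, FilterCounts]:
    """Drop multiallelic sites, then drop clustered SNPs (> ``max_in_span``
    SNPs inside any ``span``-bp interval; every member of the cluster goes)."""
    counts = FilterCounts(n_sites_in=gm.n_sites)
    bi = gm.is_biallelic
    counts.detail["sites_removed_multiallelic"] = int((~bi).sum())
    out = gm.take_sites(bi)

    marked = cluster_mask(out.chrom, out.pos, max_in_span, span)
    counts.detail["sites_removed_cluster"] = int(marked.sum())
    out = out.take_sites(~marked)
    counts.n_sites_removed = counts.n_sites_in - out.n_sites
    return out, counts
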