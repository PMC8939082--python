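"""Runs of homozygosity: scanning-window detection and length-class summaries.

The detector follows the PLINK-style scanning-window scheme: a window of
``scan_window_snps`` consecutive SNPs slides one SNP at a time; a window
"hits" when it holds at most ``max_het_per_window`` heterozygous and at most
``max_miss_per_window`` missing calls; each SNP's hit proportion is the
fraction of windows covering it that hit; SNPs at or above ``hit_frac`` are
run-eligible.  Maximal stretches of eligible SNPs are split at heterozygous
calls and reported when they span at least ``min_kb`` kb and contain at
least ``min_snps`` SNPs.  Segment coordinates are delimited by the first and
last SNP of the run (1-based inclusive).

Length classes: 0.1–0.4 Mb, >0.4 Mb, with segments >1 Mb additionally
flagged (a subset of >0.4 Mb reported separately in summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap

CLASS_SHORT = "0.1-0.4Mb"
CLASS_LONG = ">0.4Mb"
CLASS_VERY_LONG = ">1Mb"


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0

    @property
    def length_class(self) -> str:
        if self.length_kb > 1000.0:
            return CLASS_VERY_LONG
        if self.length_kb >= 400.0:
            return CLASS_LONG
        return CLASS_SHORT


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def detect_roh(gm: GenotypeMatrix, sample: str, min_kb: float = 100.0,
               min_snps: int = 50, scan_window_snps: int = 50,
               max_het_per_window: int = 1, max_miss_per_window: int = 5,
               hit_frac: float = 0.05) -> list[ROHSegment]:
    """Detect runs of homozygosity for one sample (per chromosome)."""
    if sample not in gm.sample_ids:
        raise ValueError(f"unknown sample {sample!r}")
    j = gm.sample_ids.index(sample)
    het_all = gm.is_het[:, j]
    miss_all = gm.call_missing[:, j]
    segments: list[ROHSegment] = []
    for chrom in gm.chrom_order():
        on_c = np.flatnonzero(gm.chrom == chrom)
        pos = gm.pos[on_c]
        het = het_all[on_c].astype(np.int64)
        miss = miss_all[on_c].astype(np.int64)
        n = len(on_c)
        if n == 0:
            continue
        w = min(scan_window_snps, n)
        hits = ((_sliding_sum(het, w) <= max_het_per_window)
                & (_sliding_sum(miss, w) <= max_miss_per_window)).astype(np.int64)
        # windows covering SNP s: starts in [s - w + 1, s] clipped to [0, n - w]
        n_win = n - w + 1
        cum_hits = np.concatenate([[0], np.cumsum(hits)])
        s = np.arange(n)
        lo = np.clip(s - w + 1, 0, n_win - 1)
        hi = np.clip(s, 0, n_win - 1)
        cover = hi - lo + 1
        hit_cover = cum_hits[hi + 1] - cum_hits[lo]
        eligible = (hit_cover / cover >= hit_frac) & (het == 0)
        # maximal runs of eligible SNPs (het splits are implied by eligibility)
        edges = np.diff(np.concatenate([[0], eligible.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1) - 1
        for a, b in zip(starts, ends):
            length_kb = (pos[b] - pos[a] + 1) / 1000.0
            if length_kb >= min_kb and (b - a + 1) >= min_snps:
                segments.append(ROHSegment(sample, chrom, int(pos[a]),
                                           int(pos[b]), int(b - a + 1)))
    return segments


def detect_roh_all(gm: GenotypeMatrix, **kwargs) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    for s in gm.sample_ids:
        out.extend(detect_roh(gm, s, **kwargs))
    return out


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.n_snps, s.length_kb,
          s.length_class) for s in segments],
        columns=["sample", "chrom", "start", "end", "n_snps", "length_kb",
                 "length_class"])


def roh_summary(segments: list[ROHSegment], pm: PopulationMap
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group and per-sample counts/mean lengths by length class.

    Classes reported: [100, 400) kb, >=400 kb, and a >1 Mb flag counted
    separately (every >1 Mb segment is also in the >=400 kb class).
    """
    rows_sample = []
    samples = sorted({s.sample for s in segments} | set(pm.assignment))
    by_sample = {s: [] for s in samples}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    for s in samples:
        segs = by_sample[s]
        short = [x for x in segs if x.length_kb < 400.0]
        long_ = [x for x in segs if x.length_kb >= 400.0]
        very = [x for x in segs if x.length_kb > 1000.0]
        rows_sample.append((s, pm.assignment.get(s, ""), len(segs),
                            len(short), len(long_), len(very),
                            float(np.mean([x.length_kb for x in segs]))
                            if segs else 0.0))
    per_sample = pd.DataFrame(rows_sample, columns=[
        "sample", "group", "n_total", "n_100_400kb", "n_ge_400kb",
        "n_gt_1Mb", "mean_length_kb"])

    rows_group = []
    for g in pm.groups:
        sub = per_sample[per_sample["group"] == g]
        segs = [x for x in segments if pm.assignment.get(x.sample) == g]
        rows_group.append((g, int(sub["n_total"].sum()),
                           int(sub["n_100_400kb"].sum()),
                           int(sub["n_ge_400kb"].sum()),
                           int(sub["n_gt_1Mb"].sum()),
                           float(np.mean([x.length_kb for x in segs]))
                           if segs else 0.0))
    per_group = pd.DataFrame(rows_group, columns=[
        "group", "n_total", "n_100_400kb", "n_ge_400kb", "n_gt_1Mb",
        "mean_length_kb"])
    return per_group, per_sample
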