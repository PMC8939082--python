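"""Per-group diversity summaries and windowed nucleotide diversity.

Statistics follow the standard definitions:

* Ho — per site, heterozygous calls over non-missing calls; group value is
  the mean over sites with at least one non-missing call.
* He — plug-in expected heterozygosity ``2 p (1 - p)`` from the within-group
  sample frequency; an optional ``(n/(n-1))`` small-sample correction is
  available.
* Pn — fraction of sites polymorphic within the group (0 < p < 1).
* F — method-of-moments per-sample inbreeding coefficient
  ``(O_hom - E_hom) / (L - E_hom)`` over the group's polymorphic sites,
  with the unbiased per-site expected homozygosity
  ``1 - 2 p q n / (n - 1)`` (``n`` = non-missing allele count at the site).
* theta-pi — per-site mean pairwise difference ``c_ref c_alt / C(n, 2)``
  summed over the SNPs in a window and divided by the window span in bp.

Windows are 1-based inclusive sliding windows (default 50 kb span, 25 kb
step), started at 1, 1+step, ... while the start is inside the contig;
trailing windows are truncated at the contig end and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int   # 1-based inclusive
    end: int     # inclusive
    index: int
    truncated: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class DiversitySummary:
    group: str
    n_samples: int
    Ho: float
    He: float
    Pn: float
    F_mean: float
    F_by_sample: dict[str, float]


def make_windows(contig_lengths: dict[str, int], size: int = 50_000,
                 step: int = 25_000) -> list[GenomicWindow]:
    """Sliding windows per chromosome; trailing truncated windows included."""
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    out: list[GenomicWindow] = []
    idx = 0
    for chrom, length in contig_lengths.items():
        start = 1
        while start <= length:
            end = min(start + size - 1, length)
            out.append(GenomicWindow(chrom, start, end, idx,
                                     truncated=(end - start + 1 < size)))
            idx += 1
            start += step
    return out


def windows_frame(windows: list[GenomicWindow]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "index": [w.index for w in windows],
        "truncated": [w.truncated for w in windows],
    })


# ----------------------------------------------------------------------
# allele counts
# ----------------------------------------------------------------------

def group_allele_counts(gm: GenotypeMatrix, idx: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(c_alt, n) per site over the given sample columns (biallelic sites)."""
    al = gm.alleles[:, idx, :]
    called = al != -1
    c_alt = ((al > 0) & called).sum(axis=(1, 2))
    n = called.sum(axis=(1, 2))
    return c_alt.astype(np.int64), n.astype(np.int64)


def het_summary(gm: GenotypeMatrix, pm: PopulationMap,
                unbiased_he: bool = False) -> dict[str, DiversitySummary]:
    """Ho / He / Pn / F per group (biallelic sites; all-missing sites excluded)."""
    pm.check_samples(gm)
    f_by_sample, f_means = inbreeding_f(gm, pm)
    out: dict[str, DiversitySummary] = {}
    bi = gm.is_biallelic
    for g in pm.groups:
        idx = pm.indices_of(gm, g)
        al = gm.alleles[np.ix_(np.flatnonzero(bi), idx)]
        het = (al[:, :, 0] != al[:, :, 1]) & np.all(al != -1, axis=2)
        nonmiss = np.all(al != -1, axis=2)
        n_calls = nonmiss.sum(axis=1)
        usable = n_calls > 0
        ho_site = het[usable].sum(axis=1) / n_calls[usable]
        c_alt = ((al > 0) & (al != -1)).sum(axis=(1, 2))[usable]
        n_al = (2 * n_calls[usable])
        p = c_alt / n_al
        he_site = 2.0 * p * (1.0 - p)
        if unbiased_he:
            with np.errstate(invalid="ignore"):
                he_site = np.where(n_al > 1, he_site * n_al / (n_al - 1), 0.0)
        poly = (c_alt > 0) & (c_alt < n_al)
        fs = {s: f_by_sample[s] for s in pm.samples_of(g)
              if s in f_by_sample}
        out[g] = DiversitySummary(
            group=g,
            n_samples=len(idx),
            Ho=float(ho_site.mean()) if usable.any() else float("nan"),
            He=float(he_site.mean()) if usable.any() else float("nan"),
            Pn=float(poly.mean()) if usable.any() else float("nan"),
            F_mean=f_means.get(g, float("nan")),
            F_by_sample=fs,
        )
    return out


def inbreeding_f(gm: GenotypeMatrix, pm: PopulationMap
                 ) -> tuple[dict[str, float], dict[str, float]]:
    """Method-of-moments F per sample and mean per group.

    Sites monomorphic within the group are excluded; per usable site the
    expected homozygosity is ``1 - 2 p q n/(n-1)``; a sample's F is
    ``(O_hom - E_hom) / (L - E_hom)`` over its non-missing usable sites.
    """
    pm.check_samples(gm)
    bi = np.flatnonzero(gm.is_biallelic)
    f_by_sample: dict[str, float] = {}
    f_means: dict[str, float] = {}
    for g in pm.groups:
        idx = pm.indices_of(gm, g)
        al = gm.alleles[np.ix_(bi, idx)]
        called = np.all(al != -1, axis=2)          # (S, n_g)
        c_alt = ((al > 0) & (al != -1)).sum(axis=(1, 2))
        n = 2 * called.sum(axis=1)
        poly = (c_alt > 0) & (c_alt < n) & (n >= 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, c_alt / np.maximum(n, 1), 0.0)
            e_hom_site = 1.0 - 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
        hom = (al[:, :, 0] == al[:, :, 1]) & called
        vals = []
        for local_j, s in enumerate([gm.sample_ids[i] for i in idx]):
            use = poly & called[:, local_j]
            L = int(use.sum())
            o_hom = int(hom[use, local_j].sum())
            e_hom = float(e_hom_site[use].sum())
            denom = L - e_hom
            if denom == 0:
                warnings.warn(f"inbreeding F undefined for sample {s!r} "
                              f"(L - E_hom = 0)")
                f_by_sample[s] = float("nan")
            else:
                f = (o_hom - e_hom) / denom
                f_by_sample[s] = f
                vals.append(f)
        f_means[g] = float(np.mean(vals)) if vals else float("nan")
    return f_by_sample, f_means


def site_pi(c_alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference ``c_ref c_alt / C(n, 2)``; 0 when n < 2."""
    c_alt = np.asarray(c_alt, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    pairs = n * (n - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(pairs > 0, (n - c_alt) * c_alt / np.where(pairs > 0,
                                                                pairs, 1.0), 0.0)
    return pi


def windowed_pi(gm: GenotypeMatrix, pm: PopulationMap, group: str,
                windows: list[GenomicWindow]) -> pd.DataFrame:
    """Per-window theta-pi (per bp) for one group over the given windows.

    Sites with fewer than 2 non-missing alleles in the group are skipped; a
    site contributes to every window containing its position; the window sum
    is divided by the full window span.
    """
    idx = pm.indices_of(gm, group)
    bi = gm.is_biallelic
    c_alt, n = group_allele_counts(gm, idx)
    pi = site_pi(c_alt, n)
    pi[~bi] = 0.0
    pi[n < 2] = 0.0
    counted = bi & (n >= 2)

    rows = []
    for chrom in gm.chrom_order():
        on_c = gm.chrom == chrom
        pos = gm.pos[on_c]
        pi_c = pi[on_c]
        cnt_c = counted[on_c].astype(np.int64)
        cum_pi = np.concatenate([[0.0], np.cumsum(pi_c)])
        cum_n = np.concatenate([[0], np.cumsum(cnt_c)])
        for w in windows:
            if w.chrom != chrom:
                continue
            lo = np.searchsorted(pos, w.start, side="left")
            hi = np.searchsorted(pos, w.end, side="right")
            rows.append((w.chrom, w.start, w.end, w.index, w.truncated, group,
                         int(cum_n[hi] - cum_n[lo]),
                         (cum_pi[hi] - cum_pi[lo]) / w.span))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "index",
                                       "truncated", "group", "n_snps", "pi"])
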