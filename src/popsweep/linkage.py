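"""Pairwise linkage disequilibrium, binned LD decay and LD pruning.

Two r² definitions are provided:

* ``haplotype`` — gametic ``D = p_AB - p_A p_B``;
  ``r² = D² / (p_A q_A p_B q_B)``; requires phased calls and uses the
  haplotypes that are non-missing at both sites.
* ``dosage`` — squared Pearson correlation of 0/1/2 alt-dosage vectors over
  pairwise-complete samples; phase-free, the default for pruning and decay
  (matching what genotype-based tools compute on unphased data).

Decay bins follow the right-closed convention: a pair at distance d falls in
the bin with ``d_low < d <= d_high``.  Pruning is the greedy sliding-window
scheme of PLINK's ``--indep-pairwise`` (50-SNP window, 10-SNP step,
r² > 0.1): within a window, while any surviving pair exceeds the cutoff, the
member of the worst pair with the lower minor-allele frequency (tie: later
position) is removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

DEFAULT_BIN_EDGES_KB = (0.0, 1.0, 3.0, 5.0, 15.0, 60.0, 100.0)


# ----------------------------------------------------------------------
# pairwise r2
# ----------------------------------------------------------------------

def _hap_matrix(gm: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """(n_sites, 2 * n_samples) haplotype alleles, MISSING preserved."""
    al = gm.alleles[:, idx, :]
    return al.reshape(al.shape[0], -1)


def pair_r2(gm: GenotypeMatrix, i: int, j: int,
            sample_idx: np.ndarray | None = None,
            mode: str = "dosage") -> float:
    """r² between sites ``i`` and ``j``; NaN when either site is monomorphic
    among the informative samples (callers count skipped pairs)."""
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    sample_idx = np.asarray(sample_idx)
    if mode == "haplotype":
        h = _hap_matrix(gm, sample_idx)
        a, b = h[i].astype(float), h[j].astype(float)
        ok = (a != MISSING) & (b != MISSING)
        a, b = a[ok], b[ok]
        if a.size < 2:
            return float("nan")
        pa, pb = a.mean(), b.mean()
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return float("nan")
        d = (a * b).mean() - pa * pb
        return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))
    if mode == "dosage":
        dos = gm.dosage[:, sample_idx].astype(float)
        a, b = dos[i], dos[j]
        ok = (a != MISSING) & (b != MISSING)
        a, b = a[ok], b[ok]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            return float("nan")
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    raise ValueError(f"unknown r2 mode {mode!r}")


def pair_D(gm: GenotypeMatrix, i: int, j: int,
           sample_idx: np.ndarray | None = None) -> float:
    """Gametic disequilibrium ``D = p_AB - p_A p_B`` from phased haplotypes."""
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    h = _hap_matrix(gm, np.asarray(sample_idx))
    a, b = h[i].astype(float), h[j].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    return float((a * b).mean() - a.mean() * b.mean())


def _rowwise_r2(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per row over pairwise-complete columns.

    ``A``/``B`` are (n_pairs, n_obs) float with NaN for missing.
    """
    ok = ~(np.isnan(A) | np.isnan(B))
    n = ok.sum(axis=1).astype(float)
    Az = np.where(ok, A, 0.0)
    Bz = np.where(ok, B, 0.0)
    sa, sb = Az.sum(axis=1), Bz.sum(axis=1)
    saa, sbb = (Az * Az).sum(axis=1), (Bz * Bz).sum(axis=1)
    sab = (Az * Bz).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sab - sa * sb / n
        va = saa - sa * sa / n
        vb = sbb - sb * sb / n
        r2 = cov * cov / (va * vb)
    r2[(n < 2) | (va <= 0) | (vb <= 0)] = np.nan
    return r2


def pairs_r2(gm: GenotypeMatrix, I: np.ndarray, J: np.ndarray,
             sample_idx: np.ndarray, mode: str = "dosage") -> np.ndarray:
    """Vectorized r² for site-index pairs (I[k], J[k])."""
    if mode == "haplotype":
        h = _hap_matrix(gm, sample_idx).astype(float)
        h[h == MISSING] = np.nan
        return _rowwise_r2(h[I], h[J])
    if mode == "dosage":
        dos = gm.dosage[:, sample_idx].astype(float)
        dos[dos == MISSING] = np.nan
        return _rowwise_r2(dos[I], dos[J])
    raise ValueError(f"unknown r2 mode {mode!r}")


# ----------------------------------------------------------------------
# LD decay
# ----------------------------------------------------------------------

def ld_decay(gm: GenotypeMatrix, pm: PopulationMap | None, group: str | None,
             bin_edges_kb: tuple[float, ...] = DEFAULT_BIN_EDGES_KB,
             max_pairs_per_bin: int = 50_000, seed: int = 0,
             mode: str = "dosage") -> pd.DataFrame:
    """Mean r² per physical-distance bin for one group (or all samples).

    Same-chromosome SNP pairs at distance ``d_low < d <= d_high`` (kb edges)
    enter the bin; bins larger than ``max_pairs_per_bin`` are subsampled with
    a seeded RNG.  Monomorphic pairs are skipped and counted.
    """
    if pm is not None and group is not None:
        sample_idx = pm.indices_of(gm, group)
    else:
        sample_idx = np.arange(gm.n_samples)
    edges_bp = np.asarray(bin_edges_kb, dtype=float) * 1000.0
    max_d = edges_bp[-1]
    rng = np.random.default_rng(seed)

    I_all, J_all, D_all = [], [], []
    offset = 0
    for chrom in gm.chrom_order():
        on_c = np.flatnonzero(gm.chrom == chrom)
        pos = gm.pos[on_c]
        hi = np.searchsorted(pos, pos + max_d, side="right")
        counts = hi - np.arange(len(pos)) - 1
        counts = np.maximum(counts, 0)
        I = np.repeat(np.arange(len(pos)), counts)
        J = np.concatenate([np.arange(i + 1, h) for i, h in
                            zip(np.arange(len(pos)), hi)]) if counts.sum() else \
            np.empty(0, dtype=int)
        I_all.append(on_c[I])
        J_all.append(on_c[J])
        D_all.append(gm.pos[on_c[J]] - gm.pos[on_c[I]])
        offset += len(pos)
    if I_all:
        I = np.concatenate(I_all)
        J = np.concatenate(J_all)
        D = np.concatenate(D_all).astype(float)
    else:
        I = J = np.empty(0, dtype=int)
        D = np.empty(0)

    which = np.digitize(D, edges_bp, right=True) - 1  # bin of (lo, hi]
    rows = []
    for b in range(len(edges_bp) - 1):
        sel = np.flatnonzero((which == b) & (D > edges_bp[b]))
        if len(sel) > max_pairs_per_bin:
            sel = sel[np.sort(rng.choice(len(sel), size=max_pairs_per_bin,
                                         replace=False))]
        r2 = pairs_r2(gm, I[sel], J[sel], sample_idx, mode=mode)
        ok = ~np.isnan(r2)
        rows.append((group or "all", bin_edges_kb[b], bin_edges_kb[b + 1],
                     int(ok.sum()), int((~ok).sum()),
                     float(r2[ok].mean()) if ok.any() else float("nan")))
    return pd.DataFrame(rows, columns=["group", "d_low_kb", "d_high_kb",
                                       "n_pairs", "n_skipped", "mean_r2"])


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def ld_prune(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None,
             window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.1, mode: str = "dosage") -> np.ndarray:
    """Greedy ``--indep-pairwise``-style pruning; returns kept site indices.

    Post-condition (oracle-verified in tests): no surviving pair within any
    window exceeds ``r2_max``.
    """
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    sample_idx = np.asarray(sample_idx)
    dos = gm.dosage[:, sample_idx].astype(float) if mode == "dosage" else None
    if mode == "haplotype":
        dos = _hap_matrix(gm, sample_idx).astype(float)
    dos[dos == MISSING] = np.nan

    # minor-allele frequency for the removal tie-break
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=1) / (2.0 if mode == "dosage" else 1.0)
    maf = np.minimum(p, 1.0 - p)

    keep = np.ones(gm.n_sites, dtype=bool)
    for chrom in gm.chrom_order():
        surv = list(np.flatnonzero(gm.chrom == chrom))
        # repeat passes over the survivor sequence until a fixed point, so
        # the post-condition holds for windows over the survivors themselves
        changed = True
        while changed:
            changed = False
            w0 = 0
            while True:
                win = surv[w0:w0 + window_snps]
                if len(win) >= 2:
                    active = np.asarray(win)
                    r2 = _window_r2(dos, active)
                    alive = np.ones(len(active), dtype=bool)
                    while True:
                        r2m = np.where(np.outer(alive, alive), r2, np.nan)
                        np.fill_diagonal(r2m, np.nan)
                        if not np.any(r2m > r2_max):
                            break
                        worst = np.unravel_index(np.nanargmax(r2m), r2m.shape)
                        a, b = active[worst[0]], active[worst[1]]
                        # remove lower MAF; tie -> later position
                        if (maf[a], -gm.pos[a]) < (maf[b], -gm.pos[b]):
                            drop = worst[0]
                        else:
                            drop = worst[1]
                        alive[drop] = False
                        keep[active[drop]] = False
                        surv.remove(active[drop])
                        changed = True
                if w0 + window_snps >= len(surv):
                    break
                w0 += step_snps
    return np.flatnonzero(keep)


def _window_r2(dos: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Pairwise r² matrix among a small set of sites (pairwise-complete)."""
    X = dos[sites]
    k = len(sites)
    out = np.empty((k, k))
    for i in range(k):
        out[i] = _rowwise_r2(np.tile(X[i], (k, 1)), X)
    return out
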