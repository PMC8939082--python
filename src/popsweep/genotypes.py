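"""Shared genotype data model.

A :class:`GenotypeMatrix` holds a multi-sample diploid SNP panel as dense
numpy arrays: one row per site, one column per sample, two allele slots per
genotype.  Allele values are indices into ``(ref,) + alts`` with ``-1`` for a
missing allele.  Alt-allele *dosage* (0/1/2) is defined only for biallelic
sites.

A :class:`PopulationMap` assigns each sample to a group (e.g. an ecotype or a
commercial line) and each group to one of two supersets, ``native`` or
``commercial``, so that pooled contrasts ("all native birds vs one line") can
be requested by superset name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

SUPERSETS = ("native", "commercial")


class PopmapError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """samples x biallelic-SNP diploid calls with positions and optional quality."""

    sample_ids: list[str]
    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64, 1-based
    ref: np.ndarray            # (n_sites,) str
    alt: list[tuple[str, ...]] # per-site alt alleles
    alleles: np.ndarray        # (n_sites, n_samples, 2) int8, MISSING = -1
    phased: np.ndarray         # (n_sites, n_samples) bool
    gq: np.ndarray | None = None   # (n_sites, n_samples) float32
    mq: np.ndarray | None = None   # (n_sites,) float32, NaN where absent
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample names")
        if self.alleles.shape != (self.n_sites, self.n_samples, 2):
            raise ValueError("alleles array shape mismatch")
        # positions strictly increasing within each chromosome
        for c in self.chrom_order():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ---- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def chrom_order(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    # ---- derived views --------------------------------------------------
    @property
    def is_biallelic(self) -> np.ndarray:
        return np.fromiter((len(a) == 1 for a in self.alt), dtype=bool,
                           count=self.n_sites)

    @property
    def call_missing(self) -> np.ndarray:
        """(n_sites, n_samples) True where either allele is missing."""
        return np.any(self.alleles == MISSING, axis=2)

    @property
    def dosage(self) -> np.ndarray:
        """Alt-allele dosage 0/1/2, MISSING where any allele missing.

        Defined for biallelic sites; multiallelic rows count any non-ref
        allele and must be removed before dosage-based analyses.
        """
        d = np.sum(self.alleles > 0, axis=2).astype(np.int8)
        d[self.call_missing] = MISSING
        return d

    @property
    def is_het(self) -> np.ndarray:
        """(n_sites, n_samples) True where the two called alleles differ."""
        return (self.alleles[:, :, 0] != self.alleles[:, :, 1]) & ~self.call_missing

    def effective_contig_lengths(self) -> dict[str, int]:
        """Header lengths when present, else max observed position per chrom."""
        out: dict[str, int] = {}
        for c in self.chrom_order():
            if self.contig_lengths and c in self.contig_lengths:
                out[c] = int(self.contig_lengths[c])
            else:
                out[c] = int(self.pos[self.chrom == c].max())
        return out

    # ---- subsetting ------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=[self.alt[i] for i in idx],
            alleles=self.alleles[idx],
            phased=self.phased[idx],
            gq=None if self.gq is None else self.gq[idx],
            mq=None if self.mq is None else self.mq[idx],
            contig_lengths=None if self.contig_lengths is None
            else dict(self.contig_lengths),
        )

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=list(self.alt),
            alleles=self.alleles[:, idx],
            phased=self.phased[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            mq=self.mq,
            contig_lengths=None if self.contig_lengths is None
            else dict(self.contig_lengths),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented

        def _optq(a, b):
            if a is None and b is None:
                return True
            if (a is None) != (b is None):
                return False
            return np.allclose(a, b, equal_nan=True)

        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and self.alt == other.alt
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.phased, other.phased)
            and _optq(self.gq, other.gq)
            and _optq(self.mq, other.mq)
            and (self.contig_lengths or None) == (other.contig_lengths or None)
        )


@dataclass
class PopulationMap:
    """Sample -> group assignment plus group -> {native, commercial} tag."""

    assignment: dict[str, str]               # sample -> group
    superset: dict[str, str]                 # group -> native|commercial

    def __post_init__(self) -> None:
        for g, s in self.superset.items():
            if s not in SUPERSETS:
                raise PopmapError(
                    f"unknown superset {s!r} for group {g!r}; "
                    f"expected one of {SUPERSETS}")
        for s, g in self.assignment.items():
            if g not in self.superset:
                raise PopmapError(f"sample {s!r} assigned to unmapped group {g!r}")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, label: str) -> list[str]:
        """Samples of a group, or of a whole superset when ``label`` names one."""
        if label in self.superset:
            return [s for s, g in self.assignment.items() if g == label]
        if label in SUPERSETS:
            return [s for s, g in self.assignment.items()
                    if self.superset[g] == label]
        raise PopmapError(f"unknown group or superset {label!r}")

    def indices_of(self, gm: GenotypeMatrix, label: str) -> np.ndarray:
        """Column indices in ``gm`` of the samples carrying ``label``."""
        wanted = set(self.samples_of(label))
        idx = np.array([i for i, s in enumerate(gm.sample_ids) if s in wanted],
                       dtype=np.intp)
        if idx.size == 0:
            raise PopmapError(f"no samples of {label!r} present in the matrix")
        return idx

    def check_samples(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.assignment]
        if missing:
            raise PopmapError(f"samples absent from population map: {missing[:5]}")
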