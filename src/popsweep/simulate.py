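"""Structured-population diploid genotype simulator.

The generator produces multi-population SNP panels with controllable

* divergence — population allele frequencies follow the Balding–Nichols
  model: given an ancestral frequency ``p`` drawn uniformly on
  ``[freq_low, freq_high]``, each population draws its own frequency from
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose variance is ``F p (1-p)``, so the
  genome-wide Weir–Cockerham F_ST of the panel concentrates around ``F``;
* linkage disequilibrium — each sample haplotype is a mosaic of
  ``n_founders`` founder haplotypes, with the founder identity resampled
  between adjacent SNPs ``d`` bp apart with probability
  ``1 - exp(-switch_rate * d)``; small switch rates give long founder tracts
  and hence r² that decays smoothly with distance;
* inbreeding — a fraction ``inbreeding_fis`` of individuals per group carry
  two copies of one haplotype (whole-genome autozygosity); the assignment is
  stratified so the realized fraction equals the parameter;
* selective sweeps — inside a planted interval the target group's
  frequencies are pushed toward fixation, ``p' = (1-s) p + s round(p)``,
  before haplotypes are drawn, which removes that group's local diversity
  and inflates local differentiation;
* runs of homozygosity — inside a planted interval a named sample's second
  haplotype is overwritten by its first.

Every random step is a pure function of ``(config, seed)``; emitted files
are byte-identical across reruns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotypes import GenotypeMatrix, PopulationMap
from . import variant_io


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    start: int          # 1-based inclusive
    end: int            # inclusive
    target_group: str
    s: float            # severity in [0, 1]


@dataclass(frozen=True)
class ROHSpec:
    sample: str
    chrom: str
    start: int
    end: int


@dataclass
class SimConfig:
    n_pops: int = 2
    n_diploids_per_pop: int = 20
    n_chroms: int = 1
    chrom_length: int = 5_000_000
    n_snps_per_chrom: int = 5_000
    bn_F: float = 0.2
    freq_low: float = 0.05
    freq_high: float = 0.95
    n_founders: int = 20
    switch_rate: float = 2e-5
    sweeps: list[SweepSpec] = field(default_factory=list)
    roh_plants: list[ROHSpec] = field(default_factory=list)
    inbreeding_fis: float | dict[str, float] = 0.0
    seed: int = 0
    pop_names: list[str] | None = None
    pop_supersets: list[str] | None = None

    def resolved_pop_names(self) -> list[str]:
        if self.pop_names is not None:
            return list(self.pop_names)
        if self.n_pops == 2:
            return ["native", "commercial"]
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    def resolved_supersets(self) -> list[str]:
        if self.pop_supersets is not None:
            return list(self.pop_supersets)
        # default contrast: last population is the commercial line
        return ["native"] * (self.n_pops - 1) + ["commercial"]

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def fis_of(self, group: str) -> float:
        if isinstance(self.inbreeding_fis, dict):
            return float(self.inbreeding_fis.get(group, 0.0))
        return float(self.inbreeding_fis)

    def validate(self) -> None:
        for name in ("n_pops", "n_diploids_per_pop", "n_chroms",
                     "chrom_length", "n_snps_per_chrom", "n_founders"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if not (0.0 <= self.bn_F < 1.0):
            raise SimConfigError("bn_F must lie in [0, 1)")
        if not (0.0 <= self.freq_low < self.freq_high <= 1.0):
            raise SimConfigError("freq_low/freq_high must satisfy "
                                 "0 <= freq_low < freq_high <= 1")
        if self.switch_rate < 0:
            raise SimConfigError("switch_rate must be non-negative")
        if self.n_snps_per_chrom > self.chrom_length:
            raise SimConfigError(
                "n_snps_per_chrom exceeds chrom_length (1-bp minimum spacing)")
        names = self.resolved_pop_names()
        if len(names) != self.n_pops or len(set(names)) != self.n_pops:
            raise SimConfigError("pop_names must give one unique name per pop")
        if len(self.resolved_supersets()) != self.n_pops:
            raise SimConfigError("pop_supersets must give one tag per pop")
        for g in names:
            f = self.fis_of(g)
            if not (0.0 <= f <= 1.0):
                raise SimConfigError("inbreeding_fis must lie in [0, 1]")
        for sw in self.sweeps:
            if not (0.0 <= sw.s <= 1.0):
                raise SimConfigError("sweeps: severity s must lie in [0, 1]")
            if sw.chrom not in self.chrom_names():
                raise SimConfigError(f"sweeps: unknown chrom {sw.chrom!r}")
            if not (1 <= sw.start <= sw.end <= self.chrom_length):
                raise SimConfigError("sweeps: interval outside chromosome")
            if sw.target_group not in names + ["native", "commercial"]:
                raise SimConfigError(
                    f"sweeps: unknown target_group {sw.target_group!r}")
        for rp in self.roh_plants:
            if rp.chrom not in self.chrom_names():
                raise SimConfigError(f"roh_plants: unknown chrom {rp.chrom!r}")
            if not (1 <= rp.start <= rp.end <= self.chrom_length):
                raise SimConfigError("roh_plants: interval outside chromosome")


@dataclass
class Frequencies:
    """Per-chromosome SNP positions, ancestral and per-population frequencies."""

    pos: dict[str, np.ndarray]           # chrom -> (S,) int64, sorted unique
    p_anc: dict[str, np.ndarray]         # chrom -> (S,)
    p_pop: dict[str, np.ndarray]         # chrom -> (n_pops, S)


@dataclass
class SimTruth:
    seed: int
    sweeps: list[SweepSpec] = field(default_factory=list)
    roh: list[ROHSpec] = field(default_factory=list)
    model_freqs: Frequencies | None = None       # Balding–Nichols draws (post-sweep)
    founder_freqs: dict[str, np.ndarray] | None = None  # chrom -> (n_pops, S) realized


@dataclass
class HaplotypePanel:
    """Phased haplotypes: chrom -> (2 * n_diploids_total, S) int8 array.

    Haplotypes ``2j`` and ``2j + 1`` belong to diploid ``j``; diploids are
    laid out population by population in config order.
    """

    cfg: SimConfig
    haps: dict[str, np.ndarray]
    pos: dict[str, np.ndarray]

    def sample_ids(self) -> list[str]:
        out = []
        for name in self.cfg.resolved_pop_names():
            out += [f"{name}_{i + 1:03d}"
                    for i in range(self.cfg.n_diploids_per_pop)]
        return out


# ----------------------------------------------------------------------
# generation steps
# ----------------------------------------------------------------------

def draw_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None
                     ) -> Frequencies:
    """Draw SNP positions, ancestral and Balding–Nichols per-pop frequencies."""
    cfg.validate()
    if cfg.bn_F >= 1.0:
        raise SimConfigError("bn_F must be < 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pos, p_anc, p_pop = {}, {}, {}
    for c in cfg.chrom_names():
        pos[c] = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_snps_per_chrom,
                                    replace=False)) + 1
        p = rng.uniform(cfg.freq_low, cfg.freq_high, size=cfg.n_snps_per_chrom)
        p_anc[c] = p
        if cfg.bn_F == 0.0:
            p_pop[c] = np.tile(p, (cfg.n_pops, 1))
        else:
            ratio = (1.0 - cfg.bn_F) / cfg.bn_F
            p_pop[c] = rng.beta(p * ratio, (1.0 - p) * ratio,
                                size=(cfg.n_pops, cfg.n_snps_per_chrom))
    return Frequencies(pos=pos, p_anc=p_anc, p_pop=p_pop)


def _pop_index(cfg: SimConfig, group: str) -> list[int]:
    names = cfg.resolved_pop_names()
    tags = cfg.resolved_supersets()
    if group in names:
        return [names.index(group)]
    if group in ("native", "commercial"):
        return [i for i, t in enumerate(tags) if t == group]
    raise SimConfigError(f"unknown target_group {group!r}")


def plant_sweep(freqs: Frequencies, truth: SimTruth, sweep: SweepSpec,
                cfg: SimConfig) -> None:
    """Push the target group's frequencies toward fixation inside the interval.

    ``p' = (1 - s) p + s round(p)``; ``s = 1`` fixes the locally major allele.
    Applied before haplotype drawing.  A second sweep for the same group on an
    overlapping interval is rejected.
    """
    for prev in truth.sweeps:
        if (prev.chrom == sweep.chrom
                and set(_pop_index(cfg, prev.target_group))
                & set(_pop_index(cfg, sweep.target_group))
                and prev.start <= sweep.end and sweep.start <= prev.end):
            raise SimConfigError(
                "overlapping sweeps for one group on one interval")
    pops = _pop_index(cfg, sweep.target_group)
    p = freqs.pos[sweep.chrom]
    inside = (p >= sweep.start) & (p <= sweep.end)
    for k in pops:
        pk = freqs.p_pop[sweep.chrom][k]
        pk[inside] = (1.0 - sweep.s) * pk[inside] + sweep.s * np.rint(pk[inside])
    truth.sweeps.append(sweep)


def generate_haplotypes(freqs: Frequencies, cfg: SimConfig,
                        rng: np.random.Generator,
                        truth: SimTruth | None = None) -> HaplotypePanel:
    """Draw founder haplotypes and sample mosaics; pair into diploids.

    Per site, the ``n_founders`` founder alleles carry a balanced draw from
    the population frequency: the alt-allele count is a randomized rounding
    of ``n_founders * p_pop`` assigned to founders without replacement.
    (Site-wise iid Bernoulli founders would add ``~1/n_founders`` of extra
    drift variance on top of the Balding–Nichols divergence and pull the
    realized F_ST above ``bn_F``; the balanced draw caps founder-stage drift
    at ``1/(4 n_founders^2)`` so the divergence knob stays calibrated.)

    A sample haplotype copies one founder, resampling the founder index
    between adjacent SNPs with probability ``1 - exp(-switch_rate * d)``.
    The two haplotypes of one diploid choose founders independently, so the
    expected heterozygosity at a site equals ``2 f (1 - f)`` of the realized
    founder frequency ``f`` exactly.  ``round(fis * n)`` diploids per group
    (seeded choice) are made autozygous by duplicating their first haplotype.
    """
    n_d = cfg.n_diploids_per_pop
    n_hap = 2 * n_d
    haps: dict[str, np.ndarray] = {}
    founder_freqs: dict[str, np.ndarray] = {}
    chroms = cfg.chrom_names()
    for c in chroms:
        S = len(freqs.pos[c])
        haps[c] = np.empty((cfg.n_pops * n_hap, S), dtype=np.int8)
        founder_freqs[c] = np.empty((cfg.n_pops, S))

    for k in range(cfg.n_pops):
        rows = slice(k * n_hap, (k + 1) * n_hap)
        for c in chroms:
            p = freqs.p_pop[c][k]
            S = len(p)
            K = cfg.n_founders
            target = K * p
            m = np.floor(target).astype(np.int64)
            m += rng.random(S) < (target - m)
            # assign the m alt alleles to a uniform founder subset per site
            u = rng.random((K, S))
            order = np.argsort(u, axis=0, kind="stable")
            rank = np.empty_like(order)
            np.put_along_axis(rank, order,
                              np.broadcast_to(np.arange(K)[:, None], (K, S)),
                              axis=0)
            founders = (rank < m).astype(np.int8)
            founder_freqs[c][k] = founders.mean(axis=0)
            cand = rng.integers(0, cfg.n_founders, size=(n_hap, S))
            if S > 1:
                d = np.diff(freqs.pos[c]).astype(float)
                p_sw = 1.0 - np.exp(-cfg.switch_rate * d)
                sw = rng.random((n_hap, S - 1)) < p_sw[None, :]
                full = np.concatenate(
                    [np.ones((n_hap, 1), dtype=bool), sw], axis=1)
            else:
                full = np.ones((n_hap, 1), dtype=bool)
            last = np.maximum.accumulate(
                np.where(full, np.arange(S)[None, :], 0), axis=1)
            fidx = np.take_along_axis(cand, last, axis=1)
            haps[c][rows] = np.take_along_axis(
                founders, fidx, axis=0)

    # stratified autozygosity: exactly round(fis * n) individuals per group
    names = cfg.resolved_pop_names()
    for k, g in enumerate(names):
        n_auto = int(round(cfg.fis_of(g) * n_d))
        if n_auto:
            chosen = rng.permutation(n_d)[:n_auto]
            for c in chroms:
                for i in chosen:
                    r = k * n_hap + 2 * i
                    haps[c][r + 1] = haps[c][r]

    if truth is not None:
        truth.founder_freqs = founder_freqs
        truth.model_freqs = freqs
    return HaplotypePanel(cfg=cfg, haps=haps,
                          pos={c: freqs.pos[c] for c in chroms})


def plant_roh(panel: HaplotypePanel, truth: SimTruth, spec: ROHSpec) -> None:
    """Copy the named sample's first haplotype over its second in the interval."""
    ids = panel.sample_ids()
    if spec.sample not in ids:
        raise SimConfigError(f"unknown sample {spec.sample!r}")
    if spec.chrom not in panel.haps:
        raise SimConfigError(f"unknown chrom {spec.chrom!r}")
    j = ids.index(spec.sample)
    p = panel.pos[spec.chrom]
    inside = np.flatnonzero((p >= spec.start) & (p <= spec.end))
    h = panel.haps[spec.chrom]
    h[2 * j + 1, inside] = h[2 * j, inside]
    truth.roh.append(spec)


def build_matrix(panel: HaplotypePanel, freqs: Frequencies) -> GenotypeMatrix:
    """Assemble the phased panel into a :class:`GenotypeMatrix`."""
    cfg = panel.cfg
    ids = panel.sample_ids()
    chroms = cfg.chrom_names()
    chrom_col, pos_col, allele_blocks = [], [], []
    for c in chroms:
        S = len(freqs.pos[c])
        chrom_col += [c] * S
        pos_col.append(freqs.pos[c])
        h = panel.haps[c]                       # (2N, S)
        a = np.empty((S, len(ids), 2), dtype=np.int8)
        a[:, :, 0] = h[0::2].T
        a[:, :, 1] = h[1::2].T
        allele_blocks.append(a)
    n_sites = len(chrom_col)
    alleles = np.concatenate(allele_blocks, axis=0)
    return GenotypeMatrix(
        sample_ids=ids,
        chrom=np.asarray(chrom_col, dtype=object),
        pos=np.concatenate(pos_col),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=[("C",)] * n_sites,
        alleles=alleles,
        phased=np.ones((n_sites, len(ids)), dtype=bool),
        contig_lengths={c: cfg.chrom_length for c in chroms},
    )


def population_map(cfg: SimConfig) -> PopulationMap:
    names = cfg.resolved_pop_names()
    tags = cfg.resolved_supersets()
    assignment = {}
    for name in names:
        for i in range(cfg.n_diploids_per_pop):
            assignment[f"{name}_{i + 1:03d}"] = name
    return PopulationMap(assignment=assignment,
                         superset=dict(zip(names, tags)))


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Run the whole generator: frequencies -> sweeps -> haplotypes -> ROH."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = SimTruth(seed=cfg.seed)
    freqs = draw_frequencies(cfg, rng)
    for sw in cfg.sweeps:
        plant_sweep(freqs, truth, sw, cfg)
    panel = generate_haplotypes(freqs, cfg, rng, truth)
    for rp in cfg.roh_plants:
        plant_roh(panel, truth, rp)
    gm = build_matrix(panel, freqs)
    return gm, population_map(cfg), truth


def make_roh_panel(positions: np.ndarray, plants: list[ROHSpec],
                   sample_ids: list[str], chrom: str = "chr1",
                   chrom_length: int | None = None) -> GenotypeMatrix:
    """Idealized ROH fixture: every call heterozygous except planted runs.

    A maximally heterozygous background makes run boundaries exact at the
    first/last SNP inside each planted interval, which is the designed
    condition for boundary-accuracy checks (random backgrounds extend runs by
    chance homozygous flanking SNPs).
    """
    positions = np.asarray(positions, dtype=np.int64)
    S, N = len(positions), len(sample_ids)
    alleles = np.empty((S, N, 2), dtype=np.int8)
    alleles[:, :, 0] = 0
    alleles[:, :, 1] = 1
    for rp in plants:
        if rp.sample not in sample_ids:
            raise SimConfigError(f"unknown sample {rp.sample!r}")
        j = sample_ids.index(rp.sample)
        inside = (positions >= rp.start) & (positions <= rp.end)
        alleles[inside, j, 1] = 0
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        chrom=np.asarray([chrom] * S, dtype=object),
        pos=positions,
        ref=np.asarray(["A"] * S, dtype=object),
        alt=[("C",)] * S,
        alleles=alleles,
        phased=np.ones((S, N), dtype=bool),
        contig_lengths={chrom: int(chrom_length or positions.max())},
    )


# ----------------------------------------------------------------------
# emission
# ----------------------------------------------------------------------

def _bed_line(chrom: str, start: int, end: int, name: str) -> str:
    # 1-based inclusive -> 0-based half-open at the writer boundary
    return f"{chrom}\t{start - 1}\t{end}\t{name}"


def emit(gm: GenotypeMatrix, pm: PopulationMap, truth: SimTruth,
         cfg: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write VCF, popmap, truth BEDs and a config echo; deterministic bytes."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in
             [("vcf", "sim.vcf"), ("popmap", "popmap.tsv"),
              ("sweeps", "truth_sweeps.bed"), ("roh", "truth_roh.bed"),
              ("config", "config.txt")]}
    variant_io.write_vcf(gm, paths["vcf"])
    variant_io.write_popmap(pm, paths["popmap"])
    with open(paths["sweeps"], "w") as fh:
        for sw in truth.sweeps:
            fh.write(_bed_line(sw.chrom, sw.start, sw.end,
                               f"{sw.target_group};s={sw.s:g}") + "\n")
    with open(paths["roh"], "w") as fh:
        for rp in truth.roh:
            fh.write(_bed_line(rp.chrom, rp.start, rp.end, rp.sample) + "\n")
    with open(paths["config"], "w") as fh:
        d = asdict(cfg)
        for k in sorted(d):
            fh.write(f"{k}={d[k]!r}\n")
    return paths
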