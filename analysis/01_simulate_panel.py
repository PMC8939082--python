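#!/usr/bin/env python
"""Simulate the study panel: three native ecotype populations and two
commercial lines, with two sweeps planted in the commercial lines and two
autozygous runs planted in named birds.

Writes results/panel/ (VCF, popmap, truth BEDs, config echo) and prints the
panel dimensions.  Every downstream analysis script reads this directory.
"""

import pathlib

from popsweep.simulate import ROHSpec, SimConfig, SweepSpec, emit, simulate

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "panel"

CFG = SimConfig(
    n_pops=5,
    pop_names=["yazd", "marand", "shiraz", "leghorn", "arian"],
    pop_supersets=["native", "native", "native", "commercial", "commercial"],
    n_diploids_per_pop=10,
    n_chroms=2,
    chrom_length=10_000_000,
    n_snps_per_chrom=5_000,
    bn_F=0.12,
    n_founders=8,
    switch_rate=3e-5,
    inbreeding_fis={"leghorn": 0.2, "arian": 0.2},
    sweeps=[SweepSpec("chr1", 4_000_000, 4_200_000, "commercial", 0.9),
            SweepSpec("chr2", 7_000_000, 7_180_000, "commercial", 0.9)],
    roh_plants=[ROHSpec("leghorn_001", "chr1", 2_000_000, 2_600_000),
                ROHSpec("yazd_001", "chr2", 1_000_000, 1_450_000)],
    seed=2024,
)


def main():
    gm, pm, truth = simulate(CFG)
    paths = emit(gm, pm, truth, CFG, OUT)
    print(f"panel: {gm.n_sites} SNPs x {gm.n_samples} diploids "
          f"({len(pm.groups)} groups), seed={CFG.seed}")
    print(f"planted sweeps: {[(s.chrom, s.start, s.end) for s in truth.sweeps]}")
    print(f"planted ROHs:   {[(r.sample, r.start, r.end) for r in truth.roh]}")
    for k, v in sorted(paths.items()):
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
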