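#!/usr/bin/env python
"""LD decay per group, LD pruning, and runs of homozygosity.

Writes results/linkage/*.tsv and prints (i) the binned r² decay for one
native ecotype and one commercial line — the line, built from fewer
effective founders and carrying planted autozygosity, holds more LD — and
(ii) the ROH table, which should contain the two planted runs.
"""

import pathlib

import pandas as pd

from popsweep import linkage, roh, variant_io
from popsweep.pipeline import ScanConfig, provenance, write_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    gm = variant_io.read_vcf(ROOT / "filtered.vcf")
    pm = variant_io.read_popmap(ROOT / "panel" / "popmap.tsv")
    cfg = ScanConfig()
    out = ROOT / "linkage"

    decay = pd.concat([linkage.ld_decay(gm, pm, g, seed=cfg.seed)
                       for g in ("yazd", "leghorn")], ignore_index=True)
    write_table(decay, out / "ld_decay.tsv", provenance(cfg))
    print(decay.round(4).to_string(index=False))

    kept = linkage.ld_prune(gm)
    write_table(pd.DataFrame({"chrom": gm.chrom[kept], "pos": gm.pos[kept]}),
                out / "pruned_sites.tsv", provenance(cfg))
    print(f"\nLD pruning: kept {len(kept)} of {gm.n_sites} sites")

    segs = roh.detect_roh_all(gm)
    write_table(roh.segments_frame(segs), out / "roh_segments.tsv",
                provenance(cfg))
    per_group, per_sample = roh.roh_summary(segs, pm)
    write_table(per_group, out / "roh_by_group.tsv", provenance(cfg))
    write_table(per_sample, out / "roh_by_sample.tsv", provenance(cfg))
    print(f"ROH segments detected: {len(segs)}")
    print(roh.segments_frame(segs).to_string(index=False))


if __name__ == "__main__":
    main()
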