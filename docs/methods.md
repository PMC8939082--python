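# Methods

This note records the models, estimator conventions, parameter defaults and
numerical choices behind `popsweep`, and what the synthetic-data tests do
and do not establish about real data.

## Data model and coordinates

Genotypes are held as a dense sites × samples × 2 allele-index array with
`-1` for missing; dosage (0/1/2 alt copies) is defined only for biallelic
sites. All internal coordinates are 1-based inclusive (VCF convention);
BED output converts to 0-based half-open at the writer boundary only.
When a VCF header carries no contig lengths, the maximum observed position
per chromosome is used instead — this shortens trailing windows, so
truncated windows are flagged in every windowed table.

## Site filters

* **Genotype quality** is applied per genotype: calls with GQ below the
  threshold (default 40) become missing, which preserves the remaining
  information at the site. **Mapping quality** is a site property: sites
  with INFO/MQ below the threshold (default 25) are dropped. Sites or
  calls lacking the respective field pass unchanged, and each pass reports
  input/removed/retained counts that always reconcile.
* **Cluster filter**: after removing sites with more than two alleles,
  every SNP lying in any 10-bp interval that contains more than 3 SNPs is
  removed together with the other members of that interval (the whole
  cluster goes, matching the idea that tightly clustered calls are
  alignment artefacts). Both filters are idempotent.
* No per-site missingness cutoff is applied after GQ masking by default;
  downstream estimators handle missing calls explicitly.

## Diversity statistics

Per site within a group: `ho` = heterozygous calls / non-missing calls;
`he = 2p̂(1−p̂)` with the plug-in within-group frequency (an optional
`n/(n−1)` small-sample correction exists but is off by default, matching
what genotype-based tools report); `Pn` counts sites with `0 < p̂ < 1`.
Group values average over sites with at least one non-missing call.

The inbreeding coefficient is the method-of-moments excess homozygosity
`F = (O_hom − E_hom)/(L − E_hom)` per sample, over the sites polymorphic
within the sample's own group, with the unbiased per-site expectation
`E_hom = 1 − 2p̂q̂·n/(n−1)` (n = non-missing allele count at the site).
Within-group frequencies are used because the statistic is reported per
group; `F` is invariant to adding group-monomorphic sites. When
`L − E_hom = 0` the coefficient is undefined and reported missing with a
warning.

θπ per site is `c_ref·c_alt / C(n,2)`, the mean pairwise difference among
the sampled haplotypes (exactly equal to the exhaustive pairwise count, and
unbiased for `2pq`). Windowed θπ divides the per-site sum by the full
window span (end − start + 1), including truncated trailing windows —
the convention of windowed-π tools; a callable-sites denominator would not
be comparable across groups with different missingness. Sites are assigned
to every window containing their position, so the 50 kb / 25 kb scheme
double-covers by design.

## Weir–Cockerham F_ST

The per-site variance components a (among populations), b (among
individuals within populations) and c (within individuals) follow the
classical two-level moment equations for r populations (r = 2 in the
native-vs-commercial contrast); `h_i` is the proportion of heterozygous
diploids among non-missing diploids of group i. Sites need `n̄ > 1` and at
least one non-missing diploid per group; sites monomorphic across the
contrast contribute (0, 0, 0) and are excluded from sums. The window and
genome-wide estimator is the ratio of sums Σa / Σ(a+b+c) — the "weighted"
estimator, preferred with unequal group sizes; a mean-of-per-site-ratios
variant is available because the two conventions genuinely differ and both
appear in applied work. Negative values are kept: clamping would distort
the empirical quantiles used downstream.

## Outlier scan

Windows with no usable F_ST site, or zero θπ in either group, are flagged
and excluded from ranking (counts always reported). Outliers are the
`k = ⌈frac·N⌉` largest values among usable windows (nearest-rank
convention; ties broken by genomic order, earlier window first; the
reported threshold is the smallest flagged value). Defaults: 5 % for
F_ST and 1 % for the log2 ratio. The ratio's flagged tail defaults to
`upper` — large `log2(θπ_native/θπ_commercial)` means diversity loss in the
commercial group — with `lower` available for the symmetric question.
Flagged windows merge into regions when they overlap or are book-ended;
the intersection of the two statistics' region sets is the high-confidence
candidate list. Gene annotation reports every gene overlapping a region by
at least 1 bp, once, with all supporting regions and statistics;
chromosomes absent from the annotation produce a warning, not an error.

## LD and ROH

Dosage-mode r² (squared Pearson correlation over pairwise-complete
samples) is the default for decay and pruning since it needs no phase;
haplotype-mode `D²/(p_A q_A p_B q_B)` is available for the simulator's
phased output. Decay bins are right-closed between the listed edges
(0–1–3–5–15–60–100 kb); oversized bins are subsampled with the run's seed.
Pruning repeats greedy passes over 50-SNP windows (10-SNP step) until a
fixed point, removing from each worst pair the lower-MAF member (tie: the
later position), so the post-condition — no surviving within-window pair
with r² above the cutoff — holds for windows over the survivor sequence
itself and is oracle-verified in the tests.

ROH detection is the scanning-window scheme: 50-SNP windows slide one SNP
at a time, a window hits when it has ≤1 heterozygous and ≤5 missing calls,
a SNP is run-eligible when ≥5 % of the windows covering it hit, and maximal
eligible stretches split at heterozygous calls are reported when they span
≥100 kb and ≥50 SNPs. With these thresholds the outermost SNP of a true
run is covered by only 2 hitting windows out of 50 (4 %), so detected
boundaries sit one SNP inside the truth on an otherwise heterozygous
background — boundary accuracy is therefore stated as "within one
inter-SNP gap". On random backgrounds chance homozygous flanking SNPs
extend runs by a geometric number of markers; single-gap accuracy is a
property of the idealized maximally heterozygous fixture
(`simulate.make_roh_panel`), which is what the recovery tests use.

## GRM and PCA

The relationship matrix standardizes dosages by panel-wide frequencies,
`(x − 2p̂)/√(2p̂(1−p̂))`, over polymorphic biallelic sites, with per-pair
site counts (pairwise-complete) so missingness needs no imputation. PCA
eigendecomposes the double-centered matrix; coordinates are eigenvectors
scaled by √λ, variance fractions use the positive spectrum, and each
eigenvector's sign is fixed so its largest-magnitude entry is positive,
making outputs bit-reproducible.

## The simulator

The generator emulates a structured panel of diploid SNP genotypes:

* **Divergence.** Ancestral frequencies are uniform on
  `[freq_low, freq_high]` (default 0.05–0.95); each population draws its
  frequency from the Balding–Nichols Beta with variance `F·p(1−p)`, so the
  genome-wide weighted F_ST of a no-sweep panel concentrates on `bn_F`
  (recovered within ±0.02 at 20,000 sites and 50+50 diploids; measured
  ≈0.202 and ≈0.052 at targets 0.2 and 0.05).
* **Founders and LD.** Each population has `n_founders` founder haplotypes
  (default 20); per site, the founders' alt-allele count is a randomized
  rounding of `n_founders·p_pop` assigned without replacement. A plain iid
  Bernoulli founder draw would add ≈`1/n_founders` of extra drift variance
  and push realized F_ST visibly above the knob (measured +0.04 at K = 20),
  so the balanced draw — which caps founder-stage drift at `1/(4K²)` — is
  used to keep the divergence parameter calibrated. Sample haplotypes are
  founder mosaics: the founder index is resampled between adjacent SNPs
  with probability `1 − exp(−switch_rate·Δbp)` (default 2×10⁻⁵/bp, giving
  r² decay over tens of kb). Mean r² then decays monotonically with
  distance; with very large switch rates sites decouple and every bin sits
  at the finite-sample null ≈ 1/(2N).
* **Heterozygosity identity.** The two haplotypes of a diploid choose
  founders independently, so the per-site heterozygote probability equals
  `2f(1−f)` of the realized founder frequency exactly — used as a
  generator invariant test.
* **Inbreeding.** `inbreeding_fis` is the fraction of individuals per group
  carrying two copies of one haplotype. Exactly `round(fis·n)` individuals
  are chosen by the seeded RNG — a stratified assignment, so the realized
  autozygous fraction equals the parameter instead of fluctuating
  binomially around it; the method-of-moments F then recovers the knob
  within ±0.05 at 10,000 SNPs. Autozygosity is whole-genome, which is the
  extreme of inbreeding; segmental autozygosity is produced separately by
  `plant_roh`.
* **Sweeps.** Inside a planted interval, the target group's frequencies
  move toward fixation, `p′ = (1−s)p + s·round(p)`, before haplotypes are
  drawn: severity `s = 1` makes the group locally monomorphic (windowed
  θπ = 0), `s = 0` is the identity. This both removes the group's local
  diversity and inflates local differentiation — the two signals the scan
  flags. Overlapping sweeps for one group are rejected.
* **Determinism.** Every stochastic step is a pure function of
  (config, seed); emitted files are byte-identical across reruns.

What the simulator does **not** model: demography (growth, migration,
admixture), realistic recombination maps or hotspots, sequencing error and
genotype likelihoods, allele-frequency spectra shaped by selection at
linked sites. Passing tests therefore establish the correctness of the
estimators and the scan logic under a clean structured-population model,
not calling quality or robustness to demographic confounding on real data.

## Problem sizes

The default analysis panel is 2 chromosomes × 10 Mb with 5,000 SNPs each
and 50 diploids in 5 groups; the acceptance computations use up to
100,000 sites (5 × 20 Mb, 10 planted sweeps) for scan power, 20,000 sites
and 50+50 diploids for divergence recovery, and 20,000 idealized markers
for ROH recovery — sizes at which every stochastic recovery band in the
test suite is comfortably stable across seeds while the whole suite runs
in well under a minute per component.

## Known limitations

* The cluster filter and window statistics assume sorted, deduplicated
  positions; the VCF reader enforces strictly increasing positions per
  chromosome.
* Per-window F_ST on very sparse windows is noisy; a minimum-SNPs-per-window
  option exists (`n_sites_fst` is always reported) but is off by default,
  since the empirical-quantile budget is defined over all usable windows.
* The ROH detector inherits the scanning-window scheme's insensitivity to
  runs much shorter than the 50-SNP window.
* Gene annotation is interval overlap only — no consequence prediction or
  enrichment statistics.
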