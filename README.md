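# budworm

Temporal isolation, hybridization and divergence scans for the spruce
budworm species complex (*Choristoneura fumiferana* / *C. occidentalis*).

The two budworm species are morphologically indistinguishable conifer
defoliators that hybridize freely in the laboratory but only rarely in the
wild, and the main subspecies of *C. occidentalis* in western Canada
(*C. o. biennis*) is biennial, flying in high abundance every second year.
Testing whether *timing* — seasonal flight-period divergence and
biennialism — contributes to their reproductive isolation requires
genotype-based taxon identities for moths trapped at regular intervals
across the zone of sympatry, plus phenology expressed on a thermal
(degree-day) scale so that climatically different locations can be
compared. This package implements that entire analysis as a tested,
reusable library, together with a synthetic-data generator that emulates
the field design so every stage can be exercised end to end without any
sequencing data.

It is aimed at population geneticists and forest entomologists who work
with SNP-genotyped pheromone-trap collections.

## What it computes

- **simulate** — synthetic studies: two taxa diverged at a target F_ST
  under the Balding–Nichols model (deme frequencies
  `p_j ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`), F1/F2/backcross hybrids built
  gamete-by-gamete, sinusoid+AR(1) daily temperatures with logger/station
  offsets, degree-day-driven emergence with a biennial taxon, 10-day trap
  intervals with the field subsampling rule (floor 3, cap 10, earliest and
  latest singletons kept).
- **io** — VCF/TSV/CSV readers and writers and the SNP filters: per-SNP
  call rate ≥ 0.95, pooled minor-allele frequency ≥ 0.10, 10-kb thinning
  within scaffolds, in that order, with a conserved-count filter report.
- **ancestry** — PCA; maximum-likelihood admixture
  (`g_il ~ Binomial(2, Σ_k Q_ik P_kl)`) fit by EM with monotone
  log-likelihood; Evanno Δk and LnP(k) cluster-number selection; strict
  >90% membership species assignment; within-species substructure reruns.
- **hybrids** — six-class assignment (P1, P2, F1, F2, BC1, BC2) from
  fixed parental allele frequencies: each class is a distribution
  (π₀, π₁, π₂) over the number of parental-1-origin allele copies, and
  `P(g|c) = π₂·HW(g;p₁) + π₀·HW(g;p₂) + π₁·M(g;p₁,p₂)`; hybridization
  rate `n_F1 / (n_F1 + n_P1 + n_P2)` reported as "x% (a of b)".
- **phenology** — presence and abundance co-occurrence indices at two
  spatial grains (per sympatric location, then unweighted average; or
  pooled across locations), and Wilcoxon–Mann–Whitney flight comparisons
  with both effect-size conventions.
- **degreedays** — station-vs-logger calibration by median daily offset;
  single-triangulation degree-days above the 5.5 °C threshold,
  `DD = (T_max−T_L)² / (2(T_max−T_min))` in the intermediate regime,
  accumulated from 1 January.
- **selscan** — per-locus Weir–Cockerham θ and a Bayesian F_ST outlier
  scan: beta-binomial allele counts with
  `logit F_ij = α_i + β_j`, reversible-jump MCMC over locus effects with
  10:1 prior odds for neutrality, q-values at 0.05.
- **gea** — latent-factor genotype–environment association: per-locus
  regression on standardized climate variables with rank-K SVD factors as
  covariates, genomic-control calibration (`λ = median z²/0.456`),
  Benjamini–Hochberg q-values, and the median-|z| strongest-variable rule.
- **pipeline** — `run_all(RunConfig)` orchestrates everything into a
  report bundle; a thin `budworm` CLI wraps `simulate` and `run`.

## Worked example

`examples/02_cluster_and_classify.py` simulates a study at the field
design's scale (two taxa at F_ST 0.34, five F1s among 260 moths, 800
SNPs), filters, clusters and classifies:

```
SNP filtering         : {"input_loci": 800, "output_loci": 613,
                         "removed": {"call_rate": 23, "maf": 148, "thin": 16}}
species labels        : {'cluster1': 143, 'cluster2': 102, 'ambiguous': 5}
hybrid classes        : {'P1': 143, 'P2': 102, 'F1': 5}
hybridization rate    : 2.0% (5 of 250)
```

All five simulated F1s fall below the 90% membership threshold
("ambiguous") and are recovered as F1 by the six-class classifier; the
rate line reports F1s relative to F1 + both parental classes.
`examples/03_overlap_and_flight.py` then shows the spatial-grain effect on
the same study:

```
by_location  presence  12.7%   abundance  18.2%
pooled       presence  42.9%   abundance  64.6%
median flight DOY     : 181 vs 201 (U=688, p=7.6e-23, r=0.83)
```

Pooling locations more than triples the apparent flight-period overlap,
and the two taxa's median collection dates differ by ~3 weeks.

The other examples cover the generator itself, degree-day calibration and
accumulation, the F_ST outlier scan (planted fixed differences recovered
10/10 at q ≤ 0.05), and the GEA scan (a planted climate-linked locus found
while two-population structure is absorbed by the latent factors).

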