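# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Synthetic study generator (`simulate`)

The generator produces the inputs the analysis assumes, not raw reads.

**Genotypes.** Two demes diverge under the Balding–Nichols model: an
ancestral frequency `p` is drawn uniformly on `ancestral_maf_range`
(default 0.15–0.5) and each deme's frequency from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst_target` (default 0.34, the
between-species divergence the analysis is designed around). `F = 0` and
`F = 1` are handled as exact limits. Hybrid genotypes are built
gamete-by-gamete: an F1 carries one allele drawn from each parental pool,
an F2 two alleles that are each parental-1-origin with probability ½, and
a backcross one parental and one F1 gamete — precisely the (π₀, π₁, π₂)
mixing model the classifier assumes. Loci are placed uniformly at random
on 200 synthetic 1-Mb scaffolds so the 10-kb thinning filter has real
work to do. Missing calls are i.i.d. at 2.79% by default.

**Design.** Ten locations: three hosting only the western taxon, six
sympatric, one hosting only the eastern taxon; two seasons (years 2017
and 2018) of 10-day trap intervals from 1 June to 3 September. Default
class counts are 102/153 parentals plus five F1s. The second taxon is
biennial at its locations, flying in the parity year (year 2) except an
`off_year_fraction` (default 0.05 — "very few adults" in the off year).

**Temperatures and emergence.** Daily station series are an annual
sinusoid (mean 2 °C ± location offset, amplitude 16 °C) plus AR(1) noise,
with a diurnal range around 10 °C; the logger series adds a fixed
per-location offset plus small observation noise, so the calibration step
has a known truth. An individual emerges on the first day its location's
cumulative degree-days (base 5.5 °C, single triangulation, from 1
January, on the logger series) reach its threshold: 400 °C·day for the
earlier taxon, 650 °C·day for the later one, hybrids at the parental
midpoint, plus N(0, `dd_noise_sd`) individual noise. The threshold gap
gives a ~3-week median flight-date separation at the simulated summer
accumulation rate (~13 °C·day/day). `dd_noise_sd` defaults to 80 °C·day
(≈9 days): the within-season emergence spread is a free parameter, and
this value spreads each taxon's flight over several trap intervals, as
multi-interval trap catches require. Trapping retains at most 10
genotyped individuals per location-interval (everyone is kept when ≤10
are available, which also covers the design floor of 3) and always keeps
each location-season's earliest- and latest-emerging individuals.

**What is not emulated:** read-level error and depth, linkage between
loci, spatial dispersal, sex ratios, host-plant phenology, and trap
efficiency. Passing tests therefore demonstrate correctness of the
analysis under its own model assumptions, not robustness to the
additional noise real ddRAD data carries.

## SNP filters (`io`)

Filters run in a fixed order: call rate ≥ 0.95 per SNP, pooled MAF ≥
0.10, then 10-kb thinning that scans each scaffold in position order and
keeps a locus only if it is ≥ 10 kb beyond the last *kept* locus. The
order MAF-then-thinning is a documented choice (the upstream tools leave
it ambiguous); keeping the first locus per window makes thinning
deterministic and independent of input row order, and makes the whole
filter idempotent. The filter report's removal counts always sum to the
input count.

## Admixture model (`ancestry`)

Dosages are `g_il ~ Binomial(2, Σ_k Q_ik P_kl)`. The EM treats each
allele copy's deme of origin as the latent variable; both updates are
exact M-steps, so the log-likelihood is non-decreasing (asserted in
tests). Missing genotypes contribute nothing to the likelihood.
Initialization is k-means on the leading principal components with
seed-dependent jitter (`init="random"` gives Dirichlet rows); the PCA
start matters for weak structure (two sub-demes at F = 0.01 are recovered
reliably with it, and unreliably from random starts within the default
iteration budget). Defaults: `max_iter=500`, `tol=1e-4` on the
log-likelihood change.

Replicate fits are aligned by greedy matching on the correlation of
cluster frequency vectors before averaging (a deterministic stand-in for
mode-averaging tools). Δk follows the replicate-paired form
`mean(|L(k+1)−2L(k)+L(k−1)|)/sd(L(k))`; with no interior k or zero
variance the selection falls back to the mean log-likelihood curve and is
flagged. Species assignment is strictly `Q > 0.90`, ties to "ambiguous";
cluster-to-taxon naming requires anchor samples, since nothing in the
genotypes themselves names a cluster.

## Hybrid classes (`hybrids`)

Class likelihoods mix Hardy–Weinberg terms for 0 or 2 parental-1-origin
copies with the cross term for exactly one:
`P(g|c) = π₂·HW(g;p₁) + π₀·HW(g;p₂) + π₁·M(g;p₁,p₂)`, log-summed over
non-missing loci with a uniform prior over the six classes. Parental
frequencies are estimated once from >99%-membership reference panels with
additive smoothing 0.5 (Jeffreys-style), so fixed differences never
produce zero likelihoods. This is a deterministic approximation of the
full Bayesian treatment, which samples parental frequencies jointly; with
hundreds of informative SNPs the posterior is dominated by the data and
the approximation is immaterial for F1 detection (simulated F1s at
F_ST 0.34 with 400 SNPs classify at > 0.99 posterior), but later-generation
classes (F2/backcross) are intrinsically harder and their recovery is
reported rather than assumed. The rate denominator includes the F1s
themselves (`n_F1/(n_F1+n_P1+n_P2)`), matching the printed "5 of 174"
arithmetic; F2/BC calls are tallied separately and excluded.

## Overlap indices (`phenology`)

An interval is a (year, interval-index) cell; years are never merged.
The presence index is |intervals with both taxa| / |intervals with
either|; the abundance index counts individuals of *both* taxa inside
co-occurrence intervals over all parental individuals (the conjunctive
reading of "total number of A and B individuals in the same interval"; a
minority-only numerator is available behind a flag). At the by-location
grain the ratio is computed within each sympatric location and averaged
unweighted; at the pooled grain counts are summed across locations first.
F1s count toward neither taxon. An individual's collection date is its
interval's trap-emptying date — the only date the design records.

Flight comparisons use the Wilcoxon–Mann–Whitney U with midrank ties and
the tie-corrected normal approximation. Both U1 and U2 are reported
(sources differ in which they print), as are both effect-size
conventions, rank-biserial `|1−2U/(n₁n₂)|` and `|Z|/√N`, labelled.

## Degree-days (`degreedays`)

Single triangulation: 0 below the threshold, mean-minus-threshold above,
`(T_max−T_L)²/(2(T_max−T_min))` in between; the two branches agree at
`T_min = T_L` (continuity asserted). An upper threshold (e.g. 38 °C) is
implemented by subtracting the apex triangle but is off by default, since
such temperatures are marginal in the study region. The closed form is
tested against an exact segment-clipping integration oracle to 1e-9.
Accumulation restarts every 1 January; missing days are linearly
interpolated and counted. Calibration applies separate median offsets for
daily lows and highs (the more conservative reading of "correction
factor"), over the full station series. The logger-vs-station comparison
is reported with the unpaired rank test as in the source convention; note
that on paired-by-day series the unpaired test is very conservative, so
the paired signed-rank variant is available behind a flag and is what the
null-calibration property test checks for uniform p-values.

## F_ST outlier scan (`selscan`)

Reported F_ST is Weir–Cockerham: per-locus variance components a/b/c and
the genome-wide ratio of sums. Loci monomorphic overall or with an empty
group are flagged undefined and excluded from the sums. The Bayesian scan
models alt counts as beta-binomial around an ancestral frequency with
`θ_ij = (1−F_ij)/F_ij` and `logit F_ij = α_i + β_j`; a reversible-jump
move toggles each α_i with prior odds 10 for exclusion, priors
α ~ N(0, 3²), β ~ N(−1, 1²), ancestral frequencies uniform. Proposals are
random walks (reflected for frequencies) whose scales are adapted during
pilot runs toward 25–45% acceptance. Because F_ST is estimated by two
different models, the scan's model-based per-locus F_ST and the
Weir–Cockerham values differ slightly by construction. q-values follow
the Bayesian FDR convention — cumulative mean of (1−PIP) down the
PIP-ranked list, with tied PIPs sharing one q — and decisions are at
q ≤ 0.05. Default chain settings are prior odds 10, 20 pilot runs of
5000, burn-in 50 000, 10 000 output iterations thinned by 10; a reduced
preset (8×500 pilots, burn-in 5000, 2000 kept) is used by the tests and
acceptance script so a 500-locus scan runs in about half a minute, and a
"tiny" preset exists for smoke tests. Low reversible-jump acceptance on
neutral data is expected (the sampler rarely needs to move); a diagnostic
warning fires only when the within-model updates fall below 5%.

## GEA scan (`gea`)

Latent factors are the top-K components of the mean-imputed, centered
dosage matrix — a closed-form stand-in for ridge-penalized latent-factor
regression with the same confounder-adjustment structure. Each variable
is standardized and tested separately (intercept + variable + factors);
z-scores are rescaled by `λ = median(z²)/0.4549` before p-values, and BH
runs per variable. K comes from the cluster-number selection of the
group being scanned. Latent factors can only absorb structure that
dominates the genotype matrix: a handful of structured loci among
hundreds of neutral ones will not form a leading component, which is a
property of the method class, not a defect of this implementation. For
loci significant for several (correlated) climate variables, the
strongest association is the variable with the largest median |z| across
replicate scans, ties broken lexicographically and flagged.

## Pipeline and problem sizes

`pipeline.run_all` executes filter → PCA/admixture → k-selection →
species/hybrids → overlap/flight → calibration/degree-days → F_ST scan →
GEA, writing each artefact plus a summary JSON; reruns of the same
config are byte-identical, and a missing input file produces a failure
manifest naming the path rather than a crash. Thresholds default to the
published values (0.95/0.10/10 kb/0.90/0.99/0.5/0.05/5.5 °C). The test
suite and the acceptance script run the study at 300–800 loci with the
reduced or tiny MCMC presets — these sizes preserve every qualitative
behaviour (divergence, recovery rates, index contrasts) while keeping a
full run in minutes; the full published-scale settings remain the
defaults of `SimConfig` and `ScanSettings`.

## Known limitations

- The admixture EM finds a local maximum; replicates with different
  seeds plus PCA initialization make label-swapping and bad starts rare
  but not impossible at very weak divergence.
- The hybrid classifier fixes parental frequencies; with very few
  reference individuals its posteriors are overconfident.
- The outlier scan assumes independent loci (no linkage) and biallelic
  SNPs only.
- The GEA's genomic-control calibration can over-correct when a large
  fraction of loci are truly associated.
- The generator's i.i.d. missingness and linkage-free loci make the
  filters' interplay milder than in real ddRAD data.
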