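# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Genotype QC

Genotypes are alt-allele dosages {0, 1, 2} with a missing sentinel. The
filter chain is fixed and each dropped locus is attributed to the *first*
filter it fails, so the report's accounting sums exactly:

1. per-call masking: a call becomes missing when GQ < 20 or DP < 5
   (only when those FORMAT fields are present);
2. drop non-biallelic records (they are read and flagged, never silently
   skipped);
3. drop loci with call rate < 0.80 — i.e. missingness above 20%. The
   "missing data" threshold is deliberately read as a call-rate
   requirement (the PLINK convention); the alternative reading (drop only
   when > 80% missing) would retain essentially everything and could not
   produce a zero missing-site panel;
4. drop loci with MAF ≤ 0.05, computed on non-missing calls (strictly
   greater retained).

A sample-level call-rate filter exists but is off by default; whether the
sample- or locus-level rule (or both) applies in any given protocol is a
configuration decision, so both are exposed rather than guessed.

Mean marker spacing is genome size / locus count in Kb, **truncated** (not
rounded) to two decimals — the convention used in chip-panel summary
reports this package mirrors; 350 Mb over 10,268 loci gives 34.08 Kb.

Filtering is idempotent and monotone (output loci are a subset of input
loci); both properties are tested.

## Identity-by-state distance

Per-locus similarity between two diploid genotypes is the fraction of
shared alleles: identical homozygotes 1, heterozygote vs anything sharing
one allele 0.5, opposite homozygotes 0 — in dosage terms 1 − |a−b|/2.
Distance is 1 − similarity averaged over pairwise-complete loci (both
calls non-missing). Missing-data handling is pairwise-complete deletion;
a pair with no shared loci is reported missing with a warning rather than
silently zero. No allele-frequency weighting is applied. The matrix
computation uses one-hot cross-products (three n×L multiplications), and
a brute-force per-allele oracle verifies it on random small panels.

## Gene diversity and divergence

Per locus and group, expected heterozygosity is 2p(1−p) from the group's
non-missing calls; H_S is the mean over loci (loci with no calls in a
group are excluded from that group's mean). H_T uses the pooled
all-sample frequency — which is why the total-heterozygosity column is
constant across grouping schemes of the same panel. G_ST = (H_T − H̄_S)/H_T
uses the **unweighted** mean of group H_S (Nei's classic form; a
sample-size-weighted variant is available via `weighted=True`).
Hedrick's standardization G'_ST = G_ST(k−1+H̄_S)/((k−1)(1−H̄_S)) corrects
G_ST's ceiling under high within-group diversity; it equals G_ST when
H̄_S = 0 and reaches 1 for groups fixed for distinct alleles. With a
single group both are undefined and reported as NaN. The "number of
alleles" column follows the 2 × sample-size reporting convention of
diversity tables in this literature; a count of segregating
(polymorphic) loci is reported alongside because the convention is easy
to misread as an observed allele count.

## DAPC

Missing dosages are mean-imputed per locus (standard DAPC practice;
dropping incomplete loci is available by filtering first), the matrix is
centered (unscaled by default, `scale=True` available — the choice is
not critical for dosage data on a common scale), and PCA scores are
retained up to 90% cumulative variance, capped at n/3 components (a
fixed count can be passed instead). For each K in the grid (default
2…10), k-means with 10 restarts and a 300-iteration cap runs on the
retained scores; the model score is the spherical-Gaussian BIC
n·ln(WSS_K/n) + K·ln(n), and K* is the argmin with ties broken toward
smaller K (parsimony). A linear discriminant analysis fit to the K*
k-means labels gives per-sample posteriors; a sample whose best
posterior is below 0.5 is labeled UN (unassigned). The 0.5 threshold is
a documented convention for producing an unassigned category, not an
estimate of anything.

Acceptance of this stage is by recovery: on a Balding–Nichols simulation
with F = 0.3, four subpopulations of 50 and 2,000 loci, the BIC curve
selects K = 4 and the partition matches the simulated truth with
adjusted Rand index 1.0. BIC magnitudes themselves are implementation
conventions (they match the usual criterion only up to constants) and
are not compared across implementations.

## Neighbor joining

Standard Saitou–Nei: join the pair minimizing
Q(i,j) = (r−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k); branch lengths by the
split formula; after the agglomeration the final three nodes are
resolved around a central degree-3 vertex. Negative branch lengths are
clamped to zero with the deficit shifted to the sister branch, preserving
the joined pair's path length. Q-ties break on the lowest (i,j) index
pair, making the topology deterministic. On additive matrices the tree
reproduces every pairwise distance to 1e-9 (checked both with the
package's own path-length traversal and with an independent tree library
as oracle).

## RCBD trials and heterosis

The ANOVA partitions SS_total into blocks (df b−1), genotypes (df g−1)
and error (df (g−1)(b−1)) via an ordinary least-squares fit of
`value ~ C(block) + C(entry)`; the design must be balanced and complete
(unbalanced data are rejected, not imputed). CV% = 100·√EMS / grand
mean. Sums of squares below 1e-10 relative to the total are snapped to
exact zeros so degenerate zero-noise designs report EMS = 0 and an
infinite F with a warning instead of floating-point residue.

MPH = 100(F̄₁−MP̄)/MP̄ and BPH = 100(F̄₁−BP̄)/BP̄ on entry means over
blocks. The favorable direction decides the better parent: low for days
to 50% heading and plant height, high for panicles per plant, grains per
panicle, 1,000-grain weight and grain yield per plant — recoverable from
the algebra of published heterosis tables (BPH > MPH for earliness
traits implies the lower parent) and configurable per trait. Significance
uses t statistics on the trial-wide pooled EMS: SE(F̄₁−MP̄) = √(3·EMS/2r)
(the contrast F1 − (P1+P2)/2 has variance (1+¼+¼)·EMS/r) and
SE(F̄₁−BP̄) = √(2·EMS/r), with the error df; * at α = 0.05, ** at 0.01.
The empirical type-I error of the * flag is ~5% over 1,000 simulated
null replicates (asserted ≤ 7%). Reported tables round to 2 decimals at
the reporting layer only; internal precision is full.

## Pattern deduction and GD–heterosis correlation

Registry entries are grouped by the unordered pair of parental clusters
(ordered, female-first grouping is available; unordered merges reciprocal
crosses). Cluster labels come from an assignments mapping or from
cluster columns the registry itself carries; entries with an unassigned
parent are grouped separately, within-cluster entries are flagged rather
than dropped, and entries with unresolvable parents are skipped with a
warning. Per pattern the GD min/mean/max and supporting hybrid list are
reported; hybrid lists are sorted so output is invariant to registry row
order. Cross nomination enumerates between-cluster pairs with GD inside
a closed interval (default [0.193, 0.359], the moderate-to-high window
used for parent selection in this breeding context), optionally
restricted by breeding-line type, ranked by GD descending.

The GD–heterosis association is a Pearson correlation with least-squares
slope and two-sided t-based p (n−2 df); zero variance in either column
yields NaN with a warning rather than an exception.

## Synthetic data

**Panel.** Per locus an ancestral frequency is drawn uniformly from the
ancestral MAF range and randomly oriented; subpopulation frequencies
follow Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F), giving single-knob
control of Fst-like divergence; genotypes are Binomial(2, p) per sample.
Because rice breeding lines are nearly fully inbred, each heterozygote is
then replaced — with probability 1 − h/(2p(1−p)) clamped to [0,1], h the
target heterozygous proportion — by the homozygote of one of its own two
alleles chosen uniformly, which leaves the expected allele frequency
unchanged. Missing calls are masked uniformly. Defaults are the study
conditions this package emulates: 359 samples in six subpopulations
(161, 31, 75, 41, 15, 36 — the published cluster sizes with the six
unassigned lines folded into the smallest group), 10,268 loci on 12
chromosomes, F = 0.3, h = 0.0152, no missing data; the ancestral MAF
range (0.02, 0.35) was calibrated once so the MAF>0.05-filtered panel has
mean MAF ≈ 0.22. Options plant known QC-failing loci (multi-allelic
records; loci with a single heterozygous carrier, hence MAF ≤ 0.05 at
full call rate) whose indices are returned so filter accounting can be
checked against simulator bookkeeping. Fixed seeds give bit-identical
output.

Not emulated: linkage disequilibrium and recombination maps (loci are
exchangeable given their subpopulation frequencies), mutation models,
epistasis, genotype-calling error structure. Consequently, passing tests
demonstrate estimator correctness under drift-induced structure, not
robustness to LD pruning choices or call-error patterns in real chip
data.

**Trial.** One observation per entry × block. Parent true means are
uniform draws from per-trait ranges (defaults span the published trait
ranges: 76–102 d heading, 88–131 cm height, 4.3–11 panicles, 30–174
grains, 20.9–32.0 g grain weight, 9.5–40.4 g yield). The F1 true mean is
MP̄(1 + target MPH/100), so the generator is the exact inverse of the MPH
estimator; targets can be constants, per-cross maps, or linked to
parental GD by a slope plus Gaussian noise. Observations add a block
effect ~ N(0, (σ/2)²) — the block variance is a fixed convention, as any
value exercises the block stratum — and plot error ~ N(0, σ²), with
per-trait σ defaults equal to the square roots of published error mean
squares (1.06, 2.32, 0.66, 13.26, 0.28, 1.72). At σ = 0 the trials
module recovers every target MPH/BPH to machine precision (float
averaging of identical plot values), which is tested.

## Problem sizes and determinism

Tests and the acceptance script run simulations at the sizes stated
above (the largest is the 359 × 10,268 default panel and a 200 × 2,000
DAPC recovery panel), which complete in seconds on one CPU while leaving
the statistical checks well-powered. Every stochastic component takes an
explicit seed; the CLI derives per-stage substreams from a single config
seed and writes SHA-256 manifests, so identical configs reproduce
identical artifacts.

## Known limitations

* DAPC posteriors come from the LDA Gaussian model on retained PCs; they
  are calibrated for separation, not genuine ancestry probabilities.
* G_ST/G'_ST are computed from biallelic SNPs only; multi-allelic
  diversity statistics are out of scope.
* The ANOVA rejects unbalanced data; missing-plot estimation or mixed
  models are deliberately not provided.
* The bundled F1 heterosis table reports, for GD against grain-yield
  mid-parent heterosis, a slightly negative Pearson r (−0.069 over the
  38 hybrids); associations for the other traits and heterosis kinds in
  that table are positive. Single-trait correlation signs at n = 38 are
  fragile and should not be over-interpreted.
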