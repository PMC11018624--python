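# Methods

## Scope and model chain

`glpop` implements the genotype-likelihood (GL) analysis chain for
low-coverage population genomics. The central object is the per-site,
per-individual likelihood triplet L(g) for the three diallelic genotypes,
computed under the samtools model: each read contributes a factor
(k/2)·P(read|minor) + (1−k/2)·P(read|major), with P(read|allele) = 1−e for
a matching base and e/3 otherwise, e = 10^(−q/10). Triplets are stored
log-scaled and max-normalized per individual; a missing individual-site is
the flat triplet (0,0,0), which contributes only a constant to any
downstream likelihood. Major/minor labels are assigned from the ML allele
frequency (EM under Hardy–Weinberg, tolerance 1e−8 on Δf, 100 iterations);
the minor allele is the rarer one.

Site filters mirror standard low-coverage practice and are all named
parameters: total depth ≤ 6000×, base quality ≥ 30, ≥ 25% of individuals
non-missing, SNP likelihood-ratio p ≤ 0.05 (χ²₁, no boundary correction —
the conventional, slightly conservative choice), minor allele frequency
≥ 0.05. The depth, SNP-p and MAF rules together form the "polymorphism
filters" and are switched off for diversity estimation, where monomorphic
sites must stay in the denominator. Individuals missing data at more than
25% of sites (strictly greater) are removed. Filters are applied per
analysis stratum (species × ecoregion), with the global run retained for
structure analyses.

## SFS, diversity, Tajima's D

SAF likelihoods marginalize genotypes onto the population minor-allele
count j = 0..2N by convolving the per-individual triplets weighted
binomially (L_i(g)·C(2,g)) and dividing by C(2N,j) — algebraically
identical to the exact sum over genotype configurations with hypergeometric
configuration probabilities, and verified against that brute-force sum for
N ≤ 4. The SFS is the EM maximizer of Σ_s log Σ_j SFS_j·SAF_s(j) over the
simplex (folding pools classes j and 2N−j before the EM; stopping at
Δℓ < 1e−6 or 500 iterations; the log-likelihood is non-decreasing and
asserted so in tests). With the SFS as empirical-Bayes prior, per-site
posteriors give E[π] = Σ_j P(j)·2j(2N−j)/(2N(2N−1)) and a Watterson
increment P(segregating)/a₁. Windows (default 10 kb, 5 kb step, 0-based
half-open) sum the per-site expectations; Tajima's D uses the 1989
normalization with S taken as the *expected* segregating-site count
Σ P(seg) — at low coverage no hard calls exist, so the expectation is the
only coherent choice. Windows with S = 0 report D as missing, never 0.
Both the per-window mean D and a genomewide-totals D are reported, since
either aggregation is defensible. Ne = θ/(4μ) requires an explicit mutation
rate; no default is shipped because no authoritative rate exists for the
target taxa at this resolution.

## Differentiation and outlier windows

Fst uses the Hudson estimator in Bhatia's ratio-of-sums form. Per site,
α = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and β = p₁(1−p₂)+p₂(1−p₁)
with haploid sample sizes n_k; windows and genomewide values are Σα/Σβ,
which is invariant to window partitioning. Negative per-site α is retained.
Hudson is the only estimator offered: it is sample-size-robust, and the
outlier rule below is threshold-relative, so little would change under an
alternative. At low coverage, p_k are posterior mean frequencies under the
joint 2D-SFS prior (EM analogous to the 1D case); with called genotypes
they are sample frequencies. The high-coverage GL path agrees with a
called-genotype implementation to < 0.005 genomewide (tested).

Outlier windows: with d = mode − min of the window-Fst distribution, any
window with Fst > mode + 3d is flagged. The mode is estimated
deterministically by a Gaussian KDE with Silverman bandwidth evaluated on a
512-point grid over [min, max] — a histogram-bin mode would be
bin-width-sensitive. Each comparison gets its own threshold, computed
genomewide by default. Requiring ≥ 30 finite windows guards against a
meaningless mode. Genes overlapping any outlier window by ≥ 1 bp are
reported ranked by peak window Fst; designating which gene in a peak is
causal is deliberately left to the analyst.

## Selection scans and variant effects

Garud's H statistics are computed on phased binary haplotypes in
consecutive windows of exactly 100 SNPs (step = window by default;
overlapping steps available). H depends only on the multiset of haplotype
frequencies, so row order is irrelevant; fewer than three distinct
haplotypes contribute zero-frequency classes. Input with missing or
unphased genotypes is rejected — phasing is upstream of this package.

The effect classifier handles one transcript per gene: a SNP is mapped
strand-aware onto UTR/CDS/intron structure; CDS hits are translated with
the standard table and reported as synonymous or missense with
p.Xxx123Yyy notation. GFF3 phase columns are not consulted; the CDS is
assumed complete and codon-aligned (asserted at load: length divisible
by 3).

## Structure and kinship

PCA uses the single-pass covariance of posterior dosages standardized by
fixed per-site frequencies, C_ij = (1/S)Σ_s (E[g_is]−2f_s)(E[g_js]−2f_s) /
(2f_s(1−f_s)); monomorphic sites are excluded. An iterated
individual-allele-frequency refinement is deliberately not implemented —
at the simulated coverage the single pass already separates populations by
many within-group standard deviations.

Admixture is the GL-aware EM for P(data) = Σ_g L(g)·Binom(g | 2, Σ_k
Q_ik F_sk), with Q initialized from Dirichlet(1), F from the ML frequency
plus jitter, best-of-N random starts (default 3 in the library, 2 in the
pipeline), convergence at Δℓ < 1e−6 or 2,000 iterations. K = 1 returns the
analytic optimum. Likelihoods are reported per K; choosing K is left to
the user.

Kinship uses KING-robust φ on hard-called genotypes (argmax posterior with
a 0.95 floor, else missing), counted over sites non-missing in both
individuals and outside any masked interval (inversion regions are masked
by the pipeline because inversions inflate apparent relatedness). φ can be
strongly negative between members of different subpopulations; values are
never truncated. Classification uses the published powers-of-two bins
(0.354 / 0.177 / 0.0884), with first-degree pairs split into full-sib
versus parent–offspring by the opposite-homozygote count (parent–offspring
pairs share an allele everywhere, so their count stays at the
genotyping-error floor, taken as 0.5% of informative sites).

## Isolation by distance

Distances are haversine great-circle km on the WGS84 mean radius — within
0.5% of the geodesic at the sub-500-km scale of a regional study. The
Mantel statistic is the Pearson correlation of upper triangles; its p-value
comes from jointly permuting rows/columns of one matrix (one-sided
"greater" by default, matching the positive-association alternative of an
IBD test; the permutation stream is seeded and reproducible). The
correlogram Mantel-correlates each distance-class indicator matrix against
the genetic matrix (interpreted as a similarity; distance-like matrices
should be negated), applies progressive Holm correction in
increasing-distance order, and flags classes with < 10 pairs. Default
class breaks follow Sturges' rule on the pair count; explicit breaks are
accepted. Between-site Fst matrices require ≥ 4 individuals per site;
smaller pairs are reported missing rather than estimated.

## The synthetic-data generator

The generator emulates the *design* of a two-species, multi-ecoregion,
multi-site low-coverage study, not its coalescent history: SNPs are
independent, with no recombination map, indels, multi-allelic sites or
mapping artefacts. Components:

* **Differentiation** — Balding–Nichols: per-population frequencies
  Beta(f(1−F)/F, (1−f)(1−F)/F) around an ancestral f, so realized Hudson
  Fst matches the target F in expectation (measured recovery: within
  ±0.006 of targets 0.02–0.25 at 2×40 diploids, 5,000 SNPs).
* **Ancestral spectrum** — default density ∝ 1/f truncated to
  [0.05, 0.95], a realistic stand-in for a MAF-filtered common-variant
  spectrum. This truncated spectrum is *not* neutral (it lacks rare
  variants, pushing Tajima's D positive), so a separate
  `spectrum="neutral"` mode draws per-site sample allele counts with
  P(j) ∝ 1/j and assigns them to chromosomes at random, which makes
  E[π] equal E[θ_W] exactly site by site; neutral calibrations use that
  mode.
* **Sweeps** — haplotype copying: within the window, a fraction
  `strength` of haplotypes (optionally restricted to some populations,
  emulating divergent selection) is replaced by one donor haplotype. This
  directly produces the haplotype-homozygosity signal H12/H123 measures,
  and localized Fst elevation when population-restricted.
* **Inversion block** — a contiguous region simulated with an elevated
  Beta variance parameter (F + extra), reproducing block-wise elevated
  differentiation without modelling inversion genotypes.
* **Pedigrees** — full-sib pairs bred from stored unsampled parents by
  per-site Mendelian transmission (no linkage), sufficient for
  kinship-moment statistics.
* **Reads** — per individual per site, Poisson(mean coverage) reads drawn
  from the two alleles with equal probability and flipped to a uniformly
  chosen other base with probability 10^(−phred/10); one quality stratum.
* **Geography** — collection sites on a regular grid spanning a few
  hundred km, all individuals at their site's coordinates, and *no*
  spatial autocorrelation of frequencies by default. Real site coordinates
  are not modelled; the grid is a stand-in.

Because sites are independent and phasing is exact, passing tests
demonstrate correctness of the estimators under the stated models — they
do not demonstrate robustness to linkage disequilibrium, phasing error,
reference bias or mapping artefacts, which real data add.

## Default problem sizes

The default study is 6 strata × 12 diploids, two 400-kb chromosomes at
SNP density 0.004/bp (~3,200 SNPs), 14× coverage — small enough to run in
well under a minute while leaving every statistic comfortably estimable
(≥ 30 Fst windows per comparison, ~16 H windows per chromosome). The
acceptance script uses larger single-purpose simulations (up to 50
diploids × 2 Mb at 20×) where a calibration needs the extra resolution.

## Numerical choices

All EMs run in linear space on per-site max-normalized likelihoods (the
normalization constant cancels); the SAF convolution rescales per site to
avoid overflow. Ties in haplotype counting are irrelevant (H statistics
depend on the multiset only). Degenerate inputs have defined behaviour:
all-flat SAF → uniform SFS with warning; zero-β windows, S = 0 windows,
zero-informative-site pairs and empty distance classes → missing values,
never zeros; an all-equal Fst distribution yields no outliers.
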