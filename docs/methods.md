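# Methods

This note documents the models and estimators implemented in popkit, the
choices made where the methodology was genuinely open, and what the
synthetic-data recovery tests do and do not demonstrate about real data.

## Genotype model and QC

All analyses operate on a `GenotypePanel`: a samples × SNPs matrix of
diploid alt-allele dosages (0/1/2, missing allowed), population labels,
and — when the input was fully phased — the underlying haplotypes.
Dosage orientation is fixed by the VCF REF/ALT fields; every statistic in
the package is invariant to flipping the allele labels of any subset of
SNPs (tested as an exact identity for D/f2/f3/f4/F_ST and by construction
for ASD, r² and PCA), so orientation never has to be harmonized across
datasets.

QC follows array-panel practice: non-autosomal records are dropped at
read time, and SNPs are removed when their missing-call fraction reaches
`max_missing` (default 0.05, applied strictly: a SNP with missing rate
exactly 0.05 is removed, "rate less than 0.05" being the retention rule).
Two marker-thinning filters serve the structure analyses: a greedy
left-to-right scan keeping SNPs more than `min_gap_bp` (default 500 kb)
beyond the last kept SNP, and sliding-window LD pruning on genotype
correlation (defaults: window 50 SNPs, step 5, r² ≥ 0.8 removes the
member of a pair with the higher missing rate, ties to the later
position).  The pruning defaults are a package choice, exposed in the
config, since they are not dictated by the method itself.

Genetic positions come from an optional map TSV, linearly interpolated in
bp per chromosome; with no map a uniform 1 cM/Mb is assumed.  LD-based
stages are sensitive to this choice; with array data a real map should be
supplied.

## F_ST

"Unbiased F_ST" is implemented as the Weir–Cockerham (1984) two-level
variance-component estimator for two populations with per-SNP components
a (between populations) and a+b+c (total), aggregated as a ratio of sums
over SNPs.  SNPs monomorphic across the pooled pair, or with fewer than
two genotyped samples in either population, are skipped.  A per-SNP-mean
alternative is deliberately not the default: ratio-of-sums is the
standard aggregation and is far more stable for rare variants.  The
estimator can legitimately go slightly negative for undifferentiated
pairs; downstream dating clamps negative F_ST to zero with a warning.

Under the Balding–Nichols generator with both branches at drift F, the
estimator centers on F itself (Monte-Carlo validated; note that a
Hudson-style estimator would center near 2F/(1+F) — the two conventions
answer slightly different questions, and the recovery tests are written
against the Weir–Cockerham expectation).

## ASD, NJ, PCA, K-means

The allele-sharing distance between individuals is
d(i,j) = mean over SNPs genotyped in both of |g_i − g_j|/2, i.e. one minus
the shared-allele fraction of unphased dosages; among ASD variants this
one was chosen because it is a metric on complete data and needs no
phasing.  Neighbor joining is the canonical Saitou–Nei algorithm with two
determinism rules: Q-matrix ties break to the lowest index pair, and a
negative branch length is clamped to zero with the deficit moved to its
sister branch so path lengths are preserved (additive inputs are
reproduced exactly).  NJ here substitutes for maximum-likelihood
population trees; it is the right tool for individual-level ASD trees and
a reasonable, clearly-labelled stand-in at the population level.

PCA uses the smartpca normalization: each SNP column is centered on its
mean dosage and divided by sqrt(p̂(1−p̂)) with
p̂ = (1 + Σ dosages)/(2 + 2·n_genotyped) — the add-one shrinkage keeps the
scale finite for near-monomorphic SNPs; missing cells are zeroed after
centering.  Eigenvalues are reported under both conventions used in
practice: fraction of total variance, and fraction of the top-ten
eigenvalue sum.  K-means on the top 10 PCs uses k-means++ with 25
restarts and a fixed seed, and reports each population's distribution
across clusters.

## AIM selection

Panels for a population pair are grown greedily: SNPs ranked by per-SNP
Weir–Cockerham F_ST (ties broken by genome order), each candidate
admitted only if it is more than 500 kb (configurable) from every
already-selected SNP on the same chromosome, and after each admission the
panel is scored by the MCC of a PC1 classifier: PCA on the AIM-restricted
genotypes of the two populations, threshold at the midpoint of the two
population means, orientation such that the first population is positive.
Selection stops at the target MCC (default 1.0, perfect separation) or a
size cap.  MCC is evaluated on the training individuals by default — the
same individuals used to rank SNPs — so reported panel sizes are
training-set sizes; a held-out evaluation can be run by restricting the
panel before selection.  The greedy procedure and the midpoint classifier
are package choices: the selection criteria (F_ST ranking, distance
floor, MCC target) constrain but do not fully determine an algorithm.
MCC with any zero denominator factor is defined as 0.

## LD decay, N_e(t) and divergence dating

For a phased population sample, r² between two loci is the squared
correlation of allelic indicators across haplotypes (equivalently
D²/(p(1−p)q(1−q))), computed over haplotypes non-missing at both loci.
Same-chromosome pairs are assigned to half-open genetic-distance classes
(defaults: 0.001–2.5 cM in 0.001 cM steps, i.e. 2500 classes); each class
reports mean r² − 1/n, the 1/n term removing the finite-sample floor for
n sampled chromosomes.  Loci with minor-allele frequency below 0.05
(configurable) are excluded before pairing: rare alleles make r² a poor
N_e estimator, and array panels are ascertained for common variants
anyway.

Each class is inverted through the drift–recombination balance
approximation E[r²] ≈ 1/(2 + 4 N_e c):

    N_e(c) = [(1/r²_adj) − 2] / (4c),    t = 1/(2c) generations ago,

with the class midpoint as the representative c (the choice of
representative point is not dictated by the method).  Classes with fewer
than 10 pairs or non-positive adjusted r² yield missing values rather
than estimates.  The inter-population N_e used for dating is the
harmonic mean of each population's per-class N_e over the 0.01–0.25 cM
window (t between 200 and 5000 generations), then the arithmetic mean of
the two populations; a pooled-classes harmonic mean is available behind a
flag, as the averaging order is ambiguous in principle.  Divergence time
is T_F = 2 N_e F_ST generations, converted to years at 25
years/generation by default.

### The Wright–Fisher generator and the inversion's accuracy

The phased generator is a forward-time Wright–Fisher population of 2 N_e
haplotypes with n_loci equally spaced loci; each offspring haplotype
recombines two uniformly chosen parents with Poisson(map length) crossovers
at uniform positions, starting from linkage equilibrium with locus
frequencies Uniform(0.2, 0.8) and no mutation.

The run length default is **N_e generations**, and this is a deliberate,
validated choice.  The inversion formula is only an approximation, and
its accuracy depends on the simulation regime: at 4 N_e generations the
mutation-free model's surviving polymorphic loci have drifted toward
extreme frequencies and mean r² overshoots 1/(2 + 4 N_e c) by 40–90% at
short distances, while a stationary coalescent-with-mutation oracle
(msprime) puts E[r²] at 72–94% of the formula.  At N_e generations from a
linkage-equilibrium start the two opposing deviations roughly cancel:
per-class ratios to the formula are 0.99–1.11 (N_e = 500, 12 seeds) and
end-to-end harmonic-mean recovery lands at 0.95–1.04 of truth for
N_e ∈ {200, 500, 1000} averaged over 20 seeds.  Recovery tests therefore
assert 20% per-class and 30% end-to-end bands *in this regime*; they
validate the estimator's self-consistency, not its absolute accuracy on
real (mutating, non-equilibrium, ascertained) data, where the same
formula is known to carry comparable systematic uncertainty.

## D and f-statistics

All four statistics are functions of per-population sample allele
frequencies; SNPs with an undefined frequency in any involved population
(or a zero D denominator) are skipped with a logged count.  D aggregates
per-SNP numerators and denominators as a ratio of sums (a per-SNP-mean
mode exists behind a flag for sensitivity).  f2/f3/f4 are plain means of
the per-SNP products with **no finite-sample bias correction** — the
implemented definitions contain none — with the documented consequences
that f2(A,A) on finite samples is positive and f3 of a small admixed
sample is biased upward (against detecting admixture, so significant
negative f3 calls are conservative).

Uncertainty comes from a delete-m jackknife over contiguous blocks of
SNPs in genome order (default 500 blocks), a proxy for linkage blocks;
the weighted delete-m variance handles unequal block sizes.  Z =
estimate/SE, and a statistic is called significant when |Z| > 2.58, the
two-sided 1% normal critical value.  No multiple-testing correction is
applied; each test is reported with its own Z.  Null calibration on
star-tree panels (four independently drifted populations, 200 replicates)
keeps the empirical false-positive rate of D at or below 2.5%.

## F4 regression for admixture proportions

For a series of targets X admixed between donors A and B with outgroup O,
F4(A,O;X,B) = αl and F4(B,O;X,A) = (1−α)m, so across targets the points
lie on y = l − (l/m)x.  OLS across targets gives intercept l and slope
−l/m; α_X = y_X/l, clamped to [0,1] with a flag.  Degenerate geometry is
reported: non-positive intercept is an error, non-negative slope a
warning (donors likely misspecified), and fewer than three targets a
warning (the line is exactly determined).  Per-target standard errors
jackknife the whole procedure over SNP blocks.  Recovery on simulated
5-target grids (5×10⁴ SNPs, 50 samples per population) is within ±0.05 of
truth, typically ±0.015.

Three-donor percentages are a post-processing utility: the three pairwise
regressions each yield a pairwise proportion per target; a donor's raw
share is the mean of its two pairwise proportions, renormalized to sum to
one.  This combination rule is a package choice — the pairwise model does
not extend uniquely to three donors.  It reliably ranks the dominant
donor but compresses very uneven mixtures toward the interior, and an
earlier log-odds least-squares variant was rejected as unstable when a
pairwise regression is misspecified.

## Synthetic data: what the tests show

The Balding–Nichols generator draws each population's frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared ancestral p ~ Uniform(0.05,
0.95) and genotypes as Binomial(2, q): closed-form drift per branch, so
F_ST, f2 monotonicity, AIM panel behavior and f3/f4/D signals all have
known expectations.  The admixture generator draws each target allele
from donor A's sample frequency with probability α, giving exact
E[target frequency] = α p_A + (1−α) p_B.  What these generators do *not*
emulate: linkage between SNPs (sites are independent, so jackknife blocks
are uninformative about real LD leakage), ascertainment bias beyond the
uniform ancestral band, batch effects, phasing errors, and post-admixture
drift in the targets.  Recovery under these conditions demonstrates the
estimators are implemented correctly and calibrated under their own
assumptions; real-panel accuracy additionally depends on the violations
listed, in the directions noted above.

## Numerical and determinism notes

All generators and analyses are deterministic given their seeds; K-means
uses a fixed seed with 25 restarts; NJ tie-breaks and negative-branch
handling are fixed as described; the pipeline writes a manifest with
seeds, parameters and per-stage SNP counts, and reruns are byte-identical.
Problem sizes in the test suite (10³–5×10⁴ SNPs, tens of samples per
population, N_e ≤ 10³ forward simulations) were chosen as the smallest
scales at which the statistical assertions are stable across seeds.
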