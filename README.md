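# popkit

Tools for dissecting the structure, divergence and admixture of closely
related human populations from multi-population SNP panels — the kind of
question raised by Han Chinese / Japanese / Korean array data, where
pairwise differentiation is tiny (F_ST of 0.001–0.01) and the interesting
signals are recent: who split from whom, when, and who received gene flow
from where.

The package implements, as a tested and reusable library with a CLI:

* **Population structure** — pairwise Weir–Cockerham (1984) unbiased F_ST
  with ratio-of-sums aggregation; allele-sharing distance (ASD) between
  individuals, `d(i,j) = mean |g_i − g_j| / 2`; Saitou–Nei neighbor-joining
  trees; individual-level PCA with smartpca-style `sqrt(p(1−p))`
  normalization, reporting variance fractions both of the total and of the
  top-ten eigenvalues; K-means clustering on the top PCs with
  per-population cluster fractions.
* **Ancestry-informative markers (AIMs)** — greedy panels ranked by
  per-SNP F_ST under a 500 kb inter-marker distance floor, scored after
  each addition by the Matthews correlation coefficient (MCC) of a PC1
  midpoint classifier, with the full MCC trajectory.
* **LD-based demography** — haplotype r² binned by genetic distance c;
  each class inverted to an effective population size
  `N_e = [(1/r²_adj) − 2] / (4c)` at time `t = 1/(2c)` generations ago
  (r² adjusted by −1/n for n sampled chromosomes); inter-population N_e as
  the average of the two populations' harmonic means over the 0.01–0.25 cM
  classes; divergence dating via `T_F = 2 N_e F_ST` (25 years/generation
  by default).
* **Gene-flow inference** — the ABBA-BABA D statistic
  `Σ(w−x)(y−z) / Σ(w+x−2wx)(y+z−2yz)` and the f-statistics
  `f2 = E[(a−b)²]`, `f3(C;A,B) = E[(c−a)(c−b)]`,
  `f4(A,B;C,D) = E[(a−b)(c−d)]`, all with delete-m block-jackknife standard
  errors and |Z| > 2.58 significance calls; and F4-regression estimation of
  admixture proportions: for targets X admixed between donors A and B,
  `F4(A,O;X,B) = αl` and `F4(B,O;X,A) = (1−α)m` lie on a line across
  targets, so an OLS fit eliminates the unknown drift lengths l, m and
  yields each α.
* **Synthetic panels with known truth** — Balding–Nichols drift on a star
  tree (tunable F per branch), admixed individuals with known α, and a
  forward Wright–Fisher simulator of recombining haplotypes with known
  N_e, so every estimator above has an end-to-end recovery test with no
  external data.

## Worked example

Simulate two drifted donor populations plus an outgroup, create three
admixed target populations with known mixing proportions, and recover
them:

```bash
popkit simulate admix \
  --pop OUT:0.1:50 --pop NORTH:0.02:50 --pop SOUTH:0.02:50 \
  --sources NORTH,SOUTH --alphas 0.25,0.5,0.75 \
  --n-snps 20000 --seed 7 --out-prefix ea

popkit f3 --vcf ea.vcf --pops ea.pops.tsv --triple MIX_a0.5,NORTH,SOUTH --n-blocks 200
# f3('MIX_a0.5', 'NORTH', 'SOUTH'): value=-0.00085106 se=3.67e-05 Z=-23.200
#   significant=True (n_snps=20000)

popkit f4ratio --vcf ea.vcf --pops ea.pops.tsv \
  --outgroup OUT --donors NORTH,SOUTH \
  --targets MIX_a0.25,MIX_a0.5,MIX_a0.75 --n-blocks 200 --out ea_alpha.tsv
# intercept_l=0.00545707 slope=-1.02221 m_edge=0.00533852 R2=0.9994
```

The f3 statistic for the 50/50 target is significantly negative
(Z = −23.2, far beyond the −2.58 threshold): unambiguous evidence that
`MIX_a0.5` is admixed between sources related to NORTH and SOUTH.  The
regression's per-target proportions land within ~0.01 of the simulated
truth (`alpha` column of `ea_alpha.tsv`): 0.257, 0.498 and 0.756 for true
values 0.25, 0.50 and 0.75, each with a jackknife standard error of about
0.013.  The fitted intercept is the shared drift length l on the
NORTH-to-outgroup path, and `m_edge = −intercept/slope` recovers the
corresponding SOUTH drift length m.

The same panel works for every other stage, e.g.
`popkit fst ...` (the 6×6 F_ST matrix shows the targets sliding from
NORTH toward SOUTH as α falls), `popkit pca`, `popkit aims --pair
NORTH,SOUTH`, and a phased Wright–Fisher panel from `popkit simulate wf`
feeds `popkit ne` and `popkit divergence-times`.  A JSON config can drive
all stages at once: `popkit run config.json --out results/`.

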