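# Methods

## Problem and scope

`cisxpred` predicts a gene's expression level in unseen individuals using
only their genotypes at *cis*-SNPs — variants inside the gene body or
within 100 kb of either end. The design question it answers is not "which
SNPs are significantly associated with expression" but "how well, and how
*predictably* well, can held-out individuals be predicted", including the
hardest setting where the held-out individuals come from a population
absent from training. Environmental variation and *trans*-acting variants
are outside the model by construction, so even a perfect cis predictor
explains only part of expression variance; the quantity of interest is the
agreement between training and test performance (robustness), gene by gene.

## Data model

Genotypes are minor-allele counts X ∈ {0,1,2}^(N×D); expression is a
continuous vector y per gene; SNP annotations form a feature matrix
F ∈ R^(D×M) (binary indicator columns in the standard setting); each
individual carries a population label. Expression is mean-centered within
each population before modeling so population-level expression offsets
cannot leak into the genotype signal. The default centers once over all
individuals (`center_scope="global"`); a fold-aware `train_only` variant
computes the means on training individuals only. The two differ: global
centering uses test individuals when computing a population's mean, which
is a small information leak, but it is the conventional preprocessing for
this design and is therefore the default. The `train_only` variant is
ill-posed under the cross-population scheme (a held-out population has no
training individuals to define its mean) and raises in that combination.

Missing genotype calls are imputed per SNP with the modal observed count
(ties toward the smaller count). The mode keeps the {0,1,2} support so the
L1 genotype distance stays integral; rounded-mean imputation is available
behind a flag. Zero-variance SNP columns are kept but flagged.

## Models

**Single best-SNP.** The SNP with the largest absolute Pearson correlation
to expression in the training set (ties to the lower SNP index), used in a
one-variable OLS fit. "Absolute" because a strongly negative SNP is equally
predictive under OLS. Two parameters; the baseline every multi-SNP model is
compared against.

**Elastic net.** Linear regression on all cis-SNPs with the mixed L1/L2
penalty, mixing parameter `l1_ratio` = 0.5 by default. The penalty λ is
chosen by internal cross-validation on the training set: a 50-point
log-spaced grid from the data-driven λ_max (smallest penalty with all-zero
coefficients) down by a factor 10³, 5 learning/validation splits, the λ
maximizing mean validation R² (ties to the stronger penalty), then a final
refit on the full training set. The reported training score is the mean
*validation* R², not the in-sample fit, so it is directly comparable to
test R².

**Simple KNN.** A test individual is predicted as the unweighted mean
expression of its k nearest training individuals under the L1 genotype
distance d(a,b) = Σ_i |X_ai − X_bi|. k is selected by exhaustive
leave-one-out search inside the training set over k = 1..min(50, N_train−1)
(each training individual predicted from its k nearest *other* training
individuals), ties to the smallest k. Leave-one-out is used because any
in-sample KNN score with the self-neighbor included is trivially optimistic
at k=1. The k-grid cap of 50 is comfortably above the selected-k values
observed in practice (typically ~10–15) and configurable. Distance ties at
the k-th rank break by ascending training index, making runs
bit-reproducible; this exact tie-break is verified against a full-sort
brute-force implementation.

**Combined.** The element-wise mean of the KNN and elastic-net predictions
— the two models make different assumptions (local similarity vs. additive
effects) and their errors partially cancel. Its training score is the R² of
the averaged training predictions, taking the KNN side's leave-one-out
predictions and the elastic net's in-sample fit at the selected λ (the two
honest per-individual training predictions available).

**Extended KNN (KNN-IGF).** Replaces the uniform metric with
d(a,b) = Σ_i w_i |X_ai − X_bi|, w_i = Σ_m α_m f_im: each genomic feature
gets one coefficient shared by all SNPs carrying it. Negative induced
weights are clamped to zero (an L1 "metric" with negative weights is not a
metric). The coefficients α maximize the metric-to-response correlation
(MRC): the Pearson correlation, over all unordered training pairs (a,b),
between d_ab and |y_a − y_b|. The MRC needs no k and produces no
prediction; it asks only that the metric order pairs the way the response
does. k is then selected exactly as in the simple KNN but under the learned
metric — decoupling metric learning from neighbor-count selection.

The search is greedy and derivative-free. The pool starts with the M
one-hot coefficient vectors. Each iteration keeps the `r_max` = 5 best by
MRC and forms all 25 ordered pairs; a pair (i,j) combines as
α_new = (g_i α_i + g_j α_j)/(g_i + g_j) with g = max(f, 10⁻⁶), so a strong
predictor dominates a mix with a weak one, and the epsilon floor keeps
non-positive objectives from flipping signs. Self-pairs reproduce their
parent exactly, so the pool's best objective is non-decreasing (up to
floating-point recomputation noise ≪ 10⁻¹²; asserted in tests at that
tolerance). Iteration stops when the best objective improves by less than
10⁻⁶ or after 50 iterations. `r_max` keeps per-iteration cost independent
of M after the first iteration; 5 is a deliberate small default — the
combination rule interpolates, so diversity beyond a handful of leaders
adds little. Spearman MRC and feature standardization (for continuous
annotation columns) are available behind flags; defaults are Pearson and
no standardization since standard annotation features are indicator bins.
If the learned α induces an all-zero SNP weighting (no feature tags any
cis-SNP of the gene), the metric carries no information and the fit falls
back to the uniform metric with a log warning.

## Evaluation

Three cross-validation schemes probe where the predictive signal lives:

* **Cross-Pop** — each fold holds out one entire population; training uses
  only the others. Success requires effects shared across populations.
* **Mixed-Pop** — individuals are partitioned into 5 near-equal test sets
  stratified by population (each fold's per-population count within one of
  every other fold's).
* **Intra-Pop** — a 5-fold split inside each population separately;
  training never sees another population.

R² = 1 − SS_res/SS_tot is computed against the evaluated set's own mean,
on both training (model-specific definition above) and test sets; test R²
may be negative. Per-gene values are averaged across folds before any
thresholding, binning or ranking.

Robustness statistics: a gene is *robustly predicted* at threshold t if
test R² ≥ t · train R² (genes with train R² > 0.05 considered); the
robustness curve reports this fraction over a threshold grid and is
monotone non-increasing by construction. Train/test concordance is the
Pearson and Spearman correlation of the two R² vectors across genes,
with genes binned by training R² for calibration tables. Top-gene overlap
counts intersections of the models' top-n test-R² gene lists (ties broken
lexicographically). Gene characterization compares per-gene scalars
(selected k, absolute expression, coefficient of variation, cis-SNP count,
mean SNP entropy) between predictable and unpredictable genes with a
two-sample t-test — Welch by default, because the two groups are typically
very unbalanced; the classic pooled test is a flag.

SNP entropy splits the count into two binary alleles (0→00, 1→01, 2→11),
averages the two Bernoulli Shannon entropies (base 2, so the value lies in
[0,1] bits, maximal at allele frequency 0.5), and averages over a gene's
cis-SNPs.

An optional preprocessing step regresses the top-2 principal-component
scores of the (column-centered) cis-genotype submatrix out of every SNP
column, removing broad ancestry axes; components are computed per gene on
the cis submatrix. Off by default.

## Enrichment

For each genomic feature, a hypergeometric test asks whether entities
carrying the feature are over- or under-represented among selected
entities, pooled across genes. In KNN-IGF mode an entity is a
(gene, feature) pair selected when its coefficient is non-zero (exact zero
test — the greedy search produces exact zeros only from unselected
initializations); in elastic-net mode an entity is a (gene, SNP) pair
selected when |weight| > 10⁻⁸, and carriers are SNPs annotated with the
feature. Both tails are computed (P(X ≥ k) and P(X ≤ k)); BH step-up FDR
is applied across features separately per tail, and a feature is *called*
enriched or depleted only when its adjusted p-value is below α = 0.01 in
every CV partition supplied. The background universe in KNN-IGF mode is
all features for every gene (the alternative — only features present among
the gene's cis-SNPs — is a caller-side choice of the `background`
argument). Continuous feature columns are binarized at non-zero for
carrier status. The same machinery serves generic gene-set (GO-style)
enrichment with a user-supplied two-column annotation table.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
several populations with population-specific allele frequencies (uniform
draws from `maf_range` per population × SNP, minor-allele orientation
fixed globally so cross-population folds are coherent); genes spaced 1 Mb
apart on one chromosome so each 100 kb cis window contains exactly its own
`snps_per_gene` SNPs; expression from a handful of causal cis-SNPs with
standard-normal effects under linear, dominant or epistatic (consecutive
pairwise product) effect models; Gaussian noise scaled so the genetic
variance fraction equals h2; `share_across_pops` controls the fraction of
causal SNPs whose effects are identical across populations versus
population-private; informative annotation features tag causal SNPs with
probability `p_tag_causal` and others with `p_tag_null`, noise features
are density-0.2 indicators. SNPs are independent by default; `ld_rho`
induces first-order LD blocks. The planted truth (causal SNPs, effects,
realized h2) is written alongside the dataset.

What the generator does *not* emulate: realistic LD structure from
recombination, allele-frequency spectra under drift/selection, batch and
environmental expression covariance, *trans* effects, and measurement
noise heteroskedasticity. Tests passing on these panels demonstrate the
algorithms' contracts and statistical behavior under their own
assumptions, not performance on real cohort data.

### Study conditions used by tests and the acceptance script

Problem sizes are chosen as the package's desk-scale standard: total panel
sizes of 200–400 individuals match the scale of classic multi-population
genotype panels, and 30 cis-SNPs per gene stand in for the few hundred in
real 100 kb windows. The null-calibration study uses 2 populations × 200
individuals, 30 SNPs/gene, Mixed-Pop 5-fold; note the single-SNP model's
winner's-curse bias under the null is ≈ −2 ln D / N_train, so calibration
to |mean test R²| < 0.05 is a real constraint at these sizes, not a
triviality. The planted cross-population study uses 4 populations × 75,
h2 = 0.4, 3 fully shared causal SNPs, where the mean test R² is expected
below the h2 ceiling. The metric-learning study uses 200 individuals,
50 SNPs, 5 features with the first tagging all 5 causal SNPs at h2 = 0.5.

## Numerical choices and degenerate inputs

* Distance computation scales columns by weights and uses the cityblock
  metric; for counts in {0,1,2} this is bitwise identical to weighting the
  absolute differences, so oracle comparisons are exact.
* Tie-breaks everywhere are deterministic: lowest SNP index (single-SNP),
  strongest penalty (elastic net), smallest k and ascending neighbor index
  (KNN), lexicographic gene id (rankings).
* Zero-variance y raises; zero-variance pair vectors in the MRC return 0
  with a warning; empty cis windows skip the gene with a log line; an
  all-missing SNP column is an error naming the column.
* `r_max`, convergence tolerance 10⁻⁶ and the 50-iteration cap are safety
  valves; in practice the greedy search converges in well under 10
  iterations.
* Per-gene failures inside a cross-validation run are caught and reported
  per gene; one failing gene never aborts a panel run.

## Known limitations

* Global per-population centering (the default, matching the conventional
  design) slightly couples train and test sets; use `train_only` with the
  Mixed-Pop or Intra-Pop schemes to remove it.
* The elastic net does not standardize SNP columns; allele-frequency
  differences therefore modulate effective per-SNP penalization.
* The greedy metric search finds a local maximum of the MRC; it is not
  guaranteed global, only monotone.
* KNN with very small training sets (tens of individuals) selects k
  noisily; test R² of a single gene is then volatile even when the
  cross-gene averages are well calibrated.
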