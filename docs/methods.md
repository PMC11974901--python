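# Methods

## Problem setting

`scancestry` infers the genetic ancestry of query individuals from
sparse, error-prone biallelic SNP genotypes — the situation that arises
when genotypes are called from scRNA-seq reads (a few thousand usable
common SNPs, roughly 10% missingness, and a genotype discordance
against array truth on the order of 8%) — by comparing them against a
labelled reference panel organised as K continental-scale ancestry
groups, each containing several populations. It also provides the
evaluation machinery for such inference: leave-one-population-out
(LOPO) classification error, genotype-error robustness sweeps, and
admixture-proportion recovery.

## The admixture model and its EM fit

Genotype `g_ij ∈ {0,1,2}` counts the ALT allele of individual `i` at
SNP `j`. Under the admixture model each of the two allele copies
descends from ancestral group `k` with probability `q_ik` and is then
ALT with probability `f_kj`, so

    g_ij ~ Binomial(2, Σ_k q_ik f_kj),

with SNPs independent (the reason the pipeline LD-prunes first). The
log-likelihood, up to the constant binomial coefficient, is

    ℓ = Σ_ij [ g_ij ln Σ_k q_ik f_kj + (2 − g_ij) ln Σ_k q_ik (1 − f_kj) ],

missing cells contributing zero. In supervised mode the reference
individuals' `q` rows are frozen to one-hot indicators of their
ancestry group and the query rows are estimated.

Fitting is plain EM. The E step attributes each ALT copy to group `k`
with responsibility ∝ `q_ik f_kj` (REF copies ∝ `q_ik (1 − f_kj)`);
the M step is

    q'_ik = Σ_j (a_ijk + b_ijk) / (2 M_i),
    f'_kj = Σ_i a_ijk / Σ_i (a_ijk + b_ijk),

where `a`/`b` are the expected ALT/REF copy counts and `M_i` is
individual `i`'s non-missing SNP count. We use plain EM rather than a
quasi-Newton block relaxation because it has the same stationary
points, its monotonicity gives a machine-checkable invariant (the
likelihood trace never decreases), and it is fast enough at the panel
sizes this package targets.

Two supervised variants are exposed via `update_F_with_queries`:

* **fixed-F (default).** Because the reference rows are one-hot, the
  F update restricted to reference rows reproduces exactly the
  observed group ALT frequencies — they are a fixed point. The
  implementation therefore computes `F` once from the reference and
  runs EM on the query rows only; a unit test verifies the fixed-point
  identity against the general EM step. This is the stabler choice
  when queries are few or noisy.
* **joint-F.** Queries also contribute to re-estimating `F` each
  iteration, the behaviour of supervised ADMIXTURE-style tools. With
  few queries relative to the reference the two variants agree
  closely (tested).

Numerical choices: frequencies are clamped to `[1e-6, 1 − 1e-6]` so a
discordant genotype cannot produce `ln 0`; convergence is declared
when the log-likelihood improves by less than `tol = 1e-6` (EM is
monotone, so the signed change equals the absolute change up to float
round-off — and for panel-scale likelihoods of magnitude ~1e6 the
round-off of the *difference* is ~1e-4, which the signed test handles
gracefully while a strict absolute-value test would not); the
iteration cap is 2000. Ties in every argmax assignment break
lexicographically by group label, making all outputs deterministic.

## PCA-based classifiers

The reference matrix is standardized SNP-wise to
`(g − 2p̂) / sqrt(2 p̂ (1 − p̂))` with `p̂` the reference ALT frequency —
unit variance under Hardy–Weinberg, the classical scaling for
population-structure PCA. Missing genotypes are mean-imputed (zero
after standardization) in both fitting and projection; with ≤10%
missingness this biases projections mildly toward the origin, which is
acceptable for classification. Loadings are the top right-singular
vectors of the standardized reference; queries are projected by plain
least squares onto the first five components (no shrinkage
correction — out of scope, and at sc-SNP panel sizes the projection
bias is shared by all queries). A fixed sign convention (the
largest-|entry| loading coordinate of each component is positive)
makes the model reproducible regardless of sample order.

* **PCA-Distance** assigns a query to the ancestry group whose
  centroid (per-group mean of reference scores over all five PCs) is
  nearest in Euclidean distance. Reported per-group scores are
  normalized inverse distances — a uniform output shape, explicitly
  *not* probabilities (`score_type="inverse_distance"`).
* **PCA-RandomForest** trains a 100-tree, unlimited-depth random
  forest (scikit-learn) on the labelled reference scores with a fixed
  seed and reports tree-vote class probabilities.

## QC and LD pruning

SNPs are kept when their **reference-panel** MAF is strictly above 5%
(the reference, never the query set, defines commonness); SNPs and
then samples with missingness strictly above 10% are excluded, in
that order, so the rule set is deterministic. Both cutoffs are strict:
a SNP at MAF exactly 0.05 is removed, a sample at exactly 10%
missingness is kept.

LD pruning follows windowed `r²` semantics (windows counted in SNPs:
window 50, step 10, threshold 0.1 by default; windows never span
chromosomes). `r²` is the squared Pearson correlation of raw dosages
over pairwise-complete entries, defined as 0 for constant vectors or
<2 complete pairs. Within a window, while any retained pair exceeds
the threshold, the pair with the largest `r²` is found (ties: the
lexicographically first index pair) and its member with the smaller
reference MAF is removed (MAF tie: the larger position). Sliding
passes at the configured step repeat until stable, then step-1
enforcement passes guarantee the postcondition that *no* window of 50
consecutive kept SNPs contains a pair above the threshold — this also
makes the operation idempotent. The exact removal rule is a package
decision (pruning tools differ across versions in which member of a
pair they drop); what matters is that it is deterministic and that an
independent brute-force implementation of the same rule reproduces it,
which the test suite checks on random instances.

A caution from testing: with only tens of reference samples the null
distribution of `r²` is wide enough that a 0.1 threshold removes most
truly independent SNPs (chance `r²` scales as `1/n`). At realistic
reference sizes (hundreds to thousands of samples) this artifact
vanishes; the package's own tiny-panel tests use a looser threshold
for this reason.

## Synthetic data generator

The generator emulates a worldwide reference panel and sc-SNP-scale
query data. Ancestral frequencies are `Uniform(0.05, 0.95)` (mirroring
the restriction to common SNPs); group frequencies are Balding–Nichols
draws `Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F = fst_between = 0.1`, and
populations are a second nested draw inside each group with
`fst_within = 0.01`; genotypes are Hardy–Weinberg binomial samples.
Admixed individuals draw each allele copy's ancestry from `q` and then
the allele from that group's frequency — exactly the generative model
the admixture likelihood assumes. Genotype errors replace a call, with
the target probability, by one of the *other two* genotypes uniformly,
so the marginal discordance versus truth equals the nominal rate (the
quantity actually measured when validating calls against arrays);
whether real scRNA-seq errors are symmetric between heterozygous and
homozygous calls is unknown, and this symmetric choice is a stated
assumption. Missingness is injected independently per cell.

Scenario defaults are the LOPO study conditions: 6 groups × 3
populations × 20 samples, 3,000 SNPs, FST 0.1 / 0.01. Missingness and
error rates default to 0 in the scenario because the evaluation layer
injects errors itself, per condition, into held-out genotypes only.

What the generator does **not** emulate: linkage disequilibrium (SNPs
are exchangeable and independent, so pruning on synthetic panels
removes little), realistic site-frequency spectra, correlated
missingness along transcripts, platform- or coverage-dependent error
rates, and the shared drift structure of real continental populations
(real groups are not exchangeable Beta draws around one ancestral
frequency). Consequently, passing synthetic benchmarks demonstrates
the correctness and internal calibration of the machinery, not the
real-data error rates of any particular cohort.

## Evaluation design

LOPO is strict leave-out: for each fold the held-out population is
removed *before* LD pruning, PCA, and group-frequency estimation, so
nothing about it leaks into the model that classifies it. Genotype
errors are injected into the held-out individuals' genotypes only —
the reference stays clean, as a curated panel would be. Error-rate
sweeps share fold preparation and per-fold random streams across
rates, so a rate of zero reproduces the error-free run bit for bit and
differences along the grid are attributable to the error injection
alone (the injection streams are also nested: the cells corrupted at a
lower rate are a subset of those corrupted at a higher rate).

Error rates carry 95% Wilson score intervals — chosen because the
interval behaves sensibly at zero observed errors, which near-zero
LOPO error rates produce routinely. The implementation is the closed
form with `z = Φ⁻¹(0.975)`; a test cross-checks it against
statsmodels. At `Binomial(200, 0.02)` its exact coverage is 0.933,
within the designed [0.93, 0.97] band; tests assert the exact coverage
(summing the binomial pmf over covering outcomes) rather than a
Monte-Carlo estimate whose ±0.006 sampling noise would straddle the
band edge.

Admixture recovery reports ordinary least squares (with intercept) of
estimated on true proportions plus Pearson r, per component.
Gold-standard selection for admixed cohorts keeps samples whose
full-panel estimated ancestry proportion strictly exceeds 1/8.

Sub-population inference within one ancestry group uses
leave-one-*individual*-out (populations are the classes, so holding
out a whole population would delete its class), with the same strict
per-fold recomputation.

## Problem sizes

The packaged benchmark experiments run at desk scale, chosen to keep
estimates meaningful while staying cheap: recovery uses K = 3 groups,
100 reference samples per group, 5,000 SNPs, and 50 Dirichlet(1,1,1)
queries; LOPO uses the default 360-sample, 3,000-SNP hierarchical
panel with 18 folds, swept over error rates 0–12%. On one CPU the full
test suite and the acceptance script each complete in well under half
an hour.

## Known limitations

* **Slope attenuation under genotype error.** Injecting 8%
  uniform-substitution errors makes the observed genotypes deviate
  from the binomial-mixture model; the ML proportions then shrink
  systematically toward uniform, giving recovery slopes around
  0.73–0.79 at the benchmark conditions even though correlations stay
  ≥ 0.99. This is a property of the estimator, not a defect of the
  optimizer: the EM fixed point matches direct numerical maximization
  of the likelihood to high precision, and the attenuation persists
  when the true frequencies are supplied. Milder attenuation (~0.95)
  exists even without error, from finite-reference frequency noise
  and simplex-boundary bias on near-pure queries. No error-model
  correction is applied, matching how such tools are used in practice.
* **No LD in simulations** — pruning is exercised for correctness on
  constructed correlated instances, not on realistic haplotype
  structure.
* **No projection-shrinkage correction** in PCA query projection.
* Only biallelic SNVs are supported end to end; multiallelic sites,
  indels, and dosage (non-integer) genotypes are out of scope.
* Real-data error rates from the literature (fractions of a percent
  for panel-scale references) are not reproducible from the synthetic
  benchmarks; they require the actual reference and query cohorts.
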