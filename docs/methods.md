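# Methods

Statistical conventions and algorithms used by `missnp`, in pipeline order.

## Genotype data model and PLINK I/O (`missnp.genio`)

Genotypes are minor-allele dosages in `{0, 1, 2}` with `-1` for missing,
stored as an `int8` samples × SNPs matrix plus `.bim`-style SNP and
`.fam`-style sample tables. Phenotypes use the PLINK convention:
1 = control, 2 = case, anything else = unknown.

* **Binary dialect** — `.bed` magic bytes `6C 1B`, SNP-major mode byte
  `01`, then one block of `ceil(n/4)` bytes per SNP. Two-bit codes are
  packed LSB-first: `00` = homozygous A1 (dosage 2), `10` = heterozygous,
  `11` = homozygous A2 (dosage 0), `01` = missing. Malformed magic, mode
  or truncated bodies raise `PlinkFormatError`.
* **Text dialect** — `.ped`/`.map` with `0 0` for a missing genotype;
  more than two observed alleles at a SNP is an error.
* **Orientation** — on load, any SNP whose allele-1 frequency exceeds 0.5
  is flipped to minor-allele dosage (ties are left alone). The synthetic
  generator emits data already in this canonical orientation, which makes
  write∘read the identity for both dialects.

## Synthetic cohorts (`missnp.syndata`)

* **Allele frequencies** — ancestral frequencies uniform on `maf_range`;
  each of two populations draws per-SNP frequencies from the
  Balding-Nichols Beta distribution with parameters
  `p(1-F)/F, (1-p)(1-F)/F` (`F` = fst), so the cross-population variance
  is `F·p(1-p)`; `F = 0` makes the populations identical.
* **Founder genotypes** — binomial(2, p) per SNP at the subject's
  population frequency.
* **Phenotypes** — a fraction `subclass_fraction` of subjects is flagged
  as a hidden sub-class. Everyone else's case probability is
  `logistic(α_main + β_main·Σ main-causal dosages)`; sub-class members use
  `logistic(α_sub + β_sub·Σ sub-causal dosages)` over a *disjoint* causal
  SNP set. The intercepts are solved by bisection so each group's expected
  case share equals the configured case:control balance; degenerate
  targets (all-case / all-control cohorts) clamp to the bracket edge, and
  genuinely unattainable targets raise `GenerationError`.
* **Families** — for each affected founder, parents are sampled from their
  exact posterior given the founder's genotype (Hardy-Weinberg priors at
  the founder's population frequency, Mendelian transmission likelihood),
  and full siblings are drawn from those parents. Parents appear in the
  pedigree only; siblings' phenotypes come from the same frozen model.
  This yields the textbook kinship of 0.25 between full siblings while
  leaving founder genotypes untouched.
* **Planted QC failures** — disjoint, non-causal SNP sets are overwritten:
  monomorphic (all dosage 0), Hardy-Weinberg violating (genotypes redrawn
  with inbreeding coefficient `hwe_inbreeding`), high-missingness (per-SNP
  missing rate uniform in [0.05, 0.10]), and missing rs identifiers
  (renamed `chr<c>:<pos>`). A `TruthManifest` records causal SNPs,
  sub-class members, population labels, planted failures, the true kinship
  matrix and the frozen phenotype model.

All draws flow from one `numpy.random.SeedSequence`, so a configuration is
reproducible bit for bit.

## Quality control (`missnp.qc`)

Subjects: phenotype filter (codes other than 1/2 removed) → PCA ancestry
filter → (for the unrelated analysis set) one subject per family, chosen
uniformly at random.

The ancestry filter standardizes a per-chromosome-quota SNP subsample as
`(g − 2p̂)/sqrt(p̂(1−p̂))` with missing cells zeroed after centering, takes
the top sample-space principal components (exact Gram eigendecomposition
below 2·10⁶ matrix cells, seeded randomized SVD above), and removes the
minority side of PC1 within each phenotype group. A two-means separation
statistic on PC1 (between-cluster gap over pooled within-cluster sd, cutoff
3.0) guards the homogeneous case: with no detectable cluster structure,
nobody is removed.

SNPs, in order: autosomes only (chrom ≤ 22) → rs identifier required →
call rate ≥ 0.98 within cases **and** within controls (boundary inclusive)
→ monomorphic removed → Hardy-Weinberg χ² (1 df, on controls) at
α = 10⁻⁵. Every stage reports entering/removed/retained counts and the
removed identifiers; the cascade is idempotent.

## Association (`missnp.assoc`)

* **Pedigree kinship** — recursive tabular method in topological order:
  `φ_ii = ½(1 + φ_fm)`, `φ_ij = ½(φ_fj + φ_mj)`; cycles raise.
* **Kinship-corrected χ²** — with contrast weights `w_i = 1/n_case` for
  cases and `−1/n_ctrl` for controls, score `D = wᵀx` and dosage
  covariance `Cov(x_i, x_j) = 4φ_ij p(1−p)` under the null, the variance
  estimate is `Var(D) = 2p̂(1−p̂)·wᵀ(2Φ)w` and `D²/Var(D) ~ χ²₁`. With
  `Φ = ½I` this reduces exactly to the classical allelic trend test.
  Missing genotypes are excluded pairwise (weights zeroed, quadratic form
  restricted). Monomorphic or single-class SNPs report `(0, 1)`.
* **Pre-selection** — `top_k` (k smallest p, ties broken by genomic
  position) or `p_threshold` (all p < α); output in ascending-p order.

## Model building (`missnp.model`)

* **Imputation** — k-nearest-neighbour (k = 5) median: distances are
  `nan`-aware Euclidean, donors must be called at the target SNP, the
  median is rounded to `{0, 1, 2}`.
* **Split** — stratified holdout (default 80/20) on the unrelated set.
* **LASSO** — dosages standardized on the training set; glmnet-style
  penalty grid log-spaced from `λ_max = max|Xᵀ(y−ȳ)|/n` down four
  decades (100 points); stratified 10-fold CV; the λ minimizing mean
  binomial deviance wins, ties going to the stronger penalty. The path is
  walked from strong to weak and abandoned after 15 consecutive
  non-improving grid points. Each fit is an L1 `liblinear` logistic
  regression with `C = 1/(nλ)`. The final model is refit on all training
  samples at the chosen λ; coefficients are reported on the raw dosage
  scale.
* **Evaluation** — predicted case iff score ≥ 0.5; confusion matrix,
  accuracy, sensitivity, specificity; AUC as the trapezoidal area under
  the exact ROC curve, which equals the Mann-Whitney U statistic over
  `n_case·n_ctrl`. Single-class evaluation sets report AUC as undefined
  (`None`). Misclassified sample identities are kept, split by true class.

## Re-modeling and mixing (`missnp.remodel`)

Misclassified samples from the base model (taken from the training split,
the test split, or both) are re-scanned with the corrected χ² — by default
together with all members of their families, using the kinship submatrix —
and a second LASSO model is fitted on the misclassified samples alone over
the SNPs passing p < 10⁻³. Its internal evaluation is stratified CV on the
missed set and is stamped as optimistically biased.

Two mixing strategies build a combined pool: **SNPs Mix** (union of the two
input pools) and **Models Mix** (union of the two *selected* SNP sets).
The combined pool is refit on the original training samples and evaluated
on the untouched test set; the report carries the AUC delta against the
base model and the model-length change, plus pairwise model overlap counts
and within-model selected-SNP pairs with dosage r² > 0.95.

**Leakage control** — the train/test split happens *before* base
pre-selection: the base pool is selected on the full familial cohort
excluding all held-out test subjects, so in missed-from-train mode no test
genotype or label influences any selection step. Missed-from-test mode
necessarily feeds test information back; its outputs are labelled
`test-informed selection`.

## Determinism

A single master seed spawns independent streams (simulation, PCA,
family sampling, split, CV folds, re-modeling, mixing) via
`SeedSequence.spawn`; two runs with the same configuration and seed
produce byte-identical summary JSON.
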