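# missnp

GWAS case-control classification with misclassified-sample re-modeling.

## The problem

Genome-wide association studies model a disease as one homogeneous trait,
but many complex diseases hide **genetic sub-classes**: subsets of patients
whose risk is driven by a different group of variants than the majority.
A classifier built on the strongest genome-wide signals then systematically
misclassifies exactly those subjects, and the sub-class variants never rank
high enough in a whole-cohort association scan to be picked up.

`missnp` implements a re-modeling strategy that turns that failure mode
into a feature:

1. **QC** a familial case-control cohort (call rate, Hardy-Weinberg,
   monomorphic/identifier filters, EIGENSTRAT-style PCA ancestry
   filtering, one-subject-per-family reduction).
2. **Pre-select** SNPs with a **kinship-corrected χ² test** that stays
   calibrated in the presence of relatives (the variance of the allelic
   contrast is corrected by the pedigree kinship matrix).
3. Fit an **L1-penalized logistic model** with stratified cross-validation
   over a glmnet-style penalty grid, and evaluate it on a held-out split.
4. Collect the **misclassified samples**, re-run SNP selection on them
   alone (plus their families), and fit a second model.
5. **Mix** the two models — union of selected SNPs (*Models Mix*) or union
   of input pools (*SNPs Mix*) — refit on the original training samples,
   and compare held-out AUC against the base model.

Everything runs on synthetic cohorts with a planted ground truth
(`TruthManifest`): two Balding-Nichols ancestry clusters, nuclear families,
a hidden sub-class driven by its own causal SNPs, and planted QC failures,
so every stage of the pipeline can be validated against a known answer.

## Worked example

```python
from missnp.remodel import PipelineConfig, run_full_pipeline
from missnp.syndata import SimConfig

config = PipelineConfig(
    sim=SimConfig(n_founder_cases=600, n_founder_controls=600, n_snps=5000),
    base_top_k=100,
)
result = run_full_pipeline(config, seed=42)

print("subjects after QC:",
      [s for s in result.qc_report.stages if s.unit == "subjects"][-1].n_out)
print("SNPs after QC:   ",
      [s for s in result.qc_report.stages if s.unit == "snps"][-1].n_out)
print(f"base model: {result.base_model.length} SNPs, "
      f"test AUC {result.base_test_report.auc:.3f}")
for key, mix in sorted(result.mixes.items()):
    print(f"{key}: {mix.mixed_model.length} SNPs, "
          f"test AUC {mix.report.auc:.3f} (delta {mix.delta_auc:+.3f})")
```

Output (bit-reproducible for a fixed seed):

```
subjects after QC: 1097
SNPs after QC:    4858
base model: 99 SNPs, test AUC 0.605
test:models_mix: 101 SNPs, test AUC 0.606 (delta +0.001)
test:snps_mix: 101 SNPs, test AUC 0.606 (delta +0.001)
train:models_mix: 102 SNPs, test AUC 0.610 (delta +0.004)
train:snps_mix: 103 SNPs, test AUC 0.609 (delta +0.004)
```

`mixes` is keyed `<missed source>:<strategy>`: misclassified samples can be
taken from the training split (leak-free: no test genotype or label ever
touches SNP selection) or from the test split (the optimistic variant, whose
outputs are stamped `test-informed selection`).

The same pipeline is available from the command line:

```
missnp simulate --out cohort --seed 7   # .bed/.bim/.fam + pedigree + truth.json
missnp qc --in cohort --out cohort_qc --report qc_report.json
missnp assoc --in cohort_qc --pedigree cohort.pedigree.tsv --out assoc.tsv
missnp run --seed 7 --out results/      # full pipeline: summary.json, models
```

`missnp run --config pipeline.yaml` accepts a YAML file mirroring
`PipelineConfig` (including a nested `sim:` block mirroring `SimConfig`);
`missnp run` can also start from real PLINK files via `input_prefix`
instead of a simulation block.

## Modules

| module | contents |
| --- | --- |
| `missnp.genio` | PLINK binary (`.bed/.bim/.fam`) and text (`.ped/.map`) reader/writer, dosage data model, pedigree table |
| `missnp.syndata` | synthetic cohort generator + `TruthManifest` |
| `missnp.qc` | phenotype/ancestry/relatedness subject filters, SNP QC cascade, per-stage report |
| `missnp.assoc` | pedigree kinship, Hardy-Weinberg tests, kinship-corrected χ², SNP pre-selection |
| `missnp.model` | kNN-median imputation, stratified holdout, CV-tuned L1 logistic model, evaluation metrics |
| `missnp.remodel` | misclassified-sample re-modeling, pool/model mixing, overlap reports, `run_full_pipeline` |

See `docs/methods.md` for the statistical details and conventions.

## Reproduction

```
pip install --no-build-isolation --no-deps -e .
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite covers unit/property tests per module plus
`tests/test_acceptance.py`, one test per acceptance property (oracle
equivalence of the corrected χ², type-I calibration on sib-pair families,
exact attribution of planted QC failures, sub-class recovery via Models
Mix, set-union regressions, AUC/Mann-Whitney agreement, byte-level
determinism, PLINK round trips). `scripts/acceptance.py` runs the default
pipeline plus a calibration experiment and writes every headline quantity
as `{"name": {"value": ..., "n": ...}}`.

Known limitation: with the default generator settings the planted
sub-class effect is too weak for the misclassified-training-samples scan
to recover sub-class SNPs at the pre-selection threshold (per-SNP
non-centrality ≈ 0.5 on the missed subset), so the sub-class-recovery
acceptance test currently fails its signal half; the null half
(no sub-class ⇒ no spurious gain) passes. The power analysis lives
outside the package in the project notes.
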