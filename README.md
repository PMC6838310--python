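# deprisk

Proteomic and clinical risk modelling of depression onset: repeated
cross-validated group-LASSO ensembles with AICc model averaging, evaluated
by ROC/AUC on training and extrapolation cohorts, exercised end to end on a
synthetic cohort generator with known ground truth.

## What it does

The pipeline models a case-control study in which healthy reference
individuals are contrasted with patients who have current subthreshold
depressive symptoms. Candidate predictors are targeted mass-spectrometry
(MRM) peptide log2 abundance ratios, sociodemographic variables, and ordinal
clinical symptom severities plus their total score — by default 146 + 22 +
30 features for 86 + 86 training samples, so p ≫ n. A third group of
*extrapolation* patients — healthy at sampling but developing symptoms later
— probes how far the fitted model generalizes beyond its training scope.

The analysis chain:

1. **MRM preprocessing** — pick one quantifier transition per peptide (peak
   areas summed across samples), form `log2(endogenous / SIS)` ratios, and
   screen samples by a PCA outlier rule.
2. **Feature preparation** — missingness screen, chained-equations multiple
   imputation (m = 5), dummy coding of categorical/ordinal features into
   penalty groups, and standardization of continuous columns.
3. **Group-LASSO logistic regression** — blockwise proximal coordinate
   descent over a 100-point penalty path; the penalty per group is
   λ·√p_g·‖β_g‖₂, so a categorical's dummy set enters or leaves jointly.
4. **Ensemble selection** — R = 100 repeats of 10-fold cross-validation
   (one-standard-error rule), each repeat yielding one selected model.
5. **AICc model averaging** — each repeat's model is scored by the
   small-sample AIC and Akaike weights; a single dominant model (probability
   > 0.9) is averaged directly, otherwise features selected in ≥ 90% of
   repeats are retained and their coefficients averaged over all repeats
   with absent models contributing zero.
6. **Evaluation** — logistic risk scores, ROC curves, and AUC (the
   trapezoid and Mann–Whitney computations agree exactly), with qualitative
   performance bands.

The synthetic generator plants 12 informative features (6 peptides, BMI,
childhood trauma, education, 3 symptoms) at a standardized effect of 0.8 and
attenuates all effects by 0.5 for the extrapolation group, so recovery and
generalization behaviour can be validated against ground truth. See
[docs/methods.md](docs/methods.md) for the full model, numerical choices and
generator scope.

## Quick start

One command simulates a cohort at the default study dimensions, preprocesses
the raw transition-level data, runs the full ensemble analysis, and writes
all reports:

```sh
$ deprisk all --seed 1 -o runs/demo
INFO deprisk.pipeline: simulating cohort (seed=1)
INFO deprisk.mrm_preprocess: PCA outlier screen: no outlier samples identified
INFO deprisk.feature_prep: missingness screen dropped 1 feature(s): ['irritability']
INFO deprisk.pipeline: design: 172 samples x 257 columns in 196 groups
retained 11 feature(s); training AUC 0.944 (excellent), extrapolation AUC 0.868 (good)
```

This takes about two minutes on one CPU. `runs/demo/` then contains
`summary.json`, `model_report.csv` (selection fractions and averaged
coefficients), `unique_models.csv`, per-cohort ROC curves, the resolved
`config.yaml`, and a `manifest.json` recording the seed, configuration hash
and per-stage shapes. For seed 1 the averaged model retains 11 features —
eight peptides, BMI, childhood trauma and the symptom total score — and the
most important coefficients are exactly the planted ones:

```
$ head -4 runs/demo/model_report.csv
column,feature,selection_fraction,average_coefficient
pep_001,pep_001,1.0,0.1098941767847025
pep_026,pep_026,1.0,0.48959440846367397
pep_046,pep_046,1.0,-0.18924131984879236
```

The training-vs-extrapolation gap (AUC 0.944 vs 0.868) reflects the
generator's attenuated pre-onset effects; with attenuation 0 the
extrapolation AUC drops to chance.

The same run from Python:

```python
from deprisk import CohortSpec
from deprisk.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(cohort=CohortSpec(seed=1), seed=1)
report = run_pipeline(config)
print(report.model.features)      # retained features
print(report.auc_training)        # 0.9438885884261763
print(report.auc_extrapolation)   # 0.8683218101822753
```

### Staged CLI

Each stage is also a separate command operating on files, so real (non-
simulated) data can enter at any point:

```sh
deprisk simulate   -c config.yaml -o sim/          # cohort CSVs + raw transitions
deprisk preprocess --transitions sim/transitions.csv -o ratios.csv --qc-report qc.csv
deprisk fit        --table sim/training.csv --schema sim/schema.yaml \
                   -c config.yaml -o ensemble.json
deprisk average    --ensemble ensemble.json -o avg/
deprisk evaluate   --model avg/averaged_model.json --table sim/training.csv \
                   --schema sim/schema.yaml --cohort-name training -o eval/
```

Feature tables are plain CSVs with a YAML schema sidecar declaring each
column's kind (continuous / categorical / ordinal) and levels; loading
validates kinds, ranges and unknown columns.

Every run is fully determined by its configuration and one integer seed; all
random streams (cohort groups, transitions, missingness, imputation chains,
CV partitions) are derived, named substreams of that seed.

## Layout

```
src/deprisk/
  synthetic_cohort.py    cohort generator, schema, transition tables
  mrm_preprocess.py      quantifier selection, log-ratios, PCA QC
  feature_prep.py        imputation, dummy coding, standardization
  group_lasso.py         penalized solver, lambda path, cross-validation
  ensemble_averaging.py  repeats, AICc/Akaike weights, model averaging
  evaluate.py            risk scores, ROC/AUC, performance bands
  pipeline.py            configuration, orchestration, file I/O
  cli.py                 command-line interface
docs/methods.md          methods note
scripts/acceptance.py    end-to-end headline-quantity recomputation
tests/                   unit + acceptance suites
```
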