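# episig

Discovery and classification of blood **DNA-methylation episignatures** —
reproducible genome-wide methylation patterns that mark specific genetic
neurodevelopmental disorders — from EPIC-style β-value matrices.

The package is aimed at computational (epi)geneticists who want a tested,
importable implementation of the standard episignature workflow: a small
case cohort (typically ~8 patients) is contrasted against matched controls,
a compact probe set is selected, validated without supervision, and turned
into a calibrated classifier that scores any new sample for the presence of
the signature. Because patient-level array data usually cannot be shared, a
synthetic-cohort generator with full ground truth stands in for real data
in all tests and examples.

## The method

For each CpG probe, the methylation fraction β ∈ [0, 1] is transformed to
M = log₂(β/(1−β)) and modelled per probe as

    M = β₀ + β₁·case + Σⱼ γⱼ·wⱼ + ε

where wⱼ are blood cell-type proportions estimated by constrained
projection onto reference profiles (Houseman-style: min ‖β − Rw‖² s.t.
w ≥ 0, Σw ≤ 1). Residual variances are shrunk by empirical Bayes: with
per-probe s²_g on d_g df and a scaled-inverse-χ² prior (d₀, s₀²) estimated
from the data by digamma/trigamma moment matching, the moderated t uses
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) on d₀ + d_g df.

Feature selection is three-step: keep the 1000 probes with the highest
|Δβ|·(−log₁₀ p); of those, the 250 with the most discriminative AUROC
(max(AUROC, 1−AUROC)); then greedily drop probes with Pearson r > 0.9 to an
already-kept probe within the case group and within the control group. The
surviving probes are the episignature, validated by Ward/Euclidean
clustering, classical MDS, and a leave-one-case-out cross-validation.

A linear-kernel SVM over the signature probes (cases vs matched controls +
75% of an external control/other-disorder pool, the remaining 25% held out)
emits a Platt-calibrated **MVP score** (methylation variant pathogenicity)
in [0, 1] with a 0.5 class cut-off. Region-level analysis chains probes
within 1 kb and calls DMRs with ≥ 3 CpGs, mean |Δβ| ≥ 5% and BH-adjusted
Fisher combined p < 0.01.

## Worked example

```python
import episig as es
from episig import diffmeth

config = es.CohortConfig(n_probes=12_000, n_control_pool=0,
                         n_other_disorders=1, seed=1)
cohort = es.generate_cohort(config)                       # 8 cases + 56 controls
beta, qc = es.filter_probes(cohort.beta, cohort.detp, cohort.manifest)
m = es.beta_to_m(beta)
ref = cohort.reference.loc[cohort.reference.index.intersection(beta.index)]
covars = diffmeth.celltype_covariates(es.estimate_proportions(beta, ref))

cases = sorted(cohort.samples.index[cohort.samples.group == "case"])
controls = sorted(cohort.samples.index[cohort.samples.group == "control"])
dmp = es.dmp_table(beta, m, cases, controls, covars)
sig = es.select_features(dmp, beta, cases, controls)
print(sig.provenance["step_counts"])
```

prints (from `examples/03_differential_and_signature.py`):

```
selection steps: 1000 by rank score -> 250 by AUROC -> 250 after correlation pruning
250/250 selected probes are planted signature probes
```

i.e. step 1 retained exactly 1000 probes, step 2 exactly 250, no pair of
survivors was redundant in both groups, and every selected probe belongs to
the generator's planted differential set. Scoring the full synthetic world
(`examples/05_classifier_mvp.py`) gives cases MVP ≈ 0.91 and all controls,
confounder disorders and VUS-like test samples MVP ≤ 0.008 — full
sensitivity and specificity on the held-out 25%, with the signature-free
test samples correctly called negative.

The other scripts in `examples/` each exercise one capability end to end
(simulation, QC + deconvolution, validation, regions + pipeline) and print
a short interpretation with their numbers.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic control pool from scratch, runs the matched-
control selection for the default 8-case discovery cohort at the default
7:1 ratio, and writes the resulting count (with the pool size used) as
JSON.

## Layout

- `src/episig/simulate.py` — synthetic worlds: planted signatures, cell
  composition, batches, confounder disorders, VUS-like samples
- `src/episig/preprocess.py` — probe QC, β→M, PCA outlier screen
- `src/episig/deconvolution.py` — reference-based cell-type proportions
- `src/episig/diffmeth.py` — per-probe models, empirical-Bayes moderation,
  Δβ, AUROC
- `src/episig/signature.py` — matching, three-step selection, Ward, MDS,
  LOOCV
- `src/episig/classifier.py` — SVM training, Platt calibration, MVP scores
- `src/episig/regions.py` — DMR calling and the signature adjacency rule
- `src/episig/pipeline.py` — one-call orchestration with hashed artifacts

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
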