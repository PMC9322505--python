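# Methods

This note documents the models, defaults and numerical choices behind
`episig`, and what the synthetic worlds do and do not establish.

## The synthetic world

`episig.simulate` generates cohorts with the statistical structure the
analysis assumes, with complete ground truth. One `CohortConfig` defines a
*world*: the probe manifest, baseline methylation, cell-type reference,
planted probe sets and batch offsets are drawn from seed-derived streams,
so the discovery cohort, control pool and confounder cohorts generated
from the same config share one array and can be analysed jointly.

Per-sample β at probe p is

    β = clamp( expit( logit(Σₜ wₜ Rₚₜ) + batchₚ + s·λ·𝟙[planted, case] + ε ) )

with R the per-cell-type reference profiles (β scale), w ~ Dirichlet
around a granulocyte-dominated blood composition (concentration 30),
batch offsets N(0, 0.1) per (batch, probe), a planted case shift of
λ = `effect_logit` with random per-probe sign s, noise ε ~ N(0,
`noise_sd`), and clamping to [1e−6, 1−1e−6] so M-values stay finite.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_probes` | 20 000 | desk-scale stand-in for the ~776k-probe cleaned EPIC array; large enough that the 1000→250 selection and region analysis behave as at scale |
| `n_cases` / `control_ratio` | 8 / 7 | the discovery design: 8 cases, 56 matched controls |
| `n_signature_probes` | 300 | comfortably above the 250 step-2 cut, so selection purity is measurable |
| `effect_logit` | 1.5 | ≈ 0.1–0.25 shift on the β scale depending on baseline — the magnitude at which published episignatures separate visibly in MDS |
| `noise_sd` | 0.3 | within-group logit-scale SD; keeps per-probe AUROC of null probes near 0.5 while planted probes approach 1 |
| `n_celltypes` | 6 | CD4+/CD8+ T cells, NK, monocytes, granulocytes, B cells |
| `batch_count` | 3 | a handful of processing batches, offsets N(0, 0.1) |
| `n_vus_like` | 3 | test samples drawn from the control model but labelled `test` — analogues of patients whose variant is of uncertain significance |
| `n_other_disorders` × `samples_per_disorder` | 10 × 8 | confounder cohorts with disjoint planted sets; desk-scale analogue of a large reference database of other syndromes |
| `n_control_pool` | 200 | unmatched control candidates for matching and for the classifier's negative pool |
| flag fractions | 2% / 2% / 1% | allosomal / SNP / cross-reactive probes, roughly the EPIC proportions after annotation |
| `detp_fail_rate` | 5e−4 per (probe, sample) | a few hundred probes lost to detection QC at cohort size, as on real arrays |

Baseline probe means are a two-component logit-normal mixture centred at
β ≈ 0.1 and β ≈ 0.9 (array methylation is bimodal). A 600-probe subset
carries strong cell-type deviations (SD 1.5 on the logit scale) and forms
the deconvolution reference panel; all probes carry mild deviations
(SD 0.2) so cell composition is a genuine confounder. Ages are drawn
2–50 years with ~46% females in the control pool, matching the stated
control demographics; matched controls are generated by jittering their
case's age (SD 2 years) with identical sex and array type. Three to five
planted probes trios are relocated into tight (≤ 800 bp) genomic clusters
with a coherent shift direction, so region-level calling has true
positives; all other inter-probe gaps are ≥ 2 kb, making spurious regions
essentially impossible.

What the generator does **not** emulate: Infinium I/II probe chemistry,
raw-intensity backgrounds (inputs are taken as normalized β), spatial/array
position effects, age- or sex-dependent methylation drift, and correlated
probe blocks outside the planted clusters. A green test therefore
establishes algorithmic correctness under the stated generative model, not
performance on real arrays.

## Quality control

Probes are removed if allosomal, SNP-flagged, cross-reactive, or with a
detection p > 0.01 in **any** sample — the strictest per-probe aggregation,
chosen because the filtering description gives no aggregation rule and
any-sample removal is common array-QC practice. Removal reasons are made
disjoint by the declared precedence allosomal > SNP > cross-reactive >
detection so QC counts are reproducible. PCA outlier screening flags
samples beyond 3 SD on either of the first two components; outliers are
reported, not auto-dropped (`exclude_outliers` opts in), because the
protocol states detection, not the action taken.

## Deconvolution

Houseman-style reference-based estimation: per sample, minimize
‖β − Rw‖² subject to w ≥ 0 and Σw ≤ 1 over the reference probe panel.
The inequality form is the standard projection variant and the safer
convex relaxation; `sum_to_one=True` switches to the simplex. The problem
is a 6-variable convex QP solved with SLSQP (`ftol` 1e−14); tests verify
exact recovery of noiseless mixtures to 1e−6 and dominance over a
0.05-step grid search. Rank-deficient references are rejected with the
most collinear pair named.

## Differential methylation

Per-probe OLS on M-values with intercept, case indicator and cell-type
proportions as covariates. Because estimated proportions sum to ≈ 1, the
last cell type (B cells in the default order) is dropped from the design
(`celltype_covariates`) to keep it full rank — the fit is invariant to
which category is dropped. Batch and array type can be added as optional
design columns but default off, since the protocol lists only cell
proportions as covariates.

Moderation follows the standard empirical-Bayes scheme: (d₀, s₀²) solve
the digamma/trigamma moment equations of log s²_g under a
scaled-inverse-χ² prior; the trigamma inverse uses Newton iteration. When
the observed dispersion of log s²_g does not exceed its sampling variance,
d₀ = ∞ and s₀² is the pooled mean variance (the no-heterogeneity limit;
a normal reference distribution is then used). p-values are floored at
1e−300 so the −log₁₀ p rank score stays finite.

Per-probe AUROC is the Mann–Whitney U over case/control β values with
ties counted ½. The step-1 score uses |Δβ| (a hypomethylated probe is as
informative as a hypermethylated one; `signed_rank` switches this).

## Feature selection

Step 2 keeps the probes with the most *discriminative* AUROC,
max(AUROC, 1 − AUROC): an AUROC near 0 is perfect separation with the
direction reversed, and ranking raw AUROC would silently discard every
case-hypomethylated probe. Step 3 walks survivors from the strongest and
discards a probe only when its β-correlation with an already-kept probe
exceeds 0.9 **in both** the case and control groups — the conservative
reading of "within case and control groups separately"
(`redundancy_mode="either"` gives the aggressive one). Ties in any ranking
break lexicographically by probe id, so selection is deterministic.
Constant probes have undefined correlation and are treated as
non-redundant.

## Validation

Ward/Euclidean clustering (scipy linkage) with the two-cluster cut;
classical Torgerson MDS (double-centred squared-distance matrix, top-2
eigenpairs; axes with non-positive eigenvalues are zeroed with a warning);
Kruskal stress-1 is reported. The leave-one-case-out driver refits the
differential model and reselects probes without the held-out case, embeds
all samples by MDS on the fold's probes, and assigns the held-out sample
to the nearer group centroid in the 2-D embedding — a centroid rule makes
the visual clustering judgement assertable. An empty fold selection marks
the fold failed without aborting the run.

Matched-control selection is greedy per case (cases in id order): cost
= |age difference| / pooled age range + 1 per sex mismatch + 1 per
array-type mismatch, ties broken by candidate id. The weights are a design
choice; the protocol states only the matched variables and the 7:1 ratio.

## Classification

Features are β at the signature probes (bounded features calibrate well),
standardized by training mean/SD. The margin is a linear-kernel SVC at
C = 1 with inverse-frequency class weights — with 8 positives against
~1400 negatives an unweighted fit can collapse to the majority class. The
MVP score is Platt's sigmoid fitted by cross-entropy (with Platt's
prior-corrected targets) on out-of-fold decision values from a stratified
5-fold split of the training set; the final margin is refitted on all
training data. Kernel, C and calibration are exposed but unstated in the
protocol; these defaults are the standard choice for p ≫ n methylation
features. The model serializes to plain JSON (probes, scaling, hyperplane,
sigmoid), and scoring refuses to run when any signature probe is missing —
no silent imputation.

## Regions

"Within 1 kb" is interpreted as consecutive-probe gap ≤ 1000 bp (region
growing), not total span — the span variant is available via `span_rule`.
The "Fisher multiple-comparison p" phrase conflates two steps, so both are
explicit: Fisher's combined probability per candidate (X² = −2Σln pᵢ on
2k df) then Benjamini–Hochberg across candidates, significance at adjusted
p < 0.01. The 5% minimum difference applies to the region's mean |Δβ|.
The descriptive adjacency rule over signature probes (">2 probes in direct
vicinity, consistent direction") uses the same 1 kb default for
"direct vicinity" since no number is given, and requires ≥ 3 probes.

## Pipeline

`run_discovery` chains simulate/load → QC → deconvolution → matching →
differential table → selection → validation → training → scoring →
regions. Every artifact is plain text with a `#`-prefixed provenance line
(tool version, config hash, seed) or an embedded provenance block, and the
run manifest records a sha256 per artifact; identical config + seed
reproduce identical hashes (the output directory is excluded from the
config hash for exactly this reason). A stage failure raises `StageError`
naming the stage; interrupted writes keep a `.partial` suffix. Config is
YAML, validated against the dataclass schema with unknown fields rejected.

## Known limitations

- Synthetic realism: probe-probe correlation outside planted clusters is
  absent, so correlation pruning (step 3) removes few probes at default
  settings — on real arrays the 250 → ~150 attrition is larger.
- The generator's planted effect is additive on the logit scale and equal
  in magnitude at all signature probes; real effect-size spectra are
  heavier-tailed.
- The LOOCV centroid rule summarizes an MDS plot; borderline samples that
  a human would call ambiguous are forced to a side.
- Deconvolution assumes the reference panel matches the tissue; no
  reference-free mode is provided.
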