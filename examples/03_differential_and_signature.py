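"""Differential methylation and three-step episignature selection.

Fits the per-probe linear model on M-values with cell-proportion
covariates, moderates the variances empirically, and runs the
1000 -> 250 -> correlation-pruning selection. Prints the step counts and
how many selected probes are truly planted.
"""

import episig as es
from episig import diffmeth

config = es.CohortConfig(n_probes=12_000, n_control_pool=0,
                         n_other_disorders=1, seed=1)
cohort = es.generate_cohort(config)

beta, _ = es.filter_probes(cohort.beta, cohort.detp, cohort.manifest)
m = es.beta_to_m(beta)
reference = cohort.reference.loc[cohort.reference.index.intersection(beta.index)]
props = es.estimate_proportions(beta, reference)

samples = cohort.samples
cases = sorted(samples.index[samples["group"] == "case"])
controls = sorted(samples.index[samples["group"] == "control"])

dmp = es.dmp_table(beta, m, cases, controls,
                   covariates=diffmeth.celltype_covariates(props))
print(f"moderation prior: d0 = {dmp.attrs['prior_d0']:.1f}, "
      f"s0^2 = {dmp.attrs['prior_s0_sq']:.3f}")
print("top of the differential table:")
print(dmp.sort_values("rank_score", ascending=False).head(5).round(4))

signature = es.select_features(dmp, beta, cases, controls)
counts = signature.provenance["step_counts"]
print(f"\nselection steps: {counts['step1_rank']} by rank score -> "
      f"{counts['step2_auroc']} by AUROC -> {counts['step3_pruned']} "
      f"after correlation pruning")
planted = set(cohort.truth.signature_probe_ids)
hits = sum(p in planted for p in signature.probe_ids)
print(f"{hits}/{len(signature)} selected probes are planted signature probes")
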