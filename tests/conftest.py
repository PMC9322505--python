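"""Shared fixtures: one default synthetic world, computed once per session.

The heavy end-to-end objects (20k-probe cohort with pool and confounders,
QC'd matrices, differential table, signature, trained classifier) are
session-scoped so acceptance and module tests reuse a single run.
"""

from types import SimpleNamespace

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

import episig as es
from episig import diffmeth


@pytest.fixture(scope="session")
def default_config() -> es.CohortConfig:
    """The stated default world at seed 1 (>= 10,000 probes)."""
    return es.CohortConfig(seed=1)


@pytest.fixture(scope="session")
def small_config() -> es.CohortConfig:
    """A cheap world for unit-level checks that do not need scale."""
    return es.CohortConfig(
        n_probes=4000, n_control_pool=60, n_other_disorders=3,
        samples_per_disorder=4, n_signature_probes=150, seed=1,
    )


@pytest.fixture(scope="session")
def discovery(default_config) -> es.SyntheticCohort:
    return es.generate_cohort(default_config)


@pytest.fixture(scope="session")
def run(default_config):
    """Full discovery run on the default world: every intermediate object."""
    cohort = es.generate_cohort(default_config)
    pool = es.generate_control_pool(default_config)
    confounders = es.generate_confounder_cohorts(default_config)
    combined = es.combine_cohorts(cohort, pool, confounders)

    beta, qc = es.filter_probes(combined.beta, combined.detp, combined.manifest)
    m = es.beta_to_m(beta)
    reference = combined.reference.loc[combined.reference.index.intersection(beta.index)]
    props = es.estimate_proportions(beta, reference)

    samples = combined.samples
    case_ids = sorted(samples.index[samples["group"] == "case"])
    control_pool = samples[samples["group"] == "control"]
    control_ids = es.select_matched_controls(
        samples.loc[case_ids], control_pool, ratio=default_config.control_ratio
    )

    covariates = diffmeth.celltype_covariates(props)
    dmp = es.dmp_table(beta, m, case_ids, control_ids, covariates)
    sig = es.select_features(dmp, beta, case_ids, control_ids)

    other_controls = sorted(set(control_pool.index) - set(control_ids))
    disorder_ids = sorted(samples.index[samples["group"] == "other_disorder"])
    plan = es.TrainingPlan(
        case_ids=tuple(case_ids),
        matched_control_ids=tuple(control_ids),
        other_control_ids=tuple(other_controls),
        other_disorder_ids=tuple(disorder_ids),
        disorder_of=samples.loc[disorder_ids, "disorder"].to_dict(),
        split_seed=default_config.seed,
    )
    model = es.train_classifier(beta, sig, plan)
    scores = es.score_samples(model, beta)

    return SimpleNamespace(
        config=default_config,
        cohort=cohort,
        combined=combined,
        beta=beta,
        m=m,
        qc=qc,
        props=props,
        samples=samples,
        case_ids=case_ids,
        control_ids=control_ids,
        covariates=covariates,
        dmp=dmp,
        signature=sig,
        plan=plan,
        model=model,
        scores=scores,
    )
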