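"""Linear-model fits, empirical-Bayes moderation, delta-beta and AUROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import episig as es
from episig import diffmeth
from episig.errors import DegenerateDataError, InputError


def _m_frame(values, samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"cg{i}" for i in range(len(values))],
                        columns=samples)


class TestFitProbeModels:
    def test_two_group_coefficient_is_mean_difference(self):
        m = _m_frame([[1.0, 2.0, 3.0, 7.0, 8.0, 9.0]])
        design = es.build_design(m.columns, case_ids=["s3", "s4", "s5"])
        fits = es.fit_probe_models(m, design)
        assert fits.table["coef"].iloc[0] == pytest.approx(8.0 - 2.0, abs=1e-12)

    def test_perfect_fit_has_zero_residual_variance(self):
        m = _m_frame([[1.0, 1.0, 1.0, 4.0, 4.0, 4.0]])
        design = es.build_design(m.columns, case_ids=["s3", "s4", "s5"])
        fits = es.fit_probe_models(m, design)
        assert fits.table["sigma2"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert fits.table["df_resid"].iloc[0] == 4  # 6 samples - 2 columns

    def test_matches_pseudo_inverse_oracle_with_covariate(self):
        rng = np.random.default_rng(0)
        m = _m_frame(rng.normal(size=(5, 6)))
        covar = pd.DataFrame({"cell": rng.uniform(size=6)}, index=m.columns)
        design = es.build_design(m.columns, ["s0", "s1", "s2"], covar)
        fits = es.fit_probe_models(m, design)
        x = design.to_numpy()
        expected = (np.linalg.pinv(x) @ m.to_numpy().T)[1]  # group column
        assert np.abs(fits.table["coef"].to_numpy() - expected).max() < 1e-10

    def test_rank_deficient_design_names_columns(self):
        m = _m_frame(np.ones((2, 6)))
        covar = pd.DataFrame({"dup": [0, 0, 0, 1, 1, 1.0]},
                             index=[f"s{j}" for j in range(6)])
        with pytest.raises(InputError, match="group|dup"):
            es.build_design(m.columns, ["s3", "s4", "s5"], covar)


class TestModerationPrior:
    def test_parameter_recovery_from_simulated_variances(self):
        """20k variances from the scaled-inv-chi2 prior: d0 +-15%, s0 +-5%."""
        rng = np.random.default_rng(11)
        d0, s0_sq, dg, n = 4.0, 1.0, 10.0, 20_000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, size=n)
        s2 = sigma2 * rng.chisquare(dg, size=n) / dg
        fits = diffmeth.ProbeFits(
            table=pd.DataFrame({
                "coef": 0.0, "se": np.sqrt(s2), "sigma2": s2, "df_resid": dg,
            }, index=[f"cg{i}" for i in range(n)]),
            stdev_unscaled=1.0,
        )
        prior = es.estimate_moderation_prior(fits)
        assert abs(prior.d0 - d0) / d0 < 0.15
        assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.05

    def test_identical_variances_give_infinite_prior_df(self):
        table = pd.DataFrame(
            {"coef": 0.0, "se": 1.0, "sigma2": [1.0, 1.0], "df_resid": 10.0},
            index=["a", "b"],
        )
        prior = es.estimate_moderation_prior(
            diffmeth.ProbeFits(table=table, stdev_unscaled=1.0))
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(1.0)
        # invariance to probe order
        prior2 = es.estimate_moderation_prior(
            diffmeth.ProbeFits(table=table.iloc[::-1], stdev_unscaled=1.0))
        assert prior2.s0_sq == prior.s0_sq and np.isinf(prior2.d0)

    def test_all_zero_variances_is_degenerate(self):
        table = pd.DataFrame(
            {"coef": 0.0, "se": 0.0, "sigma2": [0.0, 0.0], "df_resid": 4.0},
            index=["a", "b"],
        )
        with pytest.raises(DegenerateDataError):
            es.estimate_moderation_prior(
                diffmeth.ProbeFits(table=table, stdev_unscaled=1.0))


class TestModeratedStatistics:
    def _fits(self, sigma2, df, coef=1.0, u=1.0):
        table = pd.DataFrame(
            {"coef": coef, "se": u * np.sqrt(sigma2), "sigma2": sigma2,
             "df_resid": float(df)},
            index=[f"cg{i}" for i in range(np.size(sigma2))],
        )
        return diffmeth.ProbeFits(table=table, stdev_unscaled=u)

    def test_posterior_variance_formula(self):
        fits = self._fits([4.0], df=4)
        out = es.moderate_statistics(fits, es.ModerationPrior(d0=4.0, s0_sq=1.0))
        assert out["s2_post"].iloc[0] == pytest.approx(2.5, abs=1e-12)

    def test_vanishing_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(1)
        s2 = rng.uniform(0.5, 2.0, 10)
        fits = self._fits(s2, df=8, coef=0.7)
        out = es.moderate_statistics(fits, es.ModerationPrior(d0=1e-9, s0_sq=1.0))
        t_ols = 0.7 / np.sqrt(s2)
        assert np.abs(out["t"].to_numpy() - t_ols).max() < 1e-6
        p_ols = 2 * stats.t.sf(np.abs(t_ols), 8)
        assert np.abs(out["p"].to_numpy() - p_ols).max() < 1e-6

    def test_infinite_prior_df_uses_prior_variance_exactly(self):
        rng = np.random.default_rng(2)
        s2 = rng.uniform(0.5, 2.0, 20)
        coef = rng.normal(size=20)
        table = pd.DataFrame({"coef": coef, "se": np.sqrt(s2), "sigma2": s2,
                              "df_resid": 8.0},
                             index=[f"cg{i}" for i in range(20)])
        fits = diffmeth.ProbeFits(table=table, stdev_unscaled=1.0)
        out = es.moderate_statistics(fits, es.ModerationPrior(np.inf, 2.0))
        assert (out["s2_post"] == 2.0).all()
        order_t = np.argsort(-np.abs(out["t"].to_numpy()))
        order_c = np.argsort(-np.abs(coef))
        assert (order_t == order_c).all()

    @given(
        s2=st.floats(min_value=1e-6, max_value=1e3),
        s0=st.floats(min_value=1e-6, max_value=1e3),
        d0=st.floats(min_value=0.1, max_value=100),
    )
    def test_posterior_variance_is_a_convex_combination(self, s2, s0, d0):
        fits = self._fits([s2], df=6)
        out = es.moderate_statistics(fits, es.ModerationPrior(d0=d0, s0_sq=s0))
        post = out["s2_post"].iloc[0]
        assert min(s0, s2) - 1e-12 <= post <= max(s0, s2) + 1e-12

    def test_null_p_values_are_uniform(self):
        """Moderated p on pure-noise probes passes a KS uniformity check."""
        rng = np.random.default_rng(5)
        n_probes, n_samples = 5000, 20
        m = pd.DataFrame(rng.normal(size=(n_probes, n_samples)),
                         index=[f"cg{i}" for i in range(n_probes)],
                         columns=[f"s{j}" for j in range(n_samples)])
        design = es.build_design(m.columns, [f"s{j}" for j in range(10)])
        fits = es.fit_probe_models(m, design)
        prior = es.estimate_moderation_prior(fits)
        out = es.moderate_statistics(fits, prior)
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


class TestDeltaBetaAndAuroc:
    def test_delta_beta_arithmetic_null_and_antisymmetry(self):
        beta = _m_frame([[0.8, 0.8, 0.6, 0.6]])
        d = es.compute_delta_beta(beta, ["s0", "s1"], ["s2", "s3"])
        assert d.iloc[0] == pytest.approx(0.2)
        flipped = es.compute_delta_beta(beta, ["s2", "s3"], ["s0", "s1"])
        assert flipped.iloc[0] == pytest.approx(-0.2)
        same = es.compute_delta_beta(beta, ["s0", "s1"], ["s0", "s1"])
        assert same.iloc[0] == 0.0
        with pytest.raises(InputError):
            es.compute_delta_beta(beta, [], ["s0"])

    @pytest.mark.parametrize(
        "case, control, expected",
        [
            ([3, 4, 5], [0, 1, 2], 1.0),
            ([1, 1], [1, 1], 0.5),
            ([3, 1], [2, 0], 0.75),
        ],
    )
    def test_known_auroc_values(self, case, control, expected):
        values = np.array(case + control, float)
        labels = np.array([True] * len(case) + [False] * len(control))
        assert es.compute_auroc(values, labels) == pytest.approx(expected)

    @given(
        case=st.lists(st.integers(-5, 5), min_size=1, max_size=6),
        control=st.lists(st.integers(-5, 5), min_size=1, max_size=6),
    )
    def test_auroc_equals_brute_force_pair_counting(self, case, control):
        values = np.array(case + control, float)
        labels = np.array([True] * len(case) + [False] * len(control))
        pairs = [
            1.0 if c > k else (0.5 if c == k else 0.0)
            for c in case for k in control
        ]
        assert es.compute_auroc(values, labels) == pytest.approx(np.mean(pairs))

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=12))
    def test_auroc_negation_duality(self, values):
        v = np.asarray(values)
        labels = np.zeros(len(v), bool)
        labels[: len(v) // 2] = True
        a = es.compute_auroc(v, labels)
        b = es.compute_auroc(-v, labels)
        assert a == pytest.approx(1.0 - b)

    def test_one_class_absent_rejected(self):
        with pytest.raises(InputError):
            es.compute_auroc([1.0, 2.0], [True, True])


class TestDmpTable:
    def test_table_contract_on_synthetic_run(self, run):
        dmp = run.dmp
        assert ((dmp["auroc"] >= 0) & (dmp["auroc"] <= 1)).all()
        assert ((dmp["p"] > 0) & (dmp["p"] <= 1)).all()
        assert (dmp["rank_score"] >= 0).all()
        # planted probes dominate the significance landscape
        planted = dmp.loc[dmp.index.intersection(
            run.combined.truth.signature_probe_ids)]
        rest = dmp.drop(planted.index)
        assert planted["rank_score"].median() > rest["rank_score"].quantile(0.999)

    def test_rank_score_monotone_in_delta_beta_at_fixed_p(self):
        dmp = pd.DataFrame(
            {"delta_beta": [0.1, 0.3], "p": [1e-4, 1e-4]},
            index=["a", "b"],
        )
        score = dmp["delta_beta"].abs() * (-np.log10(dmp["p"]))
        assert score["b"] > score["a"]

    def test_sample_order_invariance(self, small_config):
        cohort = es.generate_cohort(small_config)
        beta, _ = es.filter_probes(cohort.beta, cohort.detp, cohort.manifest)
        m = es.beta_to_m(beta)
        cases = sorted(cohort.samples.index[cohort.samples["group"] == "case"])
        controls = sorted(cohort.samples.index[cohort.samples["group"] == "control"])
        t1 = es.dmp_table(beta, m, cases, controls)
        shuffled = beta[beta.columns[::-1]]
        t2 = es.dmp_table(shuffled, m[m.columns[::-1]], cases, controls)
        pd.testing.assert_frame_equal(t1, t2, check_exact=False, atol=1e-10)
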