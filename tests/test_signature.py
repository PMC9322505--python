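"""Matched-control selection, three-step selection, Ward/MDS/LOOCV."""

import numpy as np
import pandas as pd
import pytest

import episig as es
from episig import signature as sigmod
from episig.errors import InputError, ParameterError


def _pool(rows):
    return pd.DataFrame(rows).set_index("sample_id")


class TestMatchedControls:
    def _cases(self):
        return _pool([
            {"sample_id": "case_1", "age": 10.0, "sex": "F", "array_type": "EPIC"},
            {"sample_id": "case_2", "age": 30.0, "sex": "M", "array_type": "EPIC"},
        ])

    def test_exact_clones_are_selected(self):
        cases = self._cases()
        rows = []
        for i, (_, c) in enumerate(cases.iterrows()):
            for j in range(3):
                rows.append({"sample_id": f"clone_{i}{j}", "age": c["age"],
                             "sex": c["sex"], "array_type": c["array_type"]})
        # distractors with wrong sex/age
        for k in range(6):
            rows.append({"sample_id": f"far_{k}", "age": 45.0 + k,
                         "sex": "M" if k % 2 else "F", "array_type": "450k"})
        chosen = es.select_matched_controls(cases, _pool(rows), ratio=3)
        assert sorted(chosen) == sorted(r["sample_id"] for r in rows[:6])

    def test_default_discovery_design_selects_56(self, run):
        assert len(run.control_ids) == 56
        assert len(set(run.control_ids)) == 56

    def test_pool_order_does_not_change_selection(self):
        cases = self._cases()
        rng = np.random.default_rng(0)
        rows = [
            {"sample_id": f"p{k:02d}", "age": float(rng.uniform(2, 50)),
             "sex": "F" if rng.random() < 0.5 else "M",
             "array_type": "EPIC" if rng.random() < 0.8 else "450k"}
            for k in range(20)
        ]
        pool = _pool(rows)
        a = es.select_matched_controls(cases, pool, ratio=4)
        b = es.select_matched_controls(cases, pool.iloc[::-1], ratio=4)
        assert a == b

    def test_insufficient_pool_reports_counts(self):
        with pytest.raises(InputError, match="need 6"):
            es.select_matched_controls(self._cases(), self._cases(), ratio=3)


class TestSelectFeatures:
    def test_planted_duplicates_are_pruned_idempotently(self):
        """40 exact copies of stronger probes are dropped; 210 survive."""
        rng = np.random.default_rng(1)
        n, n_case, n_ctrl = 250, 8, 56
        samples = [f"c{j}" for j in range(n_case)] + [f"k{j}" for j in range(n_ctrl)]
        base = rng.uniform(0.1, 0.9, (n, n_case + n_ctrl))
        probes = [f"cg{i:04d}" for i in range(n)]
        beta = pd.DataFrame(base, index=probes, columns=samples)
        # probes 210..249 duplicate probes 0..39 exactly (r = 1 in any group)
        beta.iloc[210:250] = beta.iloc[0:40].to_numpy()
        dmp = pd.DataFrame(
            {
                "delta_beta": 0.2,
                "p": 1e-6,
                "auroc": np.linspace(1.0, 0.6, n),  # rank = index order
                "rank_score": np.linspace(10.0, 1.0, n),
            },
            index=probes,
        )
        params = es.SelectionParams(n_rank=250, n_auroc=250)
        sig = es.select_features(dmp, beta, samples[:n_case], samples[n_case:],
                                 params)
        assert len(sig) == 210
        assert not set(probes[210:]) & set(sig.probe_ids)
        # brute force: no retained pair correlated > 0.9 in both groups
        kept_case = beta.loc[sig.probe_ids, samples[:n_case]].T.corr().to_numpy()
        kept_ctrl = beta.loc[sig.probe_ids, samples[n_case:]].T.corr().to_numpy()
        both = (kept_case > 0.9) & (kept_ctrl > 0.9)
        np.fill_diagonal(both, False)
        assert not both.any()
        # idempotence: selecting again from the survivors changes nothing
        sig2 = es.select_features(
            dmp.loc[sig.probe_ids], beta.loc[sig.probe_ids],
            samples[:n_case], samples[n_case:], params,
        )
        assert sig2.probe_ids == sig.probe_ids

    def test_step_counts_recorded(self, run):
        counts = run.signature.provenance["step_counts"]
        assert counts["step1_rank"] == 1000
        assert counts["step2_auroc"] == 250
        assert counts["step3_pruned"] == len(run.signature)

    def test_raising_corr_threshold_never_shrinks_signature(self, run):
        sizes = []
        for thr in (0.6, 0.8, 0.95):
            params = es.SelectionParams(corr_threshold=thr)
            sig = es.select_features(run.dmp, run.beta, run.case_ids,
                                     run.control_ids, params)
            sizes.append(len(sig))
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_small_probe_set_keeps_all_with_warning(self):
        rng = np.random.default_rng(2)
        probes = [f"cg{i}" for i in range(20)]
        samples = [f"c{j}" for j in range(4)] + [f"k{j}" for j in range(4)]
        beta = pd.DataFrame(rng.uniform(size=(20, 8)), index=probes,
                            columns=samples)
        dmp = pd.DataFrame(
            {"delta_beta": 0.1, "p": 0.01, "auroc": 0.9, "rank_score": 1.0},
            index=probes,
        )
        sig = es.select_features(dmp, beta, samples[:4], samples[4:])
        assert sig.warnings and "20 probes" in sig.warnings[0]

    def test_directions_match_delta_beta_sign(self, run):
        delta = run.dmp.loc[run.signature.probe_ids, "delta_beta"]
        assert (run.signature.directions == np.where(delta >= 0, 1, -1)).all()

    def test_json_round_trip(self, run, tmp_path):
        path = tmp_path / "sig.json"
        run.signature.to_json(path)
        loaded = es.Episignature.from_json(path)
        assert loaded.probe_ids == run.signature.probe_ids
        assert loaded.params == run.signature.params
        assert (loaded.directions == run.signature.directions).all()


class TestWardCluster:
    def test_identical_samples_merge_at_height_zero(self):
        x = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        res = es.ward_cluster(x)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_two_cluster_cut_recovers_groups(self, run):
        ids = run.case_ids + run.control_ids
        x = run.beta.loc[run.signature.probe_ids, ids].T
        res = es.ward_cluster(x)
        case_labels = set(res.labels[run.case_ids])
        ctrl_labels = set(res.labels[run.control_ids])
        assert len(case_labels) == 1 and len(ctrl_labels) == 1
        assert case_labels != ctrl_labels

    def test_assignment_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(
            np.vstack([rng.normal(0, 1, (5, 4)), rng.normal(6, 1, (5, 4))]),
            index=[f"s{j}" for j in range(10)],
        )
        a = es.ward_cluster(x).labels
        b = es.ward_cluster(x.iloc[::-1]).labels.loc[a.index]
        # identical partition up to label swap
        agree = (a == b).all() or (a == (3 - b)).all()
        assert agree

    def test_linkage_heights_are_monotone(self, run):
        ids = run.case_ids + run.control_ids
        x = run.beta.loc[run.signature.probe_ids, ids].T
        heights = es.ward_cluster(x).linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestMdsEmbed:
    def test_planar_triangle_distances_preserved(self):
        # right triangle with side lengths 3, 4, 5 lives in the plane
        x = pd.DataFrame([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]],
                         index=["a", "b", "c"])
        coords = es.mds_embed(x)
        from scipy.spatial.distance import pdist
        d = sorted(pdist(coords.to_numpy()))
        assert np.abs(np.array(d) - np.array([3.0, 4.0, 5.0])).max() < 1e-8

    def test_identical_samples_embed_at_origin(self):
        x = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        with pytest.warns(UserWarning):
            coords = es.mds_embed(x)
        assert np.abs(coords.to_numpy()).max() == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(6, 5)))
        a = es.mds_embed(x)
        b = es.mds_embed(x + 7.5)
        # same up to rotation/reflection: compare distance matrices
        from scipy.spatial.distance import pdist
        assert np.abs(pdist(a.to_numpy()) - pdist(b.to_numpy())).max() < 1e-8

    def test_needs_three_samples(self):
        with pytest.raises(InputError):
            es.mds_embed(pd.DataFrame(np.ones((2, 3))))

    def test_ward_cut_agrees_with_first_mds_axis(self, run):
        ids = run.case_ids + run.control_ids
        x = run.beta.loc[run.signature.probe_ids, ids].T
        labels = es.ward_cluster(x).labels
        axis1 = es.mds_embed(x)["MDS1"]
        side = (axis1 > 0).map({True: 1, False: 2})
        agree = (labels == side).all() or (labels == (3 - side)).all()
        assert agree


class TestLoocv:
    def test_eight_rounds_all_assigned_to_case_centroid(self, run):
        folds = es.loocv(run.beta, run.m, run.case_ids, run.control_ids,
                         run.covariates)
        assert len(folds) == len(run.case_ids) == 8
        assert all(not f.failed for f in folds)
        assert all(f.assigned == "case" for f in folds)

    def test_null_cohort_misassigns_at_least_once_over_seeds(self):
        """Without any planted effect, held-out assignment is chance-level."""
        misassigned = 0
        for seed in range(10):
            cfg = es.CohortConfig(
                n_probes=4000, effect_logit=0.0, n_control_pool=0,
                n_other_disorders=1, n_signature_probes=150,
                n_vus_like=0, seed=seed,
            )
            cohort = es.generate_cohort(cfg)
            beta, _ = es.filter_probes(cohort.beta, cohort.detp, cohort.manifest)
            m = es.beta_to_m(beta)
            cases = sorted(cohort.samples.index[cohort.samples["group"] == "case"])
            controls = sorted(
                cohort.samples.index[cohort.samples["group"] == "control"])
            folds = es.loocv(beta, m, cases, controls)
            misassigned += sum(f.assigned != "case" for f in folds)
        assert misassigned >= 1

    def test_too_few_cases_rejected(self, run):
        with pytest.raises(InputError):
            es.loocv(run.beta, run.m, run.case_ids[:2], run.control_ids)


def test_selection_params_validation():
    with pytest.raises(ParameterError):
        es.SelectionParams(n_rank=100, n_auroc=200)
    with pytest.raises(ParameterError):
        es.SelectionParams(corr_threshold=1.2)
    with pytest.raises(ParameterError):
        es.SelectionParams(redundancy_mode="sometimes")


def test_step2_survivors_are_mostly_planted(run):
    """>= 90% of the 250 AUROC survivors come from the planted signature."""
    params = es.SelectionParams(corr_threshold=0.999999)  # disable step 3
    sig = es.select_features(run.dmp, run.beta, run.case_ids, run.control_ids,
                             params)
    planted = set(run.combined.truth.signature_probe_ids)
    frac = np.mean([p in planted for p in sig.probe_ids])
    assert len(sig) == 250
    assert frac >= 0.90
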