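"""End-to-end discovery orchestration with provenance tracking.

:func:`run_discovery` chains the stages — simulate (or load) -> probe QC
-> cell-type deconvolution -> differential methylation -> three-step
selection -> unsupervised validation (Ward, MDS, leave-one-out) -> SVM
training and MVP scoring -> region analysis — writing every artifact as a
plain-text file plus a manifest JSON with content hashes. The same config
and seed reproduce identical hashes. A stage failure raises
:class:`~episig.errors.StageError` naming the stage; files being written
by the failing stage keep a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classifier, diffmeth, io, regions, signature, simulate
from .errors import ConfigError, StageError
from .preprocess import beta_to_m, filter_probes, pca_outlier_screen
from .deconvolution import estimate_proportions

log = logging.getLogger("episig")


@dataclass
class PipelineConfig:
    """Everything :func:`run_discovery` needs, YAML-loadable.

    Either ``inputs`` names the five input files (beta, detp, manifest,
    samples, reference) or ``cohort`` gives :class:`~episig.simulate.
    CohortConfig` fields and the cohort is simulated in-run.
    """

    out_dir: str = "episig_out"
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)  # train_fraction, C
    dmr: dict = field(default_factory=dict)  # min_cpgs, window, min_delta, alpha
    control_ratio: int = 7
    exclude_outliers: bool = False
    detp_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**obj)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.inputs:
            required = {"beta", "detp", "manifest", "samples", "reference"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs missing required paths: {sorted(missing)}")
            for key in sorted(required):
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"inputs.{key}: no such file {self.inputs[key]}")
        if not 0 < self.detp_alpha < 1:
            raise ConfigError("detp_alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        # hash the scientific configuration; the output location is not part
        # of what the run computes
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_discovery(config: PipelineConfig) -> dict:
    """Execute the full discovery pipeline; returns the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {
        "tool": "episig",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    for p in out.glob("*.writing"):
                        p.rename(p.with_suffix(".partial"))
                    raise StageError(name, exc) from exc
                log.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _Stage()

    def emit(name: str, writer, *args, **kwargs) -> Path:
        final = out / name
        tmp = final.with_suffix(final.suffix + ".writing")
        writer(tmp, *args, **kwargs)
        tmp.rename(final)
        artifacts[name] = final
        return final

    with stage("simulate"):
        if config.inputs:
            beta = io.read_matrix_tsv(config.inputs["beta"])
            detp = io.read_matrix_tsv(config.inputs["detp"])
            manifest = io.read_manifest_tsv(config.inputs["manifest"])
            samples = io.read_sample_sheet_csv(config.inputs["samples"])
            reference = io.read_reference_tsv(config.inputs["reference"])
            truth = None
        else:
            cc = simulate.CohortConfig(seed=config.seed, **config.cohort)
            cohort = simulate.combine_cohorts(
                simulate.generate_cohort(cc),
                simulate.generate_control_pool(cc),
                simulate.generate_confounder_cohorts(cc),
            )
            beta, detp = cohort.beta, cohort.detp
            manifest, samples = cohort.manifest, cohort.samples
            reference, truth = cohort.reference, cohort.truth
        emit("samples.csv", lambda p: io.write_table(samples, p, "sample_id", ","))

    with stage("qc"):
        beta_f, qc = filter_probes(beta, detp, manifest, config.detp_alpha)
        m = beta_to_m(beta_f)
        qc.outlier_sample_ids = pca_outlier_screen(m)
        if config.exclude_outliers and qc.outlier_sample_ids:
            keep = [s for s in beta_f.columns if s not in qc.outlier_sample_ids]
            beta_f, m = beta_f[keep], m[keep]
            samples = samples.loc[keep]
        emit(
            "qc_report.json",
            lambda p: io.write_json(
                {
                    "n_input_probes": qc.n_input_probes,
                    "n_retained": qc.n_retained,
                    "n_removed_by_reason": qc.n_removed_by_reason,
                    "outlier_sample_ids": qc.outlier_sample_ids,
                },
                p,
                prov,
            ),
        )

    with stage("deconv"):
        ref_probes = reference.index.intersection(beta_f.index)
        props = estimate_proportions(beta_f, reference.loc[ref_probes])
        emit("cell_proportions.csv",
             lambda p: io.write_table(props, p, "sample_id", ",", prov))

    with stage("matching"):
        case_ids = sorted(samples.index[samples["group"] == "case"])
        pool = samples[samples["group"] == "control"]
        control_ids = signature.select_matched_controls(
            samples.loc[case_ids], pool, ratio=config.control_ratio
        )

    with stage("dmp"):
        covars = diffmeth.celltype_covariates(props)
        dmp = diffmeth.dmp_table(beta_f, m, case_ids, control_ids, covars)
        emit("dmp.tsv", lambda p: io.write_table(dmp, p, "probe_id", "\t", prov))

    with stage("select"):
        params = signature.SelectionParams(**config.selection)
        sig = signature.select_features(
            dmp, beta_f, case_ids, control_ids, params,
            provenance=prov | {"n_cases": len(case_ids)},
        )
        emit("episignature.json", lambda p: sig.to_json(p))

    with stage("validate"):
        cohort_ids = case_ids + control_ids
        x = beta_f.loc[sig.probe_ids, cohort_ids].T
        cluster = signature.ward_cluster(x)
        coords = signature.mds_embed(x)
        folds = signature.loocv(beta_f, m, case_ids, control_ids, covars, params)
        validation = signature.ValidationResult(
            cluster=cluster, mds=coords,
            stress=signature.mds_stress(x, coords), folds=folds,
        )
        emit("mds.tsv", lambda p: io.write_table(coords, p, "sample_id", "\t", prov))
        emit(
            "loocv.tsv",
            lambda p: io.write_table(
                validation.fold_table.set_index("held_out_id"), p,
                "held_out_id", "\t", prov,
            ),
        )

    with stage("train"):
        other_controls = [
            s for s in samples.index[samples["group"] == "control"]
            if s not in set(control_ids)
        ]
        disorder_ids = list(samples.index[samples["group"] == "other_disorder"])
        plan = classifier.TrainingPlan(
            case_ids=tuple(case_ids),
            matched_control_ids=tuple(control_ids),
            other_control_ids=tuple(other_controls),
            other_disorder_ids=tuple(disorder_ids),
            disorder_of=samples.loc[disorder_ids, "disorder"].to_dict(),
            train_fraction=config.training.get("train_fraction", 0.75),
            split_seed=config.seed,
        )
        model = classifier.train_classifier(
            beta_f, sig, plan, C=config.training.get("C", 1.0)
        )
        emit("model.json", lambda p: model.to_json(p))

    with stage("score"):
        scores = classifier.score_samples(model, beta_f)
        scores["group"] = samples.loc[scores.index, "group"]
        emit("mvp_scores.tsv",
             lambda p: io.write_table(scores, p, "sample_id", "\t", prov))

    with stage("dmr"):
        dmrs = regions.find_dmrs(dmp, manifest, **config.dmr)
        sig_regions = regions.find_signature_regions(sig, dmp, manifest)
        emit("dmrs.tsv", lambda p: io.write_table(
            regions.dmrs_to_frame(dmrs), p, "index", "\t", prov))
        emit("signature_regions.bed", lambda p: regions.write_bed(sig_regions, p))

    manifest_obj = {
        "provenance": prov,
        "timings_s": timings,
        "artifacts": {
            name: {"path": str(p), "sha256": io.sha256_of(p)}
            for name, p in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest_obj, indent=1))
    return manifest_obj
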