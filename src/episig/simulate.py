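"""Synthetic EPIC-style methylation cohorts for episignature analysis.

The generator emulates the statistical structure an episignature study rests
on: a small case cohort against matched controls, a planted set of
differentially methylated probes, reference-based cell-type composition,
batch structure, detection failures, flagged probes, signature-free
``test`` samples (VUS analogues), and confounder cohorts from other
disorders with their own (disjoint) planted probe sets.

All randomness flows from ``CohortConfig.seed`` through independent named
streams, so the "world" (probe manifest, baseline methylation, cell-type
reference, planted probe sets, batch offsets) is shared by every cohort
generated from the same config: cases, control pool and confounders live on
the same array and can be scored by one classifier.

Per-sample beta values are composed as

    beta = clamp(expit(logit(R w) + batch + s * effect + noise))

where ``R`` is the cell-type reference (beta scale), ``w`` the Dirichlet
cell proportions, ``s`` a per-probe random sign at planted probes (cases
only), and noise is Gaussian on the logit scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError

CELL_TYPES = ("CD4T", "CD8T", "NK", "monocytes", "granulocytes", "Bcells")

# typical adult whole-blood composition, granulocyte-dominated
_BLOOD_MEANS = np.array([0.15, 0.10, 0.05, 0.08, 0.55, 0.07])
_DIRICHLET_CONC = 30.0  # concentration: realistic inter-individual spread

_BETA_CLAMP = 1e-6


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic world and the cohorts drawn from it.

    Counts mirror the discovery design: ``n_cases`` cases with
    ``control_ratio`` matched controls each, ``n_vus_like`` signature-free
    test samples, a matching/negative pool of ``n_control_pool`` extra
    controls, and ``n_other_disorders`` confounder cohorts with
    ``samples_per_disorder`` samples and disjoint planted probe sets.
    """

    n_probes: int = 20_000
    n_cases: int = 8
    control_ratio: int = 7
    n_signature_probes: int = 300
    effect_logit: float = 1.5
    noise_sd: float = 0.3
    n_celltypes: int = 6
    batch_count: int = 3
    n_vus_like: int = 3
    n_other_disorders: int = 10
    samples_per_disorder: int = 8
    n_control_pool: int = 200
    seed: int = 0
    # nuisance structure
    frac_allosomal: float = 0.02
    frac_snp: float = 0.02
    frac_crossreactive: float = 0.01
    detp_fail_rate: float = 5e-4
    batch_sd: float = 0.1
    baseline_sd: float = 0.5
    celltype_sd: float = 1.5
    n_reference_probes: int = 600

    def __post_init__(self) -> None:
        for name in (
            "n_probes", "n_cases", "control_ratio", "n_signature_probes",
            "n_celltypes", "batch_count", "n_vus_like", "n_other_disorders",
            "samples_per_disorder", "n_control_pool", "n_reference_probes",
        ):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_signature_probes >= self.n_probes:
            raise ConfigError("n_signature_probes must be < n_probes")
        if self.effect_logit < 0:
            raise ConfigError("effect_logit must be >= 0")
        if self.control_ratio < 1:
            raise ConfigError("control_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_celltypes < 1 or self.n_celltypes > len(CELL_TYPES):
            raise ConfigError(
                f"n_celltypes must be in [1, {len(CELL_TYPES)}], got {self.n_celltypes}"
            )
        if not 0 <= self.detp_fail_rate < 1:
            raise ConfigError("detp_fail_rate must be in [0, 1)")
        if self.batch_count < 1:
            raise ConfigError("batch_count must be >= 1")


@dataclass
class Truth:
    """Ground truth recorded at generation time, for validation only."""

    signature_probe_ids: list[str]
    delta_direction: pd.Series  # +1 hyper / -1 hypo in cases, signature probes
    cell_proportions: pd.DataFrame  # samples x cell types
    planted_sets: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """One generated cohort plus the shared world objects it lives on."""

    beta: pd.DataFrame  # probes x samples, values in [0, 1]
    detp: pd.DataFrame  # same shape, detection p-values
    manifest: pd.DataFrame  # probe_id index; chromosome, position, flags
    samples: pd.DataFrame  # sample_id index; group, disorder, age, sex, batch, array_type
    reference: pd.DataFrame  # reference probes x cell types, mean beta
    truth: Truth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the cohort as plain-text files; returns {name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "beta": out / "beta.tsv",
            "detp": out / "detp.tsv",
            "manifest": out / "manifest.tsv",
            "samples": out / "samples.csv",
            "reference": out / "reference.tsv",
            "truth": out / "truth.json",
        }
        self.beta.to_csv(paths["beta"], sep="\t", index_label="probe_id")
        self.detp.to_csv(paths["detp"], sep="\t", index_label="probe_id")
        self.manifest.to_csv(paths["manifest"], sep="\t", index_label="probe_id")
        self.samples.to_csv(paths["samples"], index_label="sample_id")
        self.reference.to_csv(paths["reference"], sep="\t", index_label="probe_id")
        truth_obj = {
            "signature_probe_ids": self.truth.signature_probe_ids,
            "delta_direction": {k: int(v) for k, v in self.truth.delta_direction.items()},
            "cell_proportions": {
                s: [float(x) for x in row]
                for s, row in self.truth.cell_proportions.iterrows()
            },
            "planted_sets": self.truth.planted_sets,
        }
        paths["truth"].write_text(json.dumps(truth_obj, indent=1))
        return paths


class _World:
    """Probe-level state shared by all cohorts drawn from one config."""

    def __init__(self, config: CohortConfig):
        self.config = config
        n = config.n_probes
        rng = np.random.default_rng([config.seed, 101])

        probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
        chrom = rng.integers(1, 23, size=n)
        position = np.empty(n, dtype=np.int64)
        for c in range(1, 23):
            idx = np.flatnonzero(chrom == c)
            gaps = rng.integers(2_000, 20_000, size=idx.size)
            position[idx] = np.cumsum(gaps)

        flags = {}
        u = rng.random(n)
        edges = np.cumsum([config.frac_allosomal, config.frac_snp,
                           config.frac_crossreactive])
        flags["is_allosomal"] = u < edges[0]
        flags["is_snp"] = (u >= edges[0]) & (u < edges[1])
        flags["is_crossreactive"] = (u >= edges[1]) & (u < edges[2])
        clean = u >= edges[2]
        chrom_labels = np.array([f"chr{c}" for c in chrom])
        chrom_labels[flags["is_allosomal"]] = np.where(
            rng.random(int(flags["is_allosomal"].sum())) < 0.5, "chrX", "chrY"
        )

        # bimodal baseline methylation on the logit scale
        comp = rng.random(n) < 0.5
        self.mu = np.where(comp, logit(0.9), logit(0.1)) + rng.normal(
            0.0, config.baseline_sd, size=n
        )

        # cell-type reference: strong deviations on a dedicated informative
        # subset (what a deconvolution panel selects for), mild elsewhere
        T = config.n_celltypes
        dev = rng.normal(0.0, 0.2, size=(n, T))
        clean_idx = np.flatnonzero(clean)
        n_ref = min(config.n_reference_probes, clean_idx.size)
        ref_idx = rng.choice(clean_idx, size=n_ref, replace=False)
        dev[ref_idx] = rng.normal(0.0, config.celltype_sd, size=(n_ref, T))
        self.ref_beta = expit(self.mu[:, None] + dev)
        self.reference_probe_idx = np.sort(ref_idx)

        # planted probe sets: main signature + one disjoint set per disorder
        eligible = np.setdiff1d(clean_idx, ref_idx)
        n_sets = 1 + config.n_other_disorders
        need = n_sets * config.n_signature_probes
        if need > eligible.size:
            raise ConfigError(
                "n_signature_probes: cannot plant "
                f"{n_sets} disjoint sets of {config.n_signature_probes} probes "
                f"in {eligible.size} eligible probes"
            )
        drawn = rng.choice(eligible, size=need, replace=False)
        sets = drawn.reshape(n_sets, config.n_signature_probes)
        self.signature_idx = np.sort(sets[0])
        self.disorder_idx = {
            f"other_{d + 1:02d}": np.sort(sets[d + 1])
            for d in range(config.n_other_disorders)
        }
        self.signs = {
            name: rng.choice([-1.0, 1.0], size=config.n_signature_probes)
            for name in ["target", *self.disorder_idx]
        }

        # relocate a few signature probes into tight genomic clusters so the
        # region-level analysis has true positives to find
        n_clusters = min(5, config.n_signature_probes // 3)
        for k in range(n_clusters):
            trio = self.signature_idx[3 * k: 3 * k + 3]
            chrom_labels[trio] = f"chr{k + 1}"
            position[trio] = 500_000_000 + 100_000 * k + 400 * np.arange(3)
            # clustered probes shift coherently, as in a real DMR
            self.signs["target"][3 * k: 3 * k + 3] = self.signs["target"][3 * k]

        self.batch_offsets = rng.normal(
            0.0, config.batch_sd, size=(config.batch_count, n)
        )
        self.manifest = pd.DataFrame(
            {
                "chromosome": chrom_labels,
                "position": position,
                "is_allosomal": flags["is_allosomal"],
                "is_snp": flags["is_snp"],
                "is_crossreactive": flags["is_crossreactive"],
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
        self.probe_ids = probe_ids

    @property
    def reference(self) -> pd.DataFrame:
        cols = list(CELL_TYPES[: self.config.n_celltypes])
        return pd.DataFrame(
            self.ref_beta[self.reference_probe_idx],
            index=pd.Index(self.probe_ids[self.reference_probe_idx], name="probe_id"),
            columns=cols,
        )


def _draw_samples(
    world: _World,
    rng: np.random.Generator,
    meta: pd.DataFrame,
    effect_of: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw beta/detp for the samples in ``meta``; returns (beta, detp, props).

    ``effect_of`` maps sample_id -> planted-set name ("target" or a
    disorder label); absent samples carry no effect.
    """
    cfg = world.config
    n, T = cfg.n_probes, cfg.n_celltypes
    alpha = _BLOOD_MEANS[:T] / _BLOOD_MEANS[:T].sum() * _DIRICHLET_CONC
    props = rng.dirichlet(alpha, size=len(meta))
    beta = np.empty((n, len(meta)))
    for j, (sid, row) in enumerate(meta.iterrows()):
        mean_beta = world.ref_beta @ props[j]
        x = logit(np.clip(mean_beta, _BETA_CLAMP, 1 - _BETA_CLAMP))
        x = x + world.batch_offsets[int(row["batch"])]
        set_name = effect_of.get(sid)
        if set_name is not None and cfg.effect_logit > 0:
            idx = (
                world.signature_idx
                if set_name == "target"
                else world.disorder_idx[set_name]
            )
            x[idx] += cfg.effect_logit * world.signs[set_name]
        x = x + rng.normal(0.0, cfg.noise_sd, size=n)
        beta[:, j] = np.clip(expit(x), _BETA_CLAMP, 1 - _BETA_CLAMP)

    detp = rng.uniform(0.0, 0.005, size=beta.shape)
    fail = rng.random(beta.shape) < cfg.detp_fail_rate
    detp[fail] = rng.uniform(0.011, 0.6, size=int(fail.sum()))

    cols = list(CELL_TYPES[:T])
    beta_df = pd.DataFrame(beta, index=world.manifest.index, columns=meta.index)
    detp_df = pd.DataFrame(detp, index=world.manifest.index, columns=meta.index)
    props_df = pd.DataFrame(props, index=meta.index, columns=cols)
    return beta_df, detp_df, props_df


def _case_metadata(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    ages = rng.uniform(2, 40, size=cfg.n_cases).round(1)
    sexes = np.where(rng.random(cfg.n_cases) < 0.46, "F", "M")
    return pd.DataFrame(
        {
            "group": "case",
            "disorder": "target",
            "age": ages,
            "sex": sexes,
            "batch": rng.integers(0, cfg.batch_count, size=cfg.n_cases),
            "array_type": "EPIC",
        },
        index=pd.Index([f"case_{i + 1:02d}" for i in range(cfg.n_cases)],
                       name="sample_id"),
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the discovery cohort: cases, matched controls, test samples.

    Matched controls are drawn with metadata jittered around their case
    (age within ~2 years, same sex and array type), so the cohort is
    matched by construction; ``generate_control_pool`` provides the
    unmatched candidate pool the matching operation selects from.
    Deterministic for a fixed ``config.seed``.
    """
    world = _World(config)
    rng = np.random.default_rng([config.seed, 202])

    cases = _case_metadata(config, rng)
    rows = []
    for i, (_, crow) in enumerate(cases.iterrows()):
        for j in range(config.control_ratio):
            rows.append(
                {
                    "sample_id": f"ctrl_{i * config.control_ratio + j + 1:03d}",
                    "group": "control",
                    "disorder": "",
                    "age": round(float(np.clip(crow["age"] + rng.normal(0, 2), 2, 50)), 1),
                    "sex": crow["sex"],
                    "batch": int(rng.integers(0, config.batch_count)),
                    "array_type": crow["array_type"],
                }
            )
    for k in range(config.n_vus_like):
        rows.append(
            {
                "sample_id": f"vus_{k + 1:02d}",
                "group": "test",
                "disorder": "",
                "age": round(float(rng.uniform(2, 40)), 1),
                "sex": "F" if rng.random() < 0.46 else "M",
                "batch": int(rng.integers(0, config.batch_count)),
                "array_type": "EPIC",
            }
        )
    others = pd.DataFrame(rows).set_index("sample_id")
    meta = pd.concat([cases, others])

    effect_of = {sid: "target" for sid in cases.index}
    beta, detp, props = _draw_samples(world, rng, meta, effect_of)
    truth = Truth(
        signature_probe_ids=list(world.probe_ids[world.signature_idx]),
        delta_direction=pd.Series(
            world.signs["target"].astype(int),
            index=world.probe_ids[world.signature_idx],
        ),
        cell_proportions=props,
        planted_sets={"target": list(world.probe_ids[world.signature_idx])},
    )
    return SyntheticCohort(beta, detp, world.manifest, meta, world.reference, truth)


def generate_control_pool(config: CohortConfig) -> SyntheticCohort:
    """Generate ``config.n_control_pool`` unmatched healthy controls.

    Demographics follow the reference-database control population: ages
    2-50 years, ~46% female, mixed array types. Used as the candidate pool
    for matched-control selection and as "other controls" in classifier
    training.
    """
    world = _World(config)
    rng = np.random.default_rng([config.seed, 303])
    m = config.n_control_pool
    meta = pd.DataFrame(
        {
            "group": "control",
            "disorder": "",
            "age": rng.uniform(2, 50, size=m).round(1),
            "sex": np.where(rng.random(m) < 0.46, "F", "M"),
            "batch": rng.integers(0, config.batch_count, size=m),
            "array_type": np.where(rng.random(m) < 0.8, "EPIC", "450k"),
        },
        index=pd.Index([f"pool_{i + 1:04d}" for i in range(m)], name="sample_id"),
    )
    beta, detp, props = _draw_samples(world, rng, meta, {})
    truth = Truth(
        signature_probe_ids=list(world.probe_ids[world.signature_idx]),
        delta_direction=pd.Series(
            world.signs["target"].astype(int),
            index=world.probe_ids[world.signature_idx],
        ),
        cell_proportions=props,
    )
    return SyntheticCohort(beta, detp, world.manifest, meta, world.reference, truth)


def generate_confounder_cohorts(config: CohortConfig) -> SyntheticCohort:
    """Generate confounder cohorts: other disorders with disjoint signatures.

    Each of the ``config.n_other_disorders`` disorders carries its own
    planted probe set, disjoint from every other planted set (and from the
    main signature), with ``samples_per_disorder`` affected samples.
    """
    if config.n_other_disorders < 1:
        raise ConfigError("n_other_disorders must be >= 1")
    world = _World(config)
    rng = np.random.default_rng([config.seed, 404])
    rows = []
    for name in world.disorder_idx:
        for k in range(config.samples_per_disorder):
            rows.append(
                {
                    "sample_id": f"{name}_s{k + 1:02d}",
                    "group": "other_disorder",
                    "disorder": name,
                    "age": round(float(rng.uniform(2, 40)), 1),
                    "sex": "F" if rng.random() < 0.46 else "M",
                    "batch": int(rng.integers(0, config.batch_count)),
                    "array_type": "EPIC",
                }
            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    effect_of = {sid: d for sid, d in meta["disorder"].items()}
    beta, detp, props = _draw_samples(world, rng, meta, effect_of)
    truth = Truth(
        signature_probe_ids=list(world.probe_ids[world.signature_idx]),
        delta_direction=pd.Series(
            world.signs["target"].astype(int),
            index=world.probe_ids[world.signature_idx],
        ),
        cell_proportions=props,
        planted_sets={
            name: list(world.probe_ids[idx])
            for name, idx in world.disorder_idx.items()
        },
    )
    return SyntheticCohort(beta, detp, world.manifest, meta, world.reference, truth)


def combine_cohorts(*cohorts: SyntheticCohort) -> SyntheticCohort:
    """Concatenate cohorts drawn from the same world along the sample axis."""
    first = cohorts[0]
    for c in cohorts[1:]:
        if not first.manifest.index.equals(c.manifest.index):
            raise ConfigError("cohorts to combine must share one probe world")
    beta = pd.concat([c.beta for c in cohorts], axis=1)
    if beta.columns.duplicated().any():
        raise ConfigError("duplicate sample ids across combined cohorts")
    planted: dict[str, list[str]] = {}
    for c in cohorts:
        planted.update(c.truth.planted_sets)
    truth = Truth(
        signature_probe_ids=first.truth.signature_probe_ids,
        delta_direction=first.truth.delta_direction,
        cell_proportions=pd.concat([c.truth.cell_proportions for c in cohorts]),
        planted_sets=planted,
    )
    return SyntheticCohort(
        beta=beta,
        detp=pd.concat([c.detp for c in cohorts], axis=1),
        manifest=first.manifest,
        samples=pd.concat([c.samples for c in cohorts]),
        reference=first.reference,
        truth=truth,
    )


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
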