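"""Episignature construction and unsupervised validation.

The episignature is built by a three-step selection on the per-probe
differential table: (1) keep the ``n_rank`` probes with the highest
|delta-beta| * (-log10 p) score; (2) of those, keep the ``n_auroc`` with
the most discriminative AUROC; (3) walk the survivors from the top and
drop any probe whose beta profile is correlated above ``corr_threshold``
with an already-kept probe within the case group and within the control
group. AUROC discriminability is measured two-sidedly as
max(auroc, 1 - auroc): a hypomethylated probe separates the groups exactly
as well as a hypermethylated one, with the curve flipped.

Validation of the selected probes is unsupervised: Ward/Euclidean
hierarchical clustering, classical (Torgerson) multidimensional scaling,
and a leave-one-case-out cross-validation in which probes are reselected
without the held-out case and the held-out sample is assigned to the
nearer group centroid in MDS space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import diffmeth
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class SelectionParams:
    """Knobs of the three-step selection (defaults are the study protocol)."""

    n_rank: int = 1000
    n_auroc: int = 250
    corr_threshold: float = 0.9
    # discard a correlated probe only when redundant in BOTH groups
    # ("either" is the aggressive alternative reading)
    redundancy_mode: str = "both"
    signed_rank: bool = False

    def __post_init__(self) -> None:
        if self.n_auroc > self.n_rank:
            raise ParameterError("n_auroc must be <= n_rank")
        if not 0 < self.corr_threshold < 1:
            raise ParameterError("corr_threshold must lie in (0, 1)")
        if self.redundancy_mode not in ("both", "either"):
            raise ParameterError("redundancy_mode must be 'both' or 'either'")


@dataclass
class Episignature:
    """The portable artifact: ordered probes, directions, training context."""

    probe_ids: list[str]
    directions: pd.Series  # +1 hypermethylated in cases, -1 hypo
    params: SelectionParams
    case_mean: pd.Series  # reference beta at signature probes
    control_mean: pd.Series
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "probe_ids": self.probe_ids,
            "directions": {k: int(v) for k, v in self.directions.items()},
            "params": {
                "n_rank": self.params.n_rank,
                "n_auroc": self.params.n_auroc,
                "corr_threshold": self.params.corr_threshold,
                "redundancy_mode": self.params.redundancy_mode,
                "signed_rank": self.params.signed_rank,
            },
            "case_mean": {k: float(v) for k, v in self.case_mean.items()},
            "control_mean": {k: float(v) for k, v in self.control_mean.items()},
            "provenance": self.provenance,
            "warnings": self.warnings,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Episignature":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(
            probe_ids=obj["probe_ids"],
            directions=pd.Series(obj["directions"]),
            params=SelectionParams(**obj["params"]),
            case_mean=pd.Series(obj["case_mean"]),
            control_mean=pd.Series(obj["control_mean"]),
            provenance=obj.get("provenance", {}),
            warnings=obj.get("warnings", []),
        )


def select_matched_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 7,
) -> list[str]:
    """Select ``ratio`` matched controls per case from a candidate pool.

    Matching is greedy per case (cases in sample-id order): each case takes
    the unused candidates minimizing |age difference| / age-range
    + 1 per sex mismatch + 1 per array-type mismatch, ties broken by
    candidate id. Deterministic and invariant to pool row order.
    """
    need = ratio * len(cases)
    if len(pool) < need:
        raise InputError(
            f"control pool too small: need {need} ({len(cases)} cases x {ratio}), "
            f"have {len(pool)}"
        )
    ages = np.concatenate([cases["age"].to_numpy(float), pool["age"].to_numpy(float)])
    age_range = float(ages.max() - ages.min()) or 1.0

    available = pool.sort_index()
    selected: list[str] = []
    used: set[str] = set()
    for case_id in sorted(cases.index):
        crow = cases.loc[case_id]
        cand = available.loc[[s for s in available.index if s not in used]]
        cost = (
            (cand["age"].astype(float) - float(crow["age"])).abs() / age_range
            + (cand["sex"] != crow["sex"]).astype(float)
            + (cand["array_type"] != crow["array_type"]).astype(float)
        )
        order = sorted(cand.index, key=lambda s: (cost[s], s))
        take = order[:ratio]
        selected.extend(take)
        used.update(take)
    return selected


def _discriminability(auroc: pd.Series) -> pd.Series:
    return np.maximum(auroc, 1.0 - auroc)


def select_features(
    dmp: pd.DataFrame,
    beta: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    params: SelectionParams = SelectionParams(),
    provenance: dict | None = None,
) -> Episignature:
    """Run the three-step selection and package the episignature.

    ``dmp`` must carry ``rank_score``, ``auroc`` and ``delta_beta`` columns
    for every probe of ``beta`` (as produced by
    :func:`episig.diffmeth.dmp_table`).
    """
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise InputError("both groups must be non-empty")
    missing = beta.index.difference(dmp.index)
    if len(missing) > 0:
        raise InputError(f"dmp table does not cover probes: {list(missing[:5])}")
    notes: list[str] = []
    table = dmp.loc[beta.index]

    if len(table) < params.n_rank:
        notes.append(
            f"only {len(table)} probes available; step 1 keeps all of them"
        )
    # step 1: effect-size x significance ranking (ties broken by probe id)
    order = np.lexsort((table.index, -table["rank_score"].to_numpy()))
    step1 = table.iloc[order].head(params.n_rank)

    # step 2: discriminative AUROC
    disc = _discriminability(step1["auroc"])
    order = np.lexsort((step1.index, -disc.to_numpy()))
    step2 = step1.iloc[order].head(params.n_auroc)

    # step 3: greedy correlation pruning, strongest probe first
    kept = _prune_correlated(
        step2.index, beta, case_ids, control_ids,
        params.corr_threshold, params.redundancy_mode,
    )

    delta = table.loc[kept, "delta_beta"]
    directions = pd.Series(np.where(delta >= 0, 1, -1), index=kept)
    prov = dict(provenance or {})
    prov["step_counts"] = {
        "step1_rank": len(step1),
        "step2_auroc": len(step2),
        "step3_pruned": len(kept),
    }
    return Episignature(
        probe_ids=list(kept),
        directions=directions,
        params=params,
        case_mean=beta.loc[kept, list(case_ids)].mean(axis=1),
        control_mean=beta.loc[kept, list(control_ids)].mean(axis=1),
        provenance=prov,
        warnings=notes,
    )


def _prune_correlated(
    probes: pd.Index,
    beta: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    threshold: float,
    mode: str,
) -> pd.Index:
    """Drop probes correlated above threshold with a higher-ranked survivor."""
    x_case = beta.loc[probes, list(case_ids)].to_numpy(float)
    x_ctrl = beta.loc[probes, list(control_ids)].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_case = np.corrcoef(x_case)
        r_ctrl = np.corrcoef(x_ctrl)
    # constant probes yield NaN correlation: treat as not redundant
    r_case = np.nan_to_num(r_case, nan=0.0)
    r_ctrl = np.nan_to_num(r_ctrl, nan=0.0)

    kept: list[int] = []
    for i in range(len(probes)):
        if mode == "both":
            redundant = any(
                r_case[i, j] > threshold and r_ctrl[i, j] > threshold for j in kept
            )
        else:
            redundant = any(
                r_case[i, j] > threshold or r_ctrl[i, j] > threshold for j in kept
            )
        if not redundant:
            kept.append(i)
    return probes[kept]


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge tree with heights)
    labels: pd.Series  # two-cluster assignment, values in {1, 2}


def ward_cluster(x: pd.DataFrame) -> ClusterResult:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    ``x`` is samples x features; returns the full merge tree plus the
    two-cluster cut.
    """
    if len(x) < 2:
        raise InputError("need >= 2 samples to cluster")
    z = linkage(x.to_numpy(float), method="ward", metric="euclidean")
    labels = fcluster(z, t=2, criterion="maxclust")
    return ClusterResult(linkage=z, labels=pd.Series(labels, index=x.index))


def mds_embed(x: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling to ``n_components`` axes.

    Double-centres the squared Euclidean distance matrix and takes the top
    eigenpairs; coordinates are defined up to rotation/reflection. If fewer
    positive eigenvalues exist than requested, the missing axes are zero
    and a warning is issued.
    """
    if len(x) < 3:
        raise InputError("need >= 3 samples for MDS")
    d2 = squareform(pdist(x.to_numpy(float), metric="euclidean")) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-9 * max(vals.max(), 0.0))
    n_pos = int((vals > tol).sum())
    if n_pos < n_components:
        warnings.warn(
            f"only {n_pos} positive MDS eigenvalues; remaining axes set to 0",
            stacklevel=2,
        )
    coords = np.zeros((n, n_components))
    k = min(n_pos, n_components)
    if k > 0:
        coords[:, :k] = vecs[:, :k] * np.sqrt(vals[:k])
    return pd.DataFrame(
        coords, index=x.index, columns=[f"MDS{i + 1}" for i in range(n_components)]
    )


def mds_stress(x: pd.DataFrame, coords: pd.DataFrame) -> float:
    """Kruskal stress-1 of an embedding against the input distances."""
    d = pdist(x.to_numpy(float))
    dhat = pdist(coords.to_numpy(float))
    denom = float((d**2).sum()) or 1.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


@dataclass
class LoocvFold:
    held_out_id: str
    assigned: str  # "case" or "control"
    dist_case: float
    dist_control: float
    n_probes: int
    failed: bool = False


@dataclass
class ValidationResult:
    """Unsupervised validation bundle for a signature and cohort."""

    cluster: ClusterResult | None = None
    mds: pd.DataFrame | None = None
    stress: float | None = None
    folds: list[LoocvFold] = field(default_factory=list)

    @property
    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "held_out_id": f.held_out_id,
                    "assigned": f.assigned,
                    "dist_case": f.dist_case,
                    "dist_control": f.dist_control,
                    "n_probes": f.n_probes,
                    "failed": f.failed,
                }
                for f in self.folds
            ]
        )


def loocv(
    beta: pd.DataFrame,
    m: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    covariates: pd.DataFrame | None = None,
    params: SelectionParams = SelectionParams(),
) -> list[LoocvFold]:
    """Leave-one-case-out cross-validation of signature reproducibility.

    Each round drops one case, recomputes the differential table and the
    three-step selection on the remaining cases and all controls, embeds
    every sample (held-out included) by MDS on the round's probes, and
    assigns the held-out sample to the nearer of the case/control centroids
    in the 2-D embedding. One fold per case.
    """
    if len(case_ids) < 3:
        raise InputError("need >= 3 cases for leave-one-out validation")
    folds: list[LoocvFold] = []
    for held_out in case_ids:
        train_cases = [c for c in case_ids if c != held_out]
        dmp = diffmeth.dmp_table(
            beta, m, train_cases, list(control_ids),
            covariates=covariates, signed_rank=params.signed_rank,
        )
        sig = select_features(dmp, beta, train_cases, list(control_ids), params)
        if len(sig) == 0:
            folds.append(LoocvFold(held_out, "failed", np.nan, np.nan, 0, True))
            continue
        samples = train_cases + list(control_ids) + [held_out]
        coords = mds_embed(beta.loc[sig.probe_ids, samples].T)
        case_centroid = coords.loc[train_cases].mean(axis=0)
        ctrl_centroid = coords.loc[list(control_ids)].mean(axis=0)
        p = coords.loc[held_out]
        d_case = float(np.linalg.norm(p - case_centroid))
        d_ctrl = float(np.linalg.norm(p - ctrl_centroid))
        folds.append(
            LoocvFold(
                held_out_id=held_out,
                assigned="case" if d_case <= d_ctrl else "control",
                dist_case=d_case,
                dist_control=d_ctrl,
                n_probes=len(sig),
            )
        )
    return folds
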