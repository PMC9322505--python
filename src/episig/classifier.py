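"""Support-vector classification of samples against an episignature.

Features are the beta values at the signature probes, standardized by
training mean/SD. A linear-kernel SVM with balanced class weights
separates cases (positive) from the negative reference set: the matched
controls plus 75% of the other-control pool and 75% of each other-disorder
cohort; the remaining 25% are held out for testing. The raw margin is
mapped to a methylation variant pathogenicity (MVP) score in [0, 1] by
Platt sigmoid calibration fitted on out-of-fold decision values, and class
calls use a 0.5 cut-off.

The trained model is a plain JSON-serializable record (probe order,
scaling, hyperplane, sigmoid), so scoring needs no pickled estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InputError
from .signature import Episignature


@dataclass(frozen=True)
class TrainingPlan:
    """Explicit composition of the training and test sets.

    The pools (other controls, other disorders) are split
    ``train_fraction`` / 1 - ``train_fraction``; cases and matched controls
    always train. Disorder samples are split within each disorder so every
    confounder syndrome appears on both sides.
    """

    case_ids: tuple[str, ...]
    matched_control_ids: tuple[str, ...]
    other_control_ids: tuple[str, ...] = ()
    other_disorder_ids: tuple[str, ...] = ()
    disorder_of: dict = field(default_factory=dict)  # sample id -> disorder label
    train_fraction: float = 0.75
    split_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise InputError("train_fraction must lie in (0, 1)")
        groups = [
            set(self.case_ids), set(self.matched_control_ids),
            set(self.other_control_ids), set(self.other_disorder_ids),
        ]
        seen: set[str] = set()
        for g in groups:
            if g & seen:
                raise InputError(f"sample id sets overlap: {sorted(g & seen)[:5]}")
            seen |= g

    def split(self) -> tuple[list[str], list[str], list[str]]:
        """Return (positives, training negatives, held-out negatives)."""
        rng = np.random.default_rng(self.split_seed)
        train_neg = list(self.matched_control_ids)
        test_neg: list[str] = []

        def split_pool(ids: list[str]) -> None:
            ids = sorted(ids)
            n_train = int(round(self.train_fraction * len(ids)))
            perm = rng.permutation(len(ids))
            train_neg.extend(ids[i] for i in perm[:n_train])
            test_neg.extend(ids[i] for i in perm[n_train:])

        split_pool(list(self.other_control_ids))
        by_disorder: dict[str, list[str]] = {}
        for sid in self.other_disorder_ids:
            by_disorder.setdefault(self.disorder_of.get(sid, "other"), []).append(sid)
        for label in sorted(by_disorder):
            split_pool(by_disorder[label])
        return list(self.case_ids), train_neg, test_neg


@dataclass
class SvmModel:
    """Serialized linear SVM + Platt sigmoid over signature-probe betas."""

    probe_ids: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    provenance: dict = field(default_factory=dict)

    def decision_function(self, beta: pd.DataFrame) -> pd.Series:
        x = _feature_matrix(beta, self.probe_ids)
        z = (x - self.feature_mean) / self.feature_sd
        return pd.Series(z @ self.coef + self.intercept, index=beta.columns)

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "probe_ids": self.probe_ids,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "provenance": self.provenance,
        }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SvmModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(
            probe_ids=obj["probe_ids"],
            feature_mean=np.asarray(obj["feature_mean"], float),
            feature_sd=np.asarray(obj["feature_sd"], float),
            coef=np.asarray(obj["coef"], float),
            intercept=float(obj["intercept"]),
            platt_a=float(obj["platt_a"]),
            platt_b=float(obj["platt_b"]),
            provenance=obj.get("provenance", {}),
        )


def _feature_matrix(beta: pd.DataFrame, probe_ids: list[str]) -> np.ndarray:
    missing = [p for p in probe_ids if p not in beta.index]
    if missing:
        raise InputError(f"signature probes absent from beta matrix: {missing[:10]}")
    return beta.loc[probe_ids].to_numpy(float).T  # samples x probes


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid fit P(y=1|f) = 1 / (1 + exp(a f + b)).

    Uses the prior-corrected targets from Platt's algorithm and minimizes
    the cross-entropy with BFGS; ``a`` comes out negative when larger
    margins mean more case-like.
    """
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def loss(ab):
        # cross-entropy of p = 1/(1+e^z) against targets t, in stable form:
        # -[t log p + (1-t) log(1-p)] = log(1+e^z) - (1-t) z
        z = ab[0] * decision + ab[1]
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    res = minimize(loss, x0=np.array([-1.0, 0.0]), method="BFGS")
    return float(res.x[0]), float(res.x[1])


def train_classifier(
    beta: pd.DataFrame,
    episignature: Episignature,
    plan: TrainingPlan,
    C: float = 1.0,
    n_calibration_folds: int = 5,
) -> SvmModel:
    """Fit the linear SVM and its Platt calibration on the training plan.

    Deterministic for a fixed ``plan.split_seed``. The calibration sigmoid
    is fitted on out-of-fold decision values from a stratified K-fold over
    the training set, then the margin is refitted on all training samples.
    """
    pos_ids, train_neg, _ = plan.split()
    if len(pos_ids) < 2 or len(train_neg) < 2:
        raise InputError("each class needs >= 2 training samples")
    train_ids = list(pos_ids) + list(train_neg)
    missing = [s for s in train_ids if s not in beta.columns]
    if missing:
        raise InputError(f"training samples absent from beta: {missing[:5]}")

    probes = list(episignature.probe_ids)
    x = _feature_matrix(beta[train_ids], probes)
    y = np.array([1] * len(pos_ids) + [0] * len(train_neg))
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd

    svm = SVC(kernel="linear", C=C, class_weight="balanced")
    n_folds = min(n_calibration_folds, int(y.sum()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=plan.split_seed)
    oof = np.empty(len(y))
    for tr, te in cv.split(z, y):
        fold_svm = SVC(kernel="linear", C=C, class_weight="balanced")
        fold_svm.fit(z[tr], y[tr])
        oof[te] = fold_svm.decision_function(z[te])
    a, b = _fit_platt(oof, y)

    svm.fit(z, y)
    return SvmModel(
        probe_ids=probes,
        feature_mean=mean,
        feature_sd=sd,
        coef=svm.coef_.ravel().copy(),
        intercept=float(svm.intercept_[0]),
        platt_a=a,
        platt_b=b,
        provenance={
            "n_pos": len(pos_ids),
            "n_neg": len(train_neg),
            "C": C,
            "split_seed": plan.split_seed,
        },
    )


def score_samples(
    model: SvmModel, beta: pd.DataFrame, cutoff: float = 0.5
) -> pd.DataFrame:
    """MVP scores and class calls for every sample (column) of ``beta``.

    Raises when any signature probe is missing — scores are never computed
    on silently imputed features. Probe order in the input is irrelevant.
    """
    f = model.decision_function(beta)
    score = 1.0 / (1.0 + np.exp(model.platt_a * f + model.platt_b))
    return pd.DataFrame(
        {
            "mvp_score": score,
            "call": score >= cutoff,
            "decision": f,
        },
        index=beta.columns,
    )
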