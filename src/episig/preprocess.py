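"""Probe-level quality control, beta->M transformation, PCA outlier screen."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import InputError, ParameterError

# removal reasons are made disjoint by this precedence, so QC counts add up
REASON_PRECEDENCE = ("allosomal", "snp", "crossreactive", "detection")


@dataclass
class QcReport:
    """Outcome of probe filtering: counts per removal reason and survivors."""

    n_input_probes: int
    n_removed_by_reason: dict[str, int]
    retained_probe_ids: list[str]
    outlier_sample_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained_probe_ids)


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    manifest: pd.DataFrame,
    detp_alpha: float = 0.01,
) -> tuple[pd.DataFrame, QcReport]:
    """Remove allosomal, SNP-overlapping, cross-reactive and detection-failed probes.

    A probe fails detection when its detection p-value exceeds
    ``detp_alpha`` in any sample (strictest aggregation). Each removed
    probe is counted under exactly one reason, with precedence
    allosomal > snp > crossreactive > detection. Retained probe order is
    preserved and values are untouched.
    """
    if beta.shape != detp.shape or not beta.index.equals(detp.index):
        raise InputError("beta and detection-p matrices must share shape and probe ids")
    missing = beta.index.difference(manifest.index)
    if len(missing) > 0:
        raise InputError(f"probes missing from manifest: {list(missing[:5])}")

    man = manifest.loc[beta.index]
    reasons = {
        "allosomal": man["is_allosomal"].to_numpy(bool),
        "snp": man["is_snp"].to_numpy(bool),
        "crossreactive": man["is_crossreactive"].to_numpy(bool),
        "detection": (detp.to_numpy() > detp_alpha).any(axis=1),
    }
    removed = np.zeros(len(beta), dtype=bool)
    counts: dict[str, int] = {}
    for reason in REASON_PRECEDENCE:
        hit = reasons[reason] & ~removed
        counts[reason] = int(hit.sum())
        removed |= hit

    retained = beta.index[~removed]
    report = QcReport(
        n_input_probes=len(beta),
        n_removed_by_reason=counts,
        retained_probe_ids=list(retained),
    )
    return beta.loc[retained], report


def beta_to_m(beta: pd.DataFrame, clamp: float = 1e-6) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)), with beta clamped to [clamp, 1 - clamp].

    The clamp keeps M finite at fully (un)methylated probes; the map is
    strictly increasing on the clamped domain and antisymmetric about
    beta = 0.5.
    """
    if not 0 < clamp < 0.5:
        raise ParameterError(f"clamp must lie in (0, 0.5), got {clamp}")
    b = np.clip(beta.to_numpy(float), clamp, 1 - clamp)
    return pd.DataFrame(np.log2(b / (1 - b)), index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` (up to the clamp)."""
    x = np.exp2(m.to_numpy(float))
    return pd.DataFrame(x / (1 + x), index=m.index, columns=m.columns)


def pca_outlier_screen(
    m: pd.DataFrame,
    n_components: int = 2,
    sd_threshold: float = 3.0,
) -> list[str]:
    """Flag samples extreme on any leading principal component.

    Samples (columns of ``m``) are projected on the first ``n_components``
    PCs of the probe-centred M-value matrix; a sample is flagged when its
    score on any component exceeds ``sd_threshold`` times that component's
    score SD. Zero-variance components flag nothing. The flag set is
    invariant to component sign.
    """
    n_samples = m.shape[1]
    if n_samples < 3:
        raise ParameterError(f"need >= 3 samples for outlier screening, got {n_samples}")
    if n_components > n_samples:
        raise ParameterError(
            f"n_components={n_components} exceeds sample count {n_samples}"
        )
    x = m.to_numpy(float).T  # samples x probes
    x = x - x.mean(axis=0)
    if not np.any(x):
        return []
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(x)
    flagged: set[str] = set()
    for k in range(scores.shape[1]):
        sd = scores[:, k].std(ddof=1)
        if sd <= 0:
            continue
        for j in np.flatnonzero(np.abs(scores[:, k]) > sd_threshold * sd):
            flagged.add(m.columns[j])
    return sorted(flagged)
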