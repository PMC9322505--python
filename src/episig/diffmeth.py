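"""Per-probe differential methylation with empirical-Bayes moderation.

Cases are contrasted against controls probe-by-probe with an ordinary
linear model on M-values, with estimated cell-type proportions (and
optionally batch / array type) as covariates. Residual variances are then
shrunk towards a common prior by the standard empirical-Bayes scheme: the
per-probe variances s2_g are modelled as scaled-inverse-chi-square draws
around a prior (d0, s0^2) estimated by matching the mean and variance of
log s2_g (digamma/trigamma moment equations); the moderated t uses the
posterior variance

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

on d0 + d_g degrees of freedom. Alongside the test, each probe gets the
beta-scale group difference (delta-beta), the case-vs-control AUROC
(Mann-Whitney with ties counted 1/2) and the selection score
|delta_beta| * (-log10 p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .errors import DegenerateDataError, InputError

_P_FLOOR = 1e-300


def build_design(
    sample_ids: pd.Index | list[str],
    case_ids: list[str],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the model matrix: intercept, case indicator, covariates.

    ``covariates`` rows are aligned on sample id. Cell-type proportions sum
    to (approximately) one, which would be collinear with the intercept, so
    callers pass all but one cell type (see :func:`celltype_covariates`).
    """
    sample_ids = pd.Index(sample_ids)
    design = pd.DataFrame(
        {"intercept": 1.0, "group": sample_ids.isin(case_ids).astype(float)},
        index=sample_ids,
    )
    if covariates is not None:
        missing = sample_ids.difference(covariates.index)
        if len(missing) > 0:
            raise InputError(f"covariates missing for samples: {list(missing[:5])}")
        design = pd.concat([design, covariates.loc[sample_ids]], axis=1)
    _check_full_rank(design)
    return design


def celltype_covariates(proportions: pd.DataFrame) -> pd.DataFrame:
    """Drop the last (reference) cell type so the design stays full rank."""
    return proportions.iloc[:, :-1]


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # point at the most correlated column pair to aid debugging
        c = np.corrcoef(x.T)
        np.fill_diagonal(c, 0.0)
        c = np.nan_to_num(c)
        i, j = np.unravel_index(np.argmax(np.abs(c)), c.shape)
        raise InputError(
            "design matrix is rank deficient; dependent columns include "
            f"'{design.columns[i]}' and '{design.columns[j]}'"
        )


@dataclass
class ProbeFits:
    """Per-probe OLS results for the group coefficient.

    ``stdev_unscaled`` is sqrt((X'X)^-1 [group, group]) — the factor that
    multiplies the residual SD to give the coefficient SE; it is shared by
    all probes because the design is.
    """

    table: pd.DataFrame  # columns: coef, se, sigma2, df_resid
    stdev_unscaled: float

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class ModerationPrior:
    d0: float  # prior degrees of freedom; may be +inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise InputError(f"prior df must be > 0, got {self.d0}")
        if not self.s0_sq > 0:
            raise InputError(f"prior variance must be > 0, got {self.s0_sq}")


def fit_probe_models(m: pd.DataFrame, design: pd.DataFrame) -> ProbeFits:
    """Ordinary least squares per probe; returns the group-effect fits."""
    if not m.columns.equals(design.index):
        if set(m.columns) != set(design.index):
            raise InputError("design rows do not match M-value samples")
        design = design.loc[m.columns]
    _check_full_rank(design)
    x = design.to_numpy(float)
    y = m.to_numpy(float)  # probes x samples
    n, p = x.shape
    if n <= p:
        raise InputError(f"need more samples ({n}) than design columns ({p})")

    xtx_inv = np.linalg.inv(x.T @ x)
    coef = y @ x @ xtx_inv  # probes x p
    resid = y - coef @ x.T
    df_resid = n - p
    sigma2 = (resid**2).sum(axis=1) / df_resid
    g = design.columns.get_loc("group")
    u = float(np.sqrt(xtx_inv[g, g]))
    table = pd.DataFrame(
        {
            "coef": coef[:, g],
            "se": u * np.sqrt(sigma2),
            "sigma2": sigma2,
            "df_resid": float(df_resid),
        },
        index=m.index,
    )
    return ProbeFits(table=table, stdev_unscaled=u)


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def estimate_moderation_prior(fits: ProbeFits) -> ModerationPrior:
    """Estimate (d0, s0^2) by moment matching on log residual variances.

    Under the scaled-inverse-chi-square prior, e_g = log s2_g
    - digamma(d_g/2) + log(d_g/2) has mean log s0^2 + digamma(d0/2)
    - log(d0/2) and variance trigamma(d0/2) + trigamma(d_g/2). The excess
    of var(e) over the expected sampling variance identifies d0; no excess
    means no between-probe variance heterogeneity and d0 = +inf with
    s0^2 the pooled mean variance.
    """
    s2 = fits.table["sigma2"].to_numpy(float)
    df = fits.table["df_resid"].to_numpy(float)
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        raise DegenerateDataError("all residual variances are zero")
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise DegenerateDataError("need >= 2 probes with positive residual variance")

    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(_trigamma(df / 2.0)))
    if evar <= 0:
        return ModerationPrior(d0=np.inf, s0_sq=float(s2.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderate_statistics(
    fits: ProbeFits, prior: ModerationPrior
) -> pd.DataFrame:
    """Moderated t and two-sided p per probe.

    Posterior variance is the precision-weighted blend of prior and
    per-probe variance; with infinite prior df every probe uses s0^2 and
    the reference distribution is normal.
    """
    s2 = fits.table["sigma2"].to_numpy(float)
    df = fits.table["df_resid"].to_numpy(float)
    coef = fits.table["coef"].to_numpy(float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        t = coef / (fits.stdev_unscaled * np.sqrt(s2_post))
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        t = coef / (fits.stdev_unscaled * np.sqrt(s2_post))
        p = 2.0 * stats.t.sf(np.abs(t), df + prior.d0)
    return pd.DataFrame(
        {"t": t, "p": np.maximum(p, _P_FLOOR), "s2_post": s2_post},
        index=fits.table.index,
    )


def compute_delta_beta(
    beta: pd.DataFrame, case_ids: list[str], control_ids: list[str]
) -> pd.Series:
    """Mean case beta minus mean control beta, per probe (beta scale)."""
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise InputError("both groups must be non-empty")
    missing = set(case_ids) | set(control_ids)
    missing -= set(beta.columns)
    if missing:
        raise InputError(f"samples absent from beta matrix: {sorted(missing)[:5]}")
    return beta[list(case_ids)].mean(axis=1) - beta[list(control_ids)].mean(axis=1)


def compute_auroc(values, case_mask) -> float:
    """AUROC of ``values`` for separating cases from controls.

    Equals the Mann-Whitney U statistic divided by n_case * n_control:
    the probability a random case value exceeds a random control value,
    ties counted one half.
    """
    values = np.asarray(values, float)
    case_mask = np.asarray(case_mask, bool)
    n1, n0 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present to compute AUROC")
    ranks = stats.rankdata(values)
    u = ranks[case_mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auroc_per_probe(
    beta: pd.DataFrame, case_ids: list[str], control_ids: list[str]
) -> pd.Series:
    """Vectorized per-probe AUROC on beta values (cases vs controls)."""
    cols = list(case_ids) + list(control_ids)
    x = beta[cols].to_numpy(float)
    n1, n0 = len(case_ids), len(control_ids)
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present to compute AUROC")
    ranks = stats.rankdata(x, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    return pd.Series(u / (n1 * n0), index=beta.index)


def dmp_table(
    beta: pd.DataFrame,
    m: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    covariates: pd.DataFrame | None = None,
    signed_rank: bool = False,
) -> pd.DataFrame:
    """Full per-probe differential table: delta_beta, t, p, auroc, rank_score.

    ``rank_score`` is |delta_beta| * (-log10 p) (the signed variant is a
    switch); the table drives the three-step feature selection. Only
    case and control samples enter the model.
    """
    samples = list(case_ids) + list(control_ids)
    design = build_design(
        samples, list(case_ids),
        covariates.loc[samples] if covariates is not None else None,
    )
    fits = fit_probe_models(m[samples], design)
    prior = estimate_moderation_prior(fits)
    mod = moderate_statistics(fits, prior)
    delta = compute_delta_beta(beta, list(case_ids), list(control_ids))
    auroc = auroc_per_probe(beta, list(case_ids), list(control_ids))
    effect = delta if signed_rank else delta.abs()
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "t": mod["t"],
            "p": mod["p"],
            "auroc": auroc,
            "rank_score": effect * (-np.log10(mod["p"])),
        },
        index=beta.index,
    )
    table.attrs["prior_d0"] = prior.d0
    table.attrs["prior_s0_sq"] = prior.s0_sq
    return table
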