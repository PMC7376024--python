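"""Covariate-adjusted moderated differential abundance.

Each metabolite is regressed on disease status plus the cohort covariates
(sex, age, diabetes, ethnicity, BMI and optionally collection site) by
ordinary least squares. Residual variances are then shrunk toward a pooled
prior by the empirical-Bayes scheme of the moderated-t framework: the prior
(d0, s0^2) is estimated by method of moments on the log residual variances,
and the moderated variance is the precision-weighted blend

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

with the moderated t referred to a t distribution on df + d0 degrees of
freedom (standard normal when d0 is infinite). Multiplicity is controlled by
Benjamini-Hochberg at FDR 0.05.

The public surface is :class:`ModeratedDifferentialAbundance` (a fit-shaped
estimator) plus thin functional wrappers for each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "VariancePrior",
    "ModeratedDifferentialAbundance",
    "build_design",
    "fit_models",
    "squeeze_variances",
    "moderated_test",
    "bh_adjust",
]

DEFAULT_COVARIATES = ("sex", "age", "diabetes", "ethnicity", "bmi", "site")


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0^2 scale."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0 or math.isinf(self.d0)) and self.d0 != 0.0:
            raise ValueError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not self.s0_sq > 0:
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def build_design(
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    include_status: bool = True,
) -> pd.DataFrame:
    """Build the model matrix: intercept, status (case=1) and covariates.

    Categorical covariates are one-hot encoded with the most frequent level
    as the reference. Covariates absent from the metadata are skipped;
    rank-deficient designs raise an error naming the aliased columns.
    """
    n = len(metadata)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if include_status:
        cols["status"] = (metadata["status"].to_numpy() == "case").astype(float)
    for cov in covariates:
        if cov not in metadata.columns:
            continue
        s = metadata[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.to_numpy(dtype=float)
        else:
            levels = s.value_counts()
            ref = levels.index[0]
            for lev in sorted(x for x in levels.index if x != ref):
                cols[f"{cov}[{lev}]"] = (s == lev).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=metadata.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return X


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    aliased: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def fit_models(
    Y: pd.DataFrame, design: pd.DataFrame, coef: str = "status"
) -> tuple[pd.Series, pd.Series, int, float]:
    """Per-metabolite OLS of abundance on the design matrix.

    Returns the coefficient of interest per metabolite, the residual
    variances s^2, the residual degrees of freedom n - p, and the unscaled
    standard-error factor of the coefficient (sqrt of the corresponding
    diagonal entry of (X'X)^-1, identical across metabolites).
    """
    X = design.to_numpy(float)
    Ymat = Y.to_numpy(float)
    n, p = X.shape
    if n != Ymat.shape[0]:
        raise ValueError(f"design has {n} rows, matrix has {Ymat.shape[0]} samples")
    df = n - p
    if df < 1:
        raise ValueError(f"non-positive residual degrees of freedom: {df}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Ymat)
    resid = Ymat - X @ beta
    s2 = (resid * resid).sum(axis=0) / df
    j = list(design.columns).index(coef)
    se_factor = float(np.sqrt(xtx_inv[j, j]))
    coefs = pd.Series(beta[j], index=Y.columns, name=coef)
    return coefs, pd.Series(s2, index=Y.columns, name="s2"), df, se_factor


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def squeeze_variances(
    s2: np.ndarray | pd.Series, df: int
) -> tuple[VariancePrior, np.ndarray]:
    """Estimate the variance prior and return moderated variances.

    Method of moments on z = log s^2: under the scaled-F sampling model,
    z - digamma(df/2) + log(df/2) has mean log s0^2 + digamma(d0/2) -
    log(d0/2) and variance trigamma(df/2) + trigamma(d0/2). The observed
    excess of var(z) over trigamma(df/2) identifies d0 via the inverse
    trigamma; no excess means no detectable heterogeneity and d0 = inf, in
    which case every moderated variance equals s0^2.
    """
    s2_arr = np.asarray(s2, dtype=float)
    if s2_arr.size < 2:
        raise ValueError("need at least 2 variances to estimate the prior")
    if np.any(s2_arr < 0):
        raise ValueError("negative variance encountered")
    # guard exact zeros (possible with degenerate fits) before taking logs
    tiny = 1e-300
    z = np.log(np.maximum(s2_arr, tiny))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.sum((e - emean) ** 2) / (e.size - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess dispersion: infinite prior df, pooled variance as scale
        d0 = math.inf
        s0_sq = float(np.mean(s2_arr))
    prior = VariancePrior(d0=d0, s0_sq=s0_sq)
    s2_tilde = moderate_variances(s2_arr, df, prior)
    return prior, s2_tilde


def moderate_variances(
    s2: np.ndarray, df: int, prior: VariancePrior
) -> np.ndarray:
    """Blend observed variances with the prior: (d0 s0^2 + df s^2)/(d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(prior.d0):
        return np.full_like(s2, prior.s0_sq)
    if prior.d0 == 0:
        return s2.copy()
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


def moderated_test(
    coefs: pd.Series,
    s2_tilde: np.ndarray,
    df: int,
    d0: float,
    se_factor: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t-tests, 95% CIs and BH-adjusted q-values.

    The reference distribution is t on df + d0 degrees of freedom (standard
    normal when d0 is infinite). The returned table is sorted by logFC, the
    conventional presentation for a differential-abundance figure.
    """
    se = se_factor * np.sqrt(np.asarray(s2_tilde, dtype=float))
    t_mod = coefs.to_numpy(float) / se
    df_total = df + d0
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
        crit = float(stats.norm.ppf(0.975))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        crit = float(stats.t.ppf(0.975, df_total))
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "metabolite_id": coefs.index,
            "logFC": coefs.to_numpy(float),
            "ci_low": coefs.to_numpy(float) - crit * se,
            "ci_high": coefs.to_numpy(float) + crit * se,
            "t_mod": t_mod,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )
    return out.sort_values("logFC", kind="mergesort").reset_index(drop=True)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values;
    monotone non-decreasing in p.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


class ModeratedDifferentialAbundance(BaseEstimator):
    """Covariate-adjusted moderated differential abundance estimator.

    Parameters
    ----------
    covariates
        Metadata columns entered as adjustment covariates (those absent from
        the metadata are skipped).
    prior_df
        ``None`` estimates the variance-prior degrees of freedom from the
        data; ``0`` turns moderation off (ordinary per-metabolite t-tests);
        a positive float fixes d0.
    alpha
        FDR threshold for the ``significant`` flag.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame with metabolite_id, logFC, ci_low, ci_high, t_mod,
        p, q, significant (sorted by logFC).
    prior_ : VariancePrior
    design_ : the model matrix used.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        prior_df: float | None = None,
        alpha: float = 0.05,
    ):
        self.covariates = covariates
        self.prior_df = prior_df
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, metadata: pd.DataFrame):
        """Fit per-metabolite models; X is samples x metabolites."""
        metadata = metadata.loc[X.index]
        design = build_design(metadata, tuple(self.covariates))
        coefs, s2, df, se_factor = fit_models(X, design)
        if self.prior_df is None:
            prior, s2_tilde = squeeze_variances(s2, df)
        else:
            prior = VariancePrior(d0=float(self.prior_df), s0_sq=float(np.mean(s2)) or 1.0)
            s2_tilde = moderate_variances(s2.to_numpy(), df, prior)
        self.prior_ = prior
        self.design_ = design
        self.residual_df_ = df
        self.se_factor_ = se_factor
        self.s2_ = s2
        self.s2_tilde_ = pd.Series(s2_tilde, index=s2.index)
        self.results_ = moderated_test(
            coefs, s2_tilde, df, prior.d0, se_factor, alpha=self.alpha
        )
        return self
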