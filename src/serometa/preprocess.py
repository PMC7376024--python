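"""QC and normalization chain for a metabolite abundance matrix.

The chain reproduces the standard processing of relative-abundance serum
metabolomics before modelling, in this fixed order:

1. drop metabolites with more than 20% missing values (the "80% rule"),
2. impute remaining below-detection-limit cells with the metabolite minimum,
3. report (not remove) subjects flagged by Tukey-fence outlier detection on
   per-subject missingness,
4. quantile-normalize between samples,
5. scale each metabolite to zero mean and unit standard deviation,
6. PCA on samples for a visual covariate QC table.

Each step is a scikit-learn transformer operating on a samples x metabolites
DataFrame with NaN for missing cells; the module-level functions wrap the
transformers for :class:`~serometa.data_model.AbundanceMatrix` and enforce the
processing-state order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .data_model import AbundanceMatrix

__all__ = [
    "MissingnessFilter",
    "MinimumImputer",
    "QuantileNormalizer",
    "MetaboliteScaler",
    "filter_missingness",
    "impute_minimum",
    "missingness_outliers",
    "quantile_normalize",
    "scale_metabolites",
    "pca_qc",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class MissingnessFilter(TransformerMixin, BaseEstimator):
    """Drop metabolites whose missing fraction exceeds ``max_missing``.

    The inequality is strict: a metabolite missing in exactly
    ``max_missing`` of samples is retained.
    """

    def __init__(self, max_missing: float = 0.20):
        self.max_missing = max_missing

    def fit(self, X, y=None):
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError(f"max_missing must be in [0, 1], got {self.max_missing}")
        X = _as_frame(X)
        frac = X.isna().mean(axis=0)
        self.missing_fraction_ = frac
        self.keep_mask_ = (frac <= self.max_missing).to_numpy()
        self.dropped_ = list(frac.index[~self.keep_mask_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X.loc[:, X.columns[self.keep_mask_]]


class MinimumImputer(TransformerMixin, BaseEstimator):
    """Replace missing cells with the minimum observed value per metabolite.

    Missing values in this platform indicate levels below the detection
    limit, so the per-metabolite observed minimum is the natural left-censored
    surrogate. A metabolite with no observed values cannot be imputed and is a
    hard error.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        all_missing = X.isna().all(axis=0)
        if all_missing.any():
            bad = list(X.columns[all_missing])
            raise ValueError(f"cannot impute all-missing metabolites: {bad}")
        self.minimum_ = X.min(axis=0, skipna=True)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return X.fillna(self.minimum_)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Between-sample quantile normalization.

    ``fit`` learns the reference distribution (the mean of the per-sample
    sorted value vectors); ``transform`` replaces each sample's values with
    the reference value at the corresponding rank, averaging the implied
    values over ties. After ``fit_transform`` every sample has an identical
    sorted value vector, which removes broad between-sample (batch-like)
    intensity differences while preserving within-sample ranks.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.isna().any().any():
            raise ValueError("quantile normalization requires a fully imputed matrix")
        self.reference_ = np.sort(X.to_numpy(float), axis=1).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        vals = X.to_numpy(float)
        if vals.shape[1] != self.reference_.size:
            raise ValueError(
                f"matrix has {vals.shape[1]} metabolites, reference has "
                f"{self.reference_.size}"
            )
        out = np.empty_like(vals)
        ref = self.reference_
        for i in range(vals.shape[0]):
            row = vals[i]
            # ties receive the average of the reference values their rank
            # positions would imply
            uniq_inverse = np.unique(row, return_inverse=True)[1]
            order = np.argsort(row, kind="mergesort")
            sums = np.bincount(uniq_inverse[order], weights=ref)
            counts = np.bincount(uniq_inverse)
            out[i] = (sums / counts)[uniq_inverse]
        return pd.DataFrame(out, index=X.index, columns=X.columns)


class MetaboliteScaler(TransformerMixin, BaseEstimator):
    """Scale each metabolite to zero mean and unit SD (n-1 denominator)."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = ~(self.scale_ > 0)
        if zero.any():
            bad = list(X.columns[zero])
            raise ValueError(f"zero-variance metabolites cannot be scaled: {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_frame(X)
        return (X - self.mean_) / self.scale_


# --------------------------------------------------------------------------
# AbundanceMatrix-level wrappers enforcing the state machine
# --------------------------------------------------------------------------

def _require_state(m: AbundanceMatrix, *allowed: str) -> None:
    if m.state not in allowed:
        raise ValueError(
            f"operation requires state in {allowed}, matrix is {m.state!r}"
        )


def _masked_values(m: AbundanceMatrix) -> pd.DataFrame:
    return m.values.mask(m.missing_mask)


def filter_missingness(
    m: AbundanceMatrix, max_missing: float = 0.20
) -> tuple[AbundanceMatrix, list[str]]:
    """Apply the 80% rule: drop metabolites missing in > ``max_missing``."""
    _require_state(m, "raw")
    f = MissingnessFilter(max_missing=max_missing).fit(_masked_values(m))
    keep = m.values.columns[f.keep_mask_]
    out = AbundanceMatrix(
        values=m.values.loc[:, keep],
        missing_mask=m.missing_mask.loc[:, keep],
        state="filtered",
        log=list(m.log),
    )
    out.log.append(
        f"filter_missingness(max_missing={max_missing}): dropped "
        f"{len(f.dropped_)} metabolites"
    )
    return out, f.dropped_


def impute_minimum(m: AbundanceMatrix) -> AbundanceMatrix:
    """Impute masked cells with the per-metabolite observed minimum."""
    _require_state(m, "filtered")
    vals = _masked_values(m)
    imputed = MinimumImputer().fit_transform(vals)
    out = AbundanceMatrix(
        values=imputed, missing_mask=m.missing_mask.copy(), state="imputed",
        log=list(m.log),
    )
    out.log.append(
        f"impute_minimum: filled {int(m.missing_mask.to_numpy().sum())} cells"
    )
    return out


def missingness_outliers(m: AbundanceMatrix) -> list[str]:
    """Subjects whose missing fraction falls outside the Tukey fences.

    Fences are [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the per-subject missing
    fractions. The pipeline only reports these subjects; exclusion is an
    explicit opt-in at the pipeline level.
    """
    frac = m.missing_fraction_per_sample()
    q1, q3 = np.percentile(frac.to_numpy(), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return list(frac.index[(frac < lo) | (frac > hi)])


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Quantile-normalize between samples (rank-wise means, ties averaged)."""
    _require_state(m, "imputed", "normalized")
    normed = QuantileNormalizer().fit_transform(m.values)
    out = AbundanceMatrix(
        values=normed, missing_mask=m.missing_mask.copy(), state="normalized",
        log=list(m.log) + ["quantile_normalize"],
    )
    return out


def scale_metabolites(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each metabolite to mean 0, SD 1 (sample SD, n-1)."""
    _require_state(m, "normalized")
    scaled = MetaboliteScaler().fit_transform(m.values)
    return AbundanceMatrix(
        values=scaled, missing_mask=m.missing_mask.copy(), state="scaled",
        log=list(m.log) + ["scale_metabolites"],
    )


def pca_qc(m: AbundanceMatrix, metadata: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the first PCs joined to covariates, for visual QC.

    Returns one row per sample with PC scores and the covariates; the
    variance-explained fractions are attached as ``DataFrame.attrs
    ['variance_explained']``.
    """
    _require_state(m, "scaled", "normalized")
    if m.n_samples < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(m.values.to_numpy(float))
    table = pd.DataFrame(
        scores, index=m.values.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    table = table.join(metadata.drop(columns=["sample_id"], errors="ignore"))
    table.insert(0, "sample_id", table.index)
    table.attrs["variance_explained"] = pca.explained_variance_ratio_.copy()
    return table.reset_index(drop=True)
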