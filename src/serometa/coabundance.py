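"""Differential co-abundance analysis.

Metabolite-metabolite correlations can change between disease states even
when mean levels do not; such "re-wiring" is probed by:

1. residualizing every metabolite on the covariates and disease status
   (so no correlation is created or masked by shared covariate structure),
2. Pearson correlations of the residuals within cases and within controls,
3. keeping only pairs strongly correlated in at least one stratum
   (max(|r_case|, |r_control|) >= 0.5), after discarding xenobiotic
   metabolites,
4. a two-sample Fisher r-to-z test per retained pair with BH correction at
   FDR 0.1,
5. classifying significant pairs as lost/gained x positive/negative, and
6. an exact one-sided binomial test per metabolic group, with the success
   probability set to the global fraction of tested pairs that are
   significant (the p_parameter), BH-corrected at FDR 0.05.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .differential_abundance import DEFAULT_COVARIATES, bh_adjust, build_design

__all__ = [
    "DifferentialCoabundance",
    "residualize",
    "groupwise_correlations",
    "select_pairs",
    "fisher_z_test",
    "classify_pairs",
    "binomial_group_enrichment",
    "compute_p_parameter",
]


def residualize(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """OLS residuals of each metabolite on covariates + disease status."""
    metadata = metadata.loc[X.index]
    design = build_design(metadata, tuple(covariates), include_status=True)
    D = design.to_numpy(float)
    Y = X.to_numpy(float)
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    return pd.DataFrame(resid, index=X.index, columns=X.columns)


def groupwise_correlations(
    residuals: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrices of residuals within cases and controls."""
    metadata = metadata.loc[residuals.index]
    out = []
    for level in ("case", "control"):
        sub = residuals.loc[metadata["status"] == level]
        if len(sub) < 4:
            raise ValueError(f"need >= 4 samples in stratum {level!r}, got {len(sub)}")
        vals = sub.to_numpy(float)
        sd = vals.std(axis=0, ddof=1)
        degenerate = ~(sd > 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(vals, rowvar=False)
        if degenerate.any():
            bad = list(residuals.columns[degenerate])
            warnings.warn(
                f"zero-variance residuals in stratum {level!r}: {bad}; "
                "their pairs are excluded"
            )
            r[degenerate, :] = np.nan
            r[:, degenerate] = np.nan
        np.fill_diagonal(r, 1.0)
        out.append(pd.DataFrame(r, index=residuals.columns, columns=residuals.columns))
    return out[0], out[1]


def select_pairs(
    r_case: pd.DataFrame,
    r_control: pd.DataFrame,
    threshold: float = 0.5,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Unordered pairs with max(|r_case|, |r_control|) >= threshold.

    ``exclude`` lists metabolites removed before pairing (the xenobiotic
    super-class in the standard pipeline). Pairs with an undefined
    correlation in either stratum are dropped.
    """
    mets = [m for m in r_case.columns if exclude is None or m not in set(exclude)]
    rc = r_case.loc[mets, mets].to_numpy(float)
    rk = r_control.loc[mets, mets].to_numpy(float)
    iu = np.triu_indices(len(mets), k=1)
    rc_u, rk_u = rc[iu], rk[iu]
    strength = np.fmax(np.abs(rc_u), np.abs(rk_u))
    keep = ~np.isnan(rc_u) & ~np.isnan(rk_u) & (strength >= threshold)
    names = np.asarray(mets, dtype=object)
    return pd.DataFrame(
        {
            "metabolite_a": names[iu[0][keep]],
            "metabolite_b": names[iu[1][keep]],
            "r_case": rc_u[keep],
            "r_control": rk_u[keep],
        }
    )


def fisher_z_test(r1, n1, r2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample Fisher r-to-z test.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal. Vectorized over r1/r2.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if min(n1, n2) < 4:
        raise ValueError("need at least 4 samples per stratum")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def classify_pairs(pairs: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Label significant pairs by how the correlation changed.

    lost_*: strong in controls (|r_control| >= threshold) and weak in cases,
    signed by the control correlation; gained_*: the mirror image; pairs
    strong in both strata but significantly different are changed_other.
    Non-significant pairs get an empty category.
    """
    out = pairs.copy()
    cat = np.full(len(out), "", dtype=object)
    sig = out["significant"].to_numpy(bool)
    rc = out["r_case"].to_numpy(float)
    rk = out["r_control"].to_numpy(float)
    strong_ctrl = np.abs(rk) >= threshold
    strong_case = np.abs(rc) >= threshold
    lost = sig & strong_ctrl & ~strong_case
    gained = sig & strong_case & ~strong_ctrl
    cat[lost & (rk > 0)] = "lost_positive"
    cat[lost & (rk <= 0)] = "lost_negative"
    cat[gained & (rc > 0)] = "gained_positive"
    cat[gained & (rc <= 0)] = "gained_negative"
    cat[sig & strong_ctrl & strong_case] = "changed_other"
    out["category"] = cat
    return out


def compute_p_parameter(n_significant: int, n_tested: int) -> float:
    """Global success probability: significant pairs / tested pairs."""
    if n_tested <= 0:
        raise ValueError("no tested pairs")
    return n_significant / n_tested


def binomial_group_enrichment(
    pairs: pd.DataFrame,
    groups: pd.Series,
    p_parameter: float | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Exact binomial enrichment of differential co-abundance per group.

    For each metabolic group: k = significant tested pairs touching the
    group, n = tested pairs touching the group, and the success probability
    is the global fraction of significant pairs (recomputed from ``pairs``
    unless given). A pair spanning two groups counts once for each. One-sided
    upper-tail by default; BH across groups.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    groups = groups.astype(str)
    n_tested = len(pairs)
    n_sig = int(pairs["significant"].sum())
    if p_parameter is None:
        p_parameter = compute_p_parameter(n_sig, n_tested)
    if not 0 < p_parameter < 1:
        raise ValueError(f"p_parameter must be in (0, 1), got {p_parameter}")
    ga = pairs["metabolite_a"].map(groups)
    gb = pairs["metabolite_b"].map(groups)
    sig = pairs["significant"].to_numpy(bool)
    rows = []
    skipped = []
    for gname in sorted(set(groups[groups.index.intersection(
            pd.unique(pairs[["metabolite_a", "metabolite_b"]].to_numpy().ravel()))])):
        touches = ((ga == gname) | (gb == gname)).to_numpy()
        n = int(touches.sum())
        if n == 0:
            skipped.append(gname)
            continue
        k = int((touches & sig).sum())
        if alternative == "greater":
            p = float(stats.binom.sf(k - 1, n, p_parameter))
        else:
            p = float(stats.binomtest(k, n, p_parameter, alternative="two-sided").pvalue)
        rows.append({"group": gname, "k": k, "n": n, "p_parameter": p_parameter, "p": p})
    res = pd.DataFrame(rows, columns=["group", "k", "n", "p_parameter", "p"])
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["enriched"] = res["q"] < alpha
    else:
        res["q"] = np.array([], dtype=float)
        res["enriched"] = np.array([], dtype=bool)
    res.attrs["skipped_groups"] = skipped
    return res


class DifferentialCoabundance(BaseEstimator):
    """End-to-end differential co-abundance estimator.

    Parameters
    ----------
    covariates : metadata columns regressed out (with status) before
        correlating.
    threshold : minimum max-stratum |r| for a pair to be tested (0.5).
    fdr : BH threshold for calling a pair significantly differentially
        co-abundant (0.1).
    enrichment_alpha : BH threshold for group enrichment (0.05).
    alternative : binomial enrichment sidedness ('greater' by default).

    Attributes (after ``fit``)
    --------------------------
    pairs_ : tested-pair table (metabolite/group ids, r per stratum, z, p,
        q, significant, category).
    enrichment_ : per-group binomial enrichment table.
    p_parameter_ : global significant/tested ratio.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        threshold: float = 0.5,
        fdr: float = 0.1,
        enrichment_alpha: float = 0.05,
        alternative: str = "greater",
    ):
        self.covariates = covariates
        self.threshold = threshold
        self.fdr = fdr
        self.enrichment_alpha = enrichment_alpha
        self.alternative = alternative

    def fit(self, X: pd.DataFrame, metadata: pd.DataFrame, annotation: pd.DataFrame):
        metadata = metadata.loc[X.index]
        resid = residualize(X, metadata, tuple(self.covariates))
        r_case, r_control = groupwise_correlations(resid, metadata)
        xeno = list(annotation.index[annotation["is_xenobiotic"]])
        pairs = select_pairs(r_case, r_control, self.threshold, exclude=xeno)
        n1 = int((metadata["status"] == "case").sum())
        n2 = int((metadata["status"] == "control").sum())
        if len(pairs):
            z, p = fisher_z_test(
                pairs["r_case"].to_numpy(), n1, pairs["r_control"].to_numpy(), n2
            )
            pairs["z"] = z
            pairs["p"] = p
            pairs["q"] = bh_adjust(p)
            pairs["significant"] = pairs["q"] < self.fdr
        else:
            for col in ("z", "p", "q"):
                pairs[col] = np.array([], dtype=float)
            pairs["significant"] = np.array([], dtype=bool)
        pairs = classify_pairs(pairs, self.threshold)
        groups = annotation["group"]
        pairs.insert(2, "group_a", pairs["metabolite_a"].map(groups))
        pairs.insert(3, "group_b", pairs["metabolite_b"].map(groups))
        self.pairs_ = pairs
        self.n_case_ = n1
        self.n_control_ = n2
        self.n_tested_ = len(pairs)
        self.n_significant_ = int(pairs["significant"].sum())
        if self.n_tested_:
            self.p_parameter_ = compute_p_parameter(self.n_significant_, self.n_tested_)
        else:
            self.p_parameter_ = float("nan")
        if self.n_tested_ and 0 < self.p_parameter_ < 1:
            self.enrichment_ = binomial_group_enrichment(
                pairs, groups, alpha=self.enrichment_alpha,
                alternative=self.alternative,
            )
        else:
            # no significant pairs (or none tested): enrichment is undefined
            self.enrichment_ = pd.DataFrame(
                columns=["group", "k", "n", "p_parameter", "p", "q", "enriched"]
            )
        return self
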