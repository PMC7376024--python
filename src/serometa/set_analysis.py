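"""Metabolite-group (pathway) enrichment.

Two complementary self-contained tests:

* a rotation test: the per-metabolite moderated t-statistics of a group are
  summarized (mean for directional hypotheses, mean of squares for the mixed
  hypothesis) and referred to a null distribution built by random rotations
  of the fitted model's residual space — the multivariate-normal analogue of
  sample permutation that respects small samples and covariate adjustment,
  and preserves the correlation between metabolites within a group;
* a first-principal-component test for groups whose members move in opposite
  directions: the group is represented by its PC1 score per sample, which is
  then tested with the same covariate-adjusted moderated model used for
  individual metabolites.

Implementation works in the reduced orthonormal basis of the design: after a
QR decomposition with the status column last, each metabolite reduces to a
signed effect component u0 and d = n - p residual components, and a rotation
is a random unit vector applied to that (d+1)-vector, shared by all members
of a set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .differential_abundance import (
    DEFAULT_COVARIATES,
    ModeratedDifferentialAbundance,
    bh_adjust,
    build_design,
    squeeze_variances,
)

__all__ = [
    "RotationSetTest",
    "rotation_set_test",
    "pc1_group_score",
    "pc1_group_test",
]


def _effect_decomposition(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """Rotate data into the design's orthonormal basis.

    Returns (u0, resid_effects, d): u0 is the signed status-effect component
    per metabolite (its sign matches the regression coefficient), the
    residual effects span the d = n - p dimensional residual space.
    """
    n, p = X.shape
    # move the coefficient of interest to the last design column
    order = [j for j in range(p) if j != coef_index] + [coef_index]
    Q, R = np.linalg.qr(X[:, order], mode="complete")
    effects = Q.T @ Y
    sign = 1.0 if R[p - 1, p - 1] > 0 else -1.0
    u0 = sign * effects[p - 1]
    resid = effects[p:]
    return u0, resid, n - p


class RotationSetTest(BaseEstimator):
    """Self-contained rotation enrichment test for metabolite groups.

    Parameters
    ----------
    covariates : metadata columns to adjust for (skipped when absent).
    n_rotations : number of random rotations (default 9999).
    random_state : seed for the rotation draw.
    min_size : groups smaller than this are skipped with a warning entry.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame with group, n_members, direction, p_up, p_down,
        p_mixed, q (BH over the mixed p across tested groups).
    prior_ : the variance prior shared with the per-metabolite tests.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        n_rotations: int = 9999,
        random_state: int | None = None,
        min_size: int = 2,
    ):
        self.covariates = covariates
        self.n_rotations = n_rotations
        self.random_state = random_state
        self.min_size = min_size

    def fit(self, X: pd.DataFrame, metadata: pd.DataFrame, groups: pd.Series):
        """Test each group; ``groups`` maps metabolite_id -> group label."""
        metadata = metadata.loc[X.index]
        design = build_design(metadata, tuple(self.covariates))
        coef_index = list(design.columns).index("status")
        u0, resid, d = _effect_decomposition(
            X.to_numpy(float), design.to_numpy(float), coef_index
        )
        s2 = (resid * resid).sum(axis=0) / d
        prior, s2_tilde = squeeze_variances(s2, d)
        self.prior_ = prior
        d0 = prior.d0

        met_index = pd.Index(X.columns)
        V = np.vstack([u0, resid])  # (d+1) x m
        norms_sq = (V * V).sum(axis=0)

        rng = np.random.default_rng(self.random_state)
        R = rng.standard_normal((self.n_rotations, d + 1))
        R /= np.linalg.norm(R, axis=1, keepdims=True)

        if math.isinf(d0):
            denom_obs = np.full_like(s2, prior.s0_sq)
        else:
            denom_obs = s2_tilde
        t_obs_all = u0 / np.sqrt(denom_obs)

        rows = []
        skipped = []
        groups = groups.astype(str)
        for gname in sorted(groups.unique()):
            members = groups.index[groups == gname]
            members = [m for m in members if m in met_index]
            if len(members) < self.min_size:
                skipped.append(gname)
                continue
            idx = met_index.get_indexer(members)
            Vg = V[:, idx]
            nsq = norms_sq[idx]
            t_obs = t_obs_all[idx]
            stat_mean_obs = float(np.mean(t_obs))
            stat_msq_obs = float(np.mean(t_obs**2))

            U = R @ Vg  # n_rot x g
            if math.isinf(d0):
                T = U / math.sqrt(prior.s0_sq)
            else:
                s2_rot_scaled = nsq[None, :] - U * U  # = d * s2_rot
                denom = (d0 * prior.s0_sq + s2_rot_scaled) / (d0 + d)
                T = U / np.sqrt(denom)
            stat_mean = T.mean(axis=1)
            stat_msq = (T * T).mean(axis=1)

            nrot = self.n_rotations
            p_up = (np.sum(stat_mean >= stat_mean_obs) + 1) / (nrot + 1)
            p_down = (np.sum(stat_mean <= stat_mean_obs) + 1) / (nrot + 1)
            p_mixed = (np.sum(stat_msq >= stat_msq_obs) + 1) / (nrot + 1)
            rows.append(
                {
                    "group": gname,
                    "n_members": len(members),
                    "direction": "up" if stat_mean_obs > 0 else "down",
                    "p_up": p_up,
                    "p_down": p_down,
                    "p_mixed": p_mixed,
                }
            )
        self.skipped_ = skipped
        res = pd.DataFrame(
            rows, columns=["group", "n_members", "direction", "p_up", "p_down", "p_mixed"]
        )
        if len(res):
            res["q"] = bh_adjust(res["p_mixed"].to_numpy())
        else:
            res["q"] = np.array([], dtype=float)
        self.results_ = res
        return self


def rotation_set_test(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: pd.Series,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_rotations: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`RotationSetTest`."""
    est = RotationSetTest(
        covariates=covariates, n_rotations=n_rotations, random_state=seed
    ).fit(X, metadata, groups)
    return est.results_


def pc1_group_score(X: pd.DataFrame, members: list[str]) -> pd.Series:
    """Per-sample first-principal-component score of a metabolite group.

    The input is the scaled matrix; the score's sign is fixed so that it
    correlates positively with the group's mean abundance, and it is
    standardized to unit sample variance. Flipping the sign of all loadings
    therefore leaves the emitted score unchanged.
    """
    if len(members) < 2:
        raise ValueError("PC1 group score needs at least 2 members")
    sub = X.loc[:, members].to_numpy(float)
    sub = sub - sub.mean(axis=0)
    if not np.any(sub.std(axis=0) > 0):
        raise ValueError("degenerate (zero-variance) group submatrix")
    U, S, _ = np.linalg.svd(sub, full_matrices=False)
    score = U[:, 0] * S[0]
    mean_abund = sub.mean(axis=1)
    if np.dot(score, mean_abund) < 0:
        score = -score
    sd = score.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate PC1 score (zero variance)")
    return pd.Series(score / sd, index=X.index, name="pc1")


def pc1_group_test(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: pd.Series,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_size: int = 2,
) -> pd.DataFrame:
    """Test each group's PC1 score with the covariate-adjusted model.

    Returns a per-group table (group, coef, t_mod, p, q); BH correction is
    applied across groups. Intended for groups whose members shift in
    opposite directions, where directional set statistics cancel.
    """
    groups = groups.astype(str)
    met_index = pd.Index(X.columns)
    scores: dict[str, pd.Series] = {}
    for gname in sorted(groups.unique()):
        members = [m for m in groups.index[groups == gname] if m in met_index]
        if len(members) < min_size:
            continue
        scores[gname] = pc1_group_score(X, members)
    if not scores:
        return pd.DataFrame(columns=["group", "coef", "t_mod", "p", "q"])
    score_mat = pd.DataFrame(scores, index=X.index)
    # moderation needs >= 2 scores to estimate a prior; a single group falls
    # back to the ordinary covariate-adjusted t-test
    est = ModeratedDifferentialAbundance(
        covariates=tuple(covariates),
        prior_df=None if score_mat.shape[1] > 1 else 0.0,
    ).fit(score_mat, metadata.loc[X.index])
    res = est.results_.rename(
        columns={"metabolite_id": "group", "logFC": "coef"}
    )[["group", "coef", "t_mod", "p", "q"]]
    return res.sort_values("group", kind="mergesort").reset_index(drop=True)
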