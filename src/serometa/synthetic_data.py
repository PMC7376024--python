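"""Synthetic case-control metabolomics cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes in a
serum metabolomics case-control study of a retinal neurodegeneration
(60 cases / 58 controls, 946 metabolites in ~50 correlated metabolic
groups):

* log2-scale abundances drawn from a multivariate normal per disease
  status, compound-symmetric within metabolic groups (correlation ``rho``),
* planted case-vs-control mean shifts (log2 fold changes) concentrated in
  the glycine-serine-threonine, phosphatidylethanolamine and sphingomyelin
  groups,
* planted cross-group correlations present in controls and absent in cases
  (sphingomyelin <-> glycine-serine positive, sphingomyelin <->
  phosphatidylethanolamine negative), emulating disease "decoupling",
* covariates (age, sex, BMI, diabetes, ethnicity, collection site) drawn
  independently of status and added linearly with per-metabolite random
  coefficients,
* left-censoring: values below a per-metabolite detection-limit quantile are
  masked, with a subset of metabolites censored heavily enough to fail the
  80% rule.

Everything is driven by one integer seed; the returned
:class:`SimulationTruth` records every planted quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import AbundanceMatrix, XENOBIOTIC_SUPERCLASS

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "CohortSimulator",
    "generate_cohort",
    "plant_decoupling",
    "default_config",
]

GLY_SER = "glycine_serine_threonine_metabolism"
PE = "phosphatidylethanolamines"
SM = "sphingomyelins"
XENO = "xenobiotics"


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator configuration; defaults are the study conditions."""

    n_case: int = 60
    n_control: int = 58
    n_metabolites: int = 946
    n_groups: int = 50
    rho: float = 0.7
    #: per-group overrides of the within-group correlation.
    group_rho: tuple[tuple[str, float], ...] = ()
    #: named groups with fixed sizes; remaining metabolites are spread
    #: evenly over generic groups.
    special_groups: tuple[tuple[str, int], ...] = (
        (GLY_SER, 11),
        (PE, 14),
        (SM, 21),
        (XENO, 80),
    )
    #: planted log2 fold changes: group -> either a single value for all
    #: members or a tuple of per-member values (padded with the last value).
    planted_logfc: tuple[tuple[str, tuple[float, ...]], ...] = (
        (GLY_SER, (-1.31, -1.03, -0.96, -0.5)),
        (PE, (0.8,)),
        (SM, (-0.4,)),
    )
    #: planted cross-group correlation blocks:
    #: (group_a, group_b, r_control, r_case); every cross pair between the
    #: two groups gets the stated correlation in the corresponding stratum.
    #: Feasibility requires |r| <= rho (two metabolites tightly coupled to
    #: their own groups can only correlate if the groups do) and an overall
    #: positive semi-definite matrix, checked at build time. The third block
    #: is the consistency completion implied by the first two (groups
    #: correlated with a common third group must correlate with each other);
    #: it is identical in both strata, so only sphingomyelin-touching pairs
    #: are decoupled.
    planted_cross: tuple[tuple[str, str, float, float], ...] = (
        (SM, GLY_SER, 0.6, 0.0),
        (SM, PE, -0.5, 0.0),
        (GLY_SER, PE, -0.43, -0.43),
    )
    #: planted member-level cross correlations:
    #: (group_a, member_index_a, group_b, member_index_b, r_control, r_case).
    #: Unlike block planting these give (nearly) independent pairs, which is
    #: only feasible when the within-group correlation is moderate.
    planted_cross_pairs: tuple[tuple[str, int, str, int, float, float], ...] = ()
    #: per-metabolite SD of the log-normal spread of residual SDs.
    sd_log_sigma: float = 0.25
    #: fraction of metabolites censored heavily (failing the 80% rule) and
    #: the censoring-quantile ranges for the light/heavy regimes.
    heavy_censor_fraction: float = 0.205
    light_censor_range: tuple[float, float] = (0.0, 0.13)
    heavy_censor_range: tuple[float, float] = (0.22, 0.5)
    #: overall scale: per-metabolite baseline log2 abundance ~ N(mean, sd).
    baseline_mean: float = 18.0
    baseline_sd: float = 2.0
    #: covariate effect scales (SD of per-metabolite random coefficients).
    covariate_effects: tuple[tuple[str, float], ...] = (
        ("age", 0.01),
        ("bmi", 0.02),
        ("sex", 0.15),
        ("diabetes", 0.2),
        ("ethnicity", 0.1),
        ("site", 0.1),
    )
    #: years added to the case age mean (covariate-status confounding knob).
    confounding_age_shift: float = 0.0


def default_config(**overrides) -> SimConfig:
    return replace(SimConfig(), **overrides)


def plant_decoupling(
    config: SimConfig,
    group_a: str,
    group_b: str,
    r_control: float,
    r_case: float = 0.0,
    n_pairs: int | None = None,
) -> SimConfig:
    """Return a config with control-only cross-group correlations planted.

    With ``n_pairs=None`` the whole cross block is planted: every pair of
    one metabolite from ``group_a`` and one from ``group_b`` correlates
    ``r_control`` in controls and ``r_case`` in cases (the group-factor
    model of coordinated decoupling). With an integer ``n_pairs``, member
    ``i`` of each group is matched to member ``i`` for i < n_pairs, giving
    nearly independent planted pairs instead. Infeasible (non-PSD)
    combinations are rejected when the simulator is built.
    """
    if n_pairs is None:
        extra = ((group_a, group_b, float(r_control), float(r_case)),)
        return replace(config, planted_cross=config.planted_cross + extra)
    pairs = tuple(
        (group_a, i, group_b, i, float(r_control), float(r_case))
        for i in range(n_pairs)
    )
    return replace(
        config, planted_cross_pairs=config.planted_cross_pairs + pairs
    )


@dataclass
class SimulationTruth:
    """Ground-truth record for a simulated cohort."""

    logfc: pd.Series
    group_direction: dict[str, str]
    planted_pairs: pd.DataFrame  # metabolite_a, metabolite_b, r_control, r_case
    censor_threshold: pd.Series
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "logfc": {k: float(v) for k, v in self.logfc.items() if v != 0},
            "group_direction": self.group_direction,
            "planted_pairs": self.planted_pairs.to_dict(orient="records"),
            "censor_threshold": {
                k: (None if not np.isfinite(v) else float(v))
                for k, v in self.censor_threshold.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


class CohortSimulator:
    """Reusable simulator: builds the correlation structure once per config.

    ``__init__`` lays out groups, planted effects and the two status-specific
    correlation matrices (validated positive semi-definite, Cholesky
    factored); :meth:`generate` draws a cohort for a seed. Re-using one
    simulator across seeds amortizes the factorization in Monte-Carlo loops.
    """

    def __init__(self, config: SimConfig = SimConfig()):
        self.config = config
        cfg = config
        if not 0 <= cfg.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {cfg.rho}")

        # ---- group layout ---------------------------------------------------
        special = dict(cfg.special_groups)
        n_special = sum(special.values())
        if n_special > cfg.n_metabolites:
            raise ValueError("special groups exceed n_metabolites")
        n_generic_groups = cfg.n_groups - len(special)
        if n_generic_groups < 0:
            raise ValueError("more special groups than n_groups")
        n_generic = cfg.n_metabolites - n_special
        if n_generic_groups == 0:
            if n_generic:
                raise ValueError(
                    "no generic groups available for the remaining metabolites"
                )
            sizes: list[int] = []
        else:
            sizes = [n_generic // n_generic_groups] * n_generic_groups
            for i in range(n_generic % n_generic_groups):
                sizes[i] += 1
        group_names: list[str] = []
        group_of: list[str] = []
        met_ids: list[str] = []
        self.members: dict[str, list[str]] = {}
        for gname, size in list(special.items()) + [
            (f"group_{i + 1:02d}", s) for i, s in enumerate(sizes)
        ]:
            ids = [f"{gname}.m{j + 1:03d}" for j in range(size)]
            self.members[gname] = ids
            met_ids.extend(ids)
            group_of.extend([gname] * size)
            group_names.append(gname)
        self.metabolite_ids = met_ids
        self.group_of = pd.Series(group_of, index=met_ids, name="group")

        # ---- planted logFC --------------------------------------------------
        logfc = pd.Series(0.0, index=met_ids, name="logfc")
        direction: dict[str, str] = {}
        for gname, values in cfg.planted_logfc:
            ids = self.members[gname]
            vals = list(values) + [values[-1]] * (len(ids) - len(values))
            logfc.loc[ids] = vals[: len(ids)]
            mean_v = float(np.mean(vals[: len(ids)]))
            direction[gname] = "up" if mean_v > 0 else "down"
        self.logfc = logfc
        self.group_direction = direction

        # ---- correlation matrices -------------------------------------------
        m = cfg.n_metabolites
        base = np.zeros((m, m))
        pos = {mid: i for i, mid in enumerate(met_ids)}
        rho_of = dict(cfg.group_rho)
        start = 0
        for gname in self.members:
            size = len(self.members[gname])
            blk = slice(start, start + size)
            base[blk, blk] = rho_of.get(gname, cfg.rho)
            start += size
        np.fill_diagonal(base, 1.0)

        pairs = []
        corr = {"case": base.copy(), "control": base.copy()}
        for ga, gb, r_ctrl, r_case in cfg.planted_cross:
            if ga == gb:
                raise ValueError("cross-correlation blocks need two distinct groups")
            ia = np.array([pos[a] for a in self.members[ga]])
            ib = np.array([pos[b] for b in self.members[gb]])
            corr["control"][np.ix_(ia, ib)] = r_ctrl
            corr["control"][np.ix_(ib, ia)] = r_ctrl
            corr["case"][np.ix_(ia, ib)] = r_case
            corr["case"][np.ix_(ib, ia)] = r_case
            for a in self.members[ga]:
                for b in self.members[gb]:
                    pairs.append(
                        {"metabolite_a": a, "metabolite_b": b,
                         "r_control": r_ctrl, "r_case": r_case}
                    )
        for ga, ia, gb, ib, r_ctrl, r_case in cfg.planted_cross_pairs:
            a, b = self.members[ga][ia], self.members[gb][ib]
            i, j = pos[a], pos[b]
            corr["control"][i, j] = corr["control"][j, i] = r_ctrl
            corr["case"][i, j] = corr["case"][j, i] = r_case
            pairs.append(
                {"metabolite_a": a, "metabolite_b": b,
                 "r_control": r_ctrl, "r_case": r_case}
            )
        self.planted_pairs = pd.DataFrame(
            pairs, columns=["metabolite_a", "metabolite_b", "r_control", "r_case"]
        )

        self._chol: dict[str, np.ndarray] = {}
        for status, C in corr.items():
            w = np.linalg.eigvalsh(C)
            if w.min() < -1e-10:
                raise ValueError(
                    f"planted correlation matrix for {status} samples is not "
                    f"positive semi-definite (min eigenvalue {w.min():.3g})"
                )
            # tiny jitter guards numerically-semidefinite matrices
            self._chol[status] = np.linalg.cholesky(
                C + np.eye(m) * max(1e-10, -w.min() * 2 + 1e-12)
            )

        # superclass: xenobiotic group flagged, all others share a bland label
        self.superclass = pd.Series(
            [XENOBIOTIC_SUPERCLASS if g == XENO else "endogenous"
             for g in self.group_of],
            index=met_ids, name="superclass",
        )

    # -------------------------------------------------------------------------
    def generate(
        self, seed: int, censor: bool = True
    ) -> tuple[AbundanceMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
        """Draw one cohort: (matrix, metadata, annotation, truth)."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        n = cfg.n_case + cfg.n_control
        m = cfg.n_metabolites
        status = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]

        # covariates
        age = rng.normal(62.0, 8.0, n)
        age[status == "case"] += cfg.confounding_age_shift
        sex = rng.choice(["F", "M"], n, p=[0.55, 0.45])
        diabetes = rng.choice(["no", "yes"], n, p=[0.85, 0.15])
        bmi = rng.normal(27.0, 4.0, n)
        ethnicity = rng.choice(["caucasian", "asian", "other"], n, p=[0.8, 0.1, 0.1])
        site = rng.choice(["london", "melbourne", "lajolla", "leeds"], n)
        metadata = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "status": status,
                "sex": sex,
                "age": np.round(age, 1),
                "diabetes": diabetes,
                "ethnicity": ethnicity,
                "bmi": np.round(bmi, 1),
                "site": site,
            },
            index=sample_ids,
        )

        # per-metabolite baseline and SD
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, m)
        sds = np.exp(rng.normal(0.0, cfg.sd_log_sigma, m))

        # correlated noise per status
        Z = np.empty((n, m))
        is_case = status == "case"
        for stat, mask in (("case", is_case), ("control", ~is_case)):
            E = rng.standard_normal((int(mask.sum()), m))
            Z[mask] = E @ self._chol[stat].T
        X = baseline[None, :] + (Z * sds[None, :])
        X[is_case] += self.logfc.to_numpy()[None, :]

        # linear covariate effects with per-metabolite random coefficients
        effects = dict(cfg.covariate_effects)
        design_cols: list[tuple[np.ndarray, float]] = []
        if "age" in effects:
            design_cols.append((age - 62.0, effects["age"]))
        if "bmi" in effects:
            design_cols.append((bmi - 27.0, effects["bmi"]))
        if "sex" in effects:
            design_cols.append(((sex == "M").astype(float), effects["sex"]))
        if "diabetes" in effects:
            design_cols.append(((diabetes == "yes").astype(float), effects["diabetes"]))
        if "ethnicity" in effects:
            for lev in ("asian", "other"):
                design_cols.append(((ethnicity == lev).astype(float), effects["ethnicity"]))
        if "site" in effects:
            for lev in ("melbourne", "lajolla", "leeds"):
                design_cols.append(((site == lev).astype(float), effects["site"]))
        for col, tau in design_cols:
            beta = rng.normal(0.0, tau, m)
            X += col[:, None] * beta[None, :]

        # left-censoring at a per-metabolite detection-limit quantile
        thresholds = pd.Series(-np.inf, index=self.metabolite_ids, name="threshold")
        mask = np.zeros((n, m), dtype=bool)
        if censor:
            heavy = rng.random(m) < cfg.heavy_censor_fraction
            q = np.where(
                heavy,
                rng.uniform(*cfg.heavy_censor_range, m),
                rng.uniform(*cfg.light_censor_range, m),
            )
            for j in range(m):
                if q[j] <= 0:
                    continue
                thr = np.quantile(X[:, j], q[j])
                col_mask = X[:, j] < thr
                mask[:, j] = col_mask
                thresholds.iloc[j] = thr

        values = pd.DataFrame(X, index=sample_ids, columns=self.metabolite_ids)
        values = values.mask(pd.DataFrame(mask, index=sample_ids,
                                          columns=self.metabolite_ids))
        matrix = AbundanceMatrix(
            values=values,
            missing_mask=pd.DataFrame(mask, index=sample_ids,
                                      columns=self.metabolite_ids),
            state="raw",
            log=[f"simulated cohort seed={seed}"],
        )
        annotation = pd.DataFrame(
            {
                "metabolite_id": self.metabolite_ids,
                "group": self.group_of.to_numpy(),
                "superclass": self.superclass.to_numpy(),
                "is_xenobiotic": (self.superclass == XENOBIOTIC_SUPERCLASS).to_numpy(),
            },
            index=self.metabolite_ids,
        )
        truth = SimulationTruth(
            logfc=self.logfc.copy(),
            group_direction=dict(self.group_direction),
            planted_pairs=self.planted_pairs.copy(),
            censor_threshold=thresholds,
            seed=seed,
        )
        return matrix, metadata, annotation, truth


def generate_cohort(
    config: SimConfig = SimConfig(), seed: int = 0, censor: bool = True
) -> tuple[AbundanceMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """One-shot convenience wrapper over :class:`CohortSimulator`."""
    return CohortSimulator(config).generate(seed, censor=censor)
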