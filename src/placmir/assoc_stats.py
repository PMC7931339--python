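"""Cohort statistics: sex-by-treatment models, association regressions, Spearman.

Three analyses cover the cohort layer:

* ``fit_group_sex_models`` — OLS of an outcome on treatment and sex, fitted
  once without and once with the sex-by-treatment interaction.  The
  main-effect p-values come from the additive model; the interaction p and
  the four exploratory pairwise cell contrasts (Con-M vs Con-F, N3-M vs
  N3-F, N3-F vs Con-F, N3-M vs Con-M) come from the interaction model, with
  homoscedastic t-based inference.  Skewed analytes (amino acids) can be
  natural-log transformed before fitting.
* ``association_model`` — Model 1 is a simple regression of outcome on
  predictor; Model 2 adds baseline taurine and tryptophan, sex and group as
  confounders (plus breastfeeding status for postnatal outcomes).  Reports
  beta, t-based 95% CI and two-sided p, with listwise deletion and per-model
  n.  No multiplicity correction is applied anywhere.
* ``spearman_banded`` — Spearman rho with midranks; exact two-sided
  permutation p for n <= 9, t approximation otherwise; |rho| banded as
  weak (< 0.4), moderate (0.4 to < 0.7), strong (>= 0.7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupSexFit",
    "AssociationResult",
    "fit_group_sex_models",
    "association_model",
    "spearman_banded",
    "correlation_band",
]

CELLS = ("Con-F", "Con-M", "N3-F", "N3-M")
CONTRASTS = ("Con-M vs Con-F", "N3-M vs N3-F", "N3-F vs Con-F", "N3-M vs Con-M")

SPEARMAN_EXACT_MAX_N = 9


@dataclass
class GroupSexFit:
    n: int
    p_treatment: float
    p_sex: float
    p_interaction: float
    contrasts: dict[str, tuple[float, float, float]]  # name -> (estimate, se, p)
    cell_means: dict[str, float]  # fitted means from the interaction model


@dataclass
class AssociationResult:
    outcome: str
    predictor: str
    model: int
    n: int
    beta: float
    ci95: tuple[float, float]
    p: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.beta <= hi:
            raise ValueError("beta outside its own confidence interval")


def _check_cells(df: pd.DataFrame) -> None:
    counts = df.groupby(["group", "sex"]).size()
    for cell in CELLS:
        g, s = cell.split("-")
        if counts.get((g, s), 0) == 0:
            raise ValueError(f"group-sex cell {cell} is empty")


def fit_group_sex_models(
    y: Sequence[float] | pd.Series,
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    log_y: bool = False,
) -> GroupSexFit:
    """Additive and interaction OLS models of y on treatment and sex."""
    df = cohort.copy()
    df["_y"] = np.asarray(y, dtype=float)
    cols = ["_y", "group", "sex", *covariates]
    df = df.dropna(subset=cols)
    _check_cells(df)
    if log_y:
        if (df["_y"] <= 0).any():
            raise ValueError("log transform requires strictly positive outcome")
        df["_y"] = np.log(df["_y"])

    trt = (df["group"] == "N3").astype(float).to_numpy()
    male = (df["sex"] == "M").astype(float).to_numpy()
    covs = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    yv = df["_y"].to_numpy()

    X_add = np.column_stack([np.ones(len(df)), trt, male, covs])
    X_int = np.column_stack([np.ones(len(df)), trt, male, trt * male, covs])
    if np.linalg.matrix_rank(X_add) < X_add.shape[1]:
        raise ValueError("singular design matrix in additive model")
    res_add = sm.OLS(yv, X_add).fit()
    res_int = sm.OLS(yv, X_int).fit()

    k = X_int.shape[1]
    # parameter order: const, trt, male, trt*male, covariates...
    def L(*weights: float) -> np.ndarray:
        v = np.zeros(k)
        v[: len(weights)] = weights
        return v

    contrast_vecs = {
        "Con-M vs Con-F": L(0, 0, 1, 0),
        "N3-M vs N3-F": L(0, 0, 1, 1),
        "N3-F vs Con-F": L(0, 1, 0, 0),
        "N3-M vs Con-M": L(0, 1, 0, 1),
    }
    contrasts = {}
    for name, vec in contrast_vecs.items():
        t = res_int.t_test(vec)
        contrasts[name] = (
            float(np.ravel(t.effect)[0]),
            float(np.ravel(t.sd)[0]),
            float(np.ravel(t.pvalue)[0]),
        )

    b = res_int.params
    covmean = covs.mean(axis=0) if covariates else np.empty(0)
    base = float(covmean @ b[4:]) if covariates else 0.0
    cell_means = {
        "Con-F": float(b[0]) + base,
        "Con-M": float(b[0] + b[2]) + base,
        "N3-F": float(b[0] + b[1]) + base,
        "N3-M": float(b[0] + b[1] + b[2] + b[3]) + base,
    }
    return GroupSexFit(
        n=len(df),
        p_treatment=float(res_add.pvalues[1]),
        p_sex=float(res_add.pvalues[2]),
        p_interaction=float(res_int.pvalues[3]),
        contrasts=contrasts,
        cell_means=cell_means,
    )


MODEL2_COVARIATES = ("p15_tau", "p15_trp")


def association_model(
    outcome: str,
    predictor: str,
    model: int,
    cohort: pd.DataFrame,
    postnatal: bool = False,
) -> AssociationResult:
    """Model 1 (unadjusted) or Model 2 (adjusted) association regression.

    Model 2 confounders: baseline (week-15) taurine and tryptophan, sex and
    group, plus breastfeeding status for postnatal outcomes.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    cols = [outcome, predictor]
    extra: list[str] = []
    if model == 2:
        extra = [*MODEL2_COVARIATES, "sex", "group"]
        if postnatal:
            extra.append("breastfeeding")
    df = cohort.dropna(subset=cols + extra)
    n = len(df)

    parts = [np.ones(n), df[predictor].to_numpy(dtype=float)]
    if model == 2:
        parts += [df[c].to_numpy(dtype=float) for c in MODEL2_COVARIATES]
        parts.append((df["sex"] == "M").astype(float).to_numpy())
        parts.append((df["group"] == "N3").astype(float).to_numpy())
        if postnatal:
            parts.append((df["breastfeeding"] == "fully").astype(float).to_numpy())
    X = np.column_stack(parts)
    if n < X.shape[1] + 2:
        raise ValueError(
            f"insufficient complete cases for {outcome}~{predictor} model {model}: "
            f"need >= {X.shape[1] + 2}, have {n}"
        )
    res = sm.OLS(df[outcome].to_numpy(dtype=float), X).fit()
    ci = res.conf_int(alpha=0.05)
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        model=model,
        n=n,
        beta=float(res.params[1]),
        ci95=(float(ci[1][0]), float(ci[1][1])),
        p=float(res.pvalues[1]),
    )


def correlation_band(rs: float) -> str:
    a = abs(rs)
    if a < 0.4:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


def spearman_banded(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, str]:
    """Spearman rho, two-sided p, and the weak/moderate/strong band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("spearman_banded needs at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])

    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(permutations(range(n))), dtype=np.int16)
        R = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        Rc = R - R.mean(axis=1, keepdims=True)
        denom = math.sqrt(float(rxc @ rxc)) * np.sqrt((Rc**2).sum(axis=1))
        rho_perm = (Rc @ rxc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rs) - 1e-12))
    else:
        t = rs * math.sqrt((n - 2) / max(1e-300, 1.0 - rs**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rs, min(p, 1.0), correlation_band(rs)
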