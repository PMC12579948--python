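"""Comparative statistics: strike selection, correlation-matrix PCA with
broken-stick significance, phylogenetic generalized linear mixed models
(PGLMMs), pairwise contrasts, and hunting-style classification.

The PGLMM is a Gaussian mixed model

    y = X beta + a + u + eps,
    a ~ N(0, sigma2_phylo * Sigma_tree)   (species level),
    u ~ N(0, sigma2_species * I)          (species level),
    eps ~ N(0, sigma2_resid * I),

where Sigma_tree is the unit-height shared-branch-length covariance.  It is
fitted by direct profile optimization of the two variance ratios under
restricted maximum likelihood; the ML log-likelihood at the same ratios
feeds AICc.  Phylogenetic signal is reported as the variance-share form of
Pagel's lambda, sigma2_phylo / (sigma2_phylo + sigma2_species + sigma2_resid).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .exceptions import ConvergenceError
from .phylo import build_phylo_covariance

__all__ = [
    "PCAResult",
    "BrokenStickResult",
    "PGLMMFit",
    "select_fastest",
    "individual_means",
    "pca_correlation",
    "broken_stick",
    "build_phylo_covariance",
    "fit_pglmm",
    "aicc_compare",
    "pairwise_contrasts",
    "classify_hunting_style",
]


# ---------------------------------------------------------------------------
# strike selection

def select_fastest(
    strikes: pd.DataFrame,
    k: int = 3,
    femur_col: str = "Femur AV",
    tibia_col: str = "Tibia AV",
    individual_col: str = "individual",
    trial_col: str = "trial",
) -> pd.DataFrame:
    """Keep the ``k`` maximally motivated attempts per individual.

    Attempts are ranked within each individual by the sum of within-individual
    z-scores of the femur and tibia angular-velocity maxima; ties break by
    femur angular velocity (descending) then trial id (ascending).
    Individuals with fewer than ``k`` attempts keep them all, with a warning.
    """
    if strikes.empty:
        raise ValueError("strike table is empty")

    def zscore(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(0.0, index=x.index)
        return (x - x.mean()) / sd

    score = (strikes.groupby(individual_col)[femur_col].transform(zscore)
             + strikes.groupby(individual_col)[tibia_col].transform(zscore))

    kept = []
    for ind, grp in strikes.assign(_score=score).groupby(individual_col, sort=False):
        if len(grp) < k:
            warnings.warn(
                f"individual {ind!r} has only {len(grp)} attempts (< {k}); keeping all",
                stacklevel=2,
            )
        order = grp.sort_values(
            ["_score", femur_col, trial_col], ascending=[False, False, True]
        )
        kept.append(order.head(k))
    return pd.concat(kept).drop(columns="_score")


def individual_means(
    strikes: pd.DataFrame,
    individual_col: str = "individual",
    group_cols: Sequence[str] = ("species", "camouflage"),
) -> pd.DataFrame:
    """Arithmetic mean per individual of every numeric column; grouping labels
    (species, camouflage) are carried through."""
    numeric = strikes.select_dtypes(include=[np.number]).columns
    agg = {c: "mean" for c in numeric}
    for c in group_cols:
        if c in strikes.columns:
            agg[c] = "first"
    return strikes.groupby(individual_col, sort=False).agg(agg).reset_index()


# ---------------------------------------------------------------------------
# PCA and broken stick

@dataclass
class PCAResult:
    """Correlation-matrix PCA: orthonormal loadings, scores, variance shares."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    proportion_variance: pd.Series
    cumulative_variance: pd.Series


def pca_correlation(table: pd.DataFrame, variables: Sequence[str]) -> PCAResult:
    """PCA of z-scored variables (correlation matrix).

    Component signs are oriented so each component's largest-magnitude
    loading is positive.  Proportions of variance sum to 1 exactly because
    the correlation matrix has unit trace per variable.
    """
    X = table.loc[:, list(variables)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains missing values")
    sd = X.std(axis=0, ddof=1)
    dead = [v for v, s in zip(variables, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    Z = (X - X.mean(axis=0)) / sd

    p = Z.shape[1]
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(p):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    pcs = [f"PC{i + 1}" for i in range(p)]
    loadings = pd.DataFrame(eigvec, index=list(variables), columns=pcs)
    scores = pd.DataFrame(Z @ eigvec, index=table.index, columns=pcs)
    prop = pd.Series(eigval / p, index=pcs)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        proportion_variance=prop,
        cumulative_variance=prop.cumsum(),
    )


@dataclass
class BrokenStickResult:
    """Broken-stick null proportions and the count of significant components."""

    expected: np.ndarray
    n_significant: int


def broken_stick(proportions: Sequence[float]) -> BrokenStickResult:
    """Broken-stick significance count for PCA variance proportions.

    The null expectation for component k of p is
    ``b_k = (1/p) * sum_{i=k}^{p} 1/i``.  Components are counted significant
    while the observed proportion exceeds b_k, stopping at the first failure.
    """
    prop = np.asarray(proportions, dtype=float)
    if np.any(prop < 0):
        raise ValueError("proportions must be non-negative")
    if abs(prop.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {prop.sum():.8f}")
    p = prop.size
    inv = 1.0 / np.arange(1, p + 1)
    expected = np.cumsum(inv[::-1])[::-1] / p
    n_sig = 0
    for obs, exp in zip(prop, expected):
        if obs > exp:
            n_sig += 1
        else:
            break
    return BrokenStickResult(expected=expected, n_significant=n_sig)


# ---------------------------------------------------------------------------
# PGLMM

@dataclass
class PGLMMFit:
    """A fitted phylogenetic mixed model."""

    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    vcov_beta: pd.DataFrame
    sigma2_phylo: float
    sigma2_species: float
    sigma2_resid: float
    lambda_: float
    loglik_reml: float
    loglik_ml: float
    aicc: float
    n: int
    k: int
    converged: bool
    design: dict = field(default_factory=dict, repr=False)


def _design_matrix(
    data: pd.DataFrame,
    fixed_effects: Sequence[str],
) -> tuple[np.ndarray, list[str], dict]:
    """Treatment-coded design matrix with intercept; returns design info for
    marginal-mean construction."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["(Intercept)"]
    info: dict = {"factors": {}, "numeric_means": {}}
    for col in fixed_effects:
        s = data[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            info["factors"][col] = levels
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{col}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(col)
            info["numeric_means"][col] = float(s.mean())
    return np.column_stack(cols), names, info


def _pglmm_loglik(
    gammas: tuple[float, float],
    y: np.ndarray,
    X: np.ndarray,
    K_phylo: np.ndarray,
    K_species: np.ndarray,
) -> tuple[float, float, np.ndarray, float, np.ndarray]:
    """Profiled REML and ML log-likelihoods at variance ratios ``gammas``.

    Returns (loglik_reml, loglik_ml, beta, sigma2_resid_reml, cov_beta_unscaled).
    """
    gp, gs = gammas
    n, p = X.shape
    V = np.eye(n) + gp * K_phylo + gs * K_species
    try:
        cF = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, -np.inf, np.full(p, np.nan), np.nan, np.full((p, p), np.nan)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cF))))
    Xi = np.linalg.solve(cF, X)
    yi = np.linalg.solve(cF, y)
    XtWX = Xi.T @ Xi
    XtWy = Xi.T @ yi
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf, -np.inf, np.full(p, np.nan), np.nan, np.full((p, p), np.nan)
    r = yi - Xi @ beta
    q = float(r @ r)
    sign, logdetXtWX = np.linalg.slogdet(XtWX)
    if sign <= 0 or q <= 0:
        return -np.inf, -np.inf, beta, np.nan, np.linalg.pinv(XtWX)
    s2_reml = q / (n - p)
    s2_ml = q / n
    ll_reml = -0.5 * ((n - p) * (math.log(2 * math.pi * s2_reml) + 1.0)
                      + logdetV + logdetXtWX)
    ll_ml = -0.5 * (n * (math.log(2 * math.pi * s2_ml) + 1.0) + logdetV)
    return ll_reml, ll_ml, beta, s2_reml, np.linalg.inv(XtWX)


def fit_pglmm(
    data: pd.DataFrame,
    response: str,
    fixed_effects: Sequence[str],
    tree: dendropy.Tree,
    species_col: str = "species",
    fix_gamma_phylo: float | None = None,
    fix_gamma_species: float | None = None,
) -> PGLMMFit:
    """Fit the phylogenetic mixed model by profile REML.

    ``fix_gamma_phylo`` / ``fix_gamma_species`` pin the corresponding
    variance ratio (sigma2 component / sigma2_resid), which reduces the model
    to an ordinary two-level mixed model (phylo ratio 0) or OLS (both 0).
    Boundary estimates (a component at zero) are reported, not errors.
    """
    work = data.dropna(subset=[response, species_col, *fixed_effects])
    species = work[species_col].astype(str)
    labels = list(dict.fromkeys(species))
    if len(labels) < 2:
        raise ValueError("PGLMM needs >= 2 species")
    sigma = build_phylo_covariance(tree, labels).to_numpy()

    y = work[response].to_numpy(dtype=float)
    X, names, info = _design_matrix(work, fixed_effects)
    n, p = X.shape
    Z = pd.get_dummies(pd.Categorical(species, categories=labels)) \
        .to_numpy(dtype=float)
    K_phylo = Z @ sigma @ Z.T
    K_species = Z @ Z.T

    def negll(theta: np.ndarray) -> float:
        gp = fix_gamma_phylo if fix_gamma_phylo is not None else theta[0]
        gs = fix_gamma_species if fix_gamma_species is not None else theta[-1]
        ll, *_ = _pglmm_loglik((max(gp, 0.0), max(gs, 0.0)), y, X,
                               K_phylo, K_species)
        return -ll

    free = int(fix_gamma_phylo is None) + int(fix_gamma_species is None)
    if free == 0:
        gp, gs = fix_gamma_phylo, fix_gamma_species
        converged = True
    else:
        starts = [(0.0, 0.0), (0.5, 0.5), (2.0, 0.1), (0.1, 2.0),
                  (10.0, 10.0), (20.0, 0.5), (0.5, 20.0), (100.0, 1.0)]
        best, best_val = None, np.inf
        for s0 in starts:
            x0 = np.array(s0[:free], dtype=float) if free == 1 else np.array(s0)
            res = optimize.minimize(
                negll, x0, method="L-BFGS-B",
                bounds=[(0.0, 1e7)] * free,
                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
            )
            if res.fun < best_val:
                best, best_val = res, res.fun
        if best is None or not np.isfinite(best_val):
            raise ConvergenceError("PGLMM optimizer failed at every start")
        # polish the winner with a derivative-free pass (the profiled REML
        # surface is flat near boundaries, where quasi-Newton steps stall)
        polish = optimize.minimize(
            negll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if polish.fun < best_val:
            best, best_val = polish, polish.fun
        converged = bool(best.success)
        theta = np.clip(best.x, 0.0, None)
        gp = fix_gamma_phylo if fix_gamma_phylo is not None else float(theta[0])
        gs = fix_gamma_species if fix_gamma_species is not None else float(theta[-1])

    ll_reml, ll_ml, beta, s2e, cov_unscaled = _pglmm_loglik(
        (gp, gs), y, X, K_phylo, K_species)
    if not np.isfinite(ll_reml):
        raise ConvergenceError("PGLMM likelihood not finite at the optimum")

    s2p = gp * s2e
    s2s = gs * s2e
    total = s2p + s2s + s2e
    lam = s2p / total if total > 0 else 0.0
    vcov = s2e * cov_unscaled
    se = np.sqrt(np.diag(vcov))
    zval = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(zval))

    k = p + 3  # fixed effects + three variance components
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    aicc = -2.0 * ll_ml + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    info.update({"fixed_effects": list(fixed_effects), "names": names})
    return PGLMMFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        vcov_beta=pd.DataFrame(vcov, index=names, columns=names),
        sigma2_phylo=float(s2p),
        sigma2_species=float(s2s),
        sigma2_resid=float(s2e),
        lambda_=float(lam),
        loglik_reml=float(ll_reml),
        loglik_ml=float(ll_ml),
        aicc=float(aicc),
        n=n,
        k=k,
        converged=converged,
        design=info,
    )


def aicc_compare(fits: Mapping[str, PGLMMFit]) -> pd.DataFrame:
    """Rank models by AICc (ascending).  All fits must share the same rows."""
    ns = {f.n for f in fits.values()}
    if len(ns) != 1:
        raise ValueError("models compared by AICc must be fitted to identical rows")
    rows = [
        {"model": name, "logLik_ML": f.loglik_ml, "k": f.k, "n": f.n,
         "AICc": f.aicc, "lambda": f.lambda_}
        for name, f in fits.items()
    ]
    out = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    out["delta_AICc"] = out["AICc"] - out["AICc"].iloc[0]
    return out


def _marginal_mean_row(fit: PGLMMFit, factor: str, level: str) -> np.ndarray:
    names = fit.design["names"]
    row = np.zeros(len(names))
    row[names.index("(Intercept)")] = 1.0
    col = f"{factor}[{level}]"
    if col in names:
        row[names.index(col)] = 1.0
    for num, mean in fit.design["numeric_means"].items():
        if num in names:
            row[names.index(num)] = mean
    for other, levels in fit.design["factors"].items():
        if other == factor:
            continue
        for lev in levels[1:]:
            c = f"{other}[{lev}]"
            if c in names:
                row[names.index(c)] = 1.0 / len(levels)
    return row


def pairwise_contrasts(
    fit: PGLMMFit,
    factor: str = "camouflage",
    adjust: str = "none",
) -> pd.DataFrame:
    """All pairwise differences of estimated marginal means for ``factor``.

    Marginal means evaluate each level with numeric covariates at their data
    means (and any other factors averaged over their levels).  P-values are
    Wald by default; ``adjust="tukey"`` applies the studentized-range
    correction.
    """
    if factor not in fit.design["factors"]:
        raise ValueError(f"{factor!r} is not a fixed-effect factor of this model")
    levels = fit.design["factors"][factor]
    beta = fit.beta.to_numpy()
    V = fit.vcov_beta.to_numpy()
    rows = []
    m = len(levels)
    df = fit.n - fit.k
    for i in range(m):
        for j in range(i + 1, m):
            c = _marginal_mean_row(fit, factor, levels[i]) \
                - _marginal_mean_row(fit, factor, levels[j])
            est = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            z = est / se if se > 0 else np.nan
            if adjust == "tukey":
                pval = float(sps.studentized_range.sf(abs(z) * math.sqrt(2.0), m, df))
            elif adjust == "none":
                pval = float(2.0 * sps.norm.sf(abs(z)))
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append({"contrast": f"{levels[i]} - {levels[j]}",
                         "estimate": est, "se": se, "z": z, "p": pval})
    return pd.DataFrame(rows)


def add_within_species_centering(
    data: pd.DataFrame,
    cols: Sequence[str],
    species_col: str = "species",
) -> pd.DataFrame:
    """Split continuous predictors into species means and within-species
    deviations (``<col>_species_mean`` and ``<col>_within`` columns)."""
    out = data.copy()
    for col in cols:
        means = out.groupby(species_col)[col].transform("mean")
        out[f"{col}_species_mean"] = means
        out[f"{col}_within"] = out[col] - means
    return out


# ---------------------------------------------------------------------------
# hunting-style classification

def classify_hunting_style(
    coxa_start_angle_deg: float | np.ndarray,
    cut_deg: float = 50.0,
):
    """Classify strikes as ``anterograde`` (coxa start angle > 50 deg) or
    ``basigrade`` (<= 50 deg; the boundary is assigned basigrade)."""
    a = np.asarray(coxa_start_angle_deg, dtype=float)
    if np.any((a < 0) | (a >= 180)):
        raise ValueError("coxa start angle must lie in [0, 180)")
    out = np.where(a > cut_deg, "anterograde", "basigrade")
    if np.isscalar(coxa_start_angle_deg) or np.asarray(coxa_start_angle_deg).ndim == 0:
        return str(out)
    return out
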