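"""Confirmatory factor analysis by maximum likelihood.

Fits the covariance structure Sigma = Lambda Psi Lambda' + Theta with factor
variances fixed at 1 (all simple-structure loadings free) by minimizing the
normal-theory discrepancy

    F = log|Sigma| + tr(S Sigma^-1) - log|S| - p,

reporting chi-square = (N - 1) * F_min, CFI against the independence
baseline, RMSEA, and AIC = chi-square + 2q where q counts free parameters
including the saturated mean structure (p intercepts).  With saturated
means the mean structure contributes nothing to the discrepancy but does
enter the parameter and moment counts, so for a 9-item scale the
unidimensional model has df = 27 and the correlated two-factor model df = 26.

The one- versus two-factor comparison is the structural-validity check for
the severity scale: the unidimensional model is the two-factor model with
the factor correlation pinned at 1, so its fit can never be better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bank import ItemBank
from .responses import ResponseMatrix

__all__ = [
    "CfaModel",
    "CfaResult",
    "implied_covariance",
    "fit_cfa",
    "fit_indices",
    "baseline_model",
    "one_factor_model",
    "two_factor_model",
    "cov_from_responses",
]

_RESID_FLOOR_FRAC = 0.005  # Heywood floor as a fraction of the observed variance


@dataclass(frozen=True)
class CfaModel:
    """A confirmatory loading pattern with factor variances fixed at 1."""

    loading_pattern: np.ndarray  # items x factors, boolean
    mean_structure: bool = True

    def __post_init__(self) -> None:
        pattern = np.asarray(self.loading_pattern, dtype=bool)
        if pattern.ndim != 2:
            raise ValueError("loading pattern must be items x factors")
        if not np.all(pattern.sum(axis=1) == 1):
            raise ValueError("each item must load on exactly one factor")
        object.__setattr__(self, "loading_pattern", pattern)

    @property
    def n_items(self) -> int:
        return self.loading_pattern.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loading_pattern.shape[1]

    @property
    def n_free_params(self) -> int:
        p, k = self.n_items, self.n_factors
        q = p + p + k * (k - 1) // 2  # loadings + residuals + factor correlations
        if self.mean_structure:
            q += p
        return q

    @property
    def df(self) -> int:
        p = self.n_items
        moments = p * (p + 1) // 2 + (p if self.mean_structure else 0)
        return moments - self.n_free_params


def one_factor_model(n_items: int, mean_structure: bool = True) -> CfaModel:
    return CfaModel(np.ones((n_items, 1), dtype=bool), mean_structure=mean_structure)


def two_factor_model(pattern: np.ndarray | ItemBank, mean_structure: bool = True) -> CfaModel:
    """Two-factor simple-structure model from an explicit pattern or a bank."""
    if isinstance(pattern, ItemBank):
        pattern = pattern.loading_pattern
    return CfaModel(np.asarray(pattern, dtype=bool), mean_structure=mean_structure)


@dataclass
class CfaResult:
    model: CfaModel
    loadings: np.ndarray  # items x factors
    loading_se: np.ndarray | None
    residual_variances: np.ndarray
    factor_cov: np.ndarray
    chi_square: float
    df: int
    p_value: float
    CFI: float
    RMSEA: float
    AIC: float
    n_free_params: int
    N: int
    baseline_chi_square: float
    baseline_df: int
    F_min: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def loading_table(self, item_ids: list[str] | None = None) -> pd.DataFrame:
        p, k = self.loadings.shape
        if item_ids is None:
            item_ids = [f"item{j + 1}" for j in range(p)]
        data: dict = {"item_id": item_ids}
        for f in range(k):
            data[f"f{f + 1}"] = self.loadings[:, f]
            if self.loading_se is not None:
                data[f"f{f + 1}_se"] = self.loading_se[:, f]
        data["residual_variance"] = self.residual_variances
        return pd.DataFrame(data)

    def index_block(self) -> dict[str, float]:
        return {
            "CFI": self.CFI,
            "RMSEA": self.RMSEA,
            "AIC": self.AIC,
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p_value,
        }


def implied_covariance(
    loadings: np.ndarray, residual_variances: np.ndarray, factor_cov: np.ndarray
) -> np.ndarray:
    """Sigma = Lambda Psi Lambda' + Theta for diagonal Theta."""
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    residual_variances = np.asarray(residual_variances, dtype=float)
    factor_cov = np.atleast_2d(np.asarray(factor_cov, dtype=float))
    if np.any(residual_variances <= 0):
        raise ValueError("residual variances must be positive")
    if not np.allclose(np.diag(factor_cov), 1.0):
        raise ValueError("factor covariance must have unit diagonal (standardized factors)")
    np.linalg.cholesky(factor_cov)
    return loadings @ factor_cov @ loadings.T + np.diag(residual_variances)


def baseline_model(sample_cov: np.ndarray, N: int) -> tuple[float, int]:
    """Independence baseline: free variances (and means), zero covariances.

    Closed form: F_base = sum(log s_ii) - log|S|; df = p(p-1)/2.
    """
    S = np.asarray(sample_cov, dtype=float)
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is singular or not positive definite")
    F_base = float(np.sum(np.log(np.diag(S))) - logdet)
    p = S.shape[0]
    return (N - 1) * F_base, p * (p - 1) // 2


def fit_indices(
    chi_square: float,
    df: int,
    N: int,
    baseline_chi_square: float,
    baseline_df: int,
    q: int,
) -> dict[str, float]:
    """CFI, RMSEA, AIC (= chi-square + 2q) and the chi-square p-value."""
    if df < 1 or N < 2:
        raise ValueError("need df >= 1 and N >= 2")
    excess = max(chi_square - df, 0.0)
    base_excess = max(baseline_chi_square - baseline_df, excess, 0.0)
    CFI = 1.0 if base_excess == 0 else 1.0 - excess / base_excess
    CFI = float(np.clip(CFI, 0.0, 1.0))
    RMSEA = float(np.sqrt(excess / (df * (N - 1))))
    AIC = chi_square + 2 * q
    p_value = float(stats.chi2.sf(chi_square, df))
    return {"CFI": CFI, "RMSEA": RMSEA, "AIC": AIC, "p_value": p_value}


def _pack(model: CfaModel, loadings: np.ndarray, resid: np.ndarray, psi: np.ndarray) -> np.ndarray:
    lam = loadings[model.loading_pattern]
    iu = np.triu_indices(model.n_factors, k=1)
    return np.concatenate([lam, np.log(resid), np.arctanh(psi[iu])])


def _unpack(model: CfaModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p, k = model.n_items, model.n_factors
    lam = np.zeros((p, k))
    lam[model.loading_pattern] = x[:p]
    resid = np.exp(x[p : 2 * p])
    psi = np.eye(k)
    iu = np.triu_indices(k, k=1)
    vals = np.tanh(x[2 * p :])
    psi[iu] = vals
    psi[(iu[1], iu[0])] = vals
    return lam, resid, psi


def _discrepancy_and_grad(
    x: np.ndarray, model: CfaModel, S: np.ndarray, logdetS: float
) -> tuple[float, np.ndarray]:
    p, k = model.n_items, model.n_factors
    lam, resid, psi = _unpack(model, x)
    sigma = lam @ psi @ lam.T + np.diag(resid)
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(x)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    sigma_inv = np.linalg.inv(sigma)
    F = logdet + float(np.trace(S @ sigma_inv)) - logdetS - p
    G = sigma_inv @ (sigma - S) @ sigma_inv  # dF = tr(G dSigma)
    g_lam_full = 2.0 * (G @ lam @ psi)
    g_lam = g_lam_full[model.loading_pattern]
    g_resid = np.diag(G) * resid  # chain through log parameterization
    lgl = lam.T @ G @ lam
    iu = np.triu_indices(k, k=1)
    g_psi = 2.0 * lgl[iu] * (1.0 - psi[iu] ** 2)  # chain through arctanh
    return F, np.concatenate([g_lam, g_resid, g_psi])


def fit_cfa(
    sample_cov: np.ndarray,
    N: int,
    model: CfaModel,
    sample_means: np.ndarray | None = None,
    compute_se: bool = True,
) -> CfaResult:
    """Fit a confirmatory model to a sample covariance matrix.

    ``sample_means`` only documents the (saturated) mean structure; with
    means saturated they do not influence the discrepancy, but intercepts
    are counted among the free parameters for df and AIC.
    """
    S = np.asarray(sample_cov, dtype=float)
    p = model.n_items
    if S.shape != (p, p):
        raise ValueError("sample covariance does not match the model's item count")
    if N <= p:
        raise ValueError("need N greater than the number of items")
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")

    s_ii = np.diag(S)
    lam0 = np.zeros((p, model.n_factors))
    lam0[model.loading_pattern] = np.sqrt(0.5 * s_ii)
    resid0 = 0.5 * s_ii
    psi0 = np.eye(model.n_factors) * 1.0
    iu = np.triu_indices(model.n_factors, k=1)
    psi0[iu] = 0.3
    psi0[(iu[1], iu[0])] = 0.3
    x0 = _pack(model, lam0, resid0, psi0)

    res = optimize.minimize(
        _discrepancy_and_grad,
        x0,
        args=(model, S, logdetS),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    flags: list[str] = []
    converged = bool(res.success) or res.fun < 1e-9
    if not converged:
        flags.append(f"optimizer: {res.message}")
    lam, resid, psi = _unpack(model, res.x)
    floor = _RESID_FLOOR_FRAC * s_ii
    heywood = resid < floor
    if np.any(heywood):
        flags.append(
            "Heywood case: residual variance floored for items "
            + ", ".join(str(j) for j in np.flatnonzero(heywood))
        )
        resid = np.maximum(resid, floor)

    F_min = max(float(res.fun), 0.0)
    chi_square = (N - 1) * F_min
    df = model.df
    base_chi, base_df = baseline_model(S, N)
    q = model.n_free_params
    idx = fit_indices(chi_square, df, N, base_chi, base_df, q)

    loading_se = None
    if compute_se:
        loading_se = _loading_standard_errors(model, res.x, S, logdetS, N)

    return CfaResult(
        model=model,
        loadings=lam,
        loading_se=loading_se,
        residual_variances=resid,
        factor_cov=psi,
        chi_square=chi_square,
        df=df,
        p_value=idx["p_value"],
        CFI=idx["CFI"],
        RMSEA=idx["RMSEA"],
        AIC=idx["AIC"],
        n_free_params=q,
        N=N,
        baseline_chi_square=base_chi,
        baseline_df=base_df,
        F_min=F_min,
        converged=converged,
        flags=flags,
    )


def _loading_standard_errors(
    model: CfaModel, x_opt: np.ndarray, S: np.ndarray, logdetS: float, N: int
) -> np.ndarray:
    """Asymptotic SEs of the loadings from the numerical Hessian of F.

    Under normal-theory ML, acov(params) ~ (2 / (N - 1)) H^-1 with H the
    Hessian of the discrepancy at the minimum.
    """
    n = x_opt.size
    h = 1e-5
    H = np.zeros((n, n))
    grad = lambda x: _discrepancy_and_grad(x, model, S, logdetS)[1]
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        H[:, i] = (grad(x_opt + ei) - grad(x_opt - ei)) / (2 * h)
    H = (H + H.T) / 2.0
    p = model.n_items
    se = np.full((p, model.n_factors), np.nan)
    try:
        cov = 2.0 / (N - 1) * np.linalg.inv(H)
        lam_se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
        se[model.loading_pattern] = lam_se
    except np.linalg.LinAlgError:
        pass
    return se


def cov_from_responses(rm: ResponseMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    """Sample covariance (denominator N - 1), means and complete-case N.

    Categories are treated as numeric scores, matching ML factor analysis
    of ordinal items as commonly practised in scale validation; a
    polychoric correction is deliberately out of scope.
    """
    complete = rm.complete_cases()
    if complete.n_respondents < 2:
        raise ValueError("need at least 2 complete cases")
    X = complete.values
    S = np.cov(X, rowvar=False, ddof=1)
    return S, X.mean(axis=0), complete.n_respondents
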