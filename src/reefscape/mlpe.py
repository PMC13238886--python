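"""Maximum-likelihood population-effects (MLPE) mixed models for stacked
pairwise distance data.

Pairwise observations are not independent: two site pairs that share a site
are correlated.  The MLPE model (Clarke et al. 2002) handles this with a
residual correlation ``rho`` between rows of the same group that share
exactly one site, on top of an optional group (species/family) random
intercept:

    y = a + b x + u_group + e,   corr(e_r, e_s) = rho  iff r, s share a site.

The model is fitted by (restricted) maximum likelihood, profiling the error
variance out and optimizing numerically over ``rho`` in [0, 0.5) and the
variance ratio ``lambda = sigma2_u / sigma2_e``.  Covariance matrices are
assembled densely — the designs this package targets are tiny (a handful of
sites and tens of groups).

Wald inference on the slope uses a t reference distribution with
``n_pairs - n_groups - 1`` degrees of freedom by default; the convention is
recorded in the fit because it is one of several defensible choices for
pairwise designs.  Marginal and conditional R2 follow Nakagawa & Schielzeth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .pairwise import PairwiseMatrix

PAIR_COLUMNS = ["group", "site_i", "site_j", "response", "predictor"]

RHO_MAX = 0.499  # the sharing-structure correlation stays PD on [0, 0.5)
LAMBDA_MAX = 1e4


def build_pair_table(
    response_matrices: Mapping[str, PairwiseMatrix],
    predictor_matrix: PairwiseMatrix,
) -> pd.DataFrame:
    """Stack pairwise response matrices over a shared predictor matrix into
    long form (group, site_i, site_j, response, predictor).

    Rows with a flagged (non-finite) response or predictor cell are dropped.
    A predictor missing any site used by a response matrix is an error.
    """
    pred_sites = set(predictor_matrix.site_ids)
    rows = []
    n_dropped = 0
    for group, mat in response_matrices.items():
        missing = set(mat.site_ids) - pred_sites
        if missing:
            raise ValueError(
                f"predictor matrix lacks sites {sorted(missing)} used by "
                f"group {group!r}"
            )
        for si, sj, val in mat.pairs():
            x = predictor_matrix.get(si, sj)
            if not (np.isfinite(val) and np.isfinite(x)):
                n_dropped += 1
                continue
            rows.append(
                {"group": group, "site_i": si, "site_j": sj,
                 "response": val, "predictor": x}
            )
    table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    table.attrs["n_dropped"] = n_dropped
    return table


@dataclass
class MLPEFit:
    slope: float
    slope_se: float
    intercept: float
    rho: float
    sigma2_u: float
    sigma2_e: float
    loglik: float            # value of the fitted criterion (REML or ML)
    loglik_ml: float         # ML log-likelihood evaluated at the estimates
    p_value: float
    df: int
    df_method: str
    r2m: float
    r2c: float
    reml: bool
    random_intercept: bool
    n_obs: int
    n_groups: int
    converged: bool
    boundary_sigma_u: bool
    message: str = ""


def _validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing_cols:
        raise ValueError(f"pair table missing columns: {missing_cols}")
    if not np.isfinite(pairs["response"]).all() or not np.isfinite(pairs["predictor"]).all():
        raise ValueError("pair table contains non-finite response/predictor values")
    if (pairs["site_i"] == pairs["site_j"]).any():
        raise ValueError("pair table contains self-pairs (site_i == site_j)")
    key = pairs.apply(
        lambda r: (r["group"],) + tuple(sorted((r["site_i"], r["site_j"]))), axis=1
    )
    if key.duplicated().any():
        raise ValueError("an unordered site pair appears twice within a group")
    return pairs.reset_index(drop=True)


def _share_matrix(pair_sites: Sequence[tuple[str, str]]) -> np.ndarray:
    """S[r, s] = 1 if unordered pairs r and s share exactly one site."""
    n = len(pair_sites)
    sets = [frozenset(p) for p in pair_sites]
    S = np.zeros((n, n))
    for r in range(n):
        for s in range(r + 1, n):
            if len(sets[r] & sets[s]) == 1:
                S[r, s] = S[s, r] = 1.0
    return S


class _Blocks:
    """Per-group covariance blocks W_g = I + rho * S_g + lam * J_g."""

    def __init__(self, pairs: pd.DataFrame):
        self.order = pairs.sort_values("group", kind="stable").index.to_numpy()
        ordered = pairs.loc[self.order]
        self.y = ordered["response"].to_numpy(float)
        self.X = np.column_stack(
            [np.ones(len(ordered)), ordered["predictor"].to_numpy(float)]
        )
        self.groups = ordered["group"].to_numpy()
        self.S_blocks = []
        self.slices = []
        start = 0
        for g in pd.unique(self.groups):
            idx = np.flatnonzero(self.groups == g)
            sub = ordered.iloc[idx]
            self.S_blocks.append(
                _share_matrix(list(zip(sub["site_i"], sub["site_j"])))
            )
            self.slices.append(slice(start, start + len(idx)))
            start += len(idx)
        self.n = len(self.y)
        self.n_groups = len(self.S_blocks)

    def whitened(self, rho: float, lam: float):
        """Return (logdet W, W^-1 y, W^-1 X, y' W^-1 y pieces) via per-block
        Cholesky factorizations."""
        logdet = 0.0
        Wi_y = np.empty_like(self.y)
        Wi_X = np.empty_like(self.X)
        for S, sl in zip(self.S_blocks, self.slices):
            m = S.shape[0]
            W = np.eye(m) + rho * S + lam * np.ones((m, m))
            L = np.linalg.cholesky(W)
            logdet += 2.0 * np.log(np.diag(L)).sum()
            Wi_y[sl] = np.linalg.solve(L.T, np.linalg.solve(L, self.y[sl]))
            Wi_X[sl] = np.linalg.solve(L.T, np.linalg.solve(L, self.X[sl]))
        return logdet, Wi_y, Wi_X


def _profile(blocks: _Blocks, rho: float, lam: float, reml: bool):
    """GLS estimates and the profiled -2 log-likelihood at (rho, lambda)."""
    n, p = blocks.n, blocks.X.shape[1]
    logdet, Wi_y, Wi_X = blocks.whitened(rho, lam)
    XtWiX = blocks.X.T @ Wi_X
    XtWiy = blocks.X.T @ Wi_y
    beta = np.linalg.solve(XtWiX, XtWiy)
    resid = blocks.y - blocks.X @ beta
    # r' W^-1 r computed via the whitened residual identity
    quad = float(resid @ (Wi_y - Wi_X @ beta))
    quad = max(quad, 1e-300)
    if reml:
        dof = n - p
        sigma2 = quad / dof
        sign, logdet_xx = np.linalg.slogdet(XtWiX)
        neg2ll = (
            dof * np.log(2 * np.pi * sigma2) + logdet + logdet_xx + dof
        )
    else:
        sigma2 = quad / n
        neg2ll = n * np.log(2 * np.pi * sigma2) + logdet + n
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    return beta, sigma2, cov_beta, neg2ll


def mlpe_loglik(
    pairs: pd.DataFrame,
    intercept: float,
    slope: float,
    rho: float,
    sigma2_u: float,
    sigma2_e: float,
) -> float:
    """ML log-likelihood of the MLPE model at the given parameter values,
    computed through the blocked Cholesky path (checked in tests against a
    dense multivariate-normal density)."""
    pairs = _validate_pairs(pairs)
    blocks = _Blocks(pairs)
    lam = sigma2_u / sigma2_e if sigma2_e > 0 else 0.0
    logdet, Wi_y, Wi_X = blocks.whitened(rho, lam)
    beta = np.array([intercept, slope])
    resid = blocks.y - blocks.X @ beta
    # recompute W^-1 r for the residual of the *given* beta
    quad = 0.0
    for S, sl in zip(blocks.S_blocks, blocks.slices):
        m = S.shape[0]
        W = np.eye(m) + rho * S + lam * np.ones((m, m))
        quad += float(resid[sl] @ np.linalg.solve(W, resid[sl]))
    n = blocks.n
    return -0.5 * (
        n * np.log(2 * np.pi * sigma2_e) + logdet + quad / sigma2_e
    )


class MLPERegressor(RegressorMixin, BaseEstimator):
    """Sklearn-style estimator for the MLPE mixed model.

    Parameters
    ----------
    random_intercept : include a per-group random intercept (needs >= 2
        groups; with fewer the model degrades to no random effect with a
        warning).
    rho : fix the pair-sharing correlation at a value in [0, 0.5), or None
        to estimate it.
    reml : fit by restricted maximum likelihood (default) or plain ML.
    df_method : degrees-of-freedom convention for the Wald slope test;
        only "pairs_minus_groups" (n_pairs - n_groups - 1) is implemented.
    """

    def __init__(
        self,
        random_intercept: bool = True,
        rho: float | None = None,
        reml: bool = True,
        df_method: str = "pairs_minus_groups",
    ):
        self.random_intercept = random_intercept
        self.rho = rho
        self.reml = reml
        self.df_method = df_method

    def fit(self, pairs: pd.DataFrame, y=None) -> "MLPERegressor":
        pairs = _validate_pairs(pairs)
        if self.df_method != "pairs_minus_groups":
            raise ValueError(f"unknown df_method {self.df_method!r}")
        blocks = _Blocks(pairs)
        use_ri = self.random_intercept
        if use_ri and blocks.n_groups < 2:
            warnings.warn(
                "fewer than 2 groups: dropping the random intercept",
                stacklevel=2,
            )
            use_ri = False

        fit_rho = self.rho is None
        fixed_rho = 0.0 if self.rho is None else float(self.rho)
        if not 0 <= fixed_rho < 0.5:
            raise ValueError("rho must lie in [0, 0.5)")

        def unpack(theta):
            k = 0
            rho = fixed_rho
            lam = 0.0
            if fit_rho:
                rho = theta[k]
                k += 1
            if use_ri:
                lam = theta[k]
            return rho, lam

        def objective(theta):
            rho, lam = unpack(theta)
            try:
                return _profile(blocks, rho, lam, self.reml)[3]
            except np.linalg.LinAlgError:
                return np.inf

        n_par = int(fit_rho) + int(use_ri)
        best = None
        converged = True
        message = ""
        if n_par == 0:
            theta_hat = np.array([])
        else:
            bounds = ([(0.0, RHO_MAX)] if fit_rho else []) + (
                [(0.0, LAMBDA_MAX)] if use_ri else []
            )
            starts = []
            for r0 in ([0.01, 0.2, 0.4] if fit_rho else [None]):
                for l0 in ([0.01, 0.5, 5.0] if use_ri else [None]):
                    starts.append([v for v in (r0, l0) if v is not None])
            for x0 in starts:
                res = optimize.minimize(
                    objective, x0=np.array(x0), method="L-BFGS-B", bounds=bounds
                )
                if best is None or res.fun < best.fun:
                    best = res
            if best is None or not np.isfinite(best.fun):
                converged = False
                message = "optimizer failed to evaluate the likelihood"
                theta_hat = np.zeros(n_par)
            else:
                converged = bool(best.success)
                message = str(best.message)
                theta_hat = best.x

        rho_hat, lam_hat = unpack(theta_hat)
        beta, sigma2_e, cov_beta, neg2ll = _profile(
            blocks, rho_hat, lam_hat, self.reml
        )
        sigma2_u = lam_hat * sigma2_e
        slope, intercept = float(beta[1]), float(beta[0])
        slope_se = float(np.sqrt(cov_beta[1, 1]))
        df = blocks.n - blocks.n_groups - 1
        tval = slope / slope_se
        p_value = float(2 * stats.t.sf(abs(tval), df))

        sigma2_f = float(np.var(blocks.X @ beta))
        denom = sigma2_f + sigma2_u + sigma2_e
        r2m = sigma2_f / denom
        r2c = (sigma2_f + sigma2_u) / denom

        loglik_ml = mlpe_loglik(pairs, intercept, slope, rho_hat,
                                sigma2_u, sigma2_e)
        self.fit_result_ = MLPEFit(
            slope=slope,
            slope_se=slope_se,
            intercept=intercept,
            rho=float(rho_hat),
            sigma2_u=float(sigma2_u),
            sigma2_e=float(sigma2_e),
            loglik=-0.5 * float(neg2ll),
            loglik_ml=float(loglik_ml),
            p_value=p_value,
            df=int(df),
            df_method=self.df_method,
            r2m=float(r2m),
            r2c=float(r2c),
            reml=self.reml,
            random_intercept=use_ri,
            n_obs=int(blocks.n),
            n_groups=int(blocks.n_groups),
            converged=converged,
            boundary_sigma_u=bool(use_ri and lam_hat < 1e-8),
            message=message,
        )
        self.coef_ = np.array([slope])
        self.intercept_ = intercept
        self.slope_ = slope
        self.rho_ = float(rho_hat)
        self.sigma2_u_ = float(sigma2_u)
        self.sigma2_e_ = float(sigma2_e)
        self.p_value_ = p_value
        self.r2m_ = float(r2m)
        self.r2c_ = float(r2c)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Fixed-effect prediction: intercept + slope * predictor."""
        if isinstance(X, pd.DataFrame):
            x = X["predictor"].to_numpy(float)
        else:
            x = np.asarray(X, float).reshape(-1)
        return self.intercept_ + self.coef_[0] * x


def fit_mlpe(
    pairs: pd.DataFrame,
    use_random_intercept: bool = True,
    rho: float | None = None,
    reml: bool = True,
) -> MLPEFit:
    """Functional wrapper over :class:`MLPERegressor`."""
    est = MLPERegressor(
        random_intercept=use_random_intercept, rho=rho, reml=reml
    )
    est.fit(pairs)
    return est.fit_result_


def r2_nakagawa(fit: MLPEFit, pairs: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R2 (Nakagawa & Schielzeth):

        R2m = s2_f / (s2_f + s2_u + s2_e)
        R2c = (s2_f + s2_u) / (s2_f + s2_u + s2_e)

    with s2_f the variance of the fixed-effect linear predictor.
    """
    x = pairs["predictor"].to_numpy(float)
    sigma2_f = float(np.var(fit.intercept + fit.slope * x))
    denom = sigma2_f + fit.sigma2_u + fit.sigma2_e
    return sigma2_f / denom, (sigma2_f + fit.sigma2_u) / denom
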