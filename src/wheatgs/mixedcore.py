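"""One-kernel mixed-model REML solver and genomic prediction.

Solves ``y = X b + Z u + e`` with ``u ~ N(0, K s2_u)`` and
``e ~ N(0, I s2_e)`` by the spectral method: eigendecompose ``Z K Z'``
projected off the fixed effects once, then maximize the restricted
likelihood over the single ratio ``lambda = s2_e / s2_u`` by bounded 1-D
search in ``log lambda``.  Two parameterizations of genomic prediction are
supported and are numerically equivalent:

* ridge / marker-effect mode (``Z`` = genotype matrix, ``K = I``): ``u``
  holds per-marker effects, all shrunk under one common variance;
* GBLUP / kinship mode (``Z = I``, ``K`` = additive relationship matrix):
  ``u`` holds per-line genetic values.

GEBVs for unphenotyped lines come from ``G_new @ u_hat`` in marker mode
(plus the fixed-effect contribution when requested), and prediction accuracy
is the plain Pearson correlation between GEBVs and observed entry BLUPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genomat import GenotypeMatrix, RelationshipMatrix

__all__ = ["MixedModelFit", "solve_mixed", "fit_rrblup", "predict_gebv", "accuracy"]

_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


@dataclass
class MixedModelFit:
    """REML solution of the one-kernel mixed model."""

    beta: np.ndarray
    u: np.ndarray
    Vu: float
    Ve: float
    log_lambda: float
    loglik: float
    boundary: bool = False  # variance ratio pinned at a search bound
    fixed_names: list[str] = field(default_factory=list)
    marker_ids: list[str] | None = None  # set in marker-effect mode

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lambda))


def _restricted_loglik(log_lam: float, theta: np.ndarray, eta2: np.ndarray, df: int) -> float:
    lam = np.exp(log_lam)
    denom = theta + lam
    return -0.5 * (df * np.log(np.sum(eta2 / denom)) + np.sum(np.log(denom)))


def solve_mixed(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    K: np.ndarray | None = None,
    psd_tol: float = 1e-6,
    fix_log_lambda: float | None = None,
) -> MixedModelFit:
    """REML fit of ``y = X b + Z u + e``, ``u ~ N(0, K s2_u)``.

    ``K = None`` means the identity.  The restricted likelihood is profiled
    down to the ratio ``lambda = s2_e / s2_u`` and maximized by Brent search
    over ``log lambda`` in ``[-10, 10]``; solutions at a bound are returned
    with ``boundary=True`` rather than silently clamped.  Passing
    ``fix_log_lambda`` skips the search and solves at that ratio.

    Raises on rank-deficient ``X`` (naming the collinear columns) and on a
    ``K`` that fails positive semidefiniteness beyond tolerance.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.atleast_2d(np.asarray(Z, float))
    n = y.size
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("X and Z must have one row per observation")
    p = X.shape[1]
    r = np.linalg.matrix_rank(X)
    if r < p:
        # name offending columns: those whose removal restores full rank
        bad = [j for j in range(p) if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == r]
        raise ValueError(f"fixed-effect design is rank deficient (collinear columns {bad})")
    if n - p < 2:
        raise ValueError("too few residual degrees of freedom")

    if K is None:
        H = Z @ Z.T
    else:
        K = np.asarray(K, float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("K must be symmetric")
        wmin = float(np.linalg.eigvalsh(K).min())
        if wmin < -psd_tol * max(1.0, np.trace(K) / K.shape[0]):
            raise ValueError(f"K is not positive semidefinite (min eigenvalue {wmin:.3g})")
        H = Z @ K @ Z.T
    H = (H + H.T) / 2.0

    # orthonormal basis of the complement of col(X)
    q_full, _ = np.linalg.qr(X, mode="complete")
    Q = q_full[:, p:]  # n x (n-p)
    S = Q.T @ H @ Q
    theta, vec = np.linalg.eigh((S + S.T) / 2.0)
    theta = np.maximum(theta, 0.0)
    eta = vec.T @ (Q.T @ y)
    eta2 = eta**2
    df = n - p

    tot = float(np.sum(eta2))
    if tot <= 1e-12 * max(1.0, float(y @ y)):
        # y lies (numerically) in the column space of X: no residual variance
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return MixedModelFit(
            beta=beta,
            u=np.zeros(Z.shape[1] if K is None else Z.shape[1]),
            Vu=0.0,
            Ve=0.0,
            log_lambda=_LOG_LAMBDA_BOUNDS[1],
            loglik=np.inf,
            boundary=True,
        )

    if fix_log_lambda is None:
        res = optimize.minimize_scalar(
            lambda ll: -_restricted_loglik(ll, theta, eta2, df),
            bounds=_LOG_LAMBDA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
    else:
        log_lam = float(fix_log_lambda)
    boundary = bool(
        log_lam <= _LOG_LAMBDA_BOUNDS[0] + 1e-6 or log_lam >= _LOG_LAMBDA_BOUNDS[1] - 1e-6
    )
    lam = np.exp(log_lam)
    Vu = float(np.sum(eta2 / (theta + lam)) / df)
    Ve = float(lam * Vu)

    # GLS fixed effects and BLUPs at the estimated ratio, via eigen of full H
    d_full, u_full = np.linalg.eigh(H)
    d_full = np.maximum(d_full, 0.0)
    w = 1.0 / (d_full + lam)  # V^{-1} = U diag(w) U' / Vu
    Xt = u_full.T @ X
    yt = u_full.T @ y
    XtWX = Xt.T @ (Xt * w[:, None])
    XtWy = Xt.T @ (w * yt)
    beta = np.linalg.solve(XtWX, XtWy)
    resid_t = yt - Xt @ beta
    vinv_resid = u_full @ (w * resid_t)  # (H + lam I)^{-1} (y - X beta)
    if K is None:
        u = Z.T @ vinv_resid
    else:
        u = K @ (Z.T @ vinv_resid)

    return MixedModelFit(
        beta=beta,
        u=u,
        Vu=Vu,
        Ve=Ve,
        log_lambda=log_lam,
        loglik=float(_restricted_loglik(log_lam, theta, eta2, df)),
        boundary=boundary,
    )


def _build_fixed(
    n: int, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept plus covariate columns, dropping constant/collinear ones."""
    X = np.ones((n, 1))
    names = ["intercept"]
    if covariates is None:
        return X, names
    if isinstance(covariates, pd.DataFrame):
        cov_names = [str(c) for c in covariates.columns]
        cov = covariates.to_numpy(float)
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        cov_names = [f"cov{j + 1}" for j in range(cov.shape[1])]
    for j, name in enumerate(cov_names):
        cand = np.column_stack([X, cov[:, j]])
        if np.linalg.matrix_rank(cand) == X.shape[1]:
            warnings.warn(f"covariate '{name}' is constant or collinear; dropped")
            continue
        X = cand
        names.append(name)
    return X, names


def fit_rrblup(
    g_train: GenotypeMatrix,
    y_train: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> MixedModelFit:
    """Ridge-regression BLUP: markers random with one common variance.

    ``y_train`` must hold one phenotype per training line (a Series indexed
    by line ID is aligned to the genotype matrix).  Optional covariates —
    e.g. major-gene scores — enter as fixed effects next to the intercept;
    constant or collinear columns are dropped with a warning.
    """
    if g_train.missing_mask.any():
        raise ValueError("fit_rrblup requires imputed genotypes")
    if isinstance(y_train, pd.Series):
        y = y_train.reindex(g_train.line_ids).to_numpy(float)
        if np.isnan(y).any():
            raise ValueError("phenotypes missing for some training lines")
    else:
        y = np.asarray(y_train, float).ravel()
    if y.size != g_train.n_lines:
        raise ValueError("y_train must have one value per training line")
    X, names = _build_fixed(g_train.n_lines, covariates)
    fit = solve_mixed(y, X, g_train.values, K=None)
    fit.fixed_names = names
    fit.marker_ids = list(g_train.marker_ids)
    return fit


def fit_gblup(
    K: RelationshipMatrix,
    y_train: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> MixedModelFit:
    """Kinship parameterization: line effects random with covariance K."""
    if isinstance(y_train, pd.Series):
        y = y_train.reindex(K.line_ids).to_numpy(float)
    else:
        y = np.asarray(y_train, float).ravel()
    n = len(K.line_ids)
    X, names = _build_fixed(n, covariates)
    fit = solve_mixed(y, X, np.eye(n), K=K.values)
    fit.fixed_names = names
    return fit


def predict_gebv(
    fit: MixedModelFit,
    g_new: GenotypeMatrix,
    covariates_new: pd.DataFrame | np.ndarray | None = None,
    include_fixed: bool = False,
) -> pd.Series:
    """GEBVs for new lines from a marker-effect fit: ``G_new @ u_hat``.

    With ``include_fixed=True`` the fixed part (intercept plus any covariate
    effects, which requires ``covariates_new``) is added, so major-gene
    signal counts toward the prediction.  The returned Series carries an
    ``includes_fixed`` attribute recording the choice.
    """
    if fit.marker_ids is None:
        raise ValueError("predict_gebv needs a marker-effect (rrBLUP) fit")
    if list(g_new.marker_ids) != fit.marker_ids:
        raise ValueError("new genotypes are not on the training marker set; run common_markers")
    gebv = g_new.values @ fit.u
    if include_fixed:
        X_new = np.ones((g_new.n_lines, 1))
        if covariates_new is not None:
            cov = (
                covariates_new.to_numpy(float)
                if isinstance(covariates_new, pd.DataFrame)
                else np.atleast_2d(np.asarray(covariates_new, float))
            )
            if cov.shape[0] != g_new.n_lines:
                cov = cov.T
            X_new = np.column_stack([X_new, cov])
        if X_new.shape[1] != fit.beta.size:
            raise ValueError("covariates_new does not match the fitted fixed effects")
        gebv = gebv + X_new @ fit.beta
    out = pd.Series(gebv, index=g_new.line_ids, name="gebv")
    out.attrs["includes_fixed"] = include_fixed
    return out


def accuracy(gebv: pd.Series, observed: pd.Series) -> float:
    """Prediction accuracy: Pearson r between GEBVs and observed entry BLUPs.

    Computed on the overlap of the two index sets (at least 3 lines); zero
    variance on either side is an error, never a silent 0.  Negative values
    are reported as-is.
    """
    common = gebv.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping lines for accuracy")
    a = gebv.loc[common].to_numpy(float)
    b = observed.loc[common].to_numpy(float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("accuracy undefined: zero variance in GEBVs or observations")
    return float(stats.pearsonr(a, b)[0])
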