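"""Soil ordination and latent-factor environment association.

The edaphic predictor is the first principal component of 14 standardized
soil variables.  Expression (log2 FPKM of DET transcripts) is regressed
on that predictor with a ridge latent factor mixed model (LFMM): the
model Y = U V' + X B' + E jointly estimates K unobserved confounder axes
(U, V) and per-transcript environmental effects B by minimizing

    || Y - U V' - X B' ||_F^2 + lambda * || B ||_F^2

with block-coordinate descent — (U, V) from a rank-K truncated SVD of the
residual Y - X B', then B by per-transcript ridge regression — so the
objective never increases.  Test z-scores come from per-transcript OLS of
Y on [1, X, U], and p-values are recalibrated with the genomic inflation
factor lambda_GIF = median(z^2) / median(chi^2_1), which rescales the
squared statistics so null p-values are uniform.

A linear discriminant analysis (LDA) of the soil table identifies the
variables separating the parental and hybrid site groups; coefficients
are scaled so each discriminant has unit pooled within-group variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2, norm

#: Fixed roster and order of the measured soil variables.
SOIL_VARIABLES = [
    "pH", "OM", "CEC", "SB", "BSP", "ASP", "PA",
    "P", "K", "Ca", "Na", "S", "Al", "Mg",
]

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = 0.4549364


@dataclass
class OrdinationResult:
    method: str  # "pca" or "lda"
    scores: pd.DataFrame  # sites x components
    loadings: pd.DataFrame  # variables x components (PCA) / coefficients (LDA)
    variance_ratio: np.ndarray | None = None  # PCA only
    eigenvalues: np.ndarray | None = None  # LDA discriminant eigenvalues

    @property
    def pc1(self) -> pd.Series:
        return self.scores.iloc[:, 0]


@dataclass
class LFMMFit:
    U: np.ndarray  # samples x K latent factors
    V: np.ndarray  # transcripts x K loadings
    B: np.ndarray  # transcripts x d effect sizes
    ridge_lambda: float
    objective_trace: list[float]
    n_iter: int


def _soil_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [v for v in SOIL_VARIABLES if v not in table.columns]
    if missing:
        raise ValueError(f"soil table is missing variables: {missing}")
    x = table[SOIL_VARIABLES].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("soil table contains missing or non-finite values")
    return x


def soil_pca(table: pd.DataFrame, standardize: bool = True) -> OrdinationResult:
    """PCA of the 14 soil variables; PC1 is the edaphic predictor.

    Columns are standardized (correlation-matrix PCA) unless
    ``standardize`` is false.  The sign of each component is fixed so its
    loading on Na is non-negative, making the predictor orientation
    reproducible.
    """
    x = _soil_matrix(table)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 sites")
    centered = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        for var, s in zip(SOIL_VARIABLES, sd):
            if s == 0:
                raise ValueError(f"soil variable {var!r} has zero variance")
        centered = centered / sd
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    na_idx = SOIL_VARIABLES.index("Na")
    for k in range(evecs.shape[1]):
        if evecs[na_idx, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = centered @ evecs
    comp_names = [f"PC{k + 1}" for k in range(evecs.shape[1])]
    return OrdinationResult(
        method="pca",
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(evecs, index=SOIL_VARIABLES, columns=comp_names),
        variance_ratio=evals / evals.sum(),
    )


def soil_lda(
    table: pd.DataFrame, groups: pd.Series | np.ndarray
) -> OrdinationResult:
    """Linear discriminant analysis of soil variables across site groups.

    Solves the generalized eigenproblem S_b v = lambda S_w v on the
    between- and pooled within-group scatter matrices, returning at most
    (n_groups - 1) discriminants.  S_w is ridge-regularized by
     1e-8 * trace / dim when singular (more variables than sites is the
    common case for soil panels).
    """
    x = _soil_matrix(table)
    labels = np.asarray(groups)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("groups length must match number of sites")
    uniq = [g for g in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValueError("LDA needs at least 2 groups")
    p = x.shape[1]
    grand = x.mean(axis=0)
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    for g in uniq:
        xg = x[labels == g]
        if xg.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 sites")
        diff = xg - xg.mean(axis=0)
        s_w += diff.T @ diff
        md = (xg.mean(axis=0) - grand)[:, None]
        s_b += xg.shape[0] * (md @ md.T)
    # regularize when the pooled within-group scatter is singular
    if np.linalg.matrix_rank(s_w) < p:
        s_w = s_w + (1e-8 * np.trace(s_w) / p) * np.eye(p)
    evals, evecs = scipy.linalg.eigh(s_b, s_w)
    order = np.argsort(evals)[::-1]
    n_comp = len(uniq) - 1
    evals = np.clip(evals[order][:n_comp], 0.0, None)
    coefs = evecs[:, order][:, :n_comp]
    # unit pooled within-group variance per discriminant (MASS convention)
    n_g = x.shape[0] - len(uniq)
    w_cov = s_w / n_g
    for k in range(n_comp):
        scale = float(np.sqrt(coefs[:, k] @ w_cov @ coefs[:, k]))
        if scale > 0:
            coefs[:, k] = coefs[:, k] / scale
        if coefs[np.argmax(np.abs(coefs[:, k])), k] < 0:
            coefs[:, k] = -coefs[:, k]
    scores = (x - grand) @ coefs
    comp_names = [f"LD{k + 1}" for k in range(n_comp)]
    return OrdinationResult(
        method="lda",
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(coefs, index=SOIL_VARIABLES, columns=comp_names),
        eigenvalues=evals,
    )


def _as_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _objective(
    Y: np.ndarray, X: np.ndarray, U: np.ndarray, V: np.ndarray,
    B: np.ndarray, lam: float,
) -> float:
    resid = Y - U @ V.T - X @ B.T
    return float(np.sum(resid**2) + lam * np.sum(B**2))


def _analytic_latent(
    Y: np.ndarray, X: np.ndarray, K: int, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form global optimum of the latent block.

    Profiling B out of the ridge objective leaves a weighted Frobenius
    problem || T (Y - L) ||_F^2 over rank-K matrices L, where T shrinks
    each predictor direction q_i by sqrt(lambda / (sigma_i^2 + lambda)).
    Its minimizer is T^-1 applied to the rank-K truncated SVD of T Y,
    which seeds the block-coordinate loop at (numerically) the global
    minimum instead of a cold start.
    """
    n = Y.shape[0]
    Q, sing, _ = np.linalg.svd(X, full_matrices=False)
    pos = sing > 1e-12
    Q, sing = Q[:, pos], sing[pos]
    if Q.shape[1] == 0:  # null predictor: plain truncated SVD of Y
        left, s, right_t = np.linalg.svd(Y, full_matrices=False)
        return left[:, :K] * s[:K], right_t[:K].T
    shrink = np.sqrt(lam / (sing**2 + lam))
    T = np.eye(n) + Q @ np.diag(shrink - 1.0) @ Q.T
    T_inv = np.eye(n) + Q @ np.diag(1.0 / shrink - 1.0) @ Q.T
    left, s, right_t = np.linalg.svd(T @ Y, full_matrices=False)
    L = T_inv @ (left[:, :K] * s[:K]) @ right_t[:K]
    # re-factor L as U V' with orthonormal V
    left, s, right_t = np.linalg.svd(L, full_matrices=False)
    return left[:, :K] * s[:K], right_t[:K].T


def fit_lfmm_ridge(
    Y: np.ndarray,
    X: np.ndarray,
    K: int,
    ridge_lambda: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LFMMFit:
    """Ridge LFMM by block-coordinate descent.

    Y: samples x transcripts response (columns are centered internally);
    X: samples x d predictor(s) (centered and scaled internally);
    K: number of latent factor axes (0 disables the latent block and B
    reduces to the closed-form ridge estimate).

    The loop alternates (i) rank-K truncated SVD of Y - X B' for (U, V)
    and (ii) per-transcript ridge regression for B.  It is seeded at the
    analytic global minimizer of the profiled objective (see
    ``_analytic_latent``): from a cold start the two blocks are strongly
    coupled and the alternation crawls, whereas from the analytic seed it
    terminates in a handful of confirming iterations.
    """
    Y = np.asarray(Y, dtype=float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    X = _as_design(X)
    x_sd = X.std(axis=0, ddof=1)
    x_sd[x_sd == 0] = 1.0
    X = (X - X.mean(axis=0, keepdims=True)) / x_sd
    n, p = Y.shape
    d = X.shape[1]
    if K >= n:
        raise ValueError("K must be smaller than the number of samples")
    if ridge_lambda <= 0:
        raise ValueError("ridge penalty must be positive")

    gram_inv = np.linalg.inv(X.T @ X + ridge_lambda * np.eye(d))

    def ridge_b(resid: np.ndarray) -> np.ndarray:
        return resid.T @ X @ gram_inv  # p x d

    if K == 0:
        B = ridge_b(Y)
        U = np.zeros((n, 0))
        V = np.zeros((p, 0))
        return LFMMFit(
            U=U, V=V, B=B, ridge_lambda=ridge_lambda,
            objective_trace=[_objective(Y, X, U, V, B, ridge_lambda)],
            n_iter=0,
        )

    U, V = _analytic_latent(Y, X, K, ridge_lambda)
    B = ridge_b(Y - U @ V.T)
    trace = [_objective(Y, X, U, V, B, ridge_lambda)]
    for it in range(max_iter):
        # latent block: rank-K truncated SVD of the predictor residual
        left, sing, right_t = np.linalg.svd(Y - X @ B.T, full_matrices=False)
        U = left[:, :K] * sing[:K]
        V = right_t[:K].T
        # effect block: per-transcript ridge on the latent residual
        B = ridge_b(Y - U @ V.T)
        obj = _objective(Y, X, U, V, B, ridge_lambda)
        if obj > trace[-1] + 1e-9 * max(1.0, abs(trace[-1])):
            raise RuntimeError("LFMM objective increased; numerical failure")
        converged = abs(trace[-1] - obj) <= tol * max(1.0, abs(trace[-1]))
        trace.append(obj)
        if converged:
            break
    return LFMMFit(
        U=U, V=V, B=B, ridge_lambda=ridge_lambda,
        objective_trace=trace, n_iter=len(trace) - 1,
    )


def association_tests(
    Y: np.ndarray, X: np.ndarray, U: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-transcript OLS of y_j on [intercept, X, U]; z from the X slope.

    Returns (z_scores, raw_p) with p from the normal approximation to the
    t-statistic of the predictor coefficient.
    """
    Y = np.asarray(Y, dtype=float)
    X = _as_design(X)
    n = Y.shape[0]
    design = np.column_stack([np.ones(n), X, U])
    k = design.shape[1]
    if np.linalg.matrix_rank(design) < k:
        raise ValueError("rank-deficient design matrix")
    if n <= k:
        raise ValueError("not enough samples for the design")
    gram_inv = np.linalg.inv(design.T @ design)
    beta = gram_inv @ design.T @ Y  # k x p
    resid = Y - design @ beta
    sigma2 = np.sum(resid**2, axis=0) / (n - k)
    se = np.sqrt(np.maximum(sigma2 * gram_inv[1, 1], 1e-300))
    z = beta[1] / se
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def gif_calibrate(
    z: np.ndarray, alpha: float = 0.05
) -> tuple[float, np.ndarray, np.ndarray]:
    """Genomic-inflation-factor calibration of association z-scores.

    lambda_GIF = median(z^2) / median(chi^2_1); calibrated p-values are
    the upper chi^2_1 tail of z^2 / lambda_GIF.  Returns (lambda_GIF,
    calibrated_p, significant_mask) with significance at calibrated
    p < alpha.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 10:
        raise ValueError("GIF calibration needs at least 10 z-scores")
    med = float(np.median(z**2))
    if med == 0:
        raise ValueError("degenerate z-scores: median(z^2) = 0")
    gif = med / CHI2_1_MEDIAN
    p_cal = chi2.sf(z**2 / gif, df=1)
    return gif, p_cal, p_cal < alpha
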