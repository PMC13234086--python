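"""Inference for the static models.

* Coupling-tuning (CoTu) model: ordinary least squares on ``[Y_not, X]``.
* Coupling-tuning-latent (CoTuLa) model: exact expectation-maximization.

Both estimators accept a :class:`~cotula.params.SupportMask` that pins
off-support coupling/tuning coefficients of the target to exactly zero
(restricted least squares / restricted M-step).  The selection-then-estimation
architecture is deliberate: the support is chosen first (``none``, ``oracle``
or ``inferred``) and only then are the surviving coefficients estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.linear_model import lasso_path

from .params import StaticParams, SupportMask
from .static_model import StaticDataset, marginal_loglik

__all__ = [
    "PosteriorStatsStatic",
    "FitResult",
    "fit_cotu_ols",
    "em_e_step",
    "em_m_step",
    "fit_cotula_em",
    "infer_support_static",
    "normalized_error",
    "ErrorReport",
]

VARIANCE_FLOOR = 1e-8


@dataclass
class PosteriorStatsStatic:
    """Per-trial posterior statistics of the latent state.

    ``mu`` is D x K (posterior means); ``Sigma`` is the K x K posterior
    covariance, which is shared across trials because the latent precision
    ``I + L Pi^-1 L.T`` does not depend on the data.
    """

    mu: np.ndarray
    Sigma: np.ndarray

    def second_moment_sum(self) -> np.ndarray:
        """``sum_d <z z.T>_q = D * Sigma + mu.T @ mu``."""
        D = self.mu.shape[0]
        return D * self.Sigma + self.mu.T @ self.mu


@dataclass
class FitResult:
    params: StaticParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    support_used: SupportMask
    regime: str = "none"


def _design(data: StaticDataset, support: SupportMask, intercept: bool):
    """Design matrix columns of [Y_not, X] restricted to the support."""
    cols = [data.Y_not[:, support.coupling_support],
            data.X[:, support.tuning_support]]
    if intercept:
        cols.append(np.ones((data.D, 1)))
    return np.column_stack(cols)


def fit_cotu_ols(data: StaticDataset, support: SupportMask | None = None,
                 intercept: bool = False, regime: str = "none") -> FitResult:
    """Least-squares fit of the coupling-tuning model for the target unit.

    Regresses ``y`` on the support-selected columns of ``[Y_not, X]``;
    off-support coefficients are exactly zero in the returned parameters.
    The latent block of the returned :class:`StaticParams` is empty (K = 0).
    """
    N = data.Y_not.shape[1]
    M = data.X.shape[1]
    if support is None:
        support = SupportMask.dense(N, M)
    W = _design(data, support, intercept)
    n_active = W.shape[1]
    if data.D <= n_active:
        raise ValueError(f"need more trials ({data.D}) than active predictors "
                         f"({n_active}) for OLS")
    gram = W.T @ W
    rank = np.linalg.matrix_rank(gram)
    if rank < n_active:
        raise ValueError("design matrix is rank-deficient on the requested "
                         f"support (rank {rank} < {n_active})")
    coef = linalg.solve(gram, W.T @ data.y, assume_a="pos")
    a = np.zeros(N)
    b = np.zeros(M)
    nc = int(support.coupling_support.sum())
    nt = int(support.tuning_support.sum())
    a[support.coupling_support] = coef[:nc]
    b[support.tuning_support] = coef[nc:nc + nt]
    b0 = float(coef[-1]) if intercept else 0.0
    resid = data.y - W @ coef
    psi = max(float(resid @ resid / data.D), VARIANCE_FLOOR)
    # Non-target units: plain per-unit tuning regressions (no latent block).
    Xd = np.column_stack((data.X, np.ones(data.D))) if intercept else data.X
    Bfull, *_ = np.linalg.lstsq(Xd, data.Y_not, rcond=None)
    B_not = Bfull[:M]
    b0_not = Bfull[M] if intercept else np.zeros(N)
    R = data.Y_not - Xd @ Bfull
    Psi_not = np.maximum(np.mean(R * R, axis=0), VARIANCE_FLOOR)
    params = StaticParams(a=a, b=b, B_not=B_not,
                          l=np.zeros(0), L_not=np.zeros((0, N)),
                          psi=psi, Psi_not=Psi_not, b0=b0, b0_not=b0_not)
    return FitResult(params=params, loglik_trace=np.array([]), n_iter=0,
                     converged=True, support_used=support, regime=regime)


def em_e_step(params: StaticParams, data: StaticDataset) -> PosteriorStatsStatic:
    """Exact posterior of the latent state for every trial.

    The posterior precision is ``I + l psi^-1 l.T + L_not Pi^-1 L_not.T`` and
    the mean is the (shared) covariance applied to the per-trial information
    vector built from the tuning/coupling residuals.
    """
    if params.psi <= 0 or np.any(params.Psi_not <= 0):
        raise ValueError("E-step requires strictly positive private variances")
    K = params.K
    l, L = params.l, params.L_not
    prec = (np.eye(K) + np.outer(l, l) / params.psi
            + (L / params.Psi_not) @ L.T)
    Sigma = linalg.inv(prec)
    Sigma = 0.5 * (Sigma + Sigma.T)
    r_i = (data.y - params.b0 - data.X @ params.b
           - data.Y_not @ params.a)                       # D
    R_not = data.Y_not - params.b0_not - data.X @ params.B_not   # D x N
    info = (np.outer(r_i, l) / params.psi
            + R_not @ (L / params.Psi_not).T)             # D x K
    mu = info @ Sigma
    return PosteriorStatsStatic(mu=mu, Sigma=Sigma)


def em_m_step(data: StaticDataset, post: PosteriorStatsStatic,
              support: SupportMask, current: StaticParams,
              intercept: bool = False) -> StaticParams:
    """Exact maximizer of the expected complete log-likelihood.

    Target row: joint restricted least-squares for ``(a, b, l)`` using the
    extended regressor ``[Y_not, X, z]`` with the latent second moment
    ``<z z.T>`` replacing ``mu mu.T`` in the Gram matrix.  Non-target rows:
    per-unit restricted solves for ``(B_not, L_not)``.  Variances come from
    the expected residual quadratics and are floored at ``1e-8``.
    """
    D = data.D
    N, M, K = current.N, current.M, current.K
    mu, Sig = post.mu, post.Sigma
    Szz = post.second_moment_sum()                        # sum_d <z z.T>

    sc, st = support.coupling_support, support.tuning_support
    Yc = data.Y_not[:, sc]
    Xt = data.X[:, st]
    blocks = [Yc, Xt, mu]
    if intercept:
        blocks.append(np.ones((D, 1)))
    U = np.column_stack(blocks)
    gram = U.T @ U
    nc, nt = Yc.shape[1], Xt.shape[1]
    zs = slice(nc + nt, nc + nt + K)
    gram[zs, zs] = Szz                                    # correct z-z block
    rhs = U.T @ data.y
    try:
        coef = linalg.solve(gram, rhs, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise ValueError("degenerate normal equations in the M-step") from exc
    a = np.zeros(N)
    b = np.zeros(M)
    a[sc] = coef[:nc]
    b[st] = coef[nc:nc + nt]
    l = coef[zs]
    b0 = float(coef[-1]) if intercept else 0.0
    # expected residual quadratic for the target private variance
    resid = data.y - b0 - Yc @ coef[:nc] - Xt @ coef[nc:nc + nt]
    quad = (resid @ resid - 2.0 * resid @ (mu @ l)
            + l @ Szz @ l)
    psi = max(float(quad / D), VARIANCE_FLOOR)

    # non-target rows: shared design [X, z(, 1)], per-unit responses
    blocks = [data.X, mu]
    if intercept:
        blocks.append(np.ones((D, 1)))
    V = np.column_stack(blocks)
    gram2 = V.T @ V
    zs2 = slice(M, M + K)
    gram2[zs2, zs2] = Szz
    rhs2 = V.T @ data.Y_not                               # (M+K(+1)) x N
    try:
        coef2 = linalg.solve(gram2, rhs2, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise ValueError("degenerate normal equations in the M-step") from exc
    B_not = coef2[:M]
    L_not = coef2[zs2]
    b0_not = coef2[-1] if intercept else np.zeros(N)
    R = data.Y_not - b0_not - data.X @ B_not
    quad_not = (np.sum(R * R, axis=0)
                - 2.0 * np.sum(R * (mu @ L_not), axis=0)
                + np.einsum("kn,kj,jn->n", L_not, Szz, L_not))
    Psi_not = np.maximum(quad_not / D, VARIANCE_FLOOR)
    return StaticParams(a=a, b=b, B_not=B_not, l=l, L_not=L_not,
                        psi=psi, Psi_not=Psi_not, b0=b0, b0_not=b0_not)


def _init_params(data: StaticDataset, K: int, support: SupportMask,
                 intercept: bool, rng: np.random.Generator | None
                 ) -> StaticParams:
    """Factor-analysis-style initialization.

    ``a, b, B_not`` from OLS; loadings from the top-K eigenvectors of the
    pooled OLS residual covariance scaled by root eigenvalues; private
    variances from the residual variances.  When ``rng`` is given the point is
    perturbed with seeded Gaussian noise (random restarts).
    """
    ols = fit_cotu_ols(data, support, intercept=intercept).params
    r_i = data.y - ols.b0 - data.Y_not @ ols.a - data.X @ ols.b
    R_not = data.Y_not - ols.b0_not - data.X @ ols.B_not
    resid = np.column_stack((r_i, R_not))
    C = np.cov(resid, rowvar=False)
    evals, evecs = linalg.eigh(C)
    order = np.argsort(evals)[::-1][:K]
    lam = np.maximum(evals[order], 0.0)
    Lfull = (evecs[:, order] * np.sqrt(lam)).T            # K x (N+1)
    l = Lfull[:, 0].copy()
    L_not = Lfull[:, 1:].copy()
    diagC = np.clip(np.diag(C), VARIANCE_FLOOR, None)
    psi = max(float(diagC[0] - l @ l), 10 * VARIANCE_FLOOR)
    Psi_not = np.maximum(diagC[1:] - np.sum(L_not**2, axis=0), 10 * VARIANCE_FLOOR)
    params = StaticParams(a=ols.a, b=ols.b, B_not=ols.B_not, l=l, L_not=L_not,
                          psi=psi, Psi_not=Psi_not, b0=ols.b0, b0_not=ols.b0_not)
    if rng is not None:
        scale = 0.1
        params.a = params.a + scale * rng.standard_normal(params.N) * support.coupling_support
        params.b = params.b + scale * rng.standard_normal(params.M) * support.tuning_support
        params.l = params.l + scale * rng.standard_normal(K)
        params.L_not = params.L_not + scale * rng.standard_normal(params.L_not.shape)
    return params


def fit_cotula_em(data: StaticDataset, K: int,
                  support: SupportMask | None = None,
                  init: StaticParams | int | None = None,
                  max_iter: int = 500, tol: float = 1e-8,
                  intercept: bool = False, regime: str = "none") -> FitResult:
    """Expectation-maximization fit of the static coupling-tuning-latent model.

    Alternates the exact E-step and restricted M-step until the relative
    change of the marginal log-likelihood falls below ``tol`` or ``max_iter``
    sweeps are exhausted.  ``init`` may be a :class:`StaticParams` starting
    point, an integer seed for a randomly perturbed start, or ``None`` for
    the deterministic OLS/factor-analysis start.  Never raises on
    non-convergence: the result carries ``converged=False``.
    """
    if K < 1:
        raise ValueError("K must be >= 1 (use fit_cotu_ols for the "
                         "latent-free model)")
    N = data.Y_not.shape[1]
    M = data.X.shape[1]
    if support is None:
        support = SupportMask.dense(N, M)
    if isinstance(init, StaticParams):
        params = init.copy()
    else:
        rng = None if init is None else np.random.default_rng(init)
        params = _init_params(data, K, support, intercept, rng)
    trace = [marginal_loglik(params, data)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = em_e_step(params, data)
        params = em_m_step(data, post, support, params, intercept=intercept)
        ll = marginal_loglik(params, data)
        trace.append(ll)
        if abs(ll - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    return FitResult(params=params, loglik_trace=np.asarray(trace),
                     n_iter=it, converged=converged, support_used=support,
                     regime=regime)


def infer_support_static(data: StaticDataset, n_boots: int = 20,
                         n_lambdas: int = 48, holdout_frac: float = 0.1,
                         n_est_boots: int = 10, seed: int = 0,
                         intercept: bool = False) -> SupportMask:
    """Union-of-intersections-style support selection for the static target.

    An approximation of two-stage stability selection: for each of ``n_boots``
    bootstrap resamples a lasso path over a shared log-spaced regularization
    grid is fit, and the selected supports are intersected across resamples at
    each level.  Each level's intersection support is then scored by the
    out-of-sample R^2 of a restricted OLS fit, averaged over ``n_est_boots``
    ``holdout_frac`` held-out splits; the best-scoring level's support is
    returned (ties break toward stronger regularization, i.e. sparser
    supports).  Deterministic given ``seed``.
    """
    if data.D < 50:
        raise ValueError("support inference needs at least 50 trials")
    rng = np.random.default_rng(seed)
    N = data.Y_not.shape[1]
    M = data.X.shape[1]
    W = np.column_stack((data.Y_not, data.X))
    y = data.y
    if intercept:
        W = W - W.mean(axis=0)
        y = y - y.mean()
    D, p = W.shape
    lam_max = np.max(np.abs(W.T @ y)) / D
    lambdas = np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)

    inter = np.ones((n_lambdas, p), dtype=bool)
    for _ in range(n_boots):
        idx = rng.integers(0, D, size=D)
        _, coefs, _ = lasso_path(W[idx], y[idx], alphas=lambdas)
        inter &= (np.abs(coefs) > 1e-10).T
    n_hold = max(1, int(round(holdout_frac * D)))
    # score only distinct supports; carry scores back to their first level
    scores = np.zeros(n_lambdas)
    for _ in range(n_est_boots):
        perm = rng.permutation(D)
        test, train = perm[:n_hold], perm[n_hold:]
        sst = max(np.sum((y[test] - y[train].mean()) ** 2), 1e-12)
        cache: dict[bytes, float] = {}
        for s in range(n_lambdas):
            key = inter[s].tobytes()
            if key not in cache:
                sup = inter[s]
                if sup.sum() == 0:
                    pred = np.zeros(test.size)
                else:
                    coef, *_ = np.linalg.lstsq(W[train][:, sup], y[train],
                                               rcond=None)
                    pred = W[test][:, sup] @ coef
                cache[key] = 1.0 - np.sum((y[test] - pred) ** 2) / sst
            scores[s] += cache[key]
    best = int(np.argmax(scores + 1e-9 * np.arange(n_lambdas, 0, -1)))
    chosen = inter[best]
    return SupportMask(chosen[:N], chosen[N:])


@dataclass
class ErrorReport:
    """Per-parameter and aggregated fitted-vs-true errors.

    ``coupling``/``tuning`` hold raw differences (est - true) on all entries;
    ``coupling_norm``/``tuning_norm`` hold normalized errors
    ``(est - true)/true`` on the truly non-zero entries (others are NaN).
    ``n_excluded`` counts evaluated entries skipped for a zero true value.
    """

    coupling: np.ndarray
    tuning: np.ndarray
    coupling_norm: np.ndarray
    tuning_norm: np.ndarray
    n_excluded: int

    def median_abs(self) -> tuple[float, float]:
        return (float(np.nanmedian(np.abs(self.coupling_norm))),
                float(np.nanmedian(np.abs(self.tuning_norm))))


def normalized_error(estimate: StaticParams, truth: StaticParams) -> ErrorReport:
    """Normalized target-parameter errors ``(est - true)/true``.

    Only the coupling vector ``a`` and target tuning ``b`` are compared (the
    parameters shared between the CoTu and CoTuLa models); entries whose true
    value is exactly zero are excluded from the normalized arrays and counted.
    """
    dc = estimate.a - truth.a
    dt = estimate.b - truth.b
    nz_c = truth.a != 0
    nz_t = truth.b != 0
    cn = np.full(truth.a.shape, np.nan)
    tn = np.full(truth.b.shape, np.nan)
    cn[nz_c] = dc[nz_c] / truth.a[nz_c]
    tn[nz_t] = dt[nz_t] / truth.b[nz_t]
    n_excluded = int((~nz_c).sum() + (~nz_t).sum())
    return ErrorReport(coupling=dc, tuning=dt, coupling_norm=cn,
                       tuning_norm=tn, n_excluded=n_excluded)


def aggregate_errors(per_fit_norm: np.ndarray) -> float:
    """Aggregate a (models, datasets*folds, parameters) array of normalized
    errors: mean over datasets/folds, then median over parameters within each
    model, then median over models.  NaNs (excluded zero-true entries) are
    ignored at every stage."""
    per_fit_norm = np.asarray(per_fit_norm, float)
    with np.errstate(invalid="ignore"):
        by_param = np.nanmean(per_fit_norm, axis=1)      # models x params
        by_model = np.nanmedian(by_param, axis=1)        # models
        return float(np.nanmedian(by_model))
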