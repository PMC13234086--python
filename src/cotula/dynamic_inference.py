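"""Inference for the dynamic models.

* Dynamic coupling-tuning (CoTu) model: row-wise restricted least squares of
  ``y_t`` on ``[y_{t-1}, x_t]``.
* Dynamic coupling-tuning-latent (CoTuLa) model: EM with an exact linear-
  Gaussian latent posterior.  The posterior precision over the stacked latent
  trajectory is symmetric block tridiagonal; it is solved in O(T K^3) with a
  Kalman filter / RTS smoother, which also yields the observed-data
  log-likelihood used for the convergence trace.

Edge handling: the first observed sample ``y_0`` is treated as the initial
condition (its transition is dropped from the likelihood) and the latent
chain starts from the ``z_1 ~ N(0, I)`` prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._dynloops import kalman_rts, kalman_rts_1d
from .dynamic_model import DynamicDataset
from .params import DynamicParams, SupportMask
from .static_inference import VARIANCE_FLOOR, FitResult

__all__ = [
    "PosteriorStatsDynamic",
    "fit_dynamic_cotu_ols",
    "dynamic_e_step",
    "dynamic_expected_loglik",
    "fit_dynamic_cotula_em",
    "infer_support_dynamic",
    "temporal_structure_summary",
    "normalized_error_dynamic",
]


@dataclass
class PosteriorStatsDynamic:
    """Latent posterior blocks for the dynamic model.

    ``mu`` is T_eff x K (smoothed means); ``Lambda_diag[t]`` the K x K
    posterior covariance of ``z_t``; ``Lambda_offdiag[t]`` the lag-one block
    ``Cov(z_t, z_{t+1})``.  Only these blocks are stored: they are sufficient
    for every term of the expected complete log-likelihood.
    """

    mu: np.ndarray
    Lambda_diag: np.ndarray
    Lambda_offdiag: np.ndarray
    loglik: float


def _lagged(data: DynamicDataset):
    """(responses, lagged activity, stimulus) with the first transition
    dropped: Y1 = y_{1:T-1}, Y0 = y_{0:T-2}, X1 = x_{1:T-1}."""
    return data.Y[1:], data.Y[:-1], data.X[1:]


def fit_dynamic_cotu_ols(data: DynamicDataset,
                         support: SupportMask | None = None,
                         regime: str = "none"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise restricted least squares for the VAR(1) coupling-tuning model.

    Returns ``(A_hat, B_hat)``; entries outside the support are exactly zero.
    """
    Y1, Y0, X1 = _lagged(data)
    T_eff, N = Y1.shape
    M = X1.shape[1]
    if support is None:
        support = SupportMask.dense((N, N), (N, M))
    W = np.column_stack((Y0, X1))
    A_hat = np.zeros((N, N))
    B_hat = np.zeros((N, M))
    full_mask = np.column_stack((support.coupling_support,
                                 support.tuning_support))
    gram_full = W.T @ W
    rhs_full = W.T @ Y1
    for n in range(N):
        cols = np.flatnonzero(full_mask[n])
        if cols.size == 0:
            continue
        if T_eff <= cols.size:
            raise ValueError("need more time steps than active predictors")
        gram = gram_full[np.ix_(cols, cols)]
        if np.linalg.matrix_rank(gram) < cols.size:
            raise ValueError(f"rank-deficient design for unit {n}")
        coef = linalg.solve(gram, rhs_full[cols, n], assume_a="pos")
        for j, c in enumerate(cols):
            if c < N:
                A_hat[n, c] = coef[j]
            else:
                B_hat[n, c - N] = coef[j]
    return A_hat, B_hat


def dynamic_e_step(params: DynamicParams, data: DynamicDataset
                   ) -> PosteriorStatsDynamic:
    """Exact posterior of the latent trajectory given the data.

    Equivalent to inverting the symmetric block-tridiagonal posterior
    precision ``L~.T Sigma~^-1 L~ + D_G~.T D_G~`` restricted to its diagonal
    and first off-diagonal blocks, computed by Kalman filtering + RTS
    smoothing on the residuals ``r_t = y_t - A y_{t-1} - B x_t``.
    """
    if data.T < 2:
        raise ValueError("need at least two time points")
    if np.any(params.Sigma <= 0):
        raise ValueError("singular private noise covariance")
    Y1, Y0, X1 = _lagged(data)
    R = Y1 - Y0 @ params.A.T - X1 @ params.B.T
    if params.K == 1:
        # scalar-latent fast path: project the residuals once, then run the
        # purely scalar filter/smoother recursions
        l = params.L[:, 0]
        ltSi = l / params.Sigma
        info = R @ ltSi
        rq = np.sum(R * R / params.Sigma, axis=1)
        mu1, V1, Vlag1, ll = kalman_rts_1d(
            float(params.G[0, 0]), float(ltSi @ l), info, rq,
            float(np.sum(np.log(params.Sigma))), R.shape[1])
        return PosteriorStatsDynamic(
            mu=mu1[:, None], Lambda_diag=V1[:, None, None],
            Lambda_offdiag=Vlag1[:, None, None], loglik=float(ll))
    mu, V, Vlag, ll = kalman_rts(np.ascontiguousarray(params.G),
                                 np.ascontiguousarray(params.L),
                                 np.ascontiguousarray(params.Sigma),
                                 np.ascontiguousarray(R))
    return PosteriorStatsDynamic(mu=mu, Lambda_diag=V, Lambda_offdiag=Vlag,
                                 loglik=float(ll))


def dynamic_expected_loglik(params: DynamicParams, data: DynamicDataset,
                            post: PosteriorStatsDynamic) -> float:
    """Expected complete-data log-likelihood under the posterior ``post``.

    Sum of the observation quadratic and trace terms, the latent-prior
    quadratic and trace terms, and the (constant-per-step) log-determinant
    term ``T * log det Sigma``; uses only the stored diagonal and lag-one
    posterior blocks.  Additive constants (the 2*pi terms) are included so the
    value is a genuine log-density expectation.
    """
    Y1, Y0, X1 = _lagged(data)
    T_eff, N = Y1.shape
    K = params.K
    mu, V, Vlag = post.mu, post.Lambda_diag, post.Lambda_offdiag
    R = Y1 - Y0 @ params.A.T - X1 @ params.B.T
    E = R - mu @ params.L.T
    quad_obs = float(np.sum(E * E / params.Sigma))
    sumV = V.sum(axis=0)
    LtSiL = (params.L / params.Sigma[:, None]).T @ params.L
    trace_obs = float(np.trace(LtSiL @ sumV))
    D = mu[1:] - mu[:-1] @ params.G.T
    quad_prior = float(np.sum(mu[0] ** 2) + np.sum(D * D))
    G = params.G
    # tr(D_G~.T D_G~ Lambda) with [D_G~.T D_G~] having I + G.T G on the
    # diagonal (I only at the last block) and -G / -G.T off the diagonal
    trace_prior = float(np.trace(sumV) + np.trace(G.T @ G @ V[:-1].sum(axis=0))
                        - 2.0 * np.trace(G @ Vlag.sum(axis=0)))
    logdet = T_eff * float(np.sum(np.log(params.Sigma)))
    const = -0.5 * T_eff * (N + K) * np.log(2.0 * np.pi)
    return (-0.5 * (quad_obs + trace_obs + quad_prior + trace_prior + logdet)
            + const)


def _dynamic_m_step(data: DynamicDataset, post: PosteriorStatsDynamic,
                    support: SupportMask, K: int) -> DynamicParams:
    """Exact maximizer of the expected complete log-likelihood.

    Rows of ``(A, B, L)`` come from restricted least squares on the extended
    regressor ``[y_{t-1}, x_t, z_t]`` with the posterior second moment in the
    z-z Gram block; ``G`` from the latent lag regression; ``Sigma`` (diagonal)
    from the expected residuals.
    """
    Y1, Y0, X1 = _lagged(data)
    T_eff, N = Y1.shape
    M = X1.shape[1]
    mu, V, Vlag = post.mu, post.Lambda_diag, post.Lambda_offdiag
    U = np.column_stack((Y0, X1, mu))
    gram = U.T @ U
    zs = slice(N + M, N + M + K)
    Szz = V.sum(axis=0) + mu.T @ mu
    gram[zs, zs] = Szz
    rhs = U.T @ Y1
    A = np.zeros((N, N))
    B = np.zeros((N, M))
    L = np.zeros((N, K))
    full_mask = np.column_stack((support.coupling_support,
                                 support.tuning_support,
                                 np.ones((N, K), dtype=bool)))
    for n in range(N):
        cols = np.flatnonzero(full_mask[n])
        sub = gram[np.ix_(cols, cols)]
        coef = linalg.solve(sub, rhs[cols, n], assume_a="sym")
        row = np.zeros(N + M + K)
        row[cols] = coef
        A[n] = row[:N]
        B[n] = row[N:N + M]
        L[n] = row[zs]
    resid = Y1 - Y0 @ A.T - X1 @ B.T
    quad = (np.sum(resid * resid, axis=0)
            - 2.0 * np.sum(resid * (mu @ L.T), axis=0)
            + np.einsum("nk,kj,nj->n", L, Szz, L))
    Sigma = np.maximum(quad / T_eff, VARIANCE_FLOOR)
    # latent autoregression: G = (sum E[z_t z_{t-1}.T]) (sum E[z_{t-1} z_{t-1}.T])^-1
    S10 = Vlag.sum(axis=0).T + mu[1:].T @ mu[:-1]
    S00 = V[:-1].sum(axis=0) + mu[:-1].T @ mu[:-1]
    G = linalg.solve(S00.T, S10.T, assume_a="sym").T
    return DynamicParams(A=A, B=B, L=L, Sigma=Sigma, G=G,
                         H=np.zeros((M, M)))


def _init_dynamic(data: DynamicDataset, K: int, support: SupportMask,
                  rng: np.random.Generator | None) -> DynamicParams:
    """OLS start: (A, B) from the CoTu fit; latent block factor-analysis style
    from the OLS residual covariance; G from the residuals' lag-1 structure."""
    A, B = fit_dynamic_cotu_ols(data, support)
    Y1, Y0, X1 = _lagged(data)
    R = Y1 - Y0 @ A.T - X1 @ B.T
    C = np.cov(R, rowvar=False).reshape(R.shape[1], R.shape[1])
    evals, evecs = linalg.eigh(C)
    order = np.argsort(evals)[::-1][:K]
    lam = np.maximum(evals[order], VARIANCE_FLOOR)
    L = evecs[:, order] * np.sqrt(lam)
    proj = R @ evecs[:, order]                          # latent proxy series
    num = np.sum(proj[1:] * proj[:-1], axis=0)
    den = np.maximum(np.sum(proj[:-1] * proj[:-1], axis=0), 1e-12)
    g = np.clip(num / den, -0.95, 0.95)
    G = np.diag(g)
    Sigma = np.maximum(np.diag(C) - np.sum(L**2, axis=1), 10 * VARIANCE_FLOOR)
    if rng is not None:
        L = L + 0.1 * rng.standard_normal(L.shape)
    M = X1.shape[1]
    return DynamicParams(A=A, B=B, L=L, Sigma=Sigma, G=G, H=np.zeros((M, M)))


def fit_dynamic_cotula_em(data: DynamicDataset, K: int,
                          support: SupportMask | None = None,
                          init: DynamicParams | int | None = None,
                          max_iter: int = 200, tol: float = 1e-8,
                          regime: str = "none") -> FitResult:
    """EM fit of the dynamic coupling-tuning-latent model.

    The loglik trace holds the observed-data log-likelihood (from the Kalman
    filter) after each E-step; convergence is a relative change below ``tol``.
    Non-convergence is reported via ``converged=False``, never raised.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    N = data.Y.shape[1]
    M = data.X.shape[1]
    if support is None:
        support = SupportMask.dense((N, N), (N, M))
    if isinstance(init, DynamicParams):
        params = init.copy()
    else:
        rng = None if init is None else np.random.default_rng(init)
        params = _init_dynamic(data, K, support, rng)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = dynamic_e_step(params, data)
        trace.append(post.loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
        params = _dynamic_m_step(data, post, support, K)
    return FitResult(params=params, loglik_trace=np.asarray(trace),
                     n_iter=it, converged=converged, support_used=support,
                     regime=regime)


def infer_support_dynamic(data: DynamicDataset, cutoff: float = 3.0
                          ) -> SupportMask:
    """Normalization-and-cutoff support selection for the dynamic model.

    Fits the CoTu model by OLS and normalizes every coefficient by its own
    least-squares standard error; entries whose normalized magnitude exceeds
    ``cutoff`` (standard errors) are kept.  The default of 3 controls false
    positives over the tens of coefficients of a typical coupling/tuning
    matrix while keeping true coefficients, whose normalized magnitudes grow
    like sqrt(T), far above threshold.  Deterministic.  Under strong
    temporally-correlated unobserved variability the coupling bias inflates
    truly-zero entries, so selection degrades by false positives before false
    negatives.
    """
    A_hat, B_hat = fit_dynamic_cotu_ols(data)
    Y1, Y0, X1 = _lagged(data)
    T_eff, N = Y1.shape
    W = np.column_stack((Y0, X1))
    gram_inv = linalg.inv(W.T @ W)
    C_hat = np.column_stack((A_hat, B_hat))
    resid = Y1 - W @ C_hat.T
    dof = max(T_eff - W.shape[1], 1)
    sigma2 = np.sum(resid * resid, axis=0) / dof          # per response row
    se = np.sqrt(np.outer(sigma2, np.diag(gram_inv)))     # N x (N+M)
    keep = np.abs(C_hat) / np.maximum(se, 1e-300) > cutoff
    return SupportMask(keep[:, :N], keep[:, N:])


def temporal_structure_summary(A_hat: np.ndarray, X: np.ndarray,
                               G_hat: np.ndarray) -> tuple[float, float, float]:
    """Summarize temporal structure as three leading eigenvalues.

    ``a``: eigenvalue of the fitted coupling matrix with the largest real
    part; ``h``: same for a VAR(1) fit to the stimulus series ``X``;
    ``g``: same for the fitted latent autoregression ``G_hat``.
    """
    def lead(mat):
        ev = np.linalg.eigvals(np.atleast_2d(mat))
        return float(np.real(ev[np.argmax(ev.real)]))

    X = np.asarray(X, float)
    H_hat, *_ = np.linalg.lstsq(X[:-1], X[1:], rcond=None)
    return lead(A_hat), lead(H_hat.T), lead(G_hat)


def normalized_error_dynamic(A_hat, B_hat, truth: DynamicParams):
    """Normalized errors ``(est - true)/true`` for the non-zero entries of the
    true coupling and tuning matrices; returns (coupling_errs, tuning_errs)
    as flat arrays over the true supports."""
    nz_A = truth.A != 0
    nz_B = truth.B != 0
    return ((np.asarray(A_hat)[nz_A] - truth.A[nz_A]) / truth.A[nz_A],
            (np.asarray(B_hat)[nz_B] - truth.B[nz_B]) / truth.B[nz_B])
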