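"""Numba-compiled inner loops for the dynamic model.

These are the only time-stepped recursions in the package: VAR(1) simulation
and the Kalman filter / Rauch-Tung-Striebel smoother used for the latent
posterior of the dynamic coupling-tuning-latent model.  The smoother is the
O(T K^3) equivalent of solving the symmetric block-tridiagonal posterior
precision system; the dense-inversion route lives in the test suite as the
independent oracle.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def simulate_var1(coef, innov, init):
    """x_t = coef @ x_{t-1} + innov_t, iterated over the rows of ``innov``."""
    T, d = innov.shape
    out = np.empty((T, d))
    prev = init.copy()
    for t in range(T):
        cur = coef @ prev + innov[t]
        out[t] = cur
        prev = cur
    return out


@njit(cache=False)
def simulate_dynamic_y(A, B, L, X, Z, psi, y0):
    """y_t = A y_{t-1} + B x_t + L z_t + psi_t."""
    T = X.shape[0]
    N = A.shape[0]
    Y = np.empty((T, N))
    prev = y0.copy()
    for t in range(T):
        cur = A @ prev + B @ X[t] + L @ Z[t] + psi[t]
        Y[t] = cur
        prev = cur
    return Y


@njit(cache=False)
def kalman_rts_1d(g, ltSiL, info, rq, log_det_sigma, N):
    """Scalar-latent (K = 1) specialization of :func:`kalman_rts`.

    Works on precomputed per-step projections: ``info[t] = L.T Sigma^-1 r_t``
    and ``rq[t] = r_t.T Sigma^-1 r_t``; the recursions are then purely scalar.
    """
    T = info.shape[0]
    g2 = g * g
    m_p = np.empty(T)
    P_p = np.empty(T)
    m_f = np.empty(T)
    P_f = np.empty(T)
    loglik = 0.0
    log_two_pi = np.log(2.0 * np.pi)
    for t in range(T):
        if t == 0:
            mp = 0.0
            Pp = 1.0
        else:
            mp = g * m_f[t - 1]
            Pp = g2 * P_f[t - 1] + 1.0
        post_prec = 1.0 / Pp + ltSiL
        Pf = 1.0 / post_prec
        mf = Pf * (mp / Pp + info[t])
        m_p[t] = mp
        P_p[t] = Pp
        m_f[t] = mf
        P_f[t] = Pf
        u = info[t] - mp * ltSiL
        quad = rq[t] - 2.0 * mp * info[t] + mp * mp * ltSiL - u * u * Pf
        log_det_S = log_det_sigma + np.log(post_prec) + np.log(Pp)
        loglik += -0.5 * (N * log_two_pi + log_det_S + quad)
    mu = np.empty(T)
    V = np.empty(T)
    Vlag = np.empty(max(T - 1, 0))
    mu[T - 1] = m_f[T - 1]
    V[T - 1] = P_f[T - 1]
    for t in range(T - 2, -1, -1):
        C = P_f[t] * g / P_p[t + 1]
        mu[t] = m_f[t] + C * (mu[t + 1] - m_p[t + 1])
        V[t] = P_f[t] + C * C * (V[t + 1] - P_p[t + 1])
        Vlag[t] = C * V[t + 1]
    return mu, V, Vlag, loglik


@njit(cache=False)
def kalman_rts(G, L, sigma_diag, R):
    """Kalman filter + RTS smoother for the chain

        z_1 ~ N(0, I),  z_t = G z_{t-1} + N(0, I),  r_t = L z_t + N(0, Sigma)

    with diagonal observation noise ``sigma_diag`` (length N) and residual
    observations ``R`` (T x N).  Returns (mu, V, Vlag, loglik) where ``mu`` is
    the T x K smoothed mean, ``V[t]`` the smoothed covariance Cov(z_t | D),
    ``Vlag[t]`` the lag-one covariance Cov(z_t, z_{t+1} | D), and ``loglik``
    the observed-data log-likelihood of ``R``.
    """
    T, N = R.shape
    K = G.shape[0]
    Lt_Si = (L / sigma_diag.reshape(N, 1)).T        # K x N = L^T Sigma^-1
    LtSiL = Lt_Si @ L                               # K x K
    log_det_sigma = np.sum(np.log(sigma_diag))
    I_K = np.eye(K)

    m_p = np.empty((T, K))          # predicted means
    P_p = np.empty((T, K, K))       # predicted covariances
    m_f = np.empty((T, K))          # filtered means
    P_f = np.empty((T, K, K))
    loglik = 0.0
    two_pi = 2.0 * np.pi

    for t in range(T):
        if t == 0:
            mp = np.zeros(K)
            Pp = I_K.copy()
        else:
            mp = G @ m_f[t - 1]
            Pp = G @ P_f[t - 1] @ G.T + I_K
        m_p[t] = mp
        P_p[t] = Pp
        Pp_inv = np.linalg.inv(Pp)
        post_prec = Pp_inv + LtSiL
        Pf = np.linalg.inv(post_prec)
        Pf = 0.5 * (Pf + Pf.T)
        info = Lt_Si @ R[t]
        mf = Pf @ (Pp_inv @ mp + info)
        m_f[t] = mf
        P_f[t] = Pf
        # innovation log-density via the matrix-determinant / Woodbury lemmas
        e = R[t] - L @ mp
        u = Lt_Si @ e                               # K
        quad = np.sum(e * e / sigma_diag) - u @ (Pf @ u)
        sign, ld_prec = np.linalg.slogdet(post_prec)
        sign2, ld_pp = np.linalg.slogdet(Pp)
        log_det_S = log_det_sigma + ld_prec + ld_pp
        loglik += -0.5 * (N * np.log(two_pi) + log_det_S + quad)

    mu = np.empty((T, K))
    V = np.empty((T, K, K))
    Vlag = np.empty((max(T - 1, 0), K, K))
    mu[T - 1] = m_f[T - 1]
    V[T - 1] = P_f[T - 1]
    for t in range(T - 2, -1, -1):
        C = P_f[t] @ G.T @ np.linalg.inv(P_p[t + 1])
        mu[t] = m_f[t] + C @ (mu[t + 1] - m_p[t + 1])
        Vt = P_f[t] + C @ (V[t + 1] - P_p[t + 1]) @ C.T
        V[t] = 0.5 * (Vt + Vt.T)
        Vlag[t] = C @ V[t + 1]
    return mu, V, Vlag, loglik
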