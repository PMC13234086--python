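"""Static coupling-tuning-latent generative model.

This module provides exact Gaussian machinery for the trial-level model: data
generation, the joint moments of ``(y_i, y_not, z) | x``, the closed-form
precision matrix, the marginal log-likelihood of the observed activity, the
likelihood-preserving identifiability transform, and the sparsity-based
identifiability (rank) test.

Block ordering everywhere is ``(y_i, y_not, z)``: target first, then the N
non-target units, then the K latent coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .params import StaticParams, SupportMask

__all__ = [
    "StaticDataset",
    "IdentifiabilityTransform",
    "generate_static",
    "uniform_correlation_params",
    "joint_moments",
    "precision_matrix",
    "marginal_loglik",
    "apply_transform",
    "admissible_interval",
    "transform_family",
    "identifiability_check",
]


@dataclass
class StaticDataset:
    """Trial-level data: stimulus ``X`` (D x M), non-target activity ``Y_not``
    (D x N), target activity ``y`` (length D) and, when produced by the
    generator, the latent draws ``Z`` (D x K) actually used."""

    X: np.ndarray
    Y_not: np.ndarray
    y: np.ndarray
    Z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.Y_not = np.asarray(self.Y_not, float)
        self.y = np.asarray(self.y, float)
        D = self.X.shape[0]
        if self.Y_not.shape[0] != D or self.y.shape != (D,):
            raise ValueError("X, Y_not and y must agree on the number of trials")
        arrays = [self.X, self.Y_not, self.y]
        if self.Z is not None:
            self.Z = np.asarray(self.Z, float)
            if self.Z.shape[0] != D:
                raise ValueError("Z must have one row per trial")
            arrays.append(self.Z)
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("dataset contains non-finite entries")

    @property
    def D(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "StaticDataset":
        return StaticDataset(self.X[idx], self.Y_not[idx], self.y[idx],
                             None if self.Z is None else self.Z[idx])


def _draw_stimulus(rng: np.random.Generator, D: int, M: int, spec) -> np.ndarray:
    """Draw a D x M stimulus matrix.

    ``spec`` is either ``"gaussian"`` (i.i.d. standard normal, the default) or
    ``("categorical", n_levels)`` producing one-hot rows over ``M`` columns
    with ``n_levels <= M`` active levels, for tuning-curve style designs.
    """
    if spec is None or spec == "gaussian":
        return rng.standard_normal((D, M))
    if isinstance(spec, (tuple, list)) and spec[0] == "categorical":
        n_levels = int(spec[1]) if len(spec) > 1 else M
        if n_levels > M:
            raise ValueError("categorical stimulus needs n_levels <= M")
        X = np.zeros((D, M))
        X[np.arange(D), rng.integers(0, n_levels, size=D)] = 1.0
        return X
    raise ValueError(f"unrecognized stimulus_spec {spec!r}")


def generate_static(params: StaticParams, D: int, stimulus_spec="gaussian",
                    seed: int | np.random.Generator = 0) -> StaticDataset:
    """Simulate ``D`` trials from the static coupling-tuning-latent model.

    The same latent draw ``z ~ N(0, I_K)`` feeds the target and non-target
    units within a trial; the returned dataset carries the draws in ``Z``.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N, M, K = params.N, params.M, params.K
    X = _draw_stimulus(rng, D, M, stimulus_spec)
    Z = rng.standard_normal((D, K))
    psi_not = rng.standard_normal((D, N)) * np.sqrt(params.Psi_not)
    Y_not = params.b0_not + X @ params.B_not + Z @ params.L_not + psi_not
    psi_i = rng.standard_normal(D) * np.sqrt(params.psi)
    y = params.b0 + Y_not @ params.a + X @ params.b + Z @ params.l + psi_i
    return StaticDataset(X=X, Y_not=Y_not, y=y, Z=Z)


def uniform_correlation_params(a, b, B_not, noise_corr: float = 0.10,
                               total_noise_var: float = 1.0) -> StaticParams:
    """Build a model whose unobserved variability has uniform pairwise noise
    correlations across all ``N + 1`` units.

    Uses a single latent factor (K = 1) with identical loading ``l`` and
    identical private variance ``psi`` on every unit, chosen so that
    ``l**2 / (l**2 + psi) = noise_corr`` and ``l**2 + psi = total_noise_var``.
    """
    if not 0 <= noise_corr < 1:
        raise ValueError("noise_corr must be in [0, 1)")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    B_not = np.asarray(B_not, float)
    N = a.size
    l2 = noise_corr * total_noise_var
    psi = total_noise_var - l2
    return StaticParams(
        a=a, b=b, B_not=B_not,
        l=np.full(1, np.sqrt(l2)),
        L_not=np.full((1, N), np.sqrt(l2)),
        psi=psi, Psi_not=np.full(N, psi),
    )


def joint_moments(params: StaticParams, x: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and covariance of ``(y_i, y_not, z)`` given stimulus ``x``."""
    x = np.asarray(x, float)
    N, K = params.N, params.K
    a, l, L = params.a, params.l, params.L_not
    Pi = params.Pi_not
    m_not = params.b0_not + params.B_not.T @ x
    mean = np.concatenate((
        [params.b0 + x @ params.b + m_not @ a], m_not, np.zeros(K)))
    la = l + L @ a                       # K-vector: total latent path into y_i
    C_not = Pi + L.T @ L                 # Cov(y_not)
    cov = np.empty((1 + N + K, 1 + N + K))
    cov[0, 0] = params.psi + a @ Pi @ a + la @ la
    cov[0, 1:1 + N] = a @ Pi + la @ L
    cov[0, 1 + N:] = la
    cov[1:1 + N, 0] = cov[0, 1:1 + N]
    cov[1:1 + N, 1:1 + N] = C_not
    cov[1:1 + N, 1 + N:] = L.T
    cov[1 + N:, 0] = la
    cov[1 + N:, 1:1 + N] = L
    cov[1 + N:, 1 + N:] = np.eye(K)
    return mean, cov


def precision_matrix(params: StaticParams) -> np.ndarray:
    """Closed-form inverse of the joint covariance of ``(y_i, y_not, z)``.

    Requires strictly positive private variances (the covariance is singular
    otherwise).  The result is symmetric; the target/latent off-diagonal block
    is ``-l / psi`` (the transpose of the upper-right block).
    """
    if params.psi <= 0 or np.any(params.Psi_not <= 0):
        raise ValueError("precision matrix requires strictly positive "
                         "private variances")
    N, K = params.N, params.K
    a, l, L = params.a, params.l, params.L_not
    psi_inv = 1.0 / params.psi
    Pi_inv = np.diag(1.0 / params.Psi_not)
    P = np.empty((1 + N + K, 1 + N + K))
    P[0, 0] = psi_inv
    P[0, 1:1 + N] = -psi_inv * a
    P[0, 1 + N:] = -psi_inv * l
    P[1:1 + N, 0] = -psi_inv * a
    P[1:1 + N, 1:1 + N] = Pi_inv + psi_inv * np.outer(a, a)
    P[1:1 + N, 1 + N:] = psi_inv * np.outer(a, l) - Pi_inv @ L.T
    P[1 + N:, 0] = -psi_inv * l
    P[1 + N:, 1:1 + N] = P[1:1 + N, 1 + N:].T
    P[1 + N:, 1 + N:] = np.eye(K) + psi_inv * np.outer(l, l) + L @ Pi_inv @ L.T
    return P


def _observed_moments(params: StaticParams) -> tuple[np.ndarray, np.ndarray]:
    """Marginal covariance of the observed block (y_i, y_not) and the matrix
    mapping a stimulus to the observed mean."""
    N, M = params.N, params.M
    _, cov = joint_moments(params, np.zeros(M))
    cov_obs = cov[:1 + N, :1 + N]
    # mean of (y_i, y_not) is W @ x + intercept
    W = np.vstack(((params.b + params.B_not @ params.a)[None, :], params.B_not.T))
    mu0 = np.concatenate(([params.b0 + params.b0_not @ params.a], params.b0_not))
    return cov_obs, (W, mu0)


def marginal_loglik(params: StaticParams, data: StaticDataset) -> float:
    """Log-likelihood of the observed activity ``(y_i, y_not)`` given ``X``,
    with the latent state integrated out, summed over trials."""
    cov_obs, (W, mu0) = _observed_moments(params)
    try:
        cho = linalg.cho_factor(cov_obs, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("marginal covariance of the observed activity is not "
                         "positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    obs = np.column_stack((data.y, data.Y_not))       # D x (N+1)
    resid = obs - data.X @ W.T - mu0
    solved = linalg.cho_solve(cho, resid.T)
    quad = np.sum(resid.T * solved)
    D, p = data.D, 1 + params.N
    return float(-0.5 * (quad + D * (logdet + p * np.log(2.0 * np.pi))))


@dataclass
class IdentifiabilityTransform:
    """The delta-parameterized family of equal-likelihood reparameterizations.

    ``P`` is the precision of the non-target unobserved variability,
    ``Q = P L_notᵀ`` and ``R = B_not Q`` are the matrices whose rows enter the
    identifiability (rank) test; ``W = L_not P L_notᵀ`` controls the quadratic
    private-variance update.
    """

    delta: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    W: np.ndarray

    @classmethod
    def from_params(cls, params: StaticParams, delta=None) -> "IdentifiabilityTransform":
        L = params.L_not
        C = params.Pi_not + L.T @ L
        P = linalg.inv(C)
        P = 0.5 * (P + P.T)
        Q = P @ L.T
        R = params.B_not @ Q
        W = L @ Q
        W = 0.5 * (W + W.T)
        d = np.zeros(params.K) if delta is None else np.asarray(delta, float)
        return cls(delta=d, P=P, Q=Q, R=R, W=W)


def _psi_shift(params: StaticParams, W: np.ndarray, delta: np.ndarray) -> float:
    """Change in the target private variance under the transform.

    The likelihood-preserving update is
    ``psi' = psi - 2 l.T (I - W) delta - delta.T (I - W) delta`` with
    ``W = L_not P L_notᵀ``; it keeps every observed-block moment fixed.
    """
    IW = np.eye(params.K) - W
    return float(-2.0 * params.l @ IW @ delta - delta @ IW @ delta)


def apply_transform(params: StaticParams, delta, *, tol: float = 1e-12
                    ) -> StaticParams:
    """Apply the identifiability transform for direction ``delta`` (length K).

    Returns a new parameter set with identical marginal likelihood on any
    dataset.  Raises if the transformed private variance would be negative
    (inadmissible ``delta``); for K = 1 the error message reports the
    admissible interval.
    """
    delta = np.atleast_1d(np.asarray(delta, float))
    if delta.shape != (params.K,):
        raise ValueError(f"delta must have length K={params.K}")
    tr = IdentifiabilityTransform.from_params(params, delta)
    psi_new = params.psi + _psi_shift(params, tr.W, delta)
    if psi_new < -tol:
        msg = f"delta is inadmissible: transformed private variance {psi_new:.3e} < 0"
        if params.K == 1:
            lo, hi = admissible_interval(params)
            msg += f"; admissible interval is [{lo:.6g}, {hi:.6g}]"
        raise ValueError(msg)
    u = tr.Q @ delta
    return StaticParams(
        a=params.a - u,
        b=params.b + params.B_not @ u,
        B_not=params.B_not.copy(),
        l=params.l + delta,
        L_not=params.L_not.copy(),
        psi=max(psi_new, 0.0),
        Psi_not=params.Psi_not.copy(),
        # a changes, so the target intercept absorbs the non-target intercepts
        # to keep the observed mean fixed
        b0=params.b0 + params.b0_not @ u,
        b0_not=params.b0_not.copy(),
    )


def admissible_interval(params: StaticParams) -> tuple[float, float]:
    """For K = 1, the interval of ``delta`` with non-negative transformed
    private variance.  ``psi'(delta)`` is a downward parabola; the endpoints
    are its roots and the apex sits at ``delta* = -l`` (where the target
    loading vanishes)."""
    if params.K != 1:
        raise ValueError("admissible interval is scalar only for K = 1")
    tr = IdentifiabilityTransform.from_params(params)
    w = float(tr.W[0, 0])
    c = 1.0 - w
    if c <= 0:
        raise ValueError("degenerate transform geometry (1 - W <= 0)")
    l = float(params.l[0])
    disc = l * l + params.psi / c
    root = np.sqrt(max(disc, 0.0))
    return (-l - root, -l + root)


def transform_family(params: StaticParams, n_points: int) -> list[StaticParams]:
    """Equally spaced members of the K = 1 identifiability family.

    The ``n_points`` delta values span the full admissible interval, so the
    two endpoints have (numerically) zero target private variance.
    """
    if params.K != 1:
        raise ValueError("transform_family supports K = 1 only; for K > 1 the "
                         "family is a K-dimensional manifold")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    lo, hi = admissible_interval(params)
    return [apply_transform(params, [d]) for d in np.linspace(lo, hi, n_points)]


def identifiability_check(params: StaticParams, support: SupportMask
                   ) -> tuple[bool, int]:
    """Test whether sparse support removes the structural non-identifiability.

    Stacks the rows of ``Q = P L_notᵀ`` indexed by zero coupling entries and
    the rows of ``R = B_not Q`` indexed by zero tuning entries into ``S``.
    Returns ``(condition_holds, rank_deficiency)`` where ``condition_holds``
    is true iff ``K <= N k_C + M k_T`` *and* ``S`` has rank ``K`` (so the only
    support-preserving transform direction is ``delta = 0``), and
    ``rank_deficiency = K - rank(S)`` counts the independent support-preserving
    directions that remain.
    """
    N, M, K = params.N, params.M, params.K
    if support.coupling_support.shape != (N,) or support.tuning_support.shape != (M,):
        raise ValueError("support shapes must match (N, M)")
    tr = IdentifiabilityTransform.from_params(params)
    rows = []
    zc = ~support.coupling_support
    zt = ~support.tuning_support
    if zc.any():
        rows.append(tr.Q[zc])
    if zt.any():
        rows.append(tr.R[zt])
    n_zero = int(zc.sum() + zt.sum())
    if rows:
        S = np.vstack(rows)
        sv = linalg.svdvals(S)
        rank_tol = max(S.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
        rank = int(np.sum(sv > rank_tol))
    else:
        rank = 0
    condition_holds = (K <= n_zero) and (rank == K)
    return condition_holds, K - rank


def support_preserving_delta(params: StaticParams, support: SupportMask
                             ) -> np.ndarray | None:
    """A non-zero delta direction that preserves the zero pattern of ``a`` and
    ``b`` (a nullspace vector of the stacked constraint matrix ``S``), or ``None`` when
    the support renders the model identifiable."""
    tr = IdentifiabilityTransform.from_params(params)
    rows = []
    zc = ~support.coupling_support
    zt = ~support.tuning_support
    if zc.any():
        rows.append(tr.Q[zc])
    if zt.any():
        rows.append(tr.R[zt])
    S = np.vstack(rows) if rows else np.zeros((0, params.K))
    ns = linalg.null_space(S)
    if ns.shape[1] == 0:
        return None
    return ns[:, 0]
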