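"""Dynamic (VAR(1)) coupling-tuning-latent generative model.

Provides simulation of the coupled system

    y_t = A y_{t-1} + B x_t + L z_t + psi_t
    z_t = G z_{t-1} + eta_t,      eta_t ~ N(0, I_K)
    x_t = H x_{t-1} + eta_x_t

and the closed-form normalized errors of the naive least-squares estimator in
the univariate (N = M = K = 1) model, which quantify how temporally
correlated unobserved variability (g != 0) inflates the coupling estimate and
- when the stimulus is itself autocorrelated (h != 0) - deflates the tuning
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dynloops import simulate_var1, simulate_dynamic_y
from .params import DynamicParams

__all__ = [
    "DynamicDataset",
    "generate_dynamic",
    "stationary_moments_univariate",
    "analytic_univariate_errors",
]


@dataclass
class DynamicDataset:
    """Multivariate time series: stimulus ``X`` (T x M), activity ``Y``
    (T x N) and, when produced by the generator, the latent series ``Z``."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.Y = np.asarray(self.Y, float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must cover the same time points")
        arrays = [self.X, self.Y]
        if self.Z is not None:
            self.Z = np.asarray(self.Z, float)
            if self.Z.shape[0] != self.X.shape[0]:
                raise ValueError("Z must cover the same time points")
            arrays.append(self.Z)
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("dataset contains non-finite entries")

    @property
    def T(self) -> int:
        return self.X.shape[0]


def generate_dynamic(params: DynamicParams, T: int, burn_in: int = 500,
                     seed: int | np.random.Generator = 0) -> DynamicDataset:
    """Simulate ``T`` time steps (after discarding ``burn_in`` initial steps).

    All three AR(1) chains start from zero and run through the burn-in, so the
    retained samples are effectively stationary.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    params.check_stationary()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N, M, K = params.N, params.M, params.K
    Ttot = T + burn_in
    eta_x = rng.standard_normal((Ttot, M)) * np.sqrt(params.sigma_x2)
    X = simulate_var1(np.ascontiguousarray(params.H), eta_x, np.zeros(M))
    eta_z = rng.standard_normal((Ttot, K))
    Z = simulate_var1(np.ascontiguousarray(params.G), eta_z, np.zeros(K))
    psi = rng.standard_normal((Ttot, N)) * np.sqrt(params.Sigma)
    Y = simulate_dynamic_y(np.ascontiguousarray(params.A),
                           np.ascontiguousarray(params.B),
                           np.ascontiguousarray(params.L),
                           X, Z, psi, np.zeros(N))
    return DynamicDataset(X=X[burn_in:], Y=Y[burn_in:], Z=Z[burn_in:])


def stationary_moments_univariate(params: DynamicParams) -> dict:
    """Exact stationary second moments of the univariate model.

    Derived from the lag-covariance equations of the joint (y, x, z) linear
    system::

        E[x^2] = sigma_x^2 / (1 - h^2)
        E[z^2] = 1 / (1 - g^2)
        E[x_t y_{t-1}] = h b E[x^2] / (1 - h a)
        E[z_t y_{t-1}] = g l E[z^2] / (1 - g a)
        E[y^2] (1 - a^2) = b^2 E[x^2] (1+ah)/(1-ah)
                           + l^2 E[z^2] (1+ag)/(1-ag) + sigma^2
    """
    a, b, l, g, h, sig2 = params.univariate()
    sx2 = float(params.sigma_x2[0])
    if abs(1 - g * a) < 1e-12 or abs(1 - h * a) < 1e-12:
        raise ValueError("degenerate temporal structure: 1 - g a or 1 - h a is 0")
    Ex2 = sx2 / (1.0 - h * h)
    Ez2 = 1.0 / (1.0 - g * g)
    Ey2 = (b * b * Ex2 * (1 + a * h) / (1 - a * h)
           + l * l * Ez2 * (1 + a * g) / (1 - a * g)
           + sig2) / (1.0 - a * a)
    return {"E[y^2]": Ey2, "E[x^2]": Ex2, "E[z^2]": Ez2,
            "E[x_t y_{t-1}]": h * b * Ex2 / (1 - h * a),
            "E[eps_t y_{t-1}]": g * l * l * Ez2 / (1 - g * a)}


def analytic_univariate_errors(params: DynamicParams, moments="stationary"
                               ) -> tuple[float, float]:
    """Closed-form normalized least-squares errors for the univariate model.

    Returns ``(rel_err_a, rel_err_b)``, the asymptotic values of
    ``(a_hat - a)/a`` and ``(b_hat - b)/b`` for the naive OLS estimator that
    regresses ``y_t`` on ``(y_{t-1}, x_t)``::

        [rel_err_a, rel_err_b] =
            (g a / (1 - g a)) * l^2 E[z^2]
            / (a^2 E[y^2] - (h a / (1 - h a))^2 b^2 E[x^2])
            * [1, -(h a / (1 - h a))]

    ``moments`` is either the string ``"stationary"`` (computed exactly via
    :func:`stationary_moments_univariate`) or a mapping with keys
    ``E[y^2]``, ``E[x^2]``, ``E[z^2]``.
    """
    a, b, l, g, h, _ = params.univariate()
    if abs(1 - g * a) < 1e-12 or abs(1 - h * a) < 1e-12:
        raise ValueError("1 - g a and 1 - h a must be non-zero")
    if moments == "stationary":
        moments = stationary_moments_univariate(params)
    Ey2, Ex2, Ez2 = moments["E[y^2]"], moments["E[x^2]"], moments["E[z^2]"]
    if g == 0.0:
        return 0.0, 0.0
    ha = h * a / (1.0 - h * a)
    denom = a * a * Ey2 - ha * ha * b * b * Ex2
    if denom == 0.0:
        raise ValueError("error expression denominator vanished")
    scale = (g * a / (1.0 - g * a)) * (l * l * Ez2) / denom
    return float(scale), float(-scale * ha)


def analytic_univariate_raw_errors(params: DynamicParams) -> tuple[float, float]:
    """Asymptotic raw OLS errors ``(a_hat - a, b_hat - b)`` for the univariate
    model, valid also when ``a = 0`` (where the normalized error is
    undefined).  Computed directly from the population normal equations."""
    a, b, l, g, h, _ = params.univariate()
    mom = stationary_moments_univariate(params)
    Ey2, Ex2 = mom["E[y^2]"], mom["E[x^2]"]
    Exy1 = mom["E[x_t y_{t-1}]"]
    Eey1 = mom["E[eps_t y_{t-1}]"]
    det = Ey2 * Ex2 - Exy1 * Exy1
    err_a = Ex2 * Eey1 / det
    err_b = -Exy1 * Eey1 / det
    return float(err_a), float(err_b)
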