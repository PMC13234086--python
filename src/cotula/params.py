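"""Parameter containers for the static and dynamic coupling-tuning-latent models.

Conventions used throughout the package:

* The static model describes a population of ``N + 1`` simultaneously recorded
  units: one *target* unit and ``N`` *non-target* units.  Whenever a full
  population array appears (e.g. in CSV output), the target is column 0.
* ``M`` is the number of stimulus (external-variable) features and ``K`` the
  latent dimensionality.
* All arrays are float64 numpy arrays; scalars are Python floats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "StaticParams",
    "DynamicParams",
    "SupportMask",
    "load_params",
    "save_params",
]


def _as_array(x, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class StaticParams:
    """Full parameterization of the static coupling-tuning-latent model.

    The generative model for one trial with stimulus ``x`` is::

        y_not = B_not.T @ x + L_not.T @ z + psi_not,   z ~ N(0, I_K)
        y_i   = a @ y_not + b.T @ x + l.T @ z + psi_i

    where ``psi_i ~ N(0, psi)`` and ``psi_not ~ N(0, diag(Psi_not))`` are
    private (per-unit) noise terms and ``z`` is the shared latent state.

    Attributes
    ----------
    a : (N,) coupling of the target onto the non-target activity.
    b : (M,) target tuning.
    B_not : (M, N) non-target tuning matrix.
    l : (K,) target latent loading.
    L_not : (K, N) non-target latent loadings.
    psi : target private variance (>= 0).
    Psi_not : (N,) non-target private variances (>= 0).
    b0, b0_not : optional intercepts (default 0).
    """

    a: np.ndarray
    b: np.ndarray
    B_not: np.ndarray
    l: np.ndarray
    L_not: np.ndarray
    psi: float
    Psi_not: np.ndarray
    b0: float = 0.0
    b0_not: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = _as_array(self.a, 1, "a")
        self.b = _as_array(self.b, 1, "b")
        self.B_not = _as_array(self.B_not, 2, "B_not")
        self.l = _as_array(self.l, 1, "l")
        self.L_not = _as_array(self.L_not, 2, "L_not")
        self.Psi_not = _as_array(self.Psi_not, 1, "Psi_not")
        self.psi = float(self.psi)
        N, M, K = self.a.size, self.b.size, self.l.size
        if self.B_not.shape != (M, N):
            raise ValueError(f"B_not must have shape {(M, N)}, got {self.B_not.shape}")
        if self.L_not.shape != (K, N):
            raise ValueError(f"L_not must have shape {(K, N)}, got {self.L_not.shape}")
        if self.Psi_not.shape != (N,):
            raise ValueError(f"Psi_not must have shape {(N,)}, got {self.Psi_not.shape}")
        if self.psi < 0:
            raise ValueError(f"target private variance must be >= 0, got {self.psi}")
        if np.any(self.Psi_not < 0):
            raise ValueError("non-target private variances must be >= 0")
        if self.b0_not is None:
            self.b0_not = np.zeros(N)
        else:
            self.b0_not = _as_array(self.b0_not, 1, "b0_not")
            if self.b0_not.shape != (N,):
                raise ValueError("b0_not must have length N")
        self.b0 = float(self.b0)

    @property
    def N(self) -> int:
        return self.a.size

    @property
    def M(self) -> int:
        return self.b.size

    @property
    def K(self) -> int:
        return self.l.size

    @property
    def Pi_not(self) -> np.ndarray:
        """diag(Psi_not): non-target private covariance."""
        return np.diag(self.Psi_not)

    def copy(self) -> "StaticParams":
        return StaticParams(
            a=self.a.copy(), b=self.b.copy(), B_not=self.B_not.copy(),
            l=self.l.copy(), L_not=self.L_not.copy(), psi=self.psi,
            Psi_not=self.Psi_not.copy(), b0=self.b0, b0_not=self.b0_not.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "model": "static_cotula",
            "a": self.a.tolist(), "b": self.b.tolist(),
            "B_not": self.B_not.tolist(), "l": self.l.tolist(),
            "L_not": self.L_not.tolist(), "psi": self.psi,
            "Psi_not": self.Psi_not.tolist(), "b0": self.b0,
            "b0_not": self.b0_not.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StaticParams":
        return cls(
            a=np.asarray(d["a"], float), b=np.asarray(d["b"], float),
            B_not=np.asarray(d["B_not"], float), l=np.asarray(d["l"], float),
            L_not=np.asarray(d["L_not"], float), psi=d["psi"],
            Psi_not=np.asarray(d["Psi_not"], float), b0=d.get("b0", 0.0),
            b0_not=np.asarray(d["b0_not"], float) if "b0_not" in d else None,
        )


@dataclass
class DynamicParams:
    """Parameterization of the dynamic (VAR(1)) coupling-tuning-latent model::

        y_t = A y_{t-1} + B x_t + L z_t + psi_t,   psi_t ~ N(0, Sigma)
        z_t = G z_{t-1} + eta_t,                   eta_t ~ N(0, I_K)
        x_t = H x_{t-1} + eta_x_t,                 eta_x_t ~ N(0, sigma_x2 I_M)

    The latent innovation covariance is fixed to the identity, which pins the
    latent scale; ``Sigma`` is diagonal (i.i.d. private noise per unit).  By
    default the stimulus innovation variance is chosen so the stationary
    stimulus variance is 1 regardless of ``H`` (``sigma_x2 = None``).
    """

    A: np.ndarray
    B: np.ndarray
    L: np.ndarray
    Sigma: np.ndarray   # (N,) diagonal entries of the private noise covariance
    G: np.ndarray
    H: np.ndarray
    sigma_x2: np.ndarray | None = None  # (M,) stimulus innovation variances

    def __post_init__(self) -> None:
        self.A = _as_array(self.A, 2, "A")
        self.B = _as_array(self.B, 2, "B")
        self.L = _as_array(self.L, 2, "L")
        self.Sigma = _as_array(self.Sigma, 1, "Sigma")
        self.G = _as_array(np.atleast_2d(self.G), 2, "G")
        self.H = _as_array(np.atleast_2d(self.H), 2, "H")
        N = self.A.shape[0]
        if self.A.shape != (N, N):
            raise ValueError("A must be square")
        M = self.B.shape[1]
        K = self.L.shape[1]
        if self.B.shape != (N, M):
            raise ValueError(f"B must have shape {(N, M)}")
        if self.L.shape != (N, K):
            raise ValueError(f"L must have shape {(N, K)}")
        if self.Sigma.shape != (N,):
            raise ValueError("Sigma must hold the N diagonal entries")
        if np.any(self.Sigma <= 0):
            raise ValueError("private noise variances must be > 0")
        if self.G.shape != (K, K) or self.H.shape != (M, M):
            raise ValueError("G must be K x K and H must be M x M")
        if self.sigma_x2 is None:
            # stationary Var(x_m) = 1 for a diagonal H; solved exactly below
            # for scalar/diagonal H, which is the only case the generator uses.
            h2 = np.clip(np.diag(self.H) ** 2, None, 1 - 1e-12)
            self.sigma_x2 = 1.0 - h2
        else:
            self.sigma_x2 = _as_array(self.sigma_x2, 1, "sigma_x2")

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    @property
    def K(self) -> int:
        return self.L.shape[1]

    def spectral_radii(self) -> dict:
        return {
            name: float(np.max(np.abs(np.linalg.eigvals(mat))))
            for name, mat in (("A", self.A), ("G", self.G), ("H", self.H))
        }

    def check_stationary(self) -> None:
        for name, r in self.spectral_radii().items():
            if r >= 1.0:
                raise ValueError(f"spectral radius of {name} is {r:.4f} >= 1; "
                                 "the process is not stationary")

    def copy(self) -> "DynamicParams":
        return DynamicParams(
            A=self.A.copy(), B=self.B.copy(), L=self.L.copy(),
            Sigma=self.Sigma.copy(), G=self.G.copy(), H=self.H.copy(),
            sigma_x2=self.sigma_x2.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "model": "dynamic_cotula",
            "A": self.A.tolist(), "B": self.B.tolist(), "L": self.L.tolist(),
            "Sigma": self.Sigma.tolist(), "G": self.G.tolist(),
            "H": self.H.tolist(), "sigma_x2": self.sigma_x2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicParams":
        return cls(
            A=np.asarray(d["A"], float), B=np.asarray(d["B"], float),
            L=np.asarray(d["L"], float), Sigma=np.asarray(d["Sigma"], float),
            G=np.asarray(d["G"], float), H=np.asarray(d["H"], float),
            sigma_x2=np.asarray(d["sigma_x2"], float) if "sigma_x2" in d else None,
        )

    def univariate(self) -> tuple[float, float, float, float, float, float]:
        """Return (a, b, l, g, h, sigma2) for the N = M = K = 1 model."""
        if not (self.N == self.M == self.K == 1):
            raise ValueError("univariate aliases require N = M = K = 1")
        return (float(self.A[0, 0]), float(self.B[0, 0]), float(self.L[0, 0]),
                float(self.G[0, 0]), float(self.H[0, 0]), float(self.Sigma[0]))


@dataclass
class SupportMask:
    """Boolean pattern of non-zero coupling/tuning parameters.

    For the static model ``coupling_support`` masks the target coupling vector
    ``a`` (length N) and ``tuning_support`` masks the target tuning ``b``
    (length M).  For the dynamic model the same two fields mask the matrices
    ``A`` (N x N) and ``B`` (N x M) entry-wise.  The sparsity levels ``k_C``
    and ``k_T`` are the fractions of exactly-zero entries.
    """

    coupling_support: np.ndarray
    tuning_support: np.ndarray

    def __post_init__(self) -> None:
        self.coupling_support = np.asarray(self.coupling_support, dtype=bool)
        self.tuning_support = np.asarray(self.tuning_support, dtype=bool)

    @property
    def k_C(self) -> float:
        return 1.0 - self.coupling_support.mean() if self.coupling_support.size else 0.0

    @property
    def k_T(self) -> float:
        return 1.0 - self.tuning_support.mean() if self.tuning_support.size else 0.0

    @classmethod
    def dense(cls, n_coupling, n_tuning) -> "SupportMask":
        """All-true support (the "no selection" regime)."""
        return cls(np.ones(n_coupling, dtype=bool), np.ones(n_tuning, dtype=bool))

    @classmethod
    def from_params(cls, params, atol: float = 0.0) -> "SupportMask":
        """Oracle support: the exact-zero pattern of the true parameters."""
        if isinstance(params, StaticParams):
            return cls(np.abs(params.a) > atol, np.abs(params.b) > atol)
        if isinstance(params, DynamicParams):
            return cls(np.abs(params.A) > atol, np.abs(params.B) > atol)
        raise TypeError(f"unsupported parameter type {type(params)!r}")

    def to_dict(self) -> dict:
        return {"coupling_support": self.coupling_support.astype(int).tolist(),
                "tuning_support": self.tuning_support.astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SupportMask":
        return cls(np.asarray(d["coupling_support"], bool),
                   np.asarray(d["tuning_support"], bool))


def save_params(params, path) -> None:
    """Serialize a parameter object to a single JSON document."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def load_params(path):
    d = json.loads(Path(path).read_text())
    kind = d.get("model", "")
    if kind.startswith("static"):
        return StaticParams.from_dict(d)
    if kind.startswith("dynamic"):
        return DynamicParams.from_dict(d)
    raise ValueError(f"unrecognized parameter document (model={kind!r}) in {path}")
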