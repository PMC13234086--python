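"""End-to-end synthetic experiments.

Three study designs are reproduced at desk scale (all sizes configurable):

* a sweep over the means of the coupling/tuning parameter distributions in
  the static model, comparing least-squares (CoTu) and EM (CoTuLa) estimation
  under no / oracle / inferred support selection;
* the non-identifiability clustering experiment: EM started from points
  spanning an identifiability family;
* the dynamic four-condition suite crossing temporal correlation in the
  stimulus with temporal correlation in the unobserved variability.

Every run is deterministic given its master seed: child generators are
spawned with counter-based seed lists, so any (cell, model, dataset) subset
reproduces in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .params import DynamicParams, StaticParams, SupportMask
from .static_model import (generate_static, identifiability_check, transform_family,
                           uniform_correlation_params)
from .static_inference import (aggregate_errors, em_e_step, fit_cotu_ols,
                               fit_cotula_em, infer_support_static,
                               normalized_error)
from .dynamic_model import DynamicDataset, generate_dynamic
from .dynamic_inference import (dynamic_e_step, fit_dynamic_cotu_ols,
                                fit_dynamic_cotula_em, infer_support_dynamic,
                                normalized_error_dynamic)

__all__ = [
    "SweepConfig",
    "SweepReport",
    "IdentifiabilityConfig",
    "DynamicConditionsConfig",
    "ConditionsReport",
    "draw_sweep_model",
    "run_static_sweep",
    "run_identifiability_experiment",
    "run_dynamic_conditions",
    "variance_fractions",
    "tuning_modulation",
    "tuning_coupling_ratio",
]

_STATIC_METHODS = ("cotu", "cotula")
_REGIMES = ("none", "oracle", "inferred")


@dataclass
class SweepConfig:
    """Study design of the static mean sweep.

    ``grid`` holds the candidate means (shared by the coupling and tuning
    axes) of the Gaussian the non-zero parameters are drawn from; each pair of
    (coupling mean, tuning mean) defines a cell.  Defaults are the desk-scale
    design; the full-scale design (5-value grid, 10 models, 30 datasets) is
    reachable by configuration.
    """

    grid: tuple = (-1.0, 0.0, 1.0)
    n_models: int = 3
    n_datasets: int = 5
    n_folds: int = 3
    D: int = 2000
    N: int = 10
    M: int = 8
    K: int = 1
    k_C: float = 0.5
    k_T: float = 0.5
    draw_sd: float = 0.1
    noise_corr: float = 0.10
    seed: int = 0
    regimes: tuple = _REGIMES
    models: tuple = _STATIC_METHODS

    def validate(self) -> None:
        for name in ("n_models", "n_datasets", "n_folds", "D", "N", "M", "K"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not all(-1.0 <= g <= 1.0 for g in self.grid):
            raise ValueError("grid values must lie in [-1, 1]")
        if not (0.0 <= self.k_C < 1.0 and 0.0 <= self.k_T < 1.0):
            raise ValueError("sparsity levels must be in [0, 1)")


def _sparse_draw(rng, size, mean, sd, k, positive=False):
    """Vector with ``round(size * (1-k))`` non-zero N(mean, sd^2) entries at
    random positions.  ``positive`` truncates draws at zero (redraw)."""
    n_active = int(round(size * (1.0 - k)))
    vals = np.zeros(size)
    idx = rng.choice(size, size=n_active, replace=False)
    draws = mean + sd * rng.standard_normal(n_active)
    if positive:
        for _ in range(100):
            bad = draws <= 0
            if not bad.any():
                break
            draws[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
    vals[idx] = draws
    return vals


def draw_sweep_model(cfg: SweepConfig, mean_c: float, mean_t: float,
                     rng: np.random.Generator) -> StaticParams:
    """Draw one sweep model: sparse coupling/tuning with the cell's means and
    unobserved variability giving uniform pairwise noise correlations.

    The drawn model is checked to satisfy the sparsity-based identifiability
    condition (redraws a few times for non-generic draws); a configuration
    for which the condition is infeasible (no exact zeros) is rejected.
    """
    if int(round(cfg.N * cfg.k_C)) + int(round(cfg.M * cfg.k_T)) < cfg.K:
        raise ValueError(
            "identifiability is infeasible for this cell: fewer than K zero "
            "coupling/tuning entries at the requested sparsity levels")
    for _ in range(20):
        a = _sparse_draw(rng, cfg.N, mean_c, cfg.draw_sd, cfg.k_C)
        b = _sparse_draw(rng, cfg.M, mean_t, cfg.draw_sd, cfg.k_T)
        B_not = mean_t + cfg.draw_sd * rng.standard_normal((cfg.M, cfg.N))
        params = uniform_correlation_params(a, b, B_not,
                                            noise_corr=cfg.noise_corr)
        ok, _ = identifiability_check(params, SupportMask.from_params(params))
        if ok:
            return params
    raise ValueError("could not draw an identifiable model for this cell")


@dataclass
class SweepReport:
    """Raw per-fit normalized errors plus the aggregated per-cell summary.

    ``raw`` is tidy: one row per (cell, model, dataset, fold, method, regime,
    parameter); ``summary`` has one row per (cell, method, regime) with the
    aggregated coupling/tuning errors.  ``summary`` is always re-derivable
    from ``raw`` via :meth:`aggregate`.
    """

    raw: pd.DataFrame
    summary: pd.DataFrame
    config: dict

    @staticmethod
    def aggregate(raw: pd.DataFrame) -> pd.DataFrame:
        rows = []
        keys = ["mean_c", "mean_t", "method", "regime"]
        for vals, grp in raw.groupby(keys, sort=True):
            rec = dict(zip(keys, vals))
            for kind in ("coupling", "tuning"):
                sub = grp[grp["kind"] == kind]
                if sub.empty:
                    rec[f"{kind}_error"] = np.nan
                    continue
                # mean over dataset*fold, median over params, median over models
                by_param = (sub.groupby(["model", "param"])["norm_error"]
                            .mean())
                by_model = by_param.groupby("model").median()
                rec[f"{kind}_error"] = float(by_model.median())
            rows.append(rec)
        return pd.DataFrame(rows)


def _fold_indices(D: int, n_folds: int, rng: np.random.Generator):
    perm = rng.permutation(D)
    return np.array_split(perm, n_folds)


def run_static_sweep(cfg: SweepConfig) -> SweepReport:
    """Run the full static mean-sweep experiment."""
    cfg.validate()
    records = []
    for ci, mean_c in enumerate(cfg.grid):
        for ti, mean_t in enumerate(cfg.grid):
            for mi in range(cfg.n_models):
                rng_m = np.random.default_rng([cfg.seed, ci, ti, mi])
                truth = draw_sweep_model(cfg, mean_c, mean_t, rng_m)
                oracle = SupportMask.from_params(truth)
                dense = SupportMask.dense(cfg.N, cfg.M)
                for di in range(cfg.n_datasets):
                    rng_d = np.random.default_rng([cfg.seed, ci, ti, mi, di])
                    data = generate_static(truth, cfg.D, seed=rng_d)
                    folds = _fold_indices(cfg.D, cfg.n_folds, rng_d)
                    for fi, idx in enumerate(folds):
                        sub = data.subset(idx)
                        fit_id = di * cfg.n_folds + fi
                        supports = {}
                        if "none" in cfg.regimes:
                            supports["none"] = dense
                        if "oracle" in cfg.regimes:
                            supports["oracle"] = oracle
                        if "inferred" in cfg.regimes:
                            supports["inferred"] = infer_support_static(
                                sub, seed=int(rng_d.integers(2**31)))
                        for regime, sup in supports.items():
                            for method in cfg.models:
                                if method == "cotu":
                                    fit = fit_cotu_ols(sub, sup, regime=regime)
                                else:
                                    fit = fit_cotula_em(
                                        sub, cfg.K, sup, regime=regime)
                                rep = normalized_error(fit.params, truth)
                                for kind, vec in (("coupling", rep.coupling_norm),
                                                  ("tuning", rep.tuning_norm)):
                                    for pj in np.flatnonzero(~np.isnan(vec)):
                                        records.append({
                                            "mean_c": mean_c, "mean_t": mean_t,
                                            "model": mi, "dataset": di,
                                            "fold": fi, "fit": fit_id,
                                            "method": method, "regime": regime,
                                            "kind": kind, "param": int(pj),
                                            "norm_error": float(vec[pj]),
                                        })
    raw = pd.DataFrame.from_records(records)
    summary = SweepReport.aggregate(raw)
    return SweepReport(raw=raw, summary=summary, config=asdict(cfg))


@dataclass
class IdentifiabilityConfig:
    """Design of the family-spanning initialization experiment (K = 1)."""

    N: int = 8
    M: int = 8
    D: int = 2000
    mean_c: float = 0.5
    mean_t: float = 0.5
    draw_sd: float = 0.1
    k_C: float = 0.5
    k_T: float = 0.5
    noise_corr: float = 0.10
    n_inits: int = 30
    max_iter: int = 500
    tol: float = 1e-9
    seed: int = 0
    init_style: str = "family"


def run_identifiability_experiment(cfg: IdentifiabilityConfig,
                                   base_params: StaticParams | None = None,
                                   oracle_support: bool = False) -> dict:
    """EM from many initializations of a structurally non-identifiable fit.

    Generates data from a sparse identifiable model with strictly positive
    coupling/tuning parameters and runs EM without support selection from
    ``n_inits`` starting points.  With ``init_style="family"`` the starts are
    equally spaced across the identifiability family built around a perturbed
    initialization; with ``init_style="random"`` they are seeded Gaussian
    perturbations of the default least-squares/factor-analysis start.

    Returns a dict with the truth, the initializations, the fitted parameter
    sets, their two-component PCA embedding, the per-fit ratio of the target
    private variance to its own family maximum, and spread summaries.

    Note on the two designs: the family is an exactly flat ridge of the
    likelihood, and the exact E/M steps make every family member a fixed
    point of EM, so family-spanning starts converge to nearby ridge points
    and retain their spread.  Random perturbations of the least-squares start
    instead all converge near the apex of the family (maximal target private
    variance), which is where the systematic coupling error lives.
    """
    rng = np.random.default_rng(cfg.seed)
    if base_params is None:
        sweep_like = SweepConfig(N=cfg.N, M=cfg.M, K=1, k_C=cfg.k_C,
                                 k_T=cfg.k_T, draw_sd=cfg.draw_sd,
                                 noise_corr=cfg.noise_corr)
        for _ in range(20):
            a = _sparse_draw(rng, cfg.N, cfg.mean_c, cfg.draw_sd, cfg.k_C,
                             positive=True)
            b = _sparse_draw(rng, cfg.M, cfg.mean_t, cfg.draw_sd, cfg.k_T,
                             positive=True)
            B_not = np.abs(cfg.mean_t
                           + cfg.draw_sd * rng.standard_normal((cfg.M, cfg.N)))
            base_params = uniform_correlation_params(
                a, b, B_not, noise_corr=cfg.noise_corr)
            if identifiability_check(base_params,
                              SupportMask.from_params(base_params))[0]:
                break
    truth = base_params
    if truth.K != 1:
        raise ValueError("the family-spanning experiment requires K = 1")
    data = generate_static(truth, cfg.D, seed=rng)

    support = (SupportMask.from_params(truth) if oracle_support
               else SupportMask.dense(truth.N, truth.M))
    if cfg.init_style == "family":
        # an initialization family: perturb the truth, then span its family
        init0 = truth.copy()
        init0.a = init0.a + 0.05 * rng.standard_normal(truth.N)
        init0.b = init0.b + 0.05 * rng.standard_normal(truth.M)
        inits = transform_family(init0, cfg.n_inits)
        for p in inits:                   # endpoints have psi = 0 exactly
            p.psi = max(p.psi, 1e-6)
        fits = [fit_cotula_em(data, 1, support, init=p,
                              max_iter=cfg.max_iter, tol=cfg.tol)
                for p in inits]
    elif cfg.init_style == "random":
        fits = [fit_cotula_em(data, 1, support, init=int(s),
                              max_iter=cfg.max_iter, tol=cfg.tol)
                for s in rng.integers(2**31, size=cfg.n_inits)]
        inits = None
    else:
        raise ValueError("init_style must be 'family' or 'random'")
    fitted = [f.params for f in fits]

    def stack(ps):
        return np.array([np.concatenate((p.a, p.b, p.l, [p.psi]))
                         for p in ps])

    X_fit = stack(fitted)
    X_init = stack(inits) if inits else np.zeros((0, X_fit.shape[1]))
    pca = PCA(n_components=2).fit(np.vstack((X_init, X_fit)))
    psi_ratio = []
    for p in fitted:
        psi_max = _family_psi_max(p)
        psi_ratio.append(p.psi / psi_max if psi_max > 0 else np.nan)
    coupling_fit = np.array([p.a for p in fitted])
    coupling_init = (np.array([p.a for p in inits]) if inits
                     else np.full((1, truth.N), np.nan))
    syst = np.abs(coupling_fit.mean(axis=0) - truth.a)
    nz = truth.a != 0
    return {
        "truth": truth,
        "data": data,
        "inits": inits,
        "fits": fits,
        "fitted_params": fitted,
        "pca_inits": (pca.transform(X_init) if len(X_init)
                      else np.zeros((0, 2))),
        "pca_fits": pca.transform(X_fit),
        "psi_ratio": np.asarray(psi_ratio),
        "coupling_sd_across_inits": coupling_fit.std(axis=0),
        "init_spread": coupling_init.std(axis=0),
        "systematic_error": syst,
        "median_systematic_error": float(np.median(syst[nz])),
        "median_sd": float(np.median(coupling_fit.std(axis=0)[nz])),
    }


def _family_psi_max(params: StaticParams) -> float:
    """Maximal target private variance over the K = 1 identifiability family
    of ``params`` (the apex of the truncated parabola, at delta = -l)."""
    from .static_model import IdentifiabilityTransform
    tr = IdentifiabilityTransform.from_params(params)
    w = float(tr.W[0, 0])
    return float(params.psi + (1.0 - w) * params.l[0] ** 2)


@dataclass
class DynamicConditionsConfig:
    """Design of the dynamic four-condition suite.

    Conditions cross stimulus temporal correlation (h) with latent temporal
    correlation (g): "on" means AR coefficient ``ar_on``, "off" means 0.
    """

    N: int = 5
    M: int = 3
    K: int = 1
    T: int = 5000
    n_realizations: int = 50
    ar_on: float = 0.6
    coupling_mean: float = 0.2
    coupling_sd: float = 0.05
    tuning_mean: float = 1.0
    tuning_sd: float = 0.1
    latent_loading: float = 1.0
    k_C: float = 0.5
    k_T: float = 0.5
    burn_in: int = 500
    seed: int = 0
    methods: tuple = _STATIC_METHODS       # ("cotu", "cotula")
    regimes: tuple = _REGIMES
    max_iter: int = 100
    tol: float = 1e-8

    def conditions(self):
        return [("off", "off"), ("on", "off"), ("off", "on"), ("on", "on")]


def draw_dynamic_model(cfg: DynamicConditionsConfig, h: float, g: float,
                       rng: np.random.Generator) -> DynamicParams:
    """Draw one stationary dynamic model with sparse positive coupling and
    tuning, uniform positive latent loadings and unit private noise."""
    for _ in range(50):
        A = np.zeros((cfg.N, cfg.N))
        mask = rng.random((cfg.N, cfg.N)) > cfg.k_C
        A[mask] = np.abs(cfg.coupling_mean
                         + cfg.coupling_sd * rng.standard_normal(int(mask.sum())))
        if np.max(np.abs(np.linalg.eigvals(A))) < 0.9:
            break
    else:
        raise ValueError("could not draw a stationary coupling matrix")
    B = np.zeros((cfg.N, cfg.M))
    maskB = rng.random((cfg.N, cfg.M)) > cfg.k_T
    B[maskB] = np.abs(cfg.tuning_mean
                      + cfg.tuning_sd * rng.standard_normal(int(maskB.sum())))
    L = np.full((cfg.N, cfg.K), cfg.latent_loading)
    return DynamicParams(A=A, B=B, L=L, Sigma=np.ones(cfg.N),
                         G=g * np.eye(cfg.K), H=h * np.eye(cfg.M))


@dataclass
class ConditionsReport:
    raw: pd.DataFrame
    summary: pd.DataFrame
    config: dict

    @staticmethod
    def aggregate(raw: pd.DataFrame) -> pd.DataFrame:
        rows = []
        keys = ["stim_corr", "latent_corr", "method", "regime", "kind"]
        for vals, grp in raw.groupby(keys, sort=True):
            errs = grp["norm_error"].to_numpy()
            rows.append(dict(zip(keys, vals)) | {
                "median": float(np.median(errs)),
                "q25": float(np.percentile(errs, 25)),
                "q75": float(np.percentile(errs, 75)),
                "n": int(errs.size),
            })
        return pd.DataFrame(rows)


def run_dynamic_conditions(cfg: DynamicConditionsConfig) -> ConditionsReport:
    """Run the 2 x 2 temporal-correlation suite."""
    records = []
    for cond_i, (stim, lat) in enumerate(cfg.conditions()):
        h = cfg.ar_on if stim == "on" else 0.0
        g = cfg.ar_on if lat == "on" else 0.0
        for ri in range(cfg.n_realizations):
            rng = np.random.default_rng([cfg.seed, cond_i, ri])
            truth = draw_dynamic_model(cfg, h, g, rng)
            data = generate_dynamic(truth, cfg.T, burn_in=cfg.burn_in,
                                    seed=rng)
            oracle = SupportMask.from_params(truth)
            dense = SupportMask.dense((cfg.N, cfg.N), (cfg.N, cfg.M))
            supports = {}
            if "none" in cfg.regimes:
                supports["none"] = dense
            if "oracle" in cfg.regimes:
                supports["oracle"] = oracle
            if "inferred" in cfg.regimes:
                supports["inferred"] = infer_support_dynamic(data)
            for regime, sup in supports.items():
                for method in cfg.methods:
                    if method == "cotu":
                        A_hat, B_hat = fit_dynamic_cotu_ols(data, sup)
                    else:
                        fit = fit_dynamic_cotula_em(
                            data, cfg.K, sup, max_iter=cfg.max_iter,
                            tol=cfg.tol)
                        A_hat, B_hat = fit.params.A, fit.params.B
                    ce, te = normalized_error_dynamic(A_hat, B_hat, truth)
                    for kind, vec in (("coupling", ce), ("tuning", te)):
                        for v in vec:
                            records.append({
                                "stim_corr": stim, "latent_corr": lat,
                                "realization": ri, "method": method,
                                "regime": regime, "kind": kind,
                                "norm_error": float(v),
                            })
    raw = pd.DataFrame.from_records(records)
    return ConditionsReport(raw=raw, summary=ConditionsReport.aggregate(raw),
                            config=asdict(cfg))


def variance_fractions(params, data) -> dict:
    """Fraction of the target's variance contributed by each model term.

    For each term (coupling, tuning, latent, private) the variance of that
    term's contribution across trials/time is divided by the total variance
    of the target activity.  The latent contribution uses the posterior mean
    of the latent state.  Fractions need not sum to one: the terms are not
    orthogonal.
    """
    if isinstance(params, StaticParams):
        vy = float(np.var(data.y))
        if vy <= 0:
            raise ValueError("target activity has zero variance")
        out = {
            "coupling": float(np.var(data.Y_not @ params.a)) / vy,
            "tuning": float(np.var(data.X @ params.b)) / vy,
            "private": params.psi / vy,
        }
        if params.K > 0:
            post = em_e_step(params, data)
            out["latent"] = float(np.var(post.mu @ params.l)) / vy
        else:
            out["latent"] = 0.0
        return out
    if isinstance(params, DynamicParams):
        Y1, Y0, X1 = data.Y[1:], data.Y[:-1], data.X[1:]
        vy = np.var(Y1, axis=0)
        if np.any(vy <= 0):
            raise ValueError("some unit has zero variance")
        post = dynamic_e_step(params, data)
        lat = post.mu @ params.L.T
        return {
            "coupling": float(np.mean(np.var(Y0 @ params.A.T, axis=0) / vy)),
            "tuning": float(np.mean(np.var(X1 @ params.B.T, axis=0) / vy)),
            "latent": float(np.mean(np.var(lat, axis=0) / vy)),
            "private": float(np.mean(params.Sigma / vy)),
        }
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def tuning_modulation(tuning_curve) -> float:
    """Minimum-to-maximum span of a tuning curve over stimulus levels."""
    curve = np.asarray(tuning_curve, float)
    if curve.size < 2:
        raise ValueError("need at least two stimulus levels")
    return float(curve.max() - curve.min())


def tuning_coupling_ratio(fractions: dict) -> float:
    """Tuning variance fraction relative to coupling; NaN (missing) when the
    coupling fraction is zero."""
    if fractions["coupling"] <= 0:
        return float("nan")
    return float(fractions["tuning"] / fractions["coupling"])
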