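"""Cause-specific hazard flexible parametric models.

Each competing cause k gets its own model for the log cumulative
cause-specific hazard,

    ln H_k(t | x) = s_k(ln t; gamma_k) + x beta_k  (+ covariate x time terms),

with s_k a natural cubic spline.  Fitting one cause treats every other
first event and censoring identically (they contribute only the at-risk
term).  A stacked (Lunn-McNeil) variant estimates all causes in one joint
likelihood, optionally sharing covariate effects across causes.  The
cumulative incidence of cause k follows by integrating its hazard against
the all-cause survival function

    F_k(t | x) = int_0^t h_k(u | x) S(u | x) du,
    S(u | x) = exp( - sum_k H_k(u | x) ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.stats import norm

from . import _engine
from ._design import ModelDesign, TVCTerm, split_theta
from .data import CompetingRisksDataset
from .splines import KnotSet, place_knots

__all__ = [
    "FittedFPM",
    "SurvivalCurve",
    "CIFCurve",
    "fit_csh_fpm",
    "fit_stacked_csh",
    "StackedCSHFit",
    "csh_linear_predictor",
    "csh_loglik",
    "cif_from_csh",
]


@dataclass
class SurvivalCurve:
    """All-cause survival on a time grid."""

    grid: np.ndarray
    S: np.ndarray


@dataclass
class CIFCurve:
    """Cumulative incidence of one cause on a time grid, optional bands."""

    cause: int
    grid: np.ndarray
    F: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


@dataclass
class FittedFPM:
    """A fitted flexible parametric model on the log cumulative
    (sub)hazard scale.

    ``theta`` stacks the spline coefficients (intercept first), covariate
    coefficients and any covariate-time interaction coefficients; ``vcov``
    is the inverse observed information on the same layout.
    """

    scale: str  # "cause-specific" | "subdistribution"
    cause: int
    design: ModelDesign
    theta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    trace: list[str] = field(default_factory=list, repr=False)

    # -- parameter views ---------------------------------------------------
    @property
    def knots(self) -> KnotSet:
        return self.design.knots

    @property
    def gamma(self) -> np.ndarray:
        return split_theta(self.design, self.theta)[0]

    @property
    def beta(self) -> np.ndarray:
        return split_theta(self.design, self.theta)[1]

    @property
    def tvc_terms(self) -> dict[str, np.ndarray]:
        return split_theta(self.design, self.theta)[2]

    @property
    def n_params(self) -> int:
        return self.theta.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n)

    # -- predictions -------------------------------------------------------
    def _design_at(self, t, x):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t <= 0):
            raise ValueError("prediction times must be positive")
        p = len(self.design.covariate_names)
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.size != p:
            raise ValueError(f"covariate vector of length {p} expected, got {x.size}")
        X = np.broadcast_to(x, (t.size, p))
        return t, *self.design.build(np.log(t), X)

    def linear_predictor(self, t, x) -> np.ndarray:
        """eta(t, x) = ln H(t | x)."""
        _, Z, _ = self._design_at(t, x)
        return Z @ self.theta

    def linear_predictor_se(self, t, x) -> np.ndarray:
        _, Z, _ = self._design_at(t, x)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, self.vcov, Z), 0.0))

    def cumhaz(self, t, x) -> np.ndarray:
        return np.exp(self.linear_predictor(t, x))

    def hazard(self, t, x) -> np.ndarray:
        """h(t | x) = H(t | x) * d eta / d ln t / t."""
        t, Z, Zd = self._design_at(t, x)
        return np.exp(Z @ self.theta) * (Zd @ self.theta) / t

    def survival(self, t, x) -> np.ndarray:
        """exp(-H); all-cause survival only when the model is single-cause."""
        return np.exp(-self.cumhaz(t, x))

    def cif(self, t, x) -> np.ndarray:
        """1 - exp(-H); the cause's CIF on the subdistribution scale."""
        return -np.expm1(-self.cumhaz(t, x))

    def coefficient_table(self, level: float = 0.95):
        """Estimates, SEs, (S)HR = exp(beta), Wald CI, z and p per parameter."""
        import pandas as pd

        se = np.sqrt(np.maximum(np.diag(self.vcov), 0.0))
        z = norm.ppf(0.5 + level / 2)
        zstat = np.divide(self.theta, se, out=np.full_like(self.theta, np.nan), where=se > 0)
        label = "SHR" if self.scale == "subdistribution" else "HR"
        return pd.DataFrame(
            {
                "param": self.design.param_names(),
                "estimate": self.theta,
                "se": se,
                label: np.exp(self.theta),
                "ci_low": np.exp(self.theta - z * se),
                "ci_high": np.exp(self.theta + z * se),
                "z": zstat,
                "p": 2 * norm.sf(np.abs(zstat)),
            }
        )


def _prepare(dataset: CompetingRisksDataset, cause: int, covariates):
    if not 1 <= cause <= dataset.K:
        raise ValueError(f"cause must be in 1..{dataset.K}, got {cause}")
    names = list(covariates) if covariates is not None else dataset.covariate_names
    X = dataset.X(names)
    return names, X


def _tvc_terms(tvc, tvc_time_fn: str, covariate_names) -> tuple[TVCTerm, ...]:
    if not tvc:
        return ()
    terms = []
    for item in tvc:
        if isinstance(item, TVCTerm):
            terms.append(item)
        else:
            if item not in covariate_names:
                raise ValueError(f"tvc covariate '{item}' not among model covariates")
            terms.append(TVCTerm(item, tvc_time_fn))
    return tuple(terms)


def fit_csh_fpm(
    dataset: CompetingRisksDataset,
    cause: int,
    df: int,
    covariates: list[str] | None = None,
    tvc: list | None = None,
    tvc_time_fn: str = "log",
    knots: KnotSet | None = None,
) -> FittedFPM:
    """Fit the cause-specific hazard FPM for one cause.

    Competing events are treated as censored at their occurrence time.
    Knots default to equally spaced centiles of this cause's log event
    times.  ``tvc`` lists covariates given time-varying coefficients via
    interaction with ``ln t`` (``tvc_time_fn="log"``) or with the full
    baseline spline basis (``"spline"``).
    """
    names, X = _prepare(dataset, cause, covariates)
    d = (dataset.event == cause).astype(float)
    if d.sum() < 2:
        raise ValueError(f"need >= 2 events of cause {cause}, found {int(d.sum())}")
    if knots is None:
        knots = place_knots(dataset.time[d > 0], df, cause=cause)
    design = ModelDesign(knots, tuple(names), _tvc_terms(tvc, tvc_time_fn, names))
    design.check_rank(X)
    Z1, Zd1 = design.build(np.log(dataset.time), X)
    data = _engine.LogHazData(
        Z1=Z1, Zd1=Zd1, d=d, w=np.ones(len(dataset)), logt=np.log(dataset.time)
    )
    res = _engine.fit(data)
    return FittedFPM(
        scale="cause-specific",
        cause=cause,
        design=design,
        theta=res["theta"],
        vcov=res["vcov"],
        loglik=res["loglik"],
        n=len(dataset),
        n_events=int(d.sum()),
        converged=res["converged"],
        trace=res["trace"],
    )


def csh_linear_predictor(fit: FittedFPM, t, x) -> np.ndarray:
    """ln H(t | x) under a fitted cause-specific model (module-level
    convenience mirroring :meth:`FittedFPM.linear_predictor`)."""
    return fit.linear_predictor(t, x)


def csh_loglik(fit: FittedFPM, dataset: CompetingRisksDataset, cause: int | None = None) -> float:
    """Re-evaluate the cause-specific likelihood at the stored parameters."""
    cause = fit.cause if cause is None else cause
    X = dataset.X(list(fit.design.covariate_names))
    Z1, Zd1 = fit.design.build(np.log(dataset.time), X)
    d = (dataset.event == cause).astype(float)
    data = _engine.LogHazData(
        Z1=Z1, Zd1=Zd1, d=d, w=np.ones(len(dataset)), logt=np.log(dataset.time)
    )
    return _engine.loglik(fit.theta, data)


# ---------------------------------------------------------------------------
# Stacked (Lunn-McNeil) joint cause-specific model
# ---------------------------------------------------------------------------


@dataclass
class StackedCSHFit:
    """Joint cause-specific fit on stacked data: one at-risk row per
    subject per cause, separate baselines, optionally shared covariate
    effects.  ``models`` are per-cause views; ``vcov`` is the joint
    covariance over the stacked parameter vector."""

    models: list[FittedFPM]
    theta: np.ndarray
    vcov: np.ndarray
    loglik: float
    shared: tuple[str, ...]
    param_names: list[str]

    def __iter__(self):
        return iter(self.models)


def fit_stacked_csh(
    dataset: CompetingRisksDataset,
    df_per_cause: list[int] | int,
    covariates: list[str] | None = None,
    shared: list[str] | None = None,
    knots_per_cause: list[KnotSet] | None = None,
) -> StackedCSHFit:
    """Fit all causes jointly on the stacked (per-subject-per-cause) data.

    Covariates in ``shared`` get a single coefficient across causes;
    all others get one coefficient per cause.  With no shared effects and
    per-cause knots the estimates coincide with separate fits.
    """
    K = dataset.K
    if isinstance(df_per_cause, int):
        df_per_cause = [df_per_cause] * K
    if len(df_per_cause) != K:
        raise ValueError(f"df_per_cause must have length K={K}")
    shared = tuple(shared or ())
    names = list(covariates) if covariates is not None else dataset.covariate_names
    unknown = [s for s in shared if s not in names]
    if unknown:
        raise ValueError(f"shared covariates not in model: {unknown}")
    own = [c for c in names if c not in shared]
    X = dataset.X(names)
    n = len(dataset)
    logt = np.log(dataset.time)

    designs = []
    for k in range(1, K + 1):
        tk = dataset.time[dataset.event == k]
        if tk.size < 2:
            raise ValueError(f"need >= 2 events of cause {k}")
        kn = (
            knots_per_cause[k - 1]
            if knots_per_cause is not None
            else place_knots(tk, df_per_cause[k - 1], cause=k)
        )
        designs.append(ModelDesign(kn, tuple(own)))
    block_sizes = [d.n_params for d in designs]
    q = sum(block_sizes) + len(shared)
    offs = np.concatenate([[0], np.cumsum(block_sizes)])
    X_own = dataset.X(own) if own else np.empty((n, 0))
    X_sh = dataset.X(list(shared)) if shared else np.empty((n, 0))

    Z1 = np.zeros((n * K, q))
    Zd1 = np.zeros((n * K, q))
    d_all = np.zeros(n * K)
    for k in range(K):
        rows = slice(k * n, (k + 1) * n)
        Zk, Zdk = designs[k].build(logt, X_own)
        Z1[rows, offs[k] : offs[k + 1]] = Zk
        Zd1[rows, offs[k] : offs[k + 1]] = Zdk
        if shared:
            Z1[rows, offs[-1] :] = X_sh
        d_all[rows] = (dataset.event == k + 1).astype(float)

    data = _engine.LogHazData(
        Z1=Z1, Zd1=Zd1, d=d_all, w=np.ones(n * K), logt=np.tile(logt, K)
    )
    theta0 = np.zeros(q)
    for k in range(K):
        rate = max((d_all[k * n : (k + 1) * n].sum()) / max(dataset.time.sum(), 1e-12), 1e-6)
        theta0[offs[k]] = np.log(rate)
        theta0[offs[k] + 1] = 1.0
    res = _engine.fit(data, theta0=theta0)

    theta, vcov = res["theta"], res["vcov"]
    models = []
    param_names: list[str] = []
    for k in range(K):
        # assemble the per-cause view: own block + shared coefficients
        full_design = ModelDesign(designs[k].knots, tuple(own + list(shared)))
        idx = list(range(offs[k], offs[k + 1])) + list(range(offs[-1], q))
        th_k = theta[idx]
        v_k = vcov[np.ix_(idx, idx)]
        dk = (dataset.event == k + 1).astype(float)
        Zk, Zdk = full_design.build(logt, np.hstack([X_own, X_sh]))
        ll_k = _engine.loglik(
            th_k,
            _engine.LogHazData(Z1=Zk, Zd1=Zdk, d=dk, w=np.ones(n), logt=logt),
        )
        models.append(
            FittedFPM(
                scale="cause-specific",
                cause=k + 1,
                design=full_design,
                theta=th_k,
                vcov=v_k,
                loglik=ll_k,
                n=n,
                n_events=int(dk.sum()),
                converged=res["converged"],
                trace=res["trace"],
            )
        )
        param_names += [f"cause{k + 1}:{p}" for p in designs[k].param_names()]
    param_names += [f"shared:{s}" for s in shared]
    return StackedCSHFit(
        models=models,
        theta=theta,
        vcov=vcov,
        loglik=res["loglik"],
        shared=shared,
        param_names=param_names,
    )


# ---------------------------------------------------------------------------
# CIF from cause-specific hazards
# ---------------------------------------------------------------------------


def cif_from_csh(
    models: list[FittedFPM],
    x,
    grid,
    n_fine: int = 2048,
    conservation_tol: float = 1e-6,
) -> tuple[list[CIFCurve], SurvivalCurve]:
    """Cumulative incidence curves from per-cause hazard models.

    Integrates h_k(u|x) S(u|x) by composite Simpson on a grid uniform in
    ln t (augmented with the requested times), extended far enough below
    the first requested time that the truncated mass is negligible.
    Verifies the conservation identity sum_k F_k + S = 1 at every
    requested time and raises if the integration tolerance is not met.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("grid must be strictly increasing and positive")
    # lower integration limit: push down until total cumulative hazard is tiny
    u_lo = min(np.log(grid[0]), min(m.knots.boundary[0] for m in models)) - 2.0
    for _ in range(200):
        Htot = sum(float(m.cumhaz(np.exp(u_lo), x)[0]) for m in models)
        if Htot < 1e-12:
            break
        u_lo -= 2.0
    else:
        raise RuntimeError(
            "cumulative hazard does not vanish at small times; "
            "a fitted spline has nonpositive slope at the left boundary"
        )
    u = np.union1d(np.linspace(u_lo, np.log(grid[-1]), n_fine), np.log(grid))
    t = np.exp(u)
    H = np.stack([m.cumhaz(t, x) for m in models])
    Zs = []
    for m in models:
        _, Z, Zd = m._design_at(t, x)
        Zs.append((Z @ m.theta, Zd @ m.theta))
    S = np.exp(-H.sum(axis=0))
    idx = np.searchsorted(u, np.log(grid))
    curves = []
    for m, (eta, slope) in zip(models, Zs):
        integrand = np.exp(eta) * slope * S  # h(t) S(t) t, in d(ln t)
        Fk = cumulative_simpson(integrand, x=u, initial=0.0)
        curves.append(CIFCurve(cause=m.cause, grid=grid.copy(), F=Fk[idx]))
    Sg = S[idx]
    gap = np.abs(sum(c.F for c in curves) + Sg - 1.0)
    if gap.max() > conservation_tol:
        raise RuntimeError(
            f"CIF integration failed conservation check: max |sum F + S - 1| = {gap.max():.2e}"
        )
    for c in curves:
        if np.any(np.diff(c.F) < -1e-8):
            warnings.warn(
                f"CIF for cause {c.cause} decreases on the grid (negative fitted "
                "hazard region); inspect the fit",
                RuntimeWarning,
            )
    return curves, SurvivalCurve(grid=grid.copy(), S=Sg)
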