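"""Flexible parametric subdistribution hazard models.

Both parametric routes to the cumulative incidence function model

    ln H_k^sd(t | x) = ln( -ln(1 - F_k(t | x)) ) = s_k(ln t; gamma_k) + x beta_k.

Route 1 (weighted): fit the event of interest on the censoring-weighted
expanded data from :mod:`crfpm.ipcw`; each expanded row is an at-risk
segment (tstart, tstop] whose weight multiplies the cumulative-hazard
increment only (event rows always carry weight 1, so the event term is
unweighted).  One model per cause of interest.

Route 2 (direct): a single likelihood over all K causes built from the
subdistribution hazards and CIFs themselves,

    l = sum_i [ sum_k d_ik ln( h_k^sd(t_i) (1 - F_k(t_i)) )
                + (1 - sum_k d_ik) ln( 1 - sum_k F_k(t_i) ) ],

which estimates all cause-specific CIFs simultaneously without censoring
weights.  The likelihood requires sum_k F_k < 1 at censored observations;
a log-barrier keeps iterates feasible and the fit is flagged when the
constraint is active at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from . import _engine
from ._design import ModelDesign, TVCTerm
from .csh import CIFCurve, FittedFPM, fit_csh_fpm, _tvc_terms
from .data import CompetingRisksDataset
from .ipcw import ExpandedWeightedDataset
from .splines import KnotSet, place_knots

__all__ = [
    "SDHFit",
    "fit_sdh_fpm1",
    "sdh2_loglik",
    "fit_sdh_fpm2",
    "predict_cif_sdh",
    "check_cif_sum",
]

_R_FLOOR = 1e-10


@dataclass
class SDHFit:
    """Fitted subdistribution model(s).

    ``models`` maps cause code to its :class:`FittedFPM` on the
    subdistribution scale.  For the direct route the per-cause models are
    views into one joint fit: they share the joint log likelihood and
    ``joint_vcov`` holds the full parameter covariance.
    """

    models: dict[int, FittedFPM]
    method: str  # "weighted" | "direct"
    joint_vcov: np.ndarray | None = None
    loglik: float = np.nan
    boundary_active: bool = False
    trace: list[str] = field(default_factory=list, repr=False)

    def __getitem__(self, cause: int) -> FittedFPM:
        return self.models[cause]

    @property
    def causes(self) -> list[int]:
        return sorted(self.models)


def fit_sdh_fpm1(
    expanded: ExpandedWeightedDataset,
    df: int,
    covariates: list[str] | None = None,
    tvc: list | None = None,
    tvc_time_fn: str = "log",
    knots: KnotSet | None = None,
) -> SDHFit:
    """Weighted-likelihood subdistribution FPM for the expansion's cause.

    Maximizes  sum_rows [ d ln h^sd(tstop) - w (H^sd(tstop) - H^sd(tstart)) ].
    With no competing events (all weights 1, single rows) this is exactly
    the single-cause FPM fit.  The reported covariance is the inverse
    observed information of this weighted pseudo-likelihood.
    """
    ids, tstart, tstop, d, w, X = expanded.arrays()
    names = list(covariates) if covariates is not None else list(expanded.covariate_names)
    if covariates is not None:
        X = expanded.frame[names].to_numpy(dtype=float)
    if d.sum() < 2:
        raise ValueError("need >= 2 events of interest in the expansion")
    if knots is None:
        knots = place_knots(tstop[d > 0], df, cause=expanded.cause)
    design = ModelDesign(knots, tuple(names), _tvc_terms(tvc, tvc_time_fn, names))
    design.check_rank(X)
    Z1, Zd1 = design.build(np.log(tstop), X)
    idx0 = np.nonzero(tstart > 0)[0]
    Z0 = None
    w0 = None
    if idx0.size:
        Z0, _ = design.build(np.log(tstart[idx0]), X[idx0])
        w0 = w[idx0]
    data = _engine.LogHazData(
        Z1=Z1, Zd1=Zd1, d=d, w=w, logt=np.log(tstop), Z0=Z0, idx0=idx0, w0=w0
    )
    res = _engine.fit(data)
    fpm = FittedFPM(
        scale="subdistribution",
        cause=expanded.cause,
        design=design,
        theta=res["theta"],
        vcov=res["vcov"],
        loglik=res["loglik"],
        n=expanded.n_subjects,
        n_events=int(d.sum()),
        converged=res["converged"],
        trace=res["trace"],
    )
    return SDHFit(
        models={expanded.cause: fpm},
        method="weighted",
        loglik=res["loglik"],
        trace=res["trace"],
    )


# ---------------------------------------------------------------------------
# Direct joint-CIF likelihood
# ---------------------------------------------------------------------------


def _sdh2_designs(dataset, designs: list[ModelDesign], covariate_sets):
    logt = np.log(dataset.time)
    built = []
    for design, names in zip(designs, covariate_sets):
        X = dataset.X(list(names))
        built.append(design.build(logt, X))
    return built, logt


def _sdh2_ll_grad(theta, dataset, designs, built, logt, want_grad=True):
    K = len(designs)
    sizes = [d.n_params for d in designs]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    ev = dataset.event
    n = len(dataset)
    ll = 0.0
    g = np.zeros(theta.size) if want_grad else None
    cens = ev == 0
    R = np.ones(n)
    surv_k = []
    H_k = []
    for k in range(K):
        Z, Zd = built[k]
        th = theta[offs[k] : offs[k + 1]]
        eta = np.clip(Z @ th, -_engine._ETA_CAP, _engine._ETA_CAP)
        H = np.exp(eta)
        sk = np.exp(-H)  # 1 - F_k
        H_k.append(H)
        surv_k.append(sk)
        R -= -np.expm1(-H)  # subtract F_k
        is_k = ev == k + 1
        s = Zd[is_k] @ th
        ls, dls = _engine._safe_log(s)
        ll += float(np.sum(eta[is_k] + ls - logt[is_k] - H[is_k]))
        if want_grad:
            gk = (
                Z[is_k].T @ (1.0 - H[is_k])
                + Zd[is_k].T @ dls
            )
            g[offs[k] : offs[k + 1]] += gk
    lr, dlr = _engine._safe_log(np.maximum(R[cens], -1.0))
    ll += float(np.sum(lr))
    if want_grad:
        for k in range(K):
            Z, _ = built[k]
            fac = -surv_k[k][cens] * H_k[k][cens] * dlr
            g[offs[k] : offs[k + 1]] += Z[cens].T @ fac
    return ll, g


def _sdh2_hessian(theta, dataset, designs, built):
    """Analytic Hessian of the direct joint-CIF log likelihood.

    Event term of cause k:  -zd zd^T / s^2 - H z z^T  (own block only).
    Censored term ln R with R = 1 - sum_k F_k, a_k = e^(-H_k) H_k:
       own block:    -a_k (1 - H_k) z z^T / R - a_k^2 z z^T / R^2
       cross blocks: -a_k a_j z_k z_j^T / R^2.
    """
    K = len(designs)
    sizes = [d.n_params for d in designs]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    ev = dataset.event
    cens = ev == 0
    q = theta.size
    hess = np.zeros((q, q))
    H_c = []
    a_c = []
    R = np.ones(int(cens.sum()))
    for k in range(K):
        Z, Zd = built[k]
        th = theta[offs[k] : offs[k + 1]]
        eta = np.clip(Z @ th, -_engine._ETA_CAP, _engine._ETA_CAP)
        H = np.exp(eta)
        is_k = ev == k + 1
        s = np.maximum(Zd[is_k] @ th, _engine._S_FLOOR)
        blk = slice(offs[k], offs[k + 1])
        Zd_k = Zd[is_k]
        Z_k = Z[is_k]
        hess[blk, blk] += -(Zd_k / s[:, None] ** 2).T @ Zd_k
        hess[blk, blk] += -(Z_k * H[is_k][:, None]).T @ Z_k
        Hc = H[cens]
        H_c.append(Hc)
        a_c.append(np.exp(-Hc) * Hc)
        R -= -np.expm1(-Hc)
    R = np.maximum(R, _R_FLOOR)
    for k in range(K):
        Zc_k = built[k][0][cens]
        blk_k = slice(offs[k], offs[k + 1])
        wkk = -a_c[k] * (1.0 - H_c[k]) / R - a_c[k] ** 2 / R**2
        hess[blk_k, blk_k] += (Zc_k * wkk[:, None]).T @ Zc_k
        for j in range(k + 1, K):
            Zc_j = built[j][0][cens]
            blk_j = slice(offs[j], offs[j + 1])
            wkj = -a_c[k] * a_c[j] / R**2
            cross = (Zc_k * wkj[:, None]).T @ Zc_j
            hess[blk_k, blk_j] += cross
            hess[blk_j, blk_k] += cross.T
    return hess


def sdh2_loglik(
    theta_per_cause: list[np.ndarray],
    dataset: CompetingRisksDataset,
    designs: list[ModelDesign],
) -> float:
    """Evaluate the direct joint-CIF log likelihood at given per-cause
    parameters (one spline+covariate vector per cause, in cause order)."""
    theta = np.concatenate(theta_per_cause)
    covsets = [d.covariate_names for d in designs]
    built, logt = _sdh2_designs(dataset, designs, covsets)
    return _sdh2_ll_grad(theta, dataset, designs, built, logt, want_grad=False)[0]


def fit_sdh_fpm2(
    dataset: CompetingRisksDataset,
    df_per_cause: list[int] | int,
    covariates: list[str] | None = None,
    tvc: dict[int, list] | None = None,
    tvc_time_fn: str = "log",
    knots_per_cause: list[KnotSet] | None = None,
    max_restarts: int = 3,
) -> SDHFit:
    """Joint maximum likelihood for all causes' subdistribution models.

    ``tvc`` maps cause code to the covariates given time-varying effects
    for that cause.  Initial values come from per-cause cause-specific
    fits, shifted down until the CIF-sum constraint holds at every
    censored observation.  Raises on non-convergence — the direct route
    is known to struggle at small sample sizes.
    """
    K = dataset.K
    if isinstance(df_per_cause, int):
        df_per_cause = [df_per_cause] * K
    names = list(covariates) if covariates is not None else dataset.covariate_names
    tvc = tvc or {}
    designs = []
    inits = []
    for k in range(1, K + 1):
        if np.sum(dataset.event == k) < 2:
            raise ValueError(f"need >= 2 events of cause {k}")
        kn = (
            knots_per_cause[k - 1]
            if knots_per_cause is not None
            else place_knots(dataset.time[dataset.event == k], df_per_cause[k - 1], cause=k)
        )
        terms = _tvc_terms(tvc.get(k), tvc_time_fn, names)
        designs.append(ModelDesign(kn, tuple(names), terms))
        csh0 = fit_csh_fpm(
            dataset, k, df_per_cause[k - 1],
            covariates=names, tvc=tvc.get(k), tvc_time_fn=tvc_time_fn, knots=kn,
        )
        inits.append(csh0.theta.copy())

    covsets = [d.covariate_names for d in designs]
    built, logt = _sdh2_designs(dataset, designs, covsets)
    sizes = [d.n_params for d in designs]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    theta0 = np.concatenate(inits)
    # shift intercepts until the CIF-sum constraint holds at censored rows
    cens = dataset.event == 0
    for _ in range(100):
        F_sum = np.zeros(cens.sum())
        for k in range(K):
            Z, _ = built[k]
            F_sum += -np.expm1(-np.exp(np.clip(Z[cens] @ theta0[offs[k]:offs[k+1]], -300, 300)))
        if not cens.any() or F_sum.max() < 0.95:
            break
        for k in range(K):
            theta0[offs[k]] -= 0.25

    def negll(th):
        ll, g = _sdh2_ll_grad(th, dataset, designs, built, logt)
        return -ll, -g

    def neg_hess(th):
        return -_sdh2_hessian(th, dataset, designs, built)

    trace: list[str] = []
    rng = np.random.default_rng(0)
    best = None
    # damped Newton with the analytic Hessian from the feasible init;
    # quasi-Newton warm starts only as fallback
    theta, ll, gnorm, ok = _polish(negll, theta0, neg_hess)
    trace.append(
        f"newton from init: loglik={ll:.6f} max|grad|={gnorm:.2e} "
        f"{'ok' if ok else 'NOT converged'}"
    )
    best = (theta, ll, gnorm, ok)
    for attempt in range(0 if ok else max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.2, theta0.size)
        res = optimize.minimize(negll, start, jac=True, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 1000})
        theta, ll = res.x, -res.fun
        theta, ll, gnorm, ok = _polish(negll, theta, neg_hess)
        trace.append(
            f"attempt {attempt}: bfgs_iters={res.nit} loglik={ll:.6f} "
            f"max|grad|={gnorm:.2e} {'ok' if ok else 'NOT converged'}"
        )
        if ll > best[1] or (ok and not best[3]):
            best = (theta, ll, gnorm, ok)
        if ok:
            break
    theta, ll, gnorm, ok = best
    if not ok:
        raise _engine.FitError(
            "direct joint-CIF fit did not converge (this route is known to "
            "have convergence problems at small sample sizes); trace: "
            + "; ".join(trace),
            trace,
        )
    info = neg_hess(theta)
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)

    # boundary diagnostics: is the CIF-sum constraint active at the optimum?
    F_sum = np.zeros(len(dataset))
    for k in range(K):
        Z, _ = built[k]
        F_sum += -np.expm1(-np.exp(np.clip(Z @ theta[offs[k]:offs[k+1]], -300, 300)))
    boundary = bool(cens.any() and (1.0 - F_sum[cens]).min() < 1e-6)
    if boundary:
        warnings.warn(
            "CIF-sum constraint active at the optimum for at least one "
            "censored observation; estimates sit on the feasibility boundary",
            RuntimeWarning,
        )

    models = {}
    for k in range(K):
        idx = np.arange(offs[k], offs[k + 1])
        models[k + 1] = FittedFPM(
            scale="subdistribution",
            cause=k + 1,
            design=designs[k],
            theta=theta[idx],
            vcov=vcov[np.ix_(idx, idx)],
            loglik=ll,  # joint likelihood, shared by all per-cause views
            n=len(dataset),
            n_events=int(np.sum(dataset.event == k + 1)),
            converged=ok,
            trace=trace,
        )
    return SDHFit(
        models=models,
        method="direct",
        joint_vcov=vcov,
        loglik=ll,
        boundary_active=boundary,
        trace=trace,
    )


def _polish(negll, theta, neg_hess=None, gtol=1e-6, max_iter=200):
    """Damped Newton for -loglik with an analytic (or finite-difference)
    Hessian; Levenberg ridge when the Newton direction is not a descent
    direction.  Tolerances scale with |loglik| — the likelihood sum
    carries ~1e-16 * |l| rounding noise at large n."""
    f, g = negll(theta)
    if not np.isfinite(f):
        return theta, -f, np.inf, False
    gtol_eff = gtol * max(1.0, 1e-3 * abs(f))
    stalls = 0
    for _ in range(max_iter):
        gnorm = float(np.max(np.abs(g)))
        if gnorm < gtol_eff:
            return theta, -f, gnorm, True
        H = neg_hess(theta) if neg_hess is not None else _fd_information(negll, theta)
        step = None
        ridge = 0.0
        scale = float(np.mean(np.abs(np.diag(H)))) or 1.0
        for _ in range(12):
            try:
                cand_step = np.linalg.solve(H + ridge * scale * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                cand_step = None
            if cand_step is not None and np.dot(cand_step, -g) > 0:
                step = cand_step
                break
            ridge = 1e-8 if ridge == 0.0 else ridge * 100
        if step is None:
            step = -g / max(1.0, gnorm)
        alpha = 1.0
        for _ in range(40):
            cand = theta + alpha * step
            f_new, g_new = negll(cand)
            if np.isfinite(f_new) and f_new <= f + 1e-9 * (1.0 + abs(f)):
                break
            alpha *= 0.5
        else:
            return theta, -f, gnorm, False
        if np.max(np.abs(g_new)) >= gnorm:
            stalls += 1
            if stalls >= 3:
                theta, f, g = cand, f_new, g_new
                break
        else:
            stalls = 0
        theta, f, g = cand, f_new, g_new
    gnorm = float(np.max(np.abs(g)))
    return theta, -f, gnorm, gnorm < gtol_eff


def _fd_information(negll, theta, rel_step=1e-6):
    """Central finite differences of the gradient of -loglik."""
    q = theta.size
    H = np.empty((q, q))
    for j in range(q):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (negll(tp)[1] - negll(tm)[1]) / (2 * h)
    return 0.5 * (H + H.T)


def predict_cif_sdh(
    fit: SDHFit,
    cause: int,
    x,
    grid,
    level: float = 0.95,
    ci: bool = True,
) -> CIFCurve:
    """CIF F_k(t|x) = 1 - exp(-exp(eta)) with a delta-method confidence
    band computed on the ln H^sd scale and back-transformed (keeps the
    band inside [0, 1])."""
    fpm = fit[cause]
    grid = np.asarray(grid, dtype=float)
    eta = fpm.linear_predictor(grid, x)
    F = -np.expm1(-np.exp(eta))
    lo = hi = None
    if ci:
        se = fpm.linear_predictor_se(grid, x)
        z = norm.ppf(0.5 + level / 2)
        lo = -np.expm1(-np.exp(eta - z * se))
        hi = -np.expm1(-np.exp(eta + z * se))
    return CIFCurve(cause=cause, grid=grid, F=F, ci_low=lo, ci_high=hi)


def check_cif_sum(fit: SDHFit, x, grid) -> np.ndarray:
    """Report (never clip) grid times where the fitted cause-specific CIFs
    sum above 1 — neither subdistribution route constrains the sum away
    from event times.  Returns the boolean mask and warns when any."""
    grid = np.asarray(grid, dtype=float)
    total = np.zeros(grid.size)
    for k in fit.causes:
        total += -np.expm1(-fit[k].cumhaz(grid, x))
    mask = total > 1.0
    if mask.any():
        warnings.warn(
            f"sum of fitted CIFs exceeds 1 at {int(mask.sum())} of {grid.size} "
            f"grid times (max {total.max():.4f})",
            RuntimeWarning,
        )
    return mask
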