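"""Model selection, likelihood-ratio tests, time-varying-effect tests,
delta-method confidence bands and stacked-risk summaries.

Spline complexity is chosen by information criteria over a degrees-of-
freedom range (AIC by default, starting from five and taking the
minimum); covariate and proportionality hypotheses are tested by
likelihood-ratio statistics at a flat 5% level.  For the weighted
subdistribution route the "likelihood" is a censoring-weighted
pseudo-likelihood; its information criteria and LR statistics are
reported with that caveat and no exact chi-square calibration is
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .csh import CIFCurve, FittedFPM, cif_from_csh, fit_csh_fpm
from .data import CompetingRisksDataset
from .ipcw import ExpandedWeightedDataset
from .sdh import SDHFit, fit_sdh_fpm1, fit_sdh_fpm2, predict_cif_sdh

__all__ = [
    "ModelComparison",
    "LRTestResult",
    "select_df",
    "lr_test",
    "tvc_test",
    "stacked_cif",
    "cif_confidence_band",
]


@dataclass
class ModelComparison:
    """AIC/BIC over candidate spline degrees of freedom."""

    candidates: pd.DataFrame  # df, loglik, n_params, AIC, BIC, converged
    selected: int
    fits: dict[int, object]
    notices: list[str]

    def best_fit(self):
        return self.fits[self.selected]


@dataclass
class LRTestResult:
    stat: float
    df: int
    p: float

    def __post_init__(self):
        if self.stat < -1e-8:
            raise ValueError(f"negative LR statistic {self.stat}")
        self.stat = max(self.stat, 0.0)


def _fit_one(dataset, cause, kind, df, covariates, expanded, **kw):
    if kind == "csh":
        return fit_csh_fpm(dataset, cause, df, covariates=covariates, **kw)
    if kind == "sdh1":
        if expanded is None:
            raise ValueError("sdh1 selection needs the expanded weighted dataset")
        return fit_sdh_fpm1(expanded, df, covariates=covariates, **kw)
    if kind == "sdh2":
        return fit_sdh_fpm2(dataset, df, covariates=covariates, **kw)
    raise ValueError(f"unknown model kind '{kind}'")


def _ll_params_n(fit):
    if isinstance(fit, SDHFit):
        ll = fit.loglik
        n_params = sum(m.n_params for m in fit.models.values())
        n = next(iter(fit.models.values())).n
    else:
        ll, n_params, n = fit.loglik, fit.n_params, fit.n
    return ll, n_params, n


def select_df(
    dataset: CompetingRisksDataset,
    cause: int,
    model_kind: str = "csh",
    df_range=range(1, 6),
    covariates: list[str] | None = None,
    expanded: ExpandedWeightedDataset | None = None,
    criterion: str = "AIC",
    **fit_kwargs,
) -> ModelComparison:
    """Fit candidate models over ``df_range`` and pick the lowest AIC
    (or BIC).  All candidates use identical covariates; non-converging
    candidates are excluded with a notice.  ``n`` in BIC is the number of
    subjects, not expanded rows.
    """
    rows = []
    fits = {}
    notices = []
    for df in df_range:
        try:
            fit = _fit_one(dataset, cause, model_kind, df, covariates, expanded, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
            notices.append(f"df={df}: fit failed ({exc})")
            continue
        ll, n_params, n = _ll_params_n(fit)
        converged = (
            all(m.converged for m in fit.models.values())
            if isinstance(fit, SDHFit)
            else fit.converged
        )
        if not converged:
            notices.append(f"df={df}: did not converge; excluded")
            continue
        rows.append(
            {
                "df": df,
                "loglik": ll,
                "n_params": n_params,
                "AIC": -2 * ll + 2 * n_params,
                "BIC": -2 * ll + n_params * np.log(n),
            }
        )
        fits[df] = fit
    if not rows:
        raise RuntimeError(
            "no candidate converged over df range "
            f"{list(df_range)}: {'; '.join(notices)}"
        )
    table = pd.DataFrame(rows)
    selected = int(table.loc[table[criterion].idxmin(), "df"])
    return ModelComparison(candidates=table, selected=selected, fits=fits, notices=notices)


def lr_test(nested_fit, full_fit) -> LRTestResult:
    """Likelihood-ratio test of a nested against a full model.

    ``stat = 2 (l_full - l_nested)``, chi-square with df = difference in
    parameter count.  Raises when the "full" model has fewer parameters
    or a worse likelihood beyond numerical slack (non-nesting or
    non-convergence).
    """
    ll0, p0, _ = _ll_params_n(nested_fit)
    ll1, p1, _ = _ll_params_n(full_fit)
    ddf = p1 - p0
    if ddf < 0:
        raise ValueError(
            f"full model has fewer parameters ({p1}) than nested ({p0}); "
            "arguments reversed?"
        )
    stat = 2.0 * (ll1 - ll0)
    if stat < -1e-6 * max(1.0, abs(ll1)):
        raise ValueError(
            f"full-model likelihood {ll1:.6f} below nested {ll0:.6f}: models "
            "are not nested or one fit did not converge"
        )
    stat = max(stat, 0.0)
    if ddf == 0:
        return LRTestResult(stat=stat, df=0, p=1.0)
    return LRTestResult(stat=stat, df=ddf, p=float(chi2.sf(stat, ddf)))


def tvc_test(
    fit_without,
    dataset: CompetingRisksDataset,
    covariate: str,
    time_fn: str = "log",
    expanded: ExpandedWeightedDataset | None = None,
) -> LRTestResult:
    """LR test for a time-varying effect of one covariate.

    Refits the model with the covariate interacted with ``ln t``
    (``time_fn="log"``) or the full baseline spline basis (``"spline"``)
    and compares by LR.  Works on cause-specific fits and on weighted
    subdistribution fits (pass the expansion used for the base fit; the
    statistic is then based on the weighted pseudo-likelihood).
    """
    if isinstance(fit_without, SDHFit):
        if fit_without.method != "weighted" or len(fit_without.models) != 1:
            raise ValueError("tvc_test supports single-cause weighted SDH fits")
        base = next(iter(fit_without.models.values()))
        if covariate not in base.design.covariate_names:
            raise ValueError(f"covariate '{covariate}' not in the fitted model")
        if expanded is None:
            raise ValueError("pass the expanded dataset used for the base fit")
        full = fit_sdh_fpm1(
            expanded,
            base.knots.df,
            covariates=list(base.design.covariate_names),
            tvc=[covariate],
            tvc_time_fn=time_fn,
            knots=base.knots,
        )
        return lr_test(fit_without, full)
    base = fit_without
    if covariate not in base.design.covariate_names:
        raise ValueError(f"covariate '{covariate}' not in the fitted model")
    full = fit_csh_fpm(
        dataset,
        base.cause,
        base.knots.df,
        covariates=list(base.design.covariate_names),
        tvc=[covariate],
        tvc_time_fn=time_fn,
        knots=base.knots,
    )
    return lr_test(base, full)


def stacked_cif(cif_curves: list[CIFCurve]) -> pd.DataFrame:
    """Stacked risk bands: cumulative sums of the per-cause CIFs in the
    declared cause order; the top band is the total first-event risk.

    Returns a tidy long table (cause, time, F, band) where ``band`` is the
    cumulative upper edge for that cause.
    """
    if not cif_curves:
        raise ValueError("no curves")
    grid = cif_curves[0].grid
    for c in cif_curves[1:]:
        if c.grid.shape != grid.shape or not np.allclose(c.grid, grid):
            raise ValueError("curves must share the same time grid")
    rows = []
    total = np.zeros_like(grid)
    for c in cif_curves:
        total = total + c.F
        rows.append(
            pd.DataFrame({"cause": c.cause, "time": grid, "F": c.F, "band": total})
        )
    return pd.concat(rows, ignore_index=True)


def _csh_cif_band(models: list[FittedFPM], cause: int, x, grid, level: float) -> CIFCurve:
    """Delta-method band for a CSH-route CIF: numeric gradient of F_k(t)
    with respect to the stacked per-cause parameters (block-diagonal
    covariance from the separate fits), variance propagated on the
    ln(-ln(1-F)) scale and back-transformed."""
    grid = np.asarray(grid, dtype=float)
    curves, _ = cif_from_csh(models, x, grid)
    F = next(c for c in curves if c.cause == cause).F

    thetas = [m.theta.copy() for m in models]
    grads = []
    for mi, m in enumerate(models):
        gm = np.zeros((grid.size, m.theta.size))
        for j in range(m.theta.size):
            h = 1e-5 * max(1.0, abs(thetas[mi][j]))
            for sgn in (+1, -1):
                m.theta = thetas[mi].copy()
                m.theta[j] += sgn * h
                cs, _ = cif_from_csh(models, x, grid)
                Fj = next(c for c in cs if c.cause == cause).F
                gm[:, j] += sgn * Fj / (2 * h)
            m.theta = thetas[mi].copy()
        grads.append(gm)
    var = np.zeros(grid.size)
    for m, gm in zip(models, grads):
        var += np.einsum("ij,jk,ik->i", gm, m.vcov, gm)
    Fc = np.clip(F, 1e-12, 1 - 1e-12)
    # transform to g = ln(-ln(1-F)); dg/dF = -1 / ((1-F) ln(1-F))
    dg = -1.0 / ((1 - Fc) * np.log1p(-Fc))
    se_g = np.sqrt(np.maximum(var, 0.0)) * np.abs(dg)
    z = norm.ppf(0.5 + level / 2)
    g0 = np.log(-np.log1p(-Fc))
    lo = -np.expm1(-np.exp(g0 - z * se_g))
    hi = -np.expm1(-np.exp(g0 + z * se_g))
    return CIFCurve(cause=cause, grid=grid, F=F, ci_low=np.minimum(lo, F), ci_high=np.maximum(hi, F))


def cif_confidence_band(fit, x, grid, cause: int | None = None, level: float = 0.95) -> CIFCurve:
    """Pointwise delta-method confidence band for a CIF, in [0, 1].

    For subdistribution fits the variance is computed on the ln H^sd
    scale (a linear function of the parameters) and back-transformed; for
    a list of cause-specific fits the CIF integral's parameter gradient
    is taken numerically.
    """
    if isinstance(fit, SDHFit):
        cause = cause if cause is not None else next(iter(fit.models))
        return predict_cif_sdh(fit, cause, x, grid, level=level, ci=True)
    if isinstance(fit, FittedFPM):
        # single model: F = 1 - exp(-H) (a subdistribution fit, or the
        # K=1 cause-specific case); band on the linear ln H scale
        return predict_cif_sdh(SDHFit(models={fit.cause: fit}, method="weighted"),
                               fit.cause, x, grid, level=level, ci=True)
    models = list(fit)
    if cause is None:
        cause = models[0].cause
    return _csh_cif_band(models, cause, x, np.asarray(grid, dtype=float), level)
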