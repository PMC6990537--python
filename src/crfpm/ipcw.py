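"""Censoring-distribution weights and the semiparametric Fine & Gray model.

The subdistribution risk set keeps subjects who already failed from a
competing cause.  Because such subjects can no longer be observed to be
censored, their continued presence is reweighted by the conditional
probability of remaining uncensored, G(t|x) / G(s|x), where s is their
competing-event time.  Here G is estimated parametrically by a flexible
parametric model with censoring as the event (df = 3 by default), after
which each competing-event subject's follow-up beyond s is split into
short intervals carrying time-dependent weights.  The resulting expanded
data feed either a weighted Cox partial likelihood (Fine & Gray) or a
weighted flexible parametric likelihood (the parametric subdistribution
route in :mod:`crfpm.sdh`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from ._design import ModelDesign
from .csh import FittedFPM
from .data import CompetingRisksDataset
from .splines import place_knots

__all__ = [
    "CensoringModel",
    "ExpandedWeightedDataset",
    "FineGrayResult",
    "NoCensoringError",
    "fit_censoring_fpm",
    "expand_and_weight",
    "fit_fine_gray",
]

log = logging.getLogger(__name__)

_W_FLOOR = 1e-12


class NoCensoringError(ValueError):
    """No censored observations: weights are not estimable.  All weights
    equal 1 in that case, so run the expansion in weight-free mode
    (``censoring_model=None``)."""


@dataclass
class CensoringModel:
    """FPM for the censoring distribution; G(t|x) = exp(-H_c(t|x))."""

    fpm: FittedFPM
    covariates: tuple[str, ...]

    def G(self, t, x) -> np.ndarray:
        """Probability of remaining uncensored through t given covariates."""
        return np.exp(-self.fpm.cumhaz(t, x))

    def G_rows(self, t: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Row-wise G(t_i | x_i) (vectorized over subjects)."""
        Z, _ = self.fpm.design.build(np.log(t), X)
        return np.exp(-np.exp(Z @ self.fpm.theta))


@dataclass
class ExpandedWeightedDataset:
    """Post-split at-risk segments with time-dependent censoring weights.

    One row per (subject, interval]: ``tstart < tstop``, event-of-interest
    indicator ``d``, weight ``w`` in (0, 1].  Rows of subjects without a
    competing event keep w = 1; within a subject, weights are
    nonincreasing over successive intervals.
    """

    frame: pd.DataFrame  # id, tstart, tstop, d, w, covariates...
    cause: int
    covariate_names: tuple[str, ...]
    K: int
    n_subjects: int
    delta: float
    dropped_underflow: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def arrays(self):
        f = self.frame
        X = f[list(self.covariate_names)].to_numpy(dtype=float)
        return (
            f["id"].to_numpy(),
            f["tstart"].to_numpy(dtype=float),
            f["tstop"].to_numpy(dtype=float),
            f["d"].to_numpy(dtype=float),
            f["w"].to_numpy(dtype=float),
            X,
        )

    def write(self, path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)


def fit_censoring_fpm(
    dataset: CompetingRisksDataset,
    df: int = 3,
    covariates: list[str] | None = None,
) -> CensoringModel:
    """Fit the censoring-distribution FPM (event indicator flipped).

    Defaults to the full covariate set and three degrees of freedom; pass
    ``covariates=[]`` for a marginal (covariate-free) model, the classic
    Fine-Gray choice.
    """
    d = (dataset.event == 0).astype(float)
    if d.sum() < 2:
        raise NoCensoringError(
            f"only {int(d.sum())} censored subjects; censoring weights are not "
            "estimable - run expand_and_weight with censoring_model=None "
            "(all weights 1)"
        )
    names = list(covariates) if covariates is not None else dataset.covariate_names
    X = dataset.X(names)
    knots = place_knots(dataset.time[d > 0], df, cause=0)
    design = ModelDesign(knots, tuple(names))
    if names:
        design.check_rank(X)
    Z1, Zd1 = design.build(np.log(dataset.time), X)
    res = _engine.fit(
        _engine.LogHazData(
            Z1=Z1, Zd1=Zd1, d=d, w=np.ones(len(dataset)), logt=np.log(dataset.time)
        )
    )
    fpm = FittedFPM(
        scale="cause-specific",
        cause=0,
        design=design,
        theta=res["theta"],
        vcov=res["vcov"],
        loglik=res["loglik"],
        n=len(dataset),
        n_events=int(d.sum()),
        converged=res["converged"],
        trace=res["trace"],
    )
    return CensoringModel(fpm=fpm, covariates=tuple(names))


def expand_and_weight(
    dataset: CompetingRisksDataset,
    censoring_model: CensoringModel | None,
    cause: int,
    delta: float = 0.1,
) -> ExpandedWeightedDataset:
    """Build the weighted expansion for the subdistribution risk set.

    Subjects with the event of interest or censoring contribute a single
    row (0, t] with weight 1.  A subject with a competing event at s
    contributes (0, s] with weight 1, then intervals of width ``delta``
    covering (s, tau] — tau the largest observed event-of-interest time —
    with weight G(t_stop|x) / G(s|x) evaluated at each interval's right
    endpoint.  Rows whose weight underflows are dropped with a log notice.
    The expansion is deterministic.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not 1 <= cause <= dataset.K:
        raise ValueError(f"cause must be in 1..{dataset.K}")
    t = dataset.time
    ev = dataset.event
    tau = float(t[ev == cause].max())
    if delta >= t.max() - t.min() and delta >= tau:
        warnings.warn(
            "delta spans the whole follow-up range; each competing-event "
            "subject gets a single post-event interval",
            RuntimeWarning,
        )
    names = dataset.covariate_names
    Xall = dataset.X(names)
    is_comp = (ev != 0) & (ev != cause)

    # simple rows: event of interest or censored
    simple = ~is_comp
    parts_id = [dataset.subject_id[simple]]
    parts_start = [np.zeros(simple.sum())]
    parts_stop = [t[simple]]
    parts_d = [(ev[simple] == cause).astype(float)]
    parts_w = [np.ones(simple.sum())]
    parts_X = [Xall[simple]]

    idx_c = np.nonzero(is_comp)[0]
    dropped = 0
    if idx_c.size:
        s = t[idx_c]
        # pre-event row (0, s], weight 1
        parts_id.append(dataset.subject_id[idx_c])
        parts_start.append(np.zeros(idx_c.size))
        parts_stop.append(s)
        parts_d.append(np.zeros(idx_c.size))
        parts_w.append(np.ones(idx_c.size))
        parts_X.append(Xall[idx_c])
        # post-event splits (s, tau]
        m = np.maximum(np.ceil((tau - s) / delta - 1e-9), 0).astype(int)
        if m.sum() > 0:
            rep = np.repeat(np.arange(idx_c.size), m)
            # j-th interval of subject i: (s_i + (j-1) delta, min(s_i + j delta, tau)]
            j = np.concatenate([np.arange(1, mi + 1) for mi in m if mi > 0]) if m.sum() else np.array([])
            starts = s[rep] + (j - 1) * delta
            stops = np.minimum(s[rep] + j * delta, tau)
            Xrep = Xall[idx_c][rep]
            if censoring_model is not None:
                Xc = dataset.X(list(censoring_model.covariates))[idx_c]
                Gs = censoring_model.G_rows(s, Xc)
                w = censoring_model.G_rows(stops, Xc[rep]) / Gs[rep]
                w = np.minimum(w, 1.0)
            else:
                w = np.ones(stops.size)
            keep = w >= _W_FLOOR
            dropped = int((~keep).sum())
            if dropped:
                log.info("expand_and_weight: dropped %d rows with weight < %g", dropped, _W_FLOOR)
            parts_id.append(dataset.subject_id[idx_c][rep][keep])
            parts_start.append(starts[keep])
            parts_stop.append(stops[keep])
            parts_d.append(np.zeros(keep.sum()))
            parts_w.append(w[keep])
            parts_X.append(Xrep[keep])

    frame = pd.DataFrame(
        {
            "id": np.concatenate(parts_id),
            "tstart": np.concatenate(parts_start),
            "tstop": np.concatenate(parts_stop),
            "d": np.concatenate(parts_d),
            "w": np.concatenate(parts_w),
        }
    )
    Xcat = np.vstack(parts_X)
    for i, nm in enumerate(names):
        frame[nm] = Xcat[:, i]
    frame = frame.sort_values(["id", "tstop"], kind="stable").reset_index(drop=True)
    return ExpandedWeightedDataset(
        frame=frame,
        cause=cause,
        covariate_names=tuple(names),
        K=dataset.K,
        n_subjects=len(dataset),
        delta=delta,
        dropped_underflow=dropped,
    )


# ---------------------------------------------------------------------------
# Weighted Cox partial likelihood (Fine & Gray)
# ---------------------------------------------------------------------------


@dataclass
class FineGrayResult:
    """Fine & Gray proportional subdistribution hazards fit.

    ``vcov`` is the robust sandwich covariance clustered on subject (the
    expansion creates correlated rows); ``naive_vcov`` the inverse
    information.  ``baseline`` holds the weighted Breslow estimate of the
    cumulative subdistribution hazard at the event times.
    """

    beta: np.ndarray
    vcov: np.ndarray
    naive_vcov: np.ndarray
    loglik: float
    covariate_names: tuple[str, ...]
    baseline_times: np.ndarray = field(repr=False)
    baseline_cumhaz: np.ndarray = field(repr=False)
    n_events: int = 0
    n_iter: int = 0

    @property
    def shr(self) -> np.ndarray:
        return np.exp(self.beta)

    def coefficient_table(self, level: float = 0.95):
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.vcov))
        z = norm.ppf(0.5 + level / 2)
        zs = self.beta / se
        return pd.DataFrame(
            {
                "param": self.covariate_names,
                "estimate": self.beta,
                "se": se,
                "SHR": np.exp(self.beta),
                "ci_low": np.exp(self.beta - z * se),
                "ci_high": np.exp(self.beta + z * se),
                "z": zs,
                "p": 2 * norm.sf(np.abs(zs)),
            }
        )


def _risk_sums(val: np.ndarray, sorted_key: np.ndarray, order: np.ndarray, at: np.ndarray):
    """Suffix sums sum_{j: key_j >= at} val_j via sorting (val may be 2-d)."""
    v = val[order]
    csum = np.cumsum(v[::-1], axis=0)[::-1]
    idx = np.searchsorted(sorted_key, at, side="left")
    out = np.zeros((at.size,) + val.shape[1:])
    inside = idx < sorted_key.size
    out[inside] = csum[idx[inside]]
    return out


def fit_fine_gray(
    expanded: ExpandedWeightedDataset,
    covariates: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> FineGrayResult:
    """Maximize the weighted Cox partial likelihood on the expanded data.

    Breslow handling of ties; weights enter the risk sums and the score.
    Standard errors are sandwich estimates clustered on subject.  The
    baseline cumulative subdistribution hazard uses the weighted Breslow
    estimator at x = 0.
    """
    names = tuple(covariates) if covariates is not None else expanded.covariate_names
    ids, start, stop, d, w, X = expanded.arrays()
    if covariates is not None:
        X = expanded.frame[list(names)].to_numpy(dtype=float)
    p = X.shape[1]
    ev = d > 0
    if ev.sum() < 2:
        raise ValueError("need >= 2 events of interest")
    if np.linalg.matrix_rank(X[:, :p] - X.mean(axis=0)) < p:
        raise np.linalg.LinAlgError("rank-deficient covariate matrix")

    # distinct event times and their total event weight / weighted covariate sum
    te, inv = np.unique(stop[ev], return_inverse=True)
    D = np.bincount(inv, weights=w[ev], minlength=te.size)
    Sx_ev = np.zeros((te.size, p))
    np.add.at(Sx_ev, inv, w[ev, None] * X[ev])

    o_stop = np.argsort(stop, kind="stable")
    sk_stop = stop[o_stop]
    o_start = np.argsort(start, kind="stable")
    sk_start = start[o_start]

    def sums(vals):
        return _risk_sums(vals, sk_stop, o_stop, te) - _risk_sums(vals, sk_start, o_start, te)

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        r = w * np.exp(X @ beta)
        S0 = sums(r)
        if np.any(S0 <= 0):
            raise np.linalg.LinAlgError("empty risk set at an event time")
        S1 = sums(r[:, None] * X)
        ll = float(np.sum(w[ev] * (X[ev] @ beta)) - np.sum(D * np.log(S0)))
        xbar = S1 / S0[:, None]
        g = Sx_ev.sum(axis=0) - (D[:, None] * xbar).sum(axis=0)
        S2 = sums(r[:, None, None] * X[:, :, None] * X[:, None, :])
        info = np.einsum("t,tij->ij", D, S2 / S0[:, None, None]) - np.einsum(
            "t,ti,tj->ij", D, xbar, xbar
        )
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular information matrix: {exc}") from exc
        if np.max(np.abs(beta + step)) > 50:
            j = int(np.argmax(np.abs(beta + step)))
            raise np.linalg.LinAlgError(
                f"monotone likelihood (separation) on covariate '{names[j]}'"
            )
        # step-halving to guarantee ascent
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            r_c = w * np.exp(X @ cand)
            S0_c = sums(r_c)
            ll_c = float(np.sum(w[ev] * (X[ev] @ cand)) - np.sum(D * np.log(S0_c)))
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = cand
        if abs(ll_c - ll_old) < tol * (1 + abs(ll_c)) and np.max(np.abs(g)) < 1e-6:
            ll = ll_c
            break
        ll_old = ll_c
    ll = ll_c
    if np.max(np.abs(beta)) > 15:
        j = int(np.argmax(np.abs(beta)))
        raise np.linalg.LinAlgError(
            f"monotone likelihood (separation) on covariate '{names[j]}': "
            f"|beta| diverged to {beta[j]:.1f}"
        )

    # final quantities at the optimum
    r = w * np.exp(X @ beta)
    S0 = sums(r)
    S1 = sums(r[:, None] * X)
    xbar = S1 / S0[:, None]
    S2 = sums(r[:, None, None] * X[:, :, None] * X[:, None, :])
    info = np.einsum("t,tij->ij", D, S2 / S0[:, None, None]) - np.einsum(
        "t,ti,tj->ij", D, xbar, xbar
    )
    naive_vcov = np.linalg.inv(info)

    # sandwich clustered on subject: score residuals per row, summed per id
    inc0 = np.cumsum(D / S0)
    incx = np.cumsum(D[:, None] * xbar / S0[:, None], axis=0)
    c0 = np.concatenate([[0.0], inc0])
    cx = np.vstack([np.zeros(p), incx])
    # index of last event time <= t
    pos_stop = np.searchsorted(te, stop, side="right")
    pos_start = np.searchsorted(te, start, side="right")
    d0 = c0[pos_stop] - c0[pos_start]
    dx = cx[pos_stop] - cx[pos_start]
    U = -r[:, None] * (X * d0[:, None] - dx)
    xbar_at_event = np.zeros((stop.size, p))
    xbar_at_event[ev] = xbar[inv]
    U[ev] += w[ev, None] * (X[ev] - xbar_at_event[ev])
    Udf = pd.DataFrame(U)
    Udf["id"] = ids
    Uc = Udf.groupby("id", sort=False).sum().to_numpy()
    meat = Uc.T @ Uc
    vcov = naive_vcov @ meat @ naive_vcov

    baseline = inc0  # Breslow cumulative subdistribution hazard at x = 0
    return FineGrayResult(
        beta=beta,
        vcov=vcov,
        naive_vcov=naive_vcov,
        loglik=ll,
        covariate_names=names,
        baseline_times=te,
        baseline_cumhaz=baseline,
        n_events=int(ev.sum()),
        n_iter=it,
    )
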