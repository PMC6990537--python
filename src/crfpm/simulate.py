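"""Simulators with known truth for every estimator in the package.

Three generators:

* :func:`simulate_csh` — per-cause Weibull cause-specific hazards with
  proportional covariate effects; the observed first event is the minimum
  of independent per-cause latent times (equivalent to drawing the event
  time from the total hazard and the cause with probability
  h_k / sum h_j).  Truth for the cause-specific models and the CIF
  integral.
* :func:`simulate_fine_gray` — the classic proportional subdistribution
  hazards design with a unit-exponential base inside the CIF,

      F_1(t | x) = 1 - [1 - p (1 - e^(-t))]^exp(x beta1),

  so cause 1 occurs with probability 1 - (1-p)^exp(x beta1); cause-2
  times are exponential conditional on not failing from cause 1.  Truth
  for all three subdistribution estimators.
* :func:`simulate_macs_like` — a three-cause HIV seroconverter cohort
  emulator (AIDS / non-AIDS disease / unrelated death + censoring within
  a 15-year window) whose covariate prevalences match the published
  cohort marginals; hazards are chosen so the event mix is
  AIDS-dominant.  Structural fixture only.

All generators use one seeded ``numpy`` generator per call and are
reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CompetingRisksDataset

__all__ = [
    "CSHSimSpec",
    "FGSimSpec",
    "simulate_csh",
    "simulate_fine_gray",
    "simulate_macs_like",
]


Censoring = tuple  # ("exponential", rate) | ("uniform", lo, hi) | ("admin", cap) | None


def _apply_censoring(t_event, censoring, rng):
    if censoring is None:
        return t_event, np.ones(t_event.size, bool)
    kind = censoring[0]
    if kind == "exponential":
        c = rng.exponential(1.0 / censoring[1], t_event.size)
    elif kind == "uniform":
        c = rng.uniform(censoring[1], censoring[2], t_event.size)
    elif kind == "admin":
        c = np.full(t_event.size, float(censoring[1]))
    else:
        raise ValueError(f"unknown censoring kind '{kind}'")
    observed = t_event <= c
    return np.minimum(t_event, c), observed


def _gen_covariates(covariates, n, rng) -> pd.DataFrame:
    """covariates: list of (name, kind, params); kind 'bernoulli' (p) or
    'categorical' ({level: prob}, reference level first -> indicators)."""
    cols = {}
    for name, kind, params in covariates:
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, params, n).astype(float)
        elif kind == "categorical":
            levels = list(params)
            probs = np.asarray([params[lv] for lv in levels], dtype=float)
            draw = rng.choice(len(levels), size=n, p=probs / probs.sum())
            for j, lv in enumerate(levels[1:], start=1):
                cols[f"{name}_{lv}"] = (draw == j).astype(float)
        else:
            raise ValueError(f"unknown covariate kind '{kind}'")
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class CSHSimSpec:
    """Design with known cause-specific Weibull hazards
    h_k(t|x) = lam_k p_k t^(p_k - 1) exp(x beta_k)."""

    n: int
    scales: tuple[float, ...]  # lam_k > 0
    shapes: tuple[float, ...]  # p_k > 0
    betas: tuple[tuple[float, ...], ...]  # per-cause log-HR vectors
    covariates: tuple = (("x", "bernoulli", 0.5),)
    censoring: Censoring | None = ("uniform", 0.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        if not (len(self.scales) == len(self.shapes) == len(self.betas)):
            raise ValueError("scales, shapes, betas must have equal length K")
        if any(s <= 0 for s in self.scales) or any(p <= 0 for p in self.shapes):
            raise ValueError("Weibull scale and shape parameters must be positive")

    @property
    def K(self) -> int:
        return len(self.scales)


def simulate_csh(spec: CSHSimSpec) -> CompetingRisksDataset:
    """Draw a cohort from known cause-specific Weibull hazards.

    Latent per-cause times T_k = (E_k / (lam_k e^(x beta_k)))^(1/p_k),
    E_k ~ Exp(1); the first event is the minimum and its cause the
    argmin — under this construction the cause given the event time has
    probability h_k(t) / sum_j h_j(t), as required.
    """
    rng = np.random.default_rng(spec.seed)
    cov = _gen_covariates(spec.covariates, spec.n, rng)
    X = cov.to_numpy(dtype=float)
    lat = np.empty((spec.K, spec.n))
    for k in range(spec.K):
        beta = np.asarray(spec.betas[k], dtype=float)
        if beta.size != X.shape[1]:
            raise ValueError(
                f"beta vector for cause {k + 1} has length {beta.size}, "
                f"expected {X.shape[1]}"
            )
        rate = spec.scales[k] * np.exp(X @ beta)
        lat[k] = (rng.exponential(1.0, spec.n) / rate) ** (1.0 / spec.shapes[k])
    t_event = lat.min(axis=0)
    cause = lat.argmin(axis=0) + 1
    time, observed = _apply_censoring(t_event, spec.censoring, rng)
    event = np.where(observed, cause, 0)
    return CompetingRisksDataset(
        subject_id=np.arange(spec.n), time=time, event=event, covariates=cov, K=spec.K
    )


@dataclass(frozen=True)
class FGSimSpec:
    """Classic proportional subdistribution hazards design.

    ``p`` is the baseline long-run cause-1 probability (mass parameter);
    ``beta1`` the subdistribution log-SHR vector for cause 1; cause-2
    times are Exp(``cause2_rate`` * exp(x beta2)) conditional on not
    being a cause-1 failure.  The default exponential censoring rate
    yields roughly 30% censoring at p = 0.3, beta1 = 0.5.
    """

    n: int
    p: float = 0.3
    beta1: tuple[float, ...] = (0.5,)
    cause2_rate: float = 1.0
    beta2: tuple[float, ...] = (0.0,)
    covariates: tuple = (("x", "bernoulli", 0.5),)
    censoring: Censoring | None = ("exponential", 0.45)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("mass parameter p must be in (0, 1)")


def fg_cif1(t, x, spec: FGSimSpec) -> np.ndarray:
    """Analytic cause-1 CIF of the design (for oracle checks)."""
    eb = np.exp(np.dot(np.atleast_1d(x), spec.beta1))
    return 1.0 - (1.0 - spec.p * (1.0 - np.exp(-np.asarray(t, dtype=float)))) ** eb


def simulate_fine_gray(spec: FGSimSpec) -> CompetingRisksDataset:
    """Draw a cohort with a known subdistribution log-hazard ratio.

    Cause-1 indicator with P = F_1(inf|x) = 1 - (1-p)^exp(x beta1);
    cause-1 times by inverting the conditional CDF F_1(t|x)/F_1(inf|x);
    cause-2 times exponential.  Censoring applies on top.
    """
    rng = np.random.default_rng(spec.seed)
    cov = _gen_covariates(spec.covariates, spec.n, rng)
    X = cov.to_numpy(dtype=float)
    eb1 = np.exp(X @ np.asarray(spec.beta1, dtype=float))
    p1_inf = 1.0 - (1.0 - spec.p) ** eb1
    is1 = rng.uniform(size=spec.n) < p1_inf
    t_event = np.empty(spec.n)
    # cause 1: invert u * F1(inf) = 1 - [1 - p(1 - e^-t)]^eb
    u = rng.uniform(size=is1.sum())
    inner = 1.0 - (1.0 - u * p1_inf[is1]) ** (1.0 / eb1[is1])
    t_event[is1] = -np.log1p(-inner / spec.p)
    # cause 2: exponential conditional on not failing from cause 1
    rate2 = spec.cause2_rate * np.exp(X[~is1] @ np.asarray(spec.beta2, dtype=float))
    t_event[~is1] = rng.exponential(1.0, (~is1).sum()) / rate2
    cause = np.where(is1, 1, 2)
    time, observed = _apply_censoring(t_event, spec.censoring, rng)
    event = np.where(observed, cause, 0)
    return CompetingRisksDataset(
        subject_id=np.arange(spec.n), time=time, event=event, covariates=cov, K=2
    )


def simulate_macs_like(
    n: int, seed: int = 0, cap: float = 15.0, missing_rate: float = 0.0
) -> CompetingRisksDataset:
    """Emulate the structure of an HIV seroconverter cohort with three
    competing first events (1 = AIDS, 2 = non-AIDS disease, 3 = unrelated
    death) plus loss to follow-up and administrative censoring at ``cap``
    years.

    Covariate marginals follow the published cohort: recruitment period 1
    prevalence 0.862, age < 40 prevalence 0.7091, baseline CD4 categories
    (<350, 350-500, >=500) with prevalences (0.0811, 0.1622, 0.7568).
    Cause-specific hazards are chosen so the event mix is AIDS-dominant;
    joint covariate structure and fitted effect sizes are not emulated.

    ``missing_rate`` > 0 masks each covariate value independently at that
    rate (missing completely at random); the result then skips invariant
    validation and must go through ``complete_cases`` before modelling.
    """
    if n < 50:
        raise ValueError("n must be >= 50 for a usable cohort")
    rng = np.random.default_rng(seed)
    cov = _gen_covariates(
        (
            ("period1", "bernoulli", 0.862),
            ("age_lt40", "bernoulli", 0.7091),
            ("cd4", "categorical", {"ge500": 0.7568, "mid": 0.1622, "lt350": 0.0811}),
        ),
        n,
        rng,
    )
    X = cov.to_numpy(dtype=float)
    period1 = X[:, 0]
    age_lt40 = X[:, 1]
    cd4_mid = X[:, 2]
    cd4_low = X[:, 3]
    # AIDS-dominant hazards, qualitatively matching the cohort's event mix
    h_aids = 0.055 * np.exp(1.2 * period1 + 0.2 * age_lt40 + 0.6 * cd4_low + 0.3 * cd4_mid)
    h_nonaids = 0.040 * np.exp(-0.9 * age_lt40)
    h_death = 0.004 * np.exp(-0.8 * age_lt40)
    lat = np.stack(
        [
            rng.exponential(1.0, n) / h_aids,
            rng.exponential(1.0, n) / h_nonaids,
            rng.exponential(1.0, n) / h_death,
        ]
    )
    t_event = lat.min(axis=0)
    cause = lat.argmin(axis=0) + 1
    c_ltfu = rng.exponential(1.0 / 0.025, n)
    c = np.minimum(c_ltfu, cap)
    time = np.minimum(t_event, c)
    event = np.where(t_event <= c, cause, 0)
    time = np.maximum(time, 1e-6)
    if missing_rate > 0:
        mask = rng.uniform(size=cov.shape) < missing_rate
        cov = cov.mask(mask)
        ds = CompetingRisksDataset.__new__(CompetingRisksDataset)
        ds.subject_id = np.arange(n)
        ds.time = time
        ds.event = event
        ds.covariates = cov
        ds.K = 3
        return ds
    return CompetingRisksDataset(
        subject_id=np.arange(n), time=time, event=event, covariates=cov, K=3
    )
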