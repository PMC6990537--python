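import numpy as np
import pandas as pd
import pytest

from crfpm import _engine
from crfpm._design import ModelDesign
from crfpm.csh import (
    FittedFPM,
    cif_from_csh,
    csh_linear_predictor,
    csh_loglik,
    fit_csh_fpm,
    fit_stacked_csh,
)
from crfpm.data import CompetingRisksDataset
from crfpm.simulate import CSHSimSpec, simulate_csh
from crfpm.splines import KnotSet

from helpers import weibull_ph_mle


def make_fpm(gamma, beta=(), knots=None, covs=(), scale="cause-specific", cause=1):
    """Hand-built fitted model with known parameters (no fitting)."""
    knots = knots or KnotSet(boundary=(-3.0, 3.0))
    design = ModelDesign(knots, tuple(covs))
    theta = np.asarray(list(gamma) + list(beta), dtype=float)
    q = theta.size
    return FittedFPM(
        scale=scale, cause=cause, design=design, theta=theta,
        vcov=np.zeros((q, q)), loglik=0.0, n=1, n_events=1, converged=True,
    )


class TestLinearPredictorClosedForms:
    def test_exponential(self):
        """gamma = (ln lam, 1) gives H = lam t, h = lam."""
        lam = 0.5
        m = make_fpm(gamma=(np.log(lam), 1.0))
        t = np.array([0.3, 1.0, 4.0])
        assert np.allclose(m.cumhaz(t, []), lam * t, rtol=1e-12)
        assert np.allclose(m.hazard(t, []), lam, rtol=1e-12)

    def test_weibull(self):
        lam, p = 0.4, 1.7
        m = make_fpm(gamma=(np.log(lam), p))
        t = np.array([0.2, 1.0, 2.5])
        assert np.allclose(m.cumhaz(t, []), lam * t**p, rtol=1e-12)
        assert np.allclose(m.hazard(t, []), lam * p * t ** (p - 1), rtol=1e-12)

    def test_covariate_shifts_linear_predictor(self):
        m = make_fpm(gamma=(0.0, 1.0), beta=(0.7,), covs=("x",))
        t = np.array([1.0, 2.0])
        assert np.allclose(
            csh_linear_predictor(m, t, [1.0]) - csh_linear_predictor(m, t, [0.0]),
            0.7,
        )

    def test_hazard_matches_finite_difference_general_df(self, weibull_ds):
        fit = fit_csh_fpm(weibull_ds, 1, df=3)
        t = np.linspace(0.3, 4.0, 25)
        h = 1e-5
        fd = (fit.cumhaz(t + h, [1.0]) - fit.cumhaz(t - h, [1.0])) / (2 * h)
        assert np.allclose(fit.hazard(t, [1.0]), fd, rtol=1e-5)


class TestLoglik:
    def test_single_event_hand_computed(self):
        """One subject failing at t=2 under exponential lam=0.5:
        l = ln h - H = ln 0.5 - 1."""
        knots = KnotSet(boundary=(-2.0, 2.0))
        design = ModelDesign(knots, ())
        Z, Zd = design.build(np.log(np.array([2.0])), np.empty((1, 0)))
        data = _engine.LogHazData(
            Z1=Z, Zd1=Zd, d=np.array([1.0]), w=np.array([1.0]),
            logt=np.log(np.array([2.0])),
        )
        ll = _engine.loglik(np.array([np.log(0.5), 1.0]), data)
        assert np.isclose(ll, np.log(0.5) - 1.0, atol=1e-12)

    def test_censored_subject_contributes_minus_H(self):
        knots = KnotSet(boundary=(-2.0, 2.0))
        design = ModelDesign(knots, ())
        # the container requires >= 1 event; pair the censored row with an
        # event row at t=1 and subtract its known contribution
        Z2, Zd2 = design.build(np.log(np.array([3.0, 1.0])), np.empty((2, 0)))
        data = _engine.LogHazData(
            Z1=Z2, Zd1=Zd2, d=np.array([0.0, 1.0]), w=np.array([1.0, 1.0]),
            logt=np.log(np.array([3.0, 1.0])),
        )
        lam = 0.5
        ll = _engine.loglik(np.array([np.log(lam), 1.0]), data)
        # censored row: -lam*3 ; event row: ln(lam) - lam*1
        assert np.isclose(ll, -lam * 3 + np.log(lam) - lam, atol=1e-12)

    def test_stored_loglik_reproducible_at_stored_params(self, two_cause_ds):
        """AIC/BIC integrity: re-evaluating the likelihood at the stored
        parameters reproduces the stored optimum."""
        fit = fit_csh_fpm(two_cause_ds, 1, df=2)
        assert np.isclose(csh_loglik(fit, two_cause_ds), fit.loglik, atol=1e-8)


class TestFitCSH:
    def test_weibull_equivalence_df1(self, weibull_ds):
        """df=1 is exactly a Weibull PH model: coefficients and loglik
        match the independent Weibull MLE."""
        fit = fit_csh_fpm(weibull_ds, 1, df=1)
        d = (weibull_ds.event == 1).astype(float)
        loglam, p, beta, ll = weibull_ph_mle(
            weibull_ds.time, d, weibull_ds.X()
        )
        assert abs(fit.gamma[0] - loglam) < 1e-4
        assert abs(fit.gamma[1] - p) < 1e-4
        assert abs(fit.beta[0] - beta[0]) < 1e-4
        assert abs(fit.loglik - ll) < 1e-6 * abs(ll)

    def test_recovers_known_effect(self, two_cause_ds):
        fit = fit_csh_fpm(two_cause_ds, 1, df=1)
        assert 0.59 < fit.beta[0] < 0.80  # truth 0.693

    def test_constant_covariate_is_design_error(self):
        ds = CompetingRisksDataset(
            subject_id=np.arange(20),
            time=np.linspace(0.5, 5, 20),
            event=np.tile([1, 0], 10),
            covariates=pd.DataFrame({"x": np.ones(20)}),
        )
        with pytest.raises(np.linalg.LinAlgError):
            fit_csh_fpm(ds, 1, df=1)

    def test_loglik_nondecreasing_in_df_nested_knots(self, weibull_ds):
        """With identical boundary knots every higher-df basis contains
        the df=1 model, so the maximized likelihood cannot decrease."""
        lls = [fit_csh_fpm(weibull_ds, 1, df=df).loglik for df in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[0] - 1e-6

    def test_vcov_calibration_and_bias(self):
        """Parameter recovery across 100 reps at n=2000: mean within 3 MC
        SEs of truth, model SEs within 25% of the empirical SD."""
        est, ses = [], []
        for r in range(100):
            ds = simulate_csh(CSHSimSpec(
                n=2000, scales=(0.2, 0.3), shapes=(1.0, 1.0),
                betas=((0.693,), (0.0,)), censoring=("uniform", 0.0, 12.0),
                seed=20_000 + r,
            ))
            fit = fit_csh_fpm(ds, 1, df=2)
            est.append(fit.beta[0])
            i = fit.design.param_names().index("x")
            ses.append(np.sqrt(fit.vcov[i, i]))
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / 10
        assert abs(est.mean() - 0.693) < 3 * mc_se
        assert 0.8 < est.std(ddof=1) / np.mean(ses) < 1.25


class TestStacked:
    def test_equals_separate_fits_without_sharing(self, two_cause_ds):
        stacked = fit_stacked_csh(two_cause_ds, df_per_cause=[2, 2])
        for m in stacked.models:
            sep = fit_csh_fpm(two_cause_ds, m.cause, df=2)
            assert np.allclose(m.theta, sep.theta, atol=1e-5)
            assert np.isclose(m.loglik, sep.loglik, atol=1e-6)
        assert np.isclose(
            stacked.loglik, sum(fit_csh_fpm(two_cause_ds, k, df=2).loglik for k in (1, 2)),
            atol=1e-5,
        )

    def test_shared_effect_between_separate_estimates(self):
        ds = simulate_csh(CSHSimSpec(
            n=4000, scales=(0.2, 0.3), shapes=(1.0, 1.2),
            betas=((0.5,), (0.5,)), censoring=("uniform", 0.0, 10.0), seed=31,
        ))
        stacked = fit_stacked_csh(ds, df_per_cause=[1, 1], shared=["x"])
        sep = [fit_csh_fpm(ds, k, df=1).beta[0] for k in (1, 2)]
        shared = stacked.theta[-1]
        assert min(sep) - 1e-8 <= shared <= max(sep) + 1e-8

    def test_single_cause_stacking_degenerates(self, weibull_ds):
        stacked = fit_stacked_csh(weibull_ds, df_per_cause=[2])
        sep = fit_csh_fpm(weibull_ds, 1, df=2)
        assert np.allclose(stacked.models[0].theta, sep.theta, atol=1e-6)


class TestCIF:
    def test_constant_hazards_closed_form(self):
        """h1 = h2 = 1: F1(1) = (1 - e^-2)/2, S = e^-2t, conserved."""
        m1 = make_fpm(gamma=(0.0, 1.0), cause=1)
        m2 = make_fpm(gamma=(0.0, 1.0), cause=2)
        grid = np.array([0.25, 0.5, 1.0, 2.0])
        curves, surv = cif_from_csh([m1, m2], [], grid)
        expect = 0.5 * (1 - np.exp(-2 * grid))
        assert np.allclose(curves[0].F, expect, atol=1e-7)
        assert np.allclose(curves[1].F, expect, atol=1e-7)
        assert np.allclose(surv.S, np.exp(-2 * grid), rtol=1e-12)
        assert abs(curves[0].F[2] - 0.43233) < 1e-4

    def test_early_limit_vanishes(self):
        m = make_fpm(gamma=(0.0, 1.0))
        curves, _ = cif_from_csh([m], [], np.array([1e-6, 1.0]))
        assert curves[0].F[0] < 1e-5

    def test_single_cause_identity(self, weibull_ds):
        fit = fit_csh_fpm(weibull_ds, 1, df=2)
        grid = np.linspace(0.1, 5, 50)
        curves, surv = cif_from_csh([fit], [1.0], grid)
        assert np.allclose(curves[0].F, 1 - surv.S, atol=1e-8)

    def test_conservation_all_patterns(self, two_cause_ds):
        fits = [fit_csh_fpm(two_cause_ds, k, df=3) for k in (1, 2)]
        grid = np.linspace(0.05, 8, 200)
        for x in ([0.0], [1.0]):
            curves, surv = cif_from_csh(fits, x, grid)
            total = curves[0].F + curves[1].F + surv.S
            assert np.max(np.abs(total - 1)) < 1e-6
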