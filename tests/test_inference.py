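import numpy as np
import pytest

from crfpm.csh import cif_from_csh, fit_csh_fpm
from crfpm.inference import (
    LRTestResult,
    cif_confidence_band,
    lr_test,
    select_df,
    stacked_cif,
    tvc_test,
)
from crfpm.ipcw import expand_and_weight, fit_censoring_fpm
from crfpm.sdh import fit_sdh_fpm1
from crfpm.simulate import CSHSimSpec, simulate_csh

from test_csh import make_fpm


class TestSelectDF:
    def test_aic_arithmetic_and_selection(self, weibull_ds):
        comp = select_df(weibull_ds, 1, model_kind="csh", df_range=range(1, 4))
        t = comp.candidates
        assert np.allclose(t["AIC"], -2 * t["loglik"] + 2 * t["n_params"])
        assert np.allclose(
            t["BIC"], -2 * t["loglik"] + t["n_params"] * np.log(len(weibull_ds))
        )
        assert comp.selected == int(t.loc[t["AIC"].idxmin(), "df"])

    def test_weibull_data_prefers_df1(self, weibull_ds):
        comp = select_df(weibull_ds, 1, df_range=range(1, 6))
        assert comp.selected in (1, 2)  # modal choice over reps is 1

    def test_all_failures_raise(self):
        import pandas as pd

        from crfpm.data import CompetingRisksDataset

        # heavily tied event times: centile knots collide for every
        # candidate df, so no fit converges
        ds = CompetingRisksDataset(
            subject_id=np.arange(8),
            time=np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0]),
            event=np.array([1, 1, 1, 1, 1, 1, 1, 0]),
            covariates=pd.DataFrame(index=range(8)),
        )
        with pytest.raises(RuntimeError, match="no candidate converged"):
            select_df(ds, 1, df_range=[5, 6])

    def test_sdh1_selection_runs(self, fg_ds):
        cm = fit_censoring_fpm(fg_ds, df=3)
        expd = expand_and_weight(fg_ds, cm, cause=1, delta=0.1)
        comp = select_df(fg_ds, 1, model_kind="sdh1", df_range=range(1, 4),
                         expanded=expd)
        assert comp.selected in (1, 2, 3)
        assert len(comp.candidates) == 3


class TestLRTest:
    def test_model_vs_itself(self, weibull_ds):
        fit = fit_csh_fpm(weibull_ds, 1, df=2)
        res = lr_test(fit, fit)
        assert res.stat == 0.0 and res.p == 1.0

    def test_detects_real_effect(self, weibull_ds):
        full = fit_csh_fpm(weibull_ds, 1, df=2)
        nested = fit_csh_fpm(weibull_ds, 1, df=2, covariates=[])
        res = lr_test(nested, full)
        assert res.df == 1 and res.p < 1e-6

    def test_reversed_nesting_raises(self, weibull_ds):
        full = fit_csh_fpm(weibull_ds, 1, df=2)
        nested = fit_csh_fpm(weibull_ds, 1, df=2, covariates=[])
        with pytest.raises(ValueError, match="fewer parameters"):
            lr_test(full, nested)

    def test_negative_stat_beyond_slack_raises(self):
        with pytest.raises(ValueError):
            LRTestResult(stat=-0.5, df=1, p=0.5)

    def test_invariant_under_covariate_rescaling(self, weibull_ds):
        """The LR statistic for dropping a covariate does not change when
        the covariate is affinely rescaled."""
        ds2 = type(weibull_ds)(
            subject_id=weibull_ds.subject_id.copy(),
            time=weibull_ds.time.copy(),
            event=weibull_ds.event.copy(),
            covariates=weibull_ds.covariates * 7.0 + 3.0,
            K=weibull_ds.K,
        )
        nested = fit_csh_fpm(weibull_ds, 1, df=1, covariates=[])
        s1 = lr_test(nested, fit_csh_fpm(weibull_ds, 1, df=1)).stat
        s2 = lr_test(
            fit_csh_fpm(ds2, 1, df=1, covariates=[]), fit_csh_fpm(ds2, 1, df=1)
        ).stat
        assert np.isclose(s1, s2, atol=1e-5)


class TestTVC:
    def test_power_under_strong_time_dependence(self):
        """Effect beta(t) = 0.5 + 1.0 ln t must be flagged at n=3000."""
        rng = np.random.default_rng(77)
        n = 3000
        x = rng.binomial(1, 0.5, n).astype(float)
        # hazard h(t|x) = 0.3 t^{0.5 x} e^{0.5 x}: cumulative hazard
        # H = 0.3 e^{0.5x} t^{1+0.5x}/(1+0.5x); invert for sampling
        u = rng.exponential(1.0, n)
        pw = 1 + 0.5 * x
        t = (u * pw / (0.3 * np.exp(0.5 * x))) ** (1 / pw)
        c = rng.uniform(0, 6, n)
        import pandas as pd

        from crfpm.data import CompetingRisksDataset

        ds = CompetingRisksDataset(
            subject_id=np.arange(n), time=np.minimum(t, c),
            event=(t <= c).astype(int), covariates=pd.DataFrame({"x": x}),
        )
        base = fit_csh_fpm(ds, 1, df=2)
        res = tvc_test(base, ds, "x", time_fn="log")
        assert res.p < 0.01

    def test_absent_covariate_raises(self, weibull_ds):
        base = fit_csh_fpm(weibull_ds, 1, df=2)
        with pytest.raises(ValueError, match="not in the fitted model"):
            tvc_test(base, weibull_ds, "nope")

    def test_weighted_route_accepts_expansion(self, fg_ds):
        cm = fit_censoring_fpm(fg_ds, df=3)
        expd = expand_and_weight(fg_ds, cm, cause=1, delta=0.1)
        base = fit_sdh_fpm1(expd, df=2)
        res = tvc_test(base, fg_ds, "x", expanded=expd)
        assert 0.0 <= res.p <= 1.0 and res.df == 1


class TestStackedCIF:
    def test_trivial_bands(self):
        from crfpm.csh import CIFCurve

        grid = np.array([1.0, 2.0])
        c1 = CIFCurve(cause=1, grid=grid, F=np.array([0.2, 0.2]))
        c2 = CIFCurve(cause=2, grid=grid, F=np.array([0.2, 0.2]))
        tidy = stacked_cif([c1, c2])
        assert np.allclose(tidy[tidy.cause == 1].band, 0.2)
        assert np.allclose(tidy[tidy.cause == 2].band, 0.4)

    def test_top_band_is_total_risk(self, two_cause_ds):
        fits = [fit_csh_fpm(two_cause_ds, k, df=2) for k in (1, 2)]
        grid = np.linspace(0.1, 6, 60)
        curves, surv = cif_from_csh(fits, [1.0], grid)
        tidy = stacked_cif(curves)
        top = tidy[tidy.cause == curves[-1].cause].band.to_numpy()
        assert np.max(np.abs(top - (1 - surv.S))) < 1e-6
        # bands nondecreasing across causes at fixed time
        wide = tidy.pivot(index="time", columns="cause", values="band")
        assert (wide.diff(axis=1).iloc[:, 1:] >= -1e-12).all().all()


class TestConfidenceBands:
    def test_zero_vcov_zero_width(self):
        m = make_fpm(gamma=(0.0, 1.0), scale="subdistribution")
        curve = cif_confidence_band(m, [], np.array([0.5, 1.0]))
        assert np.allclose(curve.ci_low, curve.F)
        assert np.allclose(curve.ci_high, curve.F)

    def test_bands_contain_estimate_and_stay_in_unit_interval(self, fg_ds):
        cm = fit_censoring_fpm(fg_ds, df=3)
        expd = expand_and_weight(fg_ds, cm, cause=1, delta=0.1)
        s1 = fit_sdh_fpm1(expd, df=3)
        grid = np.linspace(0.1, 6, 80)
        curve = cif_confidence_band(s1, [1.0], grid)
        assert np.all(curve.ci_low <= curve.F + 1e-12)
        assert np.all(curve.F <= curve.ci_high + 1e-12)
        assert np.all(curve.ci_low >= 0) and np.all(curve.ci_high <= 1)

    def test_csh_route_band_runs_and_brackets(self, two_cause_ds):
        fits = [fit_csh_fpm(two_cause_ds, k, df=1) for k in (1, 2)]
        grid = np.array([0.5, 1.0, 2.0])
        curve = cif_confidence_band(fits, [1.0], grid, cause=1)
        assert np.all(curve.ci_low <= curve.F) and np.all(curve.F <= curve.ci_high)
        assert np.all((curve.ci_high - curve.ci_low) > 0)

    def test_coverage_single_cause(self):
        """Pointwise coverage of the delta-method band at the time-grid
        median under a known Weibull truth (nominal 0.95)."""
        lam, p, beta = 0.3, 1.3, 0.5
        t_eval = 1.5
        truth = 1 - np.exp(-lam * t_eval**p * np.exp(beta))
        hits = 0
        reps = 150
        for r in range(reps):
            ds = simulate_csh(CSHSimSpec(
                n=2000, scales=(lam,), shapes=(p,), betas=((beta,),),
                censoring=("uniform", 0.0, 6.0), seed=80_000 + r,
            ))
            fit = fit_csh_fpm(ds, 1, df=2)
            curve = cif_confidence_band(fit, [1.0], np.array([t_eval]))
            hits += curve.ci_low[0] <= truth <= curve.ci_high[0]
        assert abs(hits / reps - 0.95) < 0.04
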