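import dataclasses

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import integrate

import msmfrailty as mf
from msmfrailty import BaselineSpec, FitControl
from msmfrailty.frailty_fit import BreslowBaseline


def lifelines_cox(view, covariates):
    """Independent partial-likelihood oracle (Breslow ties)."""
    cph = CoxPHFitter()
    cph.fit(
        view[["duration", "status", *covariates]],
        duration_col="duration",
        event_col="status",
        fit_options={"precision": 1e-12},
    )
    return cph.params_.to_numpy()


def cluster_integral(view, covariates, beta, H0, sigma2, cluster):
    """Quadrature oracle: the marginal cluster likelihood as the explicit
    one-dimensional integral over the gamma frailty density."""
    from scipy import stats

    sub = view[view["cluster"] == cluster]
    X = sub[list(covariates)].to_numpy(float)
    risk = H0.cumulative_at(sub["duration"].to_numpy()) * np.exp(X @ beta)
    ev = sub["status"].to_numpy() == 1
    h0 = H0.jump_at(sub["duration"].to_numpy()[ev])
    fixed = np.prod(h0 * np.exp((X[ev] @ beta)))
    d = int(ev.sum())

    def integrand(z):
        return (
            z**d
            * np.exp(-z * risk.sum())
            * stats.gamma.pdf(z, a=1 / sigma2, scale=sigma2)
        )

    val, _ = integrate.quad(integrand, 0, np.inf)
    return fixed * val


def simulate_single_transition(n, n_clusters, sigma2, beta, baseline, seed,
                               censor_scale=10.0):
    rng = np.random.default_rng(seed)
    X = mf.draw_covariates(n, seed=rng)
    cl = np.arange(n) % n_clusters
    z = mf.draw_frailty(n_clusters, sigma2, seed=rng)[cl]
    lin = X.to_numpy() @ np.asarray(beta)
    t = mf.invert_time(rng.uniform(size=n), lin, z, baseline)
    c = rng.exponential(censor_scale, size=n)
    return pd.DataFrame({
        "id": np.arange(n), "entry": 0.0,
        "duration": np.minimum(t, c), "status": (t <= c).astype(int),
        "cluster": cl, **{k: X[k] for k in X},
    })


COVS2 = ("x1", "x2")
COVS4 = ("x1", "x2", "x3", "x4")


class TestCoxPartialFit:
    def test_null_case_two_balanced_groups(self):
        rng = np.random.default_rng(1)
        n = 2000
        view = pd.DataFrame({
            "duration": rng.exponential(1.0, size=n),
            "status": 1,
            "group": np.repeat([0.0, 1.0], n // 2),
        })
        res = mf.cox_partial_fit(view, ["group"])
        assert abs(res.beta[0]) < 3 * res.se[0]

    def test_matches_independent_implementation(self, single_transition_view):
        res = mf.cox_partial_fit(single_transition_view, COVS2)
        ref = lifelines_cox(single_transition_view, COVS2)
        np.testing.assert_allclose(res.beta, ref, atol=1e-6)

    def test_offset_shift_invariance(self, single_transition_view):
        res0 = mf.cox_partial_fit(single_transition_view, COVS2)
        shifted = np.full(len(single_transition_view), 2.5)
        res1 = mf.cox_partial_fit(single_transition_view, COVS2, offsets=shifted)
        np.testing.assert_allclose(res0.beta, res1.beta, atol=1e-8)

    def test_no_events_rejected(self, single_transition_view):
        view = single_transition_view.assign(status=0)
        with pytest.raises(ValueError):
            mf.cox_partial_fit(view, COVS2)

    def test_collinear_covariates_rejected(self, single_transition_view):
        view = single_transition_view.assign(x3=single_transition_view["x1"] * 2)
        with pytest.raises(Exception, match="singular"):
            mf.cox_partial_fit(view, ("x1", "x2", "x3"))


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen(self):
        view = pd.DataFrame({
            "duration": [1.0, 2.0, 3.0, 4.0],
            "status": [1, 1, 1, 1],
            "x": [0.0] * 4,
        })
        H0 = mf.breslow_baseline(view, ["x"], beta=[0.0])
        np.testing.assert_allclose(
            H0.cumulative, np.cumsum([1 / 4, 1 / 3, 1 / 2, 1.0]), atol=1e-12
        )

    def test_single_event_jump(self):
        view = pd.DataFrame({
            "duration": [1.0, 2.0, 3.0, 4.0],
            "status": [1, 0, 0, 0],
            "x": [0.0] * 4,
        })
        H0 = mf.breslow_baseline(view, ["x"], beta=[0.0])
        assert H0.jumps[0] == pytest.approx(0.25)

    def test_matches_brute_force_risk_sums(self, single_transition_view):
        view = single_transition_view
        res = mf.cox_partial_fit(view, COVS2)
        z = np.linspace(0.5, 1.5, len(view))
        H0 = mf.breslow_baseline(view, COVS2, res.beta, frailties=z)
        w = z * np.exp(view[list(COVS2)].to_numpy() @ res.beta)
        dur = view["duration"].to_numpy()
        status = view["status"].to_numpy()
        for t, jump in zip(H0.times, H0.jumps):
            d = np.sum((dur == t) & (status == 1))
            denom = w[dur >= t].sum()
            assert jump == pytest.approx(d / denom, abs=1e-12)
        assert np.all(np.diff(H0.cumulative) >= 0)


class TestEstimateFrailties:
    def test_posterior_mean_formula(self):
        # one cluster, two events, total cumulative hazard 3 => (1+2)/(1+3)
        view = pd.DataFrame({
            "duration": [1.0, 2.0],
            "status": [1, 1],
            "cluster": [0, 0],
            "x": [0.0, 0.0],
        })
        H0 = BreslowBaseline(times=np.array([1.0, 2.0]), jumps=np.array([1.0, 1.0]))
        # H0(1)=1, H0(2)=2 -> sum 3
        z = mf.estimate_frailties(view, ["x"], np.array([0.0]), H0, sigma2=1.0)
        assert z.loc[0] == pytest.approx((1 + 2) / (1 + 3))

    def test_degenerate_prior_forces_unit_frailty(self, single_transition_view):
        view = single_transition_view
        res = mf.cox_partial_fit(view, COVS2)
        H0 = mf.breslow_baseline(view, COVS2, res.beta)
        z = mf.estimate_frailties(view, COVS2, res.beta, H0, sigma2=1e-8)
        assert np.all(np.abs(z.to_numpy() - 1.0) < 1e-6)

    def test_matches_quadrature_posterior_mean(self, single_transition_view):
        """The closed-form posterior-mean ratio equals the posterior mean of
        the cluster integrand computed by adaptive quadrature."""
        from scipy import stats

        view = single_transition_view
        sigma2 = 0.8
        res = mf.cox_partial_fit(view, COVS2)
        H0 = mf.breslow_baseline(view, COVS2, res.beta)
        z = mf.estimate_frailties(view, COVS2, res.beta, H0, sigma2)
        for cluster in z.index:
            sub = view[view["cluster"] == cluster]
            X = sub[list(COVS2)].to_numpy(float)
            risk = (H0.cumulative_at(sub["duration"].to_numpy())
                    * np.exp(X @ res.beta)).sum()
            d = int(sub["status"].sum())

            def f(zz, power):
                return (zz ** (d + power) * np.exp(-zz * risk)
                        * stats.gamma.pdf(zz, a=1 / sigma2, scale=sigma2))

            num, _ = integrate.quad(lambda zz: f(zz, 1), 0, np.inf)
            den, _ = integrate.quad(lambda zz: f(zz, 0), 0, np.inf)
            assert z.loc[cluster] == pytest.approx(num / den, abs=1e-8)


class TestMarginalLoglik:
    def test_matches_log_quadrature_integral(self, single_transition_view):
        view = single_transition_view
        sigma2 = 0.6
        res = mf.cox_partial_fit(view, COVS2)
        H0 = mf.breslow_baseline(view, COVS2, res.beta)
        ll = mf.gamma_marginal_loglik(view, COVS2, res.beta, sigma2, H0)
        oracle = sum(
            np.log(cluster_integral(view, COVS2, res.beta, H0, sigma2, c))
            for c in view["cluster"].unique()
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_cluster_relabeling(self, single_transition_view):
        view = single_transition_view
        res = mf.cox_partial_fit(view, COVS2)
        H0 = mf.breslow_baseline(view, COVS2, res.beta)
        ll = mf.gamma_marginal_loglik(view, COVS2, res.beta, 0.5, H0)
        relabeled = view.assign(cluster=view["cluster"].map({0: 9, 1: 8, 2: 7,
                                                             3: 6, 4: 5, 5: 4}))
        ll2 = mf.gamma_marginal_loglik(relabeled, COVS2, res.beta, 0.5, H0)
        assert ll == pytest.approx(ll2, abs=1e-12)

    def test_finite_difference_in_sigma2(self, single_transition_view):
        view = single_transition_view
        res = mf.cox_partial_fit(view, COVS2)
        H0 = mf.breslow_baseline(view, COVS2, res.beta)
        s2 = 0.7
        h = 1e-5
        f = lambda s: mf.gamma_marginal_loglik(view, COVS2, res.beta, s, H0)
        central = (f(s2 + h) - f(s2 - h)) / (2 * h)
        wide = (f(s2 + 10 * h) - f(s2 - 10 * h)) / (20 * h)
        assert central == pytest.approx(wide, abs=1e-4)


class TestFitTransitionFrailty:
    def test_reduces_to_plain_cox_without_frailty(self):
        view = simulate_single_transition(
            600, 600, 1e-6, [-0.05, 0.01, 0.02, 0.01],
            BaselineSpec("weibull", 0.1, 1.5), seed=44)
        fit = mf.fit_transition_frailty(view, COVS4)
        ref = lifelines_cox(view, COVS4)
        # sigma2 driven to (near) the search floor, beta matching plain Cox
        assert fit.sigma2 < 0.05
        np.testing.assert_allclose(fit.beta.to_numpy(), ref, atol=2e-3)

    def test_profile_maximum_property(self):
        view = simulate_single_transition(
            400, 40, 1.0, [-0.05, 0.01, 0.02, 0.01],
            BaselineSpec("weibull", 0.1, 1.5), seed=45)
        fit = mf.fit_transition_frailty(view, COVS4)
        best_ll = max(ll for _, ll in fit.profile)
        assert fit.loglik == pytest.approx(best_ll)
        assert all(fit.loglik >= ll - 1e-9 for _, ll in fit.profile)

    def test_posterior_fixed_point_at_convergence(self):
        view = simulate_single_transition(
            300, 30, 0.8, [-0.05, 0.01, 0.02, 0.01],
            BaselineSpec("weibull", 0.1, 1.5), seed=46)
        fit = mf.fit_transition_frailty(view, COVS4)
        z = mf.estimate_frailties(view, COVS4, fit.beta.to_numpy(),
                                  fit.baseline, fit.sigma2)
        np.testing.assert_allclose(fit.frailty.to_numpy(), z.to_numpy(), atol=1e-6)
        assert abs(fit.frailty.mean() - 1.0) < 0.05

    def test_row_permutation_invariance(self):
        view = simulate_single_transition(
            200, 20, 0.5, [-0.05, 0.01, 0.02, 0.01],
            BaselineSpec("weibull", 0.1, 1.5), seed=47)
        fit1 = mf.fit_transition_frailty(view, COVS4)
        perm = view.sample(frac=1.0, random_state=3).reset_index(drop=True)
        fit2 = mf.fit_transition_frailty(perm, COVS4)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)
        assert fit1.sigma2 == pytest.approx(fit2.sigma2, abs=1e-10)

    def test_single_cluster_pins_sigma2_at_floor(self):
        view = simulate_single_transition(
            100, 1, 0.5, [-0.05, 0.01, 0.02, 0.01],
            BaselineSpec("weibull", 0.1, 1.5), seed=48)
        with pytest.warns(UserWarning, match="clusters"):
            fit = mf.fit_transition_frailty(view, COVS4)
        assert fit.sigma2 == pytest.approx(FitControl().sigma2_floor)

    def test_bias_shrinks_with_sample_size(self):
        """Mean absolute estimation error decreases from n=250 to n=4000."""
        beta = np.array([-0.05, 0.01, 0.02, 0.01])
        errs = {}
        for n in (250, 1000, 4000):
            devs = []
            for r in range(6):
                view = simulate_single_transition(
                    n, n // 20, 0.5, beta,
                    BaselineSpec("weibull", 0.1, 1.5), seed=900 + r)
                fit = mf.fit_transition_frailty(view, COVS4)
                devs.append(np.abs(fit.beta.to_numpy() - beta).mean())
            errs[n] = np.mean(devs)
        assert errs[250] > errs[1000] > errs[4000]


class TestFitMsm:
    def test_three_transition_shapes(self, small_dataset):
        ds, _ = small_dataset
        fits = mf.fit_msm(ds)
        assert set(fits) == {(1, 2), (1, 3), (2, 3)}
        for tr, fit in fits.items():
            assert fit is not None
            assert list(fit.beta.index) == list(ds.covariates)
            assert fit.sigma2 >= 0
            assert np.all(np.diff(fit.baseline.cumulative) >= -1e-15)

    def test_missing_transition_reported_skipped(self, small_dataset):
        ds, _ = small_dataset
        df = ds.data[~((ds.data["from_state"] == 2) & (ds.data["to_state"] == 3))]
        # dropping 2->3 rows keeps path consistency trivially
        ds2 = ds.with_data(df)
        with pytest.warns(UserWarning, match="no events"):
            fits = mf.fit_msm(ds2)
        assert fits[(2, 3)] is None
        full = mf.fit_msm(ds)
        for tr in [(1, 2), (1, 3)]:
            np.testing.assert_allclose(fits[tr].beta, full[tr].beta, atol=1e-10)

    def test_fits_independent_across_transitions(self, small_dataset):
        ds, _ = small_dataset
        joint = mf.fit_msm(ds)
        for tr in ds.structure.transitions:
            view = ds.to_transition_view(tr)
            solo = mf.fit_transition_frailty(view, ds.covariates, transition=tr)
            np.testing.assert_allclose(joint[tr].beta, solo.beta, atol=1e-12)
            assert joint[tr].sigma2 == pytest.approx(solo.sigma2, abs=1e-12)

    def test_summary_table_layout(self, small_dataset):
        ds, _ = small_dataset
        fit = mf.fit_msm(ds)[(1, 3)]
        tab = fit.summary()
        assert list(tab.columns) == ["coef", "se", "HR", "HR_lower95", "HR_upper95"]
        assert (tab["HR_lower95"] <= tab["HR"]).all()
        assert (tab["HR"] <= tab["HR_upper95"]).all()
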