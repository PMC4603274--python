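import math

import numpy as np
import pytest

import sasmodelfit as sm
from sasmodelfit.distributions import SizeDistribution
from sasmodelfit.fitting import (FitInterrupted, FitProblem, UnderdeterminedError,
                                 chi2_reduced, covariance_report, default_bounds,
                                 fit, q_factor, r_values, run_workflow,
                                 three_step_workflow)
from sasmodelfit.formfactors import FormFactorModel, Parameter
from sasmodelfit.model import Contribution, ModelConfig


def linear_model(intensity):
    """Custom registered-style model I(q) = f(q; a, b); x is the dummy
    distributed parameter (monodisperse, weight N = 1)."""
    return FormFactorModel(
        "linear-test", parameters=(
            Parameter("a", "slope-like", 1.0),
            Parameter("b", "second coefficient", 1.0),
            Parameter("x", "dummy distributed size", 1.0, lo=0.0),
        ), evaluate_intensity=intensity)


def linear_problem(intensity, data_fn, active, sigma=0.1, n=40, seed=0):
    rng = np.random.default_rng(seed)
    q = np.linspace(0.1, 4.0, n)
    I = data_fn(q) + rng.normal(0, sigma, n)
    curve = sm.SASCurve(q, I, np.full(n, sigma))
    cfg = ModelConfig([Contribution(
        form_factor=linear_model(intensity), dist_param="x",
        distribution=SizeDistribution("monodisperse", N=1.0, X0=1.0))])
    return curve, cfg, FitProblem(curve, cfg, active)


class TestStatistics:
    def test_chi2_trivial_cases(self):
        assert chi2_reduced([1, 2, 3], [1, 2, 3], [1, 1, 1], M=1) == 0.0
        # unit residual at every point
        n = 10
        I = np.zeros(n)
        assert chi2_reduced(I, I + 1.0, np.ones(n), M=2) == pytest.approx(
            n / (n - 2))
        with pytest.raises(UnderdeterminedError):
            chi2_reduced([1.0], [1.0], [1.0], M=1)

    def test_q_factor_closed_form(self):
        assert q_factor(0.0, N=10, M=3) == 1.0
        # N - M = 2: Q(1, 1) = exp(-1)
        assert q_factor(2.0, N=5, M=3) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_q_factor_monotone_decreasing(self):
        qs = [q_factor(c, N=100, M=3) for c in (50.0, 97.0, 150.0, 300.0)]
        assert all(a > b for a, b in zip(qs, qs[1:]))
        assert all(0 < v < 1 for v in qs)

    def test_r_values(self):
        I = np.array([1.0, 2.0, 4.0])
        s = np.array([0.1, 0.1, 0.2])
        perfect = r_values(I, I, s)
        assert perfect["R"] == 0.0 and perfect["wR"] == 0.0
        # model identically zero -> R = 1 under the sum-|I| normalization
        miss = r_values(I, np.zeros(3), s)
        assert miss["R"] == 1.0 and miss["wR"] == 1.0
        with pytest.raises(ValueError, match="all-zero"):
            r_values(np.zeros(3), I, s)


class TestCovariance:
    def test_single_parameter_matches_weighted_ls_closed_form(self):
        # I = a*q: stderr(a) = (sum q^2/sigma^2)^(-1/2)
        sigma = 0.25
        curve, cfg, pr = linear_problem(
            lambda q, a, b, x: a * q, lambda q: 2.0 * q, ["c0.a"], sigma=sigma)
        res = fit(pr)
        w = 1.0 / curve.sigma**2
        a_hat = np.sum(w * curve.I * curve.q) / np.sum(w * curve.q**2)
        se = 1.0 / math.sqrt(np.sum(w * curve.q**2))
        assert res.params["c0.a"] == pytest.approx(a_hat, rel=1e-8)
        assert res.stderr["c0.a"] == pytest.approx(se, rel=1e-6)

    def test_duplicated_parameter_flagged_degenerate(self):
        _, _, pr = linear_problem(
            lambda q, a, b, x: (a + b) * q, lambda q: 2.0 * q, ["c0.a", "c0.b"])
        res = fit(pr)
        assert set(res.degenerate) == {"c0.a", "c0.b"}
        assert abs(res.correlation[0, 1]) > 0.999
        assert math.isnan(res.stderr["c0.a"]) and math.isnan(res.stderr["c0.b"])
        assert res.flagged_pairs

    def test_orthogonal_design_uncorrelated(self):
        # disjoint supports -> off-diagonal correlation ~ 0
        _, _, pr = linear_problem(
            lambda q, a, b, x: np.where(q < 2.0, a, b),
            lambda q: np.where(q < 2.0, 1.0, 3.0), ["c0.a", "c0.b"])
        res = fit(pr)
        assert abs(res.correlation[0, 1]) < 0.05
        assert not res.flagged_pairs

    def test_report_mentions_caveat(self):
        _, _, pr = linear_problem(
            lambda q, a, b, x: a * q, lambda q: 2.0 * q, ["c0.a"])
        assert "normally distributed" in fit(pr).report()


class TestFit:
    def test_noiseless_start_at_truth_is_fixed_point(self):
        spec = sm.gold_like_spec(seed=0, noise_floor=0.0)
        curve, _ = sm.generate(spec)
        curve = sm.SASCurve(curve.q, curve.I, 0.02 * np.abs(curve.I))
        cfg = sm.gold_like_config()
        res = fit(FitProblem(curve, cfg, ["c0.N", "c0.X0", "c0.s"]))
        assert res.chi2red < 1e-12
        assert res.n_eval <= 40  # converges essentially immediately

    def test_interrupt_mode_names_parameter(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=3, n_points=60))
        cfg = sm.gold_like_config(X0=6.0)
        pr = FitProblem(curve, cfg, ["c0.X0"], bounds={"c0.X0": (5.5, 7.0)})
        with pytest.raises(FitInterrupted, match="c0.X0"):
            fit(pr, mode="interrupt")  # optimum (4.48) is outside the range

    def test_start_outside_bounds_interrupts_immediately(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=3, n_points=60))
        cfg = sm.gold_like_config(X0=9.0)
        pr = FitProblem(curve, cfg, ["c0.X0"], bounds={"c0.X0": (1.0, 8.0)})
        with pytest.raises(FitInterrupted, match="c0.X0"):
            fit(pr, mode="interrupt")

    def test_bounded_mode_honors_bounds(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=3, n_points=120))
        cfg = sm.gold_like_config(X0=6.0)
        pr = FitProblem(curve, cfg, ["c0.X0"], bounds={"c0.X0": (5.5, 7.0)})
        res = fit(pr, mode="bounded")
        assert 5.5 <= res.params["c0.X0"] <= 7.0

    def test_underdetermined(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=1, n_points=10))
        curve = curve.with_window(curve.q[0], curve.q[1])
        cfg = sm.gold_like_config()
        with pytest.raises(UnderdeterminedError):
            fit(FitProblem(curve, cfg, ["c0.N", "c0.X0", "c0.s"]))

    def test_sigma_rescale_invariance(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=5, n_points=150))
        lam = 3.0
        scaled = sm.SASCurve(curve.q, curve.I, lam * curve.sigma)
        res1 = fit(FitProblem(curve, sm.gold_like_config(N=8e-30, X0=4.3, s=0.5),
                              ["c0.N", "c0.X0", "c0.s"]))
        res2 = fit(FitProblem(scaled, sm.gold_like_config(N=8e-30, X0=4.3, s=0.5),
                              ["c0.N", "c0.X0", "c0.s"]))
        for k in res1.params:
            assert res2.params[k] == pytest.approx(res1.params[k], rel=1e-6)
            assert res2.stderr[k] == pytest.approx(lam * res1.stderr[k], rel=1e-4)
        assert res2.chi2red == pytest.approx(res1.chi2red / lam**2, rel=1e-6)

    def test_point_order_invariance(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=6, n_points=150))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(curve))
        shuffled = sm.SASCurve(curve.q[perm], curve.I[perm], curve.sigma[perm])
        r1 = fit(FitProblem(curve, sm.gold_like_config(N=8e-30, X0=4.3, s=0.5),
                            ["c0.N", "c0.X0", "c0.s"]))
        r2 = fit(FitProblem(shuffled, sm.gold_like_config(N=8e-30, X0=4.3, s=0.5),
                            ["c0.N", "c0.X0", "c0.s"]))
        for k in r1.params:
            assert r2.params[k] == pytest.approx(r1.params[k], rel=1e-8)

    def test_cross_check_against_lmfit(self):
        """Independent optimizer + error estimate: lmfit on the same chi^2."""
        lmfit = pytest.importorskip("lmfit")
        curve, _ = sm.generate(sm.gold_like_spec(seed=11, n_points=200))
        cfg = sm.gold_like_config(N=8.5e-30, X0=4.2, s=0.5)
        mine = fit(FitProblem(curve, cfg, ["c0.N", "c0.X0", "c0.s"]))

        def resid(p):
            c = sm.gold_like_config(N=p["N"].value * 1e-30, X0=p["X0"].value,
                                    s=p["s"].value)
            return (curve.I - sm.model_intensity(curve.q, c)) / curve.sigma

        params = lmfit.Parameters()
        params.add("N", value=8.5)  # in 1e-30 units to keep lmfit well scaled
        params.add("X0", value=4.2)
        params.add("s", value=0.5)
        out = lmfit.minimize(resid, params, method="leastsq")
        assert mine.params["c0.N"] == pytest.approx(out.params["N"].value * 1e-30,
                                                    rel=1e-5)
        assert mine.params["c0.X0"] == pytest.approx(out.params["X0"].value, rel=1e-6)
        assert mine.params["c0.s"] == pytest.approx(out.params["s"].value, rel=1e-5)
        # lmfit scales errors by sqrt(chi2red); undo for the raw-Hessian stderr
        scale = math.sqrt(out.redchi)
        assert mine.stderr["c0.X0"] == pytest.approx(
            out.params["X0"].stderr / scale, rel=2e-2)
        assert mine.stderr["c0.s"] == pytest.approx(
            out.params["s"].stderr / scale, rel=2e-2)

    def test_fixed_contribution_parameters_rejected(self):
        cfg = sm.gold_like_config()
        cfg.contributions[0].fixed = True
        curve, _ = sm.generate(sm.gold_like_spec(seed=0, n_points=60))
        with pytest.raises(ValueError, match="fixed contribution"):
            fit(FitProblem(curve, cfg, ["c0.X0"]))


class TestWorkflow:
    def test_three_step_structure(self):
        curve, _ = sm.generate(sm.gold_like_spec(seed=0, n_points=100))
        steps = three_step_workflow(curve, "c0.N", "c0.X0", "c0.s")
        assert [s.active for s in steps[:3]] == [["c0.N"], ["c0.X0"],
                                                 ["c0.N", "c0.X0"]]
        assert steps[3].active == ["c0.X0", "c0.s"]
        assert steps[0].q_window[1] < curve.q[-1]  # low-q window only

    def test_workflow_recovers_truth_single_replicate(self):
        curve, truth = sm.generate(sm.gold_like_spec(seed=0))
        cfg = sm.gold_like_config(N=7.68e-30 * 1.2, X0=4.48 * 0.85, s=0.44 * 1.2)
        results = run_workflow(curve, cfg,
                               three_step_workflow(curve, "c0.N", "c0.X0", "c0.s"))
        final = results[-1]
        tr = {"c0.N": 7.68e-30, "c0.X0": 4.48, "c0.s": 0.44}
        for k, v in tr.items():
            assert abs(final.params[k] - v) <= 3 * final.stderr[k]
        assert 0.8 < final.chi2red < 1.2
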