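"""Closed-form PK engine, model registry, and MAP estimation."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import vancomst as v
from vancomst.cohort import ConcentrationObservation, DoseEvent
from vancomst.pk import Expression, ModelSpecError, PredictionError


def ode_oracle(cl, v_, doses, times):
    """Independent numerical oracle: integrate dA/dt = in(t) − k·A piecewise.

    The infusion input is constant on segments bounded by dose starts and
    ends, so a stiff-safe high-order integration per segment recovers the
    amount without hitting discontinuities mid-step.
    """
    k = cl / v_
    edges = sorted({0.0, *[d.time for d in doses], *[d.time + d.infusion_duration for d in doses],
                    *[float(t) for t in times]})
    amount = {0.0: 0.0}
    a = 0.0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        rate = sum(
            d.amount / d.infusion_duration
            for d in doses
            if d.time <= t0 and t0 < d.time + d.infusion_duration
        )
        if t1 > t0:
            sol = solve_ivp(
                lambda t, y: [rate - k * y[0]],
                (t0, t1),
                [a],
                method="DOP853",
                rtol=1e-12,
                atol=1e-14,
            )
            a = float(sol.y[0, -1])
        amount[t1] = a
    return np.array([amount[float(t)] / v_ for t in times])


class TestClosedForm:
    def test_before_first_dose_zero(self):
        m = v.make_model("M", "5", "50")
        r = v.population_predict(m, {}, [DoseEvent(2.0, 1000, 1)], [0.0, 1.0, 2.0])
        assert np.all(r.predicted == 0.0)

    def test_hand_evaluated_example(self):
        # CL = 5 L/h, V = 50 L, 1,000 mg over 1 h
        m = v.make_model("M", "5", "50")
        r = v.population_predict(m, {}, [DoseEvent(0, 1000, 1)], [1.0, 12.0])
        assert r.predicted[0] == pytest.approx(19.03, abs=0.01)
        assert r.predicted[1] == pytest.approx(6.34, abs=0.01)

    def test_linearity_in_dose(self):
        m = v.make_model("M", "4", "40")
        doses = [DoseEvent(0, 500, 1), DoseEvent(12, 750, 2)]
        doubled = [DoseEvent(d.time, 2 * d.amount, d.infusion_duration) for d in doses]
        t = np.linspace(0.5, 48, 30)
        one = v.population_predict(m, {}, doses, t).predicted
        two = v.population_predict(m, {}, doubled, t).predicted
        assert np.allclose(two, 2 * one, rtol=1e-12)

    def test_matches_ode_oracle_on_random_regimens(self):
        """Acceptance-grade check: < 1e-6 relative error on 20 regimens."""
        rng = np.random.default_rng(1234)
        worst = 0.0
        for _ in range(20):
            cl = rng.uniform(0.5, 10.0)
            v_ = rng.uniform(20.0, 90.0)
            n_doses = rng.integers(1, 11)
            doses = [
                DoseEvent(12.0 * i + rng.uniform(0, 2), rng.uniform(250, 2000), rng.uniform(0.5, 3))
                for i in range(n_doses)
            ]
            t_max = doses[-1].time + 24
            times = np.sort(rng.uniform(0.5, t_max, size=8))
            m = v.make_model("M", str(cl), str(v_))
            closed = v.population_predict(m, {}, doses, times).predicted
            oracle = ode_oracle(cl, v_, doses, times)
            scale = np.maximum(oracle, 1e-9)
            worst = max(worst, float(np.max(np.abs(closed - oracle) / scale)))
        assert worst < 1e-6

    def test_continuous_across_infusion_end(self):
        m = v.make_model("M", "3", "45")
        doses = [DoseEvent(0, 1000, 1.5)]
        eps = 1e-9
        lo, hi = v.population_predict(m, {}, doses, [1.5 - eps, 1.5 + eps]).predicted
        assert hi == pytest.approx(lo, rel=1e-6)

    def test_strictly_decreasing_after_last_infusion(self):
        m = v.make_model("M", "3", "45")
        doses = [DoseEvent(0, 1000, 1), DoseEvent(12, 1000, 1)]
        t = np.linspace(13.01, 40, 50)
        c = v.population_predict(m, {}, doses, t).predicted
        assert np.all(np.diff(c) < 0)

    def test_steady_state_trough_accumulation(self):
        cl, vol, amount, tinf, tau = 3.0, 50.0, 1000.0, 1.0, 12.0
        m = v.make_model("M", str(cl), str(vol))
        half_life = math.log(2) / (cl / vol)
        n = int(12 * half_life / tau) + 2  # beyond ten half-lives
        doses = [DoseEvent(tau * i, amount, tinf) for i in range(n)]
        trough = v.population_predict(m, {}, doses, [tau * n]).predicted[0]
        assert trough == pytest.approx(
            v.steady_state_trough(cl, vol, amount, tinf, tau), rel=1e-4
        )

    def test_population_ignores_omega(self):
        m1 = v.make_model("M", "5", "50", omega_cl=0.2, omega_v=0.1)
        m2 = v.make_model("M", "5", "50")
        doses = [DoseEvent(0, 1000, 1)]
        assert np.array_equal(
            v.population_predict(m1, {}, doses, [3.0]).predicted,
            v.population_predict(m2, {}, doses, [3.0]).predicted,
        )


class TestRegistry:
    def test_constant_model_no_covariates(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text("name: Const\nCL: '3.5'\nV: '50'\n")
        spec = v.load_model_registry([p])[0]
        assert spec.required_covariates == frozenset()

    def test_covariate_token_scan(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text("name: Renal\nCL: '0.05*crcl_cg + 0.4'\nV: '0.7*weight'\n")
        spec = v.load_model_registry([p])[0]
        assert spec.required_covariates == {"crcl_cg", "weight"}

    def test_malformed_expression_rejected(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text("name: Bad\nCL: '3.5 *'\nV: '50'\n")
        with pytest.raises(ModelSpecError):
            v.load_model_registry([p])

    def test_unknown_token_named(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text("name: Bad\nCL: '3.5*unobtainium'\nV: '50'\n")
        with pytest.raises(ModelSpecError, match="unobtainium"):
            v.load_model_registry([p])

    def test_duplicate_names_rejected(self, tmp_path):
        for i in range(2):
            (tmp_path / f"m{i}.yaml").write_text("name: Twin\nCL: '3'\nV: '50'\n")
        with pytest.raises(ModelSpecError, match="Twin"):
            v.load_model_registry(tmp_path)

    def test_expression_rejects_arbitrary_code(self):
        with pytest.raises(ModelSpecError):
            Expression("__import__('os').system('true')")

    def test_missing_covariate_names_model(self):
        m = v.make_model("Renal", "0.05*crcl_cg", "50")
        with pytest.raises(PredictionError, match="crcl_cg"):
            v.population_predict(m, {}, [DoseEvent(0, 1000, 1)], [2.0])

    def test_shipped_reference_registry_loads(self):
        import pathlib

        models_dir = pathlib.Path(__file__).resolve().parents[1] / "models"
        registry = v.load_model_registry(models_dir)
        names = {m.name for m in registry}
        assert {"Zhou", "Kim", "Staatz"} <= names
        cov = {
            "age": 60.0, "sex": 1.0, "weight": 80.0, "height": 175.0, "bmi": 26.1,
            "creatinine": 90.0, "crcl_cg": 70.0, "egfr_ckd_epi": 85.0,
            "treatment_day": 2.0, "rrt_active": 0.0,
        }
        for spec in registry:
            cl, vol = spec.typical_values(cov)
            assert 0 < cl < 20 and 10 < vol < 300


class TestMAP:
    def _model(self):
        return v.make_model(
            "M", "0.04*crcl_cg + 0.5", "0.7*weight", omega_cl=0.09, omega_v=0.04,
            error=v.ErrorModel("proportional", sigma_prop=0.15),
        )

    def _setting(self):
        doses = [DoseEvent(12.0 * i, 1000, 1, 12.0 * i) for i in range(8)]
        cov = {"crcl_cg": 70.0, "weight": 80.0}
        return doses, cov

    def test_no_observations_prior_mode(self):
        doses, cov = self._setting()
        est = v.map_estimate(self._model(), cov, doses, [])
        assert est == v.IndividualParameters(0.0, 0.0)

    def test_exact_population_observation_keeps_etas_near_zero(self):
        # the ln sigma^2(f) term of the objective pulls the prediction very
        # slightly downward, so the mode is near — not exactly at — zero
        m = self._model()
        doses, cov = self._setting()
        f = v.population_predict(m, cov, doses, [22.0]).predicted[0]
        est = v.map_estimate(m, cov, doses, [ConcentrationObservation(22.0, f)])
        assert abs(est.eta_cl) < 0.05 and abs(est.eta_v) < 0.05

    def test_objective_never_worse_than_prior_mode(self):
        from vancomst.pk import map_objective

        m = self._model()
        doses, cov = self._setting()
        rng = np.random.default_rng(5)
        for i in range(10):
            obs = [
                ConcentrationObservation(t, float(rng.uniform(3, 40)))
                for t in (22.0, 46.0, 70.0)
            ]
            est = v.map_estimate(m, cov, doses, obs, seed=i)
            at_est = map_objective(m, cov, doses, obs, est.as_array())
            at_zero = map_objective(m, cov, doses, obs, np.zeros(2))
            assert at_est <= at_zero + 1e-9

    def test_zero_omega_fixes_eta(self):
        m = v.make_model(
            "M", "3", "50", omega_cl=0.09, omega_v=0.0,
            error=v.ErrorModel("proportional", sigma_prop=0.15),
        )
        doses, cov = self._setting()
        est = v.map_estimate(m, cov, doses, [ConcentrationObservation(22.0, 30.0)])
        assert est.eta_v == 0.0
        assert est.eta_cl != 0.0
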