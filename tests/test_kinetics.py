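"""MA1 / Logan V_T estimation and the whole-brain composite."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cb1pet.exceptions import (
    ConfigurationError,
    DegenerateFitError,
    EmptyCompositeError,
    InsufficientDataError,
)
from cb1pet.input_function import InputFunction
from cb1pet.kinetics import VTEstimate, composite_whole_brain, logan_vt, ma1_vt
from cb1pet.synthetic import KineticParams, analytic_vt, simulate_tac


class TestAnalyticVT:
    def test_one_tissue_identity(self):
        assert analytic_vt(KineticParams(0.1, 0.1)) == pytest.approx(1.0)

    def test_two_tissue_closed_form(self):
        assert analytic_vt(KineticParams(0.3, 0.15, 0.05, 0.05)) == pytest.approx(4.0)
        assert analytic_vt(KineticParams(0.25, 0.2, 0.03, 0.06)) == pytest.approx(1.875)

    def test_irreversible_binding_rejected(self):
        with pytest.raises(ConfigurationError):
            analytic_vt(KineticParams(0.1, 0.1, 0.05, 0.0))

    def test_equilibrium_ode_oracle(self):
        """V_T equals the tissue/plasma ratio at equilibrium under constant
        infusion — an independent check via direct ODE integration."""
        p = KineticParams(0.25, 0.2, 0.03, 0.06)

        def rhs(t, y):
            c1, c2 = y
            return [p.K1 * 1.0 - (p.k2 + p.k3) * c1 + p.k4 * c2,
                    p.k3 * c1 - p.k4 * c2]

        sol = solve_ivp(rhs, (0, 600), [0.0, 0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[:, -1].sum() == pytest.approx(analytic_vt(p), rel=1e-2)


class TestSimulateTac:
    def test_no_uptake_gives_zero_tac(self, true_input, schedule):
        tac = simulate_tac(KineticParams(0.0, 0.1), true_input, schedule)
        assert np.allclose(tac.activity, 0.0, atol=1e-10)

    def test_seeded_determinism(self, true_input, schedule):
        p = KineticParams(0.3, 0.15, 0.05, 0.05)
        a = simulate_tac(p, true_input, schedule, noise_scale=0.05, seed=11)
        b = simulate_tac(p, true_input, schedule, noise_scale=0.05, seed=11)
        assert np.array_equal(a.activity, b.activity)
        c = simulate_tac(p, true_input, schedule, noise_scale=0.05, seed=12)
        assert not np.array_equal(a.activity, c.activity)

    def test_default_schedule_has_33_frames(self, schedule):
        assert schedule.n_frames == 33
        assert schedule.frame_end[-1] == pytest.approx(120.0)


class TestMA1:
    def test_one_tissue_limit(self, true_input, schedule):
        tac = simulate_tac(KineticParams(0.1, 0.1), true_input, schedule)
        assert ma1_vt(tac, true_input).vt == pytest.approx(1.0, rel=0.01)

    def test_two_tissue_recovery(self, true_input, schedule):
        tac = simulate_tac(KineticParams(0.3, 0.15, 0.05, 0.05), true_input, schedule)
        est = ma1_vt(tac, true_input)
        assert est.vt == pytest.approx(4.0, rel=0.01)
        assert est.n_frames_used == 18
        assert est.valid

    def test_noisy_mean_bias_small(self, true_input, schedule):
        """Monte-Carlo: mean |bias| of MA1 under 5% count noise stays <= 5%."""
        p = KineticParams(0.3, 0.15, 0.05, 0.05)
        vts = [
            ma1_vt(
                simulate_tac(p, true_input, schedule, noise_scale=0.05, seed=s),
                true_input,
            ).vt
            for s in range(100)
        ]
        assert abs(np.mean(vts) - 4.0) / 4.0 <= 0.05

    def test_t_star_insensitivity_noiseless(self, true_input, schedule):
        tac = simulate_tac(KineticParams(0.25, 0.2, 0.03, 0.06), true_input, schedule)
        v30 = ma1_vt(tac, true_input, t_star=30.0).vt
        v40 = ma1_vt(tac, true_input, t_star=40.0).vt
        assert abs(v40 - v30) / v30 < 0.02

    def test_insufficient_frames(self, true_input, schedule):
        tac = simulate_tac(KineticParams(0.1, 0.1), true_input, schedule)
        with pytest.raises(InsufficientDataError):
            ma1_vt(tac, true_input, t_star=115.0)

    def test_zero_tac_degenerate(self, true_input, schedule):
        tac = simulate_tac(KineticParams(0.0, 0.1), true_input, schedule)
        with pytest.raises(DegenerateFitError):
            ma1_vt(tac, true_input)
        with pytest.raises(DegenerateFitError):
            logan_vt(tac, true_input)

    def test_scale_equivariance(self, true_input, schedule):
        import dataclasses

        p = KineticParams(0.3, 0.15, 0.05, 0.05)
        tac = simulate_tac(p, true_input, schedule)
        base = ma1_vt(tac, true_input).vt
        c = 3.7
        tac_c = dataclasses.replace(tac, activity=tac.activity * c, frame_weight=None)
        input_c = InputFunction(true_input.time, true_input.values * c)
        both = ma1_vt(tac_c, input_c).vt
        only_input = ma1_vt(tac, input_c).vt
        assert both == pytest.approx(base, rel=1e-6)
        assert only_input == pytest.approx(base / c, rel=1e-6)


class TestLogan:
    def test_concordance_with_ma1(self, true_input, schedule):
        for p in (KineticParams(0.3, 0.15, 0.05, 0.05), KineticParams(0.1, 0.1)):
            tac = simulate_tac(p, true_input, schedule)
            m, l = ma1_vt(tac, true_input), logan_vt(tac, true_input)
            assert l.vt == pytest.approx(m.vt, rel=0.02)
            assert l.vt == pytest.approx(analytic_vt(p), rel=0.02)


class TestComposite:
    def test_constant_invariance(self):
        ests = {
            r: VTEstimate(r, 1.2, 10.0, 5, 1.0, 0.0)
            for r in ("frontal", "temporal", "parietal", "occipital", "cerebellum")
        }
        assert composite_whole_brain(ests) == pytest.approx(1.2)

    def test_weighted_mean(self):
        ests = {"a": VTEstimate("a", 1.0, 1, 5, 1, 0), "b": VTEstimate("b", 2.0, 1, 5, 1, 0)}
        assert composite_whole_brain(ests, {"a": 1.0, "b": 3.0}) == pytest.approx(1.75)

    def test_invalid_estimates_excluded(self):
        ests = {
            "a": VTEstimate("a", 1.0, 1, 5, 1, 0),
            "b": VTEstimate("b", -2.0, 1, 5, 1, 0),   # flagged invalid
        }
        assert not ests["b"].valid
        assert composite_whole_brain(ests, {"a": 1.0}) == pytest.approx(1.0)

    def test_empty_composite_raises(self):
        with pytest.raises(EmptyCompositeError):
            composite_whole_brain({"a": VTEstimate("a", -1.0, 1, 5, 1, 0)}, {"a": 1.0})

    @given(
        vals=st.lists(st.floats(0.2, 8.0), min_size=5, max_size=5),
        weights=st.lists(st.floats(0.05, 5.0), min_size=5, max_size=5),
    )
    def test_matches_brute_force(self, vals, weights):
        regions = [f"r{i}" for i in range(5)]
        ests = {r: VTEstimate(r, v, 1, 5, 1, 0) for r, v in zip(regions, vals)}
        wmap = dict(zip(regions, weights))
        expected = sum(w * v for w, v in zip(weights, vals)) / sum(weights)
        assert composite_whole_brain(ests, wmap) == pytest.approx(expected, rel=1e-12)
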