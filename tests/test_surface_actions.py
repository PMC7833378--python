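import math

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from coulombgas import ValencyPair
from coulombgas.oracles import real_line_action
from coulombgas.surface import (
    PinchError,
    action_hypergeometric,
    dependency_relation,
    ellipse_periods,
    harmonic_slope,
    hypergeometric_coefficients,
    instanton_combination,
    monodromy_decompose,
    picard_fuchs_residual,
    wind_cycle,
)

GENUS1 = [(1, 1), (2, 1)]
ALL_PAIRS = [(1, 1), (2, 1), (3, 1), (4, 1), (3, 2)]

# closed-form reference constants
C00_11 = 8.0 * math.pi**-0.5 * gamma_fn(0.75) ** 2            # 6.77770...
C00_21 = 2.0 ** (11.0 / 6.0) * 3.0 * math.pi**1.5 / (
    gamma_fn(1.0 / 6.0) * gamma_fn(1.0 / 3.0)
)                                                             # 3.9921...


class TestClosedFormCoefficients:
    def test_monovalent_value_at_zero(self):
        assert C00_11 == pytest.approx(6.77770, abs=2e-5)
        assert action_hypergeometric(ValencyPair(1, 1), 0.0, 0) == pytest.approx(C00_11)

    def test_divalent_value_at_zero(self):
        assert C00_21 == pytest.approx(3.993, abs=1e-3)
        assert action_hypergeometric(ValencyPair(2, 1), 0.0, 0) == pytest.approx(C00_21)

    def test_reflection_identity_monovalent(self):
        # S0(u) = e^{-i pi/2} S1(e^{i pi} u)
        v = ValencyPair(1, 1)
        for u in (-0.5, 0.2, 0.9):
            lhs = action_hypergeometric(v, u, 0)
            rhs = np.exp(-0.5j * np.pi) * action_hypergeometric(v, -u, 1)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_instanton_endpoint_sixteen_i(self):
        # S1(-1) = i S0(1) = 16i exactly (Gauss summation of both 2F1)
        v = ValencyPair(1, 1)
        assert action_hypergeometric(v, 1.0 - 1e-12, 0) == pytest.approx(16.0, abs=1e-5)

    def test_unsupported_pair(self):
        with pytest.raises(ValueError):
            hypergeometric_coefficients(ValencyPair(3, 1))


class TestContourEngine:
    def test_classical_action_at_zero_energy(self, engine_for):
        s0 = engine_for((1, 1)).action(0, 0.0)
        assert s0 == pytest.approx(C00_11, rel=1e-9)

    def test_vanishing_at_potential_bottom(self, engine_for):
        s0 = engine_for((1, 1)).action(0, -1.0 + 1e-8)
        assert abs(s0) < 1e-3
        assert abs(s0) == pytest.approx(2.0 * math.pi * 1e-8, rel=1e-4)

    def test_divalent_classical_action_at_zero(self, engine_for):
        assert engine_for((2, 1)).action(0, 0.0) == pytest.approx(C00_21, rel=1e-9)

    @pytest.mark.parametrize("pair", GENUS1)
    def test_matches_hypergeometric_on_real_segment(self, pair, engine_for):
        v = ValencyPair(*pair)
        eng = engine_for(pair)
        for u in np.linspace(-0.95, 0.0, 5):
            for j in range(v.total):
                assert eng.action(j, u) == pytest.approx(
                    action_hypergeometric(v, u, j), rel=1e-8, abs=1e-8
                )

    def test_real_line_oracle(self, engine_for):
        eng = engine_for((1, 1))
        for u in (-0.9, -0.3, 0.4, 0.8):
            assert eng.action(0, u).real == pytest.approx(real_line_action(u), rel=1e-9)
            assert abs(eng.action(0, u).imag) < 1e-9

    def test_slope_at_bottom_is_2pi(self, engine_for):
        assert harmonic_slope(ValencyPair(1, 1)) == pytest.approx(2 * math.pi)
        d = engine_for((1, 1)).derivatives(0, -1.0 + 1e-6, orders=(1,))
        assert d[1].real == pytest.approx(2 * math.pi, rel=1e-5)

    def test_contour_deformation_invariance(self, engine_for):
        # shrinking/growing the confocal contour must not change the period
        eng = engine_for((2, 1))
        cyc = eng.cycle_at(0, -0.35)
        vals = [
            ellipse_periods(cyc, orders=(0,), margin=mgn)[0]
            for mgn in (0.45, 0.65, 0.85)
        ]
        assert abs(vals[0] - vals[1]) < 1e-10
        assert abs(vals[1] - vals[2]) < 1e-10

    def test_path_bump_invariance(self, engine_for):
        # perturbing the cut by an analytic bump leaves the line period alone
        from dataclasses import replace

        from coulombgas.surface.contour import Bump, line_period

        eng = engine_for((1, 1))
        cyc = eng.cycle_at(0, -0.6)
        base = line_period(cyc)
        bumped = replace(cyc, bumps=cyc.bumps + (Bump(0.5, 0.12 + 0.08j, 0.2),))
        moved = line_period(bumped)
        assert min(abs(moved - base), abs(moved + base)) < 1e-9

    def test_own_collapse_is_regular_not_pinched(self, engine_for):
        # approaching a cycle's *own* singular energy is regular: the period
        # vanishes smoothly instead of raising
        eng = engine_for((2, 1))
        u_near = np.exp(1j * np.pi / 3) * (1.0 - 1e-5)
        s = eng.cycle_at(1, u_near, cache=False).S
        assert abs(s) < 1e-3

    def test_obstructed_ellipse_reports_pinch(self, engine_for):
        # at positive real u the (1,1) classical cut is bent around the
        # origin; no confocal ellipse separates cut and obstruction, which
        # must be reported as a diagnostic, while the line route still works
        from coulombgas.surface.contour import ellipse_periods

        eng = engine_for((1, 1))
        cyc = eng.cycle_at(0, 0.3)
        with pytest.raises(PinchError):
            ellipse_periods(cyc)
        assert cyc.S == pytest.approx(action_hypergeometric(ValencyPair(1, 1), 0.3, 0), rel=1e-8)


class TestAlgebraicStructure:
    @pytest.mark.parametrize("pair", [(2, 1), (4, 1), (3, 2)])
    def test_dependency_relation(self, pair, engine_for):
        v = ValencyPair(*pair)
        eng = engine_for(pair)
        for u in (-0.5, -0.2):
            S = [eng.action(j, u) for j in range(v.total)]
            resid = sum(w * s for w, s in zip(dependency_relation(v), S))
            assert abs(resid) < 1e-9

    def test_rotation_symmetry_divalent(self, engine_for):
        # S0(u) = e^{i pi/3} S1(e^{-2 pi i/3} u) = e^{-i pi/3} S2(e^{2 pi i/3} u)
        eng = engine_for((2, 1))
        w = np.exp(2j * np.pi / 3.0)
        for u in (-0.4, -0.25 + 0.1j):
            s0 = eng.action(0, u)
            assert abs(s0 - np.exp(1j * np.pi / 3) * eng.action(1, u / w)) < 1e-9
            assert abs(s0 - np.exp(-1j * np.pi / 3) * eng.action(2, u * w)) < 1e-9

    @pytest.mark.parametrize("pair", ALL_PAIRS)
    def test_instanton_purely_imaginary_and_decaying(self, pair, engine_for):
        v = ValencyPair(*pair)
        eng = engine_for(pair)
        for u in (-0.9, -0.5, -0.1):
            s_inst = sum(
                w * eng.action(j, u)
                for j, w in enumerate(instanton_combination(v))
                if w
            )
            assert abs(s_inst.real) < 1e-9
            assert s_inst.imag > 0  # exp(i sqrt(alpha) S_inst / 2) decays

    @pytest.mark.parametrize(
        "pair,b_expected",
        [((1, 1), 8.00), ((3, 1), 7.06), ((4, 1), 6.90), ((3, 2), 5.65)],
    )
    def test_instanton_magnitude_near_bottom(self, pair, b_expected, engine_for):
        # |S_inst(-1)|/2 is the decay constant b; at u=-1+1e-3 the value is
        # within ~0.01 of the limit
        eng = engine_for(pair)
        s_inst = eng.instanton(-1.0 + 1e-3)
        assert abs(s_inst) / 2.0 == pytest.approx(b_expected, abs=0.02)


class TestPicardFuchs:
    @pytest.mark.parametrize("pair", GENUS1)
    @pytest.mark.parametrize("u", [-0.5, 0.3j, -0.3 + 0.2j])
    def test_residual_small(self, pair, u, engine_for):
        v = ValencyPair(*pair)
        res = picard_fuchs_residual(v, u, 0, engine=engine_for(pair))
        scale = abs(engine_for(pair).action(0, u))
        assert abs(res) < 1e-6 * max(scale, 1.0)

    def test_residual_all_cycles_divalent(self, engine_for):
        v = ValencyPair(2, 1)
        for j in (1, 2):
            res = picard_fuchs_residual(v, -0.5, j, engine=engine_for((2, 1)))
            assert abs(res) < 1e-6 * abs(engine_for((2, 1)).action(j, -0.5))

    def test_residual_closed_form_route(self):
        v = ValencyPair(1, 1)
        res = picard_fuchs_residual(v, 0.3j, 0, use_closed_form=True)
        assert abs(res) < 1e-6

    def test_ode_relates_curvature_to_value_at_zero(self, engine_for):
        # at u=0 the (1,1) equation forces S''(0) = S(0)/4
        d = engine_for((1, 1)).derivatives(0, 0.0, orders=(0, 2))
        assert d[2] == pytest.approx(d[0] / 4.0, rel=1e-7)

    def test_finite_difference_cross_check(self, engine_for):
        # central differences (step 1e-4, Richardson) agree with the
        # differentiated-integrand second derivative
        eng = engine_for((2, 1))
        u = -0.5
        d = eng.derivatives(0, u, orders=(2,))

        def second(h):
            return (eng.action(0, u + h) - 2 * eng.action(0, u) + eng.action(0, u - h)) / h**2

        rich = (4.0 * second(1e-4) - second(2e-4)) / 3.0
        assert rich == pytest.approx(d[2], rel=1e-5)

    def test_rejects_genus_two(self):
        with pytest.raises(ValueError):
            picard_fuchs_residual(ValencyPair(3, 1), -0.5, 0)


class TestMonodromy:
    def test_winding_shifts_instanton_cycle(self):
        # (1+u) -> (1+u) e^{2 pi i} adds -2 S0 to S1 (intersection number 2
        # with the vanishing cycle; required by the bandwidth asymptotics);
        # a private engine keeps the continuation routes canonical
        from coulombgas.surface import ActionEngine

        eng = ActionEngine(ValencyPair(1, 1))
        u = -0.7
        s0, s1 = eng.action(0, u), eng.action(1, u)
        gain = wind_cycle(eng, 1, u) - s1
        assert gain == pytest.approx(-2.0 * s0, rel=1e-6, abs=1e-8)

    def test_winding_leaves_classical_cycle_alone(self):
        from coulombgas.surface import ActionEngine

        eng = ActionEngine(ValencyPair(1, 1))
        u = -0.7
        assert wind_cycle(eng, 0, u) == pytest.approx(eng.action(0, u), abs=1e-9)

    def test_analytic_part_at_bottom(self, engine_for):
        # S0(-1) = 0, so Q1(-1) = S1(-1) = 16i
        q1, _ = monodromy_decompose(ValencyPair(1, 1), -1.0 + 1e-3, engine=engine_for((1, 1)))
        assert q1.real == pytest.approx(0.0, abs=1e-6)
        assert q1.imag == pytest.approx(16.0, abs=0.02)

    def test_decomposition_is_consistent(self, engine_for):
        # Q1 from two nearby radii agrees (analyticity of the non-log part)
        eng = engine_for((1, 1))
        q_a, _ = monodromy_decompose(ValencyPair(1, 1), -1.0 + 4e-3, engine=eng)
        q_b, _ = monodromy_decompose(ValencyPair(1, 1), -1.0 + 2e-3, engine=eng)
        assert abs(q_a - q_b) < 0.03

    def test_domain_check(self):
        with pytest.raises(ValueError):
            monodromy_decompose(ValencyPair(1, 1), 0.5)
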