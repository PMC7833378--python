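import math

import numpy as np
import pytest

from coulombgas import GasModel, ValencyPair, ChannelGeometry
from coulombgas.spectral import bandwidth_numeric, eigensystem
from coulombgas.semiclassics import (
    GAMOW_PREFACTOR,
    asymptotic_coefficients,
    bohr_sommerfeld_solve,
    branch_axis_collision,
    branch_intersection,
    classical_merge_point,
    branch_lines,
    gamow_bandwidth,
    harmonic_frequency,
    quantization_levels,
    transport_barrier,
)

ALL_PAIRS = [(1, 1), (2, 1), (3, 1), (4, 1), (3, 2)]


class TestQuantization:
    def test_linearized_levels_monovalent(self, engine_for):
        # u_m ~ -1 + (m+1/2)/sqrt(alpha), i.e. eps_m ~ -2 alpha + 2 sqrt(alpha)(m+1/2)
        alpha = 10000.0
        eng = engine_for((1, 1))
        for m in (0, 1, 2):
            u_m = bohr_sommerfeld_solve(ValencyPair(1, 1), alpha, m, engine=eng)
            assert u_m.real == pytest.approx(-1 + (m + 0.5) / math.sqrt(alpha), abs=3e-4)

    def test_ground_state_against_diagonalization(self, engine_for):
        # (1,1) at alpha=200: diagonalization gives eps0 = -385.92,
        # u0 = -0.96480; first-order quantization lands within O(1/alpha)
        w, _, _ = eigensystem(GasModel(ValencyPair(1, 1), 200.0), None)
        assert w[0].real == pytest.approx(-385.92, abs=0.01)
        u0 = bohr_sommerfeld_solve(ValencyPair(1, 1), 200.0, 0, engine=engine_for((1, 1)))
        assert u0.real == pytest.approx(-385.92 / 400.0, abs=2e-4)

    @pytest.mark.parametrize("pair", ALL_PAIRS)
    @pytest.mark.parametrize("alpha", [100.0, 400.0])
    def test_levels_match_spectrum_to_first_order(self, pair, alpha, engine_for):
        # first-order WKB error is O(1/alpha); calibrated bound alpha*|err| < 0.5
        v = ValencyPair(*pair)
        w, _, _ = eigensystem(GasModel(v, alpha), None)
        u_exact = w / (alpha * v.energy_ratio)
        m_top = 4 if pair == (3, 2) and alpha == 100.0 else 5
        for m in range(m_top + 1):
            u_m = bohr_sommerfeld_solve(v, alpha, m, engine=engine_for(pair))
            err = np.min(np.abs(u_exact - u_m))
            assert err * alpha < 0.5, (m, err)

    def test_target_beyond_termination_refused(self, engine_for):
        with pytest.raises(ValueError, match="merged|termination|converge"):
            bohr_sommerfeld_solve(ValencyPair(3, 2), 100.0, 30, engine=engine_for((3, 2)))

    def test_quantization_levels_collects_until_break(self, engine_for):
        levels = quantization_levels(ValencyPair(1, 1), 100.0, 3, engine=engine_for((1, 1)))
        assert [m for m, _, _ in levels] == [0, 1, 2, 3]
        for m, u, e in levels:
            assert e == pytest.approx(u * 100.0 * 2.0)

    def test_merged_branch_index_three_two(self, engine_for):
        # the isolated (3,2) real state at u ~ 0.89 at alpha=400 carries
        # quantization index m=17 of the summed action of the collided pair
        v = ValencyPair(3, 2)
        eng = engine_for((3, 2))
        alpha = 400.0
        lo = branch_axis_collision(v, (3,), engine=eng)
        hi = branch_axis_collision(v, (1,), engine=eng)
        w, _, _ = eigensystem(GasModel(v, alpha), 150)
        u = w / (alpha * v.energy_ratio)
        reals = sorted(
            [x.real for x in u if abs(x.imag) < 1e-8 and lo < x.real < hi]
        )
        u_star = reals[0]
        assert u_star == pytest.approx(0.89, abs=0.01)
        s_sum = eng.action(2, u_star) + eng.action(3, u_star)
        m = abs(s_sum) * math.sqrt(alpha) / (2 * math.pi) - 0.5
        assert round(m) == 17


class TestBranchGeometry:
    def test_collision_points(self, engine_for):
        assert branch_axis_collision(ValencyPair(2, 1), (1,), engine=engine_for((2, 1))) == pytest.approx(0.9597, abs=2e-3)
        assert branch_axis_collision(ValencyPair(3, 2), (3,), engine=engine_for((3, 2))) == pytest.approx(0.844, abs=2e-3)
        assert branch_axis_collision(ValencyPair(3, 2), (1,), engine=engine_for((3, 2))) == pytest.approx(0.978, abs=2e-3)

    def test_four_one_intersection(self, engine_for):
        # the two complex lines of (4,1) intersect near 0.90 + 0.32i (the
        # third decimal of the imaginary part is not reliable in the source)
        z = branch_intersection(ValencyPair(4, 1), 1, 2, 0.9 + 0.32j, engine=engine_for((4, 1)))
        assert z.real == pytest.approx(0.90, abs=0.01)
        assert z.imag == pytest.approx(0.32, abs=0.015)

    @pytest.mark.parametrize(
        "pair,expected",
        [((1, 1), 1.00), ((2, 1), 0.96), ((3, 1), 1.09), ((4, 1), 1.20), ((3, 2), 0.84)],
    )
    def test_classical_merge_points(self, pair, expected, engine_for):
        value = classical_merge_point(ValencyPair(*pair), engine=engine_for(pair))
        assert round(value, 2) == expected

    def test_monovalent_line_is_real_segment(self, engine_for):
        # Im S0 vanishes identically on (-1, 1) for the Hermitian case
        eng = engine_for((1, 1))
        for u in (-0.8, -0.2, 0.5, 0.9):
            assert abs(eng.action(0, u).imag) < 1e-9

    def test_branch_lines_trace(self, engine_for):
        lines = branch_lines(ValencyPair(2, 1), 200.0, engine=engine_for((2, 1)))
        assert 1 in lines.loci and 2 in lines.loci
        locus = lines.loci[1]
        assert len(locus) > 4
        # the traced line ends at/near the real axis close to the collision
        assert abs(locus[-1].imag) < 0.06
        assert lines.collisions[(1,)] == pytest.approx(0.9597, abs=2e-3)


class TestGamow:
    def test_harmonic_frequency(self):
        assert harmonic_frequency(ValencyPair(1, 1)) == pytest.approx(2.0)
        assert harmonic_frequency(ValencyPair(3, 2)) == pytest.approx(math.sqrt(10.0))

    def test_monovalent_matches_mathieu_asymptotics(self, engine_for):
        # (Delta eps)_0 = (4/pi)(32e/(1/2))^{1/2} alpha^{3/4} e^{-8 sqrt(alpha)}
        alpha = 100.0
        law = (4.0 / math.pi) * (64.0 * math.e) ** 0.5 * alpha**0.75 * math.exp(-8.0 * math.sqrt(alpha))
        got = gamow_bandwidth(ValencyPair(1, 1), alpha, 0, engine=engine_for((1, 1)))
        assert got == pytest.approx(law, rel=0.05)

    @pytest.mark.parametrize(
        "pair,alpha",
        [((1, 1), 9.0), ((2, 1), 16.0), ((3, 1), 10.0), ((4, 1), 12.0), ((3, 2), 16.0)],
    )
    def test_matches_numeric_bandwidth(self, pair, alpha, engine_for):
        v = ValencyPair(*pair)
        num = bandwidth_numeric(GasModel(v, alpha), m=0)
        gam = gamow_bandwidth(v, alpha, 0, engine=engine_for(pair))
        assert gam == pytest.approx(num, rel=0.25)

    def test_divalent_matches_numeric_high_precision(self, engine_for):
        # the (2,1) width at alpha=36 is ~1e-17: double-precision
        # diagonalization cannot resolve it, so the oracle subtracts band
        # edges in arbitrary precision
        from coulombgas.oracles import high_precision_bandwidth

        v = ValencyPair(2, 1)
        alpha = 36.0
        num = high_precision_bandwidth(GasModel(v, alpha), 38, dps=45)
        gam = gamow_bandwidth(v, alpha, 0, engine=engine_for((2, 1)))
        assert gam == pytest.approx(num, rel=0.1)

    def test_real_positive_despite_complex_periods(self, engine_for):
        width = gamow_bandwidth(ValencyPair(2, 1), 100.0, 0, engine=engine_for((2, 1)))
        assert width > 0


class TestAsymptoticLaw:
    @pytest.mark.parametrize(
        "pair,b",
        [((1, 1), 8.00), ((3, 1), 7.06), ((4, 1), 6.90), ((3, 2), 5.65)],
    )
    def test_decay_constants(self, pair, b, engine_for):
        law = asymptotic_coefficients(ValencyPair(*pair), engine=engine_for(pair))
        assert round(law.b, 2) == b

    def test_divalent_decay_constant_closed_form(self, engine_for):
        # derived, not read from the source (the printed row is ambiguous):
        # b = sqrt(3) (C00 F0(1) + C01 F1(1)) / 2 via Gauss summation
        from scipy.special import gamma as G

        c00 = 2.0 ** (11.0 / 6.0) * 3 * math.pi**1.5 / (G(1 / 6) * G(1 / 3))
        c01 = math.sqrt(3.0) * G(1 / 6) * G(1 / 3) / (2.0 ** (11.0 / 6.0) * math.sqrt(math.pi))
        f0_1 = G(2 / 3) / G(5 / 6) ** 2
        f1_1 = G(4 / 3) / G(7 / 6) ** 2
        b_closed = math.sqrt(3.0) * (c00 * f0_1 + c01 * f1_1) / 2.0
        law = asymptotic_coefficients(ValencyPair(2, 1), engine=engine_for((2, 1)))
        assert law.b == pytest.approx(b_closed, rel=1e-4)
        assert 7.06 < law.b < 8.00  # b shrinks with increasing valency

    def test_monovalent_k_is_32e(self, engine_for):
        law = asymptotic_coefficients(ValencyPair(1, 1), engine=engine_for((1, 1)))
        assert law.k == pytest.approx(32.0 * math.e, rel=1e-3)
        assert law.A == pytest.approx(4.0 / math.pi, rel=1e-12)
        assert law.b == pytest.approx(8.0, rel=1e-4)

    def test_genus_two_bandwidth_coefficients(self, engine_for):
        law41 = asymptotic_coefficients(ValencyPair(4, 1), engine=engine_for((4, 1)))
        assert law41.k == pytest.approx(1303.46, rel=1e-3)
        law32 = asymptotic_coefficients(ValencyPair(3, 2), engine=engine_for((3, 2)))
        assert law32.k == pytest.approx(6740.06, rel=1e-3)

    @pytest.mark.parametrize("pair", ALL_PAIRS)
    def test_log_width_slope_is_minus_b(self, pair, engine_for):
        # ln(width) - (3/4) ln(alpha) is affine in sqrt(alpha) with slope -b
        v = ValencyPair(*pair)
        eng = engine_for(pair)
        law = asymptotic_coefficients(v, engine=eng)
        alphas = np.geomspace(25.0, 400.0, 7)
        y = np.array(
            [
                math.log(gamow_bandwidth(v, a, 0, engine=eng)) - 0.75 * math.log(a)
                for a in alphas
            ]
        )
        design = np.vstack([np.sqrt(alphas), np.ones_like(alphas)]).T
        slope = np.linalg.lstsq(design, y, rcond=None)[0][0]
        assert -slope == pytest.approx(law.b, rel=0.02)

    def test_law_evaluation(self):
        from coulombgas.semiclassics import AsymptoticLaw

        law = AsymptoticLaw(A=4.0 / math.pi, k=32.0 * math.e, b=8.0)
        direct = (4 / math.pi) * (64 * math.e) ** 0.5 * 81.0 ** 0.75 * math.exp(-72.0)
        assert law.evaluate(81.0, 0) == pytest.approx(direct, rel=1e-12)


class TestTransportBarrier:
    GEOM = ChannelGeometry(a=5.0, L=40.0)

    def test_monotone_suppression_with_concentration(self, engine_for):
        v = ValencyPair(1, 1)
        b1 = transport_barrier(v, 50.0, self.GEOM)
        b2 = transport_barrier(v, 100.0, self.GEOM)
        assert b2 < b1

    def test_slower_decay_for_higher_valency(self, engine_for):
        # smaller b means slower suppression: barrier(3,2) > barrier(1,1) at
        # equal large alpha
        alpha = 200.0
        assert transport_barrier(ValencyPair(3, 2), alpha, self.GEOM) > transport_barrier(
            ValencyPair(1, 1), alpha, self.GEOM
        )

    def test_methods_agree_at_moderate_alpha(self):
        v = ValencyPair(1, 1)
        g = transport_barrier(v, 9.0, self.GEOM, method="gamow")
        n = transport_barrier(v, 9.0, self.GEOM, method="numeric")
        assert g == pytest.approx(n, rel=0.25)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            transport_barrier(ValencyPair(1, 1), 9.0, self.GEOM, method="magic")

    def test_prefactor_table(self):
        assert GAMOW_PREFACTOR[(1, 1)] == 1.0
        assert GAMOW_PREFACTOR[(2, 1)] == pytest.approx(math.sqrt(2.0))
        assert GAMOW_PREFACTOR[(3, 1)] == 1.5
        assert GAMOW_PREFACTOR[(4, 1)] == GAMOW_PREFACTOR[(3, 2)] == 2.0
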