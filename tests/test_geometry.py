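"""Lie-algebraic and phase-plane geometry checks.

Independent oracles: 2x2 determinants built from the raw fields,
central finite differences for brackets and directional derivatives,
and dense-grid bracketing for the singular-segment endpoint.
"""

import numpy as np
import pytest

import indures as ir
from indures.geometry import lie_gamma_grad
from indures.params import DomainError


def fd_bracket(s, p, h=1e-6):
    """Central finite-difference Lie bracket oracle."""

    def jac(field, s):
        J = np.empty((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            J[:, j] = (field(np.add(s, e), p) - field(np.subtract(s, e), p)) / (2 * h)
        return J

    f, g = ir.drift_field(s, p), ir.control_field(s, p)
    return jac(ir.control_field, s) @ f - jac(ir.drift_field, s) @ g


class TestLineCoefficients:
    def test_table1_like_values(self):
        p = ir.Params(alpha=0.01, d=1.0, pr=0.2, eps=1e-6)
        line = ir.line_coefficients(p)
        assert line.a == pytest.approx(0.0179010, abs=5e-8)
        assert line.b == pytest.approx(0.208, rel=1e-12)
        assert line.c == pytest.approx(0.008001, rel=1e-12)

    def test_alpha_zero_line_horizontal(self):
        p = ir.Params(alpha=0.0, d=1.0, pr=0.2, eps=1e-6)
        line = ir.line_coefficients(p)
        assert line.a == 0.0
        assert line.b == pytest.approx(p.d * p.pr)
        assert line.c == pytest.approx(p.eps * p.d)

    def test_eps_zero(self):
        p = ir.Params(alpha=0.01, d=0.5, pr=0.3, eps=0.0, Vc=0.9)
        assert ir.line_coefficients(p).c == pytest.approx(0.01 * 0.7, rel=1e-12)


class TestDetAndBracket:
    def test_det_matches_cross_product(self, table1, interior_grid):
        for s in interior_grid:
            f, g = ir.drift_field(s, table1), ir.control_field(s, table1)
            np.testing.assert_allclose(
                ir.det_A(s, table1), f[0] * g[1] - f[1] * g[0], rtol=1e-10, atol=1e-300
            )

    def test_det_zero_only_at_x1_zero(self, table1):
        assert ir.det_A((0.0, 0.4), table1) == 0.0
        # on the simplex edge kappa = 0 the eps-d term keeps det positive
        assert ir.det_A((0.5, 0.5), table1) == pytest.approx(1e-6 * 0.25, rel=1e-12)

    def test_bracket_identity(self, table1, interior_grid):
        """[f, g] = gamma f + beta g on the interior grid (1e-9 relative)."""
        for s in interior_grid:
            br = ir.lie_bracket_fg(s, table1)
            rec = ir.gamma(s, table1) * ir.drift_field(s, table1) + ir.beta(
                s, table1
            ) * ir.control_field(s, table1)
            np.testing.assert_allclose(rec, br, rtol=0, atol=1e-9 * np.linalg.norm(br))

    def test_bracket_finite_difference(self, table1):
        for s in [(0.1, 0.2), (0.4, 0.1), (0.7, 0.05)]:
            np.testing.assert_allclose(
                ir.lie_bracket_fg(s, table1), fd_bracket(s, table1), rtol=2e-5, atol=1e-10
            )

    def test_bracket_vanishes_at_x1_zero(self, table1):
        np.testing.assert_allclose(ir.lie_bracket_fg((0.0, 0.5), table1), 0.0, atol=1e-15)


class TestGammaBeta:
    def test_gamma_zero_on_line(self, table1):
        line = ir.line_coefficients(table1)
        x1 = 0.02
        s = (x1, line.x2_of_x1(x1))
        assert ir.gamma(s, table1) == pytest.approx(0.0, abs=1e-12)

    def test_gamma_sign_tracks_line_side(self, table1, interior_grid):
        line = ir.line_coefficients(table1)
        for s in interior_grid:
            assert np.sign(ir.gamma(s, table1)) == -np.sign(line.residual(s))

    def test_beta_positive_inside(self, table1, interior_grid):
        for s in interior_grid:
            if 0 < sum(s) < table1.Vc:
                assert ir.beta(s, table1) > 0

    def test_gamma_requires_positive_x1(self, table1):
        with pytest.raises(DomainError):
            ir.gamma((0.0, 0.5), table1)


class TestTangency:
    def test_fig9_coordinates(self):
        p = ir.Params(Vc=0.9, pr=0.2, d=0.05, M=5.0)
        ts = ir.tangency_point(p)
        assert ts.x1s == pytest.approx(0.1059, abs=5e-5)
        assert ts.x2s == pytest.approx(0.7941, abs=5e-5)
        # the max-dose field is tangent to N there
        assert ir.lie_V_along(ts.as_array(), p, p.M) == pytest.approx(0.0, abs=1e-14)

    def test_pr_zero_degenerates(self):
        ts = ir.tangency_point(ir.Params(pr=0.0, Vc=0.9, d=1.0, M=5.0))
        assert ts.x1s == 0.0

    def test_no_tangency_error(self):
        with pytest.raises(ValueError, match="tangency"):
            ir.tangency_point(ir.Params(d=0.01, M=5.0, Vc=0.9, pr=0.2))

    def test_volume_derivative_sign_flips_across_tangency(self):
        p = ir.Params(Vc=0.9, pr=0.2, d=0.05, M=5.0)
        x1s = ir.tangency_point(p).x1s
        below = (x1s / 2, p.Vc - x1s / 2)
        above = (2 * x1s, p.Vc - 2 * x1s)
        assert ir.lie_V_along(below, p, p.M) > 0
        assert ir.lie_V_along(above, p, p.M) < 0
        # no dose: volume always grows in the interior
        assert ir.lie_V_along((0.2, 0.3), p, 0.0) > 0


class TestLineInterior:
    def test_table1_true(self, table1):
        line = ir.line_coefficients(table1)
        assert line.c / line.a < table1.Vc and line.c / line.b < table1.Vc
        assert ir.line_interior(table1)

    def test_alpha_zero_false(self):
        assert not ir.line_interior(ir.Params(alpha=0.0))

    def test_small_vc_false(self):
        assert not ir.line_interior(ir.TABLE1.replace(Vc=0.01, x10=0.005))


class TestLieGamma:
    def test_gradient_matches_finite_difference(self, table1):
        h = 1e-6
        for s in [(0.1, 0.3), (0.3, 0.1), (0.05, 0.6)]:
            for u in (0.0, table1.M):
                vel = ir.drift_field(s, table1) + u * ir.control_field(s, table1)
                vel /= np.linalg.norm(vel)
                fd = (
                    ir.gamma(np.add(s, h * vel), table1)
                    - ir.gamma(np.subtract(s, h * vel), table1)
                ) / (2 * h)
                exact = float(lie_gamma_grad(s, table1) @ vel)
                assert exact == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_prop11_signs_on_line(self, table1):
        line = ir.line_coefficients(table1)
        # near the x2-axis end of L the max-dose derivative is negative
        x1 = 1e-3
        s = (x1, line.x2_of_x1(x1))
        assert ir.lie_gamma_along(s, table1, table1.M) < 0
        # at the x1-axis end it is positive (admissibility holds here)
        assert ir.lie_gamma_along((line.c / line.a, 0.0), table1, table1.M) > 0
        # zero-dose derivative is negative along the segment
        seg = ir.singular_segment(table1)
        mid = 0.5 * (seg[0] + seg[1])
        assert ir.lie_gamma_along((mid, line.x2_of_x1(mid)), table1, 0.0) < 0


class TestSingularSegment:
    def test_table1_segment_endpoint(self, table1):
        seg = ir.singular_segment(table1)
        assert seg is not None
        s_bar, s_max = seg
        line = ir.line_coefficients(table1)
        assert s_max == pytest.approx(line.c / line.a, rel=1e-12)
        # endpoint solves L_Y gamma = 0
        resid = ir.lie_gamma_along((s_bar, line.x2_of_x1(s_bar)), table1, table1.M)
        assert abs(resid) < 1e-8
        # grid-bracketing oracle: the sign change straddles s_bar
        grid = np.linspace(1e-4, s_max, 10_000)
        vals = [
            ir.lie_gamma_along((x, line.x2_of_x1(x)), table1, table1.M) for x in grid
        ]
        sign_change = grid[np.flatnonzero(np.diff(np.sign(vals)))[0]]
        assert abs(sign_change - s_bar) < s_max / 10_000 * 2

    def test_alpha_zero_no_segment(self):
        assert ir.singular_segment(ir.Params(alpha=0.0)) is None

    def test_weak_dose_no_segment(self, table1):
        # far below the admissibility threshold the segment disappears
        assert ir.singular_segment(table1.replace(M=1e-4, x10=1e-3)) is None


class TestMaxDoseKillsSensitive:
    @pytest.mark.parametrize(
        "alpha, d, M, expected",
        [(0.1, 1.0, 5.0, True), (0.005, 0.05, 5.0, False)],
    )
    def test_threshold(self, alpha, d, M, expected):
        p = ir.Params(alpha=alpha, d=d, M=M)
        assert ir.max_dose_kills_sensitive(p) is expected

    def test_large_eps_always_true(self):
        p = ir.Params(eps=0.99, alpha=0.001, d=0.01, M=1.0, Vc=0.009, x10=0.005)
        assert ir.max_dose_kills_sensitive(p)


def test_geometry_report_keys(table1):
    rec = ir.geometry_report(table1)
    for key in ("a", "b", "c", "line_interior", "x1_star", "s_bar"):
        assert key in rec
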