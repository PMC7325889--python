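"""Shared helper: time along a singular dwell vs the matched bang excursion."""

from scipy.integrate import solve_ivp

import indures as ir


def singular_dwell_vs_excursion(p, frac_hi=0.65, frac_lo=0.55):
    """Return (t_singular, t_X + t_Y) between two points of the singular
    segment; the singular time comes from integrating the singular
    feedback, the excursion from two-arc shooting."""
    line = ir.line_coefficients(p)
    s_bar, s_max = ir.singular_segment(p)
    x1a = s_bar + frac_hi * (s_max - s_bar)
    x1b = s_bar + frac_lo * (s_max - s_bar)
    q1 = (x1a, line.x2_of_x1(x1a))
    q2 = (x1b, line.x2_of_x1(x1b))

    def f(t, y):
        u = ir.u_singular(y, p, tol=1e-3)
        return ir.drift_field(y, p) + u * ir.control_field(y, p)

    def hit(t, y):
        return y[0] - q2[0]

    hit.terminal = True
    sol = solve_ivp(f, (0.0, 1e3), q1, method="LSODA", rtol=1e-11, atol=1e-13, events=[hit])
    t_s = float(sol.t[-1])
    t_x, t_y = ir.shoot_between(q1, q2, p, "XY")
    return t_s, t_x + t_y
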