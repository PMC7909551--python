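"""Numerical ODE reference used only as an independent oracle in tests.

Integrates the compartment mass-balance equations segment by segment
between infusion switch points with tight tolerances, so piecewise-
constant input is handled exactly at the breakpoints.
"""

import numpy as np
from scipy.integrate import solve_ivp

from amikpk.pk_model import DoseEvent, PKParams


def _rate_in(t: float, doses: list[DoseEvent]) -> float:
    return sum(d.rate for d in doses if d.start_time < t <= d.end_time)


def _breakpoints(doses, t_end):
    pts = {0.0, t_end}
    for d in doses:
        pts.update((d.start_time, d.end_time))
    return sorted(p for p in pts if p <= t_end)


def ode_profile_1cpt(params: PKParams, CL: float, doses, times):
    """One-compartment profile by high-accuracy numerical integration."""
    ke = CL / params.V
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.empty_like(times)
    order = np.argsort(times)
    a = 0.0
    t_prev = 0.0
    idx = 0
    for t_next in _breakpoints(doses, float(times.max())) + [np.inf]:
        # evaluate any requested times inside [t_prev, t_next]
        while idx < len(order) and times[order[idx]] <= min(t_next, times.max()):
            t_q = times[order[idx]]
            a_q = _integrate_segment_1cpt(a, t_prev, t_q, ke, doses)
            out[order[idx]] = a_q / params.V
            idx += 1
        if not np.isfinite(t_next) or t_next >= times.max():
            break
        a = _integrate_segment_1cpt(a, t_prev, t_next, ke, doses)
        t_prev = t_next
    return out


def _integrate_segment_1cpt(a0, t0, t1, ke, doses):
    if t1 == t0:
        return a0
    r = _rate_in(0.5 * (t0 + t1), doses)  # constant within a segment
    sol = solve_ivp(
        lambda t, y: [r - ke * y[0]], (t0, t1), [a0],
        rtol=1e-11, atol=1e-12, dense_output=False,
    )
    return float(sol.y[0, -1])


def ode_profile_2cpt(params: PKParams, CL: float, doses, times):
    """Two-compartment profile by numerical integration over segments."""
    V, Q, Vp = params.V, params.Q, params.Vp
    k10, k12, k21 = CL / V, Q / V, Q / Vp
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.empty_like(times)
    order = np.argsort(times)
    y = np.zeros(2)
    t_prev = 0.0
    idx = 0

    def seg(y0, t0, t1):
        if t1 == t0:
            return np.asarray(y0, dtype=float)
        r = _rate_in(0.5 * (t0 + t1), doses)
        sol = solve_ivp(
            lambda t, y: [
                r - (k10 + k12) * y[0] + k21 * y[1],
                k12 * y[0] - k21 * y[1],
            ],
            (t0, t1), y0, rtol=1e-11, atol=1e-12,
        )
        return sol.y[:, -1]

    for t_next in _breakpoints(doses, float(times.max())) + [np.inf]:
        while idx < len(order) and times[order[idx]] <= min(t_next, times.max()):
            t_q = times[order[idx]]
            out[order[idx]] = seg(y, t_prev, t_q)[0] / V
            idx += 1
        if not np.isfinite(t_next) or t_next >= times.max():
            break
        y = seg(y, t_prev, t_next)
        t_prev = t_next
    return out
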