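"""Independent numerical oracle: ODE integration of the 3-state system.

Depot -> central <-> peripheral with first-order elimination from central and
an absorption lag implemented by starting each dose's depot input at
t_dose + alag.  Used only to validate the closed-form evaluator.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from fcn159pk.model import IndividualParameters, MG_TO_UG


def ode_concentration(
    p: IndividualParameters,
    dose_events: list[tuple[float, float]],  # (time h, amount mg)
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Central-compartment concentration (ng/mL) at ``times``."""
    k10 = p.cl / p.vc
    k12 = p.q / p.vc
    k21 = p.q / p.vp

    def rhs(_t, y):
        a_dep, a_cen, a_per = y
        return [
            -p.ka * a_dep,
            p.ka * a_dep - (k10 + k12) * a_cen + k21 * a_per,
            k12 * a_cen - k21 * a_per,
        ]

    starts = sorted((t + p.alag, amt) for t, amt in dose_events)
    times = np.asarray(times, float)
    out = np.zeros_like(times)
    y = np.zeros(3)
    t_cur = 0.0
    breakpoints = [s for s, _ in starts] + [np.inf]
    seg_doses = {round(s, 12): amt for s, amt in starts}
    events_iter = iter(starts)
    next_event = next(events_iter, None)
    order = np.argsort(times)
    sorted_times = times[order]
    results = np.zeros_like(sorted_times)
    idx = 0
    while idx < len(sorted_times):
        t_target = sorted_times[idx]
        while next_event is not None and next_event[0] <= t_target + 1e-15:
            t_ev, amt = next_event
            if t_ev > t_cur:
                sol = solve_ivp(rhs, (t_cur, t_ev), y, rtol=rtol, atol=atol,
                                dense_output=False)
                y = sol.y[:, -1]
                t_cur = t_ev
            y[0] += amt * MG_TO_UG * p.f
            next_event = next(events_iter, None)
        if t_target > t_cur:
            sol = solve_ivp(rhs, (t_cur, t_target), y, rtol=rtol, atol=atol)
            y = sol.y[:, -1]
            t_cur = t_target
        results[idx] = y[1] / p.vc
        idx += 1
    out[order] = results
    return out
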