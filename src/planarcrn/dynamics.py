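"""Positivity-preserving integration, Poincare return maps, cycle witnesses.

All integration runs in logarithmic state coordinates, so trajectories are
structurally confined to the open positive quadrant.  Section crossings are
located by the integrator's dense-output event machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from planarcrn.network_model import (
    MassActionSystem,
    PowerLawField,
    mass_action_field,
)

__all__ = [
    "Trajectory",
    "CycleWitness",
    "integrate",
    "poincare_return",
    "count_limit_cycles",
    "homoclinic_probe",
]

_BIG_BOX = math.log(1e30)
_SAFE_BOX = math.log(1e6)


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n, 2), strictly positive
    events: tuple
    blew_up: bool = False

    def final(self) -> tuple[float, float]:
        return tuple(self.states[-1])


@dataclass(frozen=True)
class CycleWitness:
    fixed_point: float      # section coordinate x* on {y = 1, x > 1}
    period: float
    stability: str          # "stable" | "unstable"
    floquet_ratio: float    # derivative of the return map at x*


def _as_field(obj) -> PowerLawField:
    if isinstance(obj, PowerLawField):
        return obj
    if isinstance(obj, MassActionSystem):
        return mass_action_field(obj)
    if hasattr(obj, "field"):
        return obj.field()
    raise TypeError(f"cannot interpret {type(obj).__name__} as a vector field")


def _log_rhs(field: PowerLawField):
    """RHS in (log x, log y): xi' = f(x,y)/x, eta' = g(x,y)/y."""
    x, y = sp.symbols("x y", positive=True)
    fx, fy = field.exprs(x, y)
    for e in (fx, fy):
        if e.free_symbols - {x, y}:
            raise ValueError("field has free parameters; substitute numbers first")
    gx = sp.expand(fx / x)
    gy = sp.expand(fy / y)
    fn = sp.lambdify((x, y), [gx, gy], modules="numpy")

    def rhs(t, s):
        ex, ey = math.exp(s[0]), math.exp(s[1])
        vx, vy = fn(ex, ey)
        return (vx, vy)

    return rhs


def integrate(
    obj,
    start: Sequence[float],
    t_end: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    max_points: Optional[int] = None,
) -> Trajectory:
    """Integrate from a positive point; flags blow-up past ``[1e-30, 1e30]^2``."""
    field = _as_field(obj)
    x0, y0 = float(start[0]), float(start[1])
    if x0 <= 0 or y0 <= 0:
        raise ValueError("start must be strictly positive")
    rhs = _log_rhs(field)

    def big(t, s):
        return _BIG_BOX - max(abs(s[0]), abs(s[1]))

    big.terminal = True
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        [math.log(x0), math.log(y0)],
        method="DOP853",
        rtol=rtol,
        atol=atol,
        events=[big],
        dense_output=False,
    )
    states = np.exp(sol.y.T)
    blew = bool(sol.t_events[0].size)
    return Trajectory(sol.t, states, (), blew)


def poincare_return(
    obj,
    x0: float,
    t_max: float = 1e4,
    rtol: float = 1e-12,
    atol: float = 1e-14,
    compute_derivative: bool = False,
    _deriv_offset: float = 1e-4,
):
    """First return to the section ``{y = 1, x > 1}`` with matching
    crossing orientation.

    Returns ``(x_return, period, derivative_estimate)``; the derivative is
    ``None`` unless requested (centered difference with offset 1e-4).  If no
    return occurs within ``t_max`` or the trajectory leaves the safety box
    ``[1e-6, 1e6]^2``, returns ``(None, None, None)``.
    """
    field = _as_field(obj)
    if x0 <= 1.0:
        raise ValueError("section coordinate must satisfy x0 > 1")
    rhs = _log_rhs(field)
    s0 = [math.log(x0), 0.0]
    d0 = rhs(0.0, s0)[1]
    if d0 == 0.0:
        # nudge forward to pick up the orientation
        d0 = rhs(0.0, [s0[0], 1e-12])[1]
        if d0 == 0.0:
            return (x0, 0.0, None)
    direction = 1.0 if d0 > 0 else -1.0

    def section(t, s):
        return s[1]

    section.terminal = True
    section.direction = direction

    def safe(t, s):
        return _SAFE_BOX - max(abs(s[0]), abs(s[1]))

    safe.terminal = True

    # leave the section before arming the (terminal) crossing event, else the
    # start point itself registers as a crossing
    t_lead = 1e-7
    pre = solve_ivp(rhs, (0.0, t_lead), s0, method="DOP853", rtol=rtol, atol=atol)
    s1 = list(pre.y[:, -1])
    sol = solve_ivp(
        rhs, (t_lead, float(t_max)), s1,
        method="DOP853", rtol=rtol, atol=atol, events=[section, safe],
    )
    if sol.t_events[1].size:
        raise RuntimeError("trajectory left the safety box (not a fine focus or r0 too large)")
    if not sol.t_events[0].size:
        return (None, None, None)
    t_ret = float(sol.t_events[0][0])
    x_ret = float(math.exp(sol.y_events[0][0][0]))
    deriv = None
    if compute_derivative:
        h = _deriv_offset
        xp, _, _ = poincare_return(field, x0 + h, t_max=t_max, rtol=rtol, atol=atol)
        xm, _, _ = poincare_return(field, x0 - h, t_max=t_max, rtol=rtol, atol=atol)
        if xp is not None and xm is not None:
            deriv = (xp - xm) / (2 * h)
    return (x_ret, t_ret, deriv)


def count_limit_cycles(
    obj,
    x_range: tuple[float, float] = (1.01, 2.0),
    n_grid: int = 400,
    rtol: float = 1e-12,
    displacement_tol: float = 1e-7,
    fixed_point_tol: float = 1e-9,
) -> list[CycleWitness]:
    """Isolated periodic orbits crossing ``{y = 1, x in x_range}``.

    Scans the return-map displacement ``d(x) = return(x) - x`` on a grid,
    refines each sign change by bisection, and classifies stability by the
    return-map slope.  Grid points where the displacement is below
    ``displacement_tol`` are treated as non-isolated (center-like) and do
    not produce witnesses.
    """
    field = _as_field(obj)
    xs = np.linspace(x_range[0], x_range[1], n_grid)
    disp, periods = [], []
    for xv in xs:
        try:
            xr, tr, _ = poincare_return(field, float(xv), rtol=rtol)
        except RuntimeError:  # left the safety box: no return from here
            xr = tr = None
        disp.append(np.nan if xr is None else xr - xv)
        periods.append(np.nan if tr is None else tr)
    disp = np.asarray(disp)
    witnesses: list[CycleWitness] = []
    for i in range(len(xs) - 1):
        d0, d1 = disp[i], disp[i + 1]
        if np.isnan(d0) or np.isnan(d1):
            continue
        if abs(d0) < displacement_tol and abs(d1) < displacement_tol:
            continue  # center-like plateau
        if d0 == 0.0 or d0 * d1 >= 0:
            continue
        lo, hi, dlo = float(xs[i]), float(xs[i + 1]), d0
        while hi - lo > fixed_point_tol:
            mid = 0.5 * (lo + hi)
            xr, _, _ = poincare_return(field, mid, rtol=rtol)
            if xr is None:
                break
            dm = xr - mid
            if dm == 0.0:
                lo = hi = mid
                break
            if (dm > 0) == (dlo > 0):
                lo = mid
                dlo = dm
            else:
                hi = mid
        x_star = 0.5 * (lo + hi)
        xr, t_star, deriv = poincare_return(field, x_star, rtol=rtol, compute_derivative=True)
        if xr is None or deriv is None:
            continue
        stability = "stable" if deriv < 1.0 else "unstable"
        witnesses.append(CycleWitness(x_star, float(t_star), stability, float(deriv)))
    return witnesses


def homoclinic_probe(p, q, n_samples: int = 100) -> dict:
    """Boundedness probe for the reversible-center chain family.

    For ``p > 0 > q`` with ``p + q > 0`` the closed-orbit region lies in
    ``[0, L]^2`` with ``L = (1 - p/q)**(1/(p+q))``; the probe samples
    ``xdot`` on the segment ``{x = L, 0 < y < L}`` and checks it is
    negative.  For ``p + q < 0`` the closed-orbit region is unbounded.
    """
    p, q = float(p), float(q)
    if not (p > 0 and q < 0):
        raise ValueError("need p > 0 and q < 0")
    if p + q < 0:
        return {"bounded_region": False, "box_bound": None, "samples_ok": None}
    L = (1.0 - p / q) ** (1.0 / (p + q))
    ok = True
    for k in range(1, n_samples + 1):
        yv = L * k / (n_samples + 1)
        xdot = (p - q) + q * L ** p * yv ** q - p * L ** q * yv ** p
        if xdot >= 0:
            ok = False
            break
    return {"bounded_region": True, "box_bound": L, "samples_ok": ok}
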