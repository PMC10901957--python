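"""Hopf loci, degenerate Hopf points, and cycle-bifurcation schedules.

The trace of each parametric family is linear in one designated parameter,
so Hopf loci come out in closed form.  Degenerate points (zeros of focal
values along the locus) are found by bisection on high-precision focal
value evaluations, or by damped finite-difference Newton for the
two-dimensional searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import mpmath
import sympy as sp

from planarcrn import fixtures
from planarcrn.lyapunov import focal_values

__all__ = [
    "HopfLocus",
    "PerturbationSchedule",
    "hopf_locus",
    "degenerate_hopf_search",
    "perturbation_schedule",
    "focal_value_on_locus",
    "quadrangle_32_L",
    "chain_41_L",
    "three_reactions_51_L",
    "quadrangle_32_free_b4_L",
    "zigzag_scaled",
]

_PREC_DIGITS = 50


@dataclass(frozen=True)
class HopfLocus:
    family: str
    parameter: str
    constraint: sp.Expr        # closed-form solution for the parameter
    domain: Optional[str] = None


@dataclass(frozen=True)
class PerturbationSchedule:
    family: str
    degenerate_point: dict
    steps: tuple               # (parameter, direction, maintained-relations)
    expected_cycles_after_step: tuple  # (count, stability pattern outward-in order)
    witnessed: Optional[bool] = None


# ---------------------------------------------------------------------------
# Hopf loci (trace = 0 in closed form)

_K, _gamma, _q, _r, _a, _b, _d, _b4, _kap = sp.symbols(
    "K gamma q r a b d b4 kappa", positive=True
)


def hopf_locus(family: str, b4=None) -> HopfLocus:
    """Solve ``trace = 0`` for the family's designated parameter."""
    if family == "quadrangle_3_2":
        scaled = fixtures.quadrangle_3_2(K=_K, gamma=_gamma, b4=b4)
        sol = sp.solve(scaled.trace(), _gamma)
        return HopfLocus(family, "gamma", sp.simplify(sol[0]))
    if family == "chain_4_1":
        scaled = fixtures.chain_4_1(q=_q, r=_r, K=_K)
        sol = sp.solve(scaled.trace(), _K)
        return HopfLocus(family, "K", sp.simplify(sol[0]), "q > 0 and r > q*(2*q+1)")
    if family == "three_reactions_5_1":
        scaled = fixtures.three_reactions_5_1(a=_a, b=_b, d=_d, K=_K)
        sol = sp.solve(scaled.trace(), _K)
        return HopfLocus(family, "K", sp.simplify(sol[0]), "d > 1 and 1 + b*d > 0")
    if family == "zigzag":
        tr = zigzag_trace(_kap)
        sol = sp.solve(tr, _kap)
        pos = [s for s in sol if s.is_positive and s < 2]
        return HopfLocus(family, "kappa", pos[0], "kappa < 2")
    raise ValueError(f"no Hopf locus implemented for family {family!r}")


def zigzag_trace(kappa) -> sp.Expr:
    """Trace of the Jacobian at the zigzag equilibrium, as a function of kappa."""
    from planarcrn.fixtures import zigzag_scaled as _zs

    return sp.simplify(_zs(kappa).trace())


def zigzag_scaled(kappa):
    from planarcrn.fixtures import zigzag_scaled as _zs

    return _zs(kappa)


# ---------------------------------------------------------------------------
# focal values along the trace-zero locus, as high-precision callables


def _f(x):
    return sp.Float(mpmath.mpf(x), _PREC_DIGITS)


def _rat(x) -> sp.Expr:
    """Numeric input conversion: exact rationals stay exact, floats become
    50-digit Floats (their binary value is preserved)."""
    if isinstance(x, float):
        return _f(x)
    x = sp.sympify(x)
    if x.free_symbols or x.is_Rational:
        return x
    if x.is_Float:
        return sp.Float(x, _PREC_DIGITS)
    return x


def quadrangle_32_L(K, k_max: int = 2) -> list:
    """Focal values of the quadrangle family on the trace-zero locus
    ``gamma = 16 + 1/K``; exact rational arithmetic, 50-digit output."""
    K = _rat(K)
    scaled = fixtures.quadrangle_3_2(K=K, gamma=16 + 1 / K)
    return [v.evalf(_PREC_DIGITS) if v.is_number else v
            for v in focal_values(scaled, k_max=k_max).L]


def quadrangle_32_free_b4_L(K, b4, k_max: int = 2) -> list:
    """Focal values of the free-``b4`` quadrangle family on the trace-zero
    locus ``gamma = b4^2 - 3*b4 + 6 + 1/K``."""
    K, b4 = _rat(K), _rat(b4)
    gamma = b4 ** 2 - 3 * b4 + 6 + 1 / K
    scaled = fixtures.quadrangle_3_2(K=K, gamma=gamma, b4=b4)
    return [v.evalf(_PREC_DIGITS) if v.is_number else v
            for v in focal_values(scaled, k_max=k_max).L]


def chain_41_L(q, r=None, k_max: int = 2) -> list:
    """Focal values of the chain family with ``K = 2/(r - q*(2*q+1))``.

    When ``r`` is omitted it is taken on the ``L1 = 0`` curve
    ``r = q*(4*q^2+16*q+7)/(3*(1-2*q))`` (needs ``0 < q < 1/2``).
    """
    q = _rat(q)
    r = q * (4 * q ** 2 + 16 * q + 7) / (3 * (1 - 2 * q)) if r is None else _rat(r)
    K = 2 / (r - q * (2 * q + 1))
    scaled = fixtures.chain_4_1(q=q, r=r, K=K)
    return [v.evalf(_PREC_DIGITS) if v.is_number else v
            for v in focal_values(scaled, k_max=k_max).L]


def three_reactions_51_L(a, d, b=None, k_max: int = 3) -> list:
    """Focal values of the three-reaction family with ``K`` and ``b``
    eliminated: ``K = a/(1+b*d)`` kills the trace and, when ``b`` is
    omitted, ``b = (-2 + a*(1 + sqrt(1+8*d)))/(2*d)`` kills ``L1``.

    The eliminations are evaluated in 50-digit arithmetic (or exactly for
    rational inputs), so the trace residual stays far below the tolerance.
    """
    a = _rat(a)
    d = _rat(d)
    if b is None:
        b = (-2 + a * (1 + sp.sqrt(1 + 8 * d))) / (2 * d)
    else:
        b = _rat(b)
    K = a / (1 + b * d)
    scaled = fixtures.three_reactions_5_1(a=a, b=b, d=d, K=K)
    return [v.evalf(_PREC_DIGITS) if v.is_number else v
            for v in focal_values(scaled, k_max=k_max).L]


# ---------------------------------------------------------------------------
# root finding


def _bisect(fun: Callable, lo: float, hi: float, tol: float = 1e-13, max_iter: int = 200):
    flo, fhi = fun(lo), fun(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if (flo > 0) == (fhi > 0):
        raise ValueError(f"no sign change in bracket ({lo}, {hi})")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if fm == 0 or hi - lo < tol:
            return mid
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi, fhi = mid, fm
    return 0.5 * (lo + hi)


def _newton_nd(fun: Callable, seed: Sequence[float], tol: float = 1e-12,
               max_iter: int = 60, fd_rel: float = 1e-8) -> list:
    """Damped finite-difference Newton in n dimensions (mpmath precision)."""
    mpmath.mp.dps = _PREC_DIGITS
    x = [mpmath.mpf(v) for v in seed]
    n = len(x)

    def norm(v):
        return max(abs(e) for e in v)

    fx = [mpmath.mpf(v) for v in fun(x)]
    for _ in range(max_iter):
        if norm(fx) == 0:
            break
        jac = mpmath.zeros(n, n)
        for j in range(n):
            h = mpmath.mpf(fd_rel) * max(1, abs(x[j]))
            xp = list(x)
            xm = list(x)
            xp[j] += h
            xm[j] -= h
            fp = fun(xp)
            fm = fun(xm)
            for i in range(n):
                jac[i, j] = (mpmath.mpf(fp[i]) - mpmath.mpf(fm[i])) / (2 * h)
        try:
            step = mpmath.lu_solve(jac, [-v for v in fx])
        except ZeroDivisionError:
            raise RuntimeError("singular Jacobian in Newton search")
        lam = mpmath.mpf(1)
        improved = False
        for _ in range(40):
            cand = [x[i] + lam * step[i] for i in range(n)]
            fc = [mpmath.mpf(v) for v in fun(cand)]
            if norm(fc) < norm(fx):
                x, fx = cand, fc
                improved = True
                break
            lam /= 2
        if not improved:
            break
        if norm([lam * s for s in step]) < tol:
            break
    return [float(v) for v in x] + [float(norm(fx))]


def degenerate_hopf_search(family: str, target: str, bracket=None, seed=None) -> dict:
    """Kill the designated focal value along the family's Hopf locus.

    Supported searches:
      - ("quadrangle_3_2", "L1"): root K0 of L1(K) on (0.01, 0.5)
      - ("quadrangle_3_2", "L2"): joint root of (L1, L2) over (K, b4)
      - ("chain_4_1", "L2"): root q of L2 on the L1=0 curve, q in (0, 1/2)
      - ("three_reactions_5_1", "L2"): root d of L2(a=fixed, d) on the L1=0
        curve; pass bracket=(dlo, dhi) and seed=a
      - ("three_reactions_5_1", "L3"): joint root of (L2, L3) over (a, d)
    Returns a dict with the root, the residual, and a local sign chart.
    """
    if family == "quadrangle_3_2" and target == "L1":
        lo, hi = bracket or (0.01, 0.5)
        f = lambda K: float(quadrangle_32_L(K, k_max=1)[0])
        K0 = _bisect(f, lo, hi)
        return {"root": {"K": K0}, "residual": abs(f(K0)),
                "sign_chart": {"below": f(0.8 * K0) < 0 and -1 or 1,
                               "above": f(1.2 * K0) > 0 and 1 or -1}}
    if family == "chain_4_1" and target == "L2":
        lo, hi = bracket or (0.05, 0.45)
        f = lambda q: float(chain_41_L(q, k_max=2)[1])
        q0 = _bisect(f, lo, hi)
        return {"root": {"q": q0}, "residual": abs(f(q0)),
                "sign_chart": {"below": -1 if f(max(lo, 0.8 * q0)) < 0 else 1,
                               "above": 1 if f(min(hi, 1.2 * q0)) > 0 else -1}}
    if family == "three_reactions_5_1" and target == "L2":
        a = seed if seed is not None else 1.0
        lo, hi = bracket or (2.5, 4.0)
        f = lambda dv: float(three_reactions_51_L(a, dv, k_max=2)[1])
        d0 = _bisect(f, lo, hi)
        return {"root": {"a": float(a), "d": d0}, "residual": abs(f(d0))}
    if family == "three_reactions_5_1" and target == "L3":
        sd = seed or (1.01, 3.29)

        def fun(x):
            ls = three_reactions_51_L(x[0], x[1], k_max=3)
            return [float(ls[1]), float(ls[2])]

        *root, res = _newton_nd(fun, sd)
        return {"root": {"a": root[0], "d": root[1]}, "residual": res}
    if family == "quadrangle_3_2" and target == "L2":
        sd = seed or (0.09, 4.8)

        def fun(x):
            ls = quadrangle_32_free_b4_L(x[0], x[1], k_max=2)
            return [float(ls[0]), float(ls[1])]

        *root, res = _newton_nd(fun, sd)
        return {"root": {"K": root[0], "b4": root[1]}, "residual": res}
    raise ValueError(f"unsupported search ({family!r}, {target!r})")


# ---------------------------------------------------------------------------
# perturbation schedules (from the cited bifurcation arguments)


def perturbation_schedule(family: str, degenerate_point: dict) -> PerturbationSchedule:
    """Emit the step order and directions that bifurcate the small cycles."""
    if family == "chain_4_1":
        steps = (
            ("q", "+", ("r = q*(4*q^2+16*q+7)/(3*(1-2*q))", "K = 2/(r-q*(2*q+1))")),
            ("r", "-", ("K = 2/(r-q*(2*q+1))",)),
            ("K", "+", ()),
        )
        expected = (
            (1, ("stable",)),
            (2, ("stable", "unstable")),
            (3, ("stable", "unstable", "stable")),
        )
        return PerturbationSchedule(family, degenerate_point, steps, expected)
    if family == "quadrangle_3_2":
        steps = (
            ("K", "-", ("gamma = 16 + 1/K",)),
            ("gamma", "+", ()),
        )
        # the third, outermost stable cycle is supplied by permanence and
        # Poincare-Bendixson rather than by a local perturbation
        expected = (
            (1, ("unstable",)),
            (3, ("stable", "unstable", "stable")),
        )
        return PerturbationSchedule(family, degenerate_point, steps, expected,
                                    witnessed=None)
    if family == "zigzag":
        steps = (("kappa", "-", ()),)
        expected = ((1, ("unstable",)),)
        return PerturbationSchedule(family, degenerate_point, steps, expected)
    raise ValueError(f"unsupported family {family!r}")
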