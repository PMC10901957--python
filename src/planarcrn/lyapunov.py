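"""Focal values (Lyapunov quantities) at a fine focus of a scaled system.

Given a scaled system whose Jacobian at ``(1, 1)`` has zero trace and
positive determinant, the field is shifted to the origin, Taylor-expanded
(exactly, via generalized binomial coefficients), brought to the rotation
normal form ``u' = -w*v + ..., v' = w*u + ...`` by a linear change of
basis, and fed to the Poincare-Lyapunov recursion: a formal first integral
``Phi = (u^2+v^2)/2 + ...`` is constructed degree by degree, leaving
residuals ``g_{2m} * (u^2+v^2)^m``.  The reported focal values are the
return-map coefficients

    L_k = (2*pi/w) * g_{2k+2},

which carry the factor pi.  This normalization was calibrated once against
the two first focal values printed for the quadrangle and chain families
and is verified symbolically by the test suite.

The recursion's linear solves reduce to integer matrices (one per degree,
cached), so the computation is exact for rational data and loses no
precision for high-precision floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import sympy as sp

from planarcrn.equilibria import ScaledSystem

__all__ = [
    "LocalExpansion",
    "FocalValueSequence",
    "monomial_expansion",
    "local_expansion",
    "focal_values",
    "return_map_displacement",
    "hopf_classification",
]

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class LocalExpansion:
    """Taylor data of the shifted field ``(u, v) = (x - 1, y - 1)``.

    ``px`` and ``py`` map ``(i, j)`` to the coefficient of ``u^i v^j`` in
    the two components, up to total degree ``order``; constant terms vanish.
    """

    order: int
    px: dict
    py: dict


@dataclass(frozen=True)
class FocalValueSequence:
    omega: sp.Expr
    L: tuple
    first_nonzero: Optional[int]  # 1-based index, or None if all zero to order k

    def L_floats(self) -> list:
        return [complex(v).real if v.is_number else v for v in self.L]


def monomial_expansion(a, b, order: int) -> dict:
    """Coefficients of ``(1+u)^a (1+v)^b`` up to total degree ``order``.

    The ``(i, j)`` coefficient is ``binomial(a, i) * binomial(b, j)`` with
    generalized binomials, exact for rational ``a, b``.
    """
    a, b = sp.sympify(a), sp.sympify(b)
    ca = [sp.binomial(a, i) for i in range(order + 1)]
    cb = [sp.binomial(b, j) for j in range(order + 1)]
    out = {}
    for i in range(order + 1):
        if ca[i] == 0:
            continue
        for j in range(order + 1 - i):
            c = ca[i] * cb[j]
            if c != 0:
                out[(i, j)] = c
    return out


def local_expansion(scaled: ScaledSystem, order: int) -> LocalExpansion:
    """Taylor expansion of the scaled field about ``(1, 1)``."""
    if order < 2:
        raise ValueError("order must be at least 2")
    px: dict = {}
    py: dict = {}
    for i in range(scaled.n_reactions()):
        src = scaled.sources[i]
        mono = monomial_expansion(src.a, src.b, order)
        cx = scaled.xdot_coeff(i)
        cy = scaled.ydot_coeff(i)
        for key, c in mono.items():
            px[key] = px.get(key, sp.S.Zero) + cx * c
            py[key] = py.get(key, sp.S.Zero) + cy * c
    for p in (px, py):
        const = p.pop((0, 0), sp.S.Zero)
        const = sp.simplify(const)
        if const.is_number and const != 0 and abs(complex(const)) > 1e-9:
            raise ValueError("scaled field does not vanish at (1, 1)")
        for key in [k for k, v in p.items() if v == 0]:
            del p[key]
    return LocalExpansion(order, px, py)


# ---------------------------------------------------------------------------
# Poincare-Lyapunov recursion


@lru_cache(maxsize=None)
def _rotation_solver(d: int):
    """Inverse of the (integer) degree-d homogeneous stage matrix.

    Unknowns are the coefficients of ``Phi_d`` (scaled by the angular
    frequency) in the basis ``u^i v^(d-i)``, plus, for even ``d``, the
    residual coefficient ``g`` of ``(u^2+v^2)^(d/2)``.  The rotation
    operator ``u*dPhi/dv - v*dPhi/du`` maps basis element ``(i, j)`` to
    ``j*(i+1, j-1) - i*(i-1, j+1)``; for even ``d`` the system is closed by
    requiring ``Phi_d`` to have no component along ``(u^2+v^2)^(d/2)``.
    """
    n = d + 1
    idx = {(i, d - i): i for i in range(n)}
    even = d % 2 == 0
    size = n + 1 if even else n
    m = sp.zeros(size, size)
    for i in range(n):
        j = d - i
        if j > 0:
            m[idx[(i + 1, j - 1)], i] += j
        if i > 0:
            m[idx[(i - 1, j + 1)], i] += -i
    if even:
        circ = sp.Poly((sp.Symbol("_u") ** 2 + sp.Symbol("_v") ** 2) ** (d // 2),
                       sp.Symbol("_u"), sp.Symbol("_v"))
        kvec = [sp.Integer(circ.coeff_monomial(sp.Symbol("_u") ** i * sp.Symbol("_v") ** (d - i)))
                for i in range(n)]
        for i in range(n):
            m[i, n] = -kvec[i]      # -g * (u^2+v^2)^(d/2) column
            m[n, i] = kvec[i]       # orthogonality row pinning Phi_d
    return m.inv(), idx, even


def _poly_mul(p: dict, q: dict, max_deg: int) -> dict:
    out: dict = {}
    for (i1, j1), c1 in p.items():
        for (i2, j2), c2 in q.items():
            i, j = i1 + i2, j1 + j2
            if i + j > max_deg:
                continue
            key = (i, j)
            out[key] = out.get(key, sp.S.Zero) + c1 * c2
    return out


def _poly_diff(p: dict, var: int) -> dict:
    out = {}
    for (i, j), c in p.items():
        if var == 0 and i > 0:
            out[(i - 1, j)] = out.get((i - 1, j), sp.S.Zero) + i * c
        elif var == 1 and j > 0:
            out[(i, j - 1)] = out.get((i, j - 1), sp.S.Zero) + j * c
    return out


def _compose_linear(p: dict, a, b, max_deg: int) -> dict:
    """Substitute ``u -> U`` and ``v -> a*U + b*V`` into the dict polynomial."""
    # cache powers of the linear form (a*U + b*V)^j
    pows = {0: {(0, 0): sp.S.One}}
    jmax = max((j for (_, j) in p), default=0)
    lin = {(1, 0): a, (0, 1): b}
    for j in range(1, jmax + 1):
        pows[j] = _poly_mul(pows[j - 1], lin, max_deg)
    out: dict = {}
    for (i, j), c in p.items():
        for (k, l), w in pows[j].items():
            if i + k + l > max_deg:
                continue
            key = (i + k, l)
            out[key] = out.get(key, sp.S.Zero) + c * w
    return out


def _simp(e: sp.Expr) -> sp.Expr:
    e = sp.expand(e)
    if not e.free_symbols:
        return e
    if e.has(sp.Float):
        # cancel/radsimp rebuild Float coefficients in double precision;
        # plain expanded arithmetic keeps the operands' full precision
        return e
    return sp.cancel(sp.radsimp(e))


def lyapunov_residuals(pu: dict, pv: dict, omega: sp.Expr, k_max: int) -> list:
    """Residuals ``g_4, g_6, ..., g_{2*k_max+2}`` of the formal integral.

    ``pu, pv`` are the nonlinear parts (degree >= 2) of the field in
    rotation normal form with angular frequency ``omega``.
    """
    n_top = 2 * k_max + 2
    phi: dict = {(2, 0): sp.Rational(1, 2), (0, 2): sp.Rational(1, 2)}
    gs = []
    f1 = dict(pu)
    f1[(0, 1)] = f1.get((0, 1), sp.S.Zero) - omega
    f2 = dict(pv)
    f2[(1, 0)] = f2.get((1, 0), sp.S.Zero) + omega
    for d in range(3, n_top + 1):
        # degree-d part of grad(Phi_known) . F
        phi_u = _poly_diff(phi, 0)
        phi_v = _poly_diff(phi, 1)
        kd: dict = {}
        for dp, f in ((phi_u, f1), (phi_v, f2)):
            for (i1, j1), c1 in dp.items():
                if c1 == 0:
                    continue
                for (i2, j2), c2 in f.items():
                    if i1 + j1 + i2 + j2 == d:
                        key = (i1 + i2, j1 + j2)
                        kd[key] = kd.get(key, sp.S.Zero) + c1 * c2
        minv, idx, even = _rotation_solver(d)
        size = minv.shape[0]
        rhs = sp.zeros(size, 1)
        for key, c in kd.items():
            rhs[idx[key], 0] = -_simp(c)
        z = minv * rhs
        for (i, j), pos in idx.items():
            c = _simp(z[pos, 0] / omega)
            if c != 0:
                phi[(i, j)] = c
        if even:
            g = _simp(z[size - 1, 0])
            if d >= 4:
                gs.append(g)
    return gs


def _normal_form(scaled: ScaledSystem, order: int):
    """Shift to the origin and rotate the linear part to ``((0,-w),(w,0))``.

    Returns ``(pu, pv, omega)`` with ``pu, pv`` the nonlinear parts.
    """
    j = scaled.jacobian()
    tr = sp.simplify(j[0, 0] + j[1, 1])
    if tr.is_number:
        if tr != 0 and abs(complex(tr)) > _ZERO_TOL:
            raise ValueError(f"trace is not zero (got {tr})")
    elif sp.simplify(sp.expand(tr)) != 0:
        raise ValueError(f"trace does not vanish symbolically: {tr}")
    det = sp.simplify(j.det())
    if det.is_number and not (det.is_positive or complex(det).real > 0):
        raise ValueError(f"determinant must be positive (got {det})")
    omega = sp.sqrt(det)
    j11, j12 = j[0, 0], j[0, 1]
    if j12 == 0:
        raise ValueError("degenerate linear part: J12 = 0 with zero trace")
    exp = local_expansion(scaled, order)
    a = _simp(-j11 / j12)
    b = _simp(-omega / j12)
    pxt = _compose_linear(exp.px, a, b, order)
    # V' = -(j11 * P + j12 * Q) / omega
    comb: dict = {}
    for key, c in exp.px.items():
        comb[key] = comb.get(key, sp.S.Zero) + j11 * c
    for key, c in exp.py.items():
        comb[key] = comb.get(key, sp.S.Zero) + j12 * c
    comb = {k: -v / omega for k, v in comb.items()}
    pyt = _compose_linear(comb, a, b, order)
    # drop the linear parts (they are -omega*V and omega*U by construction)
    pu = {k: _simp(v) for k, v in pxt.items() if sum(k) >= 2}
    pv = {k: _simp(v) for k, v in pyt.items() if sum(k) >= 2}
    pu = {k: v for k, v in pu.items() if v != 0}
    pv = {k: v for k, v in pv.items() if v != 0}
    return pu, pv, omega


def focal_values(scaled: ScaledSystem, k_max: int = 3) -> FocalValueSequence:
    """Focal values ``L_1 ... L_k_max`` in the anchored normalization.

    Requires zero trace and positive determinant at ``(1, 1)``.  Exact for
    rational data; symbolic parameters are carried through.  Each ``L_k``
    is meaningful on the variety where the previous ones vanish.
    """
    if not 1 <= k_max <= 4:
        raise ValueError("k_max must be between 1 and 4")
    order = 2 * k_max + 1
    pu, pv, omega = _normal_form(scaled, order)
    gs = lyapunov_residuals(pu, pv, omega, k_max)
    ls = tuple(_simp(2 * sp.pi * g / omega) for g in gs[:k_max])
    first = None
    for idx, lv in enumerate(ls, start=1):
        z = _is_zero(lv)
        if z is False:
            first = idx
            break
        if z is None:
            first = idx  # cannot certify zero; report as candidate
            break
    return FocalValueSequence(omega, ls, first)


def _is_zero(e: sp.Expr) -> Optional[bool]:
    e = sp.sympify(e)
    if e.is_number:
        if e == 0:
            return True
        return abs(complex(e)) < 1e-20
    s = sp.simplify(e)
    if s == 0:
        return True
    return None


def return_map_displacement(scaled: ScaledSystem, r0: float, rtol: float = 1e-12):
    """Numeric oracle: displacement of the return map at ``x = 1 + r0``.

    Integrates from ``(1 + r0, 1)`` to the first return on the section
    ``{y = 1, x > 1}`` and returns ``x_return - (1 + r0)``.
    """
    from planarcrn import dynamics

    if not 0 < r0 <= 0.1:
        raise ValueError("r0 must lie in (0, 0.1]")
    x_ret, _, _ = dynamics.poincare_return(scaled, 1.0 + r0, rtol=rtol)
    if x_ret is None:
        raise RuntimeError("no return to the section (not a focus?)")
    return x_ret - (1.0 + r0)


def hopf_classification(
    family: ScaledSystem,
    parameter,
    value,
    k_max: int = 3,
) -> dict:
    """Classify the Hopf point of a one-parameter family at ``parameter=value``.

    Returns a record with the trace check, the first nonzero focal value
    (index and sign) and a verdict: ``supercritical`` (first nonzero L
    negative), ``subcritical`` (positive), ``degenerate-to-order-k`` when
    ``L_1..L_k`` vanish but a later one does not, or ``undetermined`` when
    all computed focal values vanish.
    """
    if isinstance(parameter, str):
        matches = [s for s in family.free_symbols() if s.name == parameter]
        if not matches:
            raise ValueError(f"family has no parameter named {parameter!r}")
        param = matches[0]
    else:
        param = parameter
    inst = family.subs({param: sp.sympify(value)})
    tr = sp.simplify(inst.trace())
    trace_zero = _is_zero(tr)
    if trace_zero is False:
        raise ValueError(f"family trace does not vanish at {parameter}={value}")
    seq = focal_values(inst, k_max=k_max)
    first = None
    sign = 0
    for idx, lv in enumerate(seq.L, start=1):
        z = _is_zero(lv)
        if z is True:
            continue
        first = idx
        sign = 1 if complex(lv).real > 0 else -1
        break
    if first is None:
        verdict = "undetermined"
    elif first == 1:
        verdict = "subcritical" if sign > 0 else "supercritical"
    else:
        verdict = f"degenerate-to-order-{first - 1}"
    return {
        "trace_zero": bool(trace_zero),
        "first_nonzero_L": (first, sign),
        "L": seq.L,
        "omega": seq.omega,
        "verdict": verdict,
    }
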