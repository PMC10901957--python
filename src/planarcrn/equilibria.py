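"""Positive equilibria, scaling to (1, 1), and Jacobian reports.

Three network classes are supported: the directed 4-cycle ("quadrangle"),
the chain of three reactions, and three disjoint reactions.  For the chain
and the three-reaction class the equilibrium solves a binomial system
exactly (a 2x2 linear solve in log coordinates); for the quadrangle a
damped Newton iteration in log coordinates is used, with existence and
uniqueness supplied by the deficiency-one theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import sympy as sp

from planarcrn.network_model import (
    ExponentPoint,
    MassActionSystem,
    NetworkError,
    PowerLawField,
    ReactionNetwork,
    mass_action_field,
)

__all__ = [
    "ChainGeometry",
    "EquilibriumReport",
    "ScaledSystem",
    "JacobianReport",
    "chain_order",
    "chain_geometry",
    "chain_equilibrium",
    "three_reaction_equilibrium",
    "quadrangle_equilibrium",
    "scale_to_unit",
    "jacobian_report",
    "trace_sign_condition_quadrangle_31",
    "classify_network",
]

_RESIDUAL_TOL = 1e-12
_CONSISTENCY_TOL = 1e-10


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ChainGeometry:
    """Signed-area data of a chain ``P1 -> P2 -> P3 -> P4``.

    ``h = (h1, h2, h3, h4)`` where ``h1 = D(243)``, ``h2 = D(134)``,
    ``h3 = D(142)``, ``h4 = D(123)`` and ``D(ijk)`` is twice the signed
    area of the triangle ``Pi Pj Pk``.  Always ``h1+h2+h3+h4 == 0``.
    """

    points: tuple[ExponentPoint, ...]
    h: tuple[sp.Expr, sp.Expr, sp.Expr, sp.Expr]

    def delta(self, i: int, j: int, k: int) -> sp.Expr:
        """Twice the signed area of triangle ``Pi Pj Pk`` (1-based)."""
        pi, pj, pk = (self.points[n - 1] for n in (i, j, k))
        return sp.expand(
            (pj.a - pi.a) * (pk.b - pi.b) - (pj.b - pi.b) * (pk.a - pi.a)
        )


@dataclass(frozen=True)
class EquilibriumReport:
    exists: bool
    point: Optional[tuple[sp.Expr, sp.Expr]]
    certificate: dict
    kappa_independent: bool

    def point_floats(self) -> tuple[float, float]:
        assert self.point is not None
        return float(self.point[0]), float(self.point[1])


@dataclass(frozen=True)
class ScaledSystem:
    """A system scaled so the positive equilibrium sits at ``(1, 1)``.

    The field is ``xdot = sum_i c_i kbar_i x^a_i y^b_i`` and
    ``ydot = K * sum_i d_i kbar_i x^a_i y^b_i``.  ``kind`` records the
    network class ("chain3", "quadrangle_cycle", "three_reactions", or
    "generic"); ``meta`` carries class data such as the chain h-vector or
    the fixture name and parameters.
    """

    sources: tuple[ExponentPoint, ...]
    cvec: tuple[sp.Expr, ...]
    dvec: tuple[sp.Expr, ...]
    kbar: tuple[sp.Expr, ...]
    K: sp.Expr
    lam: Optional[sp.Expr]
    kind: str = "generic"
    meta: dict = dc_field(default_factory=dict)

    def n_reactions(self) -> int:
        return len(self.sources)

    def xdot_coeff(self, i: int) -> sp.Expr:
        return self.cvec[i] * self.kbar[i]

    def ydot_coeff(self, i: int) -> sp.Expr:
        return self.K * self.dvec[i] * self.kbar[i]

    def field(self) -> PowerLawField:
        dx = [(self.xdot_coeff(i), self.sources[i]) for i in range(self.n_reactions())]
        dy = [(self.ydot_coeff(i), self.sources[i]) for i in range(self.n_reactions())]
        return PowerLawField(dx, dy)

    def exprs(self, x: sp.Symbol, y: sp.Symbol) -> tuple[sp.Expr, sp.Expr]:
        return self.field().exprs(x, y)

    def jacobian(self) -> sp.Matrix:
        """Jacobian of the scaled field at ``(1, 1)``."""
        j11 = sp.Add(*[self.xdot_coeff(i) * self.sources[i].a for i in range(self.n_reactions())])
        j12 = sp.Add(*[self.xdot_coeff(i) * self.sources[i].b for i in range(self.n_reactions())])
        j21 = sp.Add(*[self.ydot_coeff(i) * self.sources[i].a for i in range(self.n_reactions())])
        j22 = sp.Add(*[self.ydot_coeff(i) * self.sources[i].b for i in range(self.n_reactions())])
        return sp.Matrix([[j11, j12], [j21, j22]])

    def trace(self) -> sp.Expr:
        j = self.jacobian()
        return sp.expand(j[0, 0] + j[1, 1])

    def det(self) -> sp.Expr:
        j = self.jacobian()
        return sp.expand(j[0, 0] * j[1, 1] - j[0, 1] * j[1, 0])

    def subs(self, mapping) -> "ScaledSystem":
        s = lambda e: sp.sympify(e).subs(mapping) if e is not None else None
        return ScaledSystem(
            tuple(ExponentPoint(s(p.a), s(p.b)) for p in self.sources),
            tuple(s(c) for c in self.cvec),
            tuple(s(d) for d in self.dvec),
            tuple(s(k) for k in self.kbar),
            s(self.K),
            s(self.lam),
            self.kind,
            dict(self.meta),
        )

    def free_symbols(self) -> set:
        syms = set()
        for e in (*self.cvec, *self.dvec, *self.kbar, self.K):
            syms |= sp.sympify(e).free_symbols
        for p in self.sources:
            syms |= sp.sympify(p.a).free_symbols | sp.sympify(p.b).free_symbols
        return syms

    def vanishes_at_unit(self) -> bool:
        ex = sp.simplify(sp.Add(*[self.xdot_coeff(i) for i in range(self.n_reactions())]))
        ey = sp.simplify(sp.Add(*[self.ydot_coeff(i) for i in range(self.n_reactions())]))
        return ex == 0 and ey == 0


@dataclass(frozen=True)
class JacobianReport:
    J: sp.Matrix
    trace: sp.Expr
    det: sp.Expr
    closed_form_det: Optional[sp.Expr] = None


# ---------------------------------------------------------------------------
# class detection helpers


def classify_network(net: ReactionNetwork) -> str:
    """Best-effort classification into the three studied network classes."""
    edges = net.edges
    if len(edges) == 4 and net.m == 4:
        # directed 4-cycle?
        succ = dict(edges)
        if len(succ) == 4:
            node = edges[0][0]
            seen = []
            for _ in range(4):
                seen.append(node)
                node = succ.get(node)
                if node is None:
                    break
            if node == edges[0][0] and len(set(seen)) == 4:
                return "quadrangle_cycle"
    if len(edges) == 3 and net.m == 4:
        if chain_order(net) is not None:
            return "chain3"
    if len(edges) == 3:
        srcs = [i for i, _ in edges]
        if len(set(srcs)) == 3:
            # three reactions with distinct sources (targets may coincide
            # with other sources, e.g. 0 -> -Y feeding the -Y source)
            return "three_reactions"
    return "generic"


def chain_order(net: ReactionNetwork) -> Optional[list[int]]:
    """Vertex indices in chain order ``P1 -> P2 -> P3 -> P4``, or None."""
    if len(net.edges) != 3 or net.m != 4:
        return None
    succ = {}
    indeg = {i: 0 for i in range(net.m)}
    for i, j in net.edges:
        if i in succ:
            return None
        succ[i] = j
        indeg[j] += 1
    starts = [i for i in range(net.m) if indeg[i] == 0 and i in succ]
    if len(starts) != 1:
        return None
    order = [starts[0]]
    while order[-1] in succ:
        order.append(succ[order[-1]])
    return order if len(order) == 4 else None


def _cycle_order(net: ReactionNetwork) -> list[int]:
    succ = dict(net.edges)
    node = net.edges[0][0]
    order = []
    for _ in range(4):
        order.append(node)
        node = succ[node]
    return order


# ---------------------------------------------------------------------------
# chain geometry and equilibrium


def _delta(pi: ExponentPoint, pj: ExponentPoint, pk: ExponentPoint) -> sp.Expr:
    return sp.expand((pj.a - pi.a) * (pk.b - pi.b) - (pj.b - pi.b) * (pk.a - pi.a))


def chain_geometry(net_or_points) -> ChainGeometry:
    """Exact h-vector of a chain of three reactions."""
    if isinstance(net_or_points, ReactionNetwork):
        order = chain_order(net_or_points)
        if order is None:
            raise NetworkError("not a chain of three reactions")
        pts = tuple(net_or_points.vertices[i] for i in order)
    else:
        pts = tuple(
            p if isinstance(p, ExponentPoint) else ExponentPoint(*p) for p in net_or_points
        )
        if len(pts) != 4:
            raise NetworkError("chain geometry needs exactly 4 points")
    p1, p2, p3, p4 = pts
    if _delta(p1, p2, p3) == 0:
        raise NetworkError("P1, P2, P3 are collinear (degenerate chain)")
    h = (
        _delta(p2, p4, p3),
        _delta(p1, p3, p4),
        _delta(p1, p4, p2),
        _delta(p1, p2, p3),
    )
    return ChainGeometry(pts, h)


def _sign(e: sp.Expr) -> int:
    s = sp.sign(e)
    if s.is_number:
        return int(s)
    raise ValueError(f"cannot determine sign of {e}")


def _solve_binomial(
    e1: tuple[sp.Expr, sp.Expr], e2: tuple[sp.Expr, sp.Expr], r1: sp.Expr, r2: sp.Expr
) -> tuple[sp.Expr, sp.Expr]:
    """Solve ``x^e1[0] y^e1[1] = r1``, ``x^e2[0] y^e2[1] = r2`` for x, y > 0.

    Exact: the 2x2 linear system in ``(log x, log y)`` is inverted with the
    rational exponent matrix, so the solution is a product of rational
    powers of the right-hand sides.
    """
    m = sp.Matrix([[e1[0], e1[1]], [e2[0], e2[1]]])
    if m.det() == 0:
        raise NetworkError("binomial system is degenerate (exponents dependent)")
    minv = m.inv()
    x = sp.powsimp(r1 ** minv[0, 0] * r2 ** minv[0, 1])
    y = sp.powsimp(r1 ** minv[1, 0] * r2 ** minv[1, 1])
    return (x, y)


def _field_residual(field: PowerLawField, x: float, y: float) -> float:
    fx, fy = field(x, y)
    sx = sum(abs(float(t.coeff)) * float(sp.Float(x) ** t.expo.a * sp.Float(y) ** t.expo.b)
             for t in field.dx_terms) or 1.0
    sy = sum(abs(float(t.coeff)) * float(sp.Float(x) ** t.expo.a * sp.Float(y) ** t.expo.b)
             for t in field.dy_terms) or 1.0
    return max(abs(fx) / sx, abs(fy) / sy)


def chain_equilibrium(sys: MassActionSystem) -> EquilibriumReport:
    """Existence and exact location of the positive equilibrium of a chain.

    A positive equilibrium exists iff ``h1``, ``h1+h2`` and ``h1+h2+h3``
    share a common nonzero sign; existence is independent of the rate
    constants.  When it exists, the equilibrium solves the binomial system

        (h1+h2+h3) k1 x^a1 y^b1 = h1 k3 x^a3 y^b3
        (h1+h2)    k1 x^a1 y^b1 = h1 k2 x^a2 y^b2
    """
    net = sys.network
    order = chain_order(net)
    if order is None:
        raise NetworkError("not a chain of three reactions")
    geom = chain_geometry(net)
    h1, h2, h3, _ = geom.h
    s = [h1, h1 + h2, h1 + h2 + h3]
    signs = [_sign(e) for e in s]
    cert = {"h": geom.h, "partial_sums": tuple(s), "signs": tuple(signs)}
    if 0 in signs or len(set(signs)) != 1:
        return EquilibriumReport(False, None, cert, True)
    # rate constants in chain order
    kappa = {e: k for e, k in zip(net.edges, sys.kappa)}
    k1 = kappa[(order[0], order[1])]
    k2 = kappa[(order[1], order[2])]
    k3 = kappa[(order[2], order[3])]
    p1, p2, p3, _ = geom.points
    r1 = (h1 + h2 + h3) * k1 / (h1 * k3)
    r2 = (h1 + h2) * k1 / (h1 * k2)
    point = _solve_binomial(
        (p3.a - p1.a, p3.b - p1.b), (p2.a - p1.a, p2.b - p1.b), r1, r2
    )
    if not sys.network.vertices or _has_symbols(sys):
        return EquilibriumReport(True, point, cert, True)
    res = _field_residual(mass_action_field(sys), *map(float, point))
    if res > _RESIDUAL_TOL:
        raise RuntimeError(f"equilibrium residual {res} exceeds tolerance")
    return EquilibriumReport(True, point, cert, True)


def _has_symbols(sys: MassActionSystem) -> bool:
    for k in sys.kappa:
        if sp.sympify(k).free_symbols:
            return True
    for v in sys.network.vertices:
        if sp.sympify(v.a).free_symbols or sp.sympify(v.b).free_symbols:
            return True
    return False


def three_reaction_equilibrium(sys: MassActionSystem) -> EquilibriumReport:
    """Equilibrium of three disjoint reactions via the cross-product signs."""
    net = sys.network
    if classify_network(net) != "three_reactions":
        raise NetworkError("not a system of three disjoint reactions")
    srcs = [net.vertices[i] for i, _ in net.edges]
    vecs = [net.reaction_vector(e) for e in net.edges]
    (c1, d1), (c2, d2), (c3, d3) = vecs
    if _delta(srcs[0], srcs[1], srcs[2]) == 0:
        raise NetworkError("reaction sources are collinear (degenerate)")
    cross = (c2 * d3 - c3 * d2, c3 * d1 - c1 * d3, c1 * d2 - c2 * d1)
    signs = [_sign(e) for e in cross]
    cert = {"cross_products": cross, "signs": tuple(signs)}
    if 0 in signs or len(set(signs)) != 1:
        return EquilibriumReport(False, None, cert, True)
    k1, k2, k3 = sys.kappa
    a1, b1 = srcs[0].as_tuple()
    a2, b2 = srcs[1].as_tuple()
    a3, b3 = srcs[2].as_tuple()
    r1 = cross[2] * k1 / (cross[0] * k3)   # x^(a3-a1) y^(b3-b1)
    r2 = cross[1] * k1 / (cross[0] * k2)   # x^(a2-a1) y^(b2-b1)
    point = _solve_binomial((a3 - a1, b3 - b1), (a2 - a1, b2 - b1), r1, r2)
    if not _has_symbols(sys):
        res = _field_residual(mass_action_field(sys), *map(float, point))
        if res > _RESIDUAL_TOL:
            raise RuntimeError(f"equilibrium residual {res} exceeds tolerance")
    return EquilibriumReport(True, point, cert, True)


def quadrangle_equilibrium(sys: MassActionSystem, tol: float = 1e-14, max_iter: int = 100) -> EquilibriumReport:
    """Unique positive equilibrium of a directed 4-cycle, by damped Newton.

    The iteration runs in ``(log x, log y)`` starting from the origin
    (i.e. ``x = y = 1``) with step damping 0.5 whenever the residual does
    not decrease.  Existence and uniqueness are guaranteed by theory, so
    non-convergence signals an implementation bug rather than absence.
    """
    net = sys.network
    if classify_network(net) != "quadrangle_cycle":
        raise NetworkError("not a quadrangle cycle")
    fld = mass_action_field(sys)
    fx, fy = fld.exprs()
    x, y = sp.symbols("x y", positive=True)
    if (fx.free_symbols | fy.free_symbols) - {x, y}:
        raise NetworkError("quadrangle Newton solver needs numeric rate constants")
    # normalize each component by the sum of term magnitudes; the absolute
    # residual decays spuriously toward the quadrant boundary, the relative
    # one does not
    sx = sp.Add(*[abs(sp.Float(t.coeff)) * x ** t.expo.a * y ** t.expo.b for t in fld.dx_terms])
    sy = sp.Add(*[abs(sp.Float(t.coeff)) * x ** t.expo.a * y ** t.expo.b for t in fld.dy_terms])
    gx, gy = fx / sx, fy / sy
    jac = sp.Matrix([[sp.diff(gx, x), sp.diff(gx, y)], [sp.diff(gy, x), sp.diff(gy, y)]])
    f_num = sp.lambdify((x, y), [gx, gy], modules="math")
    j_num = sp.lambdify((x, y), jac.tolist(), modules="math")

    u = [0.0, 0.0]

    def residual(u):
        vx, vy = f_num(math.exp(u[0]), math.exp(u[1]))
        return max(abs(vx), abs(vy))

    for _ in range(max_iter):
        ex, ey = math.exp(u[0]), math.exp(u[1])
        vx, vy = f_num(ex, ey)
        if residual(u) < tol:
            break
        jm = j_num(ex, ey)
        # chain rule for log coordinates: d/du = x*d/dx
        a11, a12 = jm[0][0] * ex, jm[0][1] * ey
        a21, a22 = jm[1][0] * ex, jm[1][1] * ey
        det = a11 * a22 - a12 * a21
        if det == 0:
            raise RuntimeError("singular Jacobian in Newton iteration")
        du = [-(a22 * vx - a12 * vy) / det, -(-a21 * vx + a11 * vy) / det]
        step = 1.0
        while step > 1e-12:
            cand = [u[0] + step * du[0], u[1] + step * du[1]]
            if residual(cand) < residual(u):
                u = cand
                break
            step *= 0.5
        else:
            raise RuntimeError("Newton damping failed to reduce residual")
    else:
        raise RuntimeError("Newton iteration did not converge")
    point = (sp.Float(math.exp(u[0]), 17), sp.Float(math.exp(u[1]), 17))
    res = _field_residual(fld, float(point[0]), float(point[1]))
    if res > 1e-10:
        raise RuntimeError(f"equilibrium residual {res} exceeds tolerance")
    cert = {"method": "damped-newton-log", "residual": res}
    return EquilibriumReport(True, point, cert, True)


# ---------------------------------------------------------------------------
# scaling and Jacobian


def scale_to_unit(sys: MassActionSystem, eq) -> ScaledSystem:
    """Scale a system so its positive equilibrium moves to ``(1, 1)``.

    Per reaction ``i`` with source ``(a_i, b_i)``:
    ``kbar_i = kappa_i * xbar^a_i * ybar^b_i`` and ``K = xbar/ybar``.  The
    scaled field is ``xdot = sum c_i kbar_i x^a_i y^b_i``,
    ``ydot = K sum d_i kbar_i x^a_i y^b_i``.  ``lam`` is recovered from the
    class-specific proportionality of ``kbar`` to the geometric data, with
    a consistency check across all three relations.
    """
    if isinstance(eq, EquilibriumReport):
        if not eq.exists:
            raise NetworkError("cannot scale: no positive equilibrium")
        eq = eq.point
    xbar, ybar = (sp.sympify(e) for e in eq)
    net = sys.network
    kind = classify_network(net)
    edge_seq = list(net.edges)
    if kind == "chain3":
        order = chain_order(net)
        edge_seq = [(order[i], order[i + 1]) for i in range(3)]
    elif kind == "quadrangle_cycle":
        cyc = _cycle_order(net)
        edge_seq = [(cyc[i], cyc[(i + 1) % 4]) for i in range(4)]
    kappa = {e: k for e, k in zip(net.edges, sys.kappa)}
    sources, cvec, dvec, kbar = [], [], [], []
    for (i, j) in edge_seq:
        src = net.vertices[i]
        sources.append(src)
        va, vb = net.reaction_vector((i, j))
        cvec.append(va)
        dvec.append(vb)
        kbar.append(sp.powsimp(kappa[(i, j)] * xbar ** src.a * ybar ** src.b))
    K = sp.powsimp(xbar / ybar)
    meta: dict = {"equilibrium": (xbar, ybar)}
    lam = None
    if kind == "chain3":
        geom = chain_geometry(net)
        h1, h2, h3, _ = geom.h
        sums = [h1, h1 + h2, h1 + h2 + h3]
        lam = _recover_lambda(kbar, sums)
        meta["h"] = geom.h
    elif kind == "three_reactions":
        (c1, d1), (c2, d2), (c3, d3) = zip(cvec, dvec)
        cross = [c2 * d3 - c3 * d2, c3 * d1 - c1 * d3, c1 * d2 - c2 * d1]
        lam = _recover_lambda(kbar, cross)
        meta["cross_products"] = tuple(cross)
    scaled = ScaledSystem(
        tuple(sources), tuple(cvec), tuple(dvec), tuple(kbar), K, lam, kind, meta
    )
    _check_vanishes(scaled)
    return scaled


def _num_small(e: sp.Expr, tol: float) -> bool:
    """Numeric smallness check that avoids simplify on radical monsters."""
    try:
        return abs(complex(sp.sympify(e).evalf(30))) < tol
    except (TypeError, ValueError):
        return False


def _recover_lambda(kbar: Sequence[sp.Expr], denoms: Sequence[sp.Expr]) -> sp.Expr:
    vals = [kb / dn for kb, dn in zip(kbar, denoms) if dn != 0]
    if not vals:
        raise NetworkError("cannot recover lambda: all geometric factors vanish")
    lam = sp.powsimp(vals[0])
    for v in vals[1:]:
        diff = v - lam
        if not diff.free_symbols:
            scale = max(1.0, abs(complex(sp.sympify(lam).evalf(30))))
            if not _num_small(diff, _CONSISTENCY_TOL * scale):
                raise RuntimeError(
                    "lambda-consistency violated (wrong equilibrium passed to scale_to_unit?)"
                )
        elif sp.simplify(diff) != 0:
            raise RuntimeError("lambda-consistency violated symbolically")
    if lam.free_symbols:
        lam = sp.simplify(lam)
    return lam


def _check_vanishes(scaled: ScaledSystem) -> None:
    ex = sp.Add(*[scaled.xdot_coeff(i) for i in range(scaled.n_reactions())])
    ey = sp.Add(*[scaled.ydot_coeff(i) for i in range(scaled.n_reactions())])
    for e in (ex, ey):
        if e.free_symbols:
            if sp.simplify(e) != 0:
                raise RuntimeError("scaled field does not vanish at (1, 1)")
        elif not _num_small(e, 1e-9):
            raise RuntimeError("scaled field does not vanish at (1, 1)")


def jacobian_report(scaled: ScaledSystem) -> JacobianReport:
    """Jacobian at ``(1, 1)`` with a closed-form determinant cross-check."""
    j = scaled.jacobian()
    tr = sp.expand(j[0, 0] + j[1, 1])
    det = sp.expand(j[0, 0] * j[1, 1] - j[0, 1] * j[1, 0])
    closed = None
    if scaled.kind == "chain3" and scaled.lam is not None and "h" in scaled.meta:
        h1, h2, h3, _ = scaled.meta["h"]
        closed = (h1 + h2 + h3) / scaled.lam * scaled.K * sp.Mul(*scaled.kbar)
    elif scaled.kind == "three_reactions" and scaled.lam is not None:
        (a1, b1), (a2, b2), (a3, b3) = (s.as_tuple() for s in scaled.sources)
        bracket = a1 * (b2 - b3) + a2 * (b3 - b1) + a3 * (b1 - b2)
        closed = scaled.K * sp.Mul(*scaled.kbar) * bracket / scaled.lam
    if closed is not None:
        diff = det - closed
        if diff.free_symbols:
            if sp.simplify(diff) != 0:
                raise RuntimeError("determinant closed-form mismatch (symbolic)")
        else:
            scale = max(1.0, abs(complex(sp.sympify(det).evalf(30))))
            if not _num_small(diff, _CONSISTENCY_TOL * scale):
                raise RuntimeError("determinant closed-form mismatch")
    return JacobianReport(j, tr, det, closed)


def trace_sign_condition_quadrangle_31(kappa) -> bool:
    """Positivity test for the trace of the first quadrangle example.

    ``sqrt(k1/k2) > sqrt(k3/k4) + 6*sqrt(k4/k3)``.
    """
    k1, k2, k3, k4 = (sp.sympify(k) for k in kappa)
    lhs = sp.sqrt(k1 / k2)
    rhs = sp.sqrt(k3 / k4) + 6 * sp.sqrt(k4 / k3)
    diff = lhs - rhs
    if diff.is_number:
        return bool(diff > 0)
    raise ValueError("rate constants must be numeric")
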