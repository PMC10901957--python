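"""Built-in constructors for every worked example.

Each fixture reproduces a displayed system: either an unscaled mass-action
system (``quadrangle_3_1``, ``zigzag``, and the ``*_network`` variants) or
the scaled family with equilibrium at ``(1, 1)`` (``quadrangle_3_2``,
``chain_4_1``, ``reversible_chain_4_2``, ``three_reactions_5_1``,
``reversible_5_2``, ``lienard_5_3``).  Family parameters left unspecified
stay symbolic.
"""

from __future__ import annotations

from typing import Optional

import sympy as sp

from planarcrn.network_model import (
    ExponentPoint,
    MassActionSystem,
    ReactionNetwork,
)
from planarcrn.equilibria import ScaledSystem

__all__ = ["paper_fixture", "FIXTURE_NAMES", "FixtureDomainError"]


class FixtureDomainError(ValueError):
    """Parameter outside the fixture's stated domain."""


_K, _gamma, _q, _r, _p, _a, _b, _d, _kap = sp.symbols(
    "K gamma q r p a b d kappa", positive=True
)


def _sym(params, name, default):
    v = params.pop(name, None)
    if v is None:
        return default
    return sp.sympify(v)


def _check(cond, msg):
    # Only reject when the violation is decidable (numeric parameters).
    if cond is False or cond == False:  # noqa: E712 - sympy booleans
        raise FixtureDomainError(msg)


def _pos(e) -> Optional[bool]:
    e = sp.sympify(e)
    if e.is_number:
        return bool(e > 0)
    return None


# ---------------------------------------------------------------------------


def quadrangle_3_1(kappa=None) -> MassActionSystem:
    """Directed 4-cycle on (0,1), (1,0), (1,2), (0,3)."""
    if kappa is None:
        kappa = sp.symbols("kappa_1:5", positive=True)
    net = ReactionNetwork(
        [(0, 1), (1, 0), (1, 2), (0, 3)], [(0, 1), (1, 2), (2, 3), (3, 0)]
    )
    return MassActionSystem(net, list(kappa))


def quadrangle_3_2(K=None, gamma=None, b4=None) -> ScaledSystem:
    """Scaled 4-cycle family on (0,1), (0,0), (1,2), (1,b4); b4 defaults to 5.

    xdot = 1 - x*y^b4,
    ydot = K*[-gamma*y + 2 + (gamma+b4-3)*x*y^2 + (1-b4)*x*y^b4].
    """
    K = _K if K is None else sp.sympify(K)
    gamma = _gamma if gamma is None else sp.sympify(gamma)
    b4 = sp.Integer(5) if b4 is None else sp.sympify(b4)
    _check(sp.sympify(b4 > 2), "b4 must exceed 2")
    _check(sp.sympify(K > 0) if K.is_number else None, "K must be positive")
    sources = (
        ExponentPoint(0, 1),
        ExponentPoint(0, 0),
        ExponentPoint(1, 2),
        ExponentPoint(1, b4),
    )
    cvec = (sp.Integer(0), sp.Integer(1), sp.Integer(0), sp.Integer(-1))
    dvec = (sp.Integer(-1), sp.Integer(2), b4 - 2, 1 - b4)
    kbar = (gamma, sp.Integer(1), (gamma + b4 - 3) / (b4 - 2), sp.Integer(1))
    return ScaledSystem(
        sources, cvec, dvec, kbar, K, None, "quadrangle_cycle",
        {"family": "quadrangle_3_2", "params": {"K": K, "gamma": gamma, "b4": b4}},
    )


def quadrangle_3_2_network(kappa=None, b4=None) -> MassActionSystem:
    """Unscaled 4-cycle on (0,1), (0,0), (1,2), (1,b4)."""
    if kappa is None:
        kappa = sp.symbols("kappa_1:5", positive=True)
    b4 = sp.Integer(5) if b4 is None else sp.sympify(b4)
    net = ReactionNetwork(
        [(0, 1), (0, 0), (1, 2), (1, b4)], [(0, 1), (1, 2), (2, 3), (3, 0)]
    )
    return MassActionSystem(net, list(kappa))


def chain_4_1(q=None, r=None, K=None) -> ScaledSystem:
    """Scaled chain family with lambda = -1/q:

    xdot = y^(-q) - x*y^(1/2),
    ydot = K*[-(q+r+1/2) + (q+1/2)*y^(-q) + r*x*y^(1/2)].
    """
    q = _q if q is None else sp.sympify(q)
    r = _r if r is None else sp.sympify(r)
    K = _K if K is None else sp.sympify(K)
    for name, v in (("q", q), ("r", r), ("K", K)):
        _check(_pos(v), f"{name} must be positive")
    half = sp.Rational(1, 2)
    sources = (
        ExponentPoint(0, 0),
        ExponentPoint(0, -q),
        ExponentPoint(1, half),
    )
    cvec = (sp.Integer(0), sp.Integer(1), sp.Integer(-1))
    dvec = (-q, q + half, r)
    kbar = ((q + r + half) / q, sp.Integer(1), sp.Integer(1))
    h = (-(q + r + half), r + half, sp.Integer(0), q)
    return ScaledSystem(
        sources, cvec, dvec, kbar, K, -1 / q, "chain3",
        {"family": "chain_4_1", "params": {"q": q, "r": r, "K": K}, "h": h},
    )


def chain_4_1_network(q, r, kappa=(1, 1, 1)) -> MassActionSystem:
    """Unscaled chain (0,0) -> (0,-q) -> (1,1/2) -> (0,1/2+r)."""
    q, r = sp.sympify(q), sp.sympify(r)
    for name, v in (("q", q), ("r", r)):
        _check(_pos(v), f"{name} must be positive")
    half = sp.Rational(1, 2)
    net = ReactionNetwork(
        [(0, 0), (0, -q), (1, half), (0, half + r)], [(0, 1), (1, 2), (2, 3)]
    )
    return MassActionSystem(net, list(kappa))


def reversible_chain_4_2(p, q) -> ScaledSystem:
    """Scaled reversible-center chain family:

    xdot = (p-q) + q*x^p*y^q - p*x^q*y^p,
    ydot = (q-p) + p*x^p*y^q - q*x^q*y^p.

    Requires p*q < 0 and p + q != 0.
    """
    p, q = sp.sympify(p), sp.sympify(q)
    if (p * q).is_number:
        _check(sp.sympify(p * q < 0), "need p*q < 0")
        _check(sp.sympify(sp.Ne(p + q, 0)), "need p + q != 0")
    K = -p / q
    sources = (ExponentPoint(0, 0), ExponentPoint(p, q), ExponentPoint(q, p))
    cvec = (p, q - p, -p)
    dvec = (q, p - q, q ** 2 / p)
    kbar = ((p - q) / p, -q / (p - q), sp.Integer(1))
    h = (
        sp.expand(-((p - q) ** 2) * (p + q) / p),
        sp.expand((p + q) * (p ** 2 - p * q + q ** 2) / p),
        sp.expand(-p * (p + q)),
        sp.expand(p ** 2 - q ** 2),
    )
    return ScaledSystem(
        sources, cvec, dvec, kbar, K, -1 / (p ** 2 - q ** 2), "chain3",
        {"family": "reversible_chain_4_2", "params": {"p": p, "q": q}, "h": h},
    )


def reversible_chain_4_2_network(p, q, kappa=None) -> MassActionSystem:
    """Unscaled chain (0,0) -> (p,q) -> (q,p) -> (q-p, p+q^2/p)."""
    p, q = sp.sympify(p), sp.sympify(q)
    if (p * q).is_number:
        _check(sp.sympify(p * q < 0), "need p*q < 0")
        _check(sp.sympify(sp.Ne(p + q, 0)), "need p + q != 0")
    if kappa is None:
        kappa = sp.symbols("kappa_1:4", positive=True)
    net = ReactionNetwork(
        [(0, 0), (p, q), (q, p), (q - p, p + q ** 2 / p)], [(0, 1), (1, 2), (2, 3)]
    )
    return MassActionSystem(net, list(kappa))


def three_reactions_5_1(a=None, b=None, d=None, K=None) -> ScaledSystem:
    """Scaled three-reaction family (lambda = 1):

    xdot = 1/y - x^a*y^b,
    ydot = K*(-(d-1) - 1/y + d*x^a*y^b).

    Domain: a > 0, b > -1, d > 0, 1 + b*d > 0 (positive kbar needs d > 1).
    """
    a = _a if a is None else sp.sympify(a)
    b = _b if b is None else sp.sympify(b)
    d = _d if d is None else sp.sympify(d)
    K = _K if K is None else sp.sympify(K)
    if a.is_number:
        _check(sp.sympify(a > 0), "need a > 0")
    if b.is_number:
        _check(sp.sympify(b > -1), "need b > -1")
    if d.is_number:
        _check(sp.sympify(d > 0), "need d > 0")
    if b.is_number and d.is_number:
        _check(sp.sympify(1 + b * d > 0), "need 1 + b*d > 0")
    sources = (ExponentPoint(0, 0), ExponentPoint(0, -1), ExponentPoint(a, b))
    cvec = (sp.Integer(0), sp.Integer(1), sp.Integer(-1))
    dvec = (sp.Integer(-1), sp.Integer(-1), d)
    kbar = (d - 1, sp.Integer(1), sp.Integer(1))
    return ScaledSystem(
        sources, cvec, dvec, kbar, K, sp.Integer(1), "three_reactions",
        {"family": "three_reactions_5_1", "params": {"a": a, "b": b, "d": d, "K": K}},
    )


def _kbar_from_cross(c, d, lam):
    (c1, d1), (c2, d2), (c3, d3) = zip(c, d)
    return (
        lam * (c2 * d3 - c3 * d2),
        lam * (c3 * d1 - c1 * d3),
        lam * (c1 * d2 - c2 * d1),
    )


def reversible_5_2(p, q, c, d, K=None, lam=1) -> ScaledSystem:
    """Scaled three-reaction family on sources (0,0), (p,q), (q,p)."""
    p, q = sp.sympify(p), sp.sympify(q)
    c = tuple(sp.sympify(ci) for ci in c)
    d = tuple(sp.sympify(di) for di in d)
    lam = sp.sympify(lam)
    if (abs(p) - abs(q)).is_number:
        _check(sp.sympify(sp.Ne(abs(p), abs(q))), "need |p| != |q|")
    if K is None:
        K = -c[0] / d[0]
    K = sp.sympify(K)
    kbar = _kbar_from_cross(c, d, lam)
    for kb in kbar:
        if kb.is_number:
            _check(sp.sympify(kb > 0), "kbar must be positive (check lambda sign)")
    sources = (ExponentPoint(0, 0), ExponentPoint(p, q), ExponentPoint(q, p))
    return ScaledSystem(
        sources, c, d, kbar, K, lam, "three_reactions",
        {"family": "reversible_5_2", "params": {"p": p, "q": q, "c": c, "d": d, "K": K}},
    )


def lienard_5_3(c, d, K, lam=1) -> ScaledSystem:
    """Scaled three-reaction family on sources (1,0), (0,-1/2), (0,-2)."""
    c = tuple(sp.sympify(ci) for ci in c)
    d = tuple(sp.sympify(di) for di in d)
    K, lam = sp.sympify(K), sp.sympify(lam)
    kbar = _kbar_from_cross(c, d, lam)
    for kb in kbar:
        if kb.is_number:
            _check(sp.sympify(kb > 0), "kbar must be positive (check lambda sign)")
    sources = (
        ExponentPoint(1, 0),
        ExponentPoint(0, sp.Rational(-1, 2)),
        ExponentPoint(0, -2),
    )
    return ScaledSystem(
        sources, c, d, kbar, K, lam, "three_reactions",
        {"family": "lienard_5_3", "params": {"c": c, "d": d, "K": K}},
    )


# The single-parameter "zigzag" example: unique positive equilibrium at
# ((2-kappa)**(-1/2), (2-kappa)**(1/2)) for kappa < 2, none otherwise; the
# x-axis is invariant, consists of equilibria, and attracts nearby positive
# points exactly for kappa > 1; the Jacobian trace at the equilibrium is
# 5*kappa - 9 and the Hopf point kappa = 9/5 is subcritical with
# L1 = 5*pi/13.  Reaction data reconstructed from those properties (the
# defining display is only available as a figure in the source); every one
# of them is enforced by the test suite.
_ZZ_SOURCES = ((0, 1), (0, 1), (3, 4), (0, 3), (1, 4))
_ZZ_VECTORS = (
    (sp.Rational(2246, 225), sp.Rational(1, 3)),    # unit reaction at (0,1)
    (sp.Rational(-5, 3), sp.Rational(-1, 3)),       # kappa reaction at (0,1)
    (sp.Rational(-1496, 225), sp.Rational(1, 3)),
    (sp.Rational(-5, 3), sp.Rational(-1196, 75)),
    (sp.Integer(0), sp.Rational(1171, 75)),
)


def zigzag(kappa=None) -> MassActionSystem:
    """Five-reaction network with kappa-dependent equilibrium existence."""
    kappa = _kap if kappa is None else sp.sympify(kappa)
    if kappa.is_number:
        _check(sp.sympify(kappa > 0), "kappa must be positive")
    rates = [1, kappa, 1, 1, 1]
    verts: list = []
    index: dict = {}

    def vid(pt):
        if pt not in index:
            index[pt] = len(verts)
            verts.append(pt)
        return index[pt]

    edges = []
    for src, vec in zip(_ZZ_SOURCES, _ZZ_VECTORS):
        s = (sp.Integer(src[0]), sp.Integer(src[1]))
        t = (s[0] + vec[0], s[1] + vec[1])
        edges.append((vid(s), vid(t)))
    net = ReactionNetwork(verts, edges)
    return MassActionSystem(net, rates)


def zigzag_equilibrium(kappa):
    """The positive equilibrium ((2-k)^(-1/2), (2-k)^(1/2)); None if k >= 2."""
    kappa = sp.sympify(kappa)
    if kappa.is_number and kappa >= 2:
        return None
    return (1 / sp.sqrt(2 - kappa), sp.sqrt(2 - kappa))


def zigzag_scaled(kappa) -> ScaledSystem:
    """The zigzag system scaled so the equilibrium sits at (1, 1)."""
    kappa = sp.sympify(kappa)
    eq = zigzag_equilibrium(kappa)
    if eq is None:
        raise FixtureDomainError("no positive equilibrium for kappa >= 2")
    xb, yb = eq
    rates = (1, kappa, 1, 1, 1)
    sources = tuple(ExponentPoint(*s) for s in _ZZ_SOURCES)
    cvec = tuple(v[0] for v in _ZZ_VECTORS)
    dvec = tuple(v[1] for v in _ZZ_VECTORS)
    def tidy(e):
        e = sp.powsimp(e)
        return sp.nsimplify(e) if not e.free_symbols else e

    kbar = tuple(tidy(r * xb ** s.a * yb ** s.b) for r, s in zip(rates, sources))
    return ScaledSystem(
        sources, cvec, dvec, kbar, tidy(xb / yb), None,
        "generic", {"family": "zigzag", "params": {"kappa": kappa}},
    )


_FIXTURES = {
    "quadrangle_3_1": quadrangle_3_1,
    "quadrangle_3_2": quadrangle_3_2,
    "quadrangle_3_2_network": quadrangle_3_2_network,
    "chain_4_1": chain_4_1,
    "chain_4_1_network": chain_4_1_network,
    "reversible_chain_4_2": reversible_chain_4_2,
    "reversible_chain_4_2_network": reversible_chain_4_2_network,
    "three_reactions_5_1": three_reactions_5_1,
    "reversible_5_2": reversible_5_2,
    "lienard_5_3": lienard_5_3,
    "zigzag": zigzag,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def paper_fixture(name: str, **params):
    """Dispatch to the named fixture constructor."""
    try:
        ctor = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return ctor(**params)
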