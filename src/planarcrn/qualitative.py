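"""Center and global-stability certificates.

Three mechanisms are implemented: the monomial Bendixson-Dulac test for the
4-cycle (global stability for all rate constants), time-reversal symmetry
across ``x = y`` (reversible centers), and the Lienard composition
condition ``F = Phi o G`` for the three-reaction pattern with sources
``(1,0), (0,-1/2), (0,-2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import sympy as sp

from planarcrn.network_model import (
    MassActionSystem,
    PowerLawField,
    ReactionNetwork,
    mass_action_field,
)
from planarcrn.equilibria import ScaledSystem, _cycle_order, classify_network
from planarcrn import fixtures

__all__ = [
    "DulacCertificate",
    "CenterCertificate",
    "CertificateFailure",
    "dulac_exponent_interval",
    "dulac_test_quadrangle",
    "reversibility_check",
    "reversible_center_three_reactions",
    "center_rate_constants",
    "lienard_transform",
    "lienard_center_check",
]


@dataclass(frozen=True)
class DulacCertificate:
    alpha_interval: Optional[tuple]  # (lo, hi) with +-oo, or None if empty
    beta_interval: Optional[tuple]
    chosen: Optional[tuple]          # (alpha, beta) or None
    verdict: str                     # "globally_stable_all_kappa" | "inconclusive"
    bad_pattern_a: Optional[int]     # 1-based cyclic index of the Prop-1 pattern, or None
    bad_pattern_b: Optional[int]


@dataclass(frozen=True)
class CenterCertificate:
    kind: str  # "reversible" | "lienard"
    details: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class CertificateFailure:
    condition: str
    details: dict = dc_field(default_factory=dict)

    def __bool__(self) -> bool:
        return False


# ---------------------------------------------------------------------------
# Bendixson-Dulac for the quadrangle


def dulac_exponent_interval(seq) -> tuple[Optional[tuple], bool]:
    """Feasible exponent interval for one coordinate of ``h = x^-a y^-b``.

    For the cyclic sequence ``a_1..a_4`` the constraints are
    ``(alpha - a_i)(a_i - a_{i+1}) <= 0``: each ascent ``a_i < a_{i+1}``
    forces ``alpha >= a_i`` and each descent forces ``alpha <= a_i``.
    Returns ``((lo, hi) or None, strict_available)`` where ``lo/hi`` may be
    ``-oo/+oo`` and ``strict_available`` says whether some choice in the
    interval makes at least one constraint strict.
    """
    a = [sp.sympify(v) for v in seq]
    n = len(a)
    lowers, uppers = [], []
    moving = False
    for i in range(n):
        nxt = a[(i + 1) % n]
        if a[i] < nxt:
            lowers.append(a[i])
            moving = True
        elif a[i] > nxt:
            uppers.append(a[i])
            moving = True
    lo = max(lowers) if lowers else -sp.oo
    hi = min(uppers) if uppers else sp.oo
    if lo > hi:
        return None, False
    if not moving:
        return (lo, hi), False  # constant sequence: no strict term possible
    # a strict term exists iff some alpha in [lo, hi] differs from an a_i
    # that participates in an ascent or descent
    participants = {a[i] for i in range(n) if a[i] != a[(i + 1) % n]}
    if lo < hi:
        strict = True  # interval has interior; avoid finitely many values
    else:
        strict = any(v != lo for v in participants)
    return (lo, hi), strict


def _choose_exponent(interval: tuple, seq) -> sp.Expr:
    lo, hi = interval
    if lo == -sp.oo and hi == sp.oo:
        return sp.S.Zero
    if lo == -sp.oo:
        return hi
    if hi == sp.oo:
        return lo
    return (lo + hi) / 2


def _strict_count(alpha, seq) -> int:
    a = [sp.sympify(v) for v in seq]
    n = len(a)
    cnt = 0
    for i in range(n):
        term = (alpha - a[i]) * (a[i] - a[(i + 1) % n])
        if term < 0:
            cnt += 1
        elif term > 0:
            raise AssertionError("chosen exponent violates a Dulac constraint")
    return cnt


def _bad_pattern(seq) -> Optional[int]:
    """1-based index ``i`` with ``a_i < a_{i+3} < a_{i+1} < a_{i+2}`` (cyclic)."""
    a = [sp.sympify(v) for v in seq]
    for i in range(4):
        if a[i] < a[(i + 3) % 4] < a[(i + 1) % 4] < a[(i + 2) % 4]:
            return i + 1
    return None


def dulac_test_quadrangle(net_or_sys) -> DulacCertificate:
    """Monomial Dulac test for the directed 4-cycle.

    If exponents ``(alpha, beta)`` exist making every divergence
    coefficient nonpositive with at least one strictly negative, the unique
    positive equilibrium is globally asymptotically stable for *all* rate
    constants.  Also reports, for each coordinate, the cyclic-order pattern
    that is necessary for periodic orbits.
    """
    net = net_or_sys.network if isinstance(net_or_sys, MassActionSystem) else net_or_sys
    if classify_network(net) != "quadrangle_cycle":
        raise ValueError("not a quadrangle cycle")
    cyc = _cycle_order(net)
    aseq = [net.vertices[i].a for i in cyc]
    bseq = [net.vertices[i].b for i in cyc]
    ia, sa = dulac_exponent_interval(aseq)
    ib, sb = dulac_exponent_interval(bseq)
    bad_a = _bad_pattern(aseq)
    bad_b = _bad_pattern(bseq)
    if ia is not None and ib is not None and (sa or sb):
        alpha = _choose_exponent(ia, aseq)
        beta = _choose_exponent(ib, bseq)
        total_strict = _strict_count(alpha, aseq) + _strict_count(beta, bseq)
        if total_strict >= 1:
            return DulacCertificate(ia, ib, (alpha, beta),
                                    "globally_stable_all_kappa", bad_a, bad_b)
    return DulacCertificate(ia, ib, None, "inconclusive", bad_a, bad_b)


# ---------------------------------------------------------------------------
# reversible centers


def reversibility_check(obj) -> bool:
    """True iff the field satisfies ``ydot(x, y) == -xdot(y, x)`` termwise."""
    field = obj if isinstance(obj, PowerLawField) else (
        obj.field() if isinstance(obj, ScaledSystem) else mass_action_field(obj)
    )
    def as_map(terms):
        out = {}
        for t in terms:
            key = t.expo.as_tuple()
            out[key] = out.get(key, sp.S.Zero) + t.coeff
        return out

    fx = as_map(field.dx_terms)
    fy = as_map(field.dy_terms)
    keys = set(fx) | {(b, a) for (a, b) in fy}
    for (a, b) in keys:
        lhs = fy.get((b, a), sp.S.Zero)
        rhs = -fx.get((a, b), sp.S.Zero)
        if sp.simplify(lhs - rhs) != 0:
            return False
    return True


def reversible_center_three_reactions(
    p, q, c, d
) -> Union[CenterCertificate, CertificateFailure]:
    """Center certificate for the three-reaction family on
    sources ``(0,0), (p,q), (q,p)``.

    Checks, in order: (i) ``p^2 > q^2``; (ii) the sign chain
    ``sgn c1 = -sgn d1 = sgn d2 = -sgn c3 != 0``; (iii) ``sgn c2 = -sgn d3``;
    then, when ``c2 != 0``, the ordering ``|d3/c3| < |d1/c1| < |d2/c2|``
    and the geometric-mean identity ``|d1/c1| = sqrt(|d2/c2|*|d3/c3|)``.
    On success sets ``K = -c1/d1``, verifies ``1/lam*K*(p^2-q^2) > 0`` and
    the coupling relations, and checks the assembled scaled field is
    reversible.
    """
    p, q = sp.sympify(p), sp.sympify(q)
    c = tuple(sp.sympify(v) for v in c)
    d = tuple(sp.sympify(v) for v in d)
    c1, c2, c3 = c
    d1, d2, d3 = d
    if not p ** 2 > q ** 2:
        return CertificateFailure("condition (i): p^2 > q^2")
    s = sp.sign(c1)
    if s == 0 or not (sp.sign(d1) == -s and sp.sign(d2) == s and sp.sign(c3) == -s):
        return CertificateFailure("condition (ii): sign chain c1, d1, d2, c3")
    if sp.sign(c2) != -sp.sign(d3):
        return CertificateFailure("condition (iii): sgn c2 = -sgn d3")
    if c2 != 0:
        r1, r2, r3 = abs(d1 / c1), abs(d2 / c2), abs(d3 / c3)
        if not (r3 < r1 < r2):
            return CertificateFailure("ordering |d3/c3| < |d1/c1| < |d2/c2|")
        if sp.simplify(r1 ** 2 - r2 * r3) != 0:
            return CertificateFailure("geometric-mean condition")
    K = -c1 / d1
    lam = sp.S.One  # the sign chain makes every cross-product positive
    cross = (c2 * d3 - c3 * d2, c3 * d1 - c1 * d3, c1 * d2 - c2 * d1)
    if not all(x > 0 for x in cross):
        return CertificateFailure("cross-product positivity (lambda sign)")
    if not (K * (p ** 2 - q ** 2) / lam) > 0:
        return CertificateFailure("K*(p^2-q^2)/lambda > 0")
    scaled = fixtures.reversible_5_2(p, q, c, d, K=K, lam=lam)
    kb = scaled.kbar
    coupling = (
        sp.simplify(c1 + K * d1),
        sp.simplify(c2 * kb[1] + K * d3 * kb[2]),
        sp.simplify(c3 * kb[2] + K * d2 * kb[1]),
    )
    if any(x != 0 for x in coupling):
        return CertificateFailure("coupling relations", {"residuals": coupling})
    if not reversibility_check(scaled):
        return CertificateFailure("assembled field is not reversible")
    return CenterCertificate(
        "reversible",
        {"K": K, "lam": lam, "kbar": kb, "coupling_residuals": coupling,
         "scaled": scaled},
    )


def center_rate_constants(p, q, c, d, kappa1=1) -> tuple:
    """Rate constants making the unscaled three-reaction system a center.

    ``kappa1`` is arbitrary; ``kappa3/kappa2 = -(c2/d3) * (-c1/d1)**(p-q-1)``.
    Returns ``(kappa1, 1, kappa3)``.
    """
    cert = reversible_center_three_reactions(p, q, c, d)
    if isinstance(cert, CertificateFailure):
        raise ValueError(f"center preconditions fail: {cert.condition}")
    p, q = sp.sympify(p), sp.sympify(q)
    c = tuple(sp.sympify(v) for v in c)
    d = tuple(sp.sympify(v) for v in d)
    ratio = -(c[1] / d[2]) * (-c[0] / d[0]) ** (p - q - 1)
    return (sp.sympify(kappa1), sp.S.One, sp.simplify(ratio))


def center_system(p, q, c, d, kappa1=1) -> MassActionSystem:
    """The unscaled mass-action system realized by :func:`center_rate_constants`."""
    k1, k2, k3 = center_rate_constants(p, q, c, d, kappa1)
    p, q = sp.sympify(p), sp.sympify(q)
    c = tuple(sp.sympify(v) for v in c)
    d = tuple(sp.sympify(v) for v in d)
    srcs = [(0, 0), (p, q), (q, p)]
    verts = list(srcs) + [
        (srcs[i][0] + c[i], srcs[i][1] + d[i]) for i in range(3)
    ]
    net = ReactionNetwork(verts, [(0, 3), (1, 4), (2, 5)])
    return MassActionSystem(net, [k1, k2, k3])


# ---------------------------------------------------------------------------
# Lienard centers

_LIENARD_PATTERN = ((1, 0), (0, sp.Rational(-1, 2)), (0, -2))


def _check_lienard_pattern(scaled: ScaledSystem) -> None:
    pat = tuple(s.as_tuple() for s in scaled.sources)
    want = tuple((sp.Integer(a), sp.sympify(b)) for a, b in _LIENARD_PATTERN)
    if pat != want:
        raise ValueError(
            "wrong exponent pattern for the Lienard transform; "
            f"need sources {want}, got {pat}"
        )


def lienard_transform(scaled: ScaledSystem) -> dict:
    """Lienard data ``f, g, F, G`` (functions of ``y``) of the shifted system.

    Differentiating the shifted ``ydot`` equation once converts the system
    into ``y'' + f(y) y' + g(y) = 0``;  ``F, G`` are the antiderivatives
    vanishing at 0.
    """
    _check_lienard_pattern(scaled)
    y = sp.Symbol("y")
    c1, c2, c3 = scaled.cvec
    d1, d2, d3 = scaled.dvec
    k1, k2, k3 = scaled.kbar
    K, lam = scaled.K, scaled.lam
    f = (
        -c1 * k1
        + sp.Rational(1, 2) * K * d2 * k2 * (y + 1) ** sp.Rational(-3, 2)
        + 2 * K * d3 * k3 * (y + 1) ** (-3)
    )
    g = K * k1 * (
        (c1 * d2 - d1 * c2) * k2 * (y + 1) ** sp.Rational(-1, 2)
        + (c1 * d3 - d1 * c3) * k3 * (y + 1) ** (-2)
    )
    F = sp.integrate(f, (y, 0, y))
    G = sp.integrate(g, (y, 0, y))
    return {"y": y, "f": f, "g": g, "F": sp.simplify(F), "G": sp.simplify(G)}


def lienard_center_check(scaled: ScaledSystem) -> Union[CenterCertificate, CertificateFailure]:
    """Composition-condition center certificate for the Lienard pattern.

    Requires ``K/lam > 0`` and ``c1*kbar1 = K*d2*kbar2 = 4*K*d3*kbar3 != 0``;
    then ``F = Phi o G`` holds with ``Phi(z) = alpha*z^2 + beta*z`` for the
    printed closed-form coefficients, which is re-verified symbolically and
    re-fitted numerically from sampled ``(G, F)`` pairs.
    """
    _check_lienard_pattern(scaled)
    c1, _, _ = scaled.cvec
    d1, d2, d3 = scaled.dvec
    k1, k2, k3 = scaled.kbar
    K, lam = scaled.K, scaled.lam
    if lam is None or not sp.simplify(K / lam).is_positive:
        return CertificateFailure("K/lambda > 0")
    t1 = sp.simplify(c1 * k1)
    t2 = sp.simplify(K * d2 * k2)
    t3 = sp.simplify(4 * K * d3 * k3)
    if t1 == 0:
        return CertificateFailure("c1*kbar1 != 0")
    if sp.simplify(t1 - t2) != 0:
        return CertificateFailure("c1*kbar1 = K*d2*kbar2", {"lhs": t1, "rhs": t2})
    if sp.simplify(t1 - t3) != 0:
        return CertificateFailure("c1*kbar1 = 4*K*d3*kbar3", {"lhs": t1, "rhs": t3})
    tr = lienard_transform(scaled)
    y, F, G = tr["y"], tr["F"], tr["G"]
    prod = K * k1 * k2 * k3
    alpha = -(lam ** 2) / 4 * (c1 * k1) / prod ** 2
    beta = -sp.Rational(3, 2) * lam * (c1 * k1) / prod
    z = sp.Symbol("z")
    phi = alpha * z ** 2 + beta * z
    # symbolic residual: substitute w = sqrt(y+1) to rationalize
    w = sp.Symbol("w", positive=True)
    resid = (F - phi.subs(z, G)).subs(y, w ** 2 - 1)
    resid = sp.simplify(sp.expand(resid))
    if resid != 0:
        return CertificateFailure("F = Phi o G composition", {"residual": resid})
    # independent numeric re-fit of (alpha, beta) by least squares
    import numpy as np

    Ff = sp.lambdify(y, F, "numpy")
    Gf = sp.lambdify(y, G, "numpy")
    ys = np.linspace(-0.4, 0.6, 50)
    gv, fv = Gf(ys), Ff(ys)
    A = np.vstack([gv ** 2, gv]).T
    fit, *_ = np.linalg.lstsq(A, fv, rcond=None)
    if abs(fit[0] - float(alpha)) > 1e-10 * max(1.0, abs(float(alpha))) or \
       abs(fit[1] - float(beta)) > 1e-10 * max(1.0, abs(float(beta))):
        return CertificateFailure("numeric Phi re-fit mismatch",
                                  {"fit": tuple(fit), "closed_form": (alpha, beta)})
    det = sp.simplify(sp.Rational(3, 2) / lam * K * k1 * k2 * k3)
    return CenterCertificate(
        "lienard",
        {"alpha": sp.simplify(alpha), "beta": sp.simplify(beta),
         "F": F, "G": G, "det": det, "scaled": scaled},
    )
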