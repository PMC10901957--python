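"""Planar reaction networks and their mass-action vector fields.

A network is a finite set of *vertices* -- points ``(a, b)`` in the plane,
read as the formal complex ``aX + bY`` -- together with directed edges
carrying positive rate constants.  Each edge ``(a_i, b_i) -> (a_j, b_j)``
with rate constant ``kappa`` contributes the power-law term
``kappa * (a_j - a_i, b_j - b_i) * x**a_i * y**b_i`` to the vector field on
the open positive quadrant.

Exponents are kept as exact SymPy rationals whenever the input is rational,
so that downstream symbolic computations (equilibria, focal values) remain
exact.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import sympy as sp

__all__ = [
    "ExponentPoint",
    "ReactionNetwork",
    "MassActionSystem",
    "PowerLawTerm",
    "PowerLawField",
    "NetworkError",
    "load_network",
    "save_network",
    "parse_reactions",
    "deficiency",
    "structure_report",
    "mass_action_field",
    "translate_network",
    "paper_fixture",
    "random_network",
]


class NetworkError(ValueError):
    """Raised for invalid network data (duplicates, bad constants, rank)."""


def _exact(value) -> sp.Expr:
    """Convert user input to an exact SymPy scalar.

    Strings are parsed as rationals (``"p/q"`` or decimal notation), which
    keeps file round-trips exact.  Python floats are converted through their
    shortest decimal representation.  SymPy expressions pass through.
    """
    if isinstance(value, sp.Expr):
        return value  # SymPy scalars (incl. high-precision Floats) pass through
    if isinstance(value, bool):
        raise TypeError("boolean is not a number")
    if isinstance(value, int):
        return sp.Integer(value)
    if isinstance(value, Fraction):
        return sp.Rational(value.numerator, value.denominator)
    if isinstance(value, float):
        return sp.Rational(repr(value))
    if isinstance(value, str):
        try:
            return sp.Rational(value)
        except (ValueError, TypeError):
            expr = sp.sympify(value)
            if not expr.is_number:
                raise NetworkError(f"not a numeric value: {value!r}")
            return expr
    raise TypeError(f"cannot interpret {value!r} as a number")


def _scalar_str(value: sp.Expr) -> str:
    """Serialize a scalar so that :func:`_exact` round-trips it."""
    return str(value)


@dataclass(frozen=True)
class ExponentPoint:
    """A vertex ``(a, b)`` of a planar network, i.e. the complex ``aX + bY``."""

    a: sp.Expr
    b: sp.Expr

    def __init__(self, a, b):
        object.__setattr__(self, "a", _exact(a))
        object.__setattr__(self, "b", _exact(b))

    def shifted(self, alpha, beta) -> "ExponentPoint":
        return ExponentPoint(self.a + _exact(alpha), self.b + _exact(beta))

    def as_tuple(self) -> tuple[sp.Expr, sp.Expr]:
        return (self.a, self.b)

    def __iter__(self):
        yield self.a
        yield self.b

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.a}, {self.b})"


@dataclass(frozen=True)
class ReactionNetwork:
    """Directed graph on distinct exponent points, spanning the plane.

    ``edges`` holds 0-based ``(i, j)`` index pairs into ``vertices``.  The
    reaction vectors over all edges must span the plane; self-loops and
    duplicate vertices are rejected.
    """

    vertices: tuple[ExponentPoint, ...]
    edges: tuple[tuple[int, int], ...]

    def __init__(
        self,
        vertices: Sequence[ExponentPoint],
        edges: Sequence[tuple[int, int]],
        require_span: bool = True,
    ):
        verts = tuple(
            v if isinstance(v, ExponentPoint) else ExponentPoint(*v) for v in vertices
        )
        eds = tuple((int(i), int(j)) for i, j in edges)
        seen = set()
        for v in verts:
            key = (v.a, v.b)
            if key in seen:
                raise NetworkError(f"duplicate vertex {v}")
            seen.add(key)
        m = len(verts)
        for i, j in eds:
            if not (0 <= i < m and 0 <= j < m):
                raise NetworkError(f"edge ({i}, {j}) references a missing vertex")
            if i == j:
                raise NetworkError(f"self-loop at vertex {i}")
        if len(set(eds)) != len(eds):
            raise NetworkError("duplicate edge (merge parallel edges by summing kappa)")
        vecs = sp.Matrix([[verts[j].a - verts[i].a, verts[j].b - verts[i].b] for i, j in eds])
        if require_span and eds and vecs.rank() < 2:
            raise NetworkError("reaction vectors do not span the plane")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "edges", eds)

    @property
    def m(self) -> int:
        return len(self.vertices)

    def reaction_vector(self, edge: tuple[int, int]) -> tuple[sp.Expr, sp.Expr]:
        i, j = edge
        return (
            self.vertices[j].a - self.vertices[i].a,
            self.vertices[j].b - self.vertices[i].b,
        )

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.m))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MassActionSystem:
    """A reaction network with a positive rate constant on each edge."""

    network: ReactionNetwork
    kappa: tuple[sp.Expr, ...]

    def __init__(self, network: ReactionNetwork, kappa):
        if isinstance(kappa, Mapping):
            kappa = [kappa[e] for e in network.edges]
        ks = tuple(_exact(k) if not isinstance(k, sp.Expr) else k for k in kappa)
        if len(ks) != len(network.edges):
            raise NetworkError(
                f"expected {len(network.edges)} rate constants, got {len(ks)}"
            )
        for k in ks:
            if k.is_number and not k.is_positive:
                raise NetworkError("rate constant must be positive")
        object.__setattr__(self, "network", network)
        object.__setattr__(self, "kappa", ks)

    def subs(self, mapping) -> "MassActionSystem":
        return MassActionSystem(
            self.network, tuple(sp.sympify(k).subs(mapping) for k in self.kappa)
        )


@dataclass(frozen=True)
class PowerLawTerm:
    """A monomial term ``coeff * x**a * y**b``."""

    coeff: sp.Expr
    expo: ExponentPoint

    def expr(self, x: sp.Symbol, y: sp.Symbol) -> sp.Expr:
        return self.coeff * x ** self.expo.a * y ** self.expo.b


_X, _Y = sp.symbols("x y", positive=True)


def _collect_terms(terms: Iterable[tuple[sp.Expr, ExponentPoint]]) -> tuple[PowerLawTerm, ...]:
    acc: dict[tuple[sp.Expr, sp.Expr], sp.Expr] = {}
    order: list[tuple[sp.Expr, sp.Expr]] = []
    for coeff, expo in terms:
        key = expo.as_tuple()
        if key not in acc:
            acc[key] = sp.S.Zero
            order.append(key)
        acc[key] = sp.expand(acc[key] + coeff)
    out = []
    for key in order:
        c = acc[key]
        if c.is_number and c == 0:
            continue
        out.append(PowerLawTerm(c, ExponentPoint(*key)))
    return tuple(out)


@dataclass(frozen=True)
class PowerLawField:
    """A planar power-law vector field on the open positive quadrant.

    Terms with equal exponent pairs are merged and zero coefficients are
    dropped on construction.
    """

    dx_terms: tuple[PowerLawTerm, ...]
    dy_terms: tuple[PowerLawTerm, ...]

    def __init__(self, dx_terms, dy_terms):
        object.__setattr__(
            self,
            "dx_terms",
            _collect_terms(
                (t.coeff, t.expo) if isinstance(t, PowerLawTerm) else t for t in dx_terms
            ),
        )
        object.__setattr__(
            self,
            "dy_terms",
            _collect_terms(
                (t.coeff, t.expo) if isinstance(t, PowerLawTerm) else t for t in dy_terms
            ),
        )

    def exprs(self, x: sp.Symbol = _X, y: sp.Symbol = _Y) -> tuple[sp.Expr, sp.Expr]:
        fx = sp.Add(*[t.expr(x, y) for t in self.dx_terms])
        fy = sp.Add(*[t.expr(x, y) for t in self.dy_terms])
        return fx, fy

    def subs(self, mapping) -> "PowerLawField":
        return PowerLawField(
            [(t.coeff.subs(mapping), t.expo) for t in self.dx_terms],
            [(t.coeff.subs(mapping), t.expo) for t in self.dy_terms],
        )

    def __call__(self, x, y) -> tuple[float, float]:
        xv, yv = sp.Float(x), sp.Float(y)
        fx = sum(float(t.coeff) * float(xv ** t.expo.a * yv ** t.expo.b) for t in self.dx_terms)
        fy = sum(float(t.coeff) * float(xv ** t.expo.a * yv ** t.expo.b) for t in self.dy_terms)
        return fx, fy

    def lambdified(self):
        fx, fy = self.exprs()
        return sp.lambdify((_X, _Y), [fx, fy], modules="numpy")

    def jacobian_exprs(self, x: sp.Symbol = _X, y: sp.Symbol = _Y) -> sp.Matrix:
        fx, fy = self.exprs(x, y)
        return sp.Matrix([[sp.diff(fx, x), sp.diff(fx, y)], [sp.diff(fy, x), sp.diff(fy, y)]])


# ---------------------------------------------------------------------------
# structural analysis


def deficiency(net: ReactionNetwork) -> int:
    """``m - l - 2`` where ``l`` is the number of weakly connected components."""
    g = net.digraph()
    l = nx.number_weakly_connected_components(g)
    return net.m - l - 2


def structure_report(net: ReactionNetwork) -> dict:
    """Weak reversibility, component counts and the deficiency.

    ``t`` is the number of absorbing (terminal) strong components of the
    directed graph.  ``theorem3_applicable`` flags whether the hypotheses
    ``deficiency == 1`` and ``l == t == 1`` hold.
    """
    g = net.digraph()
    l = nx.number_weakly_connected_components(g)
    cond = nx.condensation(g)
    t = sum(1 for n in cond.nodes if cond.out_degree(n) == 0)
    scc_of = cond.graph["mapping"]
    weakly_reversible = all(scc_of[i] == scc_of[j] for i, j in net.edges)
    delta = net.m - l - 2
    return {
        "weakly_reversible": weakly_reversible,
        "l": l,
        "t": t,
        "deficiency": delta,
        "theorem3_applicable": delta == 1 and l == 1 and t == 1,
    }


def mass_action_field(sys: MassActionSystem) -> PowerLawField:
    """The associated differential equation of a mass-action system."""
    net = sys.network
    dx, dy = [], []
    for (i, j), k in zip(net.edges, sys.kappa):
        va, vb = net.reaction_vector((i, j))
        src = net.vertices[i]
        dx.append((va * k, src))
        dy.append((vb * k, src))
    return PowerLawField(dx, dy)


def translate_network(net: ReactionNetwork, shift) -> ReactionNetwork:
    """Shift every vertex by ``shift``; the edge set is unchanged."""
    if isinstance(shift, ExponentPoint):
        alpha, beta = shift.a, shift.b
    else:
        alpha, beta = shift
    return ReactionNetwork(
        [v.shifted(alpha, beta) for v in net.vertices], net.edges
    )


# ---------------------------------------------------------------------------
# file format

_JSON_SPECIES = ["X", "Y"]


def load_network(path) -> MassActionSystem:
    """Load a mass-action system from the JSON network dialect.

    Expected shape::

        {"species": ["X", "Y"],
         "vertices": [["0", "1"], ["1/2", "-2"], ...],
         "edges": [{"from": 0, "to": 1, "kappa": "1"}, ...]}

    Rationals may be given as strings (``"p/q"`` or decimals) or as numbers.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"malformed JSON in {path}: {exc}") from exc
    return network_from_dict(data)


def network_from_dict(data: Mapping) -> MassActionSystem:
    if "vertices" not in data or "edges" not in data:
        raise NetworkError("network file must contain 'vertices' and 'edges'")
    vertices = [ExponentPoint(*v) for v in data["vertices"]]
    edges, kappa = [], []
    for e in data["edges"]:
        edges.append((int(e["from"]), int(e["to"])))
        kappa.append(_exact(e.get("kappa", 1)))
    net = ReactionNetwork(vertices, edges)
    return MassActionSystem(net, kappa)


def network_to_dict(sys: MassActionSystem) -> dict:
    return {
        "species": list(_JSON_SPECIES),
        "vertices": [
            [_scalar_str(v.a), _scalar_str(v.b)] for v in sys.network.vertices
        ],
        "edges": [
            {"from": i, "to": j, "kappa": _scalar_str(k)}
            for (i, j), k in zip(sys.network.edges, sys.kappa)
        ],
    }


def save_network(sys: MassActionSystem, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(sys), fh, indent=1)
        fh.write("\n")


def parse_reactions(text: str) -> MassActionSystem:
    """Parse reaction lines like ``"X + 2Y -> 3Y @ 1/2"``.

    Vertices are created implicitly.  Species names are ``X`` and ``Y``;
    coefficients may be rationals.  The rate constant after ``@`` defaults
    to 1.
    """
    vertices: list[ExponentPoint] = []
    index: dict[tuple, int] = {}
    edges, kappa = [], []

    def complex_point(side: str) -> ExponentPoint:
        a = sp.S.Zero
        b = sp.S.Zero
        side = side.strip()
        if side in ("0", ""):
            return ExponentPoint(0, 0)
        for part in side.split("+"):
            part = part.replace(" ", "")
            if not part:
                continue
            if part.endswith("X"):
                coeff = part[:-1]
                a += _exact(coeff) if coeff else sp.S.One
            elif part.endswith("Y"):
                coeff = part[:-1]
                b += _exact(coeff) if coeff else sp.S.One
            else:
                raise NetworkError(f"cannot parse complex {side!r}")
        return ExponentPoint(a, b)

    def vid(pt: ExponentPoint) -> int:
        key = pt.as_tuple()
        if key not in index:
            index[key] = len(vertices)
            vertices.append(pt)
        return index[key]

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rate = sp.S.One
        if "@" in line:
            line, rate_s = line.split("@", 1)
            rate = _exact(rate_s.strip())
        if "->" not in line:
            raise NetworkError(f"missing '->' in reaction {line!r}")
        lhs, rhs = line.split("->", 1)
        edges.append((vid(complex_point(lhs)), vid(complex_point(rhs))))
        kappa.append(rate)
    net = ReactionNetwork(vertices, edges)
    return MassActionSystem(net, kappa)


# ---------------------------------------------------------------------------
# fixtures and random networks


def paper_fixture(name: str, **params):
    """Constructors for every worked example; see :mod:`planarcrn.fixtures`."""
    from planarcrn import fixtures

    return fixtures.paper_fixture(name, **params)


def _rand_rational(rng: random.Random, lo=-3, hi=4) -> sp.Rational:
    den = rng.choice([1, 1, 2, 2, 4])
    return sp.Rational(rng.randint(lo * den, hi * den), den)


def _rand_point(rng: random.Random) -> ExponentPoint:
    return ExponentPoint(_rand_rational(rng), _rand_rational(rng))


def random_network(cls: str, seed: int) -> MassActionSystem:
    """A seeded random system of one of the three studied classes.

    ``quadrangle_cycle``: 4 distinct, non-collinear vertices on a directed
    4-cycle.  ``chain3``: a directed path of 3 reactions whose first three
    vertices are not collinear.  ``three_reactions``: three disjoint
    reactions with non-collinear sources, nonzero reaction vectors spanning
    the plane.  Rate constants are positive small rationals.
    """
    rng = random.Random(seed)
    for _ in range(10000):
        try:
            if cls == "quadrangle_cycle":
                pts = [_rand_point(rng) for _ in range(4)]
                if len({p.as_tuple() for p in pts}) < 4:
                    continue
                if _collinear(pts):
                    continue
                net = ReactionNetwork(pts, [(0, 1), (1, 2), (2, 3), (3, 0)])
            elif cls == "chain3":
                pts = [_rand_point(rng) for _ in range(4)]
                if len({p.as_tuple() for p in pts}) < 4:
                    continue
                if _collinear(pts[:3]):
                    continue
                net = ReactionNetwork(pts, [(0, 1), (1, 2), (2, 3)])
            elif cls == "three_reactions":
                srcs = [_rand_point(rng) for _ in range(3)]
                if len({p.as_tuple() for p in srcs}) < 3 or _collinear(srcs):
                    continue
                tgts = [
                    s.shifted(_rand_rational(rng, -2, 2), _rand_rational(rng, -2, 2))
                    for s in srcs
                ]
                if any(t.as_tuple() == s.as_tuple() for s, t in zip(srcs, tgts)):
                    continue
                pts = srcs + tgts
                if len({p.as_tuple() for p in pts}) < 6:
                    continue
                net = ReactionNetwork(pts, [(0, 3), (1, 4), (2, 5)])
            else:
                raise ValueError(f"unknown network class {cls!r}")
        except NetworkError:
            continue
        kappa = [sp.Rational(rng.randint(1, 8), rng.choice([1, 2, 4])) for _ in net.edges]
        return MassActionSystem(net, kappa)
    raise RuntimeError("rejection sampling failed")  # pragma: no cover


def _collinear(pts: Sequence[ExponentPoint]) -> bool:
    if len(pts) < 3:
        return True
    p0 = pts[0]
    vs = [(p.a - p0.a, p.b - p0.b) for p in pts[1:]]
    return sp.Matrix(vs).rank() < 2
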