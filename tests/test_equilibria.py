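import math
import random

import pytest
import sympy as sp

from planarcrn import network_model as nm
from planarcrn import equilibria as eq
from planarcrn import fixtures


class TestChainGeometry:
    def test_family_41_h_values(self):
        q, r = sp.symbols("q r", positive=True)
        sys_ = fixtures.chain_4_1_network(q, r)
        geom = eq.chain_geometry(sys_.network)
        assert sp.expand(geom.h[0] + (q + r + sp.Rational(1, 2))) == 0
        assert sp.expand(geom.h[1] - (r + sp.Rational(1, 2))) == 0
        assert geom.h[2] == 0
        assert sp.expand(sum(geom.h)) == 0

    def test_family_42_h4(self):
        p, q = sp.symbols("p q", positive=True)
        pts = [(0, 0), (p, q), (q, p), (q - p, p + q ** 2 / p)]
        geom = eq.chain_geometry(pts)
        assert sp.expand(geom.h[3] - (p ** 2 - q ** 2)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_h_sum_zero_random(self, seed):
        sys_ = nm.random_network("chain3", seed)
        geom = eq.chain_geometry(sys_.network)
        assert sum(geom.h) == 0

    def test_delta_antisymmetry(self):
        sys_ = nm.random_network("chain3", 5)
        geom = eq.chain_geometry(sys_.network)
        for i, j, k in [(1, 2, 3), (2, 4, 3), (1, 4, 2)]:
            assert geom.delta(i, j, k) == -geom.delta(j, i, k)

    def test_collinear_rejected(self):
        with pytest.raises(nm.NetworkError, match="collinear"):
            eq.chain_geometry([(0, 0), (1, 1), (2, 2), (0, 1)])


class TestChainEquilibrium:
    def test_41_exact_point(self, chain_41):
        rep = eq.chain_equilibrium(chain_41)
        assert rep.exists and rep.kappa_independent
        xbar, ybar = rep.point
        assert ybar == sp.Rational(21, 2) ** 4  # 12155.0625
        assert float(ybar) == pytest.approx(12155.0625)
        assert float(xbar) == pytest.approx(8.63837598531476e-4, rel=1e-10)

    def test_41_residual_oracle(self, chain_41):
        rep = eq.chain_equilibrium(chain_41)
        fld = nm.mass_action_field(chain_41)
        fx, fy = fld(*rep.point_floats())
        assert abs(fx) < 1e-9 and abs(fy) < 1e-9

    def test_sign_test_failure(self):
        # h1 > 0 but h1 + h2 < 0: P-configuration with mixed orientation
        pts = [(0, 0), (1, 0), (1, 1), (0, -5)]
        net = nm.ReactionNetwork(pts, [(0, 1), (1, 2), (2, 3)])
        geom = eq.chain_geometry(net)
        h1, h2 = geom.h[0], geom.h[1]
        rep = eq.chain_equilibrium(nm.MassActionSystem(net, [1, 1, 1]))
        signs = rep.certificate["signs"]
        assert (0 in signs or len(set(signs)) > 1) == (not rep.exists)

    def test_41_exists_for_any_positive_q_r(self):
        rng = random.Random(0)
        for _ in range(10):
            q = sp.Rational(rng.randint(1, 8), 8)
            r = sp.Rational(rng.randint(1, 16), 8)
            rep = eq.chain_equilibrium(fixtures.chain_4_1_network(q, r))
            assert rep.exists

    def test_kappa_independence(self, chain_41):
        rng = random.Random(123)
        net = chain_41.network
        results = set()
        for _ in range(100):
            kappa = [sp.Rational(rng.randint(1, 40), rng.randint(1, 10)) for _ in range(3)]
            rep = eq.chain_equilibrium(nm.MassActionSystem(net, kappa))
            results.add(rep.exists)
        assert results == {True}

    @pytest.mark.parametrize("seed", range(20))
    def test_sign_test_vs_geometric_test(self, seed):
        # sign test <=> geometric test: same-side-of-line via Delta signs plus the
        # angle-sum criterion via h1+h2 = det(P2-P1, P4-P3)
        sys_ = nm.random_network("chain3", seed)
        geom = eq.chain_geometry(sys_.network)
        h1, h2, h3, h4 = geom.h
        sign_test = (
            sp.sign(h1) == sp.sign(h1 + h2) == sp.sign(h1 + h2 + h3) != 0
        )
        # geometric: P1, P4 strictly on the same side of line P2P3
        # Delta(231) and Delta(234) have the same sign, plus angle condition
        d234 = geom.delta(2, 3, 4)
        d231 = geom.delta(2, 3, 1)
        same_side = sp.sign(d234) == sp.sign(d231) != 0
        p = geom.points
        det_h12 = (p[1].a - p[0].a) * (p[3].b - p[2].b) - (p[1].b - p[0].b) * (p[3].a - p[2].a)
        angle_ok = same_side and sp.sign(det_h12) == sp.sign(-d231)
        assert bool(sign_test) == bool(angle_ok)


class TestThreeReactionEquilibrium:
    def test_51_exists_iff_d_gt_1(self):
        a, b = sp.Rational(1, 2), sp.Rational(1, 3)
        for d, expected in [(2, True), (3, True), (sp.Rational(1, 2), False)]:
            srcs = [(0, 0), (0, -1), (a, b)]
            vecs = [(0, -1), (1, -1), (-1, d)]
            verts, index, edges = [], {}, []

            def vid(pt):
                if pt not in index:
                    index[pt] = len(verts)
                    verts.append(pt)
                return index[pt]

            for s, v in zip(srcs, vecs):
                edges.append((vid(s), vid((s[0] + v[0], s[1] + v[1]))))
            net = nm.ReactionNetwork(verts, edges)
            rep = eq.three_reaction_equilibrium(nm.MassActionSystem(net, [1, 1, 1]))
            assert rep.exists == expected

    def test_cor2_sign_pattern(self):
        # c2 = d3 = 0 with the Cor 2 sign chain: all cross-products positive
        c = (1, 0, -1)
        d = (-1, 1, 0)
        cross = (
            c[1] * d[2] - c[2] * d[1],
            c[2] * d[0] - c[0] * d[2],
            c[0] * d[1] - c[1] * d[0],
        )
        assert all(v > 0 for v in cross)
        srcs = [(0, 0), (2, 1), (1, 2)]
        verts = srcs + [(srcs[i][0] + c[i], srcs[i][1] + d[i]) for i in range(3)]
        net = nm.ReactionNetwork(verts, [(0, 3), (1, 4), (2, 5)])
        rep = eq.three_reaction_equilibrium(nm.MassActionSystem(net, [1, 1, 1]))
        assert rep.exists

    def test_zero_cross_product_no_equilibrium(self):
        # (c2, d2) proportional to (c3, d3) makes one cross-product vanish
        srcs = [(0, 0), (2, 1), (1, 2)]
        vecs = [(1, -1), (1, 1), (2, 2)]
        verts = srcs + [(srcs[i][0] + vecs[i][0], srcs[i][1] + vecs[i][1]) for i in range(3)]
        net = nm.ReactionNetwork(verts, [(0, 3), (1, 4), (2, 5)])
        rep = eq.three_reaction_equilibrium(nm.MassActionSystem(net, [1, 1, 1]))
        assert not rep.exists
        assert 0 in rep.certificate["signs"]


class TestQuadrangleEquilibrium:
    def test_symmetric_unit(self, quadrangle_31):
        rep = eq.quadrangle_equilibrium(quadrangle_31)
        assert rep.point_floats() == pytest.approx((1.0, 1.0), abs=1e-12)

    def test_closed_form_16(self):
        rep = eq.quadrangle_equilibrium(fixtures.quadrangle_3_1(kappa=(16, 1, 1, 1)))
        assert rep.point_floats() == pytest.approx((8.0, 2.0), rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_residual(self, seed):
        sys_ = nm.random_network("quadrangle_cycle", seed)
        rep = eq.quadrangle_equilibrium(sys_)
        fld = nm.mass_action_field(sys_)
        fx, fy = fld(*rep.point_floats())
        scale = max(abs(float(t.coeff)) for t in fld.dx_terms)
        assert abs(fx) <= 1e-8 * max(1.0, scale)

    def test_closed_form_random_kappa(self):
        rng = random.Random(7)
        for _ in range(5):
            k = [sp.Rational(rng.randint(1, 30), rng.randint(1, 5)) for _ in range(4)]
            rep = eq.quadrangle_equilibrium(fixtures.quadrangle_3_1(kappa=k))
            xbar = float((k[0] ** 3 * k[3] / (k[2] ** 3 * k[1])) ** sp.Rational(1, 4))
            ybar = float((k[0] * k[1] / (k[2] * k[3])) ** sp.Rational(1, 4))
            assert rep.point_floats() == pytest.approx((xbar, ybar), rel=1e-10)


class TestScaleToUnit:
    def test_identity_scaling(self, quadrangle_31):
        scaled = eq.scale_to_unit(quadrangle_31, (1, 1))
        assert all(k == 1 for k in scaled.kbar)
        assert scaled.K == 1

    def test_42_closed_forms(self):
        for p, q in [(2, -1), (3, -2), (sp.Rational(1, 2), -2)]:
            sys_ = fixtures.reversible_chain_4_2_network(p, q, kappa=(1, 1, 1))
            rep = eq.chain_equilibrium(sys_)
            scaled = eq.scale_to_unit(sys_, rep)
            # kbar proportional to the displayed ((p-q)/p, -q/(p-q), 1)
            ref = [sp.Rational(1, 1) * (p - q) / p, -sp.Rational(q, 1) / (p - q), 1]
            ratios = {sp.simplify(kb / rf) for kb, rf in zip(scaled.kbar, ref)}
            assert len(ratios) == 1
            lam_ratio = sp.simplify(scaled.lam / (-1 / (sp.sympify(p) ** 2 - sp.sympify(q) ** 2)))
            assert lam_ratio == ratios.pop()

    def test_32_kbar_relations(self):
        # kbar1 = kbar4*gamma, kbar2 = kbar4, kbar3 = kbar4*(gamma+2)/3
        sys_ = fixtures.quadrangle_3_2_network(kappa=(2, 1, 1, 1))
        rep = eq.quadrangle_equilibrium(sys_)
        scaled = eq.scale_to_unit(sys_, rep)
        k1, k2, k3, k4 = [float(k) for k in scaled.kbar]
        gamma = k1 / k4
        assert k2 == pytest.approx(k4, rel=1e-9)
        assert k3 == pytest.approx(k4 * (gamma + 2) / 3, rel=1e-8)

    def test_scaled_field_vanishes(self, chain_41):
        rep = eq.chain_equilibrium(chain_41)
        scaled = eq.scale_to_unit(chain_41, rep)
        fx, fy = scaled.field()(1.0, 1.0)
        assert abs(fx) < 1e-12 and abs(fy) < 1e-12

    def test_wrong_equilibrium_rejected(self, chain_41):
        with pytest.raises(RuntimeError):
            eq.scale_to_unit(chain_41, (2, 3))


class TestJacobianReport:
    def test_41_trace_formula(self):
        for qv, rv, Kv in [(sp.Rational(1, 4), sp.Rational(15, 8), sp.Rational(4, 3)),
                           (sp.Rational(1, 2), 2, 1)]:
            scaled = fixtures.chain_4_1(q=qv, r=rv, K=Kv)
            rep = eq.jacobian_report(scaled)
            ref = -1 + (rv - qv * (2 * qv + 1)) * Kv / 2
            assert sp.simplify(rep.trace - ref) == 0

    def test_51_det_formula(self):
        a, b, d, K = sp.Rational(3, 2), sp.Rational(1, 2), 3, sp.Rational(2, 5)
        scaled = fixtures.three_reactions_5_1(a=a, b=b, d=d, K=K)
        rep = eq.jacobian_report(scaled)
        assert sp.simplify(rep.det - K * (d - 1) * a) == 0
        assert rep.det > 0

    def test_42_rotation_jacobian(self):
        scaled = fixtures.reversible_chain_4_2(2, -1)
        rep = eq.jacobian_report(scaled)
        assert rep.J == sp.Matrix([[0, -3], [3, 0]])  # (p^2-q^2) * rotation

    def test_chain_det_closed_form(self, chain_41):
        rep0 = eq.chain_equilibrium(chain_41)
        scaled = eq.scale_to_unit(chain_41, rep0)
        rep = eq.jacobian_report(scaled)
        assert rep.closed_form_det is not None
        assert float(sp.simplify(rep.det - rep.closed_form_det)) == pytest.approx(0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_det_positive_chains_and_quadrangles(self, seed):
        for cls, solver in [("chain3", eq.chain_equilibrium),
                            ("quadrangle_cycle", eq.quadrangle_equilibrium)]:
            sys_ = nm.random_network(cls, seed)
            try:
                rep = solver(sys_)
            except nm.NetworkError:
                continue
            if not rep.exists:
                continue
            scaled = eq.scale_to_unit(sys_, rep)
            det = float(eq.jacobian_report(scaled).det)
            assert det > 0


class TestTraceSignCondition:
    def test_examples(self):
        assert eq.trace_sign_condition_quadrangle_31((64, 1, 1, 1)) is True
        assert eq.trace_sign_condition_quadrangle_31((1, 1, 1, 1)) is False

    @pytest.mark.parametrize("k1,expected", [(sp.Rational(490001, 10000), True),
                                             (sp.Rational(489999, 10000), False)])
    def test_boundary_straddle_agrees_with_numeric_trace(self, k1, expected):
        kappa = (k1, 1, 1, 1)
        assert eq.trace_sign_condition_quadrangle_31(kappa) is expected
        sys_ = fixtures.quadrangle_3_1(kappa=kappa)
        rep = eq.quadrangle_equilibrium(sys_)
        scaled = eq.scale_to_unit(sys_, rep)
        tr = float(eq.jacobian_report(scaled).trace)
        assert (tr > 0) == expected


class TestBinomialVsNewton:
    """Chains admit both the exact binomial solve and a generic Newton solve."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agreement(self, seed):
        from scipy.optimize import fsolve
        import numpy as np

        sys_ = nm.random_network("chain3", seed)
        rep = eq.chain_equilibrium(sys_)
        if not rep.exists:
            pytest.skip("no equilibrium for this seed")
        fld = nm.mass_action_field(sys_)
        fn = lambda u: fld(math.exp(u[0]), math.exp(u[1]))
        x0 = [math.log(v) for v in rep.point_floats()]
        # perturb the start and let Newton come back
        sol = fsolve(fn, [x0[0] + 0.05, x0[1] - 0.05], full_output=False, xtol=1e-13)
        assert np.allclose(np.exp(sol), rep.point_floats(), rtol=1e-10)
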