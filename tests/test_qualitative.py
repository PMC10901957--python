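import itertools
import random

import numpy as np
import pytest
import sympy as sp

from planarcrn import network_model as nm
from planarcrn import equilibria as eq
from planarcrn import fixtures
from planarcrn import qualitative as ql
from planarcrn.qualitative import CertificateFailure, CenterCertificate

from conftest import COR2_INSTANCE, COR3_INSTANCE


class TestDulacInterval:
    def test_31_a_sequence(self):
        interval, strict = ql.dulac_exponent_interval([0, 1, 1, 0])
        assert interval == (0, 1) and strict

    def test_31_b_sequence_empty(self):
        interval, _ = ql.dulac_exponent_interval([1, 0, 2, 3])
        assert interval is None

    def test_constant_sequence(self):
        interval, strict = ql.dulac_exponent_interval([2, 2, 2, 2])
        assert interval == (-sp.oo, sp.oo) and not strict

    @pytest.mark.parametrize("perm", list(itertools.permutations([0, 1, 2, 3])))
    def test_matches_brute_force(self, perm):
        # brute force: alpha is feasible iff all cyclic constraints hold;
        # scan a fine grid plus the vertex values themselves
        seq = list(perm)
        interval, strict = ql.dulac_exponent_interval(seq)
        candidates = [sp.Rational(k, 8) for k in range(-16, 41)]
        feas = [
            a for a in candidates
            if all((a - seq[i]) * (seq[i] - seq[(i + 1) % 4]) <= 0 for i in range(4))
        ]
        if interval is None:
            assert not feas
        else:
            lo, hi = interval
            assert feas
            assert min(feas) == max(lo, candidates[0])
            assert max(feas) == min(hi, candidates[-1])

    @pytest.mark.parametrize("seq", [[0, 0, 1, 2], [1, 0, 0, 2], [0, 1, 0, 1],
                                     [2, 1, 1, 0], [0, 1, 1, 0], [1, 1, 0, 0]])
    def test_tie_patterns(self, seq):
        interval, _ = ql.dulac_exponent_interval(seq)
        for a in [sp.Rational(k, 4) for k in range(-4, 13)]:
            ok = all((a - seq[i]) * (seq[i] - seq[(i + 1) % 4]) <= 0 for i in range(4))
            inside = interval is not None and interval[0] <= a <= interval[1]
            assert ok == inside


class TestDulacQuadrangle:
    def test_unit_square_globally_stable(self, unit_square_cycle):
        cert = ql.dulac_test_quadrangle(unit_square_cycle)
        assert cert.verdict == "globally_stable_all_kappa"
        assert cert.chosen == (sp.Rational(1, 2), sp.Rational(1, 2))

    def test_31_inconclusive_with_j2_pattern(self, quadrangle_31):
        cert = ql.dulac_test_quadrangle(quadrangle_31)
        assert cert.verdict == "inconclusive"
        assert cert.bad_pattern_b == 2

    def test_32_inconclusive_with_j2_pattern(self):
        sys_ = fixtures.quadrangle_3_2_network(kappa=(1, 1, 1, 1))
        cert = ql.dulac_test_quadrangle(sys_)
        assert cert.verdict == "inconclusive"
        assert cert.bad_pattern_b == 2

    def test_soundness_divergence_negative(self, unit_square_cycle):
        # where the certificate claims global stability, div(h*f, h*g) < 0
        cert = ql.dulac_test_quadrangle(unit_square_cycle)
        alpha, beta = cert.chosen
        x, y = sp.symbols("x y", positive=True)
        rng = random.Random(0)
        for _ in range(10):
            kappa = [sp.Rational(rng.randint(1, 9), rng.randint(1, 3)) for _ in range(4)]
            sys_ = nm.MassActionSystem(unit_square_cycle, kappa)
            fx, fy = nm.mass_action_field(sys_).exprs(x, y)
            h = x ** -alpha * y ** -beta
            div = sp.diff(h * fx, x) + sp.diff(h * fy, y)
            fn = sp.lambdify((x, y), div, "numpy")
            pts = np.exp(rng.uniform(-2, 2) + np.random.default_rng(1).uniform(-2, 2, (1000, 2)))
            vals = fn(pts[:, 0], pts[:, 1])
            assert np.all(vals < 0)


class TestReversibility:
    def test_reversible_chain_field(self):
        assert ql.reversibility_check(fixtures.reversible_chain_4_2(2, -1))

    def test_quadrangle_family_not_reversible(self):
        scaled = fixtures.quadrangle_3_2(K=1, gamma=17)
        assert not ql.reversibility_check(scaled)

    def test_simple_symmetric_field(self):
        fld = nm.PowerLawField(
            [(1, nm.ExponentPoint(0, 0)), (-1, nm.ExponentPoint(0, 1))],
            [(-1, nm.ExponentPoint(0, 0)), (1, nm.ExponentPoint(1, 0))],
        )
        # xdot = 1 - y, ydot = -(1 - x)
        assert ql.reversibility_check(fld)


class TestReversibleCenterThreeReactions:
    def test_cor2_instance_certified(self):
        cert = ql.reversible_center_three_reactions(**COR2_INSTANCE)
        assert isinstance(cert, CenterCertificate)
        assert cert.kind == "reversible"
        assert ql.reversibility_check(cert.details["scaled"])

    def test_geometric_mean_violation(self):
        bad = dict(COR2_INSTANCE)
        bad["d"] = (bad["d"][0], sp.Rational(11, 10), bad["d"][2])
        cert = ql.reversible_center_three_reactions(**bad)
        assert isinstance(cert, CertificateFailure)
        assert "geometric-mean" in cert.condition or "ordering" in cert.condition

    def test_p2_less_q2_fails(self):
        bad = dict(COR2_INSTANCE)
        bad["p"], bad["q"] = 1, 2
        cert = ql.reversible_center_three_reactions(**bad)
        assert isinstance(cert, CertificateFailure)
        assert "(i)" in cert.condition

    def test_sign_chain_violation(self):
        bad = dict(COR2_INSTANCE)
        bad["c"] = (-bad["c"][0], bad["c"][1], bad["c"][2])
        cert = ql.reversible_center_three_reactions(**bad)
        assert isinstance(cert, CertificateFailure)
        assert "(ii)" in cert.condition


class TestCenterRateConstants:
    def test_formula(self):
        p, q, c, d = (COR2_INSTANCE[k] for k in ("p", "q", "c", "d"))
        k1, k2, k3 = ql.center_rate_constants(p, q, c, d)
        ref = -sp.Rational(c[1], 1) / d[2] * (-sp.Rational(c[0], 1) / d[0]) ** (p - q - 1)
        assert k2 == 1
        assert sp.simplify(k3 - ref) == 0

    def test_pipeline_verification(self):
        p, q, c, d = (COR2_INSTANCE[k] for k in ("p", "q", "c", "d"))
        sys_ = ql.center_system(p, q, c, d)
        rep = eq.three_reaction_equilibrium(sys_)
        assert rep.exists
        scaled = eq.scale_to_unit(sys_, rep)
        assert ql.reversibility_check(scaled)

    def test_wrong_exponent_negative_control(self):
        # needs -c1/d1 != 1, otherwise the exponent slip is invisible
        inst = dict(p=2, q=1, c=(1, sp.Rational(1, 2), -1), d=(-2, 2, -1))
        cert = ql.reversible_center_three_reactions(**inst)
        assert isinstance(cert, CenterCertificate)
        p, q, c, d = (inst[k] for k in ("p", "q", "c", "d"))
        k1, k2, _ = ql.center_rate_constants(p, q, c, d)
        wrong_k3 = -sp.Rational(c[1], 1) / d[2] * (-sp.Rational(c[0], 1) / d[0]) ** (p - q)
        srcs = [(0, 0), (p, q), (q, p)]
        verts = list(srcs) + [
            (srcs[i][0] + c[i], srcs[i][1] + d[i]) for i in range(3)
        ]
        net = nm.ReactionNetwork(verts, [(0, 3), (1, 4), (2, 5)])
        sys_ = nm.MassActionSystem(net, [k1, k2, wrong_k3])
        rep = eq.three_reaction_equilibrium(sys_)
        scaled = eq.scale_to_unit(sys_, rep)
        assert not ql.reversibility_check(scaled)


class TestLienard:
    def make_scaled(self, **over):
        inst = dict(COR3_INSTANCE)
        inst.update(over)
        return fixtures.lienard_5_3(**inst)

    def test_transform_matches_printed_F(self):
        scaled = self.make_scaled()
        tr = ql.lienard_transform(scaled)
        y = tr["y"]
        c1 = scaled.cvec[0]
        d2, d3 = scaled.dvec[1], scaled.dvec[2]
        k1, k2, k3 = scaled.kbar
        K = scaled.K
        F_ref = (
            -c1 * k1 * y
            - K * d2 * k2 * ((y + 1) ** sp.Rational(-1, 2) - 1)
            - K * d3 * k3 * ((y + 1) ** (-2) - 1)
        )
        assert sp.simplify(tr["F"] - F_ref) == 0
        assert tr["F"].subs(y, 0) == 0
        assert tr["G"].subs(y, 0) == 0

    def test_g_sign_near_zero(self):
        scaled = self.make_scaled()
        tr = ql.lienard_transform(scaled)
        y = tr["y"]
        for yv in (0.05, -0.05, 0.2, -0.2):
            assert float(tr["g"].subs(y, yv)) * yv > 0

    def test_cor3_certificate(self):
        scaled = self.make_scaled()
        cert = ql.lienard_center_check(scaled)
        assert isinstance(cert, CenterCertificate)
        assert cert.kind == "lienard"
        # det and trace closed forms
        k1, k2, k3 = scaled.kbar
        det_ref = sp.Rational(3, 2) / scaled.lam * scaled.K * k1 * k2 * k3
        assert sp.simplify(cert.details["det"] - det_ref) == 0
        assert sp.simplify(scaled.trace()) == 0
        assert sp.simplify(scaled.det() - det_ref) == 0
        assert det_ref > 0

    def test_wrong_factor_negative_control(self):
        # perturbing d3 breaks the coupling chain of the composition condition
        scaled = self.make_scaled(d=(-5, 2, sp.Rational(5, 4)))
        cert = ql.lienard_center_check(scaled)
        assert isinstance(cert, CertificateFailure)

    def test_wrong_pattern_rejected(self):
        scaled = fixtures.reversible_5_2(**COR2_INSTANCE)
        with pytest.raises(ValueError, match="pattern"):
            ql.lienard_transform(scaled)


class TestCentersHaveZeroFocalValues:
    """Every center certificate implies vanishing L1..L3 and a tiny return-map
    displacement."""

    @pytest.mark.parametrize("maker", ["rev_chain", "cor2", "cor3"])
    def test_center_focal_values(self, maker):
        from planarcrn import lyapunov as ly

        if maker == "rev_chain":
            scaled = fixtures.reversible_chain_4_2(2, -1)
        elif maker == "cor2":
            scaled = fixtures.reversible_5_2(**COR2_INSTANCE)
        else:
            scaled = fixtures.lienard_5_3(**COR3_INSTANCE)
        seq = ly.focal_values(scaled, k_max=3)
        for lv in seq.L:
            assert abs(complex(sp.nsimplify(lv, rational=False) if lv.is_number else 0)) < 1e-18 \
                or sp.simplify(lv) == 0
        d = ly.return_map_displacement(scaled, 0.05)
        assert abs(d) < 1e-8
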