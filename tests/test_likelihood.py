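"""Pruning-likelihood correctness: equations, propagation, reductions."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

import rangesse as r
from rangesse.likelihood import PartialVectors


def hand_geosse_rhs(E, D, p):
    """Term-by-term expansion of the six coupled equations of the two-area,
    three-state system (states A, B, AB), written independently of the
    table machinery."""
    lam, vic, d, e, mu = p.lambda_is, p.lambda_vic, p.d, p.e, p.mu
    EA, EB, EAB = E
    DA, DB, DAB = D
    dE = np.array([
        mu - (lam + d + mu) * EA + d * EAB + lam * EA * EA,
        mu - (lam + d + mu) * EB + d * EAB + lam * EB * EB,
        mu - (2 * lam + vic + 2 * e + mu) * EAB + e * EA + e * EB
        + lam * EA * EAB + lam * EB * EAB + vic * EA * EB,
    ])
    dD = np.array([
        -(lam + d + mu) * DA + d * DAB + 2 * lam * EA * DA,
        -(lam + d + mu) * DB + d * DAB + 2 * lam * EB * DB,
        -(2 * lam + vic + 2 * e + mu) * DAB + e * DA + e * DB
        + lam * (DA * EAB + DAB * EA) + lam * (DB * EAB + DAB * EB)
        + vic * (DA * EB + DB * EA),
    ])
    return dE, dD


class TestOdeRhs:
    def test_all_rates_zero_freezes_partials(self, space2, tables2):
        p = r.RateParams(0, 0, 0, 0, 0)
        pv = PartialVectors(E=np.array([0.1, 0.2, 0.3]), D=np.array([1.0, 0.5, 0.2]))
        out = r.ode_rhs(0.0, pv, p, tables2)
        assert np.all(out.E == 0) and np.all(out.D == 0)

    def test_pure_death_limit(self, tables2):
        p = r.RateParams(0, 0, 0, 0, mu=0.37)
        pv = PartialVectors(E=np.zeros(3), D=np.ones(3))
        out = r.ode_rhs(0.0, pv, p, tables2)
        assert np.allclose(out.E, 0.37)

    def test_matches_hand_expanded_two_area_system(self, tables2):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = r.RateParams(*rng.uniform(0.01, 0.6, size=5))
            E = rng.uniform(0, 0.6, 3)
            D = rng.uniform(0, 1, 3)
            out = r.ode_rhs(0.0, PartialVectors(E=E, D=D), p, tables2)
            dE, dD = hand_geosse_rhs(E, D, p)
            assert np.allclose(out.E, dE, atol=1e-12)
            assert np.allclose(out.D, dD, atol=1e-12)

    def test_rejects_wrong_length(self, tables2):
        p = r.RateParams(0.1, 0.1, 0.1, 0.1, 0.1)
        with pytest.raises(ValueError, match="length"):
            r.ode_rhs(0.0, PartialVectors(E=np.zeros(2), D=np.zeros(3)), p, tables2)


class TestIntegrateBranch:
    def test_zero_length_is_identity(self, tables2):
        p = r.RateParams(0.3, 0.2, 0.1, 0.05, 0.1)
        pv = PartialVectors(E=np.zeros(3), D=np.array([1.0, 0.0, 0.0]))
        out = r.integrate_branch(pv, 0.0, p, tables2)
        assert np.array_equal(out.D, pv.D) and np.array_equal(out.E, pv.E)

    def test_mu_zero_matches_matrix_exponential(self, tables2):
        # with E = 0 the D system is linear and autonomous
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = r.RateParams(*rng.uniform(0.02, 0.5, 4), mu=0.0)
            pv = PartialVectors(E=np.zeros(3), D=rng.uniform(0.1, 1.0, 3))
            t = float(rng.uniform(0.2, 3.0))
            out = r.integrate_branch(pv, t, p, tables2,
                                     r.LikelihoodOptions(rescale=False))
            oracle = expm(tables2.linear_generator(p) * t) @ pv.D
            assert np.allclose(out.D, oracle, rtol=1e-6, atol=1e-10)

    def test_extinction_probability_monotone_in_branch_length(self, tables2):
        p = r.RateParams(0.3, 0.2, 0.1, 0.05, mu=0.2)
        vals = []
        for t in np.linspace(0.5, 100, 10):
            out = r.integrate_branch(PartialVectors(E=np.zeros(3), D=np.ones(3)),
                                     float(t), p, tables2)
            assert np.all((out.E >= 0) & (out.E <= 1))
            if vals:
                assert np.all(out.E >= vals[-1] - 1e-9)
            vals.append(out.E)
        # each component converges to its state's total-extinction probability;
        # widespread ranges speciate faster, so their limit sits lower
        assert np.abs(vals[-1] - vals[-2]).max() < 1e-4
        assert vals[-1][2] < vals[-1][0]

    def test_negative_length_rejected(self, tables2):
        p = r.RateParams(0.1, 0.1, 0.1, 0.1, 0.0)
        with pytest.raises(ValueError, match="negative"):
            r.integrate_branch(PartialVectors(E=np.zeros(3), D=np.ones(3)),
                               -1.0, p, tables2)


class TestCombineAtNode:
    def test_single_area_space_is_one_product(self):
        space = r.build_state_space(["A"], 1)
        tb = r.ModelTables(space, "DEC")
        p = r.RateParams(0.4, 0.0, 0.0, 0.0, 0.1)
        left = PartialVectors(E=np.array([0.2]), D=np.array([0.6]))
        right = PartialVectors(E=np.array([0.2]), D=np.array([0.5]))
        out = r.combine_at_node(left, right, tb, p)
        assert np.isclose(out.D[0], 0.4 * 0.6 * 0.5)

    def test_dec_two_area_parent_expands_to_six_terms(self, space2, tables2):
        p = r.RateParams(0.3, 0.2, 0.0, 0.0, 0.0)
        Dl = np.array([0.7, 0.5, 0.3])
        Dr = np.array([0.2, 0.9, 0.4])
        out = tables2.combine_children(p, Dl, Dr)
        lam, vic = p.lambda_is, p.lambda_vic
        expected_AB = (lam * (Dl[0] * Dr[2] + Dl[2] * Dr[0])
                       + lam * (Dl[1] * Dr[2] + Dl[2] * Dr[1])
                       + vic * (Dl[0] * Dr[1] + Dl[1] * Dr[0]))
        assert np.isclose(out[2], expected_AB)
        assert np.isclose(out[0], lam * Dl[0] * Dr[0])

    def test_zero_daughter_is_absorbing(self, tables2):
        p = r.RateParams(0.3, 0.2, 0.1, 0.05, 0.1)
        left = PartialVectors(E=np.zeros(3), D=np.zeros(3))
        right = PartialVectors(E=np.zeros(3), D=np.ones(3))
        assert np.all(r.combine_at_node(left, right, tables2, p).D == 0)

    def test_mismatched_E_rejected(self, tables2):
        p = r.RateParams(0.3, 0.2, 0.1, 0.05, 0.1)
        left = PartialVectors(E=np.zeros(3), D=np.ones(3))
        right = PartialVectors(E=np.full(3, 0.5), D=np.ones(3))
        with pytest.raises(ValueError, match="time slice"):
            r.combine_at_node(left, right, tables2, p)


class TestComputeLoglik:
    def test_two_identical_calls_bitwise_equal(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        tb = r.ModelTables(fx.space, "DEC")
        a = r.compute_loglik(it, fx.sim.tip_ranges, fx.params, tb,
                             retain_partials=False).loglik
        b = r.compute_loglik(it, fx.sim.tip_ranges, fx.params, tb,
                             retain_partials=False).loglik
        assert a == b

    def test_engines_agree(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        tb = r.ModelTables(fx.space, "DEC")
        grid = r.compute_loglik(it, fx.sim.tip_ranges, fx.params, tb,
                                retain_partials=False).loglik
        ode = r.compute_loglik(it, fx.sim.tip_ranges, fx.params, tb,
                               r.LikelihoodOptions(engine="ode"),
                               retain_partials=False).loglik
        assert grid == pytest.approx(ode, abs=2e-6)

    def test_engines_agree_at_high_extinction(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        tb = r.ModelTables(fx.space, "DEC")
        p = r.RateParams(0.6, 0.3, 0.2, 0.1, mu=1.5)
        grid = r.compute_loglik(it, fx.sim.tip_ranges, p, tb,
                                retain_partials=False).loglik
        ode = r.compute_loglik(it, fx.sim.tip_ranges, p, tb,
                               r.LikelihoodOptions(engine="ode"),
                               retain_partials=False).loglik
        # extreme extinction bends E sharply near the present; the default
        # grid still tracks the reference integrator to ~1e-4 log units
        assert grid == pytest.approx(ode, abs=1e-4)

    def test_single_area_reduces_to_birth_death(self, single_area_fixture):
        fx = single_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        tb = r.ModelTables(fx.space, "DEC")
        for lam, mu in [(0.3, 0.1), (0.15, 0.12)]:
            p = r.RateParams(lam, 0, 0, 0, mu)
            ll = r.compute_loglik(it, fx.sim.tip_ranges, p, tb,
                                  retain_partials=False).loglik
            assert ll == pytest.approx(r.bd_loglik(it, lam, mu), abs=1e-4)

    def test_uniform_tips_with_frozen_ranges_reduce_to_yule(self, space2):
        # no dispersal, no extirpation, no extinction, all tips in area A:
        # only in-situ speciation acts, i.e. a pure-birth process
        tree = dendropy.Tree.get(
            data="((t1:1.2,t2:1.2):0.8,(t3:1.5,t4:1.5):0.5);", schema="newick")
        it = r.index_tree(tree)
        tb = r.ModelTables(space2, "DEC")
        ranges = {t: space2.states[0] for t in ("t1", "t2", "t3", "t4")}
        p = r.RateParams(0.4, 0.3, 0.0, 0.0, 0.0)
        ll = r.compute_loglik(it, ranges, p, tb, retain_partials=False).loglik
        assert ll == pytest.approx(r.bd_loglik(it, 0.4, 0.0), abs=1e-6)

    def test_invariant_to_tip_relabelling_and_child_rotation(self, space2):
        tb = r.ModelTables(space2, "DEC")
        p = r.RateParams(0.3, 0.2, 0.1, 0.05, 0.15)
        t1 = dendropy.Tree.get(data="((t1:1,t2:1):0.7,(t3:1.2,t4:1.2):0.5);",
                               schema="newick")
        t2 = dendropy.Tree.get(data="((t4:1.2,t3:1.2):0.5,(t2:1,t1:1):0.7);",
                               schema="newick")
        ranges = {"t1": space2.states[0], "t2": space2.states[2],
                  "t3": space2.states[1], "t4": space2.states[1]}
        ll1 = r.compute_loglik(r.index_tree(t1), ranges, p, tb,
                               retain_partials=False).loglik
        ll2 = r.compute_loglik(r.index_tree(t2), ranges, p, tb,
                               retain_partials=False).loglik
        # permuted labels with the matching permuted range table
        perm = {"t1": "u3", "t2": "u1", "t3": "u4", "t4": "u2"}
        t3 = dendropy.Tree.get(data="((u3:1,u1:1):0.7,(u4:1.2,u2:1.2):0.5);",
                               schema="newick")
        ranges3 = {perm[k]: v for k, v in ranges.items()}
        ll3 = r.compute_loglik(r.index_tree(t3), ranges3, p, tb,
                               retain_partials=False).loglik
        assert ll1 == pytest.approx(ll2, abs=1e-9)
        assert ll1 == pytest.approx(ll3, abs=1e-9)

    def test_sampling_fraction_approaches_complete_sampling(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        tb = r.ModelTables(fx.space, "DEC")
        full = r.compute_loglik(it, fx.sim.tip_ranges, fx.params, tb,
                                retain_partials=False).loglik
        gaps = []
        for rho in (0.9, 0.99, 0.999):
            o = r.LikelihoodOptions(sampling_fraction=rho)
            gaps.append(abs(r.compute_loglik(it, fx.sim.tip_ranges, fx.params, tb, o,
                                             retain_partials=False).loglik - full))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.1

    def test_missing_tip_range_and_polytomy_rejected(self, space2, tables2):
        p = r.RateParams(0.3, 0.2, 0.1, 0.05, 0.0)
        tree = dendropy.Tree.get(data="((t1:1,t2:1):1,t3:2);", schema="newick")
        it = r.index_tree(tree)
        with pytest.raises(ValueError, match="no range"):
            r.compute_loglik(it, {"t1": space2.states[0]}, p, tables2)
        poly = dendropy.Tree.get(data="(t1:1,t2:1,t3:1);", schema="newick")
        with pytest.raises(r.trees.TreeValidationError, match="children"):
            r.index_tree(poly)


class TestExtinctionVectorProperties:
    def test_E_bounded_and_monotone_over_random_draws(self, space4):
        tb = r.ModelTables(space4, "DEC")
        rng = np.random.default_rng(42)
        from rangesse.likelihood import LikelihoodOptions, _solve_E

        for _ in range(10):
            p = r.RateParams(*rng.uniform(0.01, 0.8, 5))
            E_of = _solve_E(tb, p, 30.0, LikelihoodOptions())
            grid = np.linspace(0, 30.0, 200)
            vals = np.array([E_of(t) for t in grid])
            assert np.all((vals >= 0) & (vals <= 1))
            assert np.all(np.diff(vals, axis=0) >= -1e-7)
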