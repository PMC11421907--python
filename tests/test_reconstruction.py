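"""Ancestral-range marginals, origin summary and richness profiles."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import rangesse as r
from conftest import clamped_distribution
from rangesse.likelihood import PartialVectors


class TestNodeMarginals:
    def test_rows_normalize_and_tips_are_point_masses(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        marg = r.node_marginals(it, fx.sim.tip_ranges, fx.params, fx.space, "DEC")
        assert np.allclose(marg.probs.sum(axis=1), 1.0, atol=1e-9)
        for lab, node in it.tip_index.items():
            obs = fx.space.state_index(fx.sim.tip_ranges[lab])
            assert marg.probs[node, obs] == pytest.approx(1.0, abs=1e-9)

    def test_matches_clamp_and_renormalize_oracle(self, three_tip_case, space2):
        itree, ranges, params = three_tip_case
        tb = r.ModelTables(space2, "DEC")
        base = r.compute_loglik(itree, ranges, params, tb)
        marg = r.node_marginals(itree, ranges, params, space2, "DEC")
        for node in range(itree.n_nodes):
            oracle, total = clamped_distribution(itree, ranges, params, tb,
                                                 node, base)
            assert total == pytest.approx(1.0, rel=1e-9)
            assert np.abs(marg.probs[node] - oracle).max() < 1e-6

    def test_extreme_dispersal_flattens_the_root_marginal(self, three_tip_case,
                                                          space2):
        itree, ranges, _ = three_tip_case
        peaks = []
        for d in (0.05, 0.5, 5.0):
            p = r.RateParams(0.3, 0.25, d, 0.08, 0.12)
            marg = r.node_marginals(itree, ranges, p, space2, "DEC")
            peaks.append(marg.root.max())
        assert peaks[0] > peaks[1] > peaks[2]

    def test_presence_probability_is_sum_over_containing_states(
            self, three_tip_case, space2):
        itree, ranges, params = three_tip_case
        marg = r.node_marginals(itree, ranges, params, space2, "DEC")
        root = marg.root
        # hand sum on the three-state space: P(A) = P({A}) + P({A,B})
        assert marg.presence[itree.root, 0] == pytest.approx(root[0] + root[2])
        assert marg.presence[itree.root, 1] == pytest.approx(root[1] + root[2])


class TestAncestralOrigin:
    def test_concentrated_root_yields_single_origin(self, three_tip_case, space2):
        itree, ranges, params = three_tip_case
        marg = r.node_marginals(itree, ranges, params, space2, "DEC")
        marg.probs[itree.root] = np.array([0.9, 0.06, 0.04])
        origin = r.ancestral_origin(marg, threshold=0.5)
        assert origin.origin == ("A",)
        assert origin.fallback_state is None

    def test_flat_root_falls_back_to_argmax_state(self, three_tip_case, space2):
        itree, ranges, params = three_tip_case
        marg = r.node_marginals(itree, ranges, params, space2, "DEC")
        marg.probs[itree.root] = np.array([0.4, 0.35, 0.25])
        origin = r.ancestral_origin(marg, threshold=0.9)
        assert origin.origin == ()
        assert origin.fallback_state == "A"
        assert set(origin.to_dict()["presence"]) == {"A", "B"}


class TestRichness:
    def test_present_day_slice_equals_tip_tallies(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        prof = r.richness_through_time(it, fx.sim.tip_ranges, fx.params,
                                       fx.space, "DEC", n_slices=25)
        tallies = np.zeros(2)
        for s in fx.sim.tip_ranges.values():
            for a in s.area_indices():
                tallies[a] += 1
        assert np.allclose(prof.richness[-1], tallies)
        assert prof.n_branches[-1] == it.n_tips

    def test_every_lineage_occupies_at_least_one_area(self, two_area_fixture):
        fx = two_area_fixture
        it = r.index_tree(fx.sim.pruned_tree)
        prof = r.richness_through_time(it, fx.sim.tip_ranges, fx.params,
                                       fx.space, "DEC", n_slices=25)
        assert np.all(prof.richness.sum(axis=1) >= prof.n_branches - 1e-9)
        assert np.all(prof.richness >= 0)
        # no area can hold more lineages than are alive
        assert np.all(prof.richness <= prof.n_branches[:, None] + 1e-9)

    def test_mid_branch_distribution_matches_manual_degree_two_insertion(
            self, space2):
        # oracle: propagate the tip partial to the focal time with the
        # reference integrator, clamp, continue to the node, and renormalize
        tb = r.ModelTables(space2, "DEC")
        params = r.RateParams(0.3, 0.25, 0.15, 0.08, 0.12)
        T, t_eval = 2.0, 1.25
        tree = dendropy.Tree.get(data=f"(s1:{T},s2:{T});", schema="newick")
        it = r.index_tree(tree)
        ranges = {"s1": space2.states[0], "s2": space2.states[1]}
        n_slices = 9  # uniform grid putting a slice exactly at age 1.25
        prof = r.richness_through_time(it, ranges, params, space2, "DEC",
                                       n_slices=n_slices)
        k = int(np.argmin(np.abs(prof.times - t_eval)))
        assert prof.times[k] == pytest.approx(t_eval)

        base = r.compute_loglik(it, ranges, params, tb)
        opts = r.LikelihoodOptions(rescale=False)
        expected = np.zeros(2)
        for tip, other in (("s1", "s2"), ("s2", "s1")):
            lls = []
            for st in range(space2.n_states):
                D0 = np.zeros(3)
                D0[space2.state_index(ranges[tip])] = 1.0
                low = r.integrate_branch(PartialVectors(E=np.zeros(3), D=D0),
                                         t_eval, params, tb, opts)
                low.D = low.D * np.eye(3)[st]  # clamp the inserted node
                top = r.integrate_branch(low, T - t_eval, params, tb, opts)
                D0o = np.zeros(3)
                D0o[space2.state_index(ranges[other])] = 1.0
                oth = r.integrate_branch(PartialVectors(E=np.zeros(3), D=D0o),
                                         T, params, tb, opts)
                root = tb.combine_children(params, top.D, oth.D)
                lls.append(float(base.root_weights @ root))
            dist = np.array(lls) / sum(lls)
            for a in range(2):
                expected[a] += sum(dist[s] for s in space2.states_containing(a))
        assert np.allclose(prof.richness[k], expected, atol=2e-5)

    def test_rejects_degenerate_slice_count(self, two_area_fixture):
        fx = two_area_fixture
        with pytest.raises(ValueError, match="slices"):
            r.richness_through_time(fx.sim.pruned_tree, fx.sim.tip_ranges,
                                    fx.params, fx.space, "DEC", n_slices=1)


class TestSpeciationModeSummary:
    def _fake_grid(self):
        from rangesse.inference import BDFit, RangeModelFit, ScenarioGrid
        from rangesse.likelihood import LikelihoodOptions, LikelihoodResult

        cells = {}
        rates = iter(np.linspace(0.1, 0.9, 16))
        for level in ("zero", "low", "intermediate", "high"):
            for model in ("DEC", "DIVA"):
                p = r.RateParams(next(rates), next(rates) / 3, 0.05, 0.02, 0.1)
                res = LikelihoodResult(
                    loglik=-100.0, params=p, model=model,
                    options=LikelihoodOptions(), root_weights=np.ones(3) / 3,
                    root_distribution=np.ones(3) / 3)
                cells[(level, model)] = RangeModelFit(
                    result=res, mu_fixed=0.1, converged=True, n_starts=1,
                    start_logliks=(-100.0,), speciation_exceeds_extinction=True)
        grid = ScenarioGrid(bd=BDFit(0.3, 0.0, -50.0, 20),
                            mu_levels={"zero": 0.0, "low": 0.03,
                                       "intermediate": 0.3, "high": 3.0},
                            models=("DEC", "DIVA"), cells=cells,
                            selected={lv: "DEC" for lv in
                                      ("zero", "low", "intermediate", "high")})
        return grid

    def test_eight_rows_with_ratio_column(self, tmp_path):
        df = r.speciation_mode_summary(self._fake_grid())
        assert len(df) == 8
        assert np.allclose(df["insitu_vic_ratio"],
                           df["lambda_is"] / df["lambda_vic"])
        out = tmp_path / "modes.tsv"
        df.to_csv(out, sep="\t", index=False)
        back = pd.read_csv(out, sep="\t")
        assert np.allclose(back["insitu_vic_ratio"], df["insitu_vic_ratio"])
        assert list(back["mu_level"]) == list(df["mu_level"])

    def test_vicariance_at_bound_flags_infinite_ratio(self):
        grid = self._fake_grid()
        fit = grid.cells[("zero", "DEC")]
        fit.result.params = r.RateParams(0.3, 1e-6, 0.05, 0.02, 0.1)
        df = r.speciation_mode_summary(grid)
        row = df[(df.mu_level == "zero") & (df.model == "DEC")].iloc[0]
        assert row["ratio_at_bound"]
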