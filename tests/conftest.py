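"""Shared fixtures: small state spaces and deterministic synthetic datasets."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

import rangesse as r


@pytest.fixture(scope="session")
def space2():
    return r.build_state_space(["A", "B"], 2)


@pytest.fixture(scope="session")
def space4():
    return r.build_state_space(["A", "B", "C", "D"], 3)


@pytest.fixture(scope="session")
def tables2(space2):
    return r.ModelTables(space2, "DEC")


@pytest.fixture(scope="session")
def two_area_fixture():
    return r.make_fixture("two_area_geosse")


@pytest.fixture(scope="session")
def single_area_fixture():
    return r.make_fixture("single_area_bd")


@pytest.fixture(scope="session")
def iaa_fixture():
    return r.make_fixture("iaa7_small")


@pytest.fixture()
def three_tip_case(space2):
    """A 3-tip, 2-area instance small enough for brute-force oracles."""
    tree = dendropy.Tree.get(data="((t1:1.0,t2:1.0):0.7,t3:1.7);", schema="newick")
    itree = r.index_tree(tree)
    ranges = {"t1": space2.states[0], "t2": space2.states[2], "t3": space2.states[1]}
    params = r.RateParams(0.3, 0.25, 0.15, 0.08, 0.12)
    return itree, ranges, params


def clamped_distribution(itree, ranges, params, tables, node, base_result):
    """Brute-force clamp oracle: re-evaluate the likelihood with one node
    pinned to each state in turn, root weights frozen at the unclamped run's.
    Returns (normalized distribution, sum of clamped likelihoods / unclamped).
    """
    opts = r.LikelihoodOptions(root_weighting="given",
                               root_weights=tuple(base_result.root_weights))
    lls = np.array([
        r.compute_loglik(itree, ranges, params, tables, opts, clamp={node: s},
                         retain_partials=False).loglik
        for s in range(tables.n_states)
    ])
    w = np.exp(lls - base_result.loglik)
    return w / w.sum(), w.sum()
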