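"""Ancestral ranges, clade origin and per-area richness through time.

Marginal ancestral reconstruction is defined operationally: the probability
of state i at node v is the likelihood recomputed with v clamped to i,
renormalized over states — with the root state weights (and the survival
conditioning factor) frozen at their unclamped values, so the clamped
likelihoods sum exactly to the unclamped one.  Because branch propagation is
linear in D and the node merge bilinear, all clamped likelihoods for one tree
are obtained in a single root-to-tips adjoint pass instead of one likelihood
evaluation per (node, state); the brute-force clamped recomputation remains
available through ``compute_loglik(..., clamp=...)`` and is the oracle the
up-pass is tested against.

Richness through time evaluates the same quantity on points interior to
branches: extra evaluation times are inserted into the integration grid
(equivalent to degree-2 nodes — exact under the model, no interpolation
between node marginals), and the expected number of lineages occupying each
area at time t is the sum over contemporaneous branches of their per-area
presence probabilities.  Only reconstructed (sampled-survivor) lineages are
tallied; extinct lineages influence the result through the model's E terms,
not the count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .likelihood import (
    EngineCache,
    LikelihoodOptions,
    ModelTables,
    RateParams,
    _checkpoint_downpass,
    _tip_state_indices,
)
from .statespace import RangeState, StateSpace
from .trees import IndexedTree, index_tree

__all__ = [
    "NodeMarginals",
    "OriginSummary",
    "RichnessProfile",
    "node_marginals",
    "ancestral_origin",
    "richness_through_time",
    "speciation_mode_summary",
]


@dataclass
class NodeMarginals:
    """Per-node posterior over ranges, keyed by post-order node id.

    ``probs[v]`` is the marginal state vector of node v (tips are point
    masses on their observed range); ``presence[v, a]`` sums the state
    probabilities over every range containing area a.
    """

    itree: IndexedTree
    space: StateSpace
    probs: np.ndarray  # (n_nodes, S), each row sums to 1
    loglik: float

    @property
    def presence(self) -> np.ndarray:
        cols = np.zeros((self.space.n_states, self.space.n_areas))
        for a in range(self.space.n_areas):
            cols[list(self.space.states_containing(a)), a] = 1.0
        return self.probs @ cols

    @property
    def root(self) -> np.ndarray:
        return self.probs[self.itree.root]

    def to_frame(self) -> pd.DataFrame:
        labels = [self.space.format_state(s) for s in self.space.states]
        df = pd.DataFrame(self.probs, columns=labels)
        df.insert(0, "node", np.arange(self.itree.n_nodes))
        df.insert(1, "age", self.itree.ages)
        df.insert(2, "is_tip", [self.itree.is_tip(v) for v in range(self.itree.n_nodes)])
        return df


def _uppass(cache: EngineCache, eval_times: np.ndarray | None = None):
    """Root-to-tips adjoint pass over the checkpoint engine's cache.

    Returns per-node marginals and, if ``eval_times`` is given (each must be
    a grid boundary), the conditional state distribution of every branch
    crossing each time.
    """
    itree, tables, params = cache.itree, cache.tables, cache.params
    S = tables.n_states
    edges = cache.cell_edges
    marg = np.zeros((itree.n_nodes, S))
    c_bottom: dict[int, np.ndarray] = {itree.root: cache.root_weights.copy()}
    want = None
    if eval_times is not None:
        idx = np.searchsorted(edges, np.asarray(eval_times) - 1e-12 * max(edges[-1], 1.0))
        want = {int(i): float(t) for i, t in zip(idx, eval_times)}
        slice_dists: dict[float, list[tuple[int, np.ndarray]]] = {t: [] for t in eval_times}

    for node in range(itree.n_nodes - 1, -1, -1):  # reverse post-order: root first
        c = c_bottom.pop(node)
        D = cache.node_D[node]
        row = c * D
        tot = row.sum()
        marg[node] = row / tot if tot > 0 else np.full(S, 1.0 / S)
        if itree.is_tip(node):
            continue
        l, r = int(itree.left[node]), int(itree.right[node])
        Dl, Dr = cache.child_D_at_node[node]
        for child, sib_D in ((l, Dr), (r, Dl)):
            c_top = tables.combine_adjoint(params, c, sib_D)
            # walk the child's branch from the node down to the child,
            # transposing each cell propagator; record slice distributions
            cells = cache.cells_between(float(itree.ages[child]), float(itree.ages[node]))
            if want is not None:
                D_at: dict[int, np.ndarray] = {}
                Dv = cache.node_D[child]
                for g in cells:
                    if g in want:
                        D_at[g] = Dv
                    Dv = cache.propagators[g] @ Dv
            cv = c_top
            for g in reversed(list(cells)):
                cv = cache.propagators[g].T @ cv
                m = cv.max()
                if m > 0 and (m > 1e6 or m < 1e-6):
                    cv = cv / m
                if want is not None and g in want:
                    p = cv * D_at[g]
                    s = p.sum()
                    if s > 0:
                        slice_dists[want[g]].append((child, p / s))
            c_bottom[child] = cv
    return (marg, slice_dists) if eval_times is not None else (marg, None)


def node_marginals(tree, tip_ranges: Mapping[str, RangeState], params: RateParams,
                   space: StateSpace, model: str,
                   options: LikelihoodOptions | None = None,
                   tables: ModelTables | None = None) -> NodeMarginals:
    """Marginal ancestral-range probabilities at every node.

    Tips report their observed range with probability one (reconstruction is
    run at full sampling of the given tips); internal nodes carry the
    clamp-and-renormalize posterior described in the module docstring.
    """
    opts = options or LikelihoodOptions()
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    tbl = tables if tables is not None else ModelTables(space, model)
    tip_idx = _tip_state_indices(itree, tip_ranges, space)
    D_root, log_root, E_root, cache = _checkpoint_downpass(
        itree, tip_idx, params, tbl, opts, want_cache=True)
    from .likelihood import _assemble_root

    loglik, w, _post = _assemble_root(D_root, log_root, E_root, opts, tbl.n_states)
    cache.root_weights = w
    cache.loglik = loglik
    marg, _ = _uppass(cache)
    return NodeMarginals(itree=itree, space=space, probs=marg, loglik=loglik)


@dataclass
class OriginSummary:
    """Inferred geographic origin of the clade from the root marginal.

    ``origin`` collects the areas whose root presence probability reaches the
    threshold; when none does, it falls back to the areas of the single most
    probable root state (reported via ``fallback_state``).  The full root
    distribution is always retained — the thresholding is a summary, not the
    inference.
    """

    root_distribution: np.ndarray
    presence: np.ndarray
    origin: tuple[str, ...]
    threshold: float
    fallback_state: str | None
    space: StateSpace

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "origin": list(self.origin),
            "fallback_state": self.fallback_state,
            "presence": {a.label: float(p) for a, p in zip(self.space.areas, self.presence)},
            "root_distribution": {
                self.space.format_state(s): float(p)
                for s, p in zip(self.space.states, self.root_distribution)
            },
        }


def ancestral_origin(marginals: NodeMarginals, threshold: float = 0.5) -> OriginSummary:
    """Threshold the root's per-area presence probabilities."""
    space = marginals.space
    root_p = marginals.root
    presence = marginals.presence[marginals.itree.root]
    passing = [space.areas[a].label for a in range(space.n_areas) if presence[a] >= threshold]
    fallback = None
    if not passing:
        fallback = space.format_state(space.states[int(np.argmax(root_p))])
    return OriginSummary(root_distribution=root_p, presence=presence,
                         origin=tuple(passing), threshold=threshold,
                         fallback_state=fallback, space=space)


@dataclass
class RichnessProfile:
    """Expected number of lineages per area on a root-to-present time grid.

    Widespread lineages count toward every area they occupy, so the row sums
    are at least the number of contemporaneous branches.  At t = 0 the
    profile equals the observed per-area tip tallies exactly.
    """

    times: np.ndarray  # ages, descending from root age to 0
    richness: np.ndarray  # (n_slices, n_areas)
    n_branches: np.ndarray  # reconstructed-tree branches crossing each slice
    space: StateSpace

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.richness, columns=[a.label for a in self.space.areas])
        df.insert(0, "age", self.times)
        df.insert(1, "n_lineages", self.n_branches)
        return df


def richness_through_time(tree, tip_ranges: Mapping[str, RangeState],
                          params: RateParams, space: StateSpace, model: str,
                          options: LikelihoodOptions | None = None,
                          n_slices: int = 100,
                          tables: ModelTables | None = None) -> RichnessProfile:
    """Expected per-area lineage counts on a uniform root-age-to-present grid.

    A branch alive at age t contributes its conditional per-area presence
    probabilities at t; at the root-age slice the single crown ancestor is
    represented by the root marginal.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 time slices")
    opts = options or LikelihoodOptions()
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    tbl = tables if tables is not None else ModelTables(space, model)
    tip_idx = _tip_state_indices(itree, tip_ranges, space)
    T = itree.root_age
    times = np.linspace(T, 0.0, n_slices)
    interior = times[(times > 0) & (times < T)]
    D_root, log_root, E_root, cache = _checkpoint_downpass(
        itree, tip_idx, params, tbl, opts, extra_times=interior, want_cache=True)
    from .likelihood import _assemble_root

    loglik, w, _ = _assemble_root(D_root, log_root, E_root, opts, tbl.n_states)
    cache.root_weights = w
    cache.loglik = loglik
    marg, slice_dists = _uppass(cache, eval_times=interior)

    presence_cols = np.zeros((space.n_states, space.n_areas))
    for a in range(space.n_areas):
        presence_cols[list(space.states_containing(a)), a] = 1.0

    rich = np.zeros((n_slices, space.n_areas))
    counts = np.zeros(n_slices, dtype=int)
    tip_states = {v: tip_idx[v] for v in itree.tips}
    for k, t in enumerate(times):
        if t >= T:  # crown ancestor: one lineage, the root marginal
            rich[k] = marg[itree.root] @ presence_cols
            counts[k] = 1
        elif t <= 0:
            for v, si in tip_states.items():
                rich[k] += presence_cols[si]
            counts[k] = itree.n_tips
        else:
            for _branch, p in slice_dists[float(t)]:
                rich[k] += p @ presence_cols
                counts[k] += 1
    return RichnessProfile(times=times, richness=rich, n_branches=counts, space=space)


def speciation_mode_summary(grid) -> pd.DataFrame:
    """Per-scenario rate table behind the in-situ vs vicariance comparison.

    One row per (extinction level, model) cell with the four fitted rates and
    the in-situ to vicariant speciation ratio; the ratio is flagged infinite
    when the vicariance estimate sits at its lower bound.
    """
    df = grid.to_frame()
    if df.empty:
        raise ValueError("empty scenario grid")
    ratio = np.where(df["lambda_vic"] > 0, df["lambda_is"] / df["lambda_vic"], np.inf)
    df["insitu_vic_ratio"] = ratio
    df["ratio_at_bound"] = ~np.isfinite(ratio) | (df["lambda_vic"] <= 1.01e-6)
    return df
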