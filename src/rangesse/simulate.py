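"""Forward simulation of range diversification, and tree pruning.

The simulator realizes exactly the generative process the likelihood
integrates: per-lineage competing exponential clocks over the same event
tables — in-situ speciation, vicariance, dispersal, extirpation — plus
whole-lineage extinction at ``mu``.  Hazards are recomputed after every event
(exact Gillespie, no leaping), which is what lets the simulator serve as an
independent oracle for the likelihood: conditioned outcome frequencies must
reproduce normalized likelihoods.

Extinction removes every trace of a lineage from the reconstructed tree, so
each run yields both the full tree (extinct branches included) and the
pruned tree of sampled survivors, with per-event logs for rate calibration
checks.  Conditioning on a minimum number of survivors is by rejection, with
the retry count reported — the survivorship bias this induces is precisely
what survival-conditioned likelihoods model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .likelihood import ModelTables, RateParams
from .statespace import RangeState, StateSpace, build_state_space

__all__ = [
    "SimConfig",
    "SimResult",
    "SurvivalConditioningError",
    "simulate_forward",
    "prune_extinct",
    "make_fixture",
    "cherry_outcome_counts",
    "FIXTURE_PRESETS",
]


class SurvivalConditioningError(RuntimeError):
    """Raised when no replicate meets the survivor condition within budget."""


@dataclass(frozen=True)
class SimConfig:
    """Generative settings: areas, rates, cladogenesis model and stop rule.

    The root state defaults to a uniform draw over single-area states — a
    widespread ancestor should be an inference, not an assumption.  The stop
    rule is a time horizon, a cap on extant lineages (the horizon is then the
    moment the cap would be exceeded), or both, whichever comes first.
    """

    space: StateSpace
    params: RateParams
    model: str = "DEC"
    root_state: RangeState | None = None
    max_time: float | None = None
    max_extant: int | None = None
    min_survivors: int = 2
    crown_start: bool = False  # split at t=0; both sides must leave survivors
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.max_time is None and self.max_extant is None:
            raise ValueError("stop rule required: set max_time and/or max_extant")
        if self.max_time is not None and self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.max_extant is not None and self.max_extant < 2:
            raise ValueError("max_extant must be at least 2")


@dataclass
class _Node:
    nid: int
    parent: int  # -1 for the root lineage
    t_birth: float
    state_at_birth: int
    t_end: float | None = None
    children: tuple[int, int] | None = None
    extinct: bool = False
    state: int = -1  # current state while alive
    label: str = ""


@dataclass
class SimResult:
    """Simulator output: full and pruned trees, tip ranges, event log."""

    full_tree: dendropy.Tree
    pruned_tree: dendropy.Tree
    tip_ranges: dict[str, RangeState]
    event_log: list[tuple[float, int, str, int, int]]  # (t, lineage, kind, from, to)
    lineage_labels: dict[int, str]  # lineage id -> tip label (leaves only)
    event_counts: Counter
    seed: int
    retries: int
    horizon: float
    root_state: RangeState
    crown_state: RangeState  # true state at the pruned tree's crown node
    config: SimConfig = field(repr=False, default=None)

    @property
    def n_extant(self) -> int:
        return len(self.tip_ranges)


class _EventMenu:
    """Per-state event catalogue with total hazards, shared by all lineages."""

    def __init__(self, tables: ModelTables, params: RateParams) -> None:
        S = tables.n_states
        self.kinds: list[list[str]] = [[] for _ in range(S)]
        self.payload: list[list[tuple]] = [[] for _ in range(S)]
        self.weights: list[np.ndarray] = []
        for p, l, r, kind, mult in tables.clado.events:
            lam = (params.lambda_is if kind == "in_situ" else params.lambda_vic) * mult
            if lam > 0:
                self.kinds[p].append(kind)
                self.payload[p].append((l, r, lam))
        for src, dst, kind, mult in tables.ana.entries:
            rate = (params.d if kind == "dispersal" else params.e) * mult
            if rate > 0:
                self.kinds[src].append(kind)
                self.payload[src].append((dst, None, rate))
        if params.mu > 0:
            for i in range(S):
                self.kinds[i].append("extinction")
                self.payload[i].append((None, None, params.mu))
        for i in range(S):
            self.weights.append(np.array([pl[-1] for pl in self.payload[i]]))
        self.total = np.array([w.sum() for w in self.weights])
        self.cumw = [np.cumsum(w) for w in self.weights]
        self.clado: list[list[tuple]] = [
            [pl for k, pl in zip(self.kinds[i], self.payload[i])
             if k in ("in_situ", "vicariance")]
            for i in range(S)
        ]

    def draw_event(self, state: int, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self.cumw[state], rng.random() * self.total[state]))


def _attempt(config: SimConfig, menu: _EventMenu, space: StateSpace,
             rng: np.random.Generator):
    params = config.params
    if config.root_state is None:
        a = rng.integers(space.n_areas)
        root_state = space.states[space.state_index(RangeState(1 << int(a)))]
    else:
        root_state = config.root_state
    root_idx = space.state_index(root_state)
    nodes: list[_Node] = [_Node(0, -1, 0.0, root_idx, state=root_idx)]
    active: list[int] = [0]
    log: list[tuple[float, int, str, int, int]] = []
    t = 0.0
    if config.crown_start:
        events = menu.clado[root_idx]
        if not events:
            raise ValueError("crown start requires a cladogenetic event at the root")
        wts = np.cumsum([w for (_l, _r, w) in events])
        l, r, _w = events[int(np.searchsorted(wts, rng.random() * wts[-1]))]
        if rng.random() < 0.5:
            l, r = r, l
        c1 = _Node(1, 0, 0.0, l, state=l)
        c2 = _Node(2, 0, 0.0, r, state=r)
        nodes[0].t_end = 0.0
        nodes[0].children = (1, 2)
        nodes.extend([c1, c2])
        active = [1, 2]
        log.append((0.0, 0, "crown_split", root_idx, -1))
        log.append((0.0, 1, "birth", root_idx, l))
        log.append((0.0, 2, "birth", root_idx, r))
    while True:
        rates = menu.total[[nodes[i].state for i in active]]
        R = float(rates.sum())
        if R <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / R)
        if config.max_time is not None and t_next >= config.max_time:
            t = config.max_time
            break
        if not np.isfinite(t_next):
            return None, None, None, None  # nothing can happen and no horizon
        t = t_next
        lin = active[int(np.searchsorted(np.cumsum(rates), rng.random() * R))]
        st = nodes[lin].state
        k = menu.draw_event(st, rng)
        kind = menu.kinds[st][k]
        a, b, _rate = menu.payload[st][k]
        if kind in ("in_situ", "vicariance"):
            if config.max_extant is not None and len(active) >= config.max_extant:
                break  # horizon is the moment the cap would be exceeded
            l, r = (a, b) if rng.random() < 0.5 else (b, a)
            c1 = _Node(len(nodes), lin, t, l, state=l)
            nodes.append(c1)
            c2 = _Node(len(nodes), lin, t, r, state=r)
            nodes.append(c2)
            nodes[lin].t_end = t
            nodes[lin].children = (c1.nid, c2.nid)
            active.remove(lin)
            active.extend([c1.nid, c2.nid])
            log.append((t, lin, kind, st, -1))
            log.append((t, c1.nid, "birth", st, l))
            log.append((t, c2.nid, "birth", st, r))
        elif kind == "extinction":
            nodes[lin].t_end = t
            nodes[lin].extinct = True
            active.remove(lin)
            log.append((t, lin, kind, st, -1))
            if not active:
                return nodes, log, t, []  # total extinction
        else:  # dispersal / extirpation
            nodes[lin].state = a
            log.append((t, lin, kind, st, a))
    for i in active:
        nodes[i].t_end = t
    return nodes, log, t, active


def simulate_forward(config: SimConfig) -> SimResult:
    """Exact forward simulation, rejected until >= ``min_survivors`` remain."""
    tables = ModelTables(config.space, config.model)
    menu = _EventMenu(tables, config.params)
    rng = np.random.default_rng(config.seed)
    for retry in range(config.max_retries):
        nodes, log, horizon, extant = _attempt(config, menu, config.space, rng)
        if nodes is None:
            raise SurvivalConditioningError(
                "process froze with no stop time: all rates zero and no max_time"
            )
        if extant is not None and len(extant) >= config.min_survivors:
            if config.crown_start and _crown_node(nodes, set(extant)) != 0:
                continue  # one whole crown lineage died: reject
            return _package(config, nodes, log, horizon, extant, retry)
    raise SurvivalConditioningError(
        f"no replicate with >= {config.min_survivors} survivors in "
        f"{config.max_retries} attempts; extinction may be overwhelming speciation"
    )


def _package(config: SimConfig, nodes: list[_Node], log, horizon: float,
             extant: list[int], retries: int) -> SimResult:
    space = config.space
    n_tip = 0
    n_x = 0
    for nd in nodes:
        if nd.children is None:
            if nd.extinct:
                n_x += 1
                nd.label = f"x{n_x}"
            else:
                n_tip += 1
                nd.label = f"t{n_tip}"
    full = _to_dendropy(nodes)
    extant_labels = {nodes[i].label for i in extant}
    pruned = prune_extinct(full, extant_labels=extant_labels)
    tip_ranges = {nodes[i].label: space.states[nodes[i].state] for i in extant}
    # the pruned crown: the earliest node with sampled descendants on both sides
    crown = _crown_node(nodes, set(extant))
    # truth at the reconstruction's crown node is the crown lineage's range
    # at the moment it split (after any range evolution during its lifetime)
    crown_state = space.states[nodes[crown].state]
    return SimResult(
        full_tree=full, pruned_tree=pruned, tip_ranges=tip_ranges,
        event_log=log,
        lineage_labels={nd.nid: nd.label for nd in nodes if nd.children is None},
        event_counts=Counter(e[2] for e in log if e[2] != "birth"),
        seed=config.seed, retries=retries, horizon=horizon,
        root_state=space.states[nodes[0].state_at_birth],
        crown_state=crown_state, config=config,
    )


def _crown_node(nodes: list[_Node], extant: set[int]) -> int:
    has_sampled: dict[int, bool] = {}
    for nd in reversed(nodes):  # children are appended after their parents
        if nd.children is None:
            has_sampled[nd.nid] = nd.nid in extant
        else:
            has_sampled[nd.nid] = any(has_sampled[c] for c in nd.children)
    v = 0
    while nodes[v].children is not None:
        kids = [c for c in nodes[v].children if has_sampled[c]]
        if len(kids) == 2:
            return v
        v = kids[0]
    return v


def _to_dendropy(nodes: list[_Node]) -> dendropy.Tree:
    tree = dendropy.Tree()
    tree.is_rooted = True
    dnodes: dict[int, dendropy.Node] = {}
    for nd in nodes:
        dn = dendropy.Node()
        dn.edge.length = (nd.t_end - nd.t_birth) if nd.t_end is not None else 0.0
        dnodes[nd.nid] = dn
        if nd.parent >= 0:
            dnodes[nd.parent].add_child(dn)
    tree.seed_node = dnodes[0]
    tns = tree.taxon_namespace
    for nd in nodes:
        if nd.children is None:
            dnodes[nd.nid].taxon = tns.new_taxon(nd.label)
    return tree


def prune_extinct(full_tree: dendropy.Tree, extinct_labels: set[str] | None = None,
                  extant_labels: set[str] | None = None) -> dendropy.Tree:
    """Drop extinct leaves and suppress the resulting degree-2 nodes.

    By default a leaf is extinct when its depth falls short of the maximum
    leaf depth (beyond rounding tolerance); explicit label sets override the
    heuristic.  Branch lengths merge across suppressed nodes, so extant tip
    depths and pairwise divergence times are untouched.
    """
    tree = full_tree.clone(depth=1)
    if extant_labels is None:
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        tmax = max(depths)
        tol = 1e-9 * max(tmax, 1.0)
        extant_labels = {
            lf.taxon.label for lf in tree.leaf_node_iter()
            if lf.root_distance >= tmax - tol
        }
        if extinct_labels is not None:
            extant_labels -= extinct_labels
    if not extant_labels:
        raise ValueError("all lineages extinct: nothing to reconstruct")
    taxa = [t for t in tree.taxon_namespace if t.label in extant_labels]
    tree.retain_taxa(taxa)
    # drop any remaining root knuckle so the crown node is the root
    while tree.seed_node.num_child_nodes() == 1:
        child = tree.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        tree.seed_node = child
    tree.suppress_unifurcations()
    return tree


def _run_lineage_pool(state0: int, T: float, menu: _EventMenu,
                      rng: np.random.Generator) -> list[int]:
    """Evolve one founding lineage for duration T; return extant tip states.

    Lightweight variant of the full simulator (no tree bookkeeping) used by
    the conditioned-outcome oracle checks.
    """
    states = [state0]
    totals = menu.total
    t = 0.0
    while states:
        per = [totals[s] for s in states]
        R = sum(per)
        if R <= 0:
            break
        t += rng.exponential(1.0 / R)
        if t >= T:
            break
        u = rng.random() * R
        acc = 0.0
        for j, h in enumerate(per):
            acc += h
            if u < acc:
                break
        st = states[j]
        k = menu.draw_event(st, rng)
        kind = menu.kinds[st][k]
        a, b, _ = menu.payload[st][k]
        if kind in ("in_situ", "vicariance"):
            states[j] = a
            states.append(b)
        elif kind == "extinction":
            states.pop(j)
        else:
            states[j] = a
    return states


def cherry_outcome_counts(space: StateSpace, model: str, params: RateParams,
                          root_state: RangeState, T: float, n_accepted: int,
                          seed: int, max_draws: int | None = None):
    """Conditioned tip-range outcomes on a fixed two-tip tree of depth T.

    A root in ``root_state`` splits at age T through a cladogenetic event
    drawn with probability proportional to its rate (daughter order
    randomized); both daughter lineages then evolve forward under the full
    process.  A replicate is accepted when each side leaves exactly one
    extant lineage — i.e. when the reconstructed tree is exactly the fixed
    cherry.  Returns (Counter over ordered (left bits, right bits) outcomes,
    number of draws used).  Under the model, these frequencies must match the
    likelihoods of the cherry for each tip-range pair, normalized over pairs
    and computed with the root clamped to ``root_state`` — the keystone
    agreement between the simulator and the pruning likelihood.
    """
    tables = ModelTables(space, model)
    menu = _EventMenu(tables, params)
    rng = np.random.default_rng(seed)
    ridx = space.state_index(root_state)
    events = [(l, r, w) for (p, l, r, _k, m) in tables.clado.events if p == ridx
              for w in ((params.lambda_is if _k == "in_situ" else params.lambda_vic) * m,)
              if w > 0]
    if not events:
        raise ValueError("root state has no cladogenetic events at these rates")
    wts = np.array([w for (_, _, w) in events])
    wts = wts / wts.sum()
    counts: Counter = Counter()
    draws = 0
    budget = max_draws if max_draws is not None else 200 * n_accepted
    while sum(counts.values()) < n_accepted and draws < budget:
        draws += 1
        l, r, _ = events[int(rng.choice(len(events), p=wts))]
        if rng.random() < 0.5:
            l, r = r, l
        left = _run_lineage_pool(l, T, menu, rng)
        if len(left) != 1:
            continue
        right = _run_lineage_pool(r, T, menu, rng)
        if len(right) != 1:
            continue
        counts[(space.states[left[0]].bits, space.states[right[0]].bits)] += 1
    if sum(counts.values()) < n_accepted:
        raise SurvivalConditioningError("cherry conditioning budget exhausted")
    return counts, draws


# --------------------------------------------------------------- fixtures

IAA_AREAS = ("Borneo", "Sulawesi", "Sumatra", "Java", "Philippines",
             "NewGuinea", "SEAsia")

FIXTURE_PRESETS: dict[str, dict] = {
    # seven Indo-Australian areas, M = 3, intermediate lineage extinction;
    # rates keep most tip ranges at one or two areas, as in the region's
    # empirical clades
    "iaa7_small": dict(
        areas=IAA_AREAS, max_range_size=3, model="DEC",
        params=RateParams(lambda_is=0.25, lambda_vic=0.1, d=0.04, e=0.02, mu=0.1),
        max_extant=60, seed=2094,
    ),
    # the classic two-area, three-state system
    "two_area_geosse": dict(
        areas=("A", "B"), max_range_size=2, model="DEC",
        params=RateParams(lambda_is=0.3, lambda_vic=0.2, d=0.1, e=0.05, mu=0.1),
        max_extant=40, seed=511,
    ),
    # one area: the model collapses to plain birth-death
    "single_area_bd": dict(
        areas=("A",), max_range_size=1, model="DEC",
        params=RateParams(lambda_is=0.3, lambda_vic=0.0, d=0.0, e=0.0, mu=0.1),
        max_extant=50, seed=83,
    ),
}


@dataclass
class Fixture:
    """A packaged synthetic dataset plus the truth that generated it."""

    name: str
    space: StateSpace
    model: str
    params: RateParams
    sim: SimResult

    def truth_dict(self) -> dict:
        cfg = self.sim.config
        return {
            "preset": self.name,
            "seed": self.sim.seed,
            "model": self.model,
            "areas": list(self.space.labels),
            "max_range_size": self.space.max_range_size,
            "params": {
                "lambda_is": self.params.lambda_is, "lambda_vic": self.params.lambda_vic,
                "d": self.params.d, "e": self.params.e, "mu": self.params.mu,
            },
            "root_state": self.space.format_state(self.sim.root_state),
            "crown_state": self.space.format_state(self.sim.crown_state),
            "n_extant": self.sim.n_extant,
            "horizon": self.sim.horizon,
            "retries": self.sim.retries,
            "event_counts": dict(self.sim.event_counts),
        }

    def write(self, out_dir) -> dict[str, str]:
        import json
        from pathlib import Path

        from .io import write_ranges
        from .trees import write_newick

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": str(out / f"{self.name}.nwk"),
            "full_tree": str(out / f"{self.name}_full.nwk"),
            "ranges": str(out / f"{self.name}_ranges.tsv"),
            "truth": str(out / f"{self.name}_truth.json"),
        }
        write_newick(self.sim.pruned_tree, paths["tree"])
        write_newick(self.sim.full_tree, paths["full_tree"])
        write_ranges(self.sim.tip_ranges, self.space, paths["ranges"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2)
        return paths


def make_fixture(preset: str) -> Fixture:
    """Regenerate a named synthetic dataset; deterministic for fixed preset."""
    if preset not in FIXTURE_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(FIXTURE_PRESETS)}")
    spec = FIXTURE_PRESETS[preset]
    space = build_state_space(spec["areas"], spec["max_range_size"])
    cfg = SimConfig(space=space, params=spec["params"], model=spec["model"],
                    max_extant=spec["max_extant"], seed=spec["seed"])
    sim = simulate_forward(cfg)
    return Fixture(name=preset, space=space, model=spec["model"],
                   params=spec["params"], sim=sim)
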