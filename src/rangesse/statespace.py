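"""Geographic range state spaces and event tables.

A lineage's biogeographic state is the non-empty set of areas it occupies,
encoded as a bit pattern over ``N`` named areas.  The state space enumerates
every subset of size 1..M (M is the cap on ancestral range size; analyses of
Indo-Australian clades typically use M = 3).  Two event tables drive both the
likelihood and the forward simulator:

* the anagenetic table — single-area range gains (dispersal/colonization) and
  single-area losses (extirpation) along branches;
* the cladogenetic table — in-situ speciation and vicariance at nodes, under
  either the DEC convention (subset sympatry; narrow vicariance with a
  single-area daughter) or the DIVA convention (no subset sympatry; any
  bipartition into complementary daughter ranges).

States are ordered by range size, then by ascending bit pattern, so state
indices are reproducible across runs and serialized outputs are stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Literal

__all__ = [
    "Area",
    "RangeState",
    "StateSpace",
    "AnageneticTable",
    "CladoEventTable",
    "build_state_space",
    "build_anagenetic_table",
    "build_clado_table",
    "parse_range",
    "DISPERSAL",
    "EXTIRPATION",
    "IN_SITU",
    "VICARIANCE",
]

DISPERSAL = "dispersal"
EXTIRPATION = "extirpation"
IN_SITU = "in_situ"
VICARIANCE = "vicariance"

Model = Literal["DEC", "DIVA"]


@dataclass(frozen=True)
class Area:
    """A named geographic area at a fixed position in the area ordering."""

    label: str
    index: int


@dataclass(frozen=True)
class RangeState:
    """A non-empty set of areas encoded as a bit pattern (bit i = area i)."""

    bits: int

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    def contains(self, area_index: int) -> bool:
        return bool(self.bits >> area_index & 1)

    def area_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.bits.bit_length()) if self.bits >> i & 1)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RangeState({self.bits:b})"


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of all allowed ranges over an ordered area list.

    ``states`` holds every non-empty subset of areas with size <= M, sorted by
    (size, bit pattern); ``index_of`` maps a :class:`RangeState` back to its
    index.  The enumeration is deterministic, so downstream tables, likelihood
    vectors and serialized marginals all share one stable indexing.
    """

    areas: tuple[Area, ...]
    max_range_size: int
    states: tuple[RangeState, ...] = field(default=(), compare=False)
    index_of: dict[RangeState, int] = field(default_factory=dict, compare=False, repr=False)

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.areas)

    def state_index(self, state: RangeState) -> int:
        try:
            return self.index_of[state]
        except KeyError:
            raise KeyError(f"range {self.format_state(state)!r} is not in the state space") from None

    def state_of_labels(self, labels: Iterable[str]) -> RangeState:
        lookup = {a.label: a.index for a in self.areas}
        bits = 0
        for lab in labels:
            if lab not in lookup:
                raise ValueError(f"unknown area label {lab!r}; known: {', '.join(lookup)}")
            bits |= 1 << lookup[lab]
        return self._check(RangeState(bits))

    def _check(self, state: RangeState) -> RangeState:
        if state.bits == 0:
            raise ValueError("empty range is not a valid state")
        if state.size > self.max_range_size:
            raise ValueError(
                f"range of {state.size} areas exceeds the cap of {self.max_range_size}"
            )
        if state.bits >> self.n_areas:
            raise ValueError("range refers to areas outside this space")
        return state

    def format_state(self, state: RangeState, sep: str = "+") -> str:
        return sep.join(self.areas[i].label for i in state.area_indices())

    def sizes(self) -> tuple[int, ...]:
        return tuple(s.size for s in self.states)

    def states_containing(self, area_index: int) -> tuple[int, ...]:
        """Indices of all states whose range includes the given area."""
        return tuple(i for i, s in enumerate(self.states) if s.contains(area_index))


def build_state_space(area_labels: Iterable[str], max_range_size: int) -> StateSpace:
    """Enumerate all non-empty ranges of size <= ``max_range_size``.

    The state count equals sum_{k=1..M} C(N, k); e.g. 7 areas capped at three
    give 63 states, and two uncapped areas give the familiar three-state
    {A}, {B}, {A,B} system.
    """
    labels = tuple(area_labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate area labels: {dupes}")
    if not labels:
        raise ValueError("at least one area is required")
    n = len(labels)
    if not 1 <= max_range_size <= n:
        raise ValueError(f"max_range_size must be in [1, {n}], got {max_range_size}")
    areas = tuple(Area(lab, i) for i, lab in enumerate(labels))
    states: list[RangeState] = []
    for k in range(1, max_range_size + 1):
        bits_of_size = sorted(sum(1 << i for i in combo) for combo in combinations(range(n), k))
        states.extend(RangeState(b) for b in bits_of_size)
    assert len(states) == sum(comb(n, k) for k in range(1, max_range_size + 1))
    space = StateSpace(
        areas=areas,
        max_range_size=max_range_size,
        states=tuple(states),
        index_of={s: i for i, s in enumerate(states)},
    )
    return space


@dataclass(frozen=True)
class AnageneticTable:
    """Along-branch range transitions: (from, to, kind, multiplicity).

    Dispersal entries add exactly one area; the multiplicity |S| counts the
    occupied source areas, each an independent colonization source at the
    per-pair rate d.  Extirpation entries drop one area at per-area rate e and
    never empty a range: a single-area lineage can only disappear through
    whole-lineage extinction, which is a separate instantaneous process.
    """

    entries: tuple[tuple[int, int, str, int], ...]

    def by_kind(self, kind: str) -> tuple[tuple[int, int, str, int], ...]:
        return tuple(e for e in self.entries if e[2] == kind)


@dataclass(frozen=True)
class CladoEventTable:
    """Cladogenetic events: (parent, left, right, kind, multiplicity).

    Daughter pairs are unordered and stored once, with left <= right by state
    index.  Every event reconstructs its parent: the union of daughter ranges
    equals the parent range, and vicariance daughters are disjoint.
    """

    model: Model
    events: tuple[tuple[int, int, int, str, int], ...]

    def by_kind(self, kind: str) -> tuple[tuple[int, int, int, str, int], ...]:
        return tuple(e for e in self.events if e[3] == kind)

    def events_of_parent(self, parent_index: int) -> tuple[tuple[int, int, int, str, int], ...]:
        return tuple(e for e in self.events if e[0] == parent_index)


def build_anagenetic_table(space: StateSpace) -> AnageneticTable:
    """Enumerate every legal one-area gain and one-area loss."""
    entries: list[tuple[int, int, str, int]] = []
    for i, s in enumerate(space.states):
        k = s.size
        if k < space.max_range_size:
            for a in range(space.n_areas):
                if not s.contains(a):
                    j = space.index_of[RangeState(s.bits | 1 << a)]
                    entries.append((i, j, DISPERSAL, k))
        if k >= 2:
            for a in s.area_indices():
                j = space.index_of[RangeState(s.bits & ~(1 << a))]
                entries.append((i, j, EXTIRPATION, 1))
    return AnageneticTable(entries=tuple(entries))


def _canonical_pair(space: StateSpace, left: RangeState, right: RangeState) -> tuple[int, int]:
    i, j = space.index_of[left], space.index_of[right]
    return (i, j) if i <= j else (j, i)


def build_clado_table(space: StateSpace, model: Model) -> CladoEventTable:
    """Enumerate cladogenetic events for the DEC or DIVA convention.

    DEC: a single-area parent duplicates itself; a widespread parent either
    buds off one member area while retaining its full range (subset sympatry,
    one event per member) or splits with one single-area daughter (narrow
    vicariance).  DIVA: in-situ duplication only for single-area parents, and
    vicariance over every unordered bipartition into two non-empty
    complementary subsets.  For parents of three or fewer areas the two
    vicariance sets coincide (every bipartition then has a singleton side).
    """
    if model not in ("DEC", "DIVA"):
        raise ValueError(f"model must be 'DEC' or 'DIVA', got {model!r}")
    events: list[tuple[int, int, int, str, int]] = []
    for p, s in enumerate(space.states):
        if s.size == 1:
            events.append((p, p, p, IN_SITU, 1))
            continue
        if model == "DEC":
            for a in s.area_indices():
                single = RangeState(1 << a)
                l, r = _canonical_pair(space, single, s)
                events.append((p, l, r, IN_SITU, 1))
        seen: set[tuple[int, int]] = set()
        for a_bits in _bipartition_halves(s, model):
            left = RangeState(a_bits)
            right = RangeState(s.bits & ~a_bits)
            pair = _canonical_pair(space, left, right)
            if pair not in seen:
                seen.add(pair)
                events.append((p, pair[0], pair[1], VICARIANCE, 1))
    return CladoEventTable(model=model, events=tuple(events))


def _bipartition_halves(s: RangeState, model: Model) -> Iterable[int]:
    members = s.area_indices()
    if model == "DEC":
        for a in members:
            yield 1 << a
    else:
        # all non-empty proper submasks; canonical dedup happens in the caller
        sub = (s.bits - 1) & s.bits
        while sub:
            yield sub
            sub = (sub - 1) & s.bits


_SPLIT_RE = re.compile(r"[,;|]")


def parse_range(text: str, space: StateSpace) -> RangeState:
    """Parse a range from an area-label list or a 0/1 presence vector.

    Accepts either comma/semicolon/pipe-separated labels ("Borneo,Sumatra")
    or a presence vector with one 0/1 flag per area in order ("1 0 1 0 0 0 0"
    or "1010000").  Empty ranges and ranges above the size cap are rejected.
    """
    raw = text.strip()
    if not raw:
        raise ValueError("empty range: every lineage must occupy at least one area")
    flags = [t for t in re.split(r"[\s,;|]+", raw) if t]
    if len(flags) == 1 and len(flags[0]) > 1 and set(flags[0]) <= {"0", "1"}:
        flags = list(flags[0])
    if all(t in ("0", "1") for t in flags):
        if len(flags) == space.n_areas:
            bits = sum(1 << i for i, f in enumerate(flags) if f == "1")
            if bits == 0:
                raise ValueError("presence vector is all zeros: empty range")
            return space._check(RangeState(bits))
    labels = [t.strip() for t in _SPLIT_RE.split(raw) if t.strip()]
    return space._check(space.state_of_labels(labels))
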