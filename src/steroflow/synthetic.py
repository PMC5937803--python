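"""Synthetic fixtures and stand-in Leydig enzyme activities.

Two generators make every pipeline stage testable without any external data:

* :func:`make_fixture` builds small pathway graphs (chains, branches, merges,
  random DAGs) together with injection schedules and the noise-free expected
  token trace.  The expected trace comes from :func:`naive_expected_trace`, a
  deliberately naive scalar recurrence written independently of the simulation
  engine, so engine and oracle cannot share bugs.

* :func:`make_leydig_activities` draws random three-stage enzyme-activity
  tables that reproduce the qualitative maturational programme of the rat
  Leydig cell: an immature stage dominated by androgen-inactivating
  5α-reductase (SRD5A) and 3α-HSD (AKR1C) activity with little 17β-HSD
  (HSD17B), switching to an HSD17B-dominated adult stage with collapsed
  SRD5A/AKR1C.  The programme is encoded as ratio *bounds* (fold-change
  windows and cross-enzyme floors), not merely orderings, because the
  downstream steroid crossover is a quantitative consequence of the
  order-of-magnitude activity switches reported for maturing Leydig cells.
  Tables that invert the switch are also generable (``violate=True``) and
  demonstrably break the crossover, so the constraint pattern is not vacuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mepn import MepnGraph, MepnNode, NodeKind
from .models import LEYDIG_ENZYMES, STAGES, StageActivityTable
from .schedule import InjectionSchedule, Segment

__all__ = [
    "FixtureSpec",
    "Fixture",
    "TOPOLOGIES",
    "make_fixture",
    "naive_expected_trace",
    "RatioBound",
    "ActivityConstraints",
    "UnsatisfiableConstraints",
    "make_leydig_activities",
    "random_mepn_graph",
    "random_schedule",
]

TOPOLOGIES = ("chain", "branch", "merge", "random-dag")


# ---------------------------------------------------------------------------
# Analytic fixtures


@dataclass(frozen=True)
class FixtureSpec:
    topology: str
    n_entities: int = 4
    injection_amount: float = 10.0
    seed: int = 0
    n_blocks: int = 50

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}"
            )
        if self.n_entities < 2:
            raise ValueError("n_entities must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not self.injection_amount >= 0:
            raise ValueError("injection_amount must be >= 0")


@dataclass
class Fixture:
    spec: FixtureSpec
    graph: MepnGraph
    schedules: dict[str, InjectionSchedule]
    places: tuple[str, ...]
    #: noise-free expected tokens, shape (n_blocks, n_places)
    expected: np.ndarray


def _entity_edges(spec: FixtureSpec) -> list[tuple[int, int]]:
    n = spec.n_entities
    if spec.topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if spec.topology == "branch":
        return [(0, j) for j in range(1, n)]
    if spec.topology == "merge":
        return [(i, n - 1) for i in range(n - 1)]
    rng = np.random.default_rng(spec.seed)
    edges: list[tuple[int, int]] = []
    for j in range(1, n):
        parents = [i for i in range(j) if rng.random() < 0.35]
        if not parents:
            parents = [int(rng.integers(0, j))]
        edges.extend((i, j) for i in parents)
    return edges


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build a fixture graph, its schedules, and the analytic expected trace.

    Entities are biochemical nodes ``e0..e{n-1}``; every direct edge is an
    implicit single-input/single-output transition.  Source entities (no
    incoming edge) carry a token input injecting ``injection_amount`` tokens
    per block over the whole horizon.
    """
    edges = _entity_edges(spec)
    places = tuple(f"e{i}" for i in range(spec.n_entities))

    graph = MepnGraph(name=f"fixture-{spec.topology}-{spec.seed}")
    for place in places:
        graph.add_node(place, NodeKind.BIOCHEMICAL, label=place)
    for i, j in edges:
        graph.add_edge(places[i], places[j])

    targets = {j for _, j in edges}
    sources = [i for i in range(spec.n_entities) if i not in targets]
    schedules: dict[str, InjectionSchedule] = {}
    for i in sources:
        place = places[i]
        tid = f"TI_{place}"
        graph.add_node(tid, NodeKind.TOKEN_INPUT, label=f"token input: {place}")
        graph.add_edge(tid, place)
        schedules[place] = InjectionSchedule(
            (Segment(1, spec.n_blocks, spec.injection_amount),), target=place
        )

    expected = naive_expected_trace(
        places,
        [(places[i], places[j]) for i, j in edges],
        {p: [(s.start, s.end, s.amount) for s in sched.segments]
         for p, sched in schedules.items()},
        spec.n_blocks,
    )
    return Fixture(spec, graph, schedules, places, expected)


def naive_expected_trace(
    places: Sequence[str],
    transitions: Sequence[tuple[str, str]],
    segments: Mapping[str, Sequence[tuple[int, int, float]]],
    n_blocks: int,
) -> np.ndarray:
    """Brute-force noise-free recurrence for single-input/single-output nets.

    Scalar, dictionary-based and deliberately plain: inject, take each
    transition's demand as its input place's tokens, scale demands that
    overdraw a place proportionally, then move all fluxes at once.  This is
    the engine's primary oracle and shares no code with it.
    """
    state = {p: 0.0 for p in places}
    out = np.zeros((n_blocks, len(places)))
    for block in range(1, n_blocks + 1):
        for place in sorted(segments, key=list(places).index):
            amount = 0.0
            for start, end, value in segments[place]:
                if start <= block <= end:
                    amount = value
            state[place] = state[place] + amount

        demands = []
        for source, _target in transitions:
            demands.append(state[source])

        load = {p: 0.0 for p in places}
        for (source, _target), demand in zip(transitions, demands):
            load[source] = load[source] + demand

        scale = {}
        for p in places:
            if load[p] > state[p]:
                scale[p] = state[p] / load[p]
            else:
                scale[p] = 1.0

        new = dict(state)
        for (source, target), demand in zip(transitions, demands):
            flux = demand * scale[source]
            new[source] = new[source] - flux
            new[target] = new[target] + flux
        for p in places:
            new[p] = max(new[p], 0.0)
        state = new
        for k, p in enumerate(places):
            out[block - 1, k] = state[p]
    return out


# ---------------------------------------------------------------------------
# Constraint-based activity tables

_VARIABLES: tuple[tuple[str, str], ...] = tuple(
    (enzyme, stage) for enzyme in LEYDIG_ENZYMES for stage in STAGES
)


class UnsatisfiableConstraints(ValueError):
    """The ratio constraints admit no assignment."""


@dataclass(frozen=True)
class RatioBound:
    """Require ``lo <= activity[upper] / activity[lower] <= hi``.

    ``upper`` and ``lower`` are (enzyme, stage) pairs; ``lo > 1`` encodes a
    strict "greater than" with a guaranteed fold gap.
    """

    upper: tuple[str, str]
    lower: tuple[str, str]
    lo: float
    hi: float = math.inf

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.hi:
            raise ValueError(f"invalid ratio window [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class ActivityConstraints:
    """A set of ratio bounds over (enzyme, stage) activities."""

    bounds: tuple[RatioBound, ...]

    @classmethod
    def default(cls) -> "ActivityConstraints":
        """The maturational programme of the rat Leydig cell.

        HSD17B rises sharply into adulthood while the androgen-inactivating
        SRD5A and AKR1C activities are high in immature cells and collapse in
        adults; the upstream cholesterol-to-androstenedione cascade (CYP11A1,
        HSD3B, CYP17A1) is non-decreasing with maturation and always exceeds
        the capacity of the androstenedione-consuming enzymes, so substrate
        supply is never limiting.  CYP17A1 carries double floors because one
        protein node serves two sequential reactions.
        """
        B = RatioBound
        bounds: list[RatioBound] = [
            # the 17beta-HSD switch
            B(("HSD17B", "adult"), ("HSD17B", "immature"), 7.0, 12.0),
            B(("HSD17B", "progenitor"), ("HSD17B", "immature"), 0.05, 0.3),
            # androgen-inactivating activities: high immature, collapsed adult
            B(("SRD5A", "immature"), ("HSD17B", "immature"), 3.0, 8.0),
            B(("SRD5A", "progenitor"), ("SRD5A", "immature"), 1.0, 1.8),
            B(("SRD5A", "immature"), ("SRD5A", "adult"), 10.0, 40.0),
            B(("AKR1C", "immature"), ("HSD17B", "immature"), 0.6, 1.0),
            B(("AKR1C", "progenitor"), ("AKR1C", "immature"), 0.5, 1.0),
            B(("AKR1C", "immature"), ("AKR1C", "adult"), 10.0, 40.0),
        ]
        for enzyme, m in (("CYP11A1", 1.0), ("HSD3B", 1.0), ("CYP17A1", 2.0)):
            bounds += [
                # non-decreasing with maturation
                B((enzyme, "immature"), (enzyme, "progenitor"), 1.0, 1.15),
                B((enzyme, "adult"), (enzyme, "immature"), 1.0, 1.15),
                # capacity floors: supply exceeds androstenedione drain
                B((enzyme, "progenitor"), ("SRD5A", "progenitor"), 1.5 * m, 8.0 * m),
                B((enzyme, "immature"), ("SRD5A", "immature"), 1.7 * m, 20.0 * m),
                B((enzyme, "adult"), ("HSD17B", "adult"), 1.5 * m, 20.0 * m),
            ]
        return cls(tuple(bounds))

    def _closure(self) -> np.ndarray:
        """All-pairs tightest lower bounds on log-activity differences."""
        idx = {v: i for i, v in enumerate(_VARIABLES)}
        n = len(_VARIABLES)
        need = np.full((n, n), -math.inf)
        np.fill_diagonal(need, 0.0)
        for bound in self.bounds:
            for var in (bound.upper, bound.lower):
                if var not in idx:
                    raise ValueError(f"unknown enzyme/stage pair {var!r}")
            u, l = idx[bound.upper], idx[bound.lower]
            need[u, l] = max(need[u, l], math.log(bound.lo))
            if math.isfinite(bound.hi):
                need[l, u] = max(need[l, u], -math.log(bound.hi))
        for k in range(n):
            via = need[:, k, None] + need[None, k, :]
            np.maximum(need, via, out=need)
        return need

    def check_satisfiable(self) -> np.ndarray:
        need = self._closure()
        conflict = need + need.T
        bad = np.argwhere(conflict > 1e-12)
        if bad.size:
            i, j = bad[0]
            a, b = _VARIABLES[i], _VARIABLES[j]
            raise UnsatisfiableConstraints(
                f"conflicting constraints between {a[0]}[{a[1]}] and {b[0]}[{b[1]}]"
            )
        return need

    def satisfied_by(self, table: StageActivityTable, tol: float = 1e-9) -> bool:
        for bound in self.bounds:
            num = table.activity(*bound.upper)
            den = table.activity(*bound.lower)
            if den == 0:
                return False
            ratio = num / den
            if ratio < bound.lo * (1 - tol) or ratio > bound.hi * (1 + tol):
                return False
        return True


# default magnitude window (pmol/min/million cells) for unconstrained draws
_LOG_LO, _LOG_HI = math.log(0.5), math.log(50.0)
_SPAN = math.log(10.0)

#: the maturational-switch enzymes; swapping their immature/adult activities
#: inverts the programme
SWITCH_ENZYMES = ("HSD17B", "SRD5A", "AKR1C")


def make_leydig_activities(
    constraints: ActivityConstraints | None = None,
    seed: int = 0,
    violate: bool = False,
) -> StageActivityTable:
    """Draw a random stage-activity table satisfying *constraints*.

    Values are sampled log-uniformly, one variable at a time, inside the
    tightest interval implied by the transitively-closed ratio bounds and the
    already-assigned variables; unconstrained variables fall in
    [0.5, 50] pmol/min/million cells.  Identical seeds give identical tables.

    With ``violate=True`` the immature and adult activities of the switch
    enzymes (HSD17B, SRD5A, AKR1C) are swapped after sampling, producing a
    table that inverts the maturational programme — used to show that the
    downstream crossover genuinely depends on the constraint pattern.

    Raises :class:`UnsatisfiableConstraints` (naming a conflicting pair) when
    the bounds admit no assignment.
    """
    if constraints is None:
        constraints = ActivityConstraints.default()
    need = constraints.check_satisfiable()
    rng = np.random.default_rng(seed)

    idx = {v: i for i, v in enumerate(_VARIABLES)}
    values: dict[int, float] = {}
    for var in _VARIABLES:
        i = idx[var]
        lo, hi = -math.inf, math.inf
        for j, vj in values.items():
            if math.isfinite(need[i, j]):
                lo = max(lo, vj + need[i, j])
            if math.isfinite(need[j, i]):
                hi = min(hi, vj - need[j, i])
        if not math.isfinite(lo) and not math.isfinite(hi):
            lo, hi = _LOG_LO, _LOG_HI
        elif not math.isfinite(lo):
            lo = hi - _SPAN
        elif not math.isfinite(hi):
            hi = lo + _SPAN
        if hi < lo:  # numerically tight corner; collapse to the bound
            hi = lo
        values[i] = float(rng.uniform(lo, hi))

    data = {
        enzyme: tuple(
            math.exp(values[idx[(enzyme, stage)]]) for stage in STAGES
        )
        for enzyme in LEYDIG_ENZYMES
    }
    if violate:
        for enzyme in SWITCH_ENZYMES:
            p, i, a = data[enzyme]
            data[enzyme] = (p, a, i)
    return StageActivityTable.from_dict(data)


# ---------------------------------------------------------------------------
# Random graphs for round-trip testing

_LABEL_POOL = (
    "testosterone", "3α-diol", "Δ4-androstenedione", "HSD17B", "SRD5A",
    "cholesterol", "token input", "17OH-progesterone", "",
)
_TISSUE_POOL = ("testis", "ovary", "placenta", "adrenal glomerulosa")


def random_schedule(rng: np.random.Generator, max_segments: int = 4) -> InjectionSchedule:
    """A random valid schedule: sorted, non-overlapping, non-negative."""
    n_segments = int(rng.integers(0, max_segments + 1))
    segments = []
    cursor = 1
    for _ in range(n_segments):
        start = cursor + int(rng.integers(0, 5))
        end = start + int(rng.integers(0, 30))
        if rng.random() < 0.5:
            amount = float(rng.integers(0, 50))
        else:
            amount = float(np.round(rng.uniform(0, 50), 6))
        segments.append(Segment(start, end, amount))
        cursor = end + 1
    return InjectionSchedule(tuple(segments))


def random_mepn_graph(rng: np.random.Generator, max_nodes: int = 12) -> MepnGraph:
    """A random typed graph exercising every node kind and optional field."""
    graph = MepnGraph(name=f"random-{int(rng.integers(0, 1_000_000))}")
    n_nodes = int(rng.integers(1, max_nodes + 1))
    kinds = list(NodeKind)
    for i in range(n_nodes):
        kind = kinds[int(rng.integers(0, len(kinds)))]
        url = None
        if kind == NodeKind.BIOCHEMICAL and rng.random() < 0.5:
            url = f"https://www.chemspider.com/Search.aspx?q=steroid{i}"
        elif kind == NodeKind.GENE and rng.random() < 0.5:
            url = f"https://www.ensembl.org/Multi/Search/Results?q=gene{i}"
        position = None
        if rng.random() < 0.5:
            position = (
                float(np.round(rng.uniform(-500, 500), 3)),
                float(np.round(rng.uniform(-500, 500), 3)),
            )
        graph.add_node(
            f"n{i}",
            kind,
            label=_LABEL_POOL[int(rng.integers(0, len(_LABEL_POOL)))],
            url=url,
            position=position,
        )
        if rng.random() < 0.3:
            graph.tag_tissue(
                f"n{i}", _TISSUE_POOL[int(rng.integers(0, len(_TISSUE_POOL)))]
            )
    node_ids = list(graph.nodes)
    n_edges = int(rng.integers(0, 2 * n_nodes))
    for _ in range(n_edges):
        a, b = rng.integers(0, n_nodes, size=2)
        if a == b:
            continue
        label = None
        if rng.random() < 0.3:
            from .schedule import format_schedule

            label = format_schedule(random_schedule(rng)) or None
        graph.add_edge(node_ids[int(a)], node_ids[int(b)], label)
    return graph
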