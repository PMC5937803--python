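"""Stochastic signalling-Petri-net execution of mEPN graphs.

A pathway diagram is compiled to a place/transition net: biochemical and
protein nodes become token-holding places, each process node becomes one
transition (inputs = its entity predecessors, outputs = its entity
successors), and each direct entity-to-entity edge becomes one implicit
single-input/single-output transition.  Token inputs and annotation nodes are
excluded from the net; token inputs act purely through their injection
schedules.

Execution is synchronous per time block:

1. *Injection*: every scheduled place receives ``max(0, c * (1 + sigma * z))``
   tokens, where ``c`` is the scheduled amount for the block and ``z`` is a
   standard-normal draw (``sigma = 0`` is the exact deterministic limit).
2. *Flux*: each transition demands the minimum of its input places' tokens
   (computed on the post-injection state).  When the summed demand on a place
   exceeds its tokens, every demand drawing on that place is scaled down
   proportionally.
3. *Application*: all fluxes apply simultaneously.  Consumptive transitions
   (the default) subtract the realised flux from every input place —
   catalysts included — and add it to every output place.

These semantics are order-independent and admit an exact closed-form check on
acyclic chains; tokens advance at most one transition per block, producing the
wave-front propagation characteristic of token-flow animations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mepn import MepnGraph, NodeKind, PLACE_KINDS, validate_graph
from .schedule import InjectionSchedule, amount_at, format_schedule, parse_schedule

__all__ = [
    "Transition",
    "PetriNet",
    "SimulationConfig",
    "TokenTrace",
    "CompileError",
    "compile_net",
    "step",
    "simulate",
    "knockout",
    "summarize",
    "stage_mean",
    "trace_to_csv",
    "summary_to_csv",
]


class CompileError(ValueError):
    """The graph cannot be compiled to a place/transition net."""


@dataclass(frozen=True)
class Transition:
    id: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    source: str  # "process:<node id>" or "edge:<source>-><target>"


@dataclass(frozen=True)
class PetriNet:
    places: tuple[str, ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        for t in self.transitions:
            if not t.inputs or not t.outputs:
                raise CompileError(f"transition {t.id} must have inputs and outputs")

    @property
    def place_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.places)}


def compile_net(graph: MepnGraph) -> PetriNet:
    """Deterministically compile an mEPN graph to a place/transition net.

    Raises :class:`CompileError` if the graph has error-severity validation
    findings or a process node lacks an entity predecessor or successor.
    """
    errors = [f for f in validate_graph(graph) if f.severity == "error"]
    if errors:
        detail = "; ".join(f"{f.subject}: {f.message}" for f in errors)
        raise CompileError(f"graph fails validation: {detail}")

    places = tuple(n.id for n in graph.nodes.values() if n.kind in PLACE_KINDS)
    place_set = set(places)

    transitions: list[Transition] = []
    for node in graph.nodes.values():
        if node.kind != NodeKind.PROCESS:
            continue
        inputs = tuple(p for p in graph.predecessors(node.id) if p in place_set)
        outputs = tuple(s for s in graph.successors(node.id) if s in place_set)
        if not inputs or not outputs:
            raise CompileError(
                f"process node {node.id!r} has no entity predecessor or successor"
            )
        transitions.append(Transition(node.id, inputs, outputs, f"process:{node.id}"))
    for edge in graph.edges:
        if edge.source in place_set and edge.target in place_set:
            transitions.append(
                Transition(
                    f"{edge.source}->{edge.target}",
                    (edge.source,),
                    (edge.target,),
                    f"edge:{edge.source}->{edge.target}",
                )
            )
    return PetriNet(places, tuple(transitions))


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings; the defaults are the reference experiment's settings
    (100 time blocks, 500 runs, standard-normal stochastic injections,
    consumptive transitions)."""

    n_blocks: int = 100
    n_runs: int = 500
    noise_sigma: float = 0.1
    consumptive: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.n_runs < 1:
            raise ValueError(f"n_runs must be >= 1, got {self.n_runs}")
        if not self.noise_sigma >= 0.0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")

    def to_dict(self) -> dict:
        return {
            "n_blocks": self.n_blocks,
            "n_runs": self.n_runs,
            "noise_sigma": self.noise_sigma,
            "consumptive": self.consumptive,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = {k: data[k] for k in
                 ("n_blocks", "n_runs", "noise_sigma", "consumptive", "seed")
                 if k in data}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**known)


@dataclass
class TokenTrace:
    """Per-run token tensor plus mean/variance summaries.

    ``tokens[run, block, place]`` holds the end-of-block token count; block
    indices are 0-based internally, 1-based in exported tables.  Variance is
    the sample variance across runs (runs are i.i.d. replicates); with
    ``noise_sigma = 0`` it is identically zero.
    """

    places: tuple[str, ...]
    tokens: np.ndarray  # shape (n_runs, n_blocks, n_places)
    config: SimulationConfig

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=float)
        if self.tokens.ndim != 3 or self.tokens.shape[2] != len(self.places):
            raise ValueError("tokens must have shape (runs, blocks, places)")

    @property
    def n_runs(self) -> int:
        return self.tokens.shape[0]

    @property
    def n_blocks(self) -> int:
        return self.tokens.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.tokens.mean(axis=0)

    @property
    def variance(self) -> np.ndarray:
        if self.n_runs < 2:
            return np.zeros(self.tokens.shape[1:])
        return self.tokens.var(axis=0, ddof=1)

    def place_column(self, place: str) -> int:
        try:
            return self.places.index(place)
        except ValueError:
            raise KeyError(
                f"unknown place {place!r}; known places: {list(self.places)}"
            ) from None

    def of(self, place: str) -> np.ndarray:
        """Per-run trajectories of one place, shape (n_runs, n_blocks)."""
        return self.tokens[:, :, self.place_column(place)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-run table (run, block, place, tokens)."""
        runs, blocks, nplaces = self.tokens.shape
        return pd.DataFrame(
            {
                "run": np.repeat(np.arange(runs), blocks * nplaces),
                "block": np.tile(np.repeat(np.arange(1, blocks + 1), nplaces), runs),
                "place": np.tile(np.array(self.places, dtype=object), runs * blocks),
                "tokens": self.tokens.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# Stepping


def _step_batch(
    state: np.ndarray,
    injections: np.ndarray,
    net: PetriNet,
    index: Mapping[str, int],
    consumptive: bool,
) -> np.ndarray:
    """One synchronous block update for a batch of runs.

    ``state`` and ``injections`` have shape (n_runs, n_places); returns the
    new state.  All floating-point accumulation walks the net's transitions
    in their fixed order, so results are bit-reproducible.
    """
    state = state + 0.0  # copy
    state += injections

    demands = []
    for t in net.transitions:
        cols = [index[p] for p in t.inputs]
        demands.append(np.min(state[:, cols], axis=1))

    loads = np.zeros_like(state)
    for t, d in zip(net.transitions, demands):
        for p in t.inputs:
            loads[:, index[p]] += d

    scale = np.ones_like(state)
    over = loads > state
    scale[over] = state[over] / loads[over]

    new = state.copy()
    for t, d in zip(net.transitions, demands):
        cols = [index[p] for p in t.inputs]
        flux = d * np.min(scale[:, cols], axis=1)
        if consumptive:
            for p in t.inputs:
                new[:, index[p]] -= flux
        for p in t.outputs:
            new[:, index[p]] += flux
    np.maximum(new, 0.0, out=new)
    return new


def step(
    state: Mapping[str, float],
    schedules: Mapping[str, InjectionSchedule],
    block: int,
    net: PetriNet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Advance a single state by one time block; returns the new state.

    Provided for inspection and unit-level work; :func:`simulate` runs the
    same update vectorised over replicate runs.
    """
    index = net.place_index
    vec = np.zeros((1, len(net.places)))
    for place, tokens in state.items():
        if place not in index:
            raise KeyError(f"unknown place {place!r}")
        if tokens < 0:
            raise ValueError(f"negative token count for {place!r}: {tokens}")
        vec[0, index[place]] = tokens

    inj = np.zeros_like(vec)
    sigma = config.noise_sigma
    for place in sorted(schedules, key=lambda p: index[p]):
        c = amount_at(schedules[place], block)
        if sigma > 0.0:
            if rng is None:
                raise ValueError("rng is required when noise_sigma > 0")
            c = max(0.0, c * (1.0 + sigma * rng.standard_normal()))
        inj[0, index[place]] = c

    new = _step_batch(vec, inj, net, index, config.consumptive)
    return {p: float(new[0, i]) for p, i in index.items()}


# ---------------------------------------------------------------------------
# Simulation


def _normalise_schedules(
    net: PetriNet, schedules: Mapping[str, InjectionSchedule | str]
) -> dict[str, InjectionSchedule]:
    index = net.place_index
    out: dict[str, InjectionSchedule] = {}
    unknown = [p for p in schedules if p not in index]
    if unknown:
        raise KeyError(
            f"schedules target unknown places {sorted(unknown)}; "
            f"known places: {list(net.places)}"
        )
    for place, sched in schedules.items():
        if isinstance(sched, str):
            sched = parse_schedule(sched, target=place)
        out[place] = sched
    return out


def simulate(
    net: PetriNet,
    schedules: Mapping[str, InjectionSchedule | str],
    config: SimulationConfig | None = None,
) -> TokenTrace:
    """Run ``config.n_runs`` independent replicates of ``config.n_blocks``
    sequential blocks from the all-zero state.

    Each replicate consumes an independent substream spawned from
    ``config.seed``, so traces are bit-identical across invocations (and
    independent of any batching of the runs).
    """
    if config is None:
        config = SimulationConfig()
    schedules = _normalise_schedules(net, schedules)
    index = net.place_index
    n_places = len(net.places)
    R, B = config.n_runs, config.n_blocks

    sched_places = sorted(schedules, key=lambda p: index[p])
    sched_cols = [index[p] for p in sched_places]
    base = np.zeros((B, len(sched_places)))
    for j, place in enumerate(sched_places):
        for b in range(B):
            base[b, j] = amount_at(schedules[place], b + 1)

    sigma = config.noise_sigma
    if sigma > 0.0 and sched_places:
        streams = np.random.SeedSequence(config.seed).spawn(R)
        z = np.empty((R, B, len(sched_places)))
        for r in range(R):
            z[r] = np.random.default_rng(streams[r]).standard_normal(
                (B, len(sched_places))
            )
        amounts = np.maximum(base[None, :, :] * (1.0 + sigma * z), 0.0)
    else:
        amounts = np.broadcast_to(base, (R, B, len(sched_places)))

    state = np.zeros((R, n_places))
    tokens = np.empty((R, B, n_places))
    inj = np.zeros((R, n_places))
    for b in range(B):
        inj[:] = 0.0
        for j, col in enumerate(sched_cols):
            inj[:, col] = amounts[:, b, j]
        state = _step_batch(state, inj, net, index, config.consumptive)
        tokens[:, b, :] = state

    return TokenTrace(net.places, tokens, config)


def knockout(
    schedules: Mapping[str, InjectionSchedule], target: str
) -> dict[str, InjectionSchedule]:
    """Mimic a loss-of-function mutation: remove *target*'s token input.

    Returns a copy of the schedule map without the target (injection 0 at
    every block); all other schedules are unchanged.
    """
    if target not in schedules:
        raise KeyError(
            f"no token input to remove for {target!r}; "
            f"scheduled nodes: {sorted(schedules)}"
        )
    return {p: s for p, s in schedules.items() if p != target}


def summarize(trace: TokenTrace, places: Sequence[str] | None = None) -> pd.DataFrame:
    """Long-format summary table (place, block, mean, variance)."""
    if places is None:
        places = trace.places
    cols = [trace.place_column(p) for p in places]
    mean, var = trace.mean, trace.variance
    blocks = np.arange(1, trace.n_blocks + 1)
    frames = [
        pd.DataFrame(
            {
                "place": place,
                "block": blocks,
                "mean": mean[:, c],
                "variance": var[:, c],
            }
        )
        for place, c in zip(places, cols)
    ]
    return pd.concat(frames, ignore_index=True)


def stage_mean(trace: TokenTrace, place: str, start: int, end: int) -> float:
    """Mean tokens at *place* over blocks ``start``..``end`` (inclusive),
    averaged across runs — the stage-level summary used to compare steroids."""
    if not 1 <= start <= end <= trace.n_blocks:
        raise ValueError(f"invalid block window {start}-{end}")
    col = trace.place_column(place)
    return float(trace.tokens[:, start - 1 : end, col].mean())


def trace_to_csv(trace: TokenTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def summary_to_csv(
    trace: TokenTrace, path: str | Path, places: Sequence[str] | None = None
) -> None:
    summarize(trace, places).to_csv(path, index=False)
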