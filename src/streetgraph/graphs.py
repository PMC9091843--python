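"""Street-graph models and one-step transition kernels for the Moran process.

A *street graph* is an evolutionary graph whose partitions are connected by
edges ("streets") that carry mutant offspring in one direction and resident
offspring in the opposite direction.  Two topologies are supported:

* ``cycle`` — k partition classes arranged in a ring; mutant offspring from
  class i land in class i+1 (mod k) when the direction is ``forward``.
* ``megastar`` — a central partition joined to ``m`` identical leaf chains;
  mutant offspring travel centre -> leaf position 1 -> ... -> leaf tip ->
  centre, and residents travel the reverse route.

On every time step one individual is chosen to reproduce with probability
proportional to its fitness (``r`` for mutants, 1 for residents), and its
offspring replaces a uniformly chosen individual in the partition at the end
of its street.  The mutant count vector ``S_t`` therefore performs a
multidimensional random walk absorbed at the all-mutant and all-resident
states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "StreetGraph",
    "MutantState",
    "TransitionKernel",
    "AbsorbingStateError",
    "make_cycle_graph",
    "make_megastar_graph",
    "total_fitness",
    "reproduction_weight",
    "transition_kernel",
    "jump_distribution",
    "iter_states",
    "graph_to_dict",
    "graph_from_dict",
]

#: Largest supported individual-partition size.  Products of branch values
#: raised to partition-size powers are formed directly, so very large sizes
#: would push those products to extreme magnitudes.
MAX_PARTITION_SIZE = 200

_DIRECTIONS = ("forward", "backward")
_TOPOLOGIES = ("cycle", "megastar")


class AbsorbingStateError(ValueError):
    """Raised when an active-step quantity is requested at an absorbing state."""


def _check_sizes(sizes: Sequence[int], field: str) -> tuple[int, ...]:
    out = []
    for s in sizes:
        if int(s) != s or s < 1:
            raise ValueError(f"{field} must contain positive integers, got {list(sizes)}")
        if s > MAX_PARTITION_SIZE:
            raise ValueError(f"{field}: partition size {s} exceeds the supported cap {MAX_PARTITION_SIZE}")
        out.append(int(s))
    return tuple(out)


@dataclass(frozen=True)
class StreetGraph:
    """Immutable description of a street graph.

    ``class_sizes`` lists the partition-class sizes ``[A, B, ..., Ω]``.  For a
    cycle the classes are the physical partitions; for a megastar class 0 is
    the centre and classes 1..L are the leaf positions, each realised
    ``num_leaves`` times.
    """

    topology: str
    class_sizes: tuple[int, ...]
    num_leaves: int
    fitness: float
    mutant_direction: str

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}, got {self.topology!r}")
        if self.mutant_direction not in _DIRECTIONS:
            raise ValueError(
                f"mutant_direction must be one of {_DIRECTIONS}, got {self.mutant_direction!r}"
            )
        if not (self.fitness > 0):
            raise ValueError(f"fitness must be positive, got {self.fitness}")
        if self.num_leaves < 1:
            raise ValueError(f"num_leaves must be >= 1, got {self.num_leaves}")
        if self.topology == "cycle":
            if self.num_leaves != 1:
                raise ValueError("a cycle has num_leaves == 1")
            if len(self.class_sizes) < 2:
                raise ValueError("a cycle needs at least 2 partition classes")
        else:
            if len(self.class_sizes) < 2:
                raise ValueError("a megastar needs a centre and at least one leaf position")

    # -- layout -----------------------------------------------------------

    @property
    def num_classes(self) -> int:
        return len(self.class_sizes)

    @cached_property
    def physical_sizes(self) -> tuple[int, ...]:
        if self.topology == "cycle":
            return self.class_sizes
        leaf = self.class_sizes[1:]
        return (self.class_sizes[0],) + leaf * self.num_leaves

    @cached_property
    def class_of_partition(self) -> tuple[int, ...]:
        if self.topology == "cycle":
            return tuple(range(self.num_classes))
        length = self.num_classes - 1
        out = [0]
        for _ in range(self.num_leaves):
            out.extend(range(1, length + 1))
        return tuple(out)

    @property
    def num_partitions(self) -> int:
        return len(self.physical_sizes)

    @property
    def population_size(self) -> int:
        return sum(self.physical_sizes)

    @cached_property
    def streets(self) -> tuple[tuple[int, int], ...]:
        """Directed edges (u, v): mutant offspring travel u -> v, resident
        offspring travel v -> u."""
        if self.topology == "cycle":
            k = self.num_classes
            edges = [(i, (i + 1) % k) for i in range(k)]
        else:
            length = self.num_classes - 1
            edges = []
            for j in range(self.num_leaves):
                base = 1 + j * length
                chain = [0] + list(range(base, base + length)) + [0]
                edges.extend(zip(chain[:-1], chain[1:]))
        if self.mutant_direction == "backward":
            edges = [(v, u) for (u, v) in edges]
        return tuple(edges)

    @cached_property
    def class_multiplicity(self) -> tuple[int, ...]:
        """How many physical partitions realise each class."""
        if self.topology == "cycle":
            return (1,) * self.num_classes
        return (1,) + (self.num_leaves,) * (self.num_classes - 1)

    @cached_property
    def fixation_boundary(self) -> tuple[int, ...]:
        """Class-aggregated all-mutant state ``a = [A, mB, ..., mΩ]``."""
        return tuple(s * m for s, m in zip(self.class_sizes, self.class_multiplicity))

    def with_fitness(self, r: float) -> "StreetGraph":
        return replace(self, fitness=float(r))

    def reversed(self) -> "StreetGraph":
        other = "backward" if self.mutant_direction == "forward" else "forward"
        return replace(self, mutant_direction=other)


@dataclass(frozen=True)
class MutantState:
    """Mutant counts per physical partition (the vector ``S_t``)."""

    counts: tuple[int, ...]

    @classmethod
    def all_resident(cls, graph: StreetGraph) -> "MutantState":
        return cls((0,) * graph.num_partitions)

    @classmethod
    def all_mutant(cls, graph: StreetGraph) -> "MutantState":
        return cls(tuple(graph.physical_sizes))


StateLike = MutantState | Sequence[int] | np.ndarray


def as_state(graph: StreetGraph, state: StateLike) -> np.ndarray:
    """Validate and coerce a state to an integer array over physical partitions."""
    counts = state.counts if isinstance(state, MutantState) else state
    arr = np.asarray(counts, dtype=np.int64)
    if arr.shape != (graph.num_partitions,):
        raise ValueError(
            f"state has {arr.size} entries but the graph has {graph.num_partitions} partitions"
        )
    sizes = np.asarray(graph.physical_sizes)
    if np.any(arr < 0) or np.any(arr > sizes):
        raise ValueError(f"state {arr.tolist()} outside [0, sizes={sizes.tolist()}]")
    return arr


def aggregate_classes(graph: StreetGraph, state: StateLike) -> np.ndarray:
    """Sum mutant counts over the physical partitions of each class."""
    arr = as_state(graph, state)
    out = np.zeros(graph.num_classes, dtype=np.int64)
    np.add.at(out, np.asarray(graph.class_of_partition), arr)
    return out


@dataclass(frozen=True)
class TransitionKernel:
    """One-step probabilities: ``up[i]`` (mutant count in partition i rises),
    ``down[i]`` (falls), and ``stay`` (no change)."""

    up: np.ndarray
    down: np.ndarray
    stay: float

    @property
    def is_absorbing(self) -> bool:
        return self.stay >= 1.0 - 1e-12


# -- constructors ---------------------------------------------------------


def make_cycle_graph(
    sizes: Sequence[int], r: float, mutant_direction: str = "forward"
) -> StreetGraph:
    """Cyclic k-partite street graph with partition sizes ``[A, B, ..., Ω]``.

    ``forward`` sends mutant offspring from partition i to partition i+1
    (mod k) and resident offspring from i to i-1; ``backward`` swaps the two.
    """
    sizes = _check_sizes(sizes, "sizes")
    if len(sizes) < 2:
        raise ValueError(f"sizes needs at least 2 partitions, got {len(sizes)}")
    if not (r > 0):
        raise ValueError(f"r must be positive, got {r}")
    return StreetGraph("cycle", sizes, 1, float(r), mutant_direction)


def make_megastar_graph(
    center_size: int,
    leaf_sizes: Sequence[int],
    num_leaves: int,
    r: float,
    mutant_direction: str = "forward",
) -> StreetGraph:
    """Megastar street graph: a centre of size ``center_size`` joined to
    ``num_leaves`` identical leaf chains with per-position sizes
    ``leaf_sizes``."""
    (center_size,) = _check_sizes([center_size], "center_size")
    leaf_sizes = _check_sizes(leaf_sizes, "leaf_sizes")
    if len(leaf_sizes) < 1:
        raise ValueError("leaf_sizes must name at least one partition")
    if int(num_leaves) != num_leaves or num_leaves < 1:
        raise ValueError(f"num_leaves must be a positive integer, got {num_leaves}")
    if not (r > 0):
        raise ValueError(f"r must be positive, got {r}")
    return StreetGraph(
        "megastar", (center_size,) + leaf_sizes, int(num_leaves), float(r), mutant_direction
    )


# -- kernels --------------------------------------------------------------


def total_fitness(graph: StreetGraph, state: StateLike) -> float:
    """Total fitness ``F = Σ_i (r·S_i + size_i − S_i)``."""
    arr = as_state(graph, state)
    n_mut = int(arr.sum())
    return graph.fitness * n_mut + (graph.population_size - n_mut)


def reproduction_weight(graph: StreetGraph, state: StateLike) -> float:
    """Normalising weight of the per-street reproduction lottery,
    ``W = Σ_streets (r·S_u + size_v − S_v)`` over streets (u, v).

    Each (individual, outgoing street) slot carries the individual's fitness.
    On a cycle every individual owns exactly one slot per species role, so
    ``W`` equals the total fitness ``F``; on a megastar the centre sits on
    ``m`` streets and is weighted accordingly, which keeps the kernel a
    probability distribution at every state.  Ratios of transition
    probabilities — and hence the martingale equations, the fixation
    probability and everything about the active-step count — are independent
    of this choice of normalisation; only the raw-time clock ``T`` feels it.
    """
    arr = as_state(graph, state)
    sizes = graph.physical_sizes
    r = graph.fitness
    w = 0.0
    for u, v in graph.streets:
        w += r * arr[u] + (sizes[v] - arr[v])
    return w


def transition_kernel(graph: StreetGraph, state: StateLike) -> TransitionKernel:
    """Exact one-step transition probabilities at ``state``.

    For each street (u, v): a mutant in u reproduces along it with
    probability ``r·S_u/W`` and its offspring replaces a uniform member of v
    (an active up-step in v iff that member is a resident); a resident in v
    reproduces toward u with probability ``(size_v − S_v)/W`` (an active
    down-step in u iff it replaces a mutant).  ``W`` is the street-slot
    weight of :func:`reproduction_weight`; for cycles it equals the total
    fitness ``F``.
    """
    arr = as_state(graph, state)
    sizes = np.asarray(graph.physical_sizes, dtype=np.float64)
    w = reproduction_weight(graph, arr)
    r = graph.fitness
    up = np.zeros(graph.num_partitions)
    down = np.zeros(graph.num_partitions)
    for u, v in graph.streets:
        up[v] += (r * arr[u] / w) * ((sizes[v] - arr[v]) / sizes[v])
        down[u] += ((sizes[v] - arr[v]) / w) * (arr[u] / sizes[u])
    stay = 1.0 - (up.sum() + down.sum())
    return TransitionKernel(up=up, down=down, stay=max(stay, 0.0))


def jump_distribution(graph: StreetGraph, state: StateLike) -> TransitionKernel:
    """Active-step (embedded jump chain) distribution: the kernel conditioned
    on the mutant count changing."""
    kern = transition_kernel(graph, state)
    if kern.is_absorbing:
        raise AbsorbingStateError(f"state {as_state(graph, state).tolist()} has no active transition")
    active = 1.0 - kern.stay
    return TransitionKernel(up=kern.up / active, down=kern.down / active, stay=0.0)


def iter_states(graph: StreetGraph) -> Iterator[tuple[int, ...]]:
    """All ``∏(size_i + 1)`` mutant-count vectors, lexicographically."""
    ranges = [range(s + 1) for s in graph.physical_sizes]
    return itertools.product(*ranges)


# -- plain-document round trip -------------------------------------------


def graph_to_dict(graph: StreetGraph) -> dict:
    if graph.topology == "cycle":
        return {
            "topology": "cycle",
            "sizes": list(graph.class_sizes),
            "r": graph.fitness,
            "mutant_direction": graph.mutant_direction,
        }
    return {
        "topology": "megastar",
        "sizes": graph.class_sizes[0],
        "leaf_sizes": list(graph.class_sizes[1:]),
        "num_leaves": graph.num_leaves,
        "r": graph.fitness,
        "mutant_direction": graph.mutant_direction,
    }


def graph_from_dict(spec: dict) -> StreetGraph:
    known = {"topology", "sizes", "leaf_sizes", "num_leaves", "r", "mutant_direction"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown graph-spec keys: {sorted(unknown)}")
    topology = spec.get("topology", "cycle")
    direction = spec.get("mutant_direction", "forward")
    try:
        r = float(spec["r"])
    except KeyError as exc:
        raise ValueError("graph spec is missing 'r' (fitness)") from exc
    if topology == "cycle":
        return make_cycle_graph(spec["sizes"], r, direction)
    if topology == "megastar":
        return make_megastar_graph(
            spec["sizes"], spec["leaf_sizes"], spec.get("num_leaves", 1), r, direction
        )
    raise ValueError(f"unknown topology {topology!r}")
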