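"""Seeded Monte-Carlo simulation of the Moran process on street graphs.

Each trial runs the process from ``S_0`` to absorption and records whether
the mutants fixed, the number of active steps ``C_T`` (mutant-count
changes), and the raw number of time steps ``T``.  Two modes exist:

* ``"jump"`` (default) draws each active transition from the embedded jump
  chain and adds a geometrically distributed run of null steps to ``T``
  (success probability 1 − stay) — distributionally identical to the raw
  process but much faster when the walk lingers near the boundaries;
* ``"full"`` draws every single time step from the raw kernel.

Per-trial RNG substreams are derived deterministically from the batch seed,
so batches are reproducible record-for-record regardless of execution order.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .graphs import StreetGraph, as_state, graph_to_dict, transition_kernel

__all__ = [
    "TrialRecord",
    "SimulationBatch",
    "EmpiricalSummary",
    "simulate_batch",
    "empirical_summary",
    "kappa_estimates",
]


class TrialRecord(NamedTuple):
    fixed: bool
    active_steps: int
    total_steps: int


@dataclass(frozen=True)
class SimulationBatch:
    """Vectorised per-trial records plus the spec needed to reproduce them."""

    fixed: np.ndarray  # bool, (n_trials,)
    active_steps: np.ndarray  # int64
    total_steps: np.ndarray  # int64
    seed: int
    mode: str
    graph_spec: dict
    s0: tuple[int, ...]

    @property
    def n_trials(self) -> int:
        return len(self.fixed)

    def records(self):
        return [
            TrialRecord(bool(f), int(c), int(t))
            for f, c, t in zip(self.fixed, self.active_steps, self.total_steps)
        ]


def _transition_table(graph: StreetGraph, cache: dict, state: tuple):
    """Cached per-state jump table: cumulative active probabilities, the
    (partition, ±1) move list, and the stay probability."""
    entry = cache.get(state)
    if entry is None:
        kern = transition_kernel(graph, state)
        moves, probs = [], []
        for p in range(graph.num_partitions):
            if kern.up[p] > 0:
                moves.append((p, 1))
                probs.append(kern.up[p])
            if kern.down[p] > 0:
                moves.append((p, -1))
                probs.append(kern.down[p])
        active = 1.0 - kern.stay
        cum = np.cumsum(np.asarray(probs) / active).tolist() if moves else []
        entry = (cum, moves, kern.stay)
        cache[state] = entry
    return entry


def simulate_batch(
    graph: StreetGraph,
    s0,
    n_trials: int,
    seed: int,
    mode: str = "jump",
) -> SimulationBatch:
    """Run ``n_trials`` independent trials from ``s0`` to absorption."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mode not in ("jump", "full"):
        raise ValueError(f"mode must be 'jump' or 'full', got {mode!r}")
    start = tuple(int(x) for x in as_state(graph, s0))
    fix_state = tuple(graph.physical_sizes)
    ext_state = (0,) * graph.num_partitions
    cache: dict = {}

    fixed = np.empty(n_trials, dtype=bool)
    counts = np.zeros(n_trials, dtype=np.int64)
    times = np.zeros(n_trials, dtype=np.int64)

    children = np.random.SeedSequence(seed).spawn(n_trials)
    for trial in range(n_trials):
        rng = np.random.default_rng(children[trial])
        state = start
        c = t = 0
        while state != fix_state and state != ext_state:
            cum, moves, stay = _transition_table(graph, cache, state)
            if mode == "jump":
                t += int(rng.geometric(1.0 - stay))
                c += 1
            else:
                t += 1
                if rng.random() < stay:
                    continue
                c += 1
            p, delta = moves[bisect_left(cum, rng.random())]
            lst = list(state)
            lst[p] += delta
            state = tuple(lst)
        fixed[trial] = state == fix_state
        counts[trial] = c
        times[trial] = t
    return SimulationBatch(
        fixed=fixed,
        active_steps=counts,
        total_steps=times,
        seed=int(seed),
        mode=mode,
        graph_spec=graph_to_dict(graph),
        s0=start,
    )


@dataclass(frozen=True)
class EmpiricalSummary:
    """Plug-in estimates from a batch; ``None`` marks an absent condition."""

    alpha: float
    n_fix: int
    n_ext: int
    moments_fix: tuple[float, float] | None
    moments_ext: tuple[float, float] | None
    histogram_fix: np.ndarray | None
    histogram_ext: np.ndarray | None
    theta_grid: np.ndarray
    ccf_fix: np.ndarray | None
    ccf_ext: np.ndarray | None


def _empirical_ccf(counts: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    out = np.empty(len(thetas), dtype=complex)
    for idx, th in enumerate(thetas):
        out[idx] = np.exp(1j * th * counts).mean()
    return out


def empirical_summary(batch: SimulationBatch, theta_grid) -> EmpiricalSummary:
    """Empirical fixation fraction, conditional moments, histograms and CCFs
    (``mean e^{iθ C_T}`` over trials of each absorption type)."""
    if batch.n_trials == 0:
        raise ValueError("batch is empty")
    thetas = np.asarray(theta_grid, dtype=float)
    c_fix = batch.active_steps[batch.fixed]
    c_ext = batch.active_steps[~batch.fixed]

    def side(counts: np.ndarray):
        if len(counts) == 0:
            return None, None, None
        moments = (float(counts.mean()), float((counts.astype(float) ** 2).mean()))
        hist = np.bincount(counts)
        return moments, hist, _empirical_ccf(counts, thetas)

    m_fix, h_fix, ccf_fix = side(c_fix)
    m_ext, h_ext, ccf_ext = side(c_ext)
    return EmpiricalSummary(
        alpha=float(batch.fixed.mean()),
        n_fix=int(batch.fixed.sum()),
        n_ext=int((~batch.fixed).sum()),
        moments_fix=m_fix,
        moments_ext=m_ext,
        histogram_fix=h_fix,
        histogram_ext=h_ext,
        theta_grid=thetas,
        ccf_fix=ccf_fix,
        ccf_ext=ccf_ext,
    )


def kappa_estimates(source) -> tuple[float, float]:
    """Sojourn scaling constants ``κ = E[T|·] / E[C_T|·]`` per absorption type.

    ``source`` is either a :class:`SimulationBatch` or a pair
    ``(count_moments, time_moments)`` of first-step-analysis results (objects
    with ``fix``/``ext`` moment tuples).
    """
    if isinstance(source, SimulationBatch):
        fixed = source.fixed
        if not fixed.any() or fixed.all():
            raise ZeroDivisionError(
                "kappa is undefined without trials of both absorption types"
            )
        mean_c_fix = source.active_steps[fixed].mean()
        mean_c_ext = source.active_steps[~fixed].mean()
        if mean_c_fix == 0 or mean_c_ext == 0:
            raise ZeroDivisionError("kappa is undefined when E[C_T | condition] = 0")
        return (
            float(source.total_steps[fixed].mean() / mean_c_fix),
            float(source.total_steps[~fixed].mean() / mean_c_ext),
        )
    count_moments, time_moments = source
    if count_moments.fix[0] == 0 or count_moments.ext[0] == 0:
        raise ZeroDivisionError("kappa is undefined when E[C_T | condition] = 0")
    return (
        float(time_moments.fix[0] / count_moments.fix[0]),
        float(time_moments.ext[0] / count_moments.ext[0]),
    )
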