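"""Exact, martingale-free reference computations on the full state space.

These routines answer the same questions as :mod:`streetgraph.stats` by
sparse linear algebra on the absorbing Markov chain: absorption
probabilities, the characteristic function and distribution of the
active-step count ``C_T`` (via the embedded jump chain, i.e. the chain with
self-loops removed), and first/second conditional moments of both ``C_T``
and the raw time ``T`` by first-step analysis.  They are deliberately
independent of the martingale construction so the two routes can check each
other.

The linear systems are assembled over the set of states reachable from the
initial state (breadth-first search over active transitions); configurations
the walk cannot visit never enter the computation, which keeps the systems
small for megastars.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graphs import (
    StreetGraph,
    as_state,
    iter_states,
    transition_kernel,
)

__all__ = [
    "StateIndex",
    "StateSpaceTooLargeError",
    "ExactMoments",
    "enumerate_states",
    "exact_absorption_probability",
    "exact_active_step_cf",
    "exact_active_step_cf_grid",
    "exact_active_step_distribution",
    "exact_count_moments",
    "exact_time_moments",
]

STATE_CAP = 200_000


class StateSpaceTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class StateIndex:
    """Bijection between mutant-count vectors and integers 0..M−1."""

    states: tuple[tuple[int, ...], ...]
    index: dict
    transient: np.ndarray  # indices of transient states
    fix_index: int
    ext_index: int

    @property
    def num_states(self) -> int:
        return len(self.states)

    def position(self, state) -> int:
        return self.index[tuple(int(x) for x in state)]


def _check_cap(graph: StreetGraph, cap: int) -> int:
    m = int(np.prod([s + 1 for s in graph.physical_sizes], dtype=np.int64))
    if m > cap:
        raise StateSpaceTooLargeError(f"state space has {m} states, above the cap {cap}")
    return m


def enumerate_states(graph: StreetGraph, cap: int = STATE_CAP) -> StateIndex:
    """Enumerate all ``∏ (size_i + 1)`` states and classify them.

    Absorbing states are identified by ``stay = 1``; for street graphs with
    every partition size ≥ 1 these are exactly the all-resident and
    all-mutant configurations.
    """
    m = _check_cap(graph, cap)
    states = tuple(iter_states(graph))
    index = {s: i for i, s in enumerate(states)}
    ext = index[(0,) * graph.num_partitions]
    fix = index[tuple(graph.physical_sizes)]
    transient = np.array([i for i in range(m) if i not in (ext, fix)], dtype=np.int64)
    for i in range(m):
        absorbing = transition_kernel(graph, states[i]).is_absorbing
        assert absorbing == (i in (ext, fix)), f"unexpected absorption at {states[i]}"
    return StateIndex(states=states, index=index, transient=transient, fix_index=fix, ext_index=ext)


class _ChainSystem:
    """Jump-chain operator over the transient states reachable from s0.

    ``q`` is the transient-to-transient jump matrix (self-loops eliminated
    analytically per state: active probabilities divided by 1 − stay),
    ``b_fix``/``b_ext`` the direct one-jump absorption probabilities, and
    ``stay`` the per-state self-loop probability of the raw kernel.
    """

    def __init__(self, graph: StreetGraph, s0) -> None:
        _check_cap(graph, STATE_CAP)
        start = tuple(int(x) for x in as_state(graph, s0))
        fix_state = tuple(graph.physical_sizes)
        ext_state = (0,) * graph.num_partitions
        self.start_absorbed = None
        if start == fix_state:
            self.start_absorbed = "fix"
            return
        if start == ext_state:
            self.start_absorbed = "ext"
            return

        pos: dict[tuple, int] = {start: 0}
        order = [start]
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        b_fix: list[float] = [0.0]
        b_ext: list[float] = [0.0]
        stay: list[float] = [0.0]
        queue = deque([start])
        while queue:
            state = queue.popleft()
            t = pos[state]
            kern = transition_kernel(graph, np.asarray(state))
            stay[t] = kern.stay
            active = 1.0 - kern.stay
            for p in range(graph.num_partitions):
                for delta, prob in ((1, kern.up[p]), (-1, kern.down[p])):
                    if prob == 0.0:
                        continue
                    nxt = list(state)
                    nxt[p] += delta
                    nxt = tuple(nxt)
                    q = prob / active
                    if nxt == fix_state:
                        b_fix[t] += q
                    elif nxt == ext_state:
                        b_ext[t] += q
                    else:
                        if nxt not in pos:
                            pos[nxt] = len(order)
                            order.append(nxt)
                            b_fix.append(0.0)
                            b_ext.append(0.0)
                            stay.append(0.0)
                            queue.append(nxt)
                        rows.append(t)
                        cols.append(pos[nxt])
                        vals.append(q)
        n_t = len(order)
        self.q = sp.csr_matrix((vals, (rows, cols)), shape=(n_t, n_t))
        self.b_fix = np.asarray(b_fix)
        self.b_ext = np.asarray(b_ext)
        self.stay = np.asarray(stay)
        self.start = 0  # s0 is always the first discovered state

    def full_kernel(self):
        """Raw-kernel variant (self-loops on the diagonal) for T-moments."""
        active = 1.0 - self.stay
        p_mat = sp.diags(active) @ self.q + sp.diags(self.stay)
        return p_mat, self.b_fix * active, self.b_ext * active


#: systems up to this size use a direct sparse LU; larger ones use BiCGSTAB
#: (the jump chains mix fast, so Krylov solves converge in a handful of
#: iterations where the LU factors fill in badly) with a direct fallback.
DIRECT_SOLVE_LIMIT = 2000


def _linear_solve(a_csc, rhs):
    n = a_csc.shape[0]
    if n > DIRECT_SOLVE_LIMIT:
        x, info = spla.bicgstab(a_csc, rhs, rtol=1e-13, atol=0.0, maxiter=10 * n)
        if info == 0:
            scale = np.linalg.norm(rhs) or 1.0
            if np.linalg.norm(a_csc @ x - rhs) / scale < 1e-11:
                return x
    return spla.spsolve(a_csc, rhs)


def _solve(a_mat, rhs):
    """Solve (I − A) x = rhs."""
    a_csc = (sp.eye(a_mat.shape[0], format="csc") - a_mat.tocsc()).tocsc()
    return _linear_solve(a_csc, rhs)


def exact_absorption_probability(graph: StreetGraph, s0) -> float:
    """Fixation probability by solving ``(I − Q)α = b_fix`` on the jump chain."""
    sys_ = _ChainSystem(graph, s0)
    if sys_.start_absorbed:
        return 1.0 if sys_.start_absorbed == "fix" else 0.0
    return float(_solve(sys_.q, sys_.b_fix)[sys_.start])


def exact_active_step_cf_grid(graph: StreetGraph, s0, thetas):
    """Conditional characteristic functions of ``C_T`` on a θ-grid.

    The reachable jump chain is assembled once and one phase-type system
    ``φ(s) = e^{iθ} Σ q(s→s') φ(s')`` is solved per grid point, with boundary
    value 1 at the target absorbing state and 0 at the other, normalised by
    α (resp. 1 − α).  Returns two complex arrays aligned with ``thetas``.
    """
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    sys_ = _ChainSystem(graph, s0)
    if sys_.start_absorbed:
        ones = np.ones(len(thetas), dtype=complex)
        return ones, ones.copy()
    alpha = float(_solve(sys_.q, sys_.b_fix)[sys_.start])
    n_t = sys_.q.shape[0]
    eye = sp.eye(n_t, format="csc")
    q_csc = sys_.q.tocsc().astype(complex)
    out_fix = np.empty(len(thetas), dtype=complex)
    out_ext = np.empty(len(thetas), dtype=complex)
    for idx, theta in enumerate(thetas):
        z = np.exp(1j * theta)
        a_mat = (eye - z * q_csc).tocsc()
        if n_t <= DIRECT_SOLVE_LIMIT:
            lu = spla.splu(a_mat)
            phi_fix = lu.solve(z * sys_.b_fix.astype(complex))
            phi_ext = lu.solve(z * sys_.b_ext.astype(complex))
        else:
            phi_fix = _linear_solve(a_mat, z * sys_.b_fix.astype(complex))
            phi_ext = _linear_solve(a_mat, z * sys_.b_ext.astype(complex))
        res = max(
            np.max(np.abs(a_mat @ phi_fix - z * sys_.b_fix)),
            np.max(np.abs(a_mat @ phi_ext - z * sys_.b_ext)),
        )
        if res > 1e-10:
            raise ArithmeticError(f"linear-solve residual {res:.2e} above 1e-10")
        out_fix[idx] = phi_fix[sys_.start] / alpha
        out_ext[idx] = phi_ext[sys_.start] / (1.0 - alpha)
    return out_fix, out_ext


def exact_active_step_cf(graph: StreetGraph, s0, theta: float) -> tuple[complex, complex]:
    """Scalar convenience wrapper around :func:`exact_active_step_cf_grid`."""
    fix, ext = exact_active_step_cf_grid(graph, s0, [theta])
    return complex(fix[0]), complex(ext[0])


def exact_active_step_distribution(graph: StreetGraph, s0, n_max: int):
    """Conditional distributions of ``C_T`` by propagating the sub-probability
    vector through the jump chain and recording absorption mass at each step."""
    sys_ = _ChainSystem(graph, s0)
    mass_fix = np.zeros(n_max + 1)
    mass_ext = np.zeros(n_max + 1)
    if sys_.start_absorbed:
        (mass_fix if sys_.start_absorbed == "fix" else mass_ext)[0] = 1.0
        return mass_fix, mass_ext
    alpha = float(_solve(sys_.q, sys_.b_fix)[sys_.start])
    qt = sys_.q.T.tocsr()
    v = np.zeros(sys_.q.shape[0])
    v[sys_.start] = 1.0
    for n in range(1, n_max + 1):
        mass_fix[n] = v @ sys_.b_fix
        mass_ext[n] = v @ sys_.b_ext
        v = qt @ v
    return mass_fix / alpha, mass_ext / (1.0 - alpha)


@dataclass(frozen=True)
class ExactMoments:
    """First and (optionally) second conditional moments per absorption type."""

    fix: tuple[float, ...]
    ext: tuple[float, ...]


def _exact_moments(graph: StreetGraph, s0, order: int, chain: str) -> ExactMoments:
    if not (1 <= order <= 2):
        raise ValueError("order must be 1 or 2")
    sys_ = _ChainSystem(graph, s0)
    if sys_.start_absorbed:
        zeros = (0.0,) * order
        return ExactMoments(fix=zeros, ext=zeros)
    if chain == "jump":
        a_mat, b_fix, b_ext = sys_.q, sys_.b_fix, sys_.b_ext
    else:
        a_mat, b_fix, b_ext = sys_.full_kernel()
    start = sys_.start
    alpha = _solve(a_mat, b_fix)
    one_minus = _solve(a_mat, b_ext)

    def side(avec) -> tuple[float, ...]:
        w = _solve(a_mat, avec)
        out = [float(w[start])]
        if order >= 2:
            v = _solve(a_mat, avec + 2.0 * (a_mat @ w))
            out.append(float(v[start]))
        return tuple(out)

    w_fix, w_ext = side(alpha), side(one_minus)
    a0, e0 = float(alpha[start]), float(one_minus[start])
    return ExactMoments(
        fix=tuple(x / a0 for x in w_fix),
        ext=tuple(x / e0 for x in w_ext),
    )


def exact_count_moments(graph: StreetGraph, s0, order: int = 2) -> ExactMoments:
    """Conditional moments of the active-step count ``C_T`` by first-step
    analysis on the embedded jump chain: ``(I − Q)w = α`` for
    ``E[C·1_fix]`` and ``(I − Q)v = α + 2Qw`` for ``E[C²·1_fix]``."""
    return _exact_moments(graph, s0, order, "jump")


def exact_time_moments(graph: StreetGraph, s0, order: int = 2) -> ExactMoments:
    """Conditional moments of the raw absorption time ``T`` (null steps
    included) via the same first-step analysis on the full kernel."""
    return _exact_moments(graph, s0, order, "full")
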