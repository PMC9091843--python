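"""Product-martingale construction for street graphs.

The process ``g^{C_t} ∏_i f_i(g)^{S_{i,t}}`` is a martingale whenever the
per-class functions ``f_i`` satisfy one state-independent "hyperbola"
equation per street class,

    (r / size_i) g f_i + (1 / size_j) g / f_j = r / size_i + 1 / size_j,

obtained by pairing the mutant transition into class i (from class j) with
the resident transition out of class j; the shared state-dependent factor
``S_j (size_i − S_i)`` cancels exactly.  Composing the Möbius maps implied by
the k equations around the class cycle collapses the system to a quadratic
with exactly two roots, giving two branch vectors ``f_1`` and ``f_2``.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .graphs import StreetGraph, iter_states, transition_kernel

__all__ = [
    "EdgeEquation",
    "BranchPair",
    "NeutralFitnessError",
    "BranchSolveError",
    "edge_equations",
    "branch_roots",
    "solve_branches",
    "branch_functions_at_one",
    "isothermal_branches",
    "martingale_residual",
]

DEFAULT_TOL = 1e-10
#: Default phase-grid spacing used for branch continuity tracking.
THETA_STEP = 2 * np.pi / 512


class NeutralFitnessError(ValueError):
    """Raised where r = 1 makes the requested closed form degenerate; use the
    neutral-limit path instead."""


class BranchSolveError(RuntimeError):
    """Raised when the branch solutions cannot be validated or tracked."""


@dataclass(frozen=True)
class EdgeEquation:
    """One state-independent equation
    ``coef_target·g·f[target] + coef_source·g/f[source] = rhs``."""

    target_class: int
    source_class: int
    coef_target: float  # r / size_target
    coef_source: float  # 1 / size_source
    rhs: float

    def residual(self, g: complex, f: np.ndarray) -> complex:
        return (
            self.coef_target * g * f[self.target_class]
            + self.coef_source * g / f[self.source_class]
            - self.rhs
        )


@dataclass(frozen=True)
class BranchPair:
    """The two solution vectors of the edge system at a given ``g``.

    ``branch1`` is the branch continuously connected to the all-ones vector
    at g = 1; ``branch2`` is its partner.  ``residual`` is the largest
    absolute edge-equation error over both branches.
    """

    g: complex
    branch1: np.ndarray
    branch2: np.ndarray
    residual: float


def _class_cycle(graph: StreetGraph) -> list[int]:
    """Mutant-direction order of partition classes: class_cycle[t] feeds
    class_cycle[t+1]."""
    order = list(range(graph.num_classes))
    if graph.mutant_direction == "backward":
        order = [order[0]] + order[1:][::-1]
    return order


def edge_equations(graph: StreetGraph) -> list[EdgeEquation]:
    """The k state-independent hyperbola equations, one per class street.

    For a megastar the leaf sums cancel leaf-by-leaf, so the reduced system
    coincides with the cyclic system on the class sizes ``[A, B, ..., Ω]``.
    """
    r = graph.fitness
    sizes = graph.class_sizes
    cyc = _class_cycle(graph)
    k = len(cyc)
    eqs = []
    for t in range(k):
        j, i = cyc[t], cyc[(t + 1) % k]
        eqs.append(
            EdgeEquation(
                target_class=i,
                source_class=j,
                coef_target=r / sizes[i],
                coef_source=1.0 / sizes[j],
                rhs=r / sizes[i] + 1.0 / sizes[j],
            )
        )
    return eqs


def _moebius_chain(graph: StreetGraph, g: complex) -> tuple[list[int], list[np.ndarray]]:
    """Per-edge Möbius maps f_target = M(f_source) along the class cycle.

    From the edge equation, ``f_i = (rhs·size_i·f_j − g·size_i/size_j) /
    (r·g·f_j)``.
    """
    r = graph.fitness
    sizes = graph.class_sizes
    cyc = _class_cycle(graph)
    mats = []
    for t in range(len(cyc)):
        j, i = cyc[t], cyc[(t + 1) % len(cyc)]
        rhs = r / sizes[i] + 1.0 / sizes[j]
        mats.append(
            np.array(
                [[rhs * sizes[i], -g * sizes[i] / sizes[j]], [r * g, 0.0]],
                dtype=complex,
            )
        )
    return cyc, mats


def _apply(m: np.ndarray, x: complex) -> complex:
    return (m[0, 0] * x + m[0, 1]) / (m[1, 0] * x + m[1, 1])


def _quadratic_coeffs(mats: list[np.ndarray]) -> tuple[complex, complex, complex]:
    """Coefficients of the fixed-point quadratic c x² + (d − a) x − b = 0 for
    the composed cycle map [[a, b], [c, d]]."""
    total = np.eye(2, dtype=complex)
    for m in mats:
        total = m @ total
    a, b = total[0]
    c, d = total[1]
    return c, d - a, -b


def _root_pair(graph: StreetGraph, g: complex) -> tuple[np.ndarray, np.ndarray]:
    """The two unordered solution vectors at ``g`` (indexed by class)."""
    if g == 0:
        raise ValueError("g must be nonzero")
    cyc, mats = _moebius_chain(graph, g)
    qa, qb, qc = _quadratic_coeffs(mats)
    disc = cmath.sqrt(qb * qb - 4 * qa * qc)
    # stable quadratic roots
    if abs(-qb + disc) >= abs(-qb - disc):
        x1 = (-qb + disc) / (2 * qa)
    else:
        x1 = (-qb - disc) / (2 * qa)
    x2 = qc / (qa * x1) if x1 != 0 else (-qb - disc) / (2 * qa)

    def back_substitute(x0: complex) -> np.ndarray:
        f = np.empty(graph.num_classes, dtype=complex)
        f[cyc[0]] = x0
        x = x0
        for t, m in enumerate(mats[:-1]):
            x = _apply(m, x)
            f[cyc[t + 1]] = x
        return f

    return back_substitute(x1), back_substitute(x2)


def _max_residual(graph: StreetGraph, g: complex, branches: list[np.ndarray]) -> float:
    eqs = edge_equations(graph)
    return max(abs(eq.residual(g, f)) for f in branches for eq in eqs)


def branch_roots(graph: StreetGraph, g: complex) -> tuple[np.ndarray, np.ndarray]:
    """Unordered branch pair at ``g``; cheap entry point for quantities that
    are invariant under swapping the branches (α and both CCFs)."""
    return _root_pair(graph, g)


def solve_branches(
    graph: StreetGraph, g: complex, tol: float = DEFAULT_TOL
) -> BranchPair:
    """Solve the edge system at ``g`` with branch labels continued from g = 1.

    ``branch1`` is tracked from the all-ones (trivial) solution at g = 1 by
    nearest-neighbour matching along a path from 1 to ``g``; ``branch2`` is
    the other root.  Both vectors are validated against every edge equation.
    """
    f1, f2 = _root_pair(graph, g)
    # continuity tracking of the branch-1 label from g = 1
    theta = cmath.phase(g)
    radius = abs(g)
    n_arc = max(1, int(np.ceil(abs(theta) / THETA_STEP)))
    path = [cmath.exp(1j * theta * s / n_arc) for s in range(n_arc + 1)]
    if abs(radius - 1.0) > 1e-12:
        n_rad = 16
        path += [cmath.rect(1 + (radius - 1) * s / n_rad, theta) for s in range(1, n_rad + 1)]
    current = 1.0 + 0.0j  # f of the first cycle class on branch 1
    c0 = _class_cycle(graph)[0]
    for gs in path[1:]:
        a, b = _root_pair(graph, gs)
        da, db = abs(a[c0] - current), abs(b[c0] - current)
        if abs(a[c0] - b[c0]) < 1e-12 and abs(graph.fitness - 1.0) > 1e-12:
            raise BranchSolveError(
                f"branch collision at g={gs:.6f}: nearest-neighbour tracking is ambiguous"
            )
        current = a[c0] if da <= db else b[c0]
    if abs(f1[c0] - current) > abs(f2[c0] - current):
        f1, f2 = f2, f1
    residual = _max_residual(graph, g, [f1, f2])
    if residual > tol:
        raise BranchSolveError(
            f"edge-equation residual {residual:.3e} exceeds tolerance {tol:.1e} at g={g}"
        )
    return BranchPair(g=g, branch1=f1, branch2=f2, residual=residual)


def branch_functions_at_one(graph: StreetGraph) -> np.ndarray:
    """The nontrivial branch vector ``f_i(1)`` (class-indexed).

    At g = 1 the trivial root of the fixed-point quadratic is 1, so the
    nontrivial root is the product of roots, and back-substitution recovers
    the remaining classes.  For a tripartite cycle this reproduces the
    compact closed forms, e.g. ``f_a(1) = (A + Br² + Cr)/(Ar³ + Br² + Cr)``.
    """
    if abs(graph.fitness - 1.0) < 1e-12:
        raise NeutralFitnessError(
            "f_i(1) degenerates to the all-ones vector at r = 1; use the neutral limit"
        )
    cyc, mats = _moebius_chain(graph, 1.0 + 0.0j)
    qa, qb, qc = _quadratic_coeffs(mats)
    x0 = qc / qa  # product of roots; the trivial root is exactly 1
    f = np.empty(graph.num_classes, dtype=complex)
    f[cyc[0]] = x0
    x = x0
    for t, m in enumerate(mats[:-1]):
        x = _apply(m, x)
        f[cyc[t + 1]] = x
    if _max_residual(graph, 1.0 + 0.0j, [f]) > 1e-8:
        raise BranchSolveError("nontrivial branch at g = 1 failed residual validation")
    return f


def isothermal_branches(r: float, theta: float) -> tuple[complex, complex]:
    """Branch values for an isothermal street graph (all classes equal).

    The k-dimensional system collapses to the single quadratic
    ``r g f² − (r + 1) f + g = 0`` with ``g = e^{iθ}``, i.e.
    ``f = ((r+1)e^{−τ} ± sqrt((r+1)²e^{−2τ} − 4r)) / 2r`` with ``τ = iθ`` —
    the branch functions of the fully connected Moran process.  Branch 1 is
    continued from f = 1 at θ = 0 and the pair satisfies ``f₁·f₂ = 1/r``.
    """
    if not (r > 0):
        raise ValueError(f"r must be positive, got {r}")

    def pair(th: float) -> tuple[complex, complex]:
        g = cmath.exp(1j * th)
        disc = cmath.sqrt((r + 1) ** 2 - 4 * r * g * g)
        u1 = ((r + 1) + disc) / (2 * r * g)
        u2 = ((r + 1) - disc) / (2 * r * g)
        return u1, u2

    n = max(1, int(np.ceil(abs(theta) / THETA_STEP)))
    current = 1.0 + 0.0j
    for s in range(1, n + 1):
        u1, u2 = pair(theta * s / n)
        current = u1 if abs(u1 - current) <= abs(u2 - current) else u2
    u1, u2 = pair(theta)
    if abs(u1 - current) <= abs(u2 - current):
        return u1, u2
    return u2, u1


def branch_table(graph: StreetGraph, thetas) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate both branch vectors over a θ-grid for CSV export: one row
    per θ with Re/Im columns for every class of each branch."""
    import pandas as pd

    rows = []
    for theta in np.asarray(thetas, dtype=float):
        pair = solve_branches(graph, cmath.exp(1j * theta))
        row = {"theta": theta}
        for label, vec in (("f1", pair.branch1), ("f2", pair.branch2)):
            for i, val in enumerate(vec):
                row[f"re_{label}_{i}"] = val.real
                row[f"im_{label}_{i}"] = val.imag
        rows.append(row)
    return pd.DataFrame(rows)


def martingale_residual(graph: StreetGraph, g: complex, branch: np.ndarray) -> float:
    """Largest deviation of ``E[g^{Y_t} ∏_i f_i^{X_{i,t}} | s]`` from 1 over
    all transient states, evaluated with the exact kernel.

    This is the defining conservation law of the product martingale; valid
    branch vectors drive it to solver tolerance, non-solutions do not.
    """
    f = np.asarray(branch, dtype=complex)
    if f.shape != (graph.num_classes,):
        raise ValueError(
            f"branch must have one entry per partition class ({graph.num_classes}), got {f.shape}"
        )
    cls = np.asarray(graph.class_of_partition)
    f_part = f[cls]
    worst = 0.0
    for state in iter_states(graph):
        kern = transition_kernel(graph, state)
        if kern.is_absorbing:
            continue
        expectation = kern.stay + g * (
            np.sum(kern.up * f_part) + np.sum(kern.down / f_part)
        )
        worst = max(worst, abs(expectation - 1.0))
    return worst
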