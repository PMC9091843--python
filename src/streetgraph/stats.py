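"""Absorption statistics extracted from the product martingale.

Optional stopping applied to ``g^{C_T} ∏_i f_i(g)^{S_{i,T}}`` at the two
absorbing boundaries yields, for the two branch vectors ``f_1`` and ``f_2``:

* the fixation probability
  ``α = (∏ f_i(1)^{S_{i,0}} − 1) / (∏ f_i(1)^{a_i} − 1)`` at g = 1, and
* the conditional characteristic functions (CCFs) of the active-step count
  ``C_T`` at ``g = e^{iθ}``,

  ψ_fix(θ) = (∏f₁^{S₀} − ∏f₂^{S₀}) / (α (∏f₁^a − ∏f₂^a)),
  ψ_ext(θ) = (∏f₁^a ∏f₂^{S₀} − ∏f₂^a ∏f₁^{S₀}) / ((1−α)(∏f₁^a − ∏f₂^a)).

All exponents are class-aggregated; for a megastar with m identical leaves
the fixation boundary is ``a = [A, mB, ..., mΩ]``.  Every quantity here is
invariant under swapping the two branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graphs import StreetGraph, aggregate_classes
from .martingale import branch_functions_at_one, branch_roots

__all__ = [
    "AbsorptionSpec",
    "CcfValue",
    "ConditionalMoments",
    "NMaxTooSmallError",
    "absorption_spec",
    "fixation_probability",
    "ccf_active_steps",
    "conditional_moments",
    "active_step_distribution",
    "scaled_time_ccf",
]

#: fitness windows treated as neutral (r = 1)
NEUTRAL_ATOL = 1e-9


class NMaxTooSmallError(ValueError):
    """Raised when the requested support truncation leaves visible mass."""


@dataclass(frozen=True)
class AbsorptionSpec:
    """Class-aggregated initial state and absorbing boundaries."""

    initial: tuple[int, ...]
    fixation_state: tuple[int, ...]
    extinction_state: tuple[int, ...]

    @property
    def at_fixation(self) -> bool:
        return self.initial == self.fixation_state

    @property
    def at_extinction(self) -> bool:
        return self.initial == self.extinction_state


def absorption_spec(graph: StreetGraph, s0) -> AbsorptionSpec:
    """Build an :class:`AbsorptionSpec` from either a class-aggregated vector
    (length k) or a full physical state (length = number of partitions)."""
    arr = np.asarray(s0, dtype=np.int64)
    a = graph.fixation_boundary
    if arr.shape == (graph.num_partitions,) and graph.num_partitions != graph.num_classes:
        arr = aggregate_classes(graph, arr)
    if arr.shape != (graph.num_classes,):
        raise ValueError(
            f"s0 must have {graph.num_classes} class entries or "
            f"{graph.num_partitions} partition entries, got {arr.size}"
        )
    if np.any(arr < 0) or np.any(arr > np.asarray(a)):
        raise ValueError(f"s0 {arr.tolist()} outside [0, a={list(a)}]")
    return AbsorptionSpec(tuple(int(x) for x in arr), a, (0,) * graph.num_classes)


@dataclass(frozen=True)
class CcfValue:
    """CCF sample: ψ_fix(θ) = E[e^{iθ C_T} | fixation], ψ_ext analogous."""

    theta: float
    psi_fix: complex
    psi_ext: complex


@dataclass(frozen=True)
class ConditionalMoments:
    """Conditional moments E[C_T^k | fixation] and E[C_T^k | extinction],
    k = 1..max_order."""

    fix: tuple[float, ...]
    ext: tuple[float, ...]


def _powers(f: np.ndarray, exponents) -> complex:
    return complex(np.prod(np.asarray(f, dtype=complex) ** np.asarray(exponents)))


def _alpha_from_branches(graph: StreetGraph, spec: AbsorptionSpec) -> float:
    f1 = branch_functions_at_one(graph)
    num = _powers(f1, spec.initial) - 1.0
    den = _powers(f1, spec.fixation_state) - 1.0
    return float((num / den).real)


def fixation_probability(graph: StreetGraph, s0) -> float:
    """Probability that ``s0`` fixes (absorbs at the all-mutant state).

    Uses the nontrivial branch vector at g = 1.  At neutrality the formula is
    an indeterminate 0/0; a tripartite cycle uses the exact limit
    ``(A·S_a + B·S_b + C·S_c)/(A² + B² + C²)`` and other shapes a two-sided
    numerical limit at r = 1 ± 1e−6.
    """
    spec = s0 if isinstance(s0, AbsorptionSpec) else absorption_spec(graph, s0)
    if spec.at_fixation:
        return 1.0
    if spec.at_extinction:
        return 0.0
    r = graph.fitness
    if abs(r - 1.0) < NEUTRAL_ATOL:
        if graph.topology == "cycle" and graph.num_classes == 3:
            sizes = np.asarray(graph.class_sizes, dtype=float)
            return float(np.dot(sizes, spec.initial) / np.dot(sizes, sizes))
        lo = _alpha_from_branches(graph.with_fitness(1.0 - 1e-6), spec)
        hi = _alpha_from_branches(graph.with_fitness(1.0 + 1e-6), spec)
        return 0.5 * (lo + hi)
    return _alpha_from_branches(graph, spec)


def ccf_active_steps(graph: StreetGraph, s0, theta: float) -> CcfValue:
    """Exact CCFs of the active-step count at phase ``theta``."""
    spec = s0 if isinstance(s0, AbsorptionSpec) else absorption_spec(graph, s0)
    if theta == 0.0:
        return CcfValue(0.0, 1.0 + 0.0j, 1.0 + 0.0j)
    alpha = fixation_probability(graph, spec)
    g = np.exp(1j * theta)
    f1, f2 = branch_roots(graph, g)
    p1s, p2s = _powers(f1, spec.initial), _powers(f2, spec.initial)
    p1a, p2a = _powers(f1, spec.fixation_state), _powers(f2, spec.fixation_state)
    den = p1a - p2a
    if abs(den) < 1e-10:
        warnings.warn(
            f"ill-conditioned CCF denominator |∏f1^a − ∏f2^a| = {abs(den):.2e} at θ={theta}",
            RuntimeWarning,
            stacklevel=2,
        )
    psi_fix = (p1s - p2s) / (alpha * den) if alpha > 0 else complex("nan")
    psi_ext = (p1a * p2s - p2a * p1s) / ((1.0 - alpha) * den) if alpha < 1 else complex("nan")
    return CcfValue(theta, complex(psi_fix), complex(psi_ext))


def _psi_grid(graph: StreetGraph, spec: AbsorptionSpec, thetas: np.ndarray):
    fix = np.empty(len(thetas), dtype=complex)
    ext = np.empty(len(thetas), dtype=complex)
    for idx, th in enumerate(thetas):
        val = ccf_active_steps(graph, spec, float(th))
        fix[idx], ext[idx] = val.psi_fix, val.psi_ext
    return fix, ext


_STENCILS = {
    # order -> (offsets in units of h, weights, power of h)
    1: ((-1, 1), (-0.5, 0.5), 1),
    2: ((-1, 0, 1), (1.0, -2.0, 1.0), 2),
    3: ((-2, -1, 1, 2), (-0.5, 1.0, -1.0, 0.5), 3),
    4: ((-2, -1, 0, 1, 2), (1.0, -4.0, 6.0, -4.0, 1.0), 4),
}


def conditional_moments(
    graph: StreetGraph, s0, max_order: int = 2, base_step: float = 1e-3
) -> ConditionalMoments:
    """Conditional moments of ``C_T`` from CCF derivatives at θ = 0,
    ``E[C_T^k | ·] = i^{−k} dᵏψ/dθᵏ|₀``.

    Derivatives use second-order central differences at steps ``h`` and
    ``h/2`` combined by Richardson extrapolation.  ``max_order`` is capped at
    4, the validated range of the differentiation scheme.
    """
    if not (1 <= max_order <= 4):
        raise ValueError("max_order must be between 1 and 4")
    spec = s0 if isinstance(s0, AbsorptionSpec) else absorption_spec(graph, s0)
    if spec.at_fixation or spec.at_extinction:
        zeros = (0.0,) * max_order
        return ConditionalMoments(fix=zeros, ext=zeros)

    offsets = sorted({o * s for o in (-2, -1, 1, 2) for s in (1.0, 0.5)})
    thetas = np.array(offsets) * base_step
    fix_vals, ext_vals = _psi_grid(graph, spec, thetas)
    table = {round(o, 6): (f, e) for o, f, e in zip(offsets, fix_vals, ext_vals)}
    table[0.0] = (1.0 + 0.0j, 1.0 + 0.0j)

    def derivative(order: int, which: int, h: float) -> complex:
        offs, weights, power = _STENCILS[order]
        acc = 0.0 + 0.0j
        for o, w in zip(offs, weights):
            acc += w * table[round(o * h / base_step, 6)][which]
        return acc / (h**power)

    def moments(which: int) -> tuple[float, ...]:
        out = []
        for order in range(1, max_order + 1):
            d_h = derivative(order, which, base_step)
            d_h2 = derivative(order, which, base_step / 2)
            deriv = (4.0 * d_h2 - d_h) / 3.0
            moment = deriv / (1j**order)
            scale = max(1.0, abs(moment))
            if abs(moment.imag) / scale > 1e-4:
                raise ArithmeticError(
                    f"numerical differentiation failed: imaginary residue "
                    f"{moment.imag:.2e} in conditional moment of order {order}"
                )
            out.append(float(moment.real))
        return tuple(out)

    return ConditionalMoments(fix=moments(0), ext=moments(1))


def active_step_distribution(graph: StreetGraph, s0, n_max: int):
    """Conditional distributions ``Pr(C_T = n | fix)`` and ``| ext)`` for
    ``n = 0..n_max`` via the inverse discrete Fourier transform of the CCFs.

    ψ is 2π-periodic because C_T is integer valued, so a uniform θ-grid
    (next power of two above 4·n_max) integrates the inversion formula
    exactly up to the exponentially small mass beyond the grid.
    """
    spec = s0 if isinstance(s0, AbsorptionSpec) else absorption_spec(graph, s0)
    if n_max < graph.population_size:
        raise ValueError(
            f"n_max={n_max} is below the population size {graph.population_size}; "
            "the fixation support starts at N − ΣS₀"
        )
    n_grid = 1 << int(np.ceil(np.log2(4 * n_max)))
    half = n_grid // 2
    thetas = 2 * np.pi * np.arange(1, half + 1) / n_grid
    fix_half, ext_half = _psi_grid(graph, spec, thetas)
    psi_fix = np.empty(n_grid, dtype=complex)
    psi_ext = np.empty(n_grid, dtype=complex)
    psi_fix[0] = psi_ext[0] = 1.0
    psi_fix[1 : half + 1] = fix_half
    psi_ext[1 : half + 1] = ext_half
    psi_fix[half + 1 :] = np.conj(fix_half[:-1][::-1])
    psi_ext[half + 1 :] = np.conj(ext_half[:-1][::-1])

    def invert(psi: np.ndarray) -> np.ndarray:
        probs = (np.fft.fft(psi) / n_grid).real
        tail = probs[n_max + 1 :].sum()
        if tail > 1e-6:
            raise NMaxTooSmallError(
                f"probability mass {tail:.2e} beyond n_max={n_max}; increase n_max"
            )
        probs = probs[: n_max + 1].copy()
        probs[(probs < 0) & (np.abs(probs) < 1e-8)] = 0.0
        return probs

    return invert(psi_fix), invert(psi_ext)


def scaled_time_ccf(
    graph: StreetGraph, s0, kappa_fix: float, kappa_ext: float, theta: float
) -> CcfValue:
    """κ-scaling approximation to the CCFs of the absorption time ``T``:
    ``ψ_{T|·}(θ) ≈ ψ_{C_T|·}(κ·θ)`` with ``κ = E[T|·]/E[C_T|·]``."""
    if not (kappa_fix > 0 and kappa_ext > 0):
        raise ValueError("kappa scaling constants must be positive")
    spec = s0 if isinstance(s0, AbsorptionSpec) else absorption_spec(graph, s0)
    fix = ccf_active_steps(graph, spec, kappa_fix * theta).psi_fix
    ext = ccf_active_steps(graph, spec, kappa_ext * theta).psi_ext
    return CcfValue(theta, fix, ext)
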