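"""Tests for fixation probability, CCFs, moments and distributions."""

import numpy as np
import pytest

from streetgraph import (
    absorption_spec,
    active_step_distribution,
    ccf_active_steps,
    conditional_moments,
    exact_absorption_probability,
    exact_active_step_cf,
    exact_active_step_distribution,
    exact_count_moments,
    exact_time_moments,
    fixation_probability,
    isothermal_branches,
    kappa_estimates,
    make_cycle_graph,
    make_megastar_graph,
    scaled_time_ccf,
)
from streetgraph.stats import NMaxTooSmallError, _powers


class TestFixationProbability:
    def test_matches_exact_chain(self, tripartite, s0_single):
        alpha = fixation_probability(tripartite, s0_single)
        assert alpha == pytest.approx(exact_absorption_probability(tripartite, s0_single), abs=1e-10)
        assert alpha == pytest.approx(0.4506, abs=2e-4)

    def test_boundaries(self, tripartite):
        assert fixation_probability(tripartite, [5, 3, 2]) == 1.0
        assert fixation_probability(tripartite, [0, 0, 0]) == 0.0

    def test_neutral_tripartite_limit(self):
        g = make_cycle_graph([5, 3, 2], 1.0)
        assert fixation_probability(g, [1, 0, 0]) == pytest.approx(5 / 38, abs=1e-12)
        assert exact_absorption_probability(g, [1, 0, 0]) == pytest.approx(5 / 38, abs=1e-10)

    def test_neutral_limit_general_k_conjecture(self):
        """For any cycle at r = 1 the exact solve matches
        Σ size_i S_{i,0} / Σ size_i² (the natural generalisation of the
        tripartite limit)."""
        for sizes, s0 in (([4, 2, 3, 2], [0, 1, 0, 0]), ([2, 5], [1, 0])):
            g = make_cycle_graph(sizes, 1.0)
            conj = np.dot(sizes, s0) / np.dot(sizes, sizes)
            assert exact_absorption_probability(g, s0) == pytest.approx(conj, abs=1e-10)
            assert fixation_probability(g, s0) == pytest.approx(conj, abs=1e-7)

    def test_neutral_megastar_numerical_limit(self):
        g = make_megastar_graph(3, [2], 2, 1.0)
        s0 = [1, 0, 0]
        assert fixation_probability(g, s0) == pytest.approx(
            exact_absorption_probability(g, s0), abs=1e-6
        )

    def test_megastar_aggregated_s0(self):
        """Class-aggregated and physical initial states give the same α, and
        the martingale result depends only on the class aggregate."""
        g = make_megastar_graph(5, [3, 2], 3, 1.2)
        assert fixation_probability(g, [1, 0, 2]) == pytest.approx(
            fixation_probability(g, [1, 0, 0, 0, 0, 0, 2]), abs=1e-14
        )
        a1 = exact_absorption_probability(g, [1, 0, 0, 0, 0, 0, 2])
        a2 = exact_absorption_probability(g, [1, 0, 2, 0, 0, 0, 0])
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert fixation_probability(g, [1, 0, 2]) == pytest.approx(a1, abs=1e-10)


class TestCcf:
    def test_value_at_zero(self, tripartite, s0_single):
        val = ccf_active_steps(tripartite, s0_single, 0.0)
        assert val.psi_fix == 1.0 and val.psi_ext == 1.0

    @pytest.mark.parametrize("theta", [0.5, 1.7, -2.4])
    def test_matches_jump_chain_cf(self, tripartite, s0_single, theta):
        val = ccf_active_steps(tripartite, s0_single, theta)
        fix, ext = exact_active_step_cf(tripartite, s0_single, theta)
        assert abs(val.psi_fix - fix) < 1e-8
        assert abs(val.psi_ext - ext) < 1e-8

    def test_hermitian_symmetry_and_modulus(self, tripartite, s0_single):
        for theta in (0.3, 1.1, 2.9):
            plus = ccf_active_steps(tripartite, s0_single, theta)
            minus = ccf_active_steps(tripartite, s0_single, -theta)
            assert minus.psi_fix == pytest.approx(np.conj(plus.psi_fix), abs=1e-12)
            assert minus.psi_ext == pytest.approx(np.conj(plus.psi_ext), abs=1e-12)
            assert abs(plus.psi_fix) <= 1 + 1e-9
            assert abs(plus.psi_ext) <= 1 + 1e-9

    def test_branch_swap_invariance(self, tripartite, s0_single):
        """α and the CCFs are symmetric functions of the two branches: the
        2×2 optional-stopping system is invariant under the swap."""
        from streetgraph.martingale import branch_roots

        spec = absorption_spec(tripartite, s0_single)
        alpha = fixation_probability(tripartite, s0_single)
        theta = 0.9
        f1, f2 = branch_roots(tripartite, np.exp(1j * theta))
        vals = []
        for fa, fb in ((f1, f2), (f2, f1)):
            p1s, p2s = _powers(fa, spec.initial), _powers(fb, spec.initial)
            p1a, p2a = _powers(fa, spec.fixation_state), _powers(fb, spec.fixation_state)
            den = p1a - p2a
            vals.append(
                (
                    (p1s - p2s) / (alpha * den),
                    (p1a * p2s - p2a * p1s) / ((1 - alpha) * den),
                )
            )
        assert abs(vals[0][0] - vals[1][0]) < 1e-12
        assert abs(vals[0][1] - vals[1][1]) < 1e-12

    def test_isothermal_equivalence_to_moran(self):
        """For equal partition sizes the CCFs collapse to the 1-D Moran form
        built directly from the isothermal branch pair."""
        g = make_cycle_graph([4, 4, 4], 1.5)
        s0 = [1, 0, 0]
        alpha = fixation_probability(g, s0)
        n, k0 = g.population_size, 1
        for theta in (0.4, 1.5):
            f1, f2 = isothermal_branches(1.5, theta)
            den = f1**n - f2**n
            psi_fix = (f1**k0 - f2**k0) / (alpha * den)
            psi_ext = (f1**n * f2**k0 - f2**n * f1**k0) / ((1 - alpha) * den)
            val = ccf_active_steps(g, s0, theta)
            assert abs(val.psi_fix - psi_fix) < 1e-10
            assert abs(val.psi_ext - psi_ext) < 1e-10

    def test_direction_reversal_sensitivity(self):
        """Extinction CCFs react strongly to reversing the streets for
        asymmetric sizes while fixation CCFs barely move (regression
        snapshot of the qualitative effect)."""
        g = make_cycle_graph([5, 3, 1], 1.5)
        fwd = ccf_active_steps(g, [1, 0, 0], 1.5)
        bwd = ccf_active_steps(g.reversed(), [1, 0, 0], 1.5)
        assert abs(fwd.psi_ext - bwd.psi_ext) > 0.1
        assert abs(fwd.psi_fix - bwd.psi_fix) < 0.01

    def test_neutral_ccf_matches_oracle(self):
        g = make_cycle_graph([5, 3, 2], 1.0)
        val = ccf_active_steps(g, [1, 0, 0], 0.6)
        fix, ext = exact_active_step_cf(g, [1, 0, 0], 0.6)
        assert abs(val.psi_fix - fix) < 1e-8
        assert abs(val.psi_ext - ext) < 1e-8


class TestMoments:
    def test_absorbed_start_is_zero(self, tripartite):
        m = conditional_moments(tripartite, [5, 3, 2], max_order=3)
        assert m.fix == (0.0,) * 3 and m.ext == (0.0,) * 3

    def test_agree_with_first_step_analysis(self, tripartite, s0_single):
        m = conditional_moments(tripartite, s0_single, max_order=2)
        exact = exact_count_moments(tripartite, s0_single, order=2)
        for got, want in zip(m.fix + m.ext, exact.fix + exact.ext):
            assert got == pytest.approx(want, rel=1e-5)

    def test_fixation_needs_at_least_net_gains(self, tripartite, s0_single):
        m = conditional_moments(tripartite, s0_single, max_order=1)
        assert m.fix[0] >= 9  # N − ΣS₀ net gains are required

    def test_order_validation(self, tripartite, s0_single):
        with pytest.raises(ValueError):
            conditional_moments(tripartite, s0_single, max_order=5)


class TestDistribution:
    def test_matches_jump_chain_and_parity(self, tripartite, s0_single):
        n_max = 400
        p_fix, p_ext = active_step_distribution(tripartite, s0_single, n_max)
        o_fix, o_ext = exact_active_step_distribution(tripartite, s0_single, n_max)
        assert np.max(np.abs(p_fix - o_fix)) < 1e-7
        assert np.max(np.abs(p_ext - o_ext)) < 1e-7
        assert p_fix.sum() == pytest.approx(1.0, abs=1e-6)
        assert p_ext.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p_fix >= 0) and np.all(p_ext >= 0)
        # parity: every active step changes ΣS by ±1, so C_T | fix lives on
        # N − ΣS₀ + 2j and C_T | ext on ΣS₀ + 2j
        assert p_fix[::2].sum() == pytest.approx(0.0, abs=1e-9)
        assert p_fix[:9].sum() == pytest.approx(0.0, abs=1e-12)
        assert p_ext[1::2].sum() == pytest.approx(1.0, abs=1e-6)

    def test_first_extinction_step_hand_value(self, tripartite, s0_single):
        # one active step to extinction: jump probability 2/7 over 1 − α
        alpha = fixation_probability(tripartite, s0_single)
        _, p_ext = active_step_distribution(tripartite, s0_single, 400)
        assert p_ext[1] == pytest.approx((2 / 7) / (1 - alpha), abs=1e-10)
        assert p_ext[1] == pytest.approx(0.520, abs=1e-3)

    def test_truncation_detected(self, tripartite, s0_single):
        with pytest.raises(NMaxTooSmallError):
            active_step_distribution(tripartite, s0_single, 20)

    def test_n_max_below_population_rejected(self, tripartite, s0_single):
        with pytest.raises(ValueError):
            active_step_distribution(tripartite, s0_single, 5)


class TestKappaScaling:
    def test_identity_scaling(self, tripartite, s0_single):
        for theta in (0.0, 0.7):
            a = scaled_time_ccf(tripartite, s0_single, 1.0, 1.0, theta)
            b = ccf_active_steps(tripartite, s0_single, theta)
            assert a.psi_fix == pytest.approx(b.psi_fix) and a.psi_ext == pytest.approx(b.psi_ext)

    def test_scaled_first_moment_reproduces_time_mean(self, tripartite, s0_single):
        """With κ = E[T|·]/E[C_T|·], the scaled CCF's first moment equals
        E[T|·] by construction (checked by numerical differentiation)."""
        counts = exact_count_moments(tripartite, s0_single, order=1)
        times = exact_time_moments(tripartite, s0_single, order=1)
        k_fix, k_ext = kappa_estimates((counts, times))
        h = 1e-4
        plus = scaled_time_ccf(tripartite, s0_single, k_fix, k_ext, h)
        minus = scaled_time_ccf(tripartite, s0_single, k_fix, k_ext, -h)
        mean_fix = ((plus.psi_fix - minus.psi_fix) / (2 * h)).imag
        mean_ext = ((plus.psi_ext - minus.psi_ext) / (2 * h)).imag
        assert mean_fix == pytest.approx(times.fix[0], rel=1e-4)
        assert mean_ext == pytest.approx(times.ext[0], rel=1e-4)

    def test_invalid_kappa(self, tripartite, s0_single):
        with pytest.raises(ValueError):
            scaled_time_ccf(tripartite, s0_single, 0.0, 1.0, 0.3)
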