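import numpy as np
import pytest

from conftest import random_params
from patchkin.behaviour import TraitProfile
from patchkin.params import HIGH, LOW, ModelParams
from patchkin.selection import (
    class_fitness,
    hamilton_decomposition,
    mean_fitness,
    potential_for_helping,
    resident_from_fecundity,
    selection_gradient,
    solve_resident,
)

SYMMETRIC = ModelParams(
    d=0.3, c=0.5, p=0.5, tau=0.2, mu_R=1.0, mu_P=1.0,
    q_HR=0.6, q_LR=0.6, q_HP=0.6, q_LP=0.6,
)


class TestClassFitness:
    def test_resident_neutrality(self, rng):
        """W = 1 for every class at the resident phenotypes, and mean
        fitness is 1 under the sum(u v) = 1 normalisation."""
        for _ in range(5):
            p = random_params(rng)
            z0 = float(rng.uniform(0.3, 0.9))
            state = solve_resident(TraitProfile.uniform(z0), p)
            for sigma in (0, 1):
                W_H, W_L = class_fitness([z0], [z0], sigma, state)
                assert W_H[0] == pytest.approx(1.0, abs=1e-9)
                assert W_L[0] == pytest.approx(1.0, abs=1e-9)
            assert mean_fitness(state) == pytest.approx(1.0, abs=1e-9)

    def test_effort_deviation_shifts_fitness_shares(self, caption):
        state = solve_resident(TraitProfile.uniform(0.6), caption)
        W_H_up, W_L_up = class_fitness([0.61], [0.6], 0, state)
        assert W_H_up[0] > 1.0  # raising own effort gains share
        assert W_L_up[0] < 1.0  # and harms the patch partner

    def test_symmetric_classes_equal_fitness(self):
        state = solve_resident(TraitProfile.uniform(0.6), SYMMETRIC)
        W_H, W_L = class_fitness([0.7], [0.7], 0, state)
        assert W_H[0] == pytest.approx(W_L[0], rel=1e-10)


class TestSelectionGradient:
    def test_symmetric_parameters_symmetric_gradient(self):
        S = selection_gradient(TraitProfile.uniform(0.6), SYMMETRIC)
        assert np.ptp(S) == pytest.approx(0.0, abs=1e-8)

    def test_gradient_vanishes_at_singular_point(self, caption):
        from patchkin.ess import solve_ess

        res = solve_ess(caption.with_(tau=0.5))
        S = selection_gradient(res.z_star, caption.with_(tau=0.5))
        assert np.abs(S).max() < 1e-7

    def test_selfish_resident_rich_patch_orderings(self, caption):
        """At the fully selfish resident, selection pushes competitive
        effort down, more strongly for the low-quality class (which has
        less kin competition at stake and so helps more)."""
        z = TraitProfile.uniform(1.0)
        S = selection_gradient(z, caption.with_(tau=0.5))
        assert S[HIGH, 0] < 0 and S[LOW, 0] < 0
        assert S[LOW, 0] < S[HIGH, 0]


class TestHamiltonDecomposition:
    def test_proportional_to_direct_gradient(self, rng):
        """Inclusive-fitness route equals the direct gradient divided by
        the class frequency, across random parameter sets (the module's
        central consistency check)."""
        for _ in range(20):
            p = random_params(rng)
            z = TraitProfile.from_array(rng.uniform(0.2, 0.95, size=(2, 2)))
            rep = hamilton_decomposition(z, p)
            u = np.array([[p.p, 1 - p.p], [p.p, 1 - p.p]]) / 2.0
            np.testing.assert_allclose(rep.kappa, u, rtol=1e-6)
            assert np.all(rep.kappa > 0)

    def test_full_dispersal_kills_kin_competition(self):
        p = SYMMETRIC.with_(d=1.0, c=0.2)
        rep = hamilton_decomposition(TraitProfile.uniform(0.6), p)
        np.testing.assert_allclose(rep.kin_competition, 0.0, atol=1e-12)
        # and with r = 0 the relatedness-weighted benefit vanishes too
        np.testing.assert_allclose(rep.primary_benefit, 0.0, atol=1e-12)

    def test_symmetric_classes_identical_terms(self):
        rep = hamilton_decomposition(TraitProfile.uniform(0.6), SYMMETRIC)
        np.testing.assert_allclose(rep.hamilton_lhs[0], rep.hamilton_lhs[1],
                                   rtol=1e-9)


class TestPotentialForHelping:
    def test_full_dispersal_zero_potential(self):
        p = SYMMETRIC.with_(d=1.0, c=0.2)
        A = potential_for_helping(TraitProfile.uniform(0.6), p)
        np.testing.assert_allclose(A, 0.0, atol=1e-12)

    def test_symmetric_qualities_equal_potential(self):
        A = potential_for_helping(TraitProfile.uniform(0.6), SYMMETRIC)
        assert A[HIGH, 0] == pytest.approx(A[LOW, 0], rel=1e-10)
        assert A[HIGH, 1] == pytest.approx(A[LOW, 1], rel=1e-10)

    def test_bounded_above_by_one(self, rng):
        for _ in range(10):
            p = random_params(rng)
            A = potential_for_helping(TraitProfile.uniform(0.6), p)
            assert np.all(A < 1.0)

    def test_low_quality_helps_more_fixed_fecundity(self, caption):
        """With the fecundity ratios of the reference figure held fixed
        (f_L/f_H = 0.1, F_P/F_R = 0.1) the potential for helping of the
        low-quality class exceeds the high-quality one at every tau."""
        f = np.array([[1.0, 0.1], [0.1, 0.01]])
        for tau in np.linspace(-0.9, 0.9, 7):
            state = resident_from_fecundity(f, caption.with_(tau=float(tau)))
            A = potential_for_helping(None, caption.with_(tau=float(tau)),
                                      state=state)
            assert A[LOW, 0] > A[HIGH, 0]
            assert A[LOW, 1] > A[HIGH, 1]

    def test_helping_peaks_in_stable_rich_and_unstable_poor(self, caption):
        """Across a tau grid, rich-patch helping potential peaks near the
        stable end (interior, just below tau = 1) while poor-patch
        helping peaks toward the unstable end."""
        f = np.array([[1.0, 0.1], [0.1, 0.01]])
        grid = np.linspace(-0.95, 0.98, 25)
        A_rich, A_poor = [], []
        for tau in grid:
            state = resident_from_fecundity(f, caption.with_(tau=float(tau)))
            A = potential_for_helping(None, caption.with_(tau=float(tau)),
                                      state=state)
            A_rich.append(A[:, 0].mean())
            A_poor.append(A[:, 1].mean())
        assert grid[int(np.argmax(A_rich))] > 0.5
        assert grid[int(np.argmax(A_poor))] < -0.5
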