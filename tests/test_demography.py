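import numpy as np
import pytest

from conftest import random_params
from patchkin.behaviour import TraitProfile, fecundity_table
from patchkin.demography import (
    DemographicCollapse,
    offspring_pools,
    resident_demography,
    settlement,
)
from patchkin.params import CAPTION_PARAMS, ModelParams, make_env_process

SYMMETRIC = ModelParams(
    d=0.3, c=0.5, p=0.5, tau=0.0, mu_R=1.0, mu_P=1.0,
    q_HR=0.8, q_LR=0.8, q_HP=0.8, q_LP=0.8,
)


def _state(params, z=0.6):
    env = make_env_process(params.tau, params.p)
    f = fecundity_table(TraitProfile.uniform(z), params)
    return resident_demography(f, params, env), f, env


class TestPools:
    def test_no_dispersal(self):
        p = SYMMETRIC.with_(d=0.0)
        env = make_env_process(p.tau, p.p)
        f = fecundity_table(TraitProfile.uniform(0.6), p)
        O, I = offspring_pools(f, p, env)
        assert I == 0.0
        np.testing.assert_allclose(O, f[0] + f[1])

    def test_full_dispersal(self):
        p = SYMMETRIC.with_(d=1.0, c=0.4)
        env = make_env_process(p.tau, p.p)
        f = fecundity_table(TraitProfile.uniform(0.6), p)
        O, I = offspring_pools(f, p, env)
        np.testing.assert_allclose(O, 0.0)
        assert I == pytest.approx(0.6 * float(env.stationary @ (f[0] + f[1])))

    def test_collapse_raises(self):
        p = SYMMETRIC.with_(d=1.0, c=1.0)
        env = make_env_process(p.tau, p.p)
        f = fecundity_table(TraitProfile.uniform(0.6), p)
        with pytest.raises(DemographicCollapse):
            offspring_pools(f, p, env)


class TestSettlement:
    def test_symmetric_philopatry_closed_form(self):
        # equal pools across types: h = (1-d)/(1-cd)
        env = make_env_process(SYMMETRIC.tau, SYMMETRIC.p)
        f = fecundity_table(TraitProfile.uniform(0.6), SYMMETRIC)
        h, w_phi = settlement(f, SYMMETRIC, env)
        expect = (1 - SYMMETRIC.d) / (1 - SYMMETRIC.c * SYMMETRIC.d)
        np.testing.assert_allclose(h, expect, rtol=1e-12)

    def test_costfree_dispersal(self):
        p = SYMMETRIC.with_(c=0.0, d=0.25)
        env = make_env_process(p.tau, p.p)
        f = fecundity_table(TraitProfile.uniform(0.6), p)
        h, _ = settlement(f, p, env)
        np.testing.assert_allclose(h, 1 - p.d, rtol=1e-12)

    def test_full_dispersal_no_philopatry(self):
        p = SYMMETRIC.with_(d=1.0, c=0.2)
        env = make_env_process(p.tau, p.p)
        f = fecundity_table(TraitProfile.uniform(0.6), p)
        h, w_phi = settlement(f, p, env)
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(w_phi, 0.0)


class TestEigenQuantities:
    def test_resident_equilibrium_invariants_random_params(self, rng):
        """Leading eigenvalue 1, stationary patch-type marginals of u,
        the left-eigenvector identity for v and sum(u v) = 1, across
        random feasible parameter sets."""
        for _ in range(15):
            p = random_params(rng)
            demo, f, env = _state(p, z=float(rng.uniform(0.3, 0.9)))
            assert demo.lam == pytest.approx(1.0, abs=1e-10)
            assert demo.u.sum() == pytest.approx(1.0, abs=1e-12)
            assert demo.u[:2].sum() == pytest.approx(p.p, abs=1e-10)
            assert demo.u[2:].sum() == pytest.approx(1 - p.p, abs=1e-10)
            assert float(demo.u @ demo.v) == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(demo.w @ demo.v, demo.v, atol=1e-10)

    def test_symmetric_parameters_uniform_classes(self):
        demo, _, _ = _state(SYMMETRIC)
        np.testing.assert_allclose(demo.u, 0.25, atol=1e-10)
        np.testing.assert_allclose(demo.v, 1.0, atol=1e-10)

    def test_frozen_environment_without_dispersal_is_block_solved(self):
        # d = 0 and tau = 1 decouple rich from poor patches entirely;
        # the dense/block solver must still deliver stationary marginals
        p = ModelParams(d=0.0, c=0.9, p=0.5, tau=1.0, mu_R=1.0, mu_P=0.1)
        demo, _, _ = _state(p)
        assert demo.lam == pytest.approx(1.0, abs=1e-10)
        assert demo.u[:2].sum() == pytest.approx(0.5, abs=1e-10)

    def test_caption_value_ordering(self, caption):
        demo, _, _ = _state(caption.with_(tau=0.3))
        # higher-fecundity class projects more descendants
        assert demo.v[0] > demo.v[1]  # v_HR > v_LR
        assert demo.v[2] > demo.v[3]  # v_HP > v_LP


class TestValueComponents:
    def test_offspring_value_is_mother_independent(self, rng):
        # V is indexed by natal patch type only: offspring are identical
        demo, f, env = _state(random_params(rng))
        assert demo.V.shape == (2,)
        np.testing.assert_allclose(f * demo.V[None, :], demo.v.reshape(2, 2).T,
                                   atol=1e-10)

    def test_philopatric_value_ratio_is_fecundity_ratio(self, rng):
        demo, f, _ = _state(random_params(rng))
        assert demo.v_phi[0, 0] / demo.v_phi[1, 0] == pytest.approx(
            f[0, 0] / f[1, 0], rel=1e-12
        )

    def test_philopatric_ordering_across_tau_at_caption(self, caption):
        """Kin competition is stronger for high-quality breeders: the
        philopatric value component orders v_phi_HR > v_phi_LR for every
        temporal correlation."""
        for tau in np.linspace(-0.9, 0.9, 7):
            demo, _, _ = _state(caption.with_(tau=float(tau)))
            assert demo.v_phi[0, 0] > demo.v_phi[1, 0]
            assert demo.v_phi[0, 1] > demo.v_phi[1, 1]

    def test_philopatric_below_total_value(self, rng):
        demo, _, _ = _state(random_params(rng))
        assert np.all(demo.v_phi <= demo.v.reshape(2, 2).T + 1e-12)
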