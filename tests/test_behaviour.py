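import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from patchkin.behaviour import (
    TraitProfile,
    fecundity,
    fecundity_gradients,
    fecundity_table,
    marginal_terms,
)
from patchkin.params import HIGH, LOW, ModelParams

PARAMS = ModelParams(d=0.1, c=0.9, p=0.5, tau=0.0)

efforts = st.floats(0.05, 1.0)


class TestFecundity:
    def test_fully_selfish_reduces_to_baseline(self):
        # x = 1 for everyone exhausts the public good: f = mu * q
        for rho in (HIGH, LOW):
            for sigma in (0, 1):
                f = fecundity((1.0, 1.0), rho, sigma, PARAMS)
                assert f == pytest.approx(
                    PARAMS.mu[sigma] * PARAMS.q[rho, sigma], abs=1e-15
                )

    def test_equal_half_efforts(self):
        p = ModelParams(d=0.1, c=0.9, p=0.5, tau=0.0, mu_R=1.0, q_HR=1.0)
        assert fecundity((0.5, 0.5), HIGH, 0, p) == pytest.approx(1.5)

    @given(x0=efforts)
    def test_equal_efforts_closed_form(self, x0):
        # with both members at x0: f = mu * (q + 1 - x0), decreasing in x0
        f = fecundity((x0, x0), HIGH, 0, PARAMS)
        assert f == pytest.approx(PARAMS.mu_R * (PARAMS.q_HR + 1.0 - x0), rel=1e-12)

    @given(x_h=efforts, x_l=efforts)
    def test_group_productivity_depends_on_mean_effort_only(self, x_h, x_l):
        # patch total: mu * (q_H + q_L + n*(1 - xbar)); efforts enter
        # only through their mean
        total = sum(fecundity((x_h, x_l), rho, 0, PARAMS) for rho in (0, 1))
        xbar = 0.5 * (x_h + x_l)
        expect = PARAMS.mu_R * (PARAMS.q_HR + PARAMS.q_LR + 2.0 * (1.0 - xbar))
        assert total == pytest.approx(expect, rel=1e-12)

    @given(x_h=st.floats(0.05, 0.9), x_l=st.floats(0.05, 0.9))
    def test_share_and_partner_monotonicity(self, x_h, x_l):
        # own effort always raises the own resource *share* x/xbar,
        # while any effort increase depletes the partner's fecundity
        h = 1e-7
        share = lambda a, b: a / (0.5 * (a + b))
        assert share(x_h + h, x_l) > share(x_h - h, x_l)
        up_par = fecundity((x_h, x_l + h), HIGH, 0, PARAMS)
        dn_par = fecundity((x_h, x_l - h), HIGH, 0, PARAMS)
        assert up_par < dn_par  # partner effort depletes the pool

    def test_zero_mean_effort_rejected(self):
        with pytest.raises(ValueError, match="mean effort"):
            fecundity((0.0, 0.0), HIGH, 0, PARAMS)


class TestMarginals:
    def test_selfish_corner_values(self):
        # at x = 1: Theta = 0 so C = 0; dTheta/dx = -1/2 so B = -mu/2
        C, B = marginal_terms((1.0, 1.0), HIGH, 0, PARAMS)
        assert C == pytest.approx(0.0, abs=1e-15)
        assert B == pytest.approx(-PARAMS.mu_R / 2.0, rel=1e-12)

    @given(x_h=st.floats(0.05, 0.95), x_l=st.floats(0.05, 0.95))
    def test_signs_inside_domain(self, x_h, x_l):
        C, B = marginal_terms((x_h, x_l), HIGH, 0, PARAMS)
        assert C < 0  # share channel: raising effort gains fecundity
        assert B < 0  # pool channel: always harms the partner

    def test_symmetric_classes_have_identical_marginals(self):
        p = ModelParams(d=0.1, c=0.9, p=0.5, tau=0.0,
                        q_HR=0.5, q_LR=0.5, q_HP=0.5, q_LP=0.5)
        assert marginal_terms((0.6, 0.6), HIGH, 0, p) == pytest.approx(
            marginal_terms((0.6, 0.6), LOW, 0, p)
        )

    @given(x_h=st.floats(0.1, 0.9), x_l=st.floats(0.1, 0.9))
    def test_channel_split_matches_finite_differences(self, x_h, x_l):
        """C matches the share-channel derivative (Theta frozen) and B the
        pool-channel derivative on the partner, both to 1e-8 relative."""
        h = 1e-6
        mu = PARAMS.mu_R
        C, B = marginal_terms((x_h, x_l), HIGH, 0, PARAMS)
        theta = (1.0 - 0.5 * (x_h + x_l)) / (0.5 * (x_h + x_l))
        # share channel: vary Psi = x only, Theta held at the resident value
        dpsi = mu * ((x_h + h) * theta - (x_h - h) * theta) / (2 * h)
        assert -C == pytest.approx(dpsi, rel=1e-8, abs=1e-10)
        # pool channel on the partner: full derivative of partner fecundity
        f_up = fecundity((x_h + h, x_l), LOW, 0, PARAMS)
        f_dn = fecundity((x_h - h, x_l), LOW, 0, PARAMS)
        assert B == pytest.approx((f_up - f_dn) / (2 * h), rel=1e-6, abs=1e-8)

    @given(x_h=st.floats(0.1, 0.9), x_l=st.floats(0.1, 0.9))
    def test_total_gradients_match_finite_differences(self, x_h, x_l):
        h = 1e-6
        a, b = fecundity_gradients((x_h, x_l), HIGH, 0, PARAMS)
        fd_a = (
            fecundity((x_h + h, x_l), HIGH, 0, PARAMS)
            - fecundity((x_h - h, x_l), HIGH, 0, PARAMS)
        ) / (2 * h)
        fd_b = (
            fecundity((x_h + h, x_l), LOW, 0, PARAMS)
            - fecundity((x_h - h, x_l), LOW, 0, PARAMS)
        ) / (2 * h)
        assert a == pytest.approx(fd_a, rel=1e-6, abs=1e-8)
        assert b == pytest.approx(fd_b, rel=1e-6, abs=1e-8)


class TestTraitProfile:
    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            TraitProfile(1.2, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            TraitProfile(0.0, 0.5, 0.5, 0.5)

    def test_array_round_trip(self):
        z = TraitProfile(0.1, 0.2, 0.3, 0.4)
        assert TraitProfile.from_array(z.as_array()) == z

    def test_fecundity_table_layout(self):
        z = TraitProfile(0.5, 0.5, 0.5, 0.5)
        f = fecundity_table(z, PARAMS)
        assert f.shape == (2, 2)
        assert f[HIGH, 0] == pytest.approx(1.5)   # mu_R (q_HR + 0.5)
        assert f[LOW, 1] == pytest.approx(0.06)   # mu_P (q_LP + 0.5)
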