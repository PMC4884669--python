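"""Flux laws: worked examples, symmetries and thermodynamic limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from placentaflux.config import generate_fixture
from placentaflux.core import TransporterParams
from placentaflux.kinetics import (
    MembraneSides,
    accumulative_flux,
    bias_factors,
    exchanger_flux,
    facilitative_flux,
    flow_flux,
)

conc = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)
pos_conc = st.floats(min_value=1e-3, max_value=1e4)


def _params(**kw) -> TransporterParams:
    return TransporterParams(**kw)


class TestExchanger:
    def test_identical_sides_give_zero_flux(self):
        sides = MembraneSides([100.0, 50.0, 25.0], [100.0, 50.0, 25.0])
        np.testing.assert_array_equal(exchanger_flux(sides, 5.0, 200.0), 0.0)

    def test_zero_trans_no_counter_substrate(self):
        # nothing on the far side to swap against: obligatory antiport stalls
        sides = MembraneSides([100.0, 0.0], [0.0, 0.0])
        np.testing.assert_array_equal(exchanger_flux(sides, 5.0, 200.0), 0.0)

    def test_hand_evaluated_two_substrate_flux(self):
        # A/B on side I vs pure B on side II drives A inward at 1.25 umol/min
        sides = MembraneSides([100.0, 100.0], [0.0, 200.0])
        J = exchanger_flux(sides, 5.0, 200.0)
        assert J[0] == pytest.approx(1.25, rel=1e-12)
        # strict antiport: B flux balances A exactly
        assert J.sum() == pytest.approx(0.0, abs=1e-15)

    def test_empty_empty_singularity_defined_as_zero(self):
        sides = MembraneSides([0.0, 0.0], [0.0, 0.0])
        np.testing.assert_array_equal(exchanger_flux(sides, 5.0, 200.0), 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            MembraneSides([-1.0, 2.0], [0.0, 0.0])

    @given(
        cI=st.lists(conc, min_size=4, max_size=4),
        cII=st.lists(conc, min_size=4, max_size=4),
        V=st.floats(min_value=0.1, max_value=100.0),
        K=st.floats(min_value=1.0, max_value=1e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_antisymmetry(self, cI, cII, V, K):
        """1:1 antiport conserves total substrate; swapping sides negates."""
        sides = MembraneSides(cI, cII)
        J = exchanger_flux(sides, V, K)
        scale = max(np.max(np.abs(J)), 1.0)
        assert abs(J.sum()) <= 1e-12 * scale
        np.testing.assert_allclose(
            exchanger_flux(sides.swapped(), V, K), -J, rtol=0, atol=1e-12 * scale
        )


class TestFacilitative:
    def test_equal_sides_give_zero(self):
        sides = MembraneSides([120.0, 30.0], [120.0, 30.0])
        np.testing.assert_array_equal(facilitative_flux(sides, 5.0, 1000.0), 0.0)

    def test_single_substrate_zero_trans_value(self):
        sides = MembraneSides([100.0], [0.0])
        assert facilitative_flux(sides, 5.0, 1000.0, group=0) == pytest.approx(
            5.0 * 100.0 / 1100.0, rel=1e-12
        )

    def test_competing_substrate_strictly_decreases_flux(self):
        base = facilitative_flux(MembraneSides([100.0, 0.0], [0.0, 0.0]), 5.0, 1000.0)[0]
        crowded = facilitative_flux(
            MembraneSides([100.0, 400.0], [0.0, 0.0]), 5.0, 1000.0
        )[0]
        assert crowded < base

    @given(
        cI=st.lists(conc, min_size=2, max_size=2),
        cII=st.lists(conc, min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, cI, cII):
        sides = MembraneSides(cI, cII)
        J = facilitative_flux(sides, 5.0, 1000.0)
        np.testing.assert_allclose(
            facilitative_flux(sides.swapped(), 5.0, 1000.0), -J, atol=1e-14
        )


class TestBiasFactors:
    def test_no_potential_means_no_bias(self):
        b = bias_factors(_params(delta_psi=0.0))
        assert (b.eps, b.eps_prime) == (1.0, 1.0)

    def test_reference_bias_ratio(self):
        # at -21 mV, 310 K the forward/backward ratio is exp(0.021*F/RT) ~ 2.19
        b = bias_factors(_params())
        expected = np.exp(0.021 * 9.65e4 / (8.314 * 310.0))
        assert b.eps_prime / b.eps == pytest.approx(expected, rel=1e-12)
        assert b.eps_prime / b.eps == pytest.approx(2.19, abs=0.01)

    @given(beta=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_ratio_is_beta_independent(self, beta):
        b = bias_factors(_params(beta=beta))
        ref = bias_factors(_params(beta=0.5))
        assert b.eps_prime / b.eps == pytest.approx(ref.eps_prime / ref.eps, rel=1e-12)


def _equilibrium_ratio(params: TransporterParams) -> float:
    """(Na_I/Na_II) * exp(-zF dpsi / RT): the accumulation limit."""
    x = params.z * params.F_const * params.delta_psi / (params.R_const * params.T_abs)
    return params.Na_maternal / params.Na_syncytio * np.exp(-x)


class TestAccumulative:
    def test_zero_substrate_gives_zero_flux(self):
        sides = MembraneSides([0.0, 0.0], [0.0, 0.0], 134000.0, 15000.0)
        np.testing.assert_array_equal(accumulative_flux(sides, _params()), 0.0)

    def test_equilibrium_accumulation_ratio_reference(self):
        """Zero net flux at [A]_II/[A]_I = (Na_I/Na_II) exp(-zF dpsi/RT) ~ 19.6,
        located independently by bisection on the full flux law."""
        p = _params()
        ratio = _equilibrium_ratio(p)
        assert ratio == pytest.approx(19.6, abs=0.1)
        a_I = 100.0

        def net(a_II):
            sides = MembraneSides([a_I, 0.0], [a_II, 0.0], p.Na_maternal, p.Na_syncytio)
            return accumulative_flux(sides, p, group=0)

        root = brentq(net, 1e-6, 1e6 * a_I, xtol=1e-10, rtol=1e-12)
        assert root / a_I == pytest.approx(ratio, rel=1e-6)

    def test_symmetric_limit_flux_follows_gradient(self):
        p = _params(delta_psi=0.0, Na_maternal=50000.0, Na_syncytio=50000.0)
        up = MembraneSides([200.0, 0.0], [100.0, 0.0], 50000.0, 50000.0)
        down = MembraneSides([100.0, 0.0], [200.0, 0.0], 50000.0, 50000.0)
        assert accumulative_flux(up, p, group=0) > 0
        assert accumulative_flux(down, p, group=0) < 0

    def test_requires_exactly_two_substrates_and_sodium(self):
        with pytest.raises(ValueError, match="two substrate"):
            accumulative_flux(MembraneSides([1.0], [1.0], 1.0, 1.0), _params())
        with pytest.raises(ValueError, match="sodium"):
            accumulative_flux(MembraneSides([1.0, 1.0], [1.0, 1.0]), _params())

    @given(
        a=pos_conc, b=pos_conc, a2=pos_conc, b2=pos_conc,
        beta=st.floats(min_value=0.0, max_value=1.0),
        dpsi=st.floats(min_value=-0.05, max_value=0.05),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_reversal_symmetry(self, a, b, a2, b2, beta, dpsi):
        """Relabelling the sides while flipping the potential *and* the bias
        split (dpsi -> -dpsi, beta -> 1-beta) negates the flux exactly; with
        the symmetric split beta = 1/2 the side swap + potential flip alone
        suffices."""
        p = _params(beta=beta, delta_psi=dpsi)
        sides = MembraneSides([a, b], [a2, b2], 134000.0, 15000.0)
        J = accumulative_flux(sides, p)
        p_rev = _params(beta=1.0 - beta, delta_psi=-dpsi)
        J_rev = accumulative_flux(sides.swapped(), p_rev)
        np.testing.assert_allclose(J_rev, -J, rtol=1e-12, atol=1e-18)

    def test_side_swap_with_potential_flip_at_half_beta(self):
        p = _params(beta=0.5)
        sides = MembraneSides([100.0, 400.0], [900.0, 50.0], 134000.0, 15000.0)
        J = accumulative_flux(sides, p)
        p_rev = _params(beta=0.5, delta_psi=-p.delta_psi)
        np.testing.assert_allclose(
            accumulative_flux(sides.swapped(), p_rev), -J, rtol=1e-12
        )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_equilibrium_ratio_randomized(self, seed):
        """The numerically located zero-flux ratio matches the thermodynamic
        prediction to 1e-6 relative for randomized kinetic parameters."""
        fx = generate_fixture(seed)
        p = fx["params"]
        ratio = _equilibrium_ratio(p)
        a_I = 50.0

        def net(a_II):
            sides = MembraneSides(
                [a_I, 0.0], [a_II, 0.0], p.Na_maternal, p.Na_syncytio
            )
            return accumulative_flux(sides, p, group=0)

        root = brentq(net, 1e-9 * a_I, 1e9 * a_I, xtol=1e-12, rtol=1e-14)
        assert root / a_I == pytest.approx(ratio, rel=1e-6)

    def test_literal_denominator_variant_stays_close(self):
        # the alternative typographic reading shifts fluxes only a few percent
        p = _params()
        sides = MembraneSides([826.0, 215.0], [4413.0, 1987.0], p.Na_maternal, p.Na_syncytio)
        J_dim = accumulative_flux(sides, p, denominator_convention="dimensional")
        J_lit = accumulative_flux(sides, p, denominator_convention="literal")
        np.testing.assert_allclose(J_lit, J_dim, rtol=0.1)
        assert not np.allclose(J_lit, J_dim)


class TestFlowFlux:
    def test_matched_concentrations_no_flux(self):
        assert flow_flux(100.0, 100.0, 6.0) == 0.0

    def test_zero_flow_no_flux(self):
        assert flow_flux(500.0, 100.0, 0.0) == 0.0

    def test_efflux_when_compartment_exceeds_input(self):
        # F = 6 ml/min, input 1369, compartment 1424 umol/l -> -0.33 umol/min
        assert flow_flux(1369.0, 1424.0, 6.0) == pytest.approx(-0.33, rel=1e-12)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            flow_flux(1.0, 1.0, -1.0)


@given(eps_c=st.floats(min_value=0.0, max_value=1e-6))
@settings(max_examples=25, deadline=None)
def test_fluxes_continuous_at_zero_concentration(eps_c):
    """All three carrier laws approach their zero-concentration value
    smoothly: flux magnitude vanishes with the vanishing substrate."""
    p = _params()
    ex = exchanger_flux(MembraneSides([eps_c, 100.0], [50.0, 50.0]), 5.0, 200.0)[0]
    ex0 = exchanger_flux(MembraneSides([0.0, 100.0], [50.0, 50.0]), 5.0, 200.0)[0]
    assert abs(ex - ex0) < 1e-6
    fa = facilitative_flux(MembraneSides([eps_c], [0.0]), 5.0, 1000.0)[0]
    assert abs(fa) < 1e-8
    ac = accumulative_flux(
        MembraneSides([eps_c, 0.0], [0.0, 0.0], 134000.0, 15000.0), p
    )[0]
    assert abs(ac) < 1e-8
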