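"""Forward-model unit and property tests.

The Torrey translational spectral density is checked against an
independent numerical-quadrature oracle of the defining wavenumber
integral; the distributed rotational term is checked against a dense
(10^4-node) quadrature oracle and against the single-correlation-time
BPP limit.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import constants as codata
from scipy.integrate import quad
from scipy.special import spherical_jn

import gelnmr as g
from gelnmr.relax_models import (
    DELTA_JUMP_A_EQ_D,
    torrey_reduced_spectral_density,
)


# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------

def test_c_inter_matches_codata():
    """(9/8)(mu0 gamma^2 hbar / 4pi)^2 from CODATA values, within 0.1 %."""
    gamma = codata.value("proton gyromag. ratio")
    expected = 9.0 / 8.0 * (codata.mu_0 / (4 * np.pi) * gamma**2 * codata.hbar) ** 2
    assert g.DEFAULT_CONSTANTS.c_inter == pytest.approx(expected, rel=1e-3)
    assert g.DEFAULT_CONSTANTS.c_inter == pytest.approx(6.4e-49, rel=2e-3)


def test_tau_trans_derived_from_diffusion():
    p = g.TranslationalParams(D=1.70e-12, N=4.39e28, d=3.6e-10)
    assert p.tau_trans == pytest.approx(3.6e-10**2 / (6 * 1.70e-12))
    assert p.tau_trans == pytest.approx(1.27e-8, rel=5e-3)
    assert p.delta_jump == DELTA_JUMP_A_EQ_D == pytest.approx(1 / 12)


# ---------------------------------------------------------------------------
# BPP Lorentzian rotational term
# ---------------------------------------------------------------------------

class TestLorentzianBpp:
    def test_zero_frequency_limit(self):
        # R1(0) = 5 C tau
        assert g.lorentzian_bpp_r1(0.0, 1e-9, 1e9) == pytest.approx(5.0, rel=1e-12)

    def test_omega_tau_unity(self):
        # C tau (1/2 + 4/5)
        assert g.lorentzian_bpp_r1(1e9, 1e-9, 1e9) == pytest.approx(1.3, rel=1e-12)

    def test_high_frequency_asymptote(self):
        # series expansion: R1 -> 2 C / (omega^2 tau) for omega*tau >> 1
        tau, C = 1e-9, 1e9
        omega = 1e3 / tau
        assert g.lorentzian_bpp_r1(omega, tau, C) == pytest.approx(
            2 * C / (omega**2 * tau), rel=1e-4
        )

    def test_strictly_decreasing(self):
        omega = np.geomspace(1e3, 1e12, 200)
        r1 = g.lorentzian_bpp_r1(omega, 1e-9, 1e9)
        assert np.all(np.diff(r1) < 0)

    @pytest.mark.parametrize("tau,C", [(-1e-9, 1e9), (0.0, 1e9), (1e-9, 0.0)])
    def test_domain_errors(self, tau, C):
        with pytest.raises(ValueError):
            g.lorentzian_bpp_r1(1e6, tau, C)

    def test_spectral_density_normalization(self):
        """int_0^inf tau/(1+w^2 tau^2) dw = pi/2 for every tau."""
        for tau in (1e-11, 1e-9, 1e-6):
            f = lambda w: tau / (1 + (w * tau) ** 2)
            head, _ = quad(f, 0, 1 / tau)
            # tail integrated in log-frequency; remainder beyond 1e8/tau is ~1e-8
            tail, _ = quad(lambda x: f(np.exp(x)) * np.exp(x),
                           np.log(1 / tau), np.log(1e8 / tau), limit=200)
            assert head + tail == pytest.approx(np.pi / 2, rel=1e-4)


# ---------------------------------------------------------------------------
# log-Gaussian distribution quadrature
# ---------------------------------------------------------------------------

class TestLogGaussianWeights:
    def test_normalized(self):
        _, w = g.log_gaussian_weights(1e-9, 1.5, 128)
        assert abs(w.sum() - 1.0) < 1e-9
        assert np.all(w >= 0)

    def test_point_mass_limit(self):
        taus, w = g.log_gaussian_weights(1e-9, 0.0)
        assert taus.tolist() == [1e-9] and w.tolist() == [1.0]

    def test_symmetric_about_center(self):
        taus, w = g.log_gaussian_weights(3e-10, 1.5, 128)
        logs = np.log10(taus) - math.log10(3e-10)
        assert np.allclose(logs + logs[::-1], 0.0, atol=1e-12)
        assert np.allclose(w, w[::-1], rtol=1e-12)

    def test_weighted_median_at_center(self):
        # dense-quadrature oracle: the weighted median equals tau_center
        taus, w = g.log_gaussian_weights(1e-9, 1.5, 10_000)
        cdf = np.cumsum(w)
        med = taus[np.searchsorted(cdf, 0.5)]
        spacing = np.log10(taus[1] / taus[0])
        assert abs(math.log10(med / 1e-9)) <= spacing

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            g.log_gaussian_weights(1e-9, -0.1)
        with pytest.raises(ValueError):
            g.log_gaussian_weights(1e-9, 1.5, n_nodes=8)
        with pytest.raises(ValueError):
            g.log_gaussian_weights(1e-9, 1.5, span_decades=2.0)

    @given(
        tau=st.floats(1e-12, 1e-6),
        delta=st.floats(0.1, 3.0),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_weights_properties_hypothesis(self, tau, delta):
        taus, w = g.log_gaussian_weights(tau, delta, 64)
        assert abs(w.sum() - 1.0) < 1e-9
        assert np.all(w >= 0)
        assert np.all(np.diff(taus) > 0)


class TestRotationalDistributed:
    def test_delta_zero_matches_single_tau(self):
        params = g.RotationalParams(C_intra=1e9, tau_rot=1e-9, delta_rot=0.0)
        omega = np.geomspace(1e3, 1e9, 60)  # six decades
        dist = g.rotational_r1_distributed(omega, params)
        bpp = g.lorentzian_bpp_r1(omega, 1e-9, 1e9)
        assert np.allclose(dist, bpp, rtol=1e-6)

    def test_zero_frequency_mean_tau(self):
        # R1(0) = 5 C <tau>, against a 10^4-node quadrature oracle
        params = g.RotationalParams(C_intra=1e9, tau_rot=1e-9, delta_rot=1.5)
        taus, w = g.log_gaussian_weights(1e-9, 1.5, 10_000)
        mean_tau = float((taus * w).sum())
        val = g.rotational_r1_distributed(np.array([0.0]), params, n_nodes=10_000)[0]
        assert val == pytest.approx(5 * 1e9 * mean_tau, rel=1e-9)
        # the default 128-node rule agrees with the dense oracle
        val128 = g.rotational_r1_distributed(np.array([0.0]), params)[0]
        assert val128 == pytest.approx(val, rel=1e-3)

    def test_linear_in_c_intra(self):
        omega = np.geomspace(1e4, 1e10, 20)
        p1 = g.RotationalParams(C_intra=1e9, tau_rot=1e-9, delta_rot=1.5)
        p2 = g.RotationalParams(C_intra=2e9, tau_rot=1e-9, delta_rot=1.5)
        assert np.allclose(
            2 * g.rotational_r1_distributed(omega, p1),
            g.rotational_r1_distributed(omega, p2),
            rtol=1e-12,
        )

    def test_non_increasing(self):
        omega = np.geomspace(1e3, 1e11, 150)
        params = g.RotationalParams(C_intra=1e9, tau_rot=5.7e-10, delta_rot=1.5)
        r1 = g.rotational_r1_distributed(omega, params)
        assert np.all(np.diff(r1) <= 0)


# ---------------------------------------------------------------------------
# Torrey translational term vs. quadrature oracle
# ---------------------------------------------------------------------------

def _torrey_oracle(delta, u):
    """Independent evaluation of the defining wavenumber integral.

    Integrates j1(x)^2 * [R(x) - R_inf] per oscillation lobe (fast 1/x^4
    tail) and adds the exactly-known R_inf * int j1^2 = R_inf * pi/6.
    """
    r_inf = 1.0 / (1.0 + u * u)

    def rational(x):
        B = 2 * delta * x * x
        return B * (1 + B) / (B * B + u * u * (1 + B) ** 2)

    def integrand(x):
        return spherical_jn(1, x) ** 2 * (rational(x) - r_inf)

    total = 0.0
    edges = np.concatenate([[0.0], np.arange(np.pi / 2, 1500 * np.pi, np.pi)])
    for a, b in zip(edges[:-1], edges[1:]):
        v, _ = quad(integrand, a, b, limit=200)
        total += v
    return (32.0 / 15.0) * (total + r_inf * np.pi / 6)


@pytest.mark.parametrize("u", [0.0, 1e-4, 1e-2, 0.3, 1.0, 7.0, 80.0])
def test_torrey_reduced_density_vs_quadrature(u):
    got = torrey_reduced_spectral_density(np.array([u]))[0]
    want = _torrey_oracle(1.0 / 12.0, max(u, 1e-13))
    assert got == pytest.approx(want, rel=1e-7)


def test_torrey_reduced_density_other_jump_parameter():
    # the closed form is valid for any delta, not only the a = d value
    got = torrey_reduced_spectral_density(np.array([0.5]), delta_jump=0.3)[0]
    assert got == pytest.approx(_torrey_oracle(0.3, 0.5), rel=1e-7)


class TestTorreyTranslational:
    def test_linear_in_spin_density(self):
        omega = np.geomspace(1e4, 1e10, 25)
        p1 = g.TranslationalParams(D=1.7e-12, N=1e28)
        p3 = g.TranslationalParams(D=1.7e-12, N=3e28)
        assert np.allclose(
            3 * g.torrey_translational_r1(omega, p1),
            g.torrey_translational_r1(omega, p3),
            rtol=1e-12,
        )

    def test_finite_at_zero_and_non_increasing(self):
        omega = np.concatenate([[0.0], np.geomspace(1e2, 1e11, 200)])
        r1 = g.torrey_translational_r1(omega, g.TranslationalParams(D=3.9e-13, N=1.3e28))
        assert np.all(np.isfinite(r1)) and r1[0] > 0
        assert np.all(np.diff(r1) <= 0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            g.torrey_translational_r1(np.array([-1.0]), g.TranslationalParams(D=1e-12, N=1e28))


# ---------------------------------------------------------------------------
# composite model
# ---------------------------------------------------------------------------

class TestTotalR1:
    def test_components_sum_bit_for_bit(self, suc_params_25, rng):
        omega = 2 * np.pi * 10 ** rng.uniform(4, 8.7, size=50)
        omega.sort()
        comps = g.total_r1_components(omega, suc_params_25)
        total = g.total_r1(omega, suc_params_25)
        resum = comps["rotational"] + comps["translational_mm"] + comps["translational_lm"]
        assert np.array_equal(resum, total)

    def test_zero_spin_densities_reduce_to_rotation(self, suc_params_25):
        p = g.CompositeModelParams(
            rot=suc_params_25.rot,
            mm=g.TranslationalParams(D=1.7e-12, N=0.0),
            lm=g.TranslationalParams(D=3.9e-13, N=0.0),
        )
        omega = np.geomspace(1e4, 1e9, 30)
        assert np.allclose(
            g.total_r1(omega, p),
            g.rotational_r1_distributed(omega, p.rot),
            rtol=1e-12,
        )

    def test_suc_curve_positive_and_non_increasing(self, suc_params_25):
        # published SUC 25 C parameters over 0.01 - 500 MHz
        omega = 2 * np.pi * np.geomspace(1e4, 5e8, 300)
        r1 = g.total_r1(omega, suc_params_25)
        assert np.all(r1 > 0)
        assert np.all(np.diff(r1) <= 1e-12 * r1[:-1])

    def test_mm_lm_labeling_enforced(self):
        with pytest.raises(ValueError):
            g.CompositeModelParams(
                rot=g.RotationalParams(C_intra=1e9, tau_rot=1e-9),
                mm=g.TranslationalParams(D=1e-13, N=1e28),
                lm=g.TranslationalParams(D=1e-12, N=1e28),
            )

    def test_flat_dict_round_trip(self, suc_params_25):
        flat = suc_params_25.to_flat_dict()
        assert flat["tau_rot_ns"] == pytest.approx(0.57)
        assert flat["d_angstrom"] == pytest.approx(3.6)
        back = g.CompositeModelParams.from_flat_dict(flat)
        assert back.to_flat_dict() == pytest.approx(flat)


def test_frequency_conversion_round_trip():
    nu = np.geomspace(1e4, 5e8, 40)
    back = g.relax_models.frequency_from_omega(g.relax_models.omega_from_frequency(nu))
    assert np.allclose(back, nu, rtol=1e-15, atol=0.0)
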