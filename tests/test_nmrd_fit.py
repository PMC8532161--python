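"""Joint NMRD fitting: round-trip recovery, protocol contracts, derived
quantities against the published table values, and the low-frequency
discriminant."""

import numpy as np
import pytest

import gelnmr as g
from gelnmr.nmrd_fit import JointFitResult, FitProtocol


def _synth_pair(noise, seed, grid):
    p25 = g.simulate_nmrd_profile(
        g.nmrd_params_for("SUC", 25.0), grid, noise, seed, "SUC", 25.0
    )
    p4 = g.simulate_nmrd_profile(
        g.nmrd_params_for("SUC", 4.0), grid, noise, seed + 1000, "SUC", 4.0
    )
    return p25, p4


@pytest.fixture(scope="module")
def noiseless_fit(study_grid_module):
    p25, p4 = _synth_pair(0.0, 1, study_grid_module)
    return g.fit_nmrd_joint(p25, p4, FitProtocol(seed=1)), p25, p4


@pytest.fixture(scope="module")
def study_grid_module():
    return g.make_frequency_grid(1e4, 2e7, 30, [5e8])


class TestNoiselessRecovery:
    def test_parameters_recovered_within_one_percent(self, noiseless_fit):
        res, _, _ = noiseless_fit
        truth25 = g.nmrd_params_for("SUC", 25.0)
        truth4 = g.nmrd_params_for("SUC", 4.0)
        fit25 = res.params_by_temperature[25.0]
        fit4 = res.params_by_temperature[4.0]
        pairs = [
            (fit25.rot.C_intra, truth25.rot.C_intra),
            (fit25.rot.tau_rot, truth25.rot.tau_rot),
            (fit25.mm.D, truth25.mm.D),
            (fit25.lm.D, truth25.lm.D),
            (fit25.mm.N, truth25.mm.N),
            (fit25.lm.N, truth25.lm.N),
            (fit4.rot.C_intra, truth4.rot.C_intra),
            (fit4.rot.tau_rot, truth4.rot.tau_rot),
            (fit4.mm.D, truth4.mm.D),
            (fit4.lm.D, truth4.lm.D),
        ]
        for got, want in pairs:
            assert got == pytest.approx(want, rel=0.01)

    def test_residual_norm_below_data_norm(self, noiseless_fit):
        res, p25, p4 = noiseless_fit
        for prof in (p25, p4):
            r = res.residuals[prof.temperature_C] * (0.05 * prof.R1)  # unweighted
            assert np.linalg.norm(r) < 1e-6 * np.linalg.norm(prof.R1)

    def test_frozen_parameters_bit_identical(self, noiseless_fit):
        res, _, _ = noiseless_fit
        fit25 = res.params_by_temperature[25.0]
        fit4 = res.params_by_temperature[4.0]
        assert fit4.mm.N == res.N_mm == fit25.mm.N
        assert fit4.lm.N == res.N_lm == fit25.lm.N
        assert fit4.mm.d == FitProtocol().d_fixed
        assert fit4.rot.delta_rot == FitProtocol().delta_rot_fixed

    def test_mm_lm_labels_ordered(self, noiseless_fit):
        res, _, _ = noiseless_fit
        for p in res.params_by_temperature.values():
            assert p.mm.D > p.lm.D


def test_point_order_invariance(study_grid_module):
    p25, p4 = _synth_pair(0.02, 3, study_grid_module)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(p25))
    p25_shuffled = g.NMRDProfile(
        "SUC", 25.0, p25.frequency_hz[perm], p25.R1[perm], p25.relative_error[perm]
    )
    res_a = g.fit_nmrd_joint(p25, p4, FitProtocol(seed=3))
    res_b = g.fit_nmrd_joint(p25_shuffled, p4, FitProtocol(seed=3))
    a = res_a.params_by_temperature[25.0]
    b = res_b.params_by_temperature[25.0]
    assert a.rot.C_intra == pytest.approx(b.rot.C_intra, rel=1e-9)
    assert a.mm.D == pytest.approx(b.mm.D, rel=1e-9)


def test_short_profile_rejected(study_grid_module):
    p25, _ = _synth_pair(0.0, 0, study_grid_module)
    short = g.NMRDProfile(
        "SUC", 25.0, p25.frequency_hz[:5], p25.R1[:5], p25.relative_error[:5]
    )
    with pytest.raises(ValueError, match="at least"):
        g.fit_nmrd_joint(short, None, FitProtocol())


def test_single_temperature_mode(study_grid_module):
    p25, _ = _synth_pair(0.0, 2, study_grid_module)
    res = g.fit_nmrd_joint(p25, None, FitProtocol(seed=2))
    assert list(res.params_by_temperature) == [25.0]
    truth = g.nmrd_params_for("SUC", 25.0)
    assert res.params_by_temperature[25.0].mm.D == pytest.approx(truth.mm.D, rel=0.01)


class TestDeconvolution:
    def _result_from_params(self, sample="SUC"):
        params = {t: g.nmrd_params_for(sample, t) for t in (25.0, 4.0)}
        return JointFitResult(
            sample_id=sample,
            params_by_temperature=params,
            N_mm=params[25.0].mm.N,
            N_lm=params[25.0].lm.N,
            residuals={}, stderr={}, cost=0.0,
            protocol=FitProtocol(), n_points={},
        )

    def test_components_sum_to_total(self, study_grid_module):
        res = self._result_from_params()
        curves = g.deconvolve_contributions(res, study_grid_module)
        for temp, c in curves.items():
            resum = c["rotational"] + c["translational_mm"] + c["translational_lm"]
            assert np.array_equal(resum, c["total"])

    def test_zero_lm_pool_gives_zero_curve(self):
        params = g.CompositeModelParams(
            rot=g.RotationalParams(C_intra=4.2e9, tau_rot=5.7e-10),
            mm=g.TranslationalParams(D=1.7e-12, N=4.39e28),
            lm=g.TranslationalParams(D=3.9e-13, N=0.0),
        )
        res = JointFitResult(
            sample_id="x", params_by_temperature={25.0: params},
            N_mm=params.mm.N, N_lm=0.0, residuals={}, stderr={},
            cost=0.0, protocol=FitProtocol(), n_points={},
        )
        curves = g.deconvolve_contributions(res, np.geomspace(1e4, 5e8, 20))
        assert np.all(curves[25.0]["translational_lm"] == 0.0)

    def test_rotation_dominates_at_high_field(self, study_grid_module):
        res = self._result_from_params()
        curves = g.deconvolve_contributions(res, np.array([5e8]))
        c = curves[25.0]
        assert c["rotational"][0] > c["translational_mm"][0]
        assert c["rotational"][0] > c["translational_lm"][0]


class TestDerivedQuantities:
    def _stub(self, n_mm, n_lm):
        return JointFitResult(
            sample_id="stub", params_by_temperature={}, N_mm=n_mm, N_lm=n_lm,
            residuals={}, stderr={}, cost=0.0, protocol=FitProtocol(), n_points={},
        )

    def test_suc_row(self):
        d = g.derive_quantities(self._stub(4.39e28, 1.33e28))
        assert d.N_total == pytest.approx(5.72e28)
        assert d.report()["N_total_1e28_per_m3"] == 5.72
        assert d.report()["ratio_N_mm_over_N_lm"] == 3.3

    def test_sbf10_vs_suc(self):
        ref = self._stub(4.39e28, 1.33e28)
        d = g.derive_quantities(self._stub(6.57e28, 3.79e28), reference=ref,
                                moisture_pct=8.2, reference_moisture_pct=4.0)
        rep = d.report()
        assert rep["N_total_1e28_per_m3"] == 10.36
        assert rep["relative_change_N"] == 1.81
        assert rep["ratio_N_mm_over_N_lm"] == 1.7
        assert rep["relative_change_moisture"] == 2.05

    def test_self_reference_is_unity(self):
        s = self._stub(4.39e28, 1.33e28)
        assert g.derive_quantities(s, reference=s).relative_change_N == pytest.approx(1.0)

    def test_zero_lm_pool_ratio_undefined(self):
        assert g.derive_quantities(self._stub(4e28, 0.0)).ratio is None


class TestDiscriminant:
    def _profiles(self, samples, temp, noise=0.0):
        grid = g.make_frequency_grid(1e4, 2e7, 30, [5e8])
        return [
            g.simulate_nmrd_profile(
                g.nmrd_params_for(s, temp), grid, noise, i, s, temp
            )
            for i, s in enumerate(samples)
        ]

    def test_suc_vs_sbf10_flags_suc(self):
        for temp in (25.0, 4.0):
            disc = g.low_frequency_discriminant(self._profiles(["SUC", "SBF10"], temp))
            assert disc.original_like == "SUC"
            assert not disc.tie

    def test_identical_profiles_tie(self):
        grid = g.make_frequency_grid(1e4, 2e7, 30)
        p = g.simulate_nmrd_profile(g.nmrd_params_for("SUC", 25.0), grid, 0.0, 0, "a")
        q = g.NMRDProfile("b", 25.0, p.frequency_hz, p.R1, p.relative_error)
        disc = g.low_frequency_discriminant([p, q])
        assert disc.tie

    def test_statistic_invariant_to_point_order(self):
        p = self._profiles(["SUC"], 25.0, noise=0.02)[0]
        perm = np.random.default_rng(1).permutation(len(p))
        q = g.NMRDProfile("SUC2", 25.0, p.frequency_hz[perm], p.R1[perm],
                          p.relative_error[perm])
        disc = g.low_frequency_discriminant([p, q])
        assert disc.statistic["SUC"] == pytest.approx(disc.statistic["SUC2"], rel=1e-12)
        assert disc.tie

    def test_no_points_below_cutoff(self):
        grid = g.make_frequency_grid(2e6, 2e7, 10)
        profiles = [
            g.simulate_nmrd_profile(g.nmrd_params_for(s, 25.0), grid, 0.0, 0, s)
            for s in ("SUC", "SBF10")
        ]
        with pytest.raises(ValueError, match="below"):
            g.low_frequency_discriminant(profiles)
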