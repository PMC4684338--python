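import numpy as np
import pytest

from dcepk.kinetics import (
    AIF,
    ConcentrationSeries,
    compute_augc,
    extract_aif,
    fit_parameter_maps,
    fit_tofts_voxel,
    signal_to_concentration,
    tofts_forward,
)
from dcepk.protocol import AcquisitionProtocol, RelaxivityConstants
from dcepk.relaxometry import T1MapResult, spgr_signal
from dcepk.synthetic import synthesize_signal


def step_response(ktrans, kep, c0, t_min):
    """Closed-form Tofts response to a constant plasma input from t = 0."""
    return (ktrans / kep) * c0 * (1.0 - np.exp(-kep * t_min))


class TestToftsForward:
    def test_zero_input_gives_zero_output(self, t_grid):
        ct = tofts_forward(0.3, 0.6, np.zeros_like(t_grid), t_grid)
        assert np.all(ct == 0.0)

    def test_step_input_matches_closed_form(self, t_grid):
        """Discretised convolution vs analytic step response at dt = 2.59 s."""
        c0 = 1.0
        for kt, kep in [(0.37, 0.67), (0.1, 2.0), (1.0, 0.2)]:
            ct = tofts_forward(kt, kep, np.full_like(t_grid, c0), t_grid)
            want = step_response(kt, kep, c0, t_grid / 60.0)
            err = np.abs(ct[1:] - want[1:]) / want[1:]
            assert err.max() < 1e-3

    def test_fast_exchange_limit(self, t_grid, cp_default):
        """kep -> large at fixed ve: tissue curve approaches ve * cp."""
        ve = 0.4
        kep = 500.0
        ct = tofts_forward(ve * kep, kep, cp_default, t_grid)
        late = cp_default > 0.2
        assert np.allclose(ct[late], ve * cp_default[late], rtol=0.05)

    def test_starts_at_zero_and_nonnegative(self, t_grid, cp_default):
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        assert ct[0] == 0.0
        assert np.all(ct >= 0.0)

    def test_rejects_negative_rates(self, t_grid, cp_default):
        with pytest.raises(ValueError):
            tofts_forward(-0.1, 0.5, cp_default, t_grid)
        with pytest.raises(ValueError):
            tofts_forward(0.1, -0.5, cp_default, t_grid)

    def test_nonuniform_grid_agrees_with_uniform_path(self, cp_default, t_grid):
        # drop one sample to force the nonuniform recursion
        keep = np.ones(t_grid.size, dtype=bool)
        keep[50] = False
        a = tofts_forward(0.37, 0.67, cp_default[keep], t_grid[keep])
        b = tofts_forward(0.37, 0.67, cp_default, t_grid)[keep]
        assert np.allclose(a, b, atol=5e-4)


class TestSignalToConcentration:
    def _t1map(self, t1=1100.0):
        return T1MapResult(t1=np.array(t1), m0=np.array(1000.0),
                           valid_mask=np.array(True))

    def test_constant_baseline_signal_gives_zero_concentration(self, protocol):
        sig = np.full(protocol.n_dynamics,
                      spgr_signal(1000.0, 1100.0, protocol.flip_dynamic,
                                  protocol.tr))
        cs = signal_to_concentration(sig, self._t1map(), protocol)
        assert np.allclose(cs.conc, 0.0, atol=1e-10)

    def test_round_trip_recovers_concentration(self, protocol, t_grid, cp_default):
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        sig = synthesize_signal(ct, 1100.0, 1000.0, protocol)
        cs = signal_to_concentration(sig, self._t1map(), protocol)
        nz = ct > 1e-6
        assert np.max(np.abs(cs.conc[nz] - ct[nz]) / ct[nz]) < 1e-3

    def test_signal_above_spgr_ceiling_excludes_voxel(self, protocol):
        base = spgr_signal(1000.0, 1100.0, protocol.flip_dynamic, protocol.tr)
        sig = np.full((1, protocol.n_dynamics), base)
        sig[0, 50] = 1000.0 * np.sin(np.deg2rad(protocol.flip_dynamic)) * 1.01
        cs = signal_to_concentration(
            sig,
            T1MapResult(t1=np.array([1100.0]), m0=np.array([1000.0]),
                        valid_mask=np.array([True])),
            protocol,
        )
        assert not cs.valid_mask[0]

    def test_invalid_t1_voxel_propagates(self, protocol):
        sig = np.full((1, protocol.n_dynamics), 25.0)
        t1map = T1MapResult(t1=np.array([np.nan]), m0=np.array([np.nan]),
                            valid_mask=np.array([False]))
        cs = signal_to_concentration(sig, t1map, protocol)
        assert not cs.valid_mask[0]
        assert np.all(np.isnan(cs.conc[0]))


class TestExtractAIF:
    def test_hematocrit_scaling(self, noiseless_phantom, protocol):
        ph = noiseless_phantom
        t1map_blood = 1650.0
        a42 = extract_aif(ph.signal, ph.artery_mask, t1map_blood, protocol,
                          hematocrit=0.42)
        a0 = extract_aif(ph.signal, ph.artery_mask, t1map_blood, protocol,
                         hematocrit=0.0)
        assert np.allclose(a42.cp, a0.cp / 0.58, rtol=1e-9, atol=1e-12)

    def test_phantom_aif_recovered(self, noiseless_phantom, protocol):
        ph = noiseless_phantom
        aif = extract_aif(ph.signal, ph.artery_mask, 1650.0, protocol,
                          hematocrit=ph.hematocrit)
        big = ph.cp > 0.1
        assert np.max(np.abs(aif.cp[big] - ph.cp[big]) / ph.cp[big]) < 0.01

    def test_empty_mask_rejected(self, noiseless_phantom, protocol):
        with pytest.raises(ValueError, match="no voxels"):
            extract_aif(noiseless_phantom.signal,
                        np.zeros_like(noiseless_phantom.artery_mask), 1650.0,
                        protocol)


class TestFitToftsVoxel:
    def test_noiseless_recovery_at_cohort_mean_kinetics(
        self, t_grid, cp_default, aif_default, protocol
    ):
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        cs = ConcentrationSeries(t_grid, ct, protocol.baseline_indices())
        res = fit_tofts_voxel(cs, aif_default)
        assert res.converged
        assert res.ktrans == pytest.approx(0.37, rel=0.01)
        assert res.kep == pytest.approx(0.67, rel=0.01)
        assert res.ve == pytest.approx(0.37 / 0.67, rel=0.02)
        assert res.r_squared > 0.999

    def test_ve_is_ktrans_over_kep_identity(self, t_grid, cp_default,
                                            aif_default, protocol):
        rng = np.random.default_rng(2)
        for _ in range(5):
            kt, kep = rng.uniform(0.1, 0.6), rng.uniform(0.7, 1.5)
            ct = tofts_forward(kt, kep, cp_default, t_grid)
            ct = ct + rng.normal(0, 0.01, ct.shape)
            res = fit_tofts_voxel(
                ConcentrationSeries(t_grid, ct, protocol.baseline_indices()),
                aif_default,
            )
            assert res.converged
            assert res.ve == res.ktrans / res.kep  # exact, by construction

    def test_flat_curve_flagged_not_converged(self, t_grid, aif_default, protocol):
        cs = ConcentrationSeries(t_grid, np.zeros_like(t_grid),
                                 protocol.baseline_indices())
        res = fit_tofts_voxel(cs, aif_default)
        assert not res.converged
        assert np.isnan(res.r_squared)

    def test_snr20_median_error_under_10pct(self, t_grid, cp_default,
                                            aif_default, protocol):
        """100 replicate noisy voxels at concentration SNR ~ 20."""
        rng = np.random.default_rng(99)
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        sigma = ct.max() / 20.0
        errs = []
        for _ in range(100):
            noisy = ct + rng.normal(0, sigma, ct.shape)
            res = fit_tofts_voxel(
                ConcentrationSeries(t_grid, noisy, protocol.baseline_indices()),
                aif_default,
            )
            errs.append(abs(res.ktrans - 0.37) / 0.37)
        assert np.median(errs) < 0.10

    def test_grid_mismatch_rejected(self, t_grid, cp_default, protocol):
        cs = ConcentrationSeries(t_grid, np.zeros_like(t_grid),
                                 protocol.baseline_indices())
        bad_aif = AIF(t_grid + 1.0, cp_default)
        with pytest.raises(ValueError, match="same time grid"):
            fit_tofts_voxel(cs, bad_aif)


class TestFitParameterMaps:
    def _conc(self, t_grid, curves, protocol):
        return ConcentrationSeries(t_grid, curves, protocol.baseline_indices())

    def test_uniform_truth_noiseless_gives_constant_maps(
        self, t_grid, cp_default, aif_default, protocol
    ):
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        curves = np.broadcast_to(ct, (2, 3, 1, t_grid.size)).copy()
        maps = fit_parameter_maps(self._conc(t_grid, curves, protocol),
                                  aif_default, np.ones((2, 3, 1), bool))
        assert maps.valid_mask.all()
        assert np.ptp(maps.ktrans) < 1e-8
        assert np.allclose(maps.ve, maps.ktrans / maps.kep)

    def test_pure_noise_voxels_fail_r2_filter(self, t_grid, aif_default, protocol):
        rng = np.random.default_rng(4)
        curves = rng.normal(0.0, 0.05, (3, 3, 1, t_grid.size))
        maps = fit_parameter_maps(self._conc(t_grid, curves, protocol),
                                  aif_default, np.ones((3, 3, 1), bool))
        assert not maps.valid_mask.any()

    def test_threshold_one_excludes_noisy_voxels(self, t_grid, cp_default,
                                                 aif_default, protocol):
        rng = np.random.default_rng(5)
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        curves = ct + rng.normal(0, 0.02, (2, 2, 1, t_grid.size))
        maps = fit_parameter_maps(self._conc(t_grid, curves, protocol),
                                  aif_default, np.ones((2, 2, 1), bool),
                                  r2_threshold=1.0)
        assert not maps.valid_mask.any()
        assert maps.converged.any()  # excluded by the filter, not by the fit


class TestComputeAUGC:
    def test_zero_curve(self, t_grid, protocol):
        cs = ConcentrationSeries(t_grid, np.zeros_like(t_grid),
                                 protocol.baseline_indices())
        assert compute_augc(cs) == 0.0

    def test_constant_curve_rectangle_integral(self):
        """0.3 mM held over 460 s integrates to 2.3 mM·min."""
        t = np.linspace(0.0, 460.0, 185)
        cs = ConcentrationSeries(t, np.full_like(t, 0.3), np.array([0]))
        assert compute_augc(cs) == pytest.approx(0.3 * 460.0 / 60.0, rel=1e-12)

    def test_linearity_and_additivity(self, t_grid, cp_default, protocol):
        ct = tofts_forward(0.37, 0.67, cp_default, t_grid)
        base = protocol.baseline_indices()
        a = compute_augc(ConcentrationSeries(t_grid, ct, base))
        b = compute_augc(ConcentrationSeries(t_grid, 2 * ct, base))
        assert b == pytest.approx(2 * a, rel=1e-12)
        # additivity over a time split
        k = 80
        left = compute_augc(ConcentrationSeries(t_grid[: k + 1], ct[: k + 1],
                                                np.array([0])))
        right = compute_augc(ConcentrationSeries(t_grid[k:], ct[k:],
                                                 np.array([0])))
        assert left + right == pytest.approx(a, rel=1e-12)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            compute_augc(ConcentrationSeries(np.array([0.0]), np.array([0.1]),
                                             np.array([0])))
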