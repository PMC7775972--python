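import numpy as np
import pytest
from scipy import ndimage as ndi

from pmqsm import (AcquisitionParams, BrainMask, CombinedEchoSeries,
                   average_repeat_fields, fit_field_nonlinear, generate_mask,
                   initialize_field_fit, refine_mask_phi0,
                   remove_readout_phase_gradient, unwrap_phase_3d)
from pmqsm.combine import wrap_phase
from pmqsm.fieldmap import FieldMapResult


def make_series(delta_f_Hz, params, phi0=0.0, magnitude=None):
    """Synthesize a combined echo series with linear phase evolution."""
    eff = params.effective_echo_times_ms * 1e-3
    shape = np.shape(delta_f_Hz)
    mag = np.ones((len(eff) + 1,) + shape) if magnitude is None else magnitude
    phase = np.stack([wrap_phase(phi0 + 2 * np.pi * delta_f_Hz * t)
                      for t in eff])
    return CombinedEchoSeries(magnitude=mag, phase=phase,
                              effective_echo_times_ms=params.effective_echo_times_ms,
                              params=params)


@pytest.fixture(scope="module")
def params():
    return AcquisitionParams(voxel_size_mm=(2, 2, 2))


class TestGenerateMask:
    def test_two_intensity_phantom_masked_exactly(self):
        mag = np.ones((24, 24, 24))
        brain = np.zeros_like(mag, dtype=bool)
        brain[6:18, 6:18, 6:18] = True
        mag[brain] = 100.0
        mask = generate_mask(mag, threshold_frac=0.1)
        assert np.array_equal(mask.volume, brain)

    def test_zero_threshold_keeps_all_positive_voxels(self):
        mag = np.zeros((8, 8, 8))
        mag[2:6, 2:6, 2:6] = 5.0
        mask = generate_mask(mag, threshold_frac=0.0)
        assert np.array_equal(mask.volume, mag > 0)

    def test_unreachable_threshold_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            generate_mask(np.ones((8, 8, 8)), threshold_frac=1.1)


class TestUnwrapPhase3D:
    def test_smooth_ramp_recovered_modulo_2pi(self):
        z = np.linspace(0, 6 * np.pi, 40)
        true = np.broadcast_to(z, (8, 8, 40)).copy()
        wrapped = wrap_phase(true)
        mask = BrainMask(np.ones(true.shape, bool))
        out = unwrap_phase_3d(wrapped, mask)
        # modulo-2pi agreement with the wrapped input, voxel-wise
        k = (out - wrapped) / (2 * np.pi)
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)
        # smooth: recovered ramp differs from truth by one global 2*pi*k
        offset = out - true
        assert np.ptp(offset) < 1e-9
        assert abs(offset.flat[0] / (2 * np.pi)
                   - round(offset.flat[0] / (2 * np.pi))) < 1e-9

    def test_already_unwrapped_phase_unchanged(self, rng):
        ph = ndi.gaussian_filter(rng.normal(0, 0.2, (16, 16, 16)), 3)
        ph = np.clip(ph, -np.pi / 2 + 0.01, np.pi / 2 - 0.01)
        mask = BrainMask(np.ones(ph.shape, bool))
        out = unwrap_phase_3d(ph, mask)
        np.testing.assert_allclose(out, ph, atol=1e-12)

    def test_disconnected_regions_internally_consistent(self):
        shape = (24, 12, 12)
        ph = np.zeros(shape)
        z = np.linspace(0, 4 * np.pi, 10)
        ph[1:11] = z[:, None, None]
        ph[13:23] = z[:, None, None] + 1.0
        mask = np.zeros(shape, bool)
        mask[1:11] = True
        mask[13:23] = True
        out = unwrap_phase_3d(wrap_phase(ph), BrainMask(mask))
        for sl in (slice(1, 11), slice(13, 23)):
            diff = out[sl] - ph[sl]
            assert np.ptp(diff) < 1e-9  # constant within each region

    def test_agrees_with_independent_unwrapper(self, rng):
        """Cross-check against scikit-image's 3-D unwrapper on a smooth
        field (both must agree up to one global 2-pi multiple)."""
        from skimage.restoration import unwrap_phase as sk_unwrap
        true = ndi.gaussian_filter(rng.normal(0, 4, (20, 20, 20)), 4)
        true = true / np.abs(true).max() * 9.0
        wrapped = wrap_phase(true)
        mine = unwrap_phase_3d(wrapped, BrainMask(np.ones(true.shape, bool)))
        ref = np.asarray(sk_unwrap(wrapped))
        diff = mine - ref
        assert np.ptp(diff) < 1e-6


class TestInitializeFieldFit:
    def test_constant_field_recovered_exactly(self, params):
        series = make_series(np.full((8, 8, 8), 20.0), params)
        mask = BrainMask(np.ones((8, 8, 8), bool))
        df, phi0 = initialize_field_fit(series, mask)
        np.testing.assert_allclose(df, 20.0, atol=1e-9)
        np.testing.assert_allclose(phi0, 0.0, atol=1e-9)

    def test_beyond_nyquist_blob_recovered_by_spatial_unwrapping(self, params):
        """100 Hz peak: the per-spacing increment (4.15 rad) wraps, but a
        smooth blob unwraps spatially so the init still reads 100 Hz."""
        shape = (24, 24, 24)
        X, Y, Z = np.meshgrid(*[np.arange(n) - 11.5 for n in shape],
                              indexing="ij")
        blob = 100.0 * np.exp(-(X**2 + Y**2 + Z**2) / (2 * 5.0**2))
        series = make_series(blob, params)
        mask = BrainMask(np.ones(shape, bool))
        df, _ = initialize_field_fit(series, mask)
        np.testing.assert_allclose(df, blob, atol=1e-6)

    def test_constant_phi0_residual_recovered(self, params):
        series = make_series(np.full((8, 8, 8), 10.0), params, phi0=0.3)
        mask = BrainMask(np.ones((8, 8, 8), bool))
        df, phi0 = initialize_field_fit(series, mask)
        np.testing.assert_allclose(phi0, 0.3, atol=1e-9)

    def test_requires_two_effective_echoes(self, params):
        p2 = AcquisitionParams(echo_times_ms=(2.0, 8.6))
        series = make_series(np.zeros((4, 4, 4)), p2)
        with pytest.raises(ValueError):
            initialize_field_fit(series, BrainMask(np.ones((4, 4, 4), bool)))


class TestFitFieldNonlinear:
    def test_noiseless_voxel_recovered_to_machine_precision(self, params):
        series = make_series(np.full((4, 4, 4), 50.0), params, phi0=0.2)
        mask = BrainMask(np.ones((4, 4, 4), bool))
        res = fit_field_nonlinear(series, mask)
        np.testing.assert_allclose(res.delta_f_Hz, 50.0, atol=1e-9)
        np.testing.assert_allclose(res.phi0_rad, 0.2, atol=1e-9)

    def test_two_echo_fit_equals_closed_form(self):
        """With only two noiseless effective echoes the nonlinear fit must
        reproduce the phase-difference closed form exactly."""
        p3 = AcquisitionParams(echo_times_ms=(2.0, 8.6, 15.2),
                               voxel_size_mm=(2, 2, 2))
        field = np.full((6, 6, 6), 17.0)
        series = make_series(field, p3)
        mask = BrainMask(np.ones(field.shape, bool))
        eff = p3.effective_echo_times_ms * 1e-3
        closed = wrap_phase(np.angle(
            np.exp(1j * series.phase[1]) * np.exp(-1j * series.phase[0]))) \
            / (2 * np.pi * (eff[1] - eff[0]))
        res = fit_field_nonlinear(series, mask)
        np.testing.assert_allclose(res.delta_f_Hz, closed, atol=1e-9)

    def test_invariant_to_constant_phase_on_all_echoes(self, params):
        base = make_series(np.full((4, 4, 4), 30.0), params)
        shifted = make_series(np.full((4, 4, 4), 30.0), params, phi0=1.1)
        mask = BrainMask(np.ones((4, 4, 4), bool))
        a = fit_field_nonlinear(base, mask)
        b = fit_field_nonlinear(shifted, mask)
        np.testing.assert_allclose(a.delta_f_Hz, b.delta_f_Hz, atol=1e-9)

    def test_aliased_voxel_needs_initialization(self, params):
        """Above the per-spacing aliasing threshold, the initialized fit
        lands on the true frequency; a deliberately aliased init lands a
        full 1/dTE away (the fit alone cannot disambiguate)."""
        true_f = 120.0  # > 75.76 Hz threshold
        shape = (24, 24, 24)
        X, Y, Z = np.meshgrid(*[np.arange(n) - 11.5 for n in shape],
                              indexing="ij")
        blob = true_f * np.exp(-(X**2 + Y**2 + Z**2) / (2 * 6.0**2))
        series = make_series(blob, params)
        mask = BrainMask(np.ones(shape, bool))
        good = fit_field_nonlinear(series, mask)
        np.testing.assert_allclose(good.delta_f_Hz, blob, atol=1e-6)
        aliased_init = (blob - 1 / 6.6e-3, np.zeros(shape))
        bad = fit_field_nonlinear(series, mask, init=aliased_init)
        center = (12, 12, 12)
        assert abs(bad.delta_f_Hz[center] - blob[center]) > 100.0

    def test_unbiased_at_moderate_snr(self, params, rng):
        """1000 voxels at 30 Hz, SNR 50: mean fitted frequency unbiased."""
        n = 1000
        eff = params.effective_echo_times_ms * 1e-3
        mag = np.ones((6, n, 1, 1))
        sig = np.exp(1j * 2 * np.pi * 30.0 * eff[:, None])
        noisy = sig[:, :, None, None] + (1 / 50.0) * (
            rng.standard_normal((5, n, 1, 1))
            + 1j * rng.standard_normal((5, n, 1, 1)))
        series = CombinedEchoSeries(
            magnitude=mag, phase=np.angle(noisy),
            effective_echo_times_ms=params.effective_echo_times_ms,
            params=params)
        res = fit_field_nonlinear(series, BrainMask(np.ones((n, 1, 1), bool)))
        assert res.delta_f_Hz.mean() == pytest.approx(30.0, abs=0.5)


class TestRefineMaskPhi0:
    def _result(self, phi0):
        shape = phi0.shape
        return FieldMapResult(delta_f_Hz=np.zeros(shape), phi0_rad=phi0,
                              rms_residual=np.zeros(shape),
                              mask=BrainMask(np.ones(shape, bool)))

    def test_exactly_the_outlier_voxels_removed(self):
        phi0 = np.zeros((8, 8, 8))
        bad = [(1, 1, 1), (2, 3, 4), (5, 5, 5), (6, 0, 2), (7, 7, 7)]
        for v in bad:
            phi0[v] = 2.0
        refined = refine_mask_phi0(self._result(phi0), 1.0)
        assert int((~refined.volume).sum()) == 5
        for v in bad:
            assert not refined.volume[v]

    def test_zero_phi0_leaves_mask_unchanged(self):
        refined = refine_mask_phi0(self._result(np.zeros((6, 6, 6))), 1.0)
        assert refined.volume.all()

    def test_threshold_pi_removes_nothing(self, rng):
        phi0 = wrap_phase(rng.uniform(-10, 10, (6, 6, 6)))
        refined = refine_mask_phi0(self._result(phi0), np.pi)
        assert refined.volume.all()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            refine_mask_phi0(self._result(np.zeros((4, 4, 4))), 0.0)


class TestReadoutGradientRemoval:
    def test_injected_slope_removed(self, params):
        shape = (32, 16, 16)
        series = make_series(np.full(shape, 10.0), params)
        x = np.arange(shape[0], dtype=float)
        phase = series.phase.copy()
        for j in range(1, 5):
            phase[j] = wrap_phase(phase[j] + 0.01 * x[:, None, None])
        dirty = CombinedEchoSeries(
            magnitude=series.magnitude, phase=phase,
            effective_echo_times_ms=series.effective_echo_times_ms,
            params=params)
        mask = BrainMask(np.ones(shape, bool))
        clean = remove_readout_phase_gradient(dirty, mask)
        for j in range(1, 5):
            dev = np.angle(np.exp(1j * clean.phase[j])
                           * np.exp(1j * series.phase[j]) ** (-1))
            prof = dev.mean(axis=(1, 2))
            slope = np.polyfit(x, prof, 1)[0]
            assert abs(slope) < 1e-6

    def test_clean_series_unchanged(self, params):
        series = make_series(np.full((16, 12, 12), 5.0), params)
        mask = BrainMask(np.ones((16, 12, 12), bool))
        out = remove_readout_phase_gradient(series, mask)
        err = np.angle(np.exp(1j * (out.phase - series.phase)))
        assert np.abs(err).max() < 1e-9

    def test_per_echo_slopes_removed_independently(self, params):
        shape = (32, 12, 12)
        series = make_series(np.full(shape, 8.0), params)
        x = np.arange(shape[0], dtype=float)
        phase = series.phase.copy()
        slopes = [0.0, 0.004, 0.008, 0.012, 0.016]  # accumulating mistiming
        for j in range(1, 5):
            phase[j] = wrap_phase(phase[j] + slopes[j] * x[:, None, None])
        dirty = CombinedEchoSeries(
            magnitude=series.magnitude, phase=phase,
            effective_echo_times_ms=series.effective_echo_times_ms,
            params=params)
        clean = remove_readout_phase_gradient(dirty,
                                              BrainMask(np.ones(shape, bool)))
        for j in range(1, 5):
            dev = np.angle(np.exp(1j * (clean.phase[j] - series.phase[j])))
            slope = np.polyfit(x, dev.mean(axis=(1, 2)), 1)[0]
            assert abs(slope) < 1e-6


class TestAverageRepeatFields:
    def _result(self, field, mask=None):
        m = BrainMask(np.ones(field.shape, bool) if mask is None else mask)
        return FieldMapResult(delta_f_Hz=field, phi0_rad=np.zeros(field.shape),
                              rms_residual=np.zeros(field.shape), mask=m)

    def test_global_offsets_average_and_report(self, rng):
        base = ndi.gaussian_filter(rng.normal(0, 3, (12, 12, 12)), 2)
        base -= base.mean()
        offsets = [0.0, 5.0, 8.0, 9.0]
        results = [self._result(base + o) for o in offsets]
        avg, diag = average_repeat_fields(results)
        np.testing.assert_allclose(avg.delta_f_Hz, base + 5.5, atol=1e-10)
        np.testing.assert_allclose(diag.mean_delta_f_Hz, offsets, atol=1e-10)
        np.testing.assert_allclose(diag.increments_Hz, [5.0, 3.0, 1.0],
                                   atol=1e-10)
        assert np.all(np.diff(diag.increments_Hz) < 0)

    def test_single_repeat_identity(self):
        field = np.full((6, 6, 6), 2.5)
        avg, diag = average_repeat_fields([self._result(field)])
        np.testing.assert_allclose(avg.delta_f_Hz, field)
        assert diag.increments_Hz.size == 0

    def test_local_corruption_bounded_by_quarter(self):
        base = np.zeros((8, 8, 8))
        corrupted = base.copy()
        corrupted[4, 4, 4] = 20.0
        results = [self._result(base.copy()) for _ in range(3)]
        results.append(self._result(corrupted))
        avg, _ = average_repeat_fields(results)
        assert avg.delta_f_Hz[4, 4, 4] == pytest.approx(5.0)
        assert np.abs(avg.delta_f_Hz).max() <= 20.0 / 4 + 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_repeat_fields([])
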