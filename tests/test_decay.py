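import numpy as np
import pytest

from neurofluid import decay, phantom as ph
from neurofluid.io_imaging import AcquisitionProtocol, VolumeSeries

B7 = np.array([0.0, 50.0, 100.0, 200.0, 300.0, 700.0, 1000.0])


def brute_force_ncc_shift(ref, vol, window=3):
    """Independent oracle: exhaustive circular NCC search over the +-window."""
    best, best_shift = -np.inf, (0, 0, 0)
    ref_c = ref - ref.mean()
    for dx in range(-window, window + 1):
        for dy in range(-window, window + 1):
            for dz in range(-window, window + 1):
                rolled = np.roll(vol, (dx, dy, dz), axis=(0, 1, 2))
                r_c = rolled - rolled.mean()
                denom = np.linalg.norm(ref_c) * np.linalg.norm(r_c)
                ncc = (ref_c * r_c).sum() / denom if denom > 0 else 0.0
                if ncc > best + 1e-12:
                    best, best_shift = ncc, (dx, dy, dz)
    return best_shift


class TestBulkMotionCorrection:
    def test_no_motion_means_zero_shifts(self, rng):
        base = rng.random((12, 12, 8)) + 0.5
        data = base[..., None] + rng.normal(0, 0.01, (12, 12, 8, 5))
        series = VolumeSeries(data=data)
        _, shifts = decay.correct_bulk_motion(series)
        assert shifts == [(0, 0, 0)] * 5

    @pytest.mark.parametrize("true_shift", [(2, 0, 0), (-1, 3, 0), (0, -2, 1)])
    def test_recovers_injected_shift(self, rng, true_shift):
        vol = rng.random((16, 16, 10)) + 0.5
        moved = np.roll(vol, true_shift, axis=(0, 1, 2))
        series = VolumeSeries(data=np.stack([vol, moved], axis=-1))
        aligned, shifts = decay.correct_bulk_motion(series)
        expected = tuple(-s for s in true_shift)
        assert shifts[1] == expected
        np.testing.assert_allclose(aligned.data[..., 1], vol)
        # FFT argmax must match the exhaustive search oracle
        assert shifts[1] == brute_force_ncc_shift(vol, moved)

    def test_single_volume_rejected(self, rng):
        series = VolumeSeries(data=rng.random((8, 8, 8, 1)))
        with pytest.raises(ValueError, match="nothing to align"):
            decay.correct_bulk_motion(series)

    def test_flat_volume_gets_zero_shift(self):
        data = np.ones((10, 10, 8, 2))
        _, shifts = decay.correct_bulk_motion(VolumeSeries(data=data))
        assert shifts[1] == (0, 0, 0)


class TestCombineDirections:
    def _series(self, vols):
        return VolumeSeries(data=np.stack(vols, axis=-1))

    def test_geometric_mean_of_directions(self):
        shape = (4, 4, 4)
        vols = [np.full(shape, 5.0)] + [np.full(shape, v) for v in (1.0, 2.0, 4.0)]
        prot = AcquisitionProtocol(
            b_values=[0, 500, 500, 500], direction_index=[0, 1, 2, 3]
        )
        combined, shells = decay.combine_directions(self._series(vols), prot)
        np.testing.assert_array_equal(shells, [0, 500])
        assert combined.data[0, 0, 0, 1] == pytest.approx(2.0, rel=1e-12)

    def test_b0_arithmetic_mean(self):
        shape = (3, 3, 3)
        vols = [np.full(shape, 1.0), np.full(shape, 3.0), np.full(shape, 2.0)]
        prot = AcquisitionProtocol(b_values=[0, 0, 500], direction_index=[0, 0, 1])
        combined, _ = decay.combine_directions(self._series(vols), prot)
        assert combined.data[0, 0, 0, 0] == pytest.approx(2.0)

    def test_direction_order_irrelevant(self, rng):
        shape = (4, 4, 4)
        dirs = [rng.random(shape) + 0.5 for _ in range(3)]
        b0 = rng.random(shape) + 0.5
        prot = AcquisitionProtocol(
            b_values=[0, 300, 300, 300], direction_index=[0, 1, 2, 3]
        )
        c1, _ = decay.combine_directions(self._series([b0] + dirs), prot)
        prot2 = AcquisitionProtocol(
            b_values=[0, 300, 300, 300], direction_index=[0, 3, 1, 2]
        )
        c2, _ = decay.combine_directions(
            self._series([b0, dirs[2], dirs[0], dirs[1]]), prot2
        )
        np.testing.assert_allclose(c1.data, c2.data)

    def test_isotropic_phantom_combination_is_identity(
        self, noiseless_dwi, protocol, atlas
    ):
        combined, shells = decay.combine_directions(noiseless_dwi, protocol)
        sel = np.flatnonzero(protocol.b_values == 700)[0]
        np.testing.assert_allclose(
            combined.data[..., shells == 700][..., 0],
            noiseless_dwi.data[..., sel],
            rtol=1e-12,
        )


class TestFitDecayVoxel:
    @pytest.mark.parametrize(
        "d_true", [0.00328, 0.00256, 0.00138, 0.00241], ids=str
    )
    def test_noiseless_recovery_to_machine_precision(self, d_true):
        signals = 900.0 * np.exp(-B7 * d_true)
        s0, d, r2, n_used = decay.fit_decay_voxel(signals, B7)
        assert abs(d - d_true) < 1e-10
        assert s0 == pytest.approx(900.0, rel=1e-9)
        assert r2 == pytest.approx(1.0)
        assert n_used == 7

    def test_two_shell_closed_form_with_consistent_third(self):
        # ln(2)/1000 from S(0)=1, S(1000)=0.5; third shell on the same curve
        d_true = np.log(2) / 1000
        b = np.array([0.0, 500.0, 1000.0])
        signals = np.exp(-b * d_true)
        _, d, _, _ = decay.fit_decay_voxel(signals, b)
        assert d == pytest.approx(d_true, rel=1e-10)

    def test_constant_signal_flagged_invalid(self):
        s0, d, _, n_used = decay.fit_decay_voxel(np.full(7, 100.0), B7)
        assert np.isnan(d)
        assert n_used == 7

    def test_nonpositive_shells_dropped(self):
        signals = 100.0 * np.exp(-B7 * 0.002)
        signals[3] = 0.0
        _, d, _, n_used = decay.fit_decay_voxel(signals, B7)
        assert n_used == 6
        assert d == pytest.approx(0.002, rel=1e-9)

    def test_fewer_than_three_valid_shells_invalid(self):
        signals = np.array([100.0, 50.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        s0, d, _, n_used = decay.fit_decay_voxel(signals, B7)
        assert np.isnan(d) and np.isnan(s0)
        assert n_used == 2

    def test_matches_scipy_curve_fit_on_noisy_voxel(self, rng):
        from scipy.optimize import curve_fit

        d_true, s0_true = 0.0024, 500.0
        signals = s0_true * np.exp(-B7 * d_true) + rng.normal(0, 5.0, B7.size)
        signals = np.abs(signals)
        s0, d, _, _ = decay.fit_decay_voxel(signals, B7)
        popt, _ = curve_fit(
            lambda b, s, dd: s * np.exp(-b * dd), B7, signals, p0=[s0, d]
        )
        assert s0 == pytest.approx(popt[0], rel=1e-6)
        assert d == pytest.approx(popt[1], rel=1e-6)

    def test_monotonicity_in_d(self):
        fits = []
        for d_true in (0.001, 0.002, 0.004):
            signals = 100.0 * np.exp(-B7 * d_true)
            fits.append(decay.fit_decay_voxel(signals, B7)[1])
        assert fits[0] < fits[1] < fits[2]

    def test_scale_invariance(self, rng):
        signals = np.abs(
            300.0 * np.exp(-B7 * 0.003) + rng.normal(0, 3.0, B7.size)
        )
        s0_a, d_a, _, _ = decay.fit_decay_voxel(signals, B7)
        s0_b, d_b, _, _ = decay.fit_decay_voxel(signals * 7.5, B7)
        assert d_b == pytest.approx(d_a, rel=1e-9)
        assert s0_b == pytest.approx(7.5 * s0_a, rel=1e-9)


class TestFitDecayMap:
    def test_noiseless_phantom_round_trip(self, noiseless_dwi, protocol, atlas, tissue_params):
        dmap = decay.fit_decay_map(noiseless_dwi, protocol, atlas, motion_correct=False)
        for code, d_true in tissue_params.decay.items():
            mean_d, n = decay.summarize_roi(dmap, atlas, code)
            assert n == atlas.mask(code).sum()
            assert abs(mean_d - d_true) < 1e-10

    def test_empty_mask_all_invalid(self, noiseless_dwi, protocol):
        mask = np.zeros(noiseless_dwi.shape3d, dtype=bool)
        dmap = decay.fit_decay_map(noiseless_dwi, protocol, mask, motion_correct=False)
        assert not dmap.valid_mask.any()

    def test_zeroed_voxel_isolated(self, protocol, small_atlas, tissue_params):
        series = ph.simulate_dwi_series(small_atlas, tissue_params, protocol, snr=None)
        data = series.data.copy()
        vox = tuple(np.argwhere(small_atlas.mask(ph.WM))[0])
        data[vox[0], vox[1], vox[2], :] = 0.0
        broken = VolumeSeries(data=data, affine=series.affine)
        dmap = decay.fit_decay_map(broken, protocol, small_atlas, motion_correct=False)
        assert not dmap.valid_mask[vox]
        others = small_atlas.mask(ph.WM).copy()
        others[vox] = False
        assert dmap.valid_mask[others].all()

    def test_grid_mismatch_rejected(self, noiseless_dwi, protocol):
        with pytest.raises(ValueError, match="does not match"):
            decay.fit_decay_map(
                noiseless_dwi, protocol, np.ones((4, 4, 4), dtype=bool)
            )

    def test_loglinear_and_nls_agree_noiseless(self, tissue_params):
        # initializer alone is exact on noiseless input, refinement must not move it
        for d_true in tissue_params.decay.values():
            signals = 750.0 * np.exp(-B7 * d_true)
            log_fit = np.polyfit(B7, np.log(signals), 1)
            _, d_nls, _, _ = decay.fit_decay_voxel(signals, B7)
            assert d_nls == pytest.approx(-log_fit[0], rel=1e-3)


class TestSummarizeROI:
    def test_uniform_region_mean(self, protocol):
        atlas = ph.build_tissue_atlas((32, 32, 16), seed=0)
        params = ph.TissueParameters()
        params.decay[ph.VENTRICLE_CSF] = 0.00241
        series = ph.simulate_dwi_series(atlas, params, protocol, snr=None)
        dmap = decay.fit_decay_map(series, protocol, atlas, motion_correct=False)
        mean_d, _ = decay.summarize_roi(dmap, atlas, ph.VENTRICLE_CSF)
        assert mean_d == pytest.approx(0.00241, rel=1e-10)

    def test_half_invalid_region_uses_valid_half(self, atlas):
        shape = atlas.labels.shape
        region = atlas.mask(ph.WM)
        d = np.full(shape, np.nan)
        valid = np.zeros(shape, dtype=bool)
        idx = np.argwhere(region)
        half = idx[: len(idx) // 2]
        valid[tuple(half.T)] = True
        d[valid] = 0.005
        dmap = decay.DecayMap(
            D=d, S0=np.where(valid, 1.0, np.nan), r_squared=np.zeros(shape),
            n_shells_used=np.where(valid, 7, 0), valid_mask=valid,
        )
        mean_d, n = decay.summarize_roi(dmap, atlas, ph.WM)
        assert n == len(half)
        assert mean_d == pytest.approx(0.005)

    def test_unknown_region_code(self, atlas, noiseless_dwi, protocol):
        dmap = decay.fit_decay_map(noiseless_dwi, protocol, atlas, motion_correct=False)
        with pytest.raises(KeyError):
            decay.summarize_roi(dmap, atlas, 99)
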