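"""Denoising arithmetic: volume dropping, motion QC, scrubbing, CompCor,
confound regression, band-pass, smoothing."""

import numpy as np
import pytest

from nibstarget.core import BinaryMask, BoldSeries, MotionTrace, StatMap, VolumeGrid
from nibstarget.preprocess import (
    bandpass,
    build_confounds,
    compcor_components,
    detect_outlier_volumes,
    drop_initial_volumes,
    motion_qc,
    regress_confounds,
    smooth_gaussian,
)
from nibstarget.synth import simulate_motion


def _bold(grid, data, tr=2.0):
    return BoldSeries(grid, data, tr)


@pytest.fixture
def grid6():
    return VolumeGrid.isotropic((6, 6, 6), 3.0)


class TestDropInitialVolumes:
    def test_240_minus_5_gives_235(self, grid6, rng):
        bold = _bold(grid6, rng.standard_normal((6, 6, 6, 240)))
        trace = MotionTrace(np.zeros((240, 6)))
        b, t = drop_initial_volumes(bold, trace, 5)
        assert b.n_volumes == 235
        assert t.n_volumes == 235

    def test_k_zero_is_identity(self, grid6, rng):
        bold = _bold(grid6, rng.standard_normal((6, 6, 6, 30)))
        trace = MotionTrace(np.zeros((30, 6)))
        b, t = drop_initial_volumes(bold, trace, 0)
        assert b is bold and t is trace

    def test_alignment_preserved_and_too_large_k_rejected(self, grid6, rng):
        bold = _bold(grid6, rng.standard_normal((6, 6, 6, 30)))
        trace = MotionTrace(rng.standard_normal((30, 6)))
        b, t = drop_initial_volumes(bold, trace, 7)
        assert b.n_volumes == t.n_volumes == 23
        assert np.array_equal(t.params, trace.params[7:])
        with pytest.raises(ValueError):
            drop_initial_volumes(bold, trace, 30)


class TestMotionQC:
    def test_zero_trace_passes_with_zero_rms(self):
        qc = motion_qc(MotionTrace(np.zeros((50, 6))))
        assert qc.passed and qc.mean_rms_mm == 0.0 and qc.max_displacement_mm == 0.0

    def test_constant_4mm_offset_fails_max_rule(self):
        params = np.zeros((50, 6))
        params[1:, 0] = 4.0
        qc = motion_qc(MotionTrace(params))
        assert not qc.passed
        assert qc.max_displacement_mm == pytest.approx(4.0)
        assert qc.mean_rms_mm < 0.2  # fails on the max rule alone

    def test_alternating_translation_hand_computed_rms(self):
        # x alternates +-0.3 mm: every frame-to-frame displacement is 0.6 mm
        params = np.zeros((40, 6))
        params[:, 0] = 0.3 * (-1) ** np.arange(40)
        qc = motion_qc(MotionTrace(params))
        assert qc.mean_rms_mm == pytest.approx(0.6)

    def test_rotation_scaled_on_50mm_sphere(self):
        # a 0.01 rad step in one rotation = 0.5 mm displacement
        params = np.zeros((3, 6))
        params[1:, 3] = 0.01
        qc = motion_qc(MotionTrace(params))
        assert qc.max_displacement_mm == pytest.approx(0.5)

    def test_single_volume_rejected(self):
        with pytest.raises(ValueError):
            motion_qc(MotionTrace(np.zeros((1, 6))))


class TestOutlierDetection:
    def test_clean_short_series_is_empty_in_most_seeds(self, grid6):
        empty = 0
        for s in range(100):
            g = np.random.default_rng(s)
            bold = _bold(grid6, g.standard_normal((6, 6, 6, 30)))
            trace = simulate_motion(30, 0.05, seed=s)
            if not detect_outlier_volumes(bold, trace):
                empty += 1
        assert empty >= 95

    def test_motion_spike_flagged(self, grid6, rng):
        bold = _bold(grid6, rng.standard_normal((6, 6, 6, 60)))
        trace = simulate_motion(60, 0.0, spike_volumes=[33], spike_mm=1.0, seed=0)
        out = detect_outlier_volumes(bold, trace)
        assert 33 in out and 34 in out  # spike enters and leaves

    def test_intensity_outlier_flagged(self, grid6, rng):
        data = rng.standard_normal((6, 6, 6, 60))
        data[..., 20] += 10.0 * data.std()
        out = detect_outlier_volumes(_bold(grid6, data), MotionTrace(np.zeros((60, 6))))
        assert out == [20]

    def test_and_logic_needs_both_criteria(self, grid6, rng):
        data = rng.standard_normal((6, 6, 6, 60))
        data[..., 20] += 10.0 * data.std()
        trace = simulate_motion(60, 0.0, spike_volumes=[33], spike_mm=1.0, seed=0)
        assert detect_outlier_volumes(_bold(grid6, data), trace, logic="and") == []


class TestCompCor:
    def test_rank_one_mask_recovers_the_series(self, grid6, rng):
        base = rng.standard_normal(40)
        data = np.zeros((6, 6, 6, 40))
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:2, :2, :2] = True
        data[mask] = 2.0 * base + 1.0
        comps = compcor_components(_bold(grid6, data), BinaryMask(grid6, mask), 1)
        r = np.corrcoef(comps[0], base)[0, 1]
        assert abs(r) > 0.999

    def test_components_orthonormal_and_ordered(self, grid6, rng):
        data = rng.standard_normal((6, 6, 6, 40))
        mask = BinaryMask(grid6, np.ones((6, 6, 6), dtype=bool))
        comps = compcor_components(_bold(grid6, data), mask, 5)
        gram = comps @ comps.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)
        # explained variance ordering: projections of the data matrix
        X = data.reshape(-1, 40)
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        ev = [(X @ c) @ (X @ c) for c in comps]
        assert all(ev[i] >= ev[i + 1] - 1e-9 for i in range(4))

    def test_too_many_components_rejected(self, grid6, rng):
        data = rng.standard_normal((6, 6, 6, 10))
        mask = BinaryMask(grid6, np.ones((6, 6, 6), dtype=bool))
        with pytest.raises(ValueError, match="exceeds"):
            compcor_components(_bold(grid6, data), mask, 10)


class TestConfoundRegression:
    def test_pure_trend_regressed_to_zero(self, grid6):
        n = 40
        trend = np.linspace(-1, 1, n)
        data = np.tile(trend, (6, 6, 6, 1)) * 3.0 + 7.0
        conf = build_confounds(MotionTrace(np.zeros((n, 6))))
        resid = regress_confounds(_bold(grid6, data), conf)
        assert np.abs(resid.data).max() < 1e-9

    def test_empty_confounds_demeans(self, grid6, rng):
        data = rng.standard_normal((6, 6, 6, 30)) + 5.0
        resid = regress_confounds(_bold(grid6, data), None)
        assert np.allclose(resid.data.mean(axis=3), 0.0, atol=1e-12)
        assert np.allclose(resid.data, data - data.mean(axis=3, keepdims=True))

    def test_residuals_orthogonal_to_confounds(self, grid6, rng):
        n = 50
        data = rng.standard_normal((6, 6, 6, n))
        conf = build_confounds(
            MotionTrace(rng.standard_normal((n, 6)) * 0.1),
            wm_components=rng.standard_normal((3, n)),
            outlier_volumes=[4, 30],
        )
        resid = regress_confounds(_bold(grid6, data), conf).data.reshape(-1, n)
        C = conf.to_numpy()
        C = C / np.linalg.norm(C, axis=0, keepdims=True)
        R = resid / np.maximum(np.linalg.norm(resid, axis=1, keepdims=True), 1e-30)
        assert np.abs(R @ C).max() < 1e-6

    def test_dependent_columns_dropped_not_fatal(self, grid6, rng, caplog):
        n = 30
        data = rng.standard_normal((6, 6, 6, n))
        x = rng.standard_normal(n)
        C = np.column_stack([x, 2.0 * x, rng.standard_normal(n)])
        with caplog.at_level("WARNING"):
            resid = regress_confounds(_bold(grid6, data), C)
        assert "dependent" in caplog.text
        assert resid.n_volumes == n

    def test_confound_matrix_default_column_count(self):
        conf = build_confounds(
            MotionTrace(np.zeros((40, 6))),
            wm_components=np.zeros((10, 40)),
            csf_components=np.zeros((5, 40)),
            outlier_volumes=[3, 9],
        )
        # 6 motion + 6 derivatives + 10 WM + 5 CSF + 2 outliers + trend
        assert conf.shape == (40, 27 + 2 + 1)


class TestBandpass:
    def _sine(self, grid, f, n=150, tr=2.0):
        t = np.arange(n) * tr
        series = np.sin(2 * np.pi * f * t)
        return _bold(grid, np.tile(series, (*grid.shape, 1)), tr)

    def test_in_band_sinusoid_retained(self, grid6):
        out = bandpass(self._sine(grid6, 0.05))
        ratio = out.data[0, 0, 0].std() / self._sine(grid6, 0.05).data[0, 0, 0].std()
        assert ratio > 0.95

    def test_out_of_band_sinusoid_removed(self, grid6):
        out = bandpass(self._sine(grid6, 0.2))
        ratio = out.data[0, 0, 0].std() / self._sine(grid6, 0.2).data[0, 0, 0].std()
        assert ratio < 0.05

    def test_constant_series_zeroed(self, grid6):
        out = bandpass(_bold(grid6, np.full((6, 6, 6, 50), 3.7)))
        assert np.abs(out.data).max() < 1e-12

    def test_band_outside_nyquist_rejected(self, grid6, rng):
        bold = _bold(grid6, rng.standard_normal((6, 6, 6, 50)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(bold, 0.01, 0.3)  # Nyquist at TR 2 s is 0.25 Hz


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, grid6, rng):
        m = StatMap(grid6, rng.standard_normal(grid6.shape))
        assert smooth_gaussian(m, 0.0) is m

    def test_delta_mass_conserved(self):
        grid = VolumeGrid.isotropic((15, 15, 15), 3.0)
        data = np.zeros(grid.shape)
        data[7, 7, 7] = 5.0
        out = smooth_gaussian(StatMap(grid, data), 6.0)
        assert out.data.sum() == pytest.approx(5.0, rel=1e-3)

    def test_matches_direct_convolution_oracle(self, rng):
        grid = VolumeGrid.isotropic((7, 7, 7), 3.0)
        data = rng.standard_normal(grid.shape)
        out = smooth_gaussian(StatMap(grid, data), 6.0)
        # naive separable convolution with the same truncated Gaussian kernel
        sd_vox = (6.0 / (2 * np.sqrt(2 * np.log(2)))) / 3.0
        radius = int(4.0 * sd_vox + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sd_vox) ** 2)
        k /= k.sum()
        ref = data.copy()
        for axis in range(3):
            ref = np.apply_along_axis(
                lambda v: np.convolve(np.pad(v, radius), k, mode="same")[radius:-radius],
                axis,
                ref,
            )
        assert np.abs(out.data - ref).max() < 1e-8

    def test_negative_fwhm_rejected(self, grid6):
        with pytest.raises(ValueError):
            smooth_gaussian(StatMap(grid6, np.zeros(grid6.shape)), -1.0)
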