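import numpy as np
import pytest
from scipy.stats import linregress

from stmorph.basis import STWindowSpec, lpt_basis
from stmorph.delineate import (
    EmptySeriesError,
    NormalizationModel,
    delineate_record,
    extract_pattern_vector,
    instantaneous_heart_rate,
    mahalanobis_series,
    normalize,
    project,
    residual_error,
    st_level,
    st_measurement_offset,
    st_slope,
)
from stmorph.io import UNIT_UV_PER_DISPLAY_UNIT
from stmorph.preprocess import Beat, ECGRecord, preprocess_record
from stmorph.synth import (
    BeatTemplateParams,
    SyntheticRecordConfig,
    make_beat,
    make_record,
)

FS = 250.0


class TestHeartRate:
    def test_rr_1000ms(self):
        h = instantaneous_heart_rate(np.array([0.0, 1000.0, 2000.0]))
        np.testing.assert_allclose(h, 60.0)

    def test_rr_500ms(self):
        h = instantaneous_heart_rate(np.array([0.0, 500.0]))
        np.testing.assert_allclose(h, 120.0)

    def test_direct_formula(self):
        h = instantaneous_heart_rate(np.array([0.0, 800.0, 1600.0, 2500.0]))
        np.testing.assert_allclose(h, [75.0, 75.0, 75.0, 60000.0 / 900.0])

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_heart_rate(np.array([0.0, 500.0, 400.0]))


class TestMeasurementOffset:
    @pytest.mark.parametrize("h,expected", [(80, 160), (100, 160), (110, 140), (120, 120), (150, 120)])
    def test_rate_adjustment(self, h, expected):
        assert st_measurement_offset(h) == expected

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            st_measurement_offset(0)


def _beat_record(params, fs=FS, duration=2.0, fid_s=1.0):
    """Single synthetic beat embedded in a flat record, isoelectric known 0."""
    n = int(duration * fs)
    sig = np.zeros(n)
    wave, fid_off = make_beat(params, fs)
    start = int(fid_s * fs) - fid_off
    sig[start : start + len(wave)] += wave
    beat = Beat(fiducial=int(fid_s * fs), isoelectric=np.array([0.0]))
    return ECGRecord(signals=sig[None, :], fs=fs, beats=[beat]), beat


class TestSTLevelSlope:
    def test_amplitude_equal_iso_gives_zero(self):
        rec = ECGRecord(signals=np.full((1, 600), 50.0), fs=FS)
        beat = Beat(fiducial=400, isoelectric=np.array([50.0]))
        assert st_level(rec, beat, 0, 80.0) == pytest.approx(0.0)

    def test_iso_subtraction(self):
        rec = ECGRecord(signals=np.full((1, 600), 120.0), fs=FS)
        beat = Beat(fiducial=400, isoelectric=np.array([50.0]))
        assert st_level(rec, beat, 0, 80.0) == pytest.approx(70.0)

    def test_injected_depression_recovered(self):
        rec, beat = _beat_record(BeatTemplateParams(st_level=-100.0))
        assert st_level(rec, beat, 0, 80.0) == pytest.approx(-100.0, abs=5.0)

    def test_flat_st_zero_slope(self):
        rec, beat = _beat_record(BeatTemplateParams(st_level=-80.0))
        assert st_slope(rec, beat, 0, 80.0) == pytest.approx(0.0, abs=5.0)

    def test_upsloping_st(self):
        # +1 uV/ms from F+60 to F+160 equals slope parameter 100 uV/100ms
        rec, beat = _beat_record(BeatTemplateParams(st_slope=100.0))
        assert st_slope(rec, beat, 0, 80.0) == pytest.approx(100.0, abs=5.0)

    def test_horizontal_depression_slope_independent_of_iso(self):
        rec, beat = _beat_record(BeatTemplateParams(st_level=-150.0))
        beat.isoelectric = np.array([999.0])  # slope must not read z
        assert st_slope(rec, beat, 0, 80.0) == pytest.approx(0.0, abs=5.0)


class TestPatternVector:
    def test_constant_signal_zero_vector(self):
        rec = ECGRecord(signals=np.full((1, 600), 42.0), fs=FS)
        beat = Beat(fiducial=300, isoelectric=np.array([42.0]))
        np.testing.assert_allclose(extract_pattern_vector(rec, beat, 0), 0.0, atol=1e-12)

    def test_linear_ramp_interpolation_oracle(self):
        sig = 3.0 * np.arange(600, dtype=float)
        rec = ECGRecord(signals=sig[None, :], fs=FS)
        beat = Beat(fiducial=300, isoelectric=np.array([0.0]))
        x = extract_pattern_vector(rec, beat, 0)
        # hand interpolation: value at F + offset is 3 * (300 + offset_ms*fs/1000)
        offsets = np.linspace(40.0, 160.0, 32)
        expected = 3.0 * (300 + offsets * FS / 1000.0)
        np.testing.assert_allclose(x, expected, atol=1e-9)

    def test_scoop_shape_recovered(self):
        from stmorph.synth import scoop_shape

        rec, beat = _beat_record(BeatTemplateParams(st_scoop=50.0))
        x = extract_pattern_vector(rec, beat, 0)
        expected = 50.0 * scoop_shape(np.linspace(-1, 1, 32))
        np.testing.assert_allclose(x, expected, atol=1.0)

    def test_out_of_range_flagged(self):
        rec = ECGRecord(signals=np.zeros((1, 100)), fs=FS)
        beat = Beat(fiducial=90, isoelectric=np.array([0.0]))
        with pytest.raises(ValueError):
            extract_pattern_vector(rec, beat, 0)


class TestProjection:
    def test_basis_column_projects_to_unit(self, lpt32, rng):
        a = 17.0
        for k in (0, 3, 8):
            x = a * lpt32.entries[:, k]
            s = project(x, lpt32, 9)
            assert s[k] == pytest.approx(a, rel=1e-12)
            others = np.delete(s, k)
            assert np.max(np.abs(others)) < 1e-9

    def test_zero_vector(self, lpt32):
        np.testing.assert_array_equal(project(np.zeros(32), lpt32), np.zeros(9))

    def test_completeness(self, lpt32, rng):
        x = rng.normal(size=32) * 100
        s = project(x, lpt32, 32)
        np.testing.assert_allclose(lpt32.entries @ s, x, atol=1e-9)

    def test_dimension_mismatch(self, lpt32):
        with pytest.raises(ValueError):
            project(np.zeros(16), lpt32)


class TestNormalize:
    def _model(self):
        return NormalizationModel(rho=np.arange(1.0, 10.0), theta=np.full(9, 2.0))

    def test_raw_equals_stds_gives_ones(self):
        m = self._model()
        np.testing.assert_allclose(normalize(m.rho, m, "KLT"), 1.0)

    def test_zero_raw(self):
        np.testing.assert_allclose(normalize(np.zeros(9), self._model(), "LPT"), 0.0)

    def test_table_rho1_worked_divisor(self):
        # printed leading KLT std: 112.66 display units (1 unit = 5 uV)
        rho1_uv = 112.66 * UNIT_UV_PER_DISPLAY_UNIT
        model = NormalizationModel(rho=np.array([rho1_uv] + [1.0] * 8), theta=np.ones(9))
        raw = np.zeros(9)
        raw[0] = rho1_uv
        out = normalize(raw, model, "KLT")
        np.testing.assert_allclose(out, [1.0] + [0.0] * 8)

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            NormalizationModel(rho=np.zeros(9), theta=np.ones(9))


class TestResidual:
    def test_full_rank_zero_residual(self, lpt32, rng):
        x = rng.normal(size=32)
        assert residual_error(x, lpt32, 32) <= 1e-9

    def test_orthogonal_component_is_rms(self, lpt32):
        x = lpt32.entries[:, 20] * 12.0
        assert residual_error(x, lpt32, 9) == pytest.approx(
            np.sqrt(np.mean(x**2)), rel=1e-9
        )

    def test_brute_force_oracle(self, lpt32, rng):
        x = rng.normal(size=32) * 30
        n = 9
        recon = sum(
            np.dot(lpt32.entries[:, k], x) * lpt32.entries[:, k] for k in range(n)
        )
        expected = np.sqrt(np.mean((x - recon) ** 2))
        assert residual_error(x, lpt32, n) == pytest.approx(expected, rel=1e-10)


class TestMahalanobis:
    def test_first_beat_zero(self, rng):
        series = rng.normal(size=(10, 9))
        assert mahalanobis_series(series)[0] == 0.0

    def test_3_4_5(self):
        series = np.zeros((2, 9))
        series[1, 0], series[1, 1] = 3.0, 4.0
        assert mahalanobis_series(series, n_d=5)[1] == pytest.approx(5.0)

    def test_direct_formula_oracle(self, rng):
        series = rng.normal(size=(50, 9))
        n_d = 5
        d = mahalanobis_series(series, n_d)
        expected = np.sqrt(((series[:, :n_d] - series[0, :n_d]) ** 2).sum(axis=1))
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group

        series = rng.normal(size=(20, 9))
        n_d = 5
        q = ortho_group.rvs(n_d, random_state=3)
        rotated = series.copy()
        rotated[:, :n_d] = series[:, :n_d] @ q.T
        np.testing.assert_allclose(
            mahalanobis_series(series, n_d), mahalanobis_series(rotated, n_d), atol=1e-9
        )


class TestDelineateRecord:
    def test_clean_record_null_model(self, clean_record_series):
        _, _, _, series = clean_record_series
        assert np.max(np.abs(series.st_level)) < 20.0
        assert np.max(series.d_lpt) < 3.0

    def test_episode_extremum_in_lpt1(self, episode_record_series, lpt32):
        _, episodes, _, series = episode_record_series
        lpt1_uv = series.lpt_raw[:, 0] / np.sqrt(32)  # constant-basis scaling
        i = np.argmin(lpt1_uv)
        assert lpt1_uv[i] < -100.0
        assert abs(series.time_s[i] - episodes[0].extremum_s) < 10.0

    def test_single_beat_record_rejected_or_trivial(self, lpt32, models):
        klt, norm = models
        rec = ECGRecord(signals=np.zeros((1, 50)), fs=FS, beats=[])
        with pytest.raises(EmptySeriesError):
            delineate_record(rec, lpt32, klt, norm)

    def test_st_level_matches_pattern_last_sample_at_low_hr(self, clean_record_series):
        # Eq-consistency: at h <= 100 the measurement point is F+160 ms, the
        # pattern vector's last sample (both isoelectric-corrected)
        record, _, _, series = clean_record_series
        assert np.all(series.heart_rate <= 100.0)
        lead0 = series.for_lead(0)
        # reconstruct last pattern sample from the full 9-coeff expansion is
        # lossy; instead check level against slope+pattern via residual route
        # using the raw record (interpolation tolerance only)
        from stmorph.preprocess import select_normal_beats

        clean = preprocess_record(record)
        beats = [b for b in select_normal_beats(clean.beats) if b.isoelectric is not None]
        for beat in beats[:10]:
            x = extract_pattern_vector(clean, beat, 0)
            level = st_level(clean, beat, 0, 80.0)
            assert level == pytest.approx(x[-1], abs=1e-6)

    def test_morphology_coefficient_correspondence(self, lpt32, models):
        # the central representational property: pure level/slope/scoop move
        # only coefficients 1/2/3 respectively (cross-talk < 1 % of amplitude)
        klt, norm = models
        amp = 100.0
        cases = {
            "st_level": 0,
            "st_slope": 1,
            "st_scoop": 2,
        }
        base_rec, base_beat = _beat_record(BeatTemplateParams())
        x0 = extract_pattern_vector(base_rec, base_beat, 0)
        s0 = project(x0, lpt32, 3)
        for param, idx in cases.items():
            rec, beat = _beat_record(BeatTemplateParams(**{param: amp}))
            x = extract_pattern_vector(rec, beat, 0)
            delta = project(x, lpt32, 3) - s0
            moved = np.abs(delta[idx])
            others = np.abs(np.delete(delta, idx))
            assert moved > 10.0
            assert np.max(others) < 0.01 * amp

    def test_level_shift_scaling_constant_basis(self, lpt32):
        # a pure level shift of A uV moves LPT coefficient 1 by A*sqrt(32)/theta1;
        # in raw terms the coefficient changes by exactly A*sqrt(32)... /32 norm
        a = 75.0
        rec0, b0 = _beat_record(BeatTemplateParams())
        rec1, b1 = _beat_record(BeatTemplateParams(st_level=a))
        d = project(extract_pattern_vector(rec1, b1, 0), lpt32, 1) - project(
            extract_pattern_vector(rec0, b0, 0), lpt32, 1
        )
        assert d[0] == pytest.approx(a * np.sqrt(32), rel=0.01)

    def test_ground_truth_regression(self, lpt32, models):
        # regression of delineated st_level on injected level: slope 1 +/- 0.05
        klt, norm = models
        rng = np.random.default_rng(8)
        injected, measured = [], []
        for _ in range(60):
            level = rng.uniform(-250, 250)
            rec, beat = _beat_record(BeatTemplateParams(st_level=level))
            injected.append(level)
            measured.append(st_level(rec, beat, 0, 80.0))
        fit = linregress(injected, measured)
        assert fit.slope == pytest.approx(1.0, abs=0.05)
        assert fit.rvalue**2 > 0.98
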