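"""Tests of the 12-lead → XYZ transform, median beat, and GEH metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gehroc.synthetic import EcgGenParams, generate_ecg12
from gehroc.vcg import (
    KORS_LEADS,
    KORS_MATRIX,
    LEAD_NAMES_12,
    Ecg12Record,
    MedianBeatXyz,
    SpatialVector,
    area_vectors,
    azimuth,
    build_median_beat,
    compute_geh,
    detect_origin,
    elevation,
    kors_transform,
    magnitude,
    peak_vectors,
    qtc_bazett,
    sai_qrst,
    spatial_angle,
    svg_area,
    svg_peak,
    vector_magnitude,
)

finite_vec = st.tuples(
    st.floats(-1e4, 1e4), st.floats(-1e4, 1e4), st.floats(-1e4, 1e4)
)


def _record_from_signal(signal, fs=500.0):
    n = len(signal)
    return Ecg12Record(
        signal=signal,
        fs=fs,
        beat_labels=["normal_sinus"],
        r_peaks=np.array([n // 2]),
    )


def _simple_beat(x, y, z, fs=500.0, qrs_onset=10, qrs_offset=60, t_offset=150):
    return MedianBeatXyz(
        x=x, y=y, z=z, fs=fs, qrs_onset=qrs_onset, qrs_offset=qrs_offset, t_offset=t_offset
    )


class TestKorsTransform:
    def test_all_zero_input(self):
        rec = _record_from_signal(np.zeros((100, 12)))
        assert np.all(kors_transform(rec) == 0)

    @pytest.mark.parametrize("lead", KORS_LEADS)
    def test_unit_impulse_reads_matrix_column(self, lead):
        sig = np.zeros((50, 12))
        col12 = LEAD_NAMES_12.index(lead)
        sig[25, col12] = 1.0
        xyz = kors_transform(_record_from_signal(sig))
        expected = KORS_MATRIX[:, KORS_LEADS.index(lead)]
        np.testing.assert_allclose(xyz[25], expected, atol=1e-12)
        assert np.all(xyz[:25] == 0) and np.all(xyz[26:] == 0)

    def test_limb_derived_leads_ignored(self):
        sig = np.zeros((50, 12))
        sig[:, LEAD_NAMES_12.index("aVR")] = 100.0
        assert np.all(kors_transform(_record_from_signal(sig)) == 0)

    def test_round_trip_with_generator(self, clean_record):
        # the synthetic 12-lead map is a right inverse of the Kors matrix
        xyz = kors_transform(clean_record)
        vm = np.sqrt((xyz**2).sum(axis=1))
        assert vm.max() > 1000  # dipole recovered at full scale
        # residual between two adjacent identical beats is numerically zero
        rr = clean_record.r_peaks[1] - clean_record.r_peaks[0]
        np.testing.assert_allclose(xyz[:rr], xyz[rr : 2 * rr], atol=1e-7)

    def test_nan_lead_rejected_by_name(self):
        sig = np.zeros((50, 12))
        sig[3, LEAD_NAMES_12.index("V2")] = np.nan
        with pytest.raises(ValueError, match="V2"):
            kors_transform(_record_from_signal(sig))


class TestMedianBeat:
    def _make_xyz(self, beat, n_beats, rr):
        xyz = np.zeros((n_beats * rr, 3))
        for b in range(n_beats):
            xyz[b * rr : (b + 1) * rr] = beat
        r_peaks = np.arange(n_beats) * rr + int(0.35 * rr)
        return xyz, r_peaks

    def _template(self, rr=400):
        t = np.arange(rr)
        c = int(0.35 * rr)
        beat = np.zeros((rr, 3))
        beat[:, 0] = 800 * np.exp(-0.5 * ((t - c) / 12.0) ** 2)
        beat[:, 1] = 300 * np.exp(-0.5 * ((t - c - 90) / 25.0) ** 2)
        return beat

    def test_identical_beats_reproduce_single_beat(self):
        beat = self._template()
        xyz, r_peaks = self._make_xyz(beat, 8, 400)
        labels = ["normal_sinus"] * 8
        mb = build_median_beat(xyz, labels, r_peaks, 500.0)
        np.testing.assert_allclose(np.column_stack([mb.x, mb.y, mb.z]), beat, atol=1e-9)
        assert mb.n_beats_used == 8

    def test_labelled_artifact_beat_excluded(self):
        beat = self._template()
        xyz, r_peaks = self._make_xyz(beat, 8, 400)
        xyz[3 * 400 : 4 * 400] += 5000.0  # huge artifact on beat 3
        labels = ["normal_sinus"] * 8
        labels[3] = "noisy"
        mb = build_median_beat(xyz, labels, r_peaks, 500.0)
        np.testing.assert_allclose(np.column_stack([mb.x, mb.y, mb.z]), beat, atol=1.0)
        assert mb.n_beats_used == 7

    def test_jittered_beats_realigned(self, rng):
        beat = self._template()
        rr, n_beats = 400, 9
        xyz = np.zeros((n_beats * rr, 3))
        for b in range(n_beats):
            s = int(rng.integers(-2, 3))
            xyz[b * rr : (b + 1) * rr] = np.roll(beat, s, axis=0)
        r_peaks = np.arange(n_beats) * rr + int(0.35 * rr)
        mb = build_median_beat(xyz, ["normal_sinus"] * n_beats, r_peaks, 500.0)
        out = np.column_stack([mb.x, mb.y, mb.z])
        # up to a global 1-2 sample time reference, the median is jitter-free
        rms = min(
            np.sqrt(np.mean((np.roll(out, g, axis=0) - beat) ** 2))
            for g in range(-2, 3)
        )
        assert rms < 5.0

    def test_insufficient_beats_error(self):
        beat = self._template()
        xyz, r_peaks = self._make_xyz(beat, 4, 400)
        labels = ["normal_sinus", "pvc", "pre_post_pvc", "noisy"]
        with pytest.raises(ValueError, match="insufficient beats"):
            build_median_beat(xyz, labels, r_peaks, 500.0)

    def test_idempotence_on_own_output(self, clean_record):
        xyz = kors_transform(clean_record)
        mb = build_median_beat(
            xyz, clean_record.beat_labels, clean_record.r_peaks, clean_record.fs,
            clean_record.fiducials,
        )
        # feed copies of the median beat back in
        beat = np.column_stack([mb.x, mb.y, mb.z])
        rr = len(beat)
        tiled = np.vstack([beat] * 5)
        pre = int(0.35 * rr)
        r_peaks = np.arange(5) * rr + pre
        mb2 = build_median_beat(
            tiled, ["normal_sinus"] * 5, r_peaks, clean_record.fs, clean_record.fiducials
        )
        m = min(len(mb2.x), rr)
        np.testing.assert_allclose(mb2.x[:m], mb.x[:m], atol=1e-9)
        np.testing.assert_allclose(mb2.z[:m], mb.z[:m], atol=1e-9)


class TestOrigin:
    def _beat(self, offset=(0.0, 0.0, 0.0), slope=0.0):
        n = 360
        t = np.arange(n)
        qrs = 900 * np.exp(-0.5 * ((t - 180) / 8.0) ** 2)
        x = qrs + offset[0] + slope * t
        y = 0.3 * qrs + offset[1]
        z = -0.5 * qrs + offset[2]
        return MedianBeatXyz(x=x, y=y, z=z, fs=500.0, qrs_onset=140, qrs_offset=210, t_offset=320)

    def test_zero_baseline_origin_is_zero(self):
        beat = self._beat()
        origin, corrected = detect_origin(beat)
        assert magnitude(origin) < 1e-2
        np.testing.assert_allclose(corrected.x, beat.x, atol=1e-2)

    def test_constant_offset_recovered(self):
        origin, corrected = detect_origin(self._beat(offset=(50.0, 20.0, -30.0)))
        np.testing.assert_allclose(
            [origin.vx, origin.vy, origin.vz], [50, 20, -30], atol=1e-2
        )
        # corrected pre-QRS baseline is flat at zero
        assert np.abs(corrected.x[120:140]).mean() < 1e-2

    def test_sloped_baseline_reduced(self):
        beat = self._beat(slope=0.5)
        _, corrected = detect_origin(beat)
        pre = slice(beat.qrs_onset - 10, beat.qrs_onset)
        assert np.abs(corrected.x[pre]).mean() < np.abs(beat.x[pre]).mean()


class TestVectorOps:
    def test_vector_magnitude_345(self):
        beat = _simple_beat(
            np.full(200, 3.0), np.full(200, 4.0), np.zeros(200)
        )
        np.testing.assert_allclose(vector_magnitude(beat), 5.0)

    def test_peak_vectors_recover_generator_truth(self, clean_record):
        from gehroc.vcg import build_median_beat

        xyz = kors_transform(clean_record)
        mb = build_median_beat(
            xyz, clean_record.beat_labels, clean_record.r_peaks,
            clean_record.fs, clean_record.fiducials,
        )
        _, mb = detect_origin(mb)
        qrs_p, t_p = peak_vectors(mb)
        gt = clean_record.meta["ground_truth"]
        np.testing.assert_allclose(qrs_p.as_array(), gt["qrs_peak_vector"], rtol=0.01)
        np.testing.assert_allclose(t_p.as_array(), gt["t_peak_vector"], rtol=0.01)

    def test_peak_tie_break_earliest_sample(self):
        x = np.zeros(200)
        x[30] = x[40] = 100.0  # tie inside QRS window
        beat = _simple_beat(x, np.zeros(200), np.zeros(200), qrs_onset=20, qrs_offset=60)
        qrs_p, _ = peak_vectors(beat)
        assert qrs_p.vx == 100.0
        vm = vector_magnitude(beat)
        assert np.argmax(vm[20:61]) + 20 == 30

    def test_area_constant_window(self):
        # 1 μV constant x over the 100-ms QRS window -> (100, 0, 0) μV·ms
        fs = 500.0
        beat = _simple_beat(
            np.ones(300), np.zeros(300), np.zeros(300),
            fs=fs, qrs_onset=50, qrs_offset=100, t_offset=200,
        )
        qrs_a, _ = area_vectors(beat)
        assert qrs_a.vx == pytest.approx(100.0, rel=1e-9)

    def test_area_sign_flip_linearity(self, rng):
        x, y, z = rng.normal(size=(3, 300))
        b1 = _simple_beat(x, y, z)
        b2 = _simple_beat(-x, -y, -z)
        a1, t1 = area_vectors(b1)
        a2, t2 = area_vectors(b2)
        np.testing.assert_allclose(a2.as_array(), -a1.as_array(), atol=1e-12)
        np.testing.assert_allclose(t2.as_array(), -t1.as_array(), atol=1e-12)

    def test_integrals_match_oversampled_riemann_oracle(self):
        # smooth synthetic beat sampled at 500 Hz vs 10x-oversampled Riemann sum
        fs, n = 500.0, 300
        t = np.arange(n) / fs
        f = lambda tt: np.column_stack(
            [
                900 * np.exp(-0.5 * ((tt - 0.24) / 0.02) ** 2),
                400 * np.sin(2 * np.pi * 3 * tt) ** 2,
                -250 * np.exp(-0.5 * ((tt - 0.4) / 0.05) ** 2),
            ]
        )
        coarse = f(t)
        beat = _simple_beat(coarse[:, 0], coarse[:, 1], coarse[:, 2],
                            fs=fs, qrs_onset=100, qrs_offset=150, t_offset=250)
        sv = svg_area(beat)
        t_fine = np.arange(100 / fs, 250 / fs + 1e-12, 1 / (10 * fs))
        fine = f(t_fine)
        oracle = fine.sum(axis=0) * (1000.0 / (10 * fs))  # Riemann, μV·ms
        np.testing.assert_allclose(sv.as_array(), oracle, rtol=0.005)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_spatial_angle_reference_points(self, a, b, expected):
        assert spatial_angle(SpatialVector(*a), SpatialVector(*b)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=finite_vec, b=finite_vec, s=st.floats(1e-3, 1e3))
    def test_spatial_angle_symmetry_and_scale_invariance(self, a, b, s):
        va, vb = SpatialVector(*a), SpatialVector(*b)
        if magnitude(va) == 0 or magnitude(vb) == 0:
            return
        ang = spatial_angle(va, vb)
        assert 0.0 <= ang <= 180.0
        assert spatial_angle(vb, va) == pytest.approx(ang, abs=1e-9)
        assert spatial_angle(SpatialVector(s * a[0], s * a[1], s * a[2]), vb) == pytest.approx(
            ang, abs=1e-3
        )

    def test_spatial_angle_zero_vector_error(self):
        with pytest.raises(ValueError, match="undefined angle"):
            spatial_angle(SpatialVector(0, 0, 0), SpatialVector(1, 0, 0))

    def test_svg_peak_is_componentwise_sum(self):
        v = svg_peak(SpatialVector(100, 0, 0), SpatialVector(0, 100, 0))
        assert (v.vx, v.vy, v.vz) == (100, 100, 0)
        v0 = svg_peak(SpatialVector(5, -2, 1), SpatialVector(-5, 2, -1))
        assert (v0.vx, v0.vy, v0.vz) == (0, 0, 0)

    @pytest.mark.parametrize(
        "v,expected",
        [((1, 0, 0), 0.0), ((0, 0, 1), 90.0), ((-1, 0, 0), 180.0), ((0, 0, -1), -90.0)],
    )
    def test_azimuth_quadrants(self, v, expected):
        assert azimuth(SpatialVector(*v)) == pytest.approx(expected)

    def test_azimuth_undefined(self):
        with pytest.raises(ValueError, match="undefined azimuth"):
            azimuth(SpatialVector(0, 5, 0))

    @pytest.mark.parametrize(
        "v,mode,expected",
        [
            ((0, 1, 0), "conventional", 0.0),
            ((1, 0, 0), "conventional", 90.0),
            ((0, -1, 0), "conventional", 180.0),
            ((1, 1, 0), "literal", 45.0),
        ],
    )
    def test_elevation_modes(self, v, mode, expected):
        assert elevation(SpatialVector(*v), mode) == pytest.approx(expected)

    def test_magnitude_345(self):
        assert magnitude(SpatialVector(3, 4, 0)) == 5.0
        assert magnitude(SpatialVector(0, 0, 0)) == 0.0

    def test_sai_constant_beat(self):
        # |x|=|y|=|z|=1000 μV over 200 ms -> 3 * 1000 * 200 μV·ms = 600 mV·ms
        fs = 500.0
        n = 200
        ones = np.full(n, 1000.0)
        beat = _simple_beat(ones, ones, -ones, fs=fs, qrs_onset=0, qrs_offset=50, t_offset=100)
        # window [0, 100] samples = 200 ms
        assert sai_qrst(beat) == pytest.approx(600.0, rel=1e-9)

    def test_sai_dominates_area_svg_magnitude(self, rng):
        # triangle inequality: sum of |component| integrals >= |sum| integral
        for _ in range(10):
            x, y, z = rng.normal(scale=300, size=(3, 300))
            beat = _simple_beat(x, y, z)
            assert sai_qrst(beat) * 1000.0 >= magnitude(svg_area(beat)) - 1e-9

    @pytest.mark.parametrize(
        "qt,rr,expected",
        [(400, 1000, 400.0), (400, 640, 500.0), (420, 800, 469.5742753)],
    )
    def test_qtc_bazett(self, qt, rr, expected):
        assert qtc_bazett(qt, rr) == pytest.approx(expected, abs=1e-4)

    def test_qtc_invalid_rr(self):
        with pytest.raises(ValueError):
            qtc_bazett(400, 0)


class TestComputeGeh:
    def test_orthogonal_loops_give_right_angle(self):
        rec = generate_ecg12(
            EcgGenParams(qrs_peak_dir=(0, 90), t_peak_dir=(90, 90), noise_sd=0.0)
        )
        m = compute_geh(rec)
        assert m.peak_qrst_angle == pytest.approx(90.0, abs=1.0)

    def test_homogeneity_scaling(self, clean_record):
        m1 = compute_geh(clean_record)
        rec2 = Ecg12Record(
            signal=clean_record.signal * 2.0,
            fs=clean_record.fs,
            beat_labels=clean_record.beat_labels,
            r_peaks=clean_record.r_peaks,
            fiducials=clean_record.fiducials,
        )
        m2 = compute_geh(rec2)
        assert m2.peak_qrst_angle == pytest.approx(m1.peak_qrst_angle, abs=1e-6)
        assert m2.peak_svg_azimuth == pytest.approx(m1.peak_svg_azimuth, abs=1e-6)
        assert m2.peak_svg_magnitude == pytest.approx(2 * m1.peak_svg_magnitude, rel=1e-9)
        assert m2.sai_qrst == pytest.approx(2 * m1.sai_qrst, rel=1e-9)

    def test_x_polarity_flip_reflects_azimuth_keeps_angles(self, clean_record):
        m1 = compute_geh(clean_record)
        rec = generate_ecg12(
            EcgGenParams(
                qrs_peak_dir=(180 - 20.0, 60.0),
                t_peak_dir=(180 - 35.0, 45.0),
                noise_sd=0.0,
                seed=11,
            )
        )
        m2 = compute_geh(rec)
        assert m2.peak_qrst_angle == pytest.approx(m1.peak_qrst_angle, abs=0.01)
        assert m2.peak_svg_azimuth == pytest.approx(180 - m1.peak_svg_azimuth, abs=0.01)

    def test_error_names_failing_stage(self):
        sig = np.zeros((100, 12))
        rec = Ecg12Record(signal=sig, fs=500.0, beat_labels=["normal_sinus"],
                          r_peaks=np.array([50]))
        with pytest.raises(RuntimeError, match="build_median_beat"):
            compute_geh(rec)
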