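"""Similarity, time parameters, error metrics, repeatability statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ecgpaper as ep

# repeated-crop measurements of one 60 bpm sinus page (ten sessions)
TEN_QRS = [96.51, 98.70, 110.17, 113.82, 97.10, 113.59, 95.89, 110.77, 96.74, 96.51]
TEN_QT = [360.33, 368.52, 375.72, 386.75, 361.55, 387.39, 358.03, 376.41, 361.41, 360.35]


def _fiducials(n_beats=2, rr=500, qrs_on=100):
    base = np.arange(n_beats) * rr
    return ep.FiducialSet(
        p_onset=base + qrs_on - 82,
        p_offset=base + qrs_on - 39,
        qrs_onset=base + qrs_on,
        r=base + qrs_on + 20,
        qrs_offset=base + qrs_on + 44,
        t_offset=base + qrs_on + 184,
    )


class TestPearson:
    def test_identity_is_one(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert ep.pearson_r(y, y) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert ep.pearson_r(y, -y) == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        # brute-force evaluation of the covariance form on a 4-point case
        assert ep.pearson_r([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(
            0.9827076298239908, abs=1e-12
        )

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=400)
        yt = 0.8 * y + rng.normal(size=400)
        assert ep.pearson_r(y, yt) == pytest.approx(
            stats.pearsonr(y, yt).statistic, abs=1e-12
        )

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert ep.pearson_r(a, b) == pytest.approx(ep.pearson_r(b, a), abs=1e-14)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-50.0, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_invariant_under_positive_affine_transform(self, a, b, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=60)
        yt = rng.normal(size=60)
        assert ep.pearson_r(a * y + b, yt) == pytest.approx(
            ep.pearson_r(y, yt), abs=1e-9
        )

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            ep.pearson_r(np.ones(10), np.arange(10.0))


class TestTimeParameters:
    def test_rr_1000ms_is_60bpm(self):
        tp = ep.compute_time_parameters(_fiducials(rr=500), sampling_hz=500)
        assert tp.rr_ms == pytest.approx(1000.0)
        assert tp.hr_bpm == pytest.approx(60.0)

    def test_heart_rate_conversion_printed_precision(self):
        assert round(ep.heart_rate_bpm(995.40), 2) == 60.28
        assert round(ep.heart_rate_bpm(1017.85), 2) == 58.95

    def test_qrs_from_sample_indices(self):
        tp = ep.compute_time_parameters(_fiducials(qrs_on=100), sampling_hz=500)
        # QRS onset 100, offset 144 at 500 Hz -> 44 samples = 88 ms
        assert tp.qrs_ms == pytest.approx(88.0)

    def test_hr_times_rr_is_60000(self):
        for rr in (312.5, 800.0, 1000.0, 1984.0):
            assert ep.heart_rate_bpm(rr) * rr == pytest.approx(60000.0, abs=1e-9)

    def test_unordered_fiducials_rejected(self):
        with pytest.raises(ValueError):
            ep.FiducialSet(
                p_onset=[10], p_offset=[5], qrs_onset=[20],
                r=[30], qrs_offset=[40], t_offset=[50],
            )

    def test_single_beat_has_no_rr(self):
        with pytest.raises(ValueError):
            ep.compute_time_parameters(_fiducials(n_beats=1), sampling_hz=500)


class TestAbsoluteError:
    @pytest.mark.parametrize(
        "exp,true,ae",
        [(110.51, 88.0, 22.51), (375.49, 368.0, 7.49), (368.04, 368.0, 0.04)],
    )
    def test_measured_vs_true(self, exp, true, ae):
        assert ep.absolute_error(exp, true) == pytest.approx(ae)

    def test_identity_and_symmetry(self):
        assert ep.absolute_error(3.3, 3.3) == 0.0
        assert ep.absolute_error(1.0, 4.0) == ep.absolute_error(4.0, 1.0) == 3.0


class TestMsToMm:
    @pytest.mark.parametrize(
        "ms,mm", [(40.0, 1.0), (34.04, 0.85), (22.51, 0.56), (0.0, 0.0)]
    )
    def test_paper_speed_conversion(self, ms, mm):
        assert round(ep.ms_to_mm(ms), 2) == mm

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            ep.ms_to_mm(-1.0)


class TestRepeatabilityStats:
    def test_ten_session_qrs_statistics(self):
        st_ = ep.repeatability_stats({"qrs_ms": TEN_QRS, "qt_ms": TEN_QT})
        assert round(st_.mean["qrs_ms"], 2) == 102.98
        assert round(st_.sd["qrs_ms"], 2) == 7.95
        assert round(st_.range["qrs_ms"], 2) == 17.93
        # sample (n-1) convention is pinned by the QT column
        assert round(st_.sd["qt_ms"], 2) == 11.22

    def test_identical_runs_have_zero_spread(self):
        st_ = ep.repeatability_stats({"x": [5.0, 5.0, 5.0]})
        assert st_.sd["x"] == 0.0 and st_.range["x"] == 0.0

    def test_two_point_closed_form(self):
        st_ = ep.repeatability_stats({"x": [100.0, 110.0]})
        assert st_.mean["x"] == 105.0
        assert st_.sd["x"] == pytest.approx(np.sqrt(50.0))
        assert st_.range["x"] == 10.0

    def test_accepts_time_parameter_runs(self):
        runs = [
            ep.TimeParameters(qrs_ms=q, qt_ms=t, pq_ms=160, p_wave_ms=90, rr_ms=1000)
            for q, t in zip(TEN_QRS, TEN_QT)
        ]
        st_ = ep.repeatability_stats(runs)
        assert round(st_.sd["qt_ms"], 2) == 11.22
        assert st_.range["hr_bpm"] == 0.0

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            ep.repeatability_stats({"x": [1.0]})


class TestAlignAndResample:
    def test_unity_ratio_returns_overlap_unchanged(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=1000)
        lead = ep.to_physical_units(v * 10, sf=0.05)  # 2 ms step = 500 Hz
        ref = ep.ReferenceECG(leads={"II": v}, fs_hz=500.0)
        y, yt = ep.align_and_resample(lead, ref, (100, 600), (100, 600))
        assert len(y) == len(yt) == 1000
        np.testing.assert_allclose(yt, v, atol=1e-9)

    def test_four_to_one_decimation_contract(self):
        t = np.arange(2000)
        v = np.sin(2 * np.pi * t / 400)
        lead = ep.to_physical_units(v * 10, sf=0.05)
        ref = ep.ReferenceECG(leads={"II": np.zeros(500)}, fs_hz=500.0)
        y, yt = ep.align_and_resample(lead, ref, (100, 1700), (25, 425))
        # anchor gap 1600 samples resampled to exactly 400
        assert len(y) == len(yt) == 500
        coarse = np.sin(2 * np.pi * np.arange(0, 2000, 4) / 400)
        np.testing.assert_allclose(yt[30:-30], coarse[30:-30], atol=1e-3)

    def test_aligned_r_peaks_coincide(self, closed_loop):
        res = closed_loop(hr=60.0, grid_style="lines", sf_true=0.1725)
        y, yt = ep.align_and_resample(
            res.lead, res.ecg,
            (int(res.peaks.indices[0]), int(res.peaks.indices[-1])),
            (int(res.fiducials.r[0]), int(res.fiducials.r[-1])),
        )
        # both signals now live on the 500 Hz reference grid: each reference
        # R peak must coincide with a local max of the digitized signal
        for r_idx in res.fiducials.r:
            if 2 <= r_idx < len(yt) - 2:
                window = yt[r_idx - 2 : r_idx + 3]
                assert window.max() >= 0.8 * y[r_idx]

    def test_zero_anchor_gap_rejected(self):
        lead = ep.to_physical_units(np.zeros(100), sf=0.05)
        ref = ep.ReferenceECG(leads={"II": np.zeros(100)}, fs_hz=500.0)
        with pytest.raises(ValueError):
            ep.align_and_resample(lead, ref, (50, 50), (10, 60))
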