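"""QT delineation, Bazett correction, dispersion and timecourse rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtsalvage import (
    EcgSimParams,
    LeadQtMeasurement,
    bazett_qtc,
    delineate_qt,
    dispersion,
    estimate_baseline,
    generate_ecg,
    measure_lead,
    measure_recording,
    timecourse_summary,
)
from qtsalvage.ecg import detect_r_peaks
from qtsalvage.errors import (
    InsufficientSeriesError,
    InsufficientSignalError,
    InvalidParameterError,
    LeadUnmeasurableError,
    MissingLeadsError,
)


def _meas(lead, qtc):
    # helper: RR = 1 s makes QTc numerically equal to QT
    return LeadQtMeasurement(lead=lead, qt_ms=qtc, rr_s=1.0, qtc_ms=qtc, baseline_mv=0.0)


class TestBaseline:
    @pytest.mark.parametrize("level", [0.0, 0.1])
    def test_recovers_pq_level(self, level):
        rec, _ = generate_ecg(EcgSimParams(pq_level_mv=level, noise_sd_mv=0.0))
        base = estimate_baseline(rec.signals["V4"], rec.fs_hz)
        assert base.level == pytest.approx(level, abs=1e-6)

    def test_drift_interpolated_between_pq_segments(self):
        drift = 0.08  # mV/s
        rec, _ = generate_ecg(EcgSimParams(drift_mv_per_s=drift, noise_sd_mv=0.0))
        base = estimate_baseline(rec.signals["II"], rec.fs_hz)
        line = base.line()
        programmed = drift * np.arange(rec.n_samples) / rec.fs_hz
        # within the span of the PQ plateaus the line follows the drift
        lo, hi = base.pq_centers[0], base.pq_centers[-1]
        assert np.max(np.abs(line[lo:hi] - programmed[lo:hi])) < 0.01

    def test_single_beat_insufficient(self):
        rec, _ = generate_ecg(EcgSimParams(n_beats=1))
        with pytest.raises(InsufficientSignalError):
            estimate_baseline(rec.signals["V2"], rec.fs_hz)


class TestDelineation:
    def test_recovers_programmed_qt_noise_free(self, clean_ecg):
        rec, truth = clean_ecg
        tol = 1000.0 / rec.fs_hz  # one sample
        for lead in rec.signals:
            m = measure_lead(rec.signals[lead], rec.fs_hz, lead)
            assert m.qt_ms == pytest.approx(truth.leads[lead].qt_ms, abs=tol)

    def test_u_wave_read_to_nadir(self):
        rec, truth = generate_ecg(
            EcgSimParams(qt_ms=500.0, rr_s=1.0, u_amp_mv=0.05, tu_gap_ms=80.0)
        )
        x = rec.signals["V3"]
        gt = truth.leads["V3"]
        base = estimate_baseline(x, rec.fs_hz)
        peaks = detect_r_peaks(x, rec.fs_hz)
        d = delineate_qt(x, rec.fs_hz, base, r_idx=int(peaks[1]))
        assert d.u_truncated
        assert d.t_end_idx == gt.t_end_idx[1]  # the generated T-U nadir

    def test_no_u_flag_without_u_wave(self, clean_ecg):
        rec, _ = clean_ecg
        m = measure_lead(rec.signals["V5"], rec.fs_hz, "V5")
        assert not m.u_truncated

    def test_flat_line_unmeasurable(self):
        with pytest.raises((LeadUnmeasurableError, InsufficientSignalError)):
            measure_lead(np.zeros(4000), 500.0, "V2")

    def test_noise_robustness_median_error(self):
        errors = []
        for seed in range(40):
            rec, _ = generate_ecg(
                EcgSimParams(qt_ms=420.0, rr_s=1.0, noise_sd_mv=0.02, seed=seed)
            )
            m = measure_lead(rec.signals["V3"], rec.fs_hz, "V3")
            errors.append(abs(m.qt_ms - 420.0))
        assert np.median(errors) < 10.0


class TestBazett:
    @pytest.mark.parametrize(
        "qt,rr,expected", [(400.0, 1.0, 400.0), (400.0, 0.64, 500.0), (435.0, 1.0, 435.0)]
    )
    def test_worked_values(self, qt, rr, expected):
        assert bazett_qtc(qt, rr) == pytest.approx(expected)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(InvalidParameterError):
            bazett_qtc(400.0, 0.0)
        with pytest.raises(InvalidParameterError):
            bazett_qtc(400.0, -1.0)

    @settings(max_examples=50, derandomize=True)
    @given(qt=st.floats(min_value=1.0, max_value=800.0))
    def test_identity_at_rr_one(self, qt):
        assert bazett_qtc(qt, 1.0) == pytest.approx(qt)


class TestDispersion:
    def test_worked_example(self):
        ms = [
            _meas("V2", 480.0), _meas("V3", 500.0), _meas("V4", 510.0), _meas("V5", 505.0),
            _meas("II", 430.0), _meas("III", 440.0), _meas("aVF", 435.0),
        ]
        d = dispersion(ms)
        assert d.dqtc_ai_ma_ms == pytest.approx(80.0)
        assert d.dqtc_ai_me_ms == pytest.approx(498.75 - 435.0)
        assert d.max_anterior_lead == "V4"
        assert d.min_inferior_lead == "II"

    def test_all_equal_gives_zero(self):
        ms = [_meas(l, 450.0) for l in ("V2", "V3", "V4", "V5", "II", "III", "aVF")]
        d = dispersion(ms)
        assert d.dqtc_ai_ma_ms == 0.0 and d.dqtc_ai_me_ms == 0.0

    def test_single_lead_per_group_ma_equals_me(self):
        d = dispersion([_meas("V2", 470.0), _meas("III", 430.0)])
        assert d.dqtc_ai_ma_ms == d.dqtc_ai_me_ms == pytest.approx(40.0)

    def test_missing_group_rejected(self):
        with pytest.raises(MissingLeadsError):
            dispersion([_meas("V2", 470.0)])
        with pytest.raises(MissingLeadsError):
            dispersion([_meas("II", 430.0)])

    @settings(max_examples=50, derandomize=True)
    @given(
        ant=st.lists(st.floats(300, 600), min_size=1, max_size=4),
        inf=st.lists(st.floats(300, 600), min_size=1, max_size=3),
    )
    def test_ma_dominates_me_and_permutation_invariance(self, ant, inf):
        leads_a = ["V2", "V3", "V4", "V5"][: len(ant)]
        leads_i = ["II", "III", "aVF"][: len(inf)]
        ms = [_meas(l, v) for l, v in zip(leads_a, ant)]
        ms += [_meas(l, v) for l, v in zip(leads_i, inf)]
        d1 = dispersion(ms)
        assert d1.dqtc_ai_ma_ms >= d1.dqtc_ai_me_ms - 1e-9
        d2 = dispersion(list(reversed(ms)))
        assert d2.dqtc_ai_ma_ms == d1.dqtc_ai_ma_ms
        assert d2.dqtc_ai_me_ms == pytest.approx(d1.dqtc_ai_me_ms)


class TestTimecourse:
    def test_programmed_peak_on_day3(self):
        shape = {"admission": 0.0, "post_pci": 0.5, "day1": 0.8, "day2": 0.95,
                 "day3": 1.0, "day4": 0.9, "day5": 0.8, "day6": 0.6}
        qtc = {tp: 435.0 + 70.0 * s for tp, s in shape.items()}
        dsp = {tp: 40.0 + 60.0 * s for tp, s in shape.items()}
        tc = timecourse_summary(qtc, dsp)
        assert tc.peak_qtc_timepoint == "day3"
        assert tc.peak_dispersion_timepoint == "day3"
        assert tc.admission_qtc_ms == pytest.approx(435.0)

    def test_monotone_series_peaks_last(self):
        qtc = {tp: 400.0 + i for i, tp in enumerate(("admission", "day1", "day2", "day6"))}
        tc = timecourse_summary(qtc, qtc)
        assert tc.peak_qtc_timepoint == "day6"

    def test_constant_series_ties_to_earliest(self):
        qtc = {"admission": 450.0, "day2": 450.0, "day5": 450.0}
        tc = timecourse_summary(qtc, qtc)
        assert tc.peak_qtc_timepoint == "admission"

    def test_single_timepoint_rejected(self):
        with pytest.raises(InsufficientSeriesError):
            timecourse_summary({"day1": 450.0}, {"day1": 40.0})


def test_measure_recording_skips_bad_lead(clean_ecg):
    rec, _ = clean_ecg
    signals = dict(rec.signals)
    signals["II"] = np.zeros_like(signals["II"])  # technically unmeasurable
    from qtsalvage import EcgRecording

    broken = EcgRecording(rec.subject_id, rec.timepoint, signals, rec.fs_hz)
    ms, skipped = measure_recording(broken)
    assert skipped == ["II"]
    assert {m.lead for m in ms} == {"V2", "V3", "V4", "V5", "III", "aVF"}
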