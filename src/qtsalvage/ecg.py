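"""Lead-wise QT/QTc measurement and anterior-inferior dispersion.

The measurement conventions mirror manual paper-ECG reading in reperfused
anterior STEMI: the QT interval runs from QRS onset to the return of the
T wave to the isoelectric baseline, where the baseline is the line joining
consecutive PQ segments; when a U wave follows the T wave the interval is
read to the nadir between the two; rate correction uses Bazett's formula
QTc = QT / sqrt(RR).  Dispersion between injured (anterior, V2-V5) and
remote (inferior, II/III/aVF) territories is summarised as

* ``dqtc_ai_ma`` - maximum anterior QTc minus minimum inferior QTc, and
* ``dqtc_ai_me`` - mean anterior QTc minus mean inferior QTc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    InsufficientSeriesError,
    InsufficientSignalError,
    InvalidParameterError,
    LeadUnmeasurableError,
    MissingLeadsError,
)

ANTERIOR_LEADS: tuple[str, ...] = ("V2", "V3", "V4", "V5")
INFERIOR_LEADS: tuple[str, ...] = ("II", "III", "aVF")
ALL_LEADS: tuple[str, ...] = ANTERIOR_LEADS + INFERIOR_LEADS

#: Serial ECG timepoints: admission, within 1 h of reperfusion, then daily.
TIMEPOINTS: tuple[str, ...] = (
    "admission",
    "post_pci",
    "day1",
    "day2",
    "day3",
    "day4",
    "day5",
    "day6",
)

#: Noise band floor (mV): below this, departures from baseline are ignored.
BAND_FLOOR_MV = 0.02


@dataclass(frozen=True)
class EcgRecording:
    """Multi-lead voltage series for one subject at one timepoint."""

    subject_id: str
    timepoint: str
    signals: Mapping[str, np.ndarray]  # mV, keyed by lead name
    fs_hz: float

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise InvalidParameterError(
                f"timepoint {self.timepoint!r} not in {TIMEPOINTS}"
            )
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) > 1:
            raise InvalidParameterError("all leads must have the same length")
        if self.fs_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))


@dataclass(frozen=True)
class Baseline:
    """Isoelectric reference built from per-beat PQ plateaus."""

    pq_centers: np.ndarray  # sample index of each PQ plateau centre
    pq_levels: np.ndarray  # mV
    noise_sd: float  # residual SD on the PQ plateaus, mV
    n_samples: int

    @property
    def level(self) -> float:
        """Overall isoelectric level (mean of the PQ plateau levels)."""
        return float(np.mean(self.pq_levels))

    def line(self) -> np.ndarray:
        """Per-sample baseline: linear interpolation between PQ plateaus."""
        return np.interp(
            np.arange(self.n_samples), self.pq_centers, self.pq_levels
        )


@dataclass(frozen=True)
class QtDelineation:
    qt_ms: float
    qrs_onset_idx: int
    t_end_idx: int
    t_peak_idx: int
    u_truncated: bool  # True when T end was read at the T-U nadir
    baseline_mv: float


@dataclass(frozen=True)
class LeadQtMeasurement:
    lead: str
    qt_ms: float
    rr_s: float
    qtc_ms: float
    baseline_mv: float
    u_truncated: bool = False

    def __post_init__(self):
        if self.qt_ms <= 0 or self.rr_s <= 0:
            raise InvalidParameterError("QT and RR must be positive")


@dataclass(frozen=True)
class QtcDispersion:
    timepoint: str
    dqtc_ai_ma_ms: float  # max anterior QTc - min inferior QTc
    dqtc_ai_me_ms: float  # mean anterior QTc - mean inferior QTc
    max_anterior_lead: str
    min_inferior_lead: str
    anterior_leads_used: tuple[str, ...] = ()
    inferior_leads_used: tuple[str, ...] = ()


@dataclass(frozen=True)
class TimecourseSummary:
    peak_qtc_timepoint: str
    peak_qtc_ms: float
    peak_dispersion_timepoint: str
    peak_dispersion_ms: float
    admission_qtc_ms: float | None
    admission_dispersion_ms: float | None


# ---------------------------------------------------------------------------
# beat detection and baseline


def detect_r_peaks(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """R-peak sample indices; relies on the QRS dominating the amplitude."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.ptp(x) < BAND_FLOOR_MV:
        return np.array([], dtype=int)
    ref = np.median(x)
    height = ref + 0.5 * (np.max(x) - ref)
    min_dist = max(1, int(0.30 * fs_hz))  # refractory > 300 ms
    peaks, _ = find_peaks(x, height=height, distance=min_dist)
    return peaks


def estimate_baseline(x: np.ndarray, fs_hz: float) -> Baseline:
    """Locate the PQ plateau before each QRS and join them into a baseline.

    The plateau is the minimum-variance 40 ms window inside the 150-45 ms
    stretch preceding each R peak; with two or more beats the baseline is
    the (piecewise) line through the plateau levels, which tracks linear
    drift between beats.
    """
    x = np.asarray(x, dtype=float)
    peaks = detect_r_peaks(x, fs_hz)
    if len(peaks) < 2:
        raise InsufficientSignalError(
            f"need >=2 detectable beats, found {len(peaks)}"
        )
    win = max(2, int(round(0.040 * fs_hz)))
    centers, levels, resid = [], [], []
    for r in peaks:
        lo = r - int(round(0.150 * fs_hz))
        hi = r - int(round(0.045 * fs_hz))
        if lo < 0:
            continue
        seg = x[lo:hi]
        if len(seg) <= win:
            continue
        # rolling variance; ties broken toward the window closest to QRS
        sw = np.lib.stride_tricks.sliding_window_view(seg, win)
        variances = sw.var(axis=1)
        best = len(variances) - 1 - int(np.argmin(variances[::-1]))
        centers.append(lo + best + win // 2)
        levels.append(float(sw[best].mean()))
        resid.append(float(sw[best].std()))
    if len(levels) < 2:
        raise InsufficientSignalError("fewer than 2 usable PQ plateaus")
    return Baseline(
        pq_centers=np.asarray(centers),
        pq_levels=np.asarray(levels),
        noise_sd=float(np.median(resid)),
        n_samples=len(x),
    )


def _median_beat(
    x: np.ndarray, peaks: np.ndarray, fs_hz: float, rr_s: float
) -> tuple[np.ndarray, int]:
    """Sample-wise median of R-aligned beats; returns (beat, r_idx_in_beat)."""
    pre = int(round(0.30 * fs_hz))
    post = int(round((rr_s - 0.10) * fs_hz))
    segs = [
        x[r - pre : r + post]
        for r in peaks
        if r - pre >= 0 and r + post <= len(x)
    ]
    if not segs:
        raise InsufficientSignalError("no complete beat window available")
    return np.median(np.vstack(segs), axis=0), pre


def delineate_qt(
    x: np.ndarray,
    fs_hz: float,
    baseline: Baseline | float,
    r_idx: int | None = None,
    noise_sd: float | None = None,
) -> QtDelineation:
    """Measure QT on one beat: QRS onset to T-wave end on the baseline.

    QRS onset is the last sample still on the isoelectric line before the
    signal leaves the noise band ahead of the R peak.  The T end is the
    first sample after the T peak holding inside the band for 10 ms; if a
    U wave follows within 200 ms, the T end is instead the nadir between
    the T and U peaks and the measurement is flagged as U-truncated.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(baseline, Baseline):
        base = baseline.line()[: len(x)]
        if len(base) < len(x):  # beat window extends past the fitted line
            base = np.pad(base, (0, len(x) - len(base)), mode="edge")
        level = baseline.level
        if noise_sd is None:
            noise_sd = baseline.noise_sd
    else:
        base = np.full(len(x), float(baseline))
        level = float(baseline)
        if noise_sd is None:
            noise_sd = 0.0
    band = max(3.0 * noise_sd, BAND_FLOOR_MV)
    y = x - base

    if r_idx is None:
        peaks = detect_r_peaks(x, fs_hz)
        if len(peaks) == 0:
            raise LeadUnmeasurableError("no QRS detectable above noise band")
        r_idx = int(peaks[0])

    # --- QRS onset: walk back from R until inside the band for a short run
    run_n = max(2, int(round(0.006 * fs_hz)))
    onset = None
    inside = 0
    for i in range(r_idx - 1, -1, -1):
        if abs(y[i]) <= band:
            inside += 1
            if inside >= run_n:
                onset = i + run_n - 1  # last sample on baseline
                break
        else:
            inside = 0
    if onset is None:
        raise LeadUnmeasurableError("QRS onset not found on baseline")

    # --- T peak: largest excursion after the QRS complex
    t_lo = r_idx + int(round(0.080 * fs_hz))
    t_hi = min(len(x), r_idx + int(round(0.60 * fs_hz)))
    if t_hi - t_lo < 2:
        raise LeadUnmeasurableError("trace too short after QRS")
    t_peak = t_lo + int(np.argmax(np.abs(y[t_lo:t_hi])))
    if abs(y[t_peak]) <= 1.5 * band:
        raise LeadUnmeasurableError("no T wave detectable above noise band")

    # --- U wave: a second same-signed extremum after the T peak
    t_sign = np.sign(y[t_peak])
    u_lo = t_peak + int(round(0.020 * fs_hz))
    u_hi = min(len(x), t_peak + int(round(0.320 * fs_hz)))
    u_peak = None
    if u_hi - u_lo > 2:
        cand, props = find_peaks(
            t_sign * y[u_lo:u_hi], height=1.5 * band, prominence=band
        )
        if len(cand):
            u_peak = u_lo + int(cand[np.argmax(props["peak_heights"])])

    if u_peak is not None:
        nadir = t_peak + int(np.argmin(t_sign * y[t_peak:u_peak]))
        return QtDelineation(
            qt_ms=(nadir - onset) / fs_hz * 1000.0,
            qrs_onset_idx=onset,
            t_end_idx=nadir,
            t_peak_idx=t_peak,
            u_truncated=True,
            baseline_mv=level,
        )

    # --- T end: return to the baseline band sustained for 10 ms
    run_t = max(2, int(round(0.010 * fs_hz)))
    inside = 0
    t_end = None
    for i in range(t_peak, len(x)):
        if abs(y[i]) <= band:
            inside += 1
            if inside >= run_t:
                t_end = i - run_t + 1  # first sample of the in-band run
                break
        else:
            inside = 0
    if t_end is None:
        raise LeadUnmeasurableError("T wave does not return to baseline")
    return QtDelineation(
        qt_ms=(t_end - onset) / fs_hz * 1000.0,
        qrs_onset_idx=onset,
        t_end_idx=t_end,
        t_peak_idx=t_peak,
        u_truncated=False,
        baseline_mv=level,
    )


def bazett_qtc(qt_ms: float, rr_s: float) -> float:
    """Bazett's rate correction: QTc = QT / sqrt(RR), QT in ms, RR in s."""
    if qt_ms <= 0:
        raise InvalidParameterError("QT must be positive")
    if rr_s <= 0:
        raise InvalidParameterError("RR must be positive")
    return qt_ms / math.sqrt(rr_s)


def measure_lead(
    x: np.ndarray, fs_hz: float, lead: str, beat: str | int = "median"
) -> LeadQtMeasurement:
    """Full per-lead measurement: baseline, beat selection, QT, QTc.

    ``beat="median"`` delineates the sample-wise median of R-aligned beats
    (noise suppression); an integer selects that single beat, with RR taken
    from the immediately preceding interval when one exists.
    """
    x = np.asarray(x, dtype=float)
    baseline = estimate_baseline(x, fs_hz)
    peaks = detect_r_peaks(x, fs_hz)
    rr_all = np.diff(peaks) / fs_hz

    if beat == "median":
        rr = float(np.median(rr_all))
        beat_x, r_in_beat = _median_beat(x, peaks, fs_hz, rr)
        # re-estimate level and residual noise on the median beat's own PQ
        # plateau: beat averaging shrinks the raw per-sample noise
        win = max(2, int(round(0.040 * fs_hz)))
        lo = max(0, r_in_beat - int(round(0.150 * fs_hz)))
        hi = r_in_beat - int(round(0.045 * fs_hz))
        seg = beat_x[lo:hi]
        if len(seg) > win:
            sw = np.lib.stride_tricks.sliding_window_view(seg, win)
            best = len(sw) - 1 - int(np.argmin(sw.var(axis=1)[::-1]))
            level, noise = float(sw[best].mean()), float(sw[best].std())
        else:
            level, noise = float(np.median(baseline.pq_levels)), baseline.noise_sd
        delin = delineate_qt(beat_x, fs_hz, level, r_idx=r_in_beat, noise_sd=noise)
    else:
        k = int(beat)
        if k < 0 or k >= len(peaks):
            raise InvalidParameterError(f"beat index {k} out of range")
        rr = float(rr_all[k - 1]) if k > 0 else float(rr_all[0])
        delin = delineate_qt(x, fs_hz, baseline, r_idx=int(peaks[k]))

    return LeadQtMeasurement(
        lead=lead,
        qt_ms=delin.qt_ms,
        rr_s=rr,
        qtc_ms=bazett_qtc(delin.qt_ms, rr),
        baseline_mv=delin.baseline_mv,
        u_truncated=delin.u_truncated,
    )


def measure_recording(
    rec: EcgRecording, beat: str | int = "median"
) -> tuple[list[LeadQtMeasurement], list[str]]:
    """Measure every recognised lead; unmeasurable leads are excluded.

    Returns the measurements and the list of leads that were skipped
    (mirroring the exclusion of technically unmeasurable QT readings).
    Leads outside the anterior/inferior sets are ignored.
    """
    out: list[LeadQtMeasurement] = []
    skipped: list[str] = []
    for lead in ALL_LEADS:
        if lead not in rec.signals:
            continue
        try:
            out.append(measure_lead(rec.signals[lead], rec.fs_hz, lead, beat))
        except (LeadUnmeasurableError, InsufficientSignalError):
            skipped.append(lead)
    return out, skipped


def dispersion(
    measurements: Sequence[LeadQtMeasurement], timepoint: str = "admission"
) -> QtcDispersion:
    """Anterior-inferior QTc dispersion at one timepoint.

    MA = max anterior QTc - min inferior QTc; ME = difference of the group
    means.  Ties for the extreme leads resolve in fixed order V2<V3<V4<V5
    and II<III<aVF (the Delta values are unaffected).
    """
    by_lead = {m.lead: m for m in measurements}
    ant = [l for l in ANTERIOR_LEADS if l in by_lead]
    inf = [l for l in INFERIOR_LEADS if l in by_lead]
    if not ant:
        raise MissingLeadsError("no measurable anterior lead (V2-V5)")
    if not inf:
        raise MissingLeadsError("no measurable inferior lead (II, III, aVF)")
    ant_q = np.array([by_lead[l].qtc_ms for l in ant])
    inf_q = np.array([by_lead[l].qtc_ms for l in inf])
    i_max = int(np.argmax(ant_q))  # first max in fixed lead order
    i_min = int(np.argmin(inf_q))
    return QtcDispersion(
        timepoint=timepoint,
        dqtc_ai_ma_ms=float(ant_q[i_max] - inf_q[i_min]),
        dqtc_ai_me_ms=float(ant_q.mean() - inf_q.mean()),
        max_anterior_lead=ant[i_max],
        min_inferior_lead=inf[i_min],
        anterior_leads_used=tuple(ant),
        inferior_leads_used=tuple(inf),
    )


def timecourse_summary(
    qtc_by_timepoint: Mapping[str, float],
    dispersion_by_timepoint: Mapping[str, float],
) -> TimecourseSummary:
    """Peak mean QTc and peak dispersion over the serial-ECG timepoints.

    Missing timepoints are skipped, never interpolated; ties for the peak
    resolve to the earliest timepoint in chronological order.
    """
    qtc = {t: qtc_by_timepoint[t] for t in TIMEPOINTS if t in qtc_by_timepoint}
    dsp = {
        t: dispersion_by_timepoint[t]
        for t in TIMEPOINTS
        if t in dispersion_by_timepoint
    }
    if len(qtc) < 2 or len(dsp) < 1:
        raise InsufficientSeriesError("need >=2 timepoints for a timecourse")

    def _argmax(d: Mapping[str, float]) -> str:
        best = None
        for t, v in d.items():  # insertion order is chronological
            if best is None or v > d[best]:
                best = t
        return best

    pk_q = _argmax(qtc)
    pk_d = _argmax(dsp)
    return TimecourseSummary(
        peak_qtc_timepoint=pk_q,
        peak_qtc_ms=qtc[pk_q],
        peak_dispersion_timepoint=pk_d,
        peak_dispersion_ms=dsp[pk_d],
        admission_qtc_ms=qtc.get("admission"),
        admission_dispersion_ms=dsp.get("admission"),
    )
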