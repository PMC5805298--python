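"""Synthetic ECGs, CMR phantoms and cohorts with known ground truth.

Every downstream stage of the package (QT delineation, SD-threshold CMR
segmentation, association modelling) is exercised on data produced here,
so each generator returns the ground truth alongside the data:

* ``generate_ecg`` - piecewise-analytic beats (flat PQ baseline plus
  compact-support half-sine P/QRS/T/U bumps) whose T bump ends exactly at
  QRS-onset + QT, giving an exact sample-index ground truth for the
  delineator.
* ``generate_cmr_phantom`` - short-axis annulus phantoms with sector-shaped
  edema/infarct/MVO lesions at programmed signal-intensity offsets in
  remote-SD units.
* ``generate_cohort`` - per-subject salvage index, QTc-dispersion
  timecourse and covariates with a programmable (negative) dispersion-MSI
  link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ecg import ALL_LEADS, TIMEPOINTS, EcgRecording
from .errors import InvalidParameterError

# ---------------------------------------------------------------------------
# ECG

# beat layout within one RR cycle, ms from cycle start
_P_START, _P_DUR = 40.0, 80.0
_PQ_END = 170.0  # QRS onset; PQ flat segment runs from P end to here
_QRS_DUR = 80.0
_T_DUR = 160.0
_U_DUR = 120.0


@dataclass(frozen=True)
class EcgSimParams:
    """Programmable beat geometry for the analytic ECG generator.

    ``qt_ms`` may be a single value (all leads) or a per-lead mapping over
    V2-V5 and II/III/aVF.  Exactly one of ``rr_s`` / ``heart_rate_bpm``
    fixes the cycle length.
    """

    qt_ms: float | Mapping[str, float] = 400.0
    rr_s: float | None = 1.0
    heart_rate_bpm: float | None = None
    pq_level_mv: float = 0.0  # isoelectric reference level
    qrs_amp_mv: float = 1.0
    t_amp_mv: float = 0.3
    p_amp_mv: float = 0.1
    u_amp_mv: float = 0.0
    tu_gap_ms: float = 80.0  # T-end to U-peak separation
    drift_mv_per_s: float = 0.0
    noise_sd_mv: float = 0.0
    fs_hz: float = 500.0
    n_beats: int = 5
    seed: int = 0

    @property
    def rr_resolved_s(self) -> float:
        if self.heart_rate_bpm is not None:
            if self.heart_rate_bpm <= 0:
                raise InvalidParameterError("heart rate must be positive")
            return 60.0 / self.heart_rate_bpm
        if self.rr_s is None or self.rr_s <= 0:
            raise InvalidParameterError("a positive rr_s or heart_rate_bpm is required")
        return self.rr_s

    def qt_by_lead(self) -> dict[str, float]:
        if isinstance(self.qt_ms, Mapping):
            missing = [l for l in ALL_LEADS if l not in self.qt_ms]
            if missing:
                raise InvalidParameterError(f"qt_ms missing leads: {missing}")
            return {l: float(self.qt_ms[l]) for l in ALL_LEADS}
        return {l: float(self.qt_ms) for l in ALL_LEADS}

    def validate(self) -> None:
        rr_ms = self.rr_resolved_s * 1000.0
        for lead, qt in self.qt_by_lead().items():
            if qt >= rr_ms:
                raise InvalidParameterError(
                    f"QT ({qt} ms, lead {lead}) must be < RR ({rr_ms} ms)"
                )
            # the analytic layout (P wave + PQ segment + next beat) needs
            # headroom inside the cycle beyond the bare QT < RR invariant
            budget = rr_ms - 200.0
            if self.u_amp_mv > 0:
                budget = min(budget, rr_ms - 100.0 - 2.0 * self.tu_gap_ms)
            if qt > budget:
                raise InvalidParameterError(
                    f"QT {qt} ms does not fit the beat layout at RR {rr_ms} ms"
                )
            if qt < _QRS_DUR + _T_DUR:
                raise InvalidParameterError(
                    f"QT {qt} ms shorter than QRS+T support "
                    f"({_QRS_DUR + _T_DUR} ms)"
                )
        if self.fs_hz < 250:
            raise InvalidParameterError("sampling rate must be >= 250 Hz")
        if self.noise_sd_mv < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        if self.n_beats < 1:
            raise InvalidParameterError("need at least one beat")


@dataclass(frozen=True)
class LeadGroundTruth:
    """Programmed landmarks for one lead (sample indices per beat)."""

    qt_ms: float  # programmed QRS-onset -> T-bump-end interval
    qt_measurable_ms: float  # nadir-truncated when a U wave is present
    rr_s: float
    qrs_onset_idx: np.ndarray
    t_end_idx: np.ndarray  # T-U nadir index when a U wave is present
    t_peak_idx: np.ndarray
    u_peak_idx: np.ndarray | None


@dataclass(frozen=True)
class EcgGroundTruth:
    fs_hz: float
    pq_level_mv: float
    leads: dict[str, LeadGroundTruth]


def _half_sine(x: np.ndarray, s: int, e: int, amp: float) -> None:
    """Add a compact-support half-sine bump on samples (s, e), zero at both."""
    if e <= s + 1:
        return
    i = np.arange(s + 1, e)
    x[i] += amp * np.sin(math.pi * (i - s) / (e - s))


def generate_ecg(
    params: EcgSimParams,
    subject_id: str = "synthetic",
    timepoint: str = "admission",
) -> tuple[EcgRecording, EcgGroundTruth]:
    """Generate a multi-lead recording plus its delineation ground truth."""
    params.validate()
    fs = params.fs_hz
    rr_ms = params.rr_resolved_s * 1000.0
    qt = params.qt_by_lead()
    n = int(round((params.n_beats * rr_ms + 200.0) * fs / 1000.0))
    rng = np.random.default_rng(params.seed)
    t_s = np.arange(n) / fs

    def idx(ms: float) -> int:
        return int(round(ms * fs / 1000.0))

    signals: dict[str, np.ndarray] = {}
    truth: dict[str, LeadGroundTruth] = {}
    for lead in ALL_LEADS:
        x = np.full(n, params.pq_level_mv, dtype=float)
        onsets, t_ends, t_peaks, u_peaks = [], [], [], []
        for k in range(params.n_beats):
            t0 = k * rr_ms
            _half_sine(x, idx(t0 + _P_START), idx(t0 + _P_START + _P_DUR), params.p_amp_mv)
            onset = idx(t0 + _PQ_END)
            _half_sine(x, onset, idx(t0 + _PQ_END + _QRS_DUR), params.qrs_amp_mv)
            te = idx(t0 + _PQ_END + qt[lead])
            ts = idx(t0 + _PQ_END + qt[lead] - _T_DUR)
            _half_sine(x, ts, te, params.t_amp_mv)
            tp = (ts + te) // 2
            if params.u_amp_mv > 0:
                # U bump starts 20 ms before the T end and peaks tu_gap_ms
                # after it; the overlap puts a single nadir at the T end
                us = idx(t0 + _PQ_END + qt[lead] - 20.0)
                ue = idx(t0 + _PQ_END + qt[lead] + 2.0 * params.tu_gap_ms + 20.0)
                _half_sine(x, us, ue, params.u_amp_mv)
                u_peaks.append((us + ue) // 2)
            onsets.append(onset)
            t_peaks.append(tp)
            t_ends.append(te)
        # U-truncation: the measurable T end is the nadir between T and U
        if params.u_amp_mv > 0:
            nadirs = []
            for tp, up in zip(t_peaks, u_peaks):
                nadirs.append(tp + int(np.argmin(x[tp:up])))
            t_ends = nadirs
        x += params.drift_mv_per_s * t_s
        clean_t_ends = np.asarray(t_ends)
        if params.noise_sd_mv > 0:
            x = x + rng.normal(0.0, params.noise_sd_mv, n)
        signals[lead] = x
        qt_meas = float(np.mean(clean_t_ends - np.asarray(onsets))) / fs * 1000.0
        truth[lead] = LeadGroundTruth(
            qt_ms=qt[lead],
            qt_measurable_ms=qt_meas,
            rr_s=params.rr_resolved_s,
            qrs_onset_idx=np.asarray(onsets),
            t_end_idx=clean_t_ends,
            t_peak_idx=np.asarray(t_peaks),
            u_peak_idx=np.asarray(u_peaks) if u_peaks else None,
        )
    rec = EcgRecording(
        subject_id=subject_id, timepoint=timepoint, signals=signals, fs_hz=fs
    )
    return rec, EcgGroundTruth(fs_hz=fs, pq_level_mv=params.pq_level_mv, leads=truth)


# ---------------------------------------------------------------------------
# CMR phantom


@dataclass(frozen=True)
class Sector:
    """Angular sector of the myocardial ring: centre and half-width, deg."""

    center_deg: float
    halfwidth_deg: float

    def contains(self, theta_deg: np.ndarray) -> np.ndarray:
        d = (theta_deg - self.center_deg + 180.0) % 360.0 - 180.0
        return np.abs(d) <= self.halfwidth_deg

    def within(self, other: "Sector") -> bool:
        d = (self.center_deg - other.center_deg + 180.0) % 360.0 - 180.0
        return abs(d) + self.halfwidth_deg <= other.halfwidth_deg + 1e-9

    def overlaps(self, other: "Sector") -> bool:
        d = (self.center_deg - other.center_deg + 180.0) % 360.0 - 180.0
        return abs(d) < self.halfwidth_deg + other.halfwidth_deg


@dataclass(frozen=True)
class CmrPhantomParams:
    """Short-axis annulus phantom with sector lesions.

    Signal intensities are in arbitrary units; lesion offsets are expressed
    in multiples of the programmed remote SD so that lesions sit a known
    number of SDs beyond the segmentation thresholds (edema > 2, infarct
    > 5, MVO negative).  ``noise_sd`` is additive Gaussian noise on the
    myocardial voxels of both series.
    """

    shape: tuple[int, int, int] = (8, 64, 64)  # slices x rows x cols
    spacing_mm: tuple[float, float, float] = (8.0, 1.4, 2.2)
    remote_mean: float = 100.0
    remote_sd: float = 10.0
    edema_offset_sd: float = 3.0
    infarct_offset_sd: float = 7.0
    mvo_offset_sd: float = -6.0
    r_inner_mm: float = 18.0
    r_outer_mm: float = 30.0
    edema_sector: Sector | None = Sector(0.0, 60.0)
    infarct_sector: Sector | None = Sector(0.0, 35.0)
    mvo_sector: Sector | None = None
    edema_slices: tuple[int, int] = (1, 7)  # half-open [start, stop)
    infarct_slices: tuple[int, int] = (2, 6)
    mvo_slices: tuple[int, int] = (3, 5)
    mvo_radial_margin_mm: float = 3.0
    remote_sector: Sector = Sector(180.0, 30.0)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        ns, nr, nc = self.shape
        sy, sx = self.spacing_mm[1], self.spacing_mm[2]
        if min(self.shape) < 1 or min(self.spacing_mm) <= 0:
            raise InvalidParameterError("shape and spacing must be positive")
        if not (0 < self.r_inner_mm < self.r_outer_mm):
            raise InvalidParameterError("need 0 < r_inner < r_outer")
        half_extent = min(nr * sy, nc * sx) / 2.0
        if self.r_outer_mm > half_extent:
            raise InvalidParameterError(
                f"ring radius {self.r_outer_mm} mm exceeds grid half-extent "
                f"{half_extent:.1f} mm"
            )
        for name, (a, b) in (
            ("edema", self.edema_slices),
            ("infarct", self.infarct_slices),
            ("mvo", self.mvo_slices),
        ):
            if not (0 <= a <= b <= ns):
                raise InvalidParameterError(
                    f"{name} slice range {(a, b)} exceeds grid ({ns} slices)"
                )
        if self.edema_sector is not None and self.edema_offset_sd <= 2:
            raise InvalidParameterError("edema offset must exceed 2 SD")
        if self.infarct_sector is not None and self.infarct_offset_sd <= 5:
            raise InvalidParameterError("infarct offset must exceed 5 SD")
        if self.mvo_sector is not None and self.mvo_offset_sd >= 0:
            raise InvalidParameterError("MVO offset must be negative")
        if self.infarct_sector is not None:
            if self.edema_sector is None or not self.infarct_sector.within(self.edema_sector):
                raise InvalidParameterError("infarct sector must lie within edema")
            if not (
                self.edema_slices[0] <= self.infarct_slices[0]
                and self.infarct_slices[1] <= self.edema_slices[1]
            ):
                raise InvalidParameterError("infarct slices must nest in edema")
        if self.mvo_sector is not None:
            if self.infarct_sector is None or not self.mvo_sector.within(self.infarct_sector):
                raise InvalidParameterError("MVO sector must lie within infarct")
            if not (
                self.infarct_slices[0] <= self.mvo_slices[0]
                and self.mvo_slices[1] <= self.infarct_slices[1]
            ):
                raise InvalidParameterError("MVO slices must nest in infarct")
        if self.edema_sector is not None and self.remote_sector.overlaps(self.edema_sector):
            raise InvalidParameterError("remote ROI overlaps the edema sector")
        if self.noise_sd < 0 or self.remote_sd < 0:
            raise InvalidParameterError("SDs must be >= 0")


@dataclass(frozen=True)
class CmrPhantom:
    t2w: np.ndarray
    lge: np.ndarray
    myo_mask: np.ndarray
    remote_mask: np.ndarray
    truth_edema: np.ndarray  # ground-truth AAR (includes infarct)
    truth_infarct: np.ndarray  # includes the MVO core
    truth_mvo: np.ndarray
    spacing_mm: tuple[float, float, float]
    params: CmrPhantomParams

    def to_study(self, subject_id: str = "phantom"):
        from .cmr import CmrStudy

        return CmrStudy(
            subject_id=subject_id,
            t2w=self.t2w,
            lge=self.lge,
            myo_mask=self.myo_mask,
            remote_mask=self.remote_mask,
            spacing_mm=self.spacing_mm,
        )


def generate_cmr_phantom(params: CmrPhantomParams) -> CmrPhantom:
    """Build T2w/LGE volumes with ground-truth lesion masks."""
    params.validate()
    ns, nr, nc = params.shape
    _, sy, sx = params.spacing_mm
    rng = np.random.default_rng(params.seed)

    yy, xx = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    dy, dx = (yy - cy) * sy, (xx - cx) * sx
    r_mm = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx))
    ring = (r_mm >= params.r_inner_mm) & (r_mm <= params.r_outer_mm)

    def sector_mask(sector, slices, radial=None):
        m = np.zeros(params.shape, dtype=bool)
        if sector is None:
            return m
        plane = ring & sector.contains(theta)
        if radial is not None:
            plane = plane & (r_mm >= radial[0]) & (r_mm <= radial[1])
        m[slices[0] : slices[1]] = plane
        return m

    myo = np.zeros(params.shape, dtype=bool)
    myo[:] = ring
    remote = sector_mask(params.remote_sector, (0, ns))
    edema = sector_mask(params.edema_sector, params.edema_slices)
    infarct = sector_mask(params.infarct_sector, params.infarct_slices)
    mvo = sector_mask(
        params.mvo_sector,
        params.mvo_slices,
        radial=(
            params.r_inner_mm + params.mvo_radial_margin_mm,
            params.r_outer_mm - params.mvo_radial_margin_mm,
        ),
    )

    t2w = np.zeros(params.shape, dtype=float)
    t2w[myo] = params.remote_mean
    t2w[edema] += params.edema_offset_sd * params.remote_sd

    lge = np.zeros(params.shape, dtype=float)
    lge[myo] = params.remote_mean
    lge[infarct] += params.infarct_offset_sd * params.remote_sd
    lge[mvo] = params.remote_mean + params.mvo_offset_sd * params.remote_sd

    if params.noise_sd > 0:
        t2w[myo] += rng.normal(0.0, params.noise_sd, int(myo.sum()))
        lge[myo] += rng.normal(0.0, params.noise_sd, int(myo.sum()))

    return CmrPhantom(
        t2w=t2w,
        lge=lge,
        myo_mask=myo,
        remote_mask=remote,
        truth_edema=edema | infarct,
        truth_infarct=infarct,
        truth_mvo=mvo,
        spacing_mm=params.spacing_mm,
        params=params,
    )


# ---------------------------------------------------------------------------
# cohort


#: Relative shape of the mean-QTc timecourse (fraction of the peak increment
#: reached at each timepoint; peak on day 3, partial recovery by day 6).
QTC_TIMECOURSE_SHAPE: dict[str, float] = {
    "admission": 0.0,
    "post_pci": 0.45,
    "day1": 0.75,
    "day2": 0.93,
    "day3": 1.0,
    "day4": 0.90,
    "day5": 0.78,
    "day6": 0.62,
}

#: Dispersion timecourse weights relative to day 6 (= 1.0), peaking day 3.
DISPERSION_TIMECOURSE_WEIGHTS: dict[str, float] = {
    "admission": 0.30,
    "post_pci": 0.50,
    "day1": 0.80,
    "day2": 1.10,
    "day3": 1.30,
    "day4": 1.20,
    "day5": 1.10,
    "day6": 1.00,
}


@dataclass(frozen=True)
class LogLgeModel:
    """Direct linear generator for ln(LGE): used for recovery simulations."""

    intercept: float = 1.7
    slope_dqtc: float = 0.010  # per ms of day-6 dispersion
    slope_troponin: float = 0.004  # per ng/mL peak troponin I
    noise_sd: float = 0.5


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort of reperfused anterior-STEMI subjects with known links.

    The salvage index is truncated-normal on [0, 1]; day-6 dispersion is
    linear in MSI with a negative default slope (poor salvage -> larger
    anterior-inferior dispersion); the other timepoints follow a peaked
    (day-3) timecourse.  When ``loglge_model`` is given, ln(LGE) is drawn
    from that linear model instead of the AAR x (1 - MSI) identity.
    """

    n: int = 50
    msi_mean: float = 0.45
    msi_sd: float = 0.32
    dqtc_intercept_ms: float = 120.0
    dqtc_slope_ms: float = -90.0  # per unit MSI; negative = study direction
    dqtc_noise_sd_ms: float = 25.0
    dispersion_tp_noise_sd_ms: float = 8.0
    qtc_admission_mean_ms: float = 435.0
    qtc_admission_sd_ms: float = 39.0
    qtc_peak_increment_ms: float = 70.0
    qtc_tp_noise_sd_ms: float = 10.0
    troponin_log_mean: float = math.log(50.0)
    troponin_log_sd: float = 1.0
    lvef_mean: float = 49.0
    lvef_sd: float = 8.0
    age_mean: float = 59.0
    age_sd: float = 10.0
    male_frac: float = 0.88
    awm_mean: float = 7.0
    awm_sd: float = 3.0
    aar_log_mean: float = math.log(40.0)
    aar_log_sd: float = 0.5
    lv_mass_mean: float = 150.0
    lv_mass_sd: float = 25.0
    mvo_frac: float = 0.72
    loglge_model: LogLgeModel | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("cohort needs n >= 2 subjects")
        if self.msi_sd <= 0 or self.dqtc_noise_sd_ms < 0:
            raise InvalidParameterError("SDs must be positive")
        if not 0 <= self.male_frac <= 1 or not 0 <= self.mvo_frac <= 1:
            raise InvalidParameterError("fractions must be in [0, 1]")


def generate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, dict]:
    """One row per subject; returns (table, ground-truth parameters)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    a = (0.0 - params.msi_mean) / params.msi_sd
    b = (1.0 - params.msi_mean) / params.msi_sd
    msi = truncnorm.rvs(
        a, b, loc=params.msi_mean, scale=params.msi_sd, size=n, random_state=rng
    )

    dqtc6 = (
        params.dqtc_intercept_ms
        + params.dqtc_slope_ms * msi
        + rng.normal(0.0, params.dqtc_noise_sd_ms, n)
    )

    troponin = np.exp(rng.normal(params.troponin_log_mean, params.troponin_log_sd, n))
    lvef = rng.normal(params.lvef_mean, params.lvef_sd, n)
    age = rng.normal(params.age_mean, params.age_sd, n)
    male = (rng.random(n) < params.male_frac).astype(int)
    awm = np.clip(np.round(rng.normal(params.awm_mean, params.awm_sd, n)), 0, 17)
    lv_mass = np.clip(rng.normal(params.lv_mass_mean, params.lv_mass_sd, n), 60, None)
    mvo_present = (rng.random(n) < params.mvo_frac).astype(int)

    # dispersion and mean-QTc timecourses (generated before LGE so that a
    # direct ln-LGE model can condition on the observed day-6 column)
    qtc_base = rng.normal(params.qtc_admission_mean_ms, params.qtc_admission_sd_ms, n)
    qtc_cols: dict[str, np.ndarray] = {}
    ma_cols: dict[str, np.ndarray] = {}
    me_cols: dict[str, np.ndarray] = {}
    for tp in TIMEPOINTS:
        qtc_cols[tp] = (
            qtc_base
            + params.qtc_peak_increment_ms * QTC_TIMECOURSE_SHAPE[tp]
            + rng.normal(0.0, params.qtc_tp_noise_sd_ms, n)
        )
        ma = dqtc6 * DISPERSION_TIMECOURSE_WEIGHTS[tp] + rng.normal(
            0.0, params.dispersion_tp_noise_sd_ms, n
        )
        ma_cols[tp] = ma
        me_cols[tp] = ma - np.abs(rng.normal(12.0, 4.0, n))

    if params.loglge_model is None:
        aar = np.minimum(
            np.exp(rng.normal(params.aar_log_mean, params.aar_log_sd, n)),
            0.70 * lv_mass,
        )
        lge = aar * (1.0 - msi)  # the salvage-index identity
    else:
        m = params.loglge_model
        lge = np.exp(
            m.intercept
            + m.slope_dqtc * ma_cols["day6"]
            + m.slope_troponin * troponin
            + rng.normal(0.0, m.noise_sd, n)
        )
        aar = lge / np.clip(1.0 - msi, 0.05, 1.0)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "age": np.round(age, 1),
            "male": male,
            "peak_troponin_ng_ml": troponin,
            "lvef_pct": lvef,
            "awm_segments": awm.astype(int),
            "lv_mass_g": lv_mass,
            "aar_g": aar,
            "lge_g": lge,
            "lge_pct_lv": 100.0 * lge / lv_mass,
            "msi": msi,
            "mvo_present": mvo_present,
        }
    )

    for tp in TIMEPOINTS:
        df[f"qtc_mean_{tp}"] = qtc_cols[tp]
        df[f"dqtc_ai_ma_{tp}"] = ma_cols[tp]
        df[f"dqtc_ai_me_{tp}"] = me_cols[tp]

    truth = {
        "dqtc_intercept_ms": params.dqtc_intercept_ms,
        "dqtc_slope_ms": params.dqtc_slope_ms,
        "peak_timepoint": "day3",
        "msi_mean": params.msi_mean,
        "msi_sd": params.msi_sd,
        "loglge_model": None
        if params.loglge_model is None
        else vars(params.loglge_model).copy(),
    }
    return df, truth
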