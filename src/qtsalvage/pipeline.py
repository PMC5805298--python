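"""End-to-end orchestration: exclusion filter, ECG and CMR measurement on
synthetic subjects, cohort merge and the association suite.

``run_pipeline`` reproduces the full study flow on generated data: a
roster passes the exclusion filter; each included subject gets serial
multi-lead ECGs (measured lead by lead into QTc dispersions) and a CMR
phantom (segmented into AAR/infarct/MVO and a salvage index); the merged
table feeds the correlation, regression and ROC analyses.  All randomness
fans out from a single seed, and the results bundle is byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cmr import quantify_study
from .ecg import (
    ANTERIOR_LEADS,
    INFERIOR_LEADS,
    TIMEPOINTS,
    dispersion,
    measure_recording,
    timecourse_summary,
)
from .errors import InvalidParameterError, QtSalvageError
from .io import write_json
from .simulate import (
    CmrPhantomParams,
    CohortSimParams,
    EcgSimParams,
    Sector,
    generate_cmr_phantom,
    generate_cohort,
    generate_ecg,
)
from .stats import (
    cohen_kappa,
    fit_linear_log_lge,
    fit_logistic_msi,
    paired_qtc_test,
    roc_youden,
    spearman,
    univariate_screen,
)

logger = logging.getLogger(__name__)

#: Exclusion criteria in their canonical a)-k) order.  When a subject
#: carries several flags, per-criterion counts attribute the subject to the
#: first matching criterion in this order.
EXCLUSION_CRITERIA: tuple[tuple[str, str], ...] = (
    ("previous_mi", "previous myocardial infarction"),
    ("af_or_antiarrhythmics", "atrial fibrillation or antiarrhythmic drugs"),
    ("catecholamines", "catecholamine administration"),
    ("late_pci", "PCI performed more than 12 h after chest-pain onset"),
    ("bundle_branch_block", "bundle branch block"),
    ("incomplete_reperfusion", "incomplete reperfusion"),
    ("electrolyte_imbalance", "electrolyte imbalance"),
    ("conduction_disorder", "conduction disorder (AV block or pre-excitation)"),
    ("qt_unmeasurable", "technical difficulties in QT measurement"),
    ("pericardial_effusion", "pericardial effusion"),
    ("competing_trial", "enrolment in a competing interventional trial"),
)

EXCLUSION_KEYS: tuple[str, ...] = tuple(k for k, _ in EXCLUSION_CRITERIA)


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Drop subjects with any exclusion flag set; count per criterion.

    Missing flag columns are treated as all-False.  Returns the included
    subjects and a per-criterion count series (first-match attribution).
    """
    if len(roster) == 0:
        raise InvalidParameterError("roster is empty")
    flags = pd.DataFrame(index=roster.index)
    for key in EXCLUSION_KEYS:
        flags[key] = (
            roster[key].fillna(False).astype(bool)
            if key in roster.columns
            else False
        )
    any_flag = flags.any(axis=1)
    counts = pd.Series(0, index=list(EXCLUSION_KEYS), dtype=int)
    remaining = any_flag.copy()
    for key in EXCLUSION_KEYS:
        hit = remaining & flags[key]
        counts[key] = int(hit.sum())
        remaining &= ~flags[key]
    included = roster[~any_flag].copy()
    logger.info(
        "exclusion filter: %d of %d excluded, %d included",
        int(any_flag.sum()),
        len(roster),
        len(included),
    )
    return included, counts


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full synthetic end-to-end run."""

    n_subjects: int = 30
    msi_cut: float = 0.6
    screen_alpha: float = 0.1
    density_g_per_ml: float = 1.05
    exclusion_prob: float = 0.02  # per-criterion flag probability
    ecg_noise_sd_mv: float = 0.01
    ecg_fs_hz: float = 500.0
    ecg_n_beats: int = 4
    phantom_shape: tuple[int, int, int] = (6, 48, 48)
    phantom_noise_rel_sd: float = 0.3  # noise as a fraction of remote SD
    dqtc_slope_ms: float = -90.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.msi_cut < 1:
            raise InvalidParameterError("msi_cut must be in (0, 1)")
        if not 0 < self.screen_alpha < 1:
            raise InvalidParameterError("screen_alpha must be in (0, 1)")
        if self.n_subjects < 8:
            raise InvalidParameterError("need at least 8 subjects end-to-end")


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    measured: pd.DataFrame
    exclusion_counts: pd.Series
    n_input: int
    n_excluded: int
    n_dropped: int
    n_analyzed: int
    summary: dict
    linear_model: pd.DataFrame | None
    logistic_model: pd.DataFrame | None
    roc: pd.DataFrame | None
    dropped_reasons: dict[str, str]


# ------------------------------------------------------------- ECG stage


def _lead_qtc_targets(qtc_inferior: float, dqtc_ma: float) -> dict[str, float]:
    """Per-lead QTc targets realising a programmed max-anterior minus
    min-inferior dispersion (II carries the inferior minimum, V3 the
    anterior maximum)."""
    top = qtc_inferior + dqtc_ma
    return {
        "V2": top - 8.0,
        "V3": top,
        "V4": top - 14.0,
        "V5": top - 20.0,
        "II": qtc_inferior,
        "III": qtc_inferior + 6.0,
        "aVF": qtc_inferior + 10.0,
    }


def _measure_subject_ecgs(
    row: pd.Series, config: RunConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Generate and measure serial ECGs for one subject.

    The per-lead QT values are derived from the subject's programmed QTc
    timecourse at RR = 1 s (QT = QTc under Bazett), then re-measured from
    the waveforms.
    """
    out: dict[str, float] = {}
    for tp in TIMEPOINTS:
        qtc_inf = float(row[f"qtc_mean_{tp}"]) - 25.0
        targets = _lead_qtc_targets(qtc_inf, float(row[f"dqtc_ai_ma_{tp}"]))
        qt_ms = {l: float(np.clip(v, 260.0, 780.0)) for l, v in targets.items()}
        params = EcgSimParams(
            qt_ms=qt_ms,
            rr_s=1.0,
            noise_sd_mv=config.ecg_noise_sd_mv,
            fs_hz=config.ecg_fs_hz,
            n_beats=config.ecg_n_beats,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, _ = generate_ecg(params, subject_id=str(row["subject_id"]), timepoint=tp)
        measurements, skipped = measure_recording(rec)
        if skipped:
            logger.info("subject %s %s: skipped leads %s", row["subject_id"], tp, skipped)
        disp = dispersion(measurements, timepoint=tp)
        out[f"meas_dqtc_ai_ma_{tp}"] = disp.dqtc_ai_ma_ms
        out[f"meas_dqtc_ai_me_{tp}"] = disp.dqtc_ai_me_ms
        out[f"meas_qtc_mean_{tp}"] = float(
            np.mean([m.qtc_ms for m in measurements])
        )
    return out


# ------------------------------------------------------------- CMR stage


def _subject_phantom_params(
    row: pd.Series, config: RunConfig, seed: int
) -> CmrPhantomParams:
    """Size the phantom's lesion sectors from the subject's programmed
    masses so the segmented %LV (and hence MSI) recovers the cohort value."""
    lv = float(row["lv_mass_g"])
    aar_frac = float(np.clip(row["aar_g"] / lv, 0.04, 0.75))
    lge_frac = float(np.clip(row["lge_g"] / lv, 0.0, aar_frac))
    ns = config.phantom_shape[0]
    edema_hw = aar_frac * 180.0
    lge_hw = lge_frac * 180.0
    infarct = Sector(0.0, lge_hw) if lge_hw >= 2.0 else None
    mvo = None
    mvo_slices = (1, max(2, ns - 1))
    if infarct is not None and bool(row.get("mvo_present", 0)) and lge_hw >= 12.0:
        mvo = Sector(0.0, min(8.0, lge_hw - 4.0))
    remote_sd = 10.0
    return CmrPhantomParams(
        shape=config.phantom_shape,
        spacing_mm=(8.0, 1.4, 2.2),
        remote_mean=100.0,
        remote_sd=remote_sd,
        r_inner_mm=14.0,
        r_outer_mm=26.0,
        edema_sector=Sector(0.0, edema_hw),
        infarct_sector=infarct,
        mvo_sector=mvo,
        edema_slices=(0, ns),
        infarct_slices=(0, ns),
        mvo_slices=mvo_slices if mvo is not None else (0, ns),
        remote_sector=Sector(180.0, 20.0),
        noise_sd=config.phantom_noise_rel_sd * remote_sd,
        seed=seed,
    )


# ----------------------------------------------------------- association


def _association_suite(df: pd.DataFrame, config: RunConfig):
    """Run the statistical chain on the merged measured table."""
    out: dict = {}
    tc = timecourse_summary(
        {tp: float(df[f"meas_qtc_mean_{tp}"].mean()) for tp in TIMEPOINTS},
        {tp: float(df[f"meas_dqtc_ai_ma_{tp}"].mean()) for tp in TIMEPOINTS},
    )
    out["timecourse"] = {
        "peak_qtc_timepoint": tc.peak_qtc_timepoint,
        "peak_qtc_ms": tc.peak_qtc_ms,
        "admission_qtc_ms": tc.admission_qtc_ms,
        "peak_dispersion_timepoint": tc.peak_dispersion_timepoint,
        "peak_dispersion_ms": tc.peak_dispersion_ms,
    }
    peak_tp = tc.peak_qtc_timepoint
    paired = paired_qtc_test(
        df["meas_qtc_mean_admission"], df[f"meas_qtc_mean_{peak_tp}"]
    )
    out["paired_admission_vs_peak"] = {
        "t": paired.t,
        "p": paired.p,
        "mean_diff_ms": paired.mean_diff,
        "n": paired.n,
    }

    dq = "meas_dqtc_ai_ma_day6"
    for target in ("meas_lge_g", "meas_lge_pct", "meas_msi"):
        r, p = spearman(df[dq], df[target])
        out[f"spearman_{target}"] = {"r": r, "p": p}

    candidates = [dq, "peak_troponin_ng_ml", "lvef_pct", "age", "awm_segments"]
    lin_df = df[df["meas_lge_g"] > 0].copy()
    lin_df["log_lge"] = np.log(lin_df["meas_lge_g"])
    lin_screen = univariate_screen(
        lin_df, "log_lge", candidates, alpha=config.screen_alpha, model="linear"
    )
    out["screen_linear_selected"] = list(lin_screen.selected)
    linear = (
        fit_linear_log_lge(df, list(lin_screen.selected), lge_col="meas_lge_g")
        if lin_screen.selected
        else None
    )

    log_df = df.copy()
    log_df["poor_salvage"] = (log_df["meas_msi"] < config.msi_cut).astype(int)
    logistic = None
    roc = None
    if log_df["poor_salvage"].nunique() == 2:
        log_screen = univariate_screen(
            log_df,
            "poor_salvage",
            candidates,
            alpha=config.screen_alpha,
            model="logistic",
        )
        out["screen_logistic_selected"] = list(log_screen.selected)
        if log_screen.selected:
            try:
                logistic = fit_logistic_msi(
                    df,
                    list(log_screen.selected),
                    msi_cut=config.msi_cut,
                    msi_col="meas_msi",
                )
            except QtSalvageError as exc:
                out["logistic_error"] = str(exc)
        roc = roc_youden(df[dq], log_df["poor_salvage"])
        out["roc"] = {
            "auc": roc.auc,
            "cutoff_ms": roc.cutoff,
            "sensitivity": roc.sensitivity_at_cutoff,
            "specificity": roc.specificity_at_cutoff,
        }
        # agreement between programmed and re-measured salvage dichotomy
        out["kappa_msi_dichotomy"] = cohen_kappa(
            (df["msi"] < config.msi_cut).astype(int), log_df["poor_salvage"]
        )
    return out, linear, logistic, roc


# ------------------------------------------------------------------- run


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Synthetic end-to-end run; optionally writes the results bundle."""
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31 - 1)
    cohort_params = CohortSimParams(
        n=config.n_subjects, dqtc_slope_ms=config.dqtc_slope_ms, seed=int(seeds[0])
    )
    cohort, truth = generate_cohort(cohort_params)

    # roster with sparse exclusion flags
    flag_rng = np.random.default_rng(int(seeds[1]))
    roster = cohort.copy()
    for key in EXCLUSION_KEYS:
        roster[key] = flag_rng.random(len(roster)) < config.exclusion_prob
    included, excl_counts = apply_exclusions(roster)
    n_input = len(roster)
    n_excluded = n_input - len(included)

    ecg_rng = np.random.default_rng(int(seeds[2]))
    cmr_rng = np.random.default_rng(int(seeds[3]))
    rows = []
    dropped: dict[str, str] = {}
    for _, row in included.iterrows():
        sid = str(row["subject_id"])
        try:
            meas = _measure_subject_ecgs(row, config, ecg_rng)
            phantom = generate_cmr_phantom(
                _subject_phantom_params(row, config, int(cmr_rng.integers(0, 2**31 - 1)))
            )
            quant = quantify_study(
                phantom.to_study(sid), density_g_per_ml=config.density_g_per_ml
            )
            if not np.isfinite(quant.msi):
                raise QtSalvageError("no detectable area at risk")
            lv = float(row["lv_mass_g"])
            meas.update(
                {
                    "meas_aar_g": quant.aar_pct_lv / 100.0 * lv,
                    "meas_lge_g": quant.infarct_pct_lv / 100.0 * lv,
                    "meas_lge_pct": quant.infarct_pct_lv,
                    "meas_msi": quant.msi,
                    "meas_mvo_present": int(quant.mvo_present),
                }
            )
            rows.append({**row.to_dict(), **meas})
        except QtSalvageError as exc:
            dropped[sid] = str(exc)
            logger.warning("subject %s dropped: %s", sid, exc)
    measured = pd.DataFrame(rows)
    n_analyzed = len(measured)
    if n_analyzed < 8:
        raise QtSalvageError(f"only {n_analyzed} analyzable subjects")

    assoc, linear, logistic, roc = _association_suite(measured, config)
    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_input": n_input,
        "n_excluded": n_excluded,
        "n_dropped": len(dropped),
        "n_analyzed": n_analyzed,
        "exclusion_counts": excl_counts.to_dict(),
        "dropped_reasons": dropped,
        "ground_truth": truth,
        "association": assoc,
    }

    result = PipelineResult(
        cohort=cohort,
        measured=measured,
        exclusion_counts=excl_counts,
        n_input=n_input,
        n_excluded=n_excluded,
        n_dropped=len(dropped),
        n_analyzed=n_analyzed,
        summary=summary,
        linear_model=linear.to_frame() if linear is not None else None,
        logistic_model=logistic.to_frame() if logistic is not None else None,
        roc=pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        )
        if roc is not None
        else None,
        dropped_reasons=dropped,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.6f"
    result.cohort.to_csv(outdir / "cohort.csv", index=False, float_format=ff)
    result.measured.to_csv(outdir / "measured.csv", index=False, float_format=ff)
    result.exclusion_counts.rename("n_excluded").to_csv(
        outdir / "exclusion_counts.csv", index_label="criterion"
    )
    if result.linear_model is not None:
        result.linear_model.to_csv(
            outdir / "table_linear_loglge.csv", index=False, float_format=ff
        )
    if result.logistic_model is not None:
        result.logistic_model.to_csv(
            outdir / "table_logistic_msi.csv", index=False, float_format=ff
        )
    if result.roc is not None:
        result.roc.to_csv(outdir / "roc_coordinates.csv", index=False, float_format=ff)
    write_json(result.summary, outdir / "summary.json")
    manifest = {
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "package_version": __version__,
        "seed": result.summary["seed"],
    }
    write_json(manifest, outdir / "manifest.json")
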