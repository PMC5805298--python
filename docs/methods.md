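# Methods

This note documents what the package computes, the conventions it fixes
where manual clinical practice leaves them open, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## 1. ECG measurement

**Model of the measurement.**  QT is read per lead from QRS onset to the
end of the T wave on the isoelectric baseline; the baseline is the line
joining consecutive PQ segments.  When a U wave follows the T wave, the
interval is read to the nadir of the curve between the T and U peaks and
the measurement is flagged (`u_truncated`).  Rate correction is Bazett's,
QTc = QT/√RR with RR in seconds.  Dispersion between injured and remote
territory is summarised at each timepoint as ΔQTc-AI-MA (max anterior −
min inferior QTc) and ΔQTc-AI-ME (difference of group means) over the
anterior leads V2–V5 and inferior leads II, III, aVF.  Eight serial
timepoints are recognised: admission, within 1 h post-PCI, and days 1–6.

**Conventions fixed by this package** (manual reading specifies none of
these precisely):

* *Baseline*: the PQ plateau is the minimum-variance 40 ms window inside
  the 150–45 ms stretch before each R peak; the per-sample baseline
  linearly interpolates the plateau levels, so linear drift between beats
  is followed exactly.
* *Noise band*: departures from baseline count only beyond
  max(3 × PQ-residual SD, 0.02 mV).  The 0.02 mV floor is one fifth of a
  small-division on standard 10 mm/mV paper — below manual resolution.
* *QRS onset*: the last sample still inside the band before the sustained
  pre-R departure.  *T end*: the first sample after the T peak that stays
  inside the band for 10 ms.  *U wave*: a second same-signed extremum
  above 1.5 × band within ~320 ms of the T peak; if present, T end
  becomes the T–U nadir.
* *Beat selection*: with several beats the sample-wise median of
  R-aligned beats is delineated (suppresses noise by ≈√n); its PQ level
  and residual SD are re-estimated on the median beat itself.  RR is the
  median R–R interval (for a single selected beat, the immediately
  preceding interval).
* *Ties* for the extreme lead resolve in fixed order V2<V3<V4<V5 and
  II<III<aVF; only the reported lead label is affected, never the Δ.
* *Missing leads*: group statistics use the measurable leads; the leads
  used are recorded.  A lead with no T wave above the band raises a
  lead-unmeasurable error and is excluded, mirroring the clinical
  exclusion for technically unmeasurable QT.
* *Timecourse*: peaks are arg-max over available timepoints; missing
  timepoints are skipped, never interpolated; ties go to the earliest
  timepoint.

## 2. The ECG generator

Beats are piecewise-analytic: a flat segment at the programmed PQ level
with compact-support half-sine bumps for P, QRS, T and (optionally) U.
Compact support — rather than Gaussian bumps — is deliberate: the T bump
ends *exactly* at QRS-onset + QT, so the programmed QT is an exact
sample-index ground truth and delineation accuracy can be asserted to ±1
sample.  The U bump starts 20 ms before the T end and peaks `tu_gap_ms`
after it; the superposition then has exactly one local minimum, at the T
end, which the generator reports as the nadir ground truth for the
U-truncation rule.  Within each cycle: P wave at 40–120 ms, PQ segment to
170 ms, QRS of 80 ms, T of 160 ms ending at onset + QT.  Because the
layout must fit in the cycle, the generator enforces QT ≤ RR − 200 ms
(stricter with a U wave) in addition to QT < RR; combinations outside
this are unphysiological beats, not measurable signals.  Defaults:
500 Hz sampling (paper ECGs at 25 mm/s have no standard digitisation
rate; 500 Hz makes one sample = 2 ms, comfortably below manual reading
precision), QRS 1.0 mV, T 0.3 mV, additive white Gaussian noise.

The generator does **not** emulate morphology variation, arrhythmia,
baseline wander beyond linear drift, or lead-field physics; passing tests
demonstrate that the delineation rules are implemented correctly, not
that they are robust to every real-world artefact.

## 3. CMR quantification

Signal-intensity thresholds against a contralateral remote ROI: edema
(area at risk) is myocardium with SI strictly greater than remote mean
+ 2 SD on T2w; infarct is SI strictly greater than mean + 5 SD on LGE.
SD is the sample SD (ddof = 1).  Strict inequality means boundary voxels
equal to the threshold are excluded.  MVO is defined here as 4-connected
in-slice regions of myocardium with SI ≤ remote mean whose every in-slice
neighbour is infarct; "hypo-enhanced" has no numeric definition in
clinical reports, so the ≤-remote-mean rule is this package's choice, as
is in-slice connectivity (slices are 8 mm thick against ~1.4–2.2 mm
in-plane).  MVO voxels count toward infarct mass (common convention; the
MVO mass is also reported separately so the opposite convention is
recoverable).  Masses are voxel-count × voxel volume × 1.05 g/mL
(standard myocardial density).  MSI = (AAR − infarct)/AAR, clipped to
[0, 1] with a warning when noise pushes infarct above AAR; zero AAR makes
MSI undefined and raises.

**Phantom.**  A circular annulus (inner/outer radius in mm, so the
anisotropic in-plane spacing is honoured) per slice; lesions are angular
sectors with nesting enforced at parameter level (infarct ⊆ edema,
MVO ⊆ infarct, with a radial margin so MVO cores stay strictly inside
infarct); the remote ROI is a sector on the opposite wall.  Lesion SI
offsets are expressed in units of the programmed remote SD and validated
to lie beyond their thresholds (edema > 2, infarct > 5), so noise-free
phantoms are recoverable voxel-exactly by construction — the recovery
tests then verify the segmentation code, not the phantom.  Additive
Gaussian noise (both series, myocardium only) drives the stochastic Dice
checks.  The phantom does not emulate partial-volume effects, surface-coil
intensity gradients, motion, or realistic lesion shapes.

## 4. Cohort generator and association analysis

Per subject: MSI from a truncated normal on [0, 1] (defaults 0.45 ± 0.32,
which yields both salvage classes around the 0.6 cut); day-6 dispersion
linear in MSI (default slope −90 ms per unit MSI, noise SD 25 ms — the
negative slope is the study direction: poor salvage, higher dispersion);
dispersion at the other timepoints follows a weighted timecourse peaking
on day 3; mean QTc follows a rise from 435 ± 39 ms at admission by +70 ms
to the day-3 peak with partial recovery by day 6.  Covariates: log-normal
peak troponin I (median 50 ng/mL), LVEF 49 ± 8%, age 59 ± 10, 88% male,
wall-motion count, LV mass.  By default LGE = AAR × (1 − MSI) (the
salvage identity), with log-normal AAR; for parameter-recovery studies an
explicit linear model for ln(LGE) on the *observed* day-6 dispersion and
troponin can be requested instead (`LogLgeModel`), so the fitted model is
exactly the generating one and 2-SE coverage is nominal.

**Statistics.**  Paired two-sided t-tests for serial QTc change (all-zero
differences return t = 0, p = 1; a constant non-zero shift has an
undefined statistic and raises).  Spearman with mid-rank ties.  The
univariate screen fits each candidate alone (OLS on ln LGE, or logistic
on the salvage dichotomy) and keeps p < 0.1.  The multivariable linear
model uses natural log of LGE (base only rescales coefficients);
zero-LGE subjects are excluded from it — the log is undefined — but
retained in the logistic/ROC analyses.  The logistic model reports Wald
odds ratios with delta-method SEs for the event MSI < cut (cut default
0.6; the coding is stated in the output and can be flipped).  Collinear
designs raise a rank-deficiency error naming the offending columns;
separation raises rather than returning unstable estimates.  The ROC is
empirical over observed thresholds (positive call: score ≥ threshold);
AUC is trapezoidal, identical to the rescaled Mann–Whitney U; the Youden
cut-off maximises sens + spec − 1 with ties broken toward higher
specificity, then the higher threshold.  Cohen's kappa uses
marginal-product chance agreement and is undefined (raises) when both
raters use a single shared category.  p-values are two-sided throughout;
no multiplicity correction is applied.

## 5. Pipeline

Exclusion flags follow the canonical a)–k) list (previous MI, AF or
antiarrhythmics, catecholamines, PCI > 12 h, bundle-branch block,
incomplete reperfusion, electrolyte imbalance, conduction disorder —
AV block and pre-excitation grouped as one criterion, QT technically
unmeasurable, pericardial effusion, competing-trial enrolment); any flag
excludes, and per-criterion counts attribute multi-flagged subjects to
the first matching criterion in that order so counts are well defined.
Subject accounting always satisfies
n(input) = n(excluded) + n(dropped with reason) + n(analyzed).

The synthetic end-to-end run sizes each subject's phantom lesion sectors
from the programmed AAR/LGE fractions of LV mass (so measured %LV and
MSI recover the programmed values up to voxelisation) and derives
per-lead QT targets from the programmed QTc timecourse at RR = 1 s.  All
randomness fans out from one seed; output files contain no timestamps,
so a results bundle is byte-identical across runs.  Default problem
sizes — 30 subjects, 6×48×48 phantoms, 4-beat recordings at 500 Hz —
keep a full run in seconds while leaving every stage non-trivial.

## 6. Known limitations

* The delineator is tuned to single-morphology beats; biphasic T waves,
  atrial fibrillation and bundle-branch block are out of scope (such
  subjects are excluded upstream by design).
* The T-end band rule carries a small systematic early bias (≈1 sample
  noise-free, a few ms under noise) inherent to any finite noise band.
* Threshold segmentation replaces the manual contouring step of clinical
  workflows; no contour editing is modelled.
* The cohort generator encodes marginal distributions and one structural
  link (dispersion–MSI); it does not model confounding between
  covariates, so multivariable selection behaviour on real data may
  differ.
* Real-cohort regression coefficients, AUC and cut-offs are not
  reproducible from this package: no patient-level data are deposited.
  The tests substitute ground-truth recovery and oracle equivalence on
  synthetic data.
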