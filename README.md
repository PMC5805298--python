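# qtsalvage

Serial-ECG QTc dispersion versus CMR-derived myocardial salvage in
reperfused anterior STEMI — simulation, measurement and association
analysis in one tested Python package.

## The problem

After primary PCI for an anterior ST-elevation myocardial infarction, how
much of the jeopardised myocardium was actually saved?  Cardiac magnetic
resonance answers this with the **myocardial salvage index**

```
MSI = (AAR − infarct) / AAR
```

where the area at risk (AAR) is edema on T2-weighted imaging and the
infarct is late gadolinium enhancement (LGE); MSI = 1 is complete salvage,
MSI = 0 means the whole at-risk area infarcted.  CMR is not always
available, so a bedside surrogate is attractive: injured (anterior) and
remote (inferior) myocardium repolarise differently, and the
anterior–inferior **QTc dispersion** on serial 12-lead ECGs

```
ΔQTc-AI-MA = max QTc(V2…V5) − min QTc(II, III, aVF)
ΔQTc-AI-ME = mean QTc(V2…V5) − mean QTc(II, III, aVF)
```

with Bazett's correction QTc = QT/√RR, tracks the extent of irreversible
injury: larger late dispersion, less salvage.  The package implements the
whole analysis chain and, because no patient data are deposited anywhere,
ships first-class synthetic generators (analytic ECG beats, short-axis CMR
phantoms, linked cohorts) whose ground truth makes every stage testable.

## What is in the box

| module | contents |
| --- | --- |
| `qtsalvage.simulate` | ECG beats with programmable per-lead QT/RR/noise, annulus CMR phantoms with sector lesions at known SD offsets, cohorts with a programmable dispersion–MSI link |
| `qtsalvage.ecg` | PQ-baseline estimation, QT delineation (T-end on the baseline, U-wave nadir rule), Bazett QTc, anterior–inferior dispersion, timecourse summary |
| `qtsalvage.cmr` | remote-ROI statistics, >2 SD edema and >5 SD infarct segmentation, MVO detection (hypo-enhanced cores inside infarct), gram conversion, MSI |
| `qtsalvage.stats` | paired t-test, Spearman, p<0.1 univariate screen, OLS on ln(LGE), logistic model for MSI < 0.6 (odds ratios), empirical ROC + Youden cut-off, Cohen's kappa |
| `qtsalvage.pipeline` | exclusion filter (the a–k criteria), end-to-end synthetic run, results bundle |
| `qtsalvage.cli` | `qtsalvage simulate / ecg / cmr / associate / run-all` |

## Worked example

```python
import qtsalvage as q

# 1. a synthetic recording with prolonged anterior QT, measured back
rec, truth = q.generate_ecg(q.EcgSimParams(
    qt_ms={"V2": 470, "V3": 490, "V4": 480, "V5": 465,
           "II": 420, "III": 425, "aVF": 430},
    rr_s=0.8, noise_sd_mv=0.01, seed=1))
measurements, skipped = q.measure_recording(rec)
d = q.dispersion(measurements)

# 2. a noisy CMR phantom, segmented by the SD-threshold rules
from qtsalvage.simulate import Sector
phantom = q.generate_cmr_phantom(q.CmrPhantomParams(
    mvo_sector=Sector(0.0, 15.0), noise_sd=5.0, seed=2))
quant = q.quantify_study(phantom.to_study("case-1"))

# 3. a linked cohort: dispersion against salvage
df, gt = q.generate_cohort(q.CohortSimParams(n=200, seed=3))
r, p = q.spearman(df["dqtc_ai_ma_day6"], df["msi"])
roc = q.roc_youden(df["dqtc_ai_ma_day6"], df["msi"] < 0.6)
```

prints (via the obvious format calls):

```
V2: QT 468 ms, RR 0.80 s, QTc 523 ms
dQTc-AI-MA = 80.5 ms (V3 - II)
dQTc-AI-ME = 56.9 ms
LV 122 g; AAR 32.5 g (27% LV); LGE 12.0 g (10% LV); MVO True; MSI 0.63
Spearman r = -0.66 (p = 2.0e-26); AUC = 0.81; Youden cut-off = 62 ms (sens 83%, spec 66%)
```

The delineator recovers the programmed QT within one sample (468 vs
470 ms at 500 Hz under noise); the phantom's measured MSI reflects its
programmed lesion geometry; and the cohort's negative dispersion–salvage
link surfaces as a negative Spearman correlation and an informative ROC
curve with its Youden-optimal cut-off.

A full synthetic run — exclusion filter, per-timepoint ECG measurement,
phantom quantification, merge and the complete statistical suite — is one
command:

```sh
qtsalvage run-all --out results/bundle --n 30 --seed 3
```

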