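"""Association pipeline: timecourse tests, correlation, screening models,
multivariable regression, ROC/Youden cut-off and observer agreement.

The modelling chain mirrors a standard clinical-imaging analysis: paired
t-tests for serial QTc change, Spearman rank correlation between
dispersion and CMR outcomes, a univariate p < 0.1 screen feeding a
multivariable OLS model on log-transformed infarct mass and a logistic
model for poor salvage (MSI below a cut, default 0.6), an empirical ROC
with the Youden-optimal threshold, and Cohen's kappa for repeated
readings.  Ordinary fits delegate to scipy/statsmodels; the ROC/Youden
search and kappa are implemented directly so their tie-break rules are
explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    DegenerateTestError,
    InvalidParameterError,
    RankDeficiencyError,
    SeparationError,
    SingleClassError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    mean_diff: float
    n: int


@dataclass(frozen=True)
class ModelResult:
    """Fitted model table: one row per term.

    ``scale`` is "coefficient" for linear models and "odds_ratio" for
    logistic ones (estimates, SEs and CIs are then on the OR scale, the SE
    by the delta method).  ``outcome_coding`` documents, for logistic
    models, which event the odds refer to.
    """

    terms: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray  # (k, 2)
    scale: str
    nobs: int
    n_dropped: int = 0
    r_squared: float | None = None
    r_squared_adj: float | None = None
    outcome_coding: str | None = None

    def to_frame(self) -> pd.DataFrame:
        label = "odds_ratio" if self.scale == "odds_ratio" else "coefficient"
        return pd.DataFrame(
            {
                "term": self.terms,
                label: self.estimates,
                "std_err": self.se,
                "p_value": self.pvalues,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "estimate": float(self.estimates[i]),
            "se": float(self.se[i]),
            "p": float(self.pvalues[i]),
            "ci": (float(self.conf_int[i, 0]), float(self.conf_int[i, 1])),
        }


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # observed score values, ascending
    sensitivity: np.ndarray  # P(score >= t | event)
    specificity: np.ndarray  # P(score < t | no event)
    auc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class ScreenResult:
    selected: tuple[str, ...]
    pvalues: pd.Series
    alpha: float
    n_dropped: int


# ---------------------------------------------------------------------------


def paired_qtc_test(a, b) -> PairedTestResult:
    """Two-sided paired t-test for serial QTc values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("paired samples must have equal length")
    if a.size < 3:
        raise InvalidParameterError("paired t-test needs n >= 3")
    d = b - a
    if np.allclose(d, 0.0):
        return PairedTestResult(t=0.0, p=1.0, mean_diff=0.0, n=a.size)
    if np.isclose(d.std(ddof=1), 0.0):
        raise DegenerateTestError(
            "zero variance of non-zero paired differences: t undefined"
        )
    res = sps.ttest_rel(b, a)
    return PairedTestResult(
        t=float(res.statistic), p=float(res.pvalue), mean_diff=float(d.mean()), n=a.size
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties), with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for constant input")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def _clean_design(
    df: pd.DataFrame, cols: list[str]
) -> tuple[pd.DataFrame, int]:
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(sub).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with non-finite values", n_dropped)
    return sub[keep], n_dropped


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name columns whose removal restores full rank
        offending = [
            c
            for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank
        ]
        raise RankDeficiencyError(offending or list(X.columns))


def univariate_screen(
    df: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    alpha: float = 0.1,
    model: str = "linear",
) -> ScreenResult:
    """Fit each candidate alone against the outcome; keep p < alpha.

    ``model`` is "linear" (OLS, continuous outcome such as log-LGE) or
    "logistic" (binary outcome such as poor salvage).  Rows with
    non-finite values are dropped per candidate with a logged count.
    """
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    pvals: dict[str, float] = {}
    dropped = 0
    for cand in candidates:
        sub, nd = _clean_design(df, [outcome, cand])
        dropped = max(dropped, nd)
        y = sub[outcome].to_numpy()
        X = sm.add_constant(sub[[cand]].to_numpy())
        try:
            if model == "linear":
                fit = sm.OLS(y, X).fit()
            elif model == "logistic":
                if len(np.unique(y)) < 2:
                    raise SingleClassError("outcome has a single class")
                fit = sm.Logit(y, X).fit(disp=0)
            else:
                raise InvalidParameterError(f"unknown model kind {model!r}")
            pvals[cand] = float(fit.pvalues[1])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # a perfectly separating candidate is trivially associated
            pvals[cand] = 0.0
    series = pd.Series(pvals, dtype=float)
    selected = tuple(c for c in candidates if series.get(c, 1.0) < alpha)
    return ScreenResult(
        selected=selected, pvalues=series, alpha=alpha, n_dropped=dropped
    )


def fit_linear_log_lge(
    df: pd.DataFrame,
    covariates: list[str],
    lge_col: str = "lge_g",
) -> ModelResult:
    """OLS of ln(LGE mass) on the selected covariates.

    Subjects without enhancement (LGE <= 0) are excluded — the log is
    undefined there — with the count reported in ``n_dropped``.
    """
    if not covariates:
        raise InvalidParameterError("no covariates given")
    sub, nd = _clean_design(df, [lge_col] + list(covariates))
    positive = sub[lge_col] > 0
    n_zero = int((~positive).sum())
    if n_zero:
        logger.info("dropped %d rows with non-positive LGE", n_zero)
    sub = sub[positive]
    if len(sub) <= len(covariates) + 1:
        raise InvalidParameterError("too few positive-LGE rows to fit")
    y = np.log(sub[lge_col].to_numpy())
    Xdf = sub[list(covariates)]
    _check_rank(Xdf)
    X = sm.add_constant(Xdf.to_numpy())
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    terms = ("const",) + tuple(covariates)
    return ModelResult(
        terms=terms,
        estimates=np.asarray(fit.params),
        se=np.asarray(fit.bse),
        pvalues=np.asarray(fit.pvalues),
        conf_int=np.asarray(ci),
        scale="coefficient",
        nobs=int(fit.nobs),
        n_dropped=nd + n_zero,
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
    )


def fit_logistic_msi(
    df: pd.DataFrame,
    covariates: list[str],
    msi_cut: float = 0.6,
    msi_col: str = "msi",
    event: str = "below",
) -> ModelResult:
    """Logistic model for poor salvage; estimates reported as odds ratios.

    The event is ``msi < msi_cut`` when ``event="below"`` (the default,
    stated in ``outcome_coding``); ``event="above"`` flips the coding.
    Wald-type CIs, exponentiated.
    """
    if not covariates:
        raise InvalidParameterError("no covariates given")
    if not 0 < msi_cut < 1:
        raise InvalidParameterError("msi_cut must be in (0, 1)")
    sub, nd = _clean_design(df, [msi_col] + list(covariates))
    if event == "below":
        y = (sub[msi_col] < msi_cut).astype(int).to_numpy()
        coding = f"event = MSI < {msi_cut}"
    elif event == "above":
        y = (sub[msi_col] >= msi_cut).astype(int).to_numpy()
        coding = f"event = MSI >= {msi_cut}"
    else:
        raise InvalidParameterError("event must be 'below' or 'above'")
    if len(np.unique(y)) < 2:
        raise SingleClassError("both MSI classes must be present")
    Xdf = sub[list(covariates)]
    _check_rank(Xdf)
    X = sm.add_constant(Xdf.to_numpy())
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
        raise SeparationError("complete or quasi-complete separation detected")
    beta = np.asarray(fit.params)
    se_b = np.asarray(fit.bse)
    terms = ("const",) + tuple(covariates)
    return ModelResult(
        terms=terms,
        estimates=np.exp(beta),
        se=np.exp(beta) * se_b,  # delta-method SE on the OR scale
        pvalues=np.asarray(fit.pvalues),
        conf_int=np.exp(np.asarray(fit.conf_int())),
        scale="odds_ratio",
        nobs=int(fit.nobs),
        n_dropped=nd,
        outcome_coding=coding,
    )


def roc_youden(scores, outcome) -> RocResult:
    """Empirical ROC over observed thresholds with the Youden cut-off.

    A subject is called positive when score >= threshold.  AUC is the
    trapezoidal area (equal to the rescaled Mann-Whitney U statistic).
    Ties in J = sens + spec - 1 break toward higher specificity, then
    toward the higher threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome).astype(bool)
    if s.size != y.size or s.size < 2:
        raise InvalidParameterError("need equal-length scores and outcomes")
    if y.all() or (~y).all():
        raise SingleClassError("both outcome classes required for a ROC curve")
    pos, neg = s[y], s[~y]
    thr = np.unique(s)
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    # curve endpoints: threshold -inf -> (1,1); +inf -> (0,0) in ROC space
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    j = sens + spec - 1.0
    order = np.lexsort((thr, spec, j))  # ascending; last index is the winner
    best = order[-1]
    return RocResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=float(thr[best]),
        sensitivity_at_cutoff=float(sens[best]),
        specificity_at_cutoff=float(spec[best]),
        youden_j=float(j[best]),
    )


def cohen_kappa(ratings_a, ratings_b, categories=None) -> float:
    """Cohen's kappa: (po - pe) / (1 - pe) with marginal-product chance."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size != b.size or a.size == 0:
        raise InvalidParameterError("rating vectors must have equal length")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    try:
        ai = np.array([index[v] for v in a])
        bi = np.array([index[v] for v in b])
    except KeyError as exc:
        raise InvalidParameterError(f"rating outside categories: {exc}") from exc
    k = len(categories)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    table /= a.size
    po = float(np.trace(table))
    pe = float(table.sum(axis=1) @ table.sum(axis=0))
    if np.isclose(pe, 1.0):
        raise DegenerateTestError(
            "kappa undefined: a single shared category (pe = 1)"
        )
    return (po - pe) / (1.0 - pe)
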