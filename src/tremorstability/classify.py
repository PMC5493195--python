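"""Cohort-level diagnostic evaluation of per-recording features.

Essential tremor (ET) is the positive class throughout, matching the
convention of targeting an ET diagnosis over Parkinson's disease (PD); the
``direction`` flag of :func:`diagnostic_metrics` recomputes the swapped
(PD-positive) columns.  Fixed-cutoff classification uses the strict rule
score > threshold → ET, score ≤ threshold → PD (default threshold 1.05 Hz).

AUC is the Mann–Whitney concordance probability (ties counted ½); its
confidence interval uses the Hanley–McNeil asymptotic standard error by
default, with DeLong as an alternative.  All stochastic operations (cross
validation folds, bootstrap resampling) are reproducible bit-for-bit given
a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .config import DEFAULT_CONFIG, AnalysisConfig
from .exceptions import BoundsError, ConfigurationError, DataError
from .features import condition_recording

POSITIVE_LABEL = "ET"
NEGATIVE_LABEL = "PD"

#: recording durations (s) evaluated by the duration bootstrap:
#: 1-10 s in 1 s steps, then 20-100 s in 10 s steps
DEFAULT_BOOTSTRAP_DURATIONS = tuple(range(1, 11)) + tuple(range(20, 101, 10))


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    y = labels == POSITIVE_LABEL
    bad = ~(y | (labels == NEGATIVE_LABEL))
    if bad.any():
        raise DataError(f"labels must be PD or ET, found {set(labels[bad])}")
    return y


def _require_both_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise DataError("both PD and ET must be present")


# ---------------------------------------------------------------------------
# confusion counts and derived metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with ET as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative

    def swapped(self) -> "ConfusionCounts":
        """Counts with the roles of the two classes exchanged."""
        return ConfusionCounts(tp=self.tn, fn=self.fp, tn=self.tp, fp=self.fn)


def classify_fixed(scores, labels=None, threshold: float = 1.05):
    """Apply the fixed cutoff: score > threshold → ET, score ≤ threshold → PD.

    Returns the predicted labels, and additionally the confusion counts when
    true ``labels`` are supplied.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise DataError("empty feature table")
    if np.any(np.isnan(scores)):
        raise DataError("feature contains missing values")
    predictions = np.where(scores > threshold, POSITIVE_LABEL, NEGATIVE_LABEL)
    if labels is None:
        return predictions
    y = _as_binary(labels)
    pred_pos = scores > threshold
    counts = ConfusionCounts(
        tp=int(np.sum(pred_pos & y)),
        fn=int(np.sum(~pred_pos & y)),
        tn=int(np.sum(~pred_pos & ~y)),
        fp=int(np.sum(pred_pos & ~y)),
    )
    return predictions, counts


@dataclass(frozen=True)
class DiagnosticReport:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: float  # sensitivity / (1 - specificity); inf when specificity = 1
    lr_neg: float  # (1 - sensitivity) / specificity; inf when specificity = 0
    direction: str = "ET_vs_PD"
    threshold: float = math.nan

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "direction": self.direction,
            "threshold": self.threshold,
        }


def diagnostic_metrics(
    counts: ConfusionCounts, direction: str = "ET_vs_PD", threshold: float = math.nan
) -> DiagnosticReport:
    """Sensitivity, specificity, accuracy and likelihood ratios from counts.

    ``direction="PD_vs_ET"`` exchanges the roles of the two classes before
    computing the metrics.
    """
    if direction not in ("ET_vs_PD", "PD_vs_ET"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    c = counts if direction == "ET_vs_PD" else counts.swapped()
    if c.n_positive < 1 or c.n_negative < 1:
        raise DataError("need at least one subject of each class")
    sens = c.tp / c.n_positive
    spec = c.tn / c.n_negative
    accuracy = (c.tp + c.tn) / c.total
    lr_pos = sens / (1 - spec) if spec < 1 else math.inf
    lr_neg = (1 - sens) / spec if spec > 0 else math.inf
    return DiagnosticReport(
        counts=c,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        direction=direction,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    auc: float
    se: float
    ci95: tuple
    ci_method: str = "hanley"

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "fpr": self.fpr,
            }
        )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    # asymptotic SE of the Mann-Whitney AUC (exponential approximation)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    # structural components: per-subject placement values
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    return math.sqrt(s10 / len(pos) + s01 / len(neg))


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the pairwise concordance probability, ties counted ½."""
    y = _as_binary(labels)
    _require_both_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc(
    scores,
    labels,
    ci_method: str = "hanley",
    alpha: float = 0.05,
) -> RocResult:
    """Empirical ROC over all observed thresholds with AUC and 95% CI.

    The CI is ``auc ± z·SE`` clipped to [0, 1], with SE from Hanley–McNeil
    (default, matching SPSS's asymptotic interval) or DeLong.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    _require_both_classes(y)
    if np.any(np.isnan(scores)):
        raise DataError("feature contains missing values")
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if ci_method == "hanley":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif ci_method == "delong":
        se = _delong_se(scores[y], scores[~y])
    else:
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        fpr=fpr,
        auc=auc,
        se=se,
        ci95=ci,
        ci_method=ci_method,
    )


@dataclass(frozen=True)
class ThresholdChoice:
    """Youden-style cutoff restricted to observed feature values.

    ``observed`` is the observed value c maximising sensitivity − (1 −
    specificity) under the rule score > c → ET; ``midpoint`` places the
    deployable threshold halfway to the next larger observed value.
    """

    observed: float
    midpoint: float
    youden_j: float
    sensitivity: float
    specificity: float


def optimal_threshold(scores, labels) -> ThresholdChoice:
    """Cutoff maximising sensitivity − (1 − specificity) over observed values.

    Ties are broken toward higher specificity (the larger cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    _require_both_classes(y)
    candidates = np.unique(scores)
    best = None
    for c in candidates:  # ascending: later ties have higher specificity
        pred_pos = scores > c
        sens = np.sum(pred_pos & y) / y.sum()
        spec = np.sum(~pred_pos & ~y) / (~y).sum()
        j = sens - (1 - spec)
        if best is None or j >= best[0] - 1e-12:
            best = (j, c, sens, spec)
    j, c, sens, spec = best
    larger = candidates[candidates > c]
    midpoint = float((c + larger[0]) / 2) if larger.size else float(c)
    return ThresholdChoice(
        observed=float(c),
        midpoint=midpoint,
        youden_j=float(j),
        sensitivity=float(sens),
        specificity=float(spec),
    )


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    b: float            # log-odds change per unit of the feature
    exp_b: float        # odds ratio
    exp_b_ci95: tuple   # Wald interval
    p_value: float
    converged: bool


def logistic_odds(scores, labels) -> LogisticFit:
    """Single-predictor maximum-likelihood logistic regression (no penalty).

    Exp(B) is the multiplicative change in the odds of an ET diagnosis per
    unit increase of the feature, with a Wald 95% CI.  Perfectly separated
    data are flagged as non-converged rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(scores_labels := np.asarray(labels)).astype(float)
    _require_both_classes(y.astype(bool))
    if np.ptp(scores) == 0:
        raise DataError("feature is constant; logistic fit is undefined")
    exog = sm.add_constant(scores)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        converged = bool(result.mle_retvals.get("converged", False))
        if any("erfect" in str(w.message) or "onverge" in str(w.message) for w in caught):
            converged = False  # perfect separation or failed optimisation
        b = float(result.params[1])
        intercept = float(result.params[0])
        ci = result.conf_int()[1]
        p = float(result.pvalues[1])
    except Exception:
        return LogisticFit(math.nan, math.nan, math.nan, (math.nan, math.nan), math.nan, False)
    if not np.isfinite(b) or abs(b) > 50:
        converged = False
    return LogisticFit(
        intercept=intercept,
        b=b,
        exp_b=math.exp(b) if abs(b) < 700 else math.inf,
        exp_b_ci95=(math.exp(ci[0]), math.exp(ci[1]) if ci[1] < 700 else math.inf),
        p_value=p,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CrossValidationResult:
    pooled: DiagnosticReport
    fold_reports: tuple
    fold_thresholds: tuple


def cross_validate(
    scores,
    labels,
    folds: int = 10,
    seed: int = 0,
    threshold: Optional[float] = None,
) -> CrossValidationResult:
    """Stratified k-fold validation of the threshold rule.

    Per fold, the cutoff is chosen on the training rows (Youden midpoint) —
    or fixed to ``threshold`` when given — and applied to the held-out rows;
    pooled confusion counts aggregate all held-out predictions.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    _require_both_classes(y)
    if len(scores) < folds:
        raise DataError(f"need at least {folds} subjects for {folds}-fold CV")
    if min(y.sum(), (~y).sum()) < folds:
        raise DataError("each class must have at least `folds` members for stratified CV")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    labels_arr = np.asarray(labels)
    pooled = np.zeros(4, dtype=int)  # tp, fn, tn, fp
    fold_reports, fold_thresholds = [], []
    for train, test in splitter.split(scores.reshape(-1, 1), y):
        if threshold is None:
            cut = optimal_threshold(scores[train], labels_arr[train]).midpoint
        else:
            cut = threshold
        _, counts = classify_fixed(scores[test], labels_arr[test], threshold=cut)
        pooled += np.array([counts.tp, counts.fn, counts.tn, counts.fp])
        fold_thresholds.append(cut)
        # fold report only when both classes are held out
        if counts.n_positive and counts.n_negative:
            fold_reports.append(diagnostic_metrics(counts, threshold=cut))
    pooled_counts = ConfusionCounts(*pooled.tolist())
    return CrossValidationResult(
        pooled=diagnostic_metrics(pooled_counts),
        fold_reports=tuple(fold_reports),
        fold_thresholds=tuple(fold_thresholds),
    )


# ---------------------------------------------------------------------------
# bootstrap analyses


def duration_bootstrap(
    recordings: Sequence,
    labels: Sequence,
    durations: Sequence[float] = DEFAULT_BOOTSTRAP_DURATIONS,
    iterations: int = 1000,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
    min_delta_f: int = 2,
) -> pd.DataFrame:
    """Classification performance (ROC AUC) versus recording duration.

    Each recording is conditioned once; per iteration and duration a random
    contiguous segment is drawn from every recording, the TSI is recomputed
    from the zero-crossing cycles inside the segment, and the cohort AUC is
    evaluated.  Returns per-duration mean and SD of the AUC distribution.

    Subjects whose segment yields fewer than ``min_delta_f`` Δf values are
    excluded from that iteration's AUC.
    """
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    y = _as_binary(labels)
    _require_both_classes(y)
    conditioned = [condition_recording(rec, config) for rec in recordings]
    spans = []
    for cond in conditioned:
        t = cond.cycles.crossing_times
        spans.append((float(t[0]), float(t[-1])))
    max_d = max(durations)
    shortest = min(hi - lo for lo, hi in spans)
    if max_d > shortest + 1e-9:
        raise BoundsError(
            f"requested duration {max_d} s exceeds the shortest usable "
            f"recording span ({shortest:.2f} s)"
        )
    rng = np.random.default_rng(seed)
    rows = []
    n = len(conditioned)
    for d in durations:
        aucs = np.full(iterations, np.nan)
        for it in range(iterations):
            tsis = np.full(n, np.nan)
            for i, (cond, (lo, hi)) in enumerate(zip(conditioned, spans)):
                slack = hi - lo - d
                start = lo if slack <= 0 else lo + rng.uniform(0.0, slack)
                df = cond.cycles.window_delta_f(start, start + d)
                if df.size >= min_delta_f:
                    q1, q3 = np.percentile(df, [25.0, 75.0])
                    tsis[i] = q3 - q1
            ok = ~np.isnan(tsis)
            if ok.sum() >= 2 and y[ok].any() and (~y[ok]).any():
                aucs[it] = roc_auc_score(y[ok], tsis[ok])
        valid = aucs[~np.isnan(aucs)]
        rows.append(
            {
                "duration_s": float(d),
                "auc_mean": float(valid.mean()) if valid.size else math.nan,
                "auc_sd": float(valid.std(ddof=0)) if valid.size else math.nan,
                "n_valid_iterations": int(valid.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AucComparison:
    fraction_a_better: float  # P(AUC_a - AUC_b > 0) over bootstrap replicates
    fraction_tied: float
    mean_difference: float
    sd_difference: float
    ci95_difference: tuple
    iterations: int


def compare_auc_bootstrap(
    scores_a,
    scores_b,
    labels,
    iterations: int = 10000,
    seed: int = 0,
) -> AucComparison:
    """Paired bootstrap comparison of two features' discriminative power.

    Subjects are resampled with replacement, stratified by class so that
    every replicate contains both diagnoses; both AUCs are computed on the
    same replicate and their difference (a minus b) recorded.
    """
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("features must be paired per subject")
    y = _as_binary(labels)
    _require_both_classes(y)
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise DataError("features contain missing values")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    diffs = np.empty(iterations)
    for it in range(iterations):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        yy = y[idx]
        diffs[it] = roc_auc_score(yy, a[idx]) - roc_auc_score(yy, b[idx])
    return AucComparison(
        fraction_a_better=float(np.mean(diffs > 0)),
        fraction_tied=float(np.mean(diffs == 0)),
        mean_difference=float(diffs.mean()),
        sd_difference=float(diffs.std(ddof=0)),
        ci95_difference=(
            float(np.percentile(diffs, 2.5)),
            float(np.percentile(diffs, 97.5)),
        ),
        iterations=iterations,
    )
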