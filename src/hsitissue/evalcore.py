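"""Contingency metrics, threshold calibration, and model introspection.

The positive class throughout is *cancerous*.  Binarization is strict:
a pixel is predicted cancerous iff ``p > t``, so sensitivity is 1 at t = 0
and specificity is 1 at t = 1; the same convention is used everywhere.

Metrics that are undefined for a patient (e.g. sensitivity when no
cancerous pixels are annotated) are flagged as NaN and skipped when
averaging over patients, never silently zeroed.  The one exception is the
Matthews correlation coefficient, whose zero-denominator case is defined
as 0 by the usual convention.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

from .containers import (
    CANCEROUS,
    NONMALIGNANT,
    AnnotationMask,
    InvalidInputError,
    ProbabilityMap,
)

#: Grid step for raw-threshold calibration (thresholds are reported to
#: four decimals).
DEFAULT_THRESHOLD_STEP = 1e-4


class EmptyEvaluationError(ValueError):
    """No labeled pixels to evaluate."""


@dataclass
class ContingencyCounts:
    """TP/TN/FP/FN pixel counts; cancerous is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """One patient's (or one mean) metric vector; NaN marks undefined."""

    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    f1_nonmalignant: float = np.nan
    f1_cancerous: float = np.nan
    auc: float = np.nan
    mcc: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_NAMES = [f.name for f in fields(MetricSet)]


@dataclass
class ThresholdCurve:
    """Patient-mean sensitivity/specificity along a threshold grid."""

    thresholds: np.ndarray
    sens_at: np.ndarray
    spec_at: np.ndarray


@dataclass
class MetricComparison:
    """Paired-t comparison of one metric before/after post-processing."""

    metric: str
    baseline_mean: float
    post_mean: float
    t_statistic: float
    p_value: float
    n_patients: int
    degenerate: bool = False


def confusion_counts(binary_map: np.ndarray, mask: AnnotationMask
                     ) -> ContingencyCounts:
    """Exact pixel counts over class-labeled pixels; margin/unlabeled ignored."""
    binary_map = np.asarray(binary_map)
    if binary_map.shape != mask.shape:
        raise InvalidInputError("prediction and mask shapes differ")
    labeled = mask.class_pixels()
    if not labeled.any():
        raise EmptyEvaluationError("mask contains no class-labeled pixels")
    pred = binary_map[labeled].astype(bool)
    truth = mask.labels[labeled] == CANCEROUS
    return ContingencyCounts(
        tp=int(np.count_nonzero(pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
    )


def compute_metrics(counts: ContingencyCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, per-class F1 and MCC from counts.

    ``sens = TP/(TP+FN)``, ``spec = TN/(TN+FP)``,
    ``F1_c = 2TP/(2TP+FP+FN)`` and ``F1_n`` with non-malignant as positive,
    ``MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` (0 when
    the denominator vanishes).  AUC needs probabilities and is computed
    separately by :func:`auc_score`.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    m = MetricSet()
    if counts.total:
        m.accuracy = (tp + tn) / counts.total
    if tp + fn:
        m.sensitivity = tp / (tp + fn)
    if tn + fp:
        m.specificity = tn / (tn + fp)
    if 2 * tp + fp + fn:
        m.f1_cancerous = 2 * tp / (2 * tp + fp + fn)
    if 2 * tn + fn + fp:
        m.f1_nonmalignant = 2 * tn / (2 * tn + fn + fp)
    denom = (float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom:
        m.mcc = (float(tp) * tn - float(fp) * fn) / np.sqrt(denom)
    else:
        m.mcc = 0.0
    return m


def auc_score(prob_map: ProbabilityMap, mask: AnnotationMask) -> float:
    """Rank-based ROC AUC over labeled pixels, midranks for ties.

    Returns NaN when only one class is present.
    """
    labeled = mask.class_pixels()
    probs = prob_map.probs[labeled]
    pos = mask.labels[labeled] == CANCEROUS
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(probs)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def _per_patient_rates(prob_map: ProbabilityMap, mask: AnnotationMask,
                       thresholds: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """(sens, spec) per threshold for one patient; NaN where undefined."""
    labeled = mask.class_pixels()
    probs = prob_map.probs[labeled]
    pos = mask.labels[labeled] == CANCEROUS
    p_pos = np.sort(probs[pos])
    p_neg = np.sort(probs[~pos])
    # strict '>' binarization: predicted positive iff p > t
    if len(p_pos):
        sens = (len(p_pos)
                - np.searchsorted(p_pos, thresholds, side="right")) / len(p_pos)
    else:
        sens = np.full(len(thresholds), np.nan)
    if len(p_neg):
        spec = np.searchsorted(p_neg, thresholds, side="right") / len(p_neg)
    else:
        spec = np.full(len(thresholds), np.nan)
    return sens, spec


def sens_spec_curves(prob_maps: list[ProbabilityMap],
                     masks: list[AnnotationMask],
                     thresholds: np.ndarray | None = None) -> ThresholdCurve:
    """Patient-mean sensitivity and specificity over a threshold grid.

    Per-patient rates that are undefined (a patient without one of the
    classes) are skipped in the mean at every threshold.
    """
    if not prob_maps:
        raise EmptyEvaluationError("no patients to evaluate")
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0 + DEFAULT_THRESHOLD_STEP / 2,
                               DEFAULT_THRESHOLD_STEP)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise InvalidInputError("threshold grid must be increasing")
    sens = np.empty((len(prob_maps), len(thresholds)))
    spec = np.empty_like(sens)
    for i, (pm, mk) in enumerate(zip(prob_maps, masks)):
        sens[i], spec[i] = _per_patient_rates(pm, mk, thresholds)
    with np.errstate(invalid="ignore"):
        return ThresholdCurve(thresholds,
                              np.nanmean(sens, axis=0),
                              np.nanmean(spec, axis=0))


def optimal_raw_threshold(curve: ThresholdCurve
                          ) -> tuple[float, float, float]:
    """Grid threshold where the sensitivity and specificity curves cross.

    Minimizes ``|sens - spec|`` over the grid, ties broken toward the
    smaller threshold; returns ``(threshold, sens, spec)`` at the optimum.
    """
    gap = np.abs(curve.sens_at - curve.spec_at)
    i = int(np.nanargmin(gap))  # first minimum -> smallest threshold
    return (float(curve.thresholds[i]), float(curve.sens_at[i]),
            float(curve.spec_at[i]))


def mean_over_patients(per_patient: list[MetricSet]
                       ) -> tuple[MetricSet, MetricSet]:
    """Unweighted mean and sample sd (n-1) per metric, skipping NaNs.

    A metric undefined for every patient stays NaN in both outputs.
    """
    if not per_patient:
        raise EmptyEvaluationError("no patients to average")
    mean, sd = MetricSet(), MetricSet()
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in per_patient], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals):
            setattr(mean, name, float(vals.mean()))
            setattr(sd, name,
                    float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return mean, sd


def paired_comparison(baseline: np.ndarray, post: np.ndarray,
                      metric: str = "") -> MetricComparison:
    """Classical two-tailed paired t-test; NaN pairs are dropped.

    Identical vectors give t = 0, p = 1.  A constant non-zero shift makes
    the difference variance vanish; that degenerate case is flagged and
    reported with the limiting p -> 0.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if baseline.shape != post.shape:
        raise InvalidInputError("paired vectors must have equal length")
    keep = ~(np.isnan(baseline) | np.isnan(post))
    b, p = baseline[keep], post[keep]
    n = len(b)
    if n < 2:
        raise InvalidInputError("need >= 2 defined pairs for a paired t-test")
    diff = p - b
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            return MetricComparison(metric, b.mean(), p.mean(), 0.0, 1.0, n)
        return MetricComparison(metric, b.mean(), p.mean(),
                                np.inf * np.sign(diff[0]), 0.0, n,
                                degenerate=True)
    res = stats.ttest_rel(p, b)
    return MetricComparison(metric, float(b.mean()), float(p.mean()),
                            float(res.statistic), float(res.pvalue), n)


def key_wavelength_importance(model, samples, batch_size: int = 512
                              ) -> np.ndarray:
    """Channel-occlusion importance of each spectral band.

    For each band, all 25 spatial positions of that channel are replaced by
    the channel's mean over the sample set and the mean absolute change in
    predicted probability is recorded.  Returns one importance per band.
    """
    patches = samples.patches.astype(np.float64)
    base = model.predict_proba(patches, batch_size=batch_size)
    n_bands = patches.shape[3]
    channel_means = patches.mean(axis=(0, 1, 2))  # per-band scalar
    importance = np.empty(n_bands)
    for b in range(n_bands):
        occluded = patches.copy()
        occluded[..., b] = channel_means[b]
        pred = model.predict_proba(occluded, batch_size=batch_size)
        importance[b] = np.abs(pred - base).mean()
    return importance


def top_wavelengths(importance: np.ndarray, wavelengths_nm: np.ndarray,
                    k: int = 5) -> list[tuple[float, float]]:
    """The k most important bands as (wavelength_nm, importance) pairs."""
    order = np.argsort(importance)[::-1][:k]
    return [(float(wavelengths_nm[i]), float(importance[i])) for i in order]
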