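"""Median-filter post-processing of probability maps and the parameter search.

Raw pixel-wise prediction maps carry salt-and-pepper speckle.  Two
post-processing routes remove it with an m x m median filter (m odd so the
window centers on the pixel):

* AP ("plain"): median-filter the raw probability map, then threshold.
* AWT ("with threshold"): threshold first, then median-filter the binary map.

Because thresholding is a monotone indicator and the odd-window median is
an order statistic, the two commute: ``binarize(MF(P), t) ==
MF(binarize(P, t))`` exactly.  AP is preferred in practice since the
filtered probability map remains available for visualization.

The optimal (MF size, threshold) pair is found by an exhaustive grid
search: a cell's improvement is the sum of the sensitivity and specificity
gains over the no-filter baseline, counted only when both gains are
positive, so the selected configuration can never fall below baseline in
either rate.  The search evaluates the AWT route with summed-area-table
majority votes, which is exact and fast even for large windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import AnnotationMask, CANCEROUS, InvalidInputError, ProbabilityMap
from .evalcore import (
    EmptyEvaluationError,
    MetricSet,
    auc_score,
    compute_metrics,
    confusion_counts,
    mean_over_patients,
)

#: Default search grids: window sizes 3..75 (odd) and a 1e-3 threshold grid.
DEFAULT_MF_SIZES = tuple(range(3, 76, 2))
DEFAULT_SEARCH_THRESHOLD_STEP = 1e-3


class InvalidParameterError(ValueError):
    """Raised for even window sizes or out-of-range thresholds."""


@dataclass(frozen=True)
class PostprocParams:
    """A median-filter window size (odd) and a discrimination threshold."""

    m: int
    t: float

    def __post_init__(self) -> None:
        if self.m < 1 or self.m % 2 == 0:
            raise InvalidParameterError(
                f"median-filter size must be odd and >= 1, got {self.m}")
        if not (0.0 <= self.t <= 1.0):
            raise InvalidParameterError(f"threshold must be in [0, 1], got {self.t}")


@dataclass
class SearchResult:
    """Outcome of the post-processing parameter search."""

    sens_baseline: float
    spec_baseline: float
    t_baseline: float
    mf_sizes: np.ndarray
    thresholds: np.ndarray
    improvements: np.ndarray  # (len(mf_sizes), len(thresholds)), >= 0
    m_opt: int
    t_opt: float
    improvement_sens: float
    improvement_spec: float
    improvement: float
    post_metrics_per_patient: list[MetricSet] = field(default_factory=list)
    post_metrics_mean: MetricSet | None = None
    post_metrics_sd: MetricSet | None = None


def median_filter(map2d: np.ndarray, m: int) -> np.ndarray:
    """Exact m x m median filter with reflect borders; m must be odd."""
    map2d = np.asarray(map2d)
    if map2d.ndim != 2:
        raise InvalidInputError("median_filter expects a 2-D map")
    if m % 2 == 0 or m < 1:
        raise InvalidParameterError(
            f"window size must be odd (centering), got {m}")
    if m > 2 * min(map2d.shape):
        raise InvalidParameterError(
            f"window size {m} too large for map of shape {map2d.shape}")
    if m == 1:
        return map2d.copy()
    return ndimage.median_filter(map2d, size=m, mode="reflect")


def binarize(map2d: np.ndarray, t: float) -> np.ndarray:
    """Strict thresholding: 1 where p > t, else 0."""
    if not (0.0 <= t <= 1.0):
        raise InvalidParameterError(f"threshold must be in [0, 1], got {t}")
    return (np.asarray(map2d) > t).astype(np.uint8)


def apply_ap(prob_map: ProbabilityMap, params: PostprocParams
             ) -> tuple[np.ndarray, np.ndarray]:
    """Plain algorithm: median-filter the probabilities, then threshold.

    Returns ``(filtered_probability_map, binary_map)``; the filtered map is
    kept because it still conveys per-pixel uncertainty.
    """
    filtered = median_filter(prob_map.probs, params.m)
    return filtered, binarize(filtered, params.t)


def apply_awt(prob_map: ProbabilityMap, params: PostprocParams) -> np.ndarray:
    """Algorithm with threshold: binarize first, then median-filter.

    The median of an odd window of binary values is binary, and the result
    is identical to :func:`apply_ap`'s binary map.
    """
    return median_filter(binarize(prob_map.probs, params.t),
                         params.m).astype(np.uint8)


def _rate_grids(prob_map: ProbabilityMap, mask: AnnotationMask,
                mf_sizes: np.ndarray, thresholds: np.ndarray,
                threshold_block: int = 256
                ) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-(m, t) sensitivity/specificity for one patient.

    Evaluates the AWT route: for each threshold the binary map's m x m
    median is a majority vote, computed for all windows at once from a
    summed-area table of the indicator.  NaN where a class is absent.
    """
    probs = prob_map.probs
    h, w = probs.shape
    labeled = mask.class_pixels()
    pos_r, pos_c = np.nonzero(labeled & (mask.labels == CANCEROUS))
    neg_r, neg_c = np.nonzero(labeled & (mask.labels != CANCEROUS))
    n_pos, n_neg = len(pos_r), len(neg_r)

    max_pad = int(max(mf_sizes)) // 2
    padded = np.pad(probs, max_pad, mode="symmetric")  # == scipy 'reflect'
    sens = np.full((len(mf_sizes), len(thresholds)), np.nan)
    spec = np.full_like(sens, np.nan)

    for t0 in range(0, len(thresholds), threshold_block):
        ts = thresholds[t0:t0 + threshold_block]
        ind = (padded[None] > ts[:, None, None])
        sat = np.zeros((len(ts), padded.shape[0] + 1, padded.shape[1] + 1),
                       dtype=np.int32)
        np.cumsum(np.cumsum(ind, axis=1), axis=2, out=sat[:, 1:, 1:])
        for mi, m in enumerate(mf_sizes):
            half = int(m) // 2
            a0, b0 = max_pad - half, max_pad - half
            win = (sat[:, a0 + m:a0 + m + h, b0 + m:b0 + m + w]
                   - sat[:, a0:a0 + h, b0 + m:b0 + m + w]
                   - sat[:, a0 + m:a0 + m + h, b0:b0 + w]
                   + sat[:, a0:a0 + h, b0:b0 + w])
            pred = win * 2 > int(m) * int(m)  # odd window: majority == median
            if n_pos:
                sens[mi, t0:t0 + len(ts)] = pred[:, pos_r, pos_c].sum(1) / n_pos
            if n_neg:
                spec[mi, t0:t0 + len(ts)] = 1.0 - pred[:, neg_r, neg_c].sum(1) / n_neg
    return sens, spec


def search_optimal_postproc(prob_maps: list[ProbabilityMap],
                            masks: list[AnnotationMask],
                            baseline: tuple[float, float, float],
                            mf_sizes=DEFAULT_MF_SIZES,
                            thresholds: np.ndarray | None = None
                            ) -> SearchResult:
    """Exhaustive grid search for the optimal (MF size, threshold).

    ``baseline`` is ``(threshold, sens, spec)`` from the raw-threshold
    calibration.  For every grid cell the patient-mean sensitivity and
    specificity after filtering are compared with the baseline; the cell
    value is the sum of the two gains when both are positive, else 0.  The
    argmax breaks ties toward the smaller window, then the smaller
    threshold.  If no cell improves both rates, the baseline configuration
    (m = 1, baseline threshold) is returned with improvement 0.
    """
    if not prob_maps:
        raise EmptyEvaluationError("no patients to evaluate")
    mf_sizes = np.asarray(mf_sizes, dtype=int)
    if np.any(mf_sizes % 2 == 0) or np.any(mf_sizes < 1):
        raise InvalidParameterError("all median-filter sizes must be odd")
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0 + DEFAULT_SEARCH_THRESHOLD_STEP / 2,
                               DEFAULT_SEARCH_THRESHOLD_STEP)
    thresholds = np.asarray(thresholds, dtype=float)
    t_base, sens_base, spec_base = baseline

    sens_sum = np.zeros((len(mf_sizes), len(thresholds)))
    spec_sum = np.zeros_like(sens_sum)
    sens_n = np.zeros_like(sens_sum)
    spec_n = np.zeros_like(sens_sum)
    for pm, mk in zip(prob_maps, masks):
        s, c = _rate_grids(pm, mk, mf_sizes, thresholds)
        ok_s, ok_c = ~np.isnan(s), ~np.isnan(c)
        sens_sum[ok_s] += s[ok_s]
        spec_sum[ok_c] += c[ok_c]
        sens_n += ok_s
        spec_n += ok_c
    with np.errstate(invalid="ignore"):
        sens_grid = sens_sum / sens_n
        spec_grid = spec_sum / spec_n

    imp_sens = sens_grid - sens_base
    imp_spec = spec_grid - spec_base
    improvements = np.where((imp_sens > 0) & (imp_spec > 0),
                            imp_sens + imp_spec, 0.0)
    improvements = np.nan_to_num(improvements, nan=0.0)

    if improvements.max() > 0:
        flat = int(np.argmax(improvements))  # C-order: smallest m, then t
        mi, ti = np.unravel_index(flat, improvements.shape)
        m_opt, t_opt = int(mf_sizes[mi]), float(thresholds[ti])
        best_sens, best_spec = imp_sens[mi, ti], imp_spec[mi, ti]
        total = float(improvements[mi, ti])
    else:
        m_opt, t_opt = 1, float(t_base)
        best_sens = best_spec = total = 0.0

    result = SearchResult(
        sens_baseline=float(sens_base), spec_baseline=float(spec_base),
        t_baseline=float(t_base), mf_sizes=mf_sizes, thresholds=thresholds,
        improvements=improvements, m_opt=m_opt, t_opt=t_opt,
        improvement_sens=float(best_sens), improvement_spec=float(best_spec),
        improvement=total,
    )

    params = PostprocParams(m=m_opt, t=t_opt)
    for pm, mk in zip(prob_maps, masks):
        filtered, binary = apply_ap(pm, params)
        metrics = compute_metrics(confusion_counts(binary, mk))
        metrics.auc = auc_score(
            ProbabilityMap(filtered, pm.valid, pm.patient_id), mk)
        result.post_metrics_per_patient.append(metrics)
    result.post_metrics_mean, result.post_metrics_sd = mean_over_patients(
        result.post_metrics_per_patient)
    return result
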