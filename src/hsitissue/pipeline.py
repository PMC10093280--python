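"""Study orchestration: leave-k-out cross-validation, tables and maps.

A *study* is one named model configuration — architecture, spectral
scaling, how many patients are held out per fold, and whether every third
sample is used — evaluated over a cohort by leave-k-out cross-validation:
each fold trains on all patients except a held-out block (90/10
train/validation split of the pooled samples) and predicts full
probability maps for the held-out patients, so no held-out pixel ever
influences training.

Model names follow the ``Architecture_Preprocessing_K_T/F`` scheme, e.g.
``Inc_Norm_4_T`` (inception, unit-length normalization, 4 patients held
out, every third sample used), with `` + SW`` appended when per-patient
sample weights replace class weights.

All randomness derives from a single master seed through named
sub-streams (cohort, per-fold shuffles, initialization, training), so two
runs with the same master seed produce identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import AnnotationMask, InvalidInputError, PatientPhantom, ProbabilityMap
from .evalcore import (
    METRIC_NAMES,
    MetricComparison,
    MetricSet,
    auc_score,
    compute_metrics,
    confusion_counts,
    key_wavelength_importance,
    mean_over_patients,
    optimal_raw_threshold,
    paired_comparison,
    sens_spec_curves,
)
from .models import (
    INCEPTION,
    RS,
    ArchitectureSpec,
    TrainingConfig,
    build_model,
    predict_probability_map,
    train_classifier,
)
from .postproc import (
    DEFAULT_MF_SIZES,
    PostprocParams,
    SearchResult,
    apply_ap,
    binarize,
    search_optimal_postproc,
)
from .preprocess import (
    NORMALIZATION,
    STANDARDIZATION,
    SampleSet,
    compute_class_weights,
    compute_sample_weights,
    exclude_noisy_channels,
    extract_samples,
    scale_cube,
    subsample_every_third,
)
from .synthdata import PhantomConfig, generate_cohort

_ARCH_SHORT = {INCEPTION: "Inc", RS: "RS"}
_SCALING_SHORT = {NORMALIZATION: "Norm", STANDARDIZATION: "Stan"}


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed from the master seed and a stream key."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyConfig:
    """Everything one study needs, from phantoms to search grids."""

    architecture: str = INCEPTION
    scaling: str = NORMALIZATION
    k_excluded: int = 4
    every_third: bool = True
    use_sample_weights: bool = False
    width_scale: float = 0.08
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    mf_sizes: tuple = DEFAULT_MF_SIZES
    search_threshold_step: float = 1e-3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in _ARCH_SHORT:
            raise InvalidInputError(f"unknown architecture {self.architecture!r}")
        if self.scaling not in _SCALING_SHORT:
            raise InvalidInputError(f"unknown scaling {self.scaling!r}")
        if self.k_excluded < 1:
            raise InvalidInputError("k_excluded must be >= 1")

    @property
    def model_name(self) -> str:
        name = (f"{_ARCH_SHORT[self.architecture]}_"
                f"{_SCALING_SHORT[self.scaling]}_{self.k_excluded}_"
                f"{'T' if self.every_third else 'F'}")
        if self.use_sample_weights:
            name += " + SW"
        return name


@dataclass
class FoldResult:
    """One cross-validation fold: held-out patients and their maps."""

    held_out: list[str]
    prob_maps: dict[str, ProbabilityMap]
    history: list[dict]
    probe_samples: SampleSet | None = None
    model: object = None


@dataclass
class StudyReport:
    """Everything the result tables are built from."""

    model_name: str
    baseline_threshold: float
    baseline_per_patient: list[MetricSet]
    baseline_mean: MetricSet
    baseline_sd: MetricSet
    search: SearchResult
    comparisons: list[MetricComparison]
    baseline_table: pd.DataFrame
    post_table: pd.DataFrame
    improvements_table: pd.DataFrame
    key_wavelength_importance: np.ndarray | None = None
    wavelengths_nm: np.ndarray | None = None


def preprocess_phantom(phantom: PatientPhantom, scaling: str):
    """Channel exclusion then per-spectrum scaling, ready for sampling."""
    return scale_cube(exclude_noisy_channels(phantom.cube), scaling)


def cohort_for_study(cfg: StudyConfig) -> list[PatientPhantom]:
    """Generate the study cohort with its seed derived from the master."""
    phantom_cfg = replace(cfg.phantom, seed=derive_seed(cfg.master_seed, 0))
    return generate_cohort(phantom_cfg)


def run_lkocv(cohort: list[PatientPhantom], cfg: StudyConfig
              ) -> list[FoldResult]:
    """Leave-k-out cross-validation over the cohort.

    Patients are shuffled once (master seed) and split into contiguous
    blocks of size ``k_excluded``; each block is held out in turn.  Per
    fold: pool the remaining patients' samples, shuffle, split 90/10 into
    train/validation, optionally keep every third sample, compute weights
    on the train split only, train, and predict full maps for the held-out
    patients.
    """
    n = len(cohort)
    if n < cfg.k_excluded + 1:
        raise InvalidInputError(
            f"cohort of {n} too small for k_excluded={cfg.k_excluded}")
    order = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.master_seed, spawn_key=(1,))).permutation(n)
    blocks = [order[i:i + cfg.k_excluded]
              for i in range(0, n, cfg.k_excluded)]

    cubes = [preprocess_phantom(ph, cfg.scaling) for ph in cohort]
    samples = [extract_samples(cubes[i], cohort[i].mask,
                               cohort[i].patient_id) for i in range(n)]

    folds: list[FoldResult] = []
    for fold_i, block in enumerate(blocks):
        held = set(int(i) for i in block)
        pool = SampleSet.concatenate(
            [samples[i] for i in range(n) if i not in held])
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.master_seed, spawn_key=(2, fold_i)))
        perm = rng.permutation(len(pool))
        n_train = int(round(0.9 * len(pool)))
        train = pool.subset(perm[:n_train])
        val = pool.subset(perm[n_train:])
        if cfg.every_third:
            sub_seed = derive_seed(cfg.master_seed, 3, fold_i)
            train = subsample_every_third(train, sub_seed)
            if len(val):
                val = subsample_every_third(val, sub_seed + 1)

        weights = (compute_sample_weights(train) if cfg.use_sample_weights
                   else compute_class_weights(train))
        spec = ArchitectureSpec(
            name=cfg.architecture, width_scale=cfg.width_scale,
            init_seed=derive_seed(cfg.master_seed, 4, fold_i))
        model = build_model(spec)
        train_cfg = replace(cfg.training,
                            use_sample_weights=cfg.use_sample_weights,
                            seed=derive_seed(cfg.master_seed, 5, fold_i))
        model, history = train_classifier(model, train, val, train_cfg, weights)

        prob_maps = {
            cohort[i].patient_id: replace(
                predict_probability_map(model, cubes[i], cohort[i].mask),
                patient_id=cohort[i].patient_id)
            for i in sorted(held)
        }
        probe_idx = rng.permutation(len(train))[:256]
        folds.append(FoldResult(
            held_out=[cohort[i].patient_id for i in sorted(held)],
            prob_maps=prob_maps, history=history,
            probe_samples=train.subset(probe_idx), model=model))
    return folds


def _format_pct(mean: float, sd: float, stars: str = "") -> str:
    if np.isnan(mean):
        return "undefined"
    return f"{100 * mean:.1f} ± {100 * sd:.1f}{(' ' + stars) if stars else ''}"


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


_TABLE_COLUMNS = {"accuracy": "Accuracy", "sensitivity": "Sensitivity",
                  "specificity": "Specificity", "f1_nonmalignant": "F1-n",
                  "f1_cancerous": "F1-c", "auc": "AUC", "mcc": "MCC"}


def evaluate_study(folds: list[FoldResult], cohort: list[PatientPhantom],
                   cfg: StudyConfig) -> StudyReport:
    """Assemble the study report from completed folds.

    Produces the baseline table (optimal raw threshold + patient-mean
    metrics ± sd), the post-processing table (optimal MF size/threshold,
    metrics with paired-t significance stars), the improvements table
    (sensitivity/specificity gains and their sum, in percent points), and
    channel-occlusion wavelength importances from the first fold's model.
    """
    masks_by_id = {ph.patient_id: ph.mask for ph in cohort}
    maps: list[ProbabilityMap] = []
    masks: list[AnnotationMask] = []
    for fold in folds:
        for pid, pm in fold.prob_maps.items():
            maps.append(pm)
            masks.append(masks_by_id[pid])
    if len(maps) != len(cohort):
        raise InvalidInputError("folds do not cover the cohort exactly once")

    curve = sens_spec_curves(maps, masks)
    t_base, sens_base, spec_base = optimal_raw_threshold(curve)

    baseline_per_patient = []
    for pm, mk in zip(maps, masks):
        m = compute_metrics(confusion_counts(binarize(pm.probs, t_base), mk))
        m.auc = auc_score(pm, mk)
        baseline_per_patient.append(m)
    baseline_mean, baseline_sd = mean_over_patients(baseline_per_patient)

    thresholds = np.arange(0.0, 1.0 + cfg.search_threshold_step / 2,
                           cfg.search_threshold_step)
    search = search_optimal_postproc(maps, masks,
                                     (t_base, sens_base, spec_base),
                                     mf_sizes=cfg.mf_sizes,
                                     thresholds=thresholds)

    comparisons = []
    for name in METRIC_NAMES:
        b = np.array([getattr(m, name) for m in baseline_per_patient])
        p = np.array([getattr(m, name)
                      for m in search.post_metrics_per_patient])
        comparisons.append(paired_comparison(b, p, metric=name))

    name = cfg.model_name
    baseline_table = pd.DataFrame([{
        "Name": name, "Threshold": round(t_base, 4),
        **{col: _format_pct(getattr(baseline_mean, key),
                            getattr(baseline_sd, key))
           for key, col in _TABLE_COLUMNS.items()},
    }])
    post_mean, post_sd = search.post_metrics_mean, search.post_metrics_sd
    star_by_metric = {c.metric: _stars(c.p_value) for c in comparisons}
    post_table = pd.DataFrame([{
        "Name": name, "MF Size": search.m_opt,
        "Threshold": round(search.t_opt, 4),
        **{col: _format_pct(getattr(post_mean, key), getattr(post_sd, key),
                            star_by_metric.get(key, ""))
           for key, col in _TABLE_COLUMNS.items()},
    }])
    improvements_table = pd.DataFrame([{
        "Name": name,
        "Improvement Sensitivity": round(100 * search.improvement_sens, 3),
        "Improvement Specificity": round(100 * search.improvement_spec, 3),
        "Improvement": round(100 * search.improvement, 3),
    }])

    importance = wavelengths = None
    first = folds[0]
    if first.model is not None and first.probe_samples is not None \
            and len(first.probe_samples) >= 100:
        importance = key_wavelength_importance(first.model,
                                               first.probe_samples)
        wavelengths = exclude_noisy_channels(cohort[0].cube).wavelengths_nm

    return StudyReport(
        model_name=name, baseline_threshold=t_base,
        baseline_per_patient=baseline_per_patient,
        baseline_mean=baseline_mean, baseline_sd=baseline_sd,
        search=search, comparisons=comparisons,
        baseline_table=baseline_table, post_table=post_table,
        improvements_table=improvements_table,
        key_wavelength_importance=importance, wavelengths_nm=wavelengths)


# ---------------------------------------------------------------------------
# visual maps


def probability_rgb(prob_map2d: np.ndarray) -> np.ndarray:
    """Probability map in the green-shade uncertainty scheme.

    0 maps to purple (non-malignant), 1 to yellow (cancerous), intermediate
    probabilities to shades of green.
    """
    p = np.clip(np.asarray(prob_map2d, dtype=float), 0, 1)
    purple = np.array([128, 0, 128], dtype=float) / 255
    green = np.array([0, 160, 60], dtype=float) / 255
    yellow = np.array([255, 255, 0], dtype=float) / 255
    lo = np.clip(p * 2, 0, 1)[..., None]
    hi = np.clip(p * 2 - 1, 0, 1)[..., None]
    rgb = (1 - lo) * purple + lo * green
    rgb = np.where(p[..., None] > 0.5, (1 - hi) * green + hi * yellow, rgb)
    return (255 * rgb).astype(np.uint8)


def binary_rgb(binary_map: np.ndarray) -> np.ndarray:
    """Binary map in purple/yellow."""
    rgb = np.empty(binary_map.shape + (3,), dtype=np.uint8)
    rgb[...] = (128, 0, 128)
    rgb[np.asarray(binary_map).astype(bool)] = (255, 255, 0)
    return rgb


def error_rgb(binary_map: np.ndarray, mask: AnnotationMask) -> np.ndarray:
    """Error map: misclassified annotated pixels in red, rest dark gray.

    The red-pixel count equals FP + FN of the confusion counts.
    """
    truth = mask.labels
    rgb = np.full(truth.shape + (3,), 40, dtype=np.uint8)
    labeled = mask.class_pixels()
    wrong = labeled & (np.asarray(binary_map).astype(bool)
                       != (truth == 2))
    rgb[wrong] = (255, 0, 0)
    return rgb


def render_maps(prob_map: ProbabilityMap, mask: AnnotationMask,
                params: PostprocParams,
                sweep_sizes: tuple = (1, 5, 25, 51),
                sweep_thresholds: tuple = (0.2, 0.4, 0.6)):
    """Render the standard visual set for one patient.

    Returns a dict of matplotlib figures: the raw probability map, the
    post-processed binary map, the error map, and an MF-size x threshold
    sweep grid.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    max_m = 2 * min(prob_map.probs.shape)  # practical filter bound
    sweep_sizes = tuple(m for m in sweep_sizes if m <= max_m)
    filtered, binary = apply_ap(prob_map, params)
    figures = {}

    for key, rgb, title in (
        ("probability", probability_rgb(prob_map.probs), "raw probability"),
        ("binary", binary_rgb(binary),
         f"AP m={params.m}, t={params.t:.4f}"),
        ("error", error_rgb(binary, mask), "errors (annotated pixels)"),
    ):
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.imshow(rgb)
        ax.set_title(title)
        ax.axis("off")
        figures[key] = fig

    fig, axes = plt.subplots(len(sweep_sizes), len(sweep_thresholds),
                             figsize=(2.2 * len(sweep_thresholds),
                                      1.8 * len(sweep_sizes)),
                             squeeze=False)
    for i, m in enumerate(sweep_sizes):
        for j, t in enumerate(sweep_thresholds):
            _, b = apply_ap(prob_map, PostprocParams(m=m, t=t))
            axes[i][j].imshow(binary_rgb(b))
            axes[i][j].set_title(f"m={m}, t={t:.2f}", fontsize=7)
            axes[i][j].axis("off")
    fig.tight_layout()
    figures["sweep"] = fig
    return figures
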