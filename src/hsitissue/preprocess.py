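"""Spectral pre-processing and sample extraction.

Order of operations: the first 8 spectral channels are excluded (they are
dominated by sensor noise and would corrupt per-spectrum statistics), then
each pixel spectrum is scaled independently with one of two methods:

* standardization (z-score): ``x' = (x - mean(x)) / sd(x)``
* normalization (unit length): ``x' = x / ||x||``

Both act per pixel spectrum, which is what removes patient-to-patient gain
and offset differences.  The standard deviation uses the population
(divide-by-N) convention.

Training samples are 5 x 5 x B patches around each class-labeled pixel;
the label is the center pixel's, and border patches use reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    CANCEROUS,
    NONMALIGNANT,
    AnnotationMask,
    InvalidInputError,
    SpectralCube,
)

N_NOISY_CHANNELS = 8
PATCH_SIZE = 5

STANDARDIZATION = "standardization"
NORMALIZATION = "normalization"


class DegenerateSpectrumError(ValueError):
    """A spectrum with zero variance (or zero length) cannot be scaled."""


class MissingClassError(ValueError):
    """Weight formulas need at least one sample of every class."""


@dataclass
class SampleSet:
    """Extracted patches with center labels, provenance and optional weights.

    ``patches`` has shape ``(N, 5, 5, B)``; ``labels`` is binary with
    0 = non-malignant, 1 = cancerous.
    """

    patches: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    center_coords: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.patient_ids = np.asarray(self.patient_ids)
        self.center_coords = np.asarray(self.center_coords)
        n = len(self.labels)
        if self.patches.shape[0] != n or len(self.patient_ids) != n:
            raise InvalidInputError("sample arrays have inconsistent lengths")
        if n and self.patches.shape[1:3] != (PATCH_SIZE, PATCH_SIZE):
            raise InvalidInputError(
                f"patches must be {PATCH_SIZE}x{PATCH_SIZE} spatially")
        if n and not np.isin(self.labels, [0, 1]).all():
            raise InvalidInputError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SampleSet":
        return SampleSet(
            patches=self.patches[idx],
            labels=self.labels[idx],
            patient_ids=self.patient_ids[idx],
            center_coords=self.center_coords[idx],
            weights=None if self.weights is None else self.weights[idx],
        )

    @staticmethod
    def concatenate(sets: list["SampleSet"]) -> "SampleSet":
        return SampleSet(
            patches=np.concatenate([s.patches for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            patient_ids=np.concatenate([s.patient_ids for s in sets]),
            center_coords=np.concatenate([s.center_coords for s in sets]),
        )


@dataclass
class WeightTable:
    """Class weights (total/count per class) and per-(class, patient)
    sample weights (total/count per stratum)."""

    class_weight_per_class: dict[int, float] = field(default_factory=dict)
    sample_weight_per_class_patient: dict[tuple[int, str], float] = field(
        default_factory=dict)


def exclude_noisy_channels(cube: SpectralCube) -> SpectralCube:
    """Drop the first 8 spectral channels and shift the wavelength axis.

    A native 100-band cube starting at 500 nm becomes a 92-band cube
    starting at 540 nm.
    """
    if cube.n_bands <= N_NOISY_CHANNELS:
        raise InvalidInputError(
            f"cube must have > {N_NOISY_CHANNELS} bands, got {cube.n_bands}")
    return SpectralCube(cube.values[..., N_NOISY_CHANNELS:],
                        cube.wavelengths_nm[N_NOISY_CHANNELS:])


def scale_spectrum(x: np.ndarray, method: str) -> np.ndarray:
    """Scale one pixel spectrum by z-score or to unit Euclidean length."""
    x = np.asarray(x, dtype=np.float64)
    if method == STANDARDIZATION:
        sigma = x.std()  # population convention
        if sigma == 0:
            raise DegenerateSpectrumError("constant spectrum: sd is zero")
        return (x - x.mean()) / sigma
    if method == NORMALIZATION:
        norm = np.linalg.norm(x)
        if norm == 0:
            raise DegenerateSpectrumError("all-zero spectrum: length is zero")
        return x / norm
    raise InvalidInputError(f"unknown scaling method {method!r}")


def scale_cube(cube: SpectralCube, method: str) -> SpectralCube:
    """Apply :func:`scale_spectrum` independently to every pixel.

    Degenerate pixels are reported with their coordinates.
    """
    v = cube.values.astype(np.float64)
    if method == STANDARDIZATION:
        mean = v.mean(axis=2, keepdims=True)
        sd = v.std(axis=2, keepdims=True)
        bad = np.argwhere(sd[..., 0] == 0)
        if len(bad):
            raise DegenerateSpectrumError(
                f"zero-variance spectra at pixels {bad[:5].tolist()}")
        scaled = (v - mean) / sd
    elif method == NORMALIZATION:
        norm = np.linalg.norm(v, axis=2, keepdims=True)
        bad = np.argwhere(norm[..., 0] == 0)
        if len(bad):
            raise DegenerateSpectrumError(
                f"zero-length spectra at pixels {bad[:5].tolist()}")
        scaled = v / norm
    else:
        raise InvalidInputError(f"unknown scaling method {method!r}")
    return SpectralCube(scaled.astype(np.float32), cube.wavelengths_nm)


def extract_samples(cube: SpectralCube, mask: AnnotationMask,
                    patient_id: str) -> SampleSet:
    """One 5x5xB patch per class-labeled pixel; label = center pixel's.

    Margin and unlabeled pixels yield no sample.  The cube is expected to be
    channel-excluded and scaled already; border patches reflect-pad the cube.
    """
    if cube.shape[:2] != mask.shape:
        raise InvalidInputError("cube and mask spatial dimensions differ")
    half = PATCH_SIZE // 2
    padded = np.pad(cube.values, ((half, half), (half, half), (0, 0)),
                    mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (PATCH_SIZE, PATCH_SIZE), axis=(0, 1))
    # windows: (H, W, B, 5, 5) -> select labeled centers, reorder to (N,5,5,B)
    rows, cols = np.nonzero(mask.class_pixels())
    patches = np.moveaxis(windows[rows, cols], 1, 3)
    labels = (mask.labels[rows, cols] == CANCEROUS).astype(np.int8)
    return SampleSet(
        patches=np.ascontiguousarray(patches, dtype=np.float32),
        labels=labels,
        patient_ids=np.full(len(labels), patient_id, dtype=object),
        center_coords=np.stack([rows, cols], axis=1) if len(labels)
        else np.empty((0, 2), dtype=int),
    )


def compute_class_weights(samples: SampleSet) -> WeightTable:
    """``weight(X) = total_samples / samples_of_class_X`` for X in {0, 1}."""
    total = len(samples)
    table = WeightTable()
    for cls in (0, 1):
        count = int(np.count_nonzero(samples.labels == cls))
        if count == 0:
            raise MissingClassError(f"no samples of class {cls}")
        table.class_weight_per_class[cls] = total / count
    return table


def compute_sample_weights(samples: SampleSet) -> WeightTable:
    """``weight(X, Y) = total_samples / count(class X of patient Y)``."""
    total = len(samples)
    table = WeightTable()
    for cls in (0, 1):
        in_cls = samples.labels == cls
        if not in_cls.any():
            raise MissingClassError(f"no samples of class {cls}")
        for pid in np.unique(samples.patient_ids[in_cls]):
            count = int(np.count_nonzero(
                in_cls & (samples.patient_ids == pid)))
            table.sample_weight_per_class_patient[(cls, str(pid))] = total / count
    return table


def per_sample_weights(samples: SampleSet, table: WeightTable,
                       use_sample_weights: bool = False) -> np.ndarray:
    """Materialize one weight per sample from a weight table."""
    if use_sample_weights:
        return np.array([
            table.sample_weight_per_class_patient[(int(c), str(p))]
            for c, p in zip(samples.labels, samples.patient_ids)])
    return np.array([table.class_weight_per_class[int(c)]
                     for c in samples.labels])


def subsample_every_third(samples: SampleSet, seed: int) -> SampleSet:
    """Seeded shuffle, then keep shuffled positions 0, 3, 6, ...

    The result has ``ceil(N / 3)`` samples.
    """
    if len(samples) == 0:
        raise InvalidInputError("cannot subsample an empty SampleSet")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    perm = rng.permutation(len(samples))
    return samples.subset(perm[::3])
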