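"""Seeded synthetic patient cohorts for hyperspectral tissue classification.

Real ex vivo colorectal records (480 x 640 x 100 reflectance cubes over
500-1000 nm with pathologist masks) are available only on request, so this
module generates phantoms with the statistical features the downstream
stages care about:

* two tissue classes with smooth, overlapping reflectance spectra whose
  difference is concentrated in the 550-650 nm and 900-1000 nm windows
  (the regions that dominate trained-model importances),
* patient-to-patient multiplicative gain and additive offset,
* per-pixel Gaussian sensor noise,
* an ~10:1 non-malignant : cancerous labeled-pixel imbalance,
* partial annotation and a margin ring around each lesion (margin pixels
  are annotated but excluded from training and metrics).

Independently of the cubes, :func:`simulate_probability_map` produces
classifier-like probability maps with salt-and-pepper speckle so the
post-processing and evaluation stages can be exercised without training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .containers import (
    CANCEROUS,
    MARGIN,
    NONMALIGNANT,
    UNLABELED,
    AnnotationMask,
    InvalidInputError,
    PatientPhantom,
    ProbabilityMap,
    SpectralCube,
)

_MIN_DIM = 5  # patch size; phantoms smaller than one patch are useless


class InvalidConfigError(ValueError):
    """Raised for phantom configurations that cannot be generated."""


@dataclass
class PhantomConfig:
    """Generative parameters for a synthetic patient cohort.

    Spatial defaults are scaled down from the native 480 x 640 sensor frame
    so that a full cross-validation run stays desk-sized; the native frame
    remains configurable.  ``class_contrast`` scales the spectral separation
    between the classes (0 means the classes are spectrally identical).
    """

    n_patients: int = 8
    height: int = 96
    width: int = 128
    n_bands: int = 100
    wavelength_start_nm: float = 500.0
    wavelength_step_nm: float = 5.0
    target_imbalance: float = 10.0
    annotated_fraction: float = 0.6
    lesion_count_range: tuple[int, int] = (1, 3)
    margin_width_px: int = 2
    patient_gain_sd: float = 0.08
    patient_offset_sd: float = 0.02
    pixel_noise_sd: float = 0.02
    class_contrast: float = 1.0
    contrast_window_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < _MIN_DIM or self.width < _MIN_DIM:
            raise InvalidConfigError(
                f"spatial dimensions must be >= {_MIN_DIM}, "
                f"got {self.height}x{self.width}"
            )
        if self.n_patients < 1 or self.n_bands < 1:
            raise InvalidConfigError("n_patients and n_bands must be positive")
        if self.target_imbalance <= 0:
            raise InvalidConfigError("target_imbalance must be > 0")
        if not (0.0 < self.annotated_fraction <= 1.0):
            raise InvalidConfigError("annotated_fraction must be in (0, 1]")
        if self.wavelength_step_nm <= 0:
            raise InvalidConfigError("wavelength grid must be strictly increasing")
        lo, hi = self.lesion_count_range
        if lo < 1 or hi < lo:
            raise InvalidConfigError("lesion_count_range must be a valid interval")
        if min(self.patient_gain_sd, self.patient_offset_sd,
               self.pixel_noise_sd, self.class_contrast) < 0:
            raise InvalidConfigError("noise and contrast parameters must be >= 0")
        if self.margin_width_px < 0:
            raise InvalidConfigError("margin_width_px must be >= 0")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return (self.wavelength_start_nm
                + self.wavelength_step_nm * np.arange(self.n_bands))


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def class_base_spectra(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free mean reflectance spectra of the two tissue classes.

    The shared baseline is a sum of broad Gaussian bumps; the cancerous
    class adds ``class_contrast``-scaled bumps at 600 nm and 950 nm, i.e.
    exactly in the windows where trained models find their key wavelengths.
    ``contrast_window_weights`` weights the two bumps individually, so a
    cohort can carry class contrast in only one of the windows.
    Returns ``(non_malignant, cancerous)``, each of length ``n_bands``.
    """
    wl = config.wavelengths_nm
    w_low, w_high = config.contrast_window_weights
    baseline = (0.30
                + 0.25 * _gauss(wl, 760.0, 150.0)
                + 0.10 * _gauss(wl, 560.0, 60.0))
    delta = 0.05 * config.class_contrast * (
        w_low * _gauss(wl, 600.0, 35.0) + w_high * _gauss(wl, 950.0, 45.0))
    return baseline, baseline + delta


def _patient_seed(config: PhantomConfig, patient_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(patient_index,))
    return np.random.default_rng(ss)


def _smooth_blob(shape: tuple[int, int], center: tuple[float, float],
                 radius: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one smooth lesion blob via a low-order radial perturbation."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # low-frequency boundary wobble keeps the blob smooth but non-circular
    wobble = np.zeros_like(theta)
    for k in (2, 3):
        a = rng.normal(0.0, 0.08)
        b = rng.uniform(0.0, 2 * np.pi)
        wobble += a * np.cos(k * theta + b)
    return r <= radius * (1.0 + wobble)


def _plan_lesions(config: PhantomConfig, rng: np.random.Generator
                  ) -> list[tuple[tuple[float, float], float]]:
    """Choose lesion centers and radii targeting the configured imbalance.

    The labeled-pixel ratio equals the non-malignant : cancerous area ratio
    (annotation subsampling is class-blind), so the total lesion area is set
    to (A - margin) / (imbalance + 1), with the margin-ring area estimated
    from the planned perimeters.
    """
    area = config.height * config.width
    n_lesions = int(rng.integers(config.lesion_count_range[0],
                                 config.lesion_count_range[1] + 1))
    shares = rng.dirichlet(np.full(n_lesions, 4.0))
    w = config.margin_width_px

    lesion_area = area / (config.target_imbalance + 1.0)
    for _ in range(3):  # fixed-point refinement of the margin correction
        radii = np.sqrt(shares * lesion_area / np.pi)
        margin_area = float(np.sum(np.pi * ((radii + w) ** 2 - radii ** 2)))
        lesion_area = (area - margin_area) / (config.target_imbalance + 1.0)

    radii = np.sqrt(shares * lesion_area / np.pi)
    placed: list[tuple[tuple[float, float], float]] = []
    for r in radii:
        clearance = 1.15 * r + w + 1
        if 2 * clearance >= min(config.height, config.width):
            # lesion too large to keep off the border; center it
            center = (config.height / 2.0, config.width / 2.0)
            placed.append((center, r))
            continue
        for attempt in range(40):
            cy = rng.uniform(clearance, config.height - clearance)
            cx = rng.uniform(clearance, config.width - clearance)
            ok = all(np.hypot(cy - py, cx - px) > 1.2 * (r + pr) + w
                     for (py, px), pr in placed)
            if ok or attempt == 39:
                placed.append(((cy, cx), r))
                break
    return placed


def generate_patient_cube(config: PhantomConfig, patient_index: int
                          ) -> PatientPhantom:
    """Generate one synthetic patient record, deterministic in (seed, index).

    Reflectance is ``class spectrum x patient gain + patient offset +
    pixel noise``, clipped at zero.  Lesions are smooth random blobs; a ring
    of ``margin_width_px`` around each lesion is labeled MARGIN, and a
    class-blind random subset of the remaining pixels is left UNLABELED so
    that only ``annotated_fraction`` of them carry a class label.
    """
    if not (0 <= patient_index < config.n_patients):
        raise InvalidConfigError(
            f"patient_index {patient_index} outside [0, {config.n_patients})")
    rng = _patient_seed(config, patient_index)
    shape = (config.height, config.width)

    lesion = np.zeros(shape, dtype=bool)
    for center, radius in _plan_lesions(config, rng):
        lesion |= _smooth_blob(shape, center, radius, rng)

    labels = np.where(lesion, CANCEROUS, NONMALIGNANT).astype(np.uint8)
    if config.margin_width_px > 0:
        ring = ndimage.binary_dilation(
            lesion, iterations=config.margin_width_px) & ~lesion
        labels[ring] = MARGIN

    # class-blind partial annotation outside the margin ring
    if config.annotated_fraction < 1.0:
        candidates = labels != MARGIN
        drop = rng.random(shape) >= config.annotated_fraction
        labels[candidates & drop] = UNLABELED

    base_n, base_c = class_base_spectra(config)
    gain = 1.0 + rng.normal(0.0, config.patient_gain_sd)
    offset = rng.normal(0.0, config.patient_offset_sd)
    spectra = np.where(lesion[..., None], base_c, base_n)
    cube = spectra * gain + offset
    if config.pixel_noise_sd > 0:
        cube = cube + rng.normal(0.0, config.pixel_noise_sd,
                                 size=cube.shape)
    cube = np.clip(cube, 0.0, None).astype(np.float32)

    return PatientPhantom(
        patient_id=f"P{patient_index:03d}",
        cube=SpectralCube(cube, config.wavelengths_nm),
        mask=AnnotationMask(labels),
        true_lesion_field=lesion,
    )


def generate_cohort(config: PhantomConfig) -> list[PatientPhantom]:
    """Generate the full cohort; per-patient sub-seeds derive from the seed."""
    if config.n_patients < 2:
        raise InvalidConfigError("a cohort needs at least 2 patients")
    return [generate_patient_cube(config, i) for i in range(config.n_patients)]


def simulate_probability_map(phantom: PatientPhantom, sharpness: float = 2.5,
                             flip_rate: float = 0.1, seed: int = 0,
                             latent_noise_sd: float = 0.35) -> ProbabilityMap:
    """Emulate a pixel-wise classifier's probability map for one phantom.

    ``p = logistic(sharpness * (s + noise))`` with the signed latent class
    ``s in {-1, +1}`` and Gaussian latent noise; then exactly
    ``round(flip_rate * n_pixels)`` randomly chosen pixels are replaced by
    ``1 - p``, emulating the salt-and-pepper speckle of raw prediction maps.
    """
    if sharpness <= 0:
        raise InvalidConfigError("sharpness must be > 0")
    if not (0.0 <= flip_rate < 1.0):
        raise InvalidConfigError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    s = np.where(phantom.true_lesion_field, 1.0, -1.0)
    z = sharpness * (s + rng.normal(0.0, latent_noise_sd, size=s.shape))
    p = expit(z)

    n_flip = int(round(flip_rate * p.size))
    if n_flip:
        idx = rng.choice(p.size, size=n_flip, replace=False)
        flat = p.ravel()
        flat[idx] = 1.0 - flat[idx]
        p = flat.reshape(p.shape)

    return ProbabilityMap(probs=p, valid=phantom.mask.class_pixels(),
                          patient_id=phantom.patient_id)
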