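"""Core in-memory containers shared by every stage of the pipeline.

A hyperspectral record is a reflectance datacube (height x width x bands)
with an explicit wavelength axis, plus a per-pixel annotation mask.  Mask
labels follow a fixed integer code so that masks can round-trip through
HDF5 and PNG without a side table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Annotation label codes (stable on-disk contract).
UNLABELED = 0
NONMALIGNANT = 1
CANCEROUS = 2
MARGIN = 3

#: PNG color scheme for masks: purple = non-malignant, yellow = cancerous,
#: red = margin ring, black = unlabeled.
LABEL_COLORS = {
    UNLABELED: (0, 0, 0),
    NONMALIGNANT: (128, 0, 128),
    CANCEROUS: (255, 255, 0),
    MARGIN: (255, 0, 0),
}


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass
class SpectralCube:
    """A reflectance datacube with its wavelength axis.

    Parameters
    ----------
    values
        Array of shape ``(height, width, n_bands)``, reflectance >= 0.
    wavelengths_nm
        Strictly increasing wavelength per band, in nanometres.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise InvalidInputError(
                f"cube must be 3-D (H, W, B), got shape {self.values.shape}"
            )
        if self.values.shape[2] != self.wavelengths_nm.shape[0]:
            raise InvalidInputError(
                "band count does not match wavelength axis: "
                f"{self.values.shape[2]} vs {self.wavelengths_nm.shape[0]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise InvalidInputError("wavelength axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class AnnotationMask:
    """Per-pixel ground-truth labels aligned to a cube."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        if self.labels.max(initial=0) > MARGIN:
            raise InvalidInputError("mask contains unknown label codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_pixels(self) -> np.ndarray:
        """Boolean map of pixels carrying a binary class label (1 or 2)."""
        return (self.labels == NONMALIGNANT) | (self.labels == CANCEROUS)

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


@dataclass
class ProbabilityMap:
    """Per-pixel cancer probability for one patient.

    ``valid`` marks the pixels that carry a binary class label and therefore
    enter metric computation; the probability itself is defined everywhere.
    """

    probs: np.ndarray
    valid: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.probs.ndim != 2 or self.probs.shape != self.valid.shape:
            raise InvalidInputError("probability map and validity mask misaligned")
        if self.probs.min(initial=0.0) < 0.0 or self.probs.max(initial=0.0) > 1.0:
            raise InvalidInputError("probabilities must lie in [0, 1]")


@dataclass
class PatientPhantom:
    """One synthetic patient record: cube, mask, and the latent truth.

    ``true_lesion_field`` is the per-pixel latent cancer indicator, defined
    also at pixels the mask leaves unlabeled (it is what the probability-map
    simulator sees).
    """

    patient_id: str
    cube: SpectralCube
    mask: AnnotationMask
    true_lesion_field: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.cube.shape[:2] != self.mask.shape:
            raise InvalidInputError("cube and mask spatial dimensions differ")
        if self.true_lesion_field is not None:
            self.true_lesion_field = np.asarray(self.true_lesion_field, dtype=bool)
            if self.true_lesion_field.shape != self.mask.shape:
                raise InvalidInputError("latent field misaligned with mask")
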