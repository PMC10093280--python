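"""On-disk formats: HDF5 patient containers, PNG masks, maps and models.

One HDF5 container per patient holds the cube (H x W x B float32), the mask
(H x W uint8 with the fixed label codes) and the wavelength axis plus
metadata as attributes.  Masks can additionally round-trip through PNG with
the standard color scheme (purple non-malignant / yellow cancerous / red
margin / black unlabeled).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from . import nn
from .containers import (
    LABEL_COLORS,
    AnnotationMask,
    PatientPhantom,
    ProbabilityMap,
    SpectralCube,
)
from .models import ArchitectureSpec, build_model


class ContainerFormatError(ValueError):
    """A container file is missing a required dataset or attribute."""


def write_patient_container(phantom: PatientPhantom, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=phantom.cube.values.astype(np.float32))
        f.create_dataset("mask", data=phantom.mask.labels)
        if phantom.true_lesion_field is not None:
            f.create_dataset("true_lesion_field",
                             data=phantom.true_lesion_field.astype(np.uint8))
        f.attrs["wavelengths_nm"] = phantom.cube.wavelengths_nm
        f.attrs["patient_id"] = phantom.patient_id


def read_patient_container(path) -> PatientPhantom:
    with h5py.File(path, "r") as f:
        for name in ("cube", "mask"):
            if name not in f:
                raise ContainerFormatError(
                    f"{path}: missing dataset {name!r}")
        for attr in ("wavelengths_nm", "patient_id"):
            if attr not in f.attrs:
                raise ContainerFormatError(
                    f"{path}: missing attribute {attr!r}")
        latent = (np.asarray(f["true_lesion_field"]).astype(bool)
                  if "true_lesion_field" in f else None)
        return PatientPhantom(
            patient_id=str(f.attrs["patient_id"]),
            cube=SpectralCube(np.asarray(f["cube"]),
                              np.asarray(f.attrs["wavelengths_nm"])),
            mask=AnnotationMask(np.asarray(f["mask"])),
            true_lesion_field=latent,
        )


def write_cohort(cohort: list[PatientPhantom], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for phantom in cohort:
        p = directory / f"{phantom.patient_id}.h5"
        write_patient_container(phantom, p)
        paths.append(p)
    return paths


def read_cohort(directory) -> list[PatientPhantom]:
    paths = sorted(Path(directory).glob("*.h5"))
    if not paths:
        raise ContainerFormatError(f"no patient containers in {directory}")
    return [read_patient_container(p) for p in paths]


def mask_to_png(mask: AnnotationMask, path) -> None:
    """Export a mask with the standard color scheme."""
    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    for label, color in LABEL_COLORS.items():
        rgb[mask.labels == label] = color
    Image.fromarray(rgb).save(path, format="PNG")


def png_to_mask(path) -> AnnotationMask:
    """Re-import a color-coded mask PNG to the integer label grid."""
    rgb = np.asarray(Image.open(path).convert("RGB"))
    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    matched = np.zeros(rgb.shape[:2], dtype=bool)
    for label, color in LABEL_COLORS.items():
        hit = np.all(rgb == color, axis=-1)
        labels[hit] = label
        matched |= hit
    if not matched.all():
        raise ContainerFormatError(f"{path}: pixels with unknown colors")
    return AnnotationMask(labels)


def write_probability_map(pm: ProbabilityMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("probs", data=pm.probs)
        f.create_dataset("valid", data=pm.valid.astype(np.uint8))
        f.attrs["patient_id"] = pm.patient_id


def read_probability_map(path) -> ProbabilityMap:
    with h5py.File(path, "r") as f:
        for name in ("probs", "valid"):
            if name not in f:
                raise ContainerFormatError(f"{path}: missing dataset {name!r}")
        return ProbabilityMap(probs=np.asarray(f["probs"]),
                              valid=np.asarray(f["valid"]).astype(bool),
                              patient_id=str(f.attrs.get("patient_id", "")))


def save_model(model: nn.Network, path) -> None:
    """Serialize a trained classifier with its architecture spec embedded."""
    spec = model.spec
    meta = {
        "name": spec.name,
        "input_shape": list(spec.input_shape),
        "branch_kernel_sizes": list(spec.branch_kernel_sizes),
        "dropout_rate": spec.dropout_rate,
        "width_scale": spec.width_scale,
        "init_seed": spec.init_seed,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, spec_json=np.bytes_(json.dumps(meta)), **arrays)


def load_model(path) -> nn.Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["spec_json"]).decode())
        spec = ArchitectureSpec(
            name=meta["name"],
            input_shape=tuple(meta["input_shape"]),
            branch_kernel_sizes=tuple(meta["branch_kernel_sizes"]),
            dropout_rate=meta["dropout_rate"],
            width_scale=meta["width_scale"],
            init_seed=meta["init_seed"],
        )
        model = build_model(spec)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
    return model


def history_to_csv(history: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)
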