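"""Intensity normalization and atlas-based ROI extraction for aligned PET volumes.

Volumes are assumed to already live on a common voxel grid (spatial
normalization is upstream and out of scope here). The operations are

* :func:`intensity_normalize` -- divide a volume by the mean intensity of the
  voxels falling in the 40--90% band of the maximum voxel intensity, the
  standard reference-free normalization for FDG uptake maps;
* :func:`extract_roi_means` -- mean uptake per labelled region;
* :func:`global_mean` -- mean uptake over the brain mask (all nonzero labels),
  used downstream as a nuisance covariate in the voxel-wise model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PETVolume",
    "ROIAtlas",
    "intensity_normalize",
    "extract_roi_means",
    "global_mean",
    "load_volume",
    "save_volume",
    "load_atlas",
    "save_atlas",
]

BAND_LOW = 0.4
BAND_HIGH = 0.9


@dataclass
class PETVolume:
    """A 3-D PET intensity grid with its voxel-to-mm affine.

    ``units`` is ``"SUV"`` for raw standardized-uptake-value maps and
    ``"normalized"`` after intensity normalization.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = "SUV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"PETVolume data must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PETVolume data contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")


@dataclass
class ROIAtlas:
    """Integer label grid plus a label -> region-name map."""

    labels: np.ndarray
    name_map: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be nonnegative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.name_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in grid but absent from name_map")
        self.name_map = {int(k): str(v) for k, v in self.name_map.items()}

    @property
    def region_names(self) -> list[str]:
        return [self.name_map[k] for k in sorted(self.name_map)]


def intensity_normalize(vol: PETVolume) -> PETVolume:
    """Divide every voxel by the mean of the 40--90%-of-max intensity band.

    The band mask ``B = {v : 0.4*max <= v <= 0.9*max}`` is computed on the
    *input* volume (bounds inclusive); the output is tagged ``normalized`` and
    its mean over ``B`` is exactly 1 up to floating round-off.  The operation
    is invariant to any positive rescaling of the input, which is the point:
    it removes arbitrary per-subject intensity scale.
    """
    data = vol.data
    vmax = data.max()
    if vmax <= 0:
        raise ValueError("intensity_normalize: maximum voxel intensity is not positive")
    band = (data >= BAND_LOW * vmax) & (data <= BAND_HIGH * vmax)
    if not band.any():
        raise ValueError(
            "intensity_normalize: empty 40-90%-of-max band "
            "(e.g. a constant volume has every voxel above 0.9*max)"
        )
    band_mean = data[band].mean()
    return PETVolume(data=data / band_mean, affine=vol.affine.copy(), units="normalized")


def _check_shapes(vol: PETVolume, atlas: ROIAtlas) -> None:
    if vol.data.shape != atlas.labels.shape:
        raise ValueError(
            f"volume shape {vol.data.shape} does not match atlas shape {atlas.labels.shape}"
        )


def extract_roi_means(vol: PETVolume, atlas: ROIAtlas) -> dict[str, float]:
    """Arithmetic mean of the volume over each named atlas region."""
    _check_shapes(vol, atlas)
    out: dict[str, float] = {}
    for label in sorted(atlas.name_map):
        mask = atlas.labels == label
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"region '{atlas.name_map[label]}' (label {label}) has zero voxels")
        out[atlas.name_map[label]] = float(vol.data[mask].mean())
    return out


def global_mean(vol: PETVolume, atlas: ROIAtlas) -> float:
    """Mean uptake over the brain mask (every voxel with a nonzero label)."""
    _check_shapes(vol, atlas)
    mask = atlas.labels > 0
    if not mask.any():
        raise ValueError("global_mean: brain mask (nonzero atlas labels) is empty")
    return float(vol.data[mask].mean())


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(vol: PETVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header["descrip"] = vol.units.encode()[:79]
    nib.save(img, str(path))


def load_volume(path: str | Path, units: str = "SUV") -> PETVolume:
    img = nib.load(str(path))
    return PETVolume(data=np.asarray(img.get_fdata(), dtype=float), affine=img.affine, units=units)


def save_atlas(atlas: ROIAtlas, path: str | Path) -> None:
    """Write label grid as NIfTI plus a ``<stem>_labels.json`` name sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, str(path))
    stem = path.name
    for suff in (".nii.gz", ".nii"):
        if stem.endswith(suff):
            stem = stem[: -len(suff)]
            break
    sidecar = path.parent / f"{stem}_labels.json"
    sidecar.write_text(json.dumps({str(k): v for k, v in atlas.name_map.items()}, indent=1))


def load_atlas(path: str | Path) -> ROIAtlas:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    stem = path.name
    for suff in (".nii.gz", ".nii"):
        if stem.endswith(suff):
            stem = stem[: -len(suff)]
            break
    sidecar = path.parent / f"{stem}_labels.json"
    name_map = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return ROIAtlas(labels=labels, name_map=name_map, affine=img.affine)
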