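"""In-memory containers for image volumes and tissue masks, with NIfTI I/O.

All volumes in one cohort live on a single shared grid; spatial registration
is assumed to have happened upstream, so a shape mismatch is a hard error
rather than a resampling trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: Integer codes used in the label volume emitted by the synthetic generator.
LABEL_CODES = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "lesion": 4}

RAW_MODALITIES = ("t1w", "t2w")
MODALITIES = RAW_MODALITIES + ("ratio", "st_ratio", "field")


class VolumeError(ValueError):
    """An image volume or mask set violates its invariants."""


@dataclass
class ImageVolume:
    """One 3D scalar modality volume on a fixed grid.

    ``modality`` is one of ``t1w``, ``t2w``, ``ratio``, ``st_ratio`` or
    ``field``; raw modalities must be non-negative and all values finite.
    """

    data: np.ndarray
    voxel_size_mm: float
    modality: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError("volume must be 3D")
        if self.modality not in MODALITIES:
            raise VolumeError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite values")
        if self.modality in RAW_MODALITIES and np.any(self.data < 0):
            raise VolumeError(f"{self.modality} volume must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def _affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff

    def save_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self._affine())
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path: str | Path, modality: str) -> "ImageVolume":
        img = nib.load(str(path))
        voxel = float(img.header.get_zooms()[0])
        return cls(np.asanyarray(img.dataobj), voxel, modality)


def _as_bool(mask: np.ndarray, name: str, shape: tuple) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.shape != shape:
        raise VolumeError(f"mask {name} shape {arr.shape} != {shape}")
    return arr.astype(bool)


@dataclass
class TissueMaskSet:
    """Boolean brain/GM/WM/CSF/lesion masks plus derived NAGM/NAWM.

    The WM and GM masks include any lesion voxels falling inside them; the
    normal-appearing masks are the lesion-subtracted versions and are filled
    in by :func:`st1t2.preprocess.make_na_masks`.
    """

    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    lesion: np.ndarray
    nagm: np.ndarray | None = None
    nawm: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = np.asarray(self.brain).shape
        self.brain = _as_bool(self.brain, "brain", shape)
        for name in ("gm", "wm", "csf", "lesion"):
            setattr(self, name, _as_bool(getattr(self, name), name, shape))
        for name in ("nagm", "nawm"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, _as_bool(val, name, shape))

    @property
    def shape(self) -> tuple:
        return self.brain.shape

    def validate(self) -> None:
        for name in ("gm", "wm", "csf", "lesion"):
            if np.any(getattr(self, name) & ~self.brain):
                raise VolumeError(f"{name} mask extends outside brain")
        for a, b in (("gm", "wm"), ("gm", "csf"), ("wm", "csf")):
            if np.any(getattr(self, a) & getattr(self, b)):
                raise VolumeError(f"{a} and {b} masks overlap")
        if self.nagm is not None and np.any(self.nagm != (self.gm & ~self.lesion)):
            raise VolumeError("nagm is not gm minus lesion")
        if self.nawm is not None and np.any(self.nawm != (self.wm & ~self.lesion)):
            raise VolumeError("nawm is not wm minus lesion")

    def to_labels(self) -> np.ndarray:
        """Collapse to an integer label volume (lesion code wins over WM/GM)."""
        labels = np.zeros(self.shape, dtype=np.uint8)
        labels[self.csf] = LABEL_CODES["csf"]
        labels[self.gm] = LABEL_CODES["gm"]
        labels[self.wm] = LABEL_CODES["wm"]
        labels[self.lesion] = LABEL_CODES["lesion"]
        return labels

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "TissueMaskSet":
        """Split an integer label volume into masks.

        Lesion voxels are counted as white matter underneath, which is where
        the synthetic generator places them; the brain mask is the union of
        all non-background codes.
        """
        labels = np.asarray(labels)
        lesion = labels == LABEL_CODES["lesion"]
        wm = (labels == LABEL_CODES["wm"]) | lesion
        gm = labels == LABEL_CODES["gm"]
        csf = labels == LABEL_CODES["csf"]
        brain = labels != LABEL_CODES["background"]
        return cls(brain=brain, gm=gm, wm=wm, csf=csf, lesion=lesion)

    def save_labels_nifti(self, path: str | Path, voxel_size_mm: float) -> None:
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.to_labels(), aff), str(path))

    @classmethod
    def load_labels_nifti(cls, path: str | Path) -> "TissueMaskSet":
        img = nib.load(str(path))
        return cls.from_labels(np.asanyarray(img.dataobj))
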