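"""T1w/T2w ratio, standardized sT1w/T2w ratio, and tissue median extraction.

The classic ratio is the voxelwise T1w / T2w quotient. The standardized
variant rescales the T2w image by the scaling factor

    scaling_factor = median(T1w over NAGM) / median(T2w over NAGM)

to form sT2, then maps each voxel to (T1w - sT2) / (T1w + sT2). On voxels
with strictly positive inputs this lies in (-1, 1): gray matter near 0,
white matter positive, CSF negative. Because the scaling factor rescales by
the ratio of any global per-modality gains, the sT1w/T2w map is exactly
invariant to such gains, which is the mechanism behind its reduced
between-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, TissueMaskSet, VolumeError

MEASURES = ("t1w", "t2w", "t1t2", "st1t2")
REGIONS = ("nagm", "nawm", "csf")


class DegenerateRegionError(ValueError):
    """A region has no valid voxels to take a median over."""


@dataclass
class RatioMaps:
    """Per-subject ratio maps; invalid voxels are zeroed and excluded."""

    t1t2: np.ndarray
    st1t2: np.ndarray
    scaling_factor: float
    valid_mask: np.ndarray


@dataclass
class TissueMedians:
    """Median of each measure (T1w, T2w, T1w/T2w, sT1w/T2w) per region."""

    subject_id: str
    values: dict  # keys (measure, region)

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        for (measure, region), v in self.values.items():
            row[f"{measure}_{region}"] = v
        return row


def _masked_median(data: np.ndarray, mask: np.ndarray, what: str) -> float:
    if not mask.any():
        raise DegenerateRegionError(f"no valid voxels for {what}")
    return float(np.median(data[mask]))


def default_eps(denom: np.ndarray, brain: np.ndarray, rel: float = 1e-6) -> float:
    """Denominator guard: a small fraction of the median brain intensity."""
    return rel * float(np.median(denom[brain]))


def compute_scaling_factor(t1w: ImageVolume, t2w: ImageVolume, nagm: np.ndarray) -> float:
    """Median NAGM T1w intensity divided by median NAGM T2w intensity.

    NAGM (lesion-excluded gray matter) anchors the standardization so that
    gray-matter lesions cannot drag the scaling.
    """
    nagm = np.asarray(nagm, dtype=bool)
    if not nagm.any():
        raise DegenerateRegionError("empty NAGM mask")
    med1 = float(np.median(t1w.data[nagm]))
    med2 = float(np.median(t2w.data[nagm]))
    if med1 <= 0 or med2 <= 0:
        raise VolumeError("non-positive NAGM median; corrupt input")
    return med1 / med2


def compute_t1t2_ratio(
    t1w: ImageVolume, t2w: ImageVolume, brain: np.ndarray, eps: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise T1w / T2w inside the brain; guarded against tiny denominators.

    Returns (map, valid_mask); voxels with T2w <= eps are excluded, not
    infinite.
    """
    brain = np.asarray(brain, dtype=bool)
    if t1w.shape != t2w.shape or brain.shape != t1w.shape:
        raise VolumeError("T1w, T2w and brain mask must share one grid")
    if eps is None:
        eps = default_eps(t2w.data, brain)
    valid = brain & (t2w.data > eps)
    out = np.zeros(t1w.shape)
    out[valid] = t1w.data[valid] / t2w.data[valid]
    return out, valid


def compute_st1t2_ratio(
    t1w: ImageVolume,
    t2w: ImageVolume,
    scaling_factor: float,
    brain: np.ndarray,
    eps: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise (T1w - sT2) / (T1w + sT2) with sT2 = scaling_factor * T2w."""
    if scaling_factor <= 0:
        raise ValueError("scaling factor must be strictly positive")
    brain = np.asarray(brain, dtype=bool)
    if t1w.shape != t2w.shape or brain.shape != t1w.shape:
        raise VolumeError("T1w, T2w and brain mask must share one grid")
    st2 = scaling_factor * t2w.data
    denom = t1w.data + st2
    if eps is None:
        eps = default_eps(denom, brain)
    valid = brain & (denom > eps)
    out = np.zeros(t1w.shape)
    out[valid] = (t1w.data[valid] - st2[valid]) / denom[valid]
    return out, valid


def compute_ratio_maps(
    t1w: ImageVolume,
    t2w: ImageVolume,
    masks: TissueMaskSet,
    eps_rel: float = 1e-6,
) -> RatioMaps:
    """Both ratio maps for one subject; valid where both maps are defined."""
    if masks.nagm is None:
        raise VolumeError("masks must carry NAGM (run make_na_masks first)")
    scaling = compute_scaling_factor(t1w, t2w, masks.nagm)
    ratio, valid_r = compute_t1t2_ratio(
        t1w, t2w, masks.brain, eps=default_eps(t2w.data, masks.brain, eps_rel)
    )
    denom = t1w.data + scaling * t2w.data
    st, valid_s = compute_st1t2_ratio(
        t1w, t2w, scaling, masks.brain, eps=default_eps(denom, masks.brain, eps_rel)
    )
    valid = valid_r & valid_s
    ratio[~valid] = 0.0
    st[~valid] = 0.0
    return RatioMaps(t1t2=ratio, st1t2=st, scaling_factor=scaling, valid_mask=valid)


def extract_tissue_medians(
    subject_id: str,
    t1w: ImageVolume,
    t2w: ImageVolume,
    maps: RatioMaps,
    masks: TissueMaskSet,
) -> TissueMedians:
    """Median of each measure over NAGM, NAWM and CSF.

    Ratio measures are restricted to the maps' valid voxels before the
    median; raw modality medians use the full region.
    """
    if masks.nagm is None or masks.nawm is None:
        raise VolumeError("masks must carry NAGM/NAWM (run make_na_masks first)")
    regions = {"nagm": masks.nagm, "nawm": masks.nawm, "csf": masks.csf}
    values: dict = {}
    for region, rmask in regions.items():
        values[("t1w", region)] = _masked_median(t1w.data, rmask, f"t1w/{region}")
        values[("t2w", region)] = _masked_median(t2w.data, rmask, f"t2w/{region}")
        vmask = rmask & maps.valid_mask
        values[("t1t2", region)] = _masked_median(maps.t1t2, vmask, f"t1t2/{region}")
        values[("st1t2", region)] = _masked_median(maps.st1t2, vmask, f"st1t2/{region}")
    if any(not np.isfinite(v) for v in values.values()):
        raise VolumeError("non-finite tissue median")
    return TissueMedians(subject_id=subject_id, values=values)
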