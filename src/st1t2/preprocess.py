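"""Bias-field correction and lesion-aware mask arithmetic.

The bias corrector is a self-contained log-domain polynomial fit: the log
intensity inside the brain is regressed on a 3D polynomial basis (default
total degree 2) and the exponentiated fit, normalized to unit mean over the
brain, is divided out. When a tissue partition is supplied, per-tissue
intercept columns absorb the piecewise tissue contrast so the polynomial
part captures only the smooth multiplicative field.
"""

from __future__ import annotations

import logging

import numpy as np

from .volume import ImageVolume, TissueMaskSet, VolumeError

log = logging.getLogger(__name__)


class UnderdeterminedFitError(RuntimeError):
    """Fewer fit voxels than basis terms."""


def polynomial_exponents(degree: int, include_constant: bool = True):
    """Monomial exponent triples (i, j, k) with total degree <= ``degree``."""
    exps = [
        (i, j, k)
        for i in range(degree + 1)
        for j in range(degree + 1)
        for k in range(degree + 1)
        if i + j + k <= degree
    ]
    exps.sort(key=lambda e: (sum(e), e))
    if not include_constant:
        exps = [e for e in exps if sum(e) > 0]
    return exps


def _basis_volumes(shape, exponents):
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij", sparse=True
    )
    return [grids[0] ** i * grids[1] ** j * grids[2] ** k for (i, j, k) in exponents]


def estimate_bias_field(
    volume: ImageVolume,
    brain: np.ndarray,
    degree: int = 2,
    tissue_masks=None,
) -> ImageVolume:
    """Estimate a smooth multiplicative bias field inside the brain.

    Least-squares fit of log intensity to a 3D polynomial basis of the given
    total degree; the returned field is the exponentiated polynomial part,
    rescaled so its mean over the brain is exactly 1. Voxels with value <= 0
    inside the brain are excluded from the fit (and logged), not clamped.

    ``tissue_masks``, if given, is a sequence of disjoint boolean masks (for
    example CSF / NAGM / NAWM / lesion); each contributes an intercept column
    so the tissue piecewise levels do not leak into the field estimate, and
    the fit is restricted to their union.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != volume.shape:
        raise VolumeError("brain mask shape does not match volume")
    vals = volume.data
    fit_mask = brain & (vals > 0)
    excluded = int(brain.sum() - fit_mask.sum())
    if excluded:
        log.warning("stage=preprocess event=nonpositive_voxels_excluded value=%d", excluded)

    if tissue_masks is not None:
        union = np.zeros(volume.shape, dtype=bool)
        for m in tissue_masks:
            union |= np.asarray(m, dtype=bool)
        fit_mask &= union
        exponents = polynomial_exponents(degree, include_constant=False)
    else:
        exponents = polynomial_exponents(degree, include_constant=True)

    basis = _basis_volumes(volume.shape, exponents)
    columns = [b if b.shape == volume.shape else np.broadcast_to(b, volume.shape) for b in basis]
    design = [c[fit_mask] for c in columns]
    if tissue_masks is not None:
        for m in tissue_masks:
            dummy = np.asarray(m, dtype=bool)[fit_mask].astype(np.float64)
            if dummy.any():
                design.append(dummy)
    X = np.column_stack(design)
    if X.shape[0] < X.shape[1]:
        raise UnderdeterminedFitError(
            f"{X.shape[0]} fit voxels for {X.shape[1]} basis terms"
        )
    beta, *_ = np.linalg.lstsq(X, np.log(vals[fit_mask]), rcond=None)

    log_field = np.zeros(volume.shape)
    for b, c in zip(beta[: len(columns)], columns):
        log_field = log_field + b * c
    field = np.exp(log_field)
    field = field / field[brain].mean()
    return ImageVolume(field, volume.voxel_size_mm, "field")


def correct_bias(volume: ImageVolume, field: ImageVolume, brain: np.ndarray) -> ImageVolume:
    """Divide the volume by the field inside the brain; pass through outside."""
    brain = np.asarray(brain, dtype=bool)
    if field.shape != volume.shape or brain.shape != volume.shape:
        raise VolumeError("volume, field and brain mask must share one grid")
    if np.any(field.data[brain] <= 0):
        raise VolumeError("bias field must be strictly positive inside brain")
    out = volume.data.copy()
    out[brain] = out[brain] / field.data[brain]
    return volume.with_data(out)


def make_na_masks(masks: TissueMaskSet) -> TissueMaskSet:
    """Subtract the lesion mask from WM and GM to form NAWM and NAGM."""
    masks.validate()
    nawm = masks.wm & ~masks.lesion
    nagm = masks.gm & ~masks.lesion
    if not nawm.any() or not nagm.any():
        raise VolumeError("degenerate segmentation: empty NAWM or NAGM")
    log.info(
        "stage=preprocess event=na_masks nagm=%d nawm=%d lesion=%d",
        int(nagm.sum()),
        int(nawm.sum()),
        int(masks.lesion.sum()),
    )
    out = TissueMaskSet(
        brain=masks.brain,
        gm=masks.gm,
        wm=masks.wm,
        csf=masks.csf,
        lesion=masks.lesion,
        nagm=nagm,
        nawm=nawm,
    )
    out.validate()
    return out
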