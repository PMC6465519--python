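"""Fully synthetic two-group MRI cohort: subject table, phantoms, intensities.

The generator emulates the cohort structure the downstream analysis assumes:
sex- and age-matched patient/control pairs, overdispersed T2 lesion counts,
lognormal lesion volumes, per-subject multiplicative scanner gains, smooth
multiplicative bias fields, additive Gaussian noise, and a NAWM sT1w/T2w
median implanted through the white-matter T1w mean so that the T2w gray
matter anchor used by the scaling factor stays group-neutral.

Every random draw is keyed to the single configured seed plus a stage code
and a CRC of the subject id, so any subject can be regenerated independently.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import GeneratorConfig, InvalidConfigError
from .volume import ImageVolume, TissueMaskSet

_STAGE_TABLE = 1
_STAGE_LABELS = 2
_STAGE_RENDER = 3

#: Column order of the cohort subject table (TSV header).
SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "head_size_scale",
    "edss",
    "disease_duration_months",
    "lesion_volume_ml",
    "lesion_count",
]

# Brain ellipsoid semi-axes as fractions of the half grid extent, and the
# normalized radii of the nested CSF core / WM interior / GM shell.
_SEMI_AXES = (0.84, 0.74, 0.70)
_R_CSF = 0.35
_R_WM = 0.75


class InfeasiblePhantomError(RuntimeError):
    """The requested lesion load cannot be placed inside the phantom WM."""


def _subject_rng(seed: int, stage: int, subject_id: str) -> np.random.Generator:
    key = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, key]))


def _sample_counts(moments, n: int, rng: np.random.Generator) -> np.ndarray:
    """Counts from a moment-matched negative binomial, Poisson fallback.

    The negative binomial handles the overdispersion of MS lesion counts
    (variance far above the mean); when the configured variance does not
    exceed the mean a Poisson with the configured mean is used instead.
    """
    mean, sd = float(moments[0]), float(moments[1])
    if mean < 0:
        raise InvalidConfigError("lesion count mean must be >= 0")
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    var = sd * sd
    if var > mean:
        r = mean * mean / (var - mean)
        p = mean / var
        return rng.negative_binomial(r, p, size=n).astype(np.int64)
    return rng.poisson(mean, size=n).astype(np.int64)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def _truncnorm(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_subject_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the paired MS/HC subject table.

    Each MS subject has an HC partner of identical sex and age within
    ±0.5 years. Lesion counts come from a moment-matched negative binomial
    per group, volumes from a moment-matched lognormal; EDSS lives on the
    0.5 grid and, like disease duration, is absent for controls.
    """
    config.validate()
    if config.seed is None:
        raise InvalidConfigError("generate_subject_table requires a seed")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _STAGE_TABLE]))
    n = config.n_per_group
    lo, hi = config.age_range

    ages_ms = _truncnorm(config.age_mean, config.age_sd, lo, hi, n, rng)
    ages_hc = np.clip(ages_ms + rng.uniform(-0.5, 0.5, n), lo, hi)
    sexes = np.array(["F"] * config.female_count + ["M"] * (n - config.female_count))

    def head_sizes(sex_arr):
        base = np.where(
            sex_arr == "F",
            config.head_size_mean + config.head_size_sex_gap / 2,
            config.head_size_mean - config.head_size_sex_gap / 2,
        )
        return np.clip(base + rng.normal(0.0, config.head_size_sd, len(sex_arr)), 1.0, 1.6)

    head_ms = head_sizes(sexes)
    head_hc = head_sizes(sexes)

    elo, ehi = config.edss_range
    edss = np.clip(np.round(_truncnorm(2.0, 1.5, elo, ehi, n, rng) * 2) / 2, elo, ehi)
    dmu, dsigma = _lognormal_params(*config.duration_moments)
    duration = rng.lognormal(dmu, dsigma, n)

    def lesions(group, size):
        counts = _sample_counts(config.lesion_count_moments[group], size, rng)
        vols = np.zeros(size)
        vmean, vsd = config.lesion_volume_moments[group]
        pos = counts > 0
        if pos.any():
            mu, sigma = _lognormal_params(vmean, vsd)
            vols[pos] = np.maximum(rng.lognormal(mu, sigma, int(pos.sum())), 1e-3)
        return counts, vols

    counts_ms, vols_ms = lesions("MS", n)
    counts_hc, vols_hc = lesions("HC", n)

    width = max(2, len(str(n)))
    rows = []
    for i in range(n):
        rows.append(
            {
                "subject_id": f"MS{i + 1:0{width}d}",
                "group": "MS",
                "age": round(float(ages_ms[i]), 2),
                "sex": sexes[i],
                "head_size_scale": round(float(head_ms[i]), 4),
                "edss": float(edss[i]),
                "disease_duration_months": round(float(duration[i]), 1),
                "lesion_volume_ml": round(float(vols_ms[i]), 3),
                "lesion_count": int(counts_ms[i]),
            }
        )
    for i in range(n):
        rows.append(
            {
                "subject_id": f"HC{i + 1:0{width}d}",
                "group": "HC",
                "age": round(float(ages_hc[i]), 2),
                "sex": sexes[i],
                "head_size_scale": round(float(head_hc[i]), 4),
                "edss": np.nan,
                "disease_duration_months": np.nan,
                "lesion_volume_ml": round(float(vols_hc[i]), 3),
                "lesion_count": int(counts_hc[i]),
            }
        )
    table = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    if config.missing_head_size and len(table) > 0:
        table.loc[0, "head_size_scale"] = np.nan
    return table


def _normalized_radius(shape, head_size_scale: float, head_size_mean: float):
    """Ellipsoidal radius field, 1.0 on the brain surface."""
    scale = (head_size_mean / head_size_scale) ** (1.0 / 3.0)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij", sparse=True
    )
    r2 = sum(
        (g / (f * scale)) ** 2 for g, f in zip(grids, _SEMI_AXES)
    )
    return np.sqrt(r2)


def _place_lesions(
    wm: np.ndarray, count: int, target_voxels: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow ``count`` compact blobs covering exactly ``target_voxels`` WM voxels."""
    coords = np.argwhere(wm).astype(np.float64)
    m = len(coords)
    if target_voxels > m:
        raise InfeasiblePhantomError(
            f"lesion load of {target_voxels} voxels exceeds WM ({m} voxels)"
        )
    weights = rng.lognormal(0.0, 0.5, count)
    alloc = np.maximum(1, np.round(target_voxels * weights / weights.sum())).astype(int)
    # largest-remainder style fixup so allocations sum exactly to the target
    while alloc.sum() > target_voxels:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < target_voxels:
        alloc[np.argmin(alloc)] += 1

    available = np.ones(m, dtype=bool)
    taken = np.zeros(m, dtype=bool)
    for n_i in alloc:
        free = np.flatnonzero(available)
        center = coords[rng.choice(free)]
        d2 = np.square(coords - center).sum(axis=1)
        d2[~available] = np.inf
        chosen = np.argpartition(d2, n_i - 1)[:n_i]
        taken[chosen] = True
        available[chosen] = False

    lesion = np.zeros(wm.shape, dtype=bool)
    idx = np.argwhere(wm)[taken]
    lesion[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return lesion


def generate_label_volume(record, config: GeneratorConfig) -> TissueMaskSet:
    """Geometric phantom for one subject: ellipsoidal brain with a CSF core,
    WM interior, GM shell, and the record's lesion load as compact WM blobs.

    The total lesion voxel volume matches ``lesion_volume_ml`` to rounding
    (floored at one voxel per lesion); ``head_size_scale`` shrinks or grows
    the ellipsoid radii as an inverse-cube-root head-size analog.
    """
    config.validate()
    if config.seed is None:
        raise InvalidConfigError("generate_label_volume requires a seed")
    rng = _subject_rng(config.seed, _STAGE_LABELS, record["subject_id"])
    r = _normalized_radius(config.grid_shape, record["head_size_scale"], config.head_size_mean)
    brain = r <= 1.0
    csf = r <= _R_CSF
    wm = (r > _R_CSF) & (r <= _R_WM)
    gm = (r > _R_WM) & brain

    count = int(record["lesion_count"])
    lesion = np.zeros(brain.shape, dtype=bool)
    if count > 0:
        target = int(round(record["lesion_volume_ml"] * 1000.0 / config.voxel_volume_mm3))
        target = max(target, count)
        lesion = _place_lesions(wm, count, target, rng)

    masks = TissueMaskSet(brain=brain, gm=gm, wm=wm, csf=csf, lesion=lesion)
    masks.validate()
    return masks


def implanted_st_median(record, config: GeneratorConfig) -> float:
    """Target NAWM sT1w/T2w median s* for one subject record."""
    s = (
        config.baseline_st
        + config.effect_ms * (record["group"] == "MS")
        + config.effect_age * (record["age"] - config.age_mean)
        + config.effect_lesion_count * record["lesion_count"]
    )
    return float(s)


def _bias_poly_exponents(degree: int = 2):
    return [
        (i, j, k)
        for i in range(degree + 1)
        for j in range(degree + 1)
        for k in range(degree + 1)
        if 0 < i + j + k <= degree
    ]


def _random_bias_field(
    shape, brain: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field: exp of a random degree-2 polynomial,
    scaled to the requested maximum fractional deviation and normalized to
    unit mean over the brain."""
    coeffs = rng.normal(0.0, 1.0, len(_bias_poly_exponents()))
    if amplitude == 0:
        return np.ones(shape)
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij", sparse=True
    )
    logf = np.zeros(shape)
    for c, (i, j, k) in zip(coeffs, _bias_poly_exponents()):
        logf = logf + c * grids[0] ** i * grids[1] ** j * grids[2] ** k
    logf -= logf[brain].mean()
    peak = np.max(np.abs(logf[brain]))
    if peak > 0:
        logf *= np.log1p(amplitude) / peak
    field = np.exp(logf)
    return field / field[brain].mean()


def render_intensity_volumes(
    masks: TissueMaskSet, record, config: GeneratorConfig
) -> tuple[ImageVolume, ImageVolume]:
    """Render T1w and T2w volumes for one subject.

    Tissue voxels get their configured modality means, except that the WM
    T1w mean is set to ``w (1 + s*) / (1 - s*)`` — where ``w`` is the WM
    value of the noiselessly scaled T2w — so the downstream NAWM sT1w/T2w
    median equals the implanted s*. Lesions are T1w-hypointense and
    T2w-hyperintense. Each modality is then multiplied by its per-subject
    lognormal gain and its own smooth bias field, Gaussian noise is added,
    and values are clipped strictly positive.
    """
    config.validate()
    if config.seed is None:
        raise InvalidConfigError("render_intensity_volumes requires a seed")
    s_star = implanted_st_median(record, config)
    if not -1.0 < s_star < 1.0:
        raise InvalidConfigError(f"implanted sT1w/T2w median {s_star:.3f} outside (-1, 1)")

    m1, m2 = config.tissue_means_t1w, config.tissue_means_t2w
    scale0 = m1["gm"] / m2["gm"]
    wm_t1_mean = scale0 * m2["wm"] * (1.0 + s_star) / (1.0 - s_star)

    t1 = np.zeros(masks.shape)
    t2 = np.zeros(masks.shape)
    for tissue, mask in (("csf", masks.csf), ("gm", masks.gm)):
        t1[mask] = m1[tissue]
        t2[mask] = m2[tissue]
    t1[masks.wm] = wm_t1_mean
    t2[masks.wm] = m2["wm"]
    t1[masks.lesion] = m1["lesion"]
    t2[masks.lesion] = m2["lesion"]

    rng = _subject_rng(config.seed, _STAGE_RENDER, record["subject_id"])
    gain1 = float(np.exp(rng.normal(0.0, config.gain_sd_t1w))) if config.gain_sd_t1w else 1.0
    gain2 = float(np.exp(rng.normal(0.0, config.gain_sd_t2w))) if config.gain_sd_t2w else 1.0
    field1 = _random_bias_field(masks.shape, masks.brain, config.bias_amplitude, rng)
    field2 = _random_bias_field(masks.shape, masks.brain, config.bias_amplitude, rng)

    t1 = t1 * gain1 * field1
    t2 = t2 * gain2 * field2
    if config.noise_sd > 0:
        t1 = t1 + rng.normal(0.0, config.noise_sd, masks.shape)
        t2 = t2 + rng.normal(0.0, config.noise_sd, masks.shape)
    t1 = np.maximum(t1, 1e-6)
    t2 = np.maximum(t2, 1e-6)

    return (
        ImageVolume(t1, config.voxel_size_mm, "t1w"),
        ImageVolume(t2, config.voxel_size_mm, "t2w"),
    )
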