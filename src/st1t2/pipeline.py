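"""Orchestration: simulate → preprocess → ratio → stats as one seeded run.

Each stage writes plain-text or NIfTI artifacts under the output directory;
a run can resume from any stage's outputs (for example re-running only the
statistics from an existing medians table). All randomness descends from the
single configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig, RunConfig
from .preprocess import correct_bias, estimate_bias_field, make_na_masks
from .ratio import MEASURES, compute_ratio_maps, extract_tissue_medians
from .stats import (
    backward_stepwise_ols,
    chi_square_2x2,
    coefficient_of_variation,
    cov_equality_test,
    pearson_with_adj_r2,
    welch_t,
)
from .synthetic import generate_label_volume, generate_subject_table, render_intensity_volumes
from .volume import ImageVolume, TissueMaskSet

log = logging.getLogger(__name__)

GROUP_TEST_REGIONS = ("nagm", "nawm")

#: Whole-cohort model terms (sex enters only via the head-size interaction).
COHORT_TERMS = {
    "ms": ["ms"],
    "age": ["age"],
    "sex_by_head": ["female_head", "male_head"],
}

#: Patient-only model terms.
PATIENT_TERMS = {
    "age": ["age"],
    "disease_duration": ["disease_duration_months"],
    "edss": ["edss"],
    "lesion_volume": ["lesion_volume_ml"],
    "lesion_count": ["lesion_count"],
    "age_by_duration": ["age_by_duration"],
    "sex_by_head": ["female_head", "male_head"],
}


def process_subject(record, config: GeneratorConfig, bias_degree: int = 2, eps_rel: float = 1e-6):
    """Run one subject through phantom → render → bias correction → ratios.

    Returns (TissueMedians, artifacts dict) with the intermediate volumes.
    """
    masks = generate_label_volume(record, config)
    t1w, t2w = render_intensity_volumes(masks, record, config)
    masks = make_na_masks(masks)
    partition = [masks.csf, masks.nagm, masks.nawm, masks.lesion]
    f1 = estimate_bias_field(t1w, masks.brain, bias_degree, tissue_masks=partition)
    f2 = estimate_bias_field(t2w, masks.brain, bias_degree, tissue_masks=partition)
    t1c = correct_bias(t1w, f1, masks.brain)
    t2c = correct_bias(t2w, f2, masks.brain)
    maps = compute_ratio_maps(t1c, t2c, masks, eps_rel=eps_rel)
    medians = extract_tissue_medians(record["subject_id"], t1c, t2c, maps, masks)
    artifacts = {
        "masks": masks,
        "t1w": t1w,
        "t2w": t2w,
        "t1w_corrected": t1c,
        "t2w_corrected": t2c,
        "fields": (f1, f2),
        "maps": maps,
    }
    return medians, artifacts


def compute_cohort_medians(
    config: GeneratorConfig, bias_degree: int = 2, eps_rel: float = 1e-6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-memory cohort run: subject table plus per-subject tissue medians."""
    subjects = generate_subject_table(config)
    rows = []
    for record in subjects.to_dict("records"):
        medians, _ = process_subject(record, config, bias_degree, eps_rel)
        rows.append(medians.to_row())
    return subjects, pd.DataFrame(rows)


def _design_frame(joined: pd.DataFrame) -> pd.DataFrame:
    df = joined.copy()
    df["ms"] = (df["group"] == "MS").astype(float)
    df["female_head"] = (df["sex"] == "F").astype(float) * df["head_size_scale"]
    df["male_head"] = (df["sex"] == "M").astype(float) * df["head_size_scale"]
    df["age_by_duration"] = df["age"] * df["disease_duration_months"]
    return df


def _stepwise_to_dict(result) -> dict:
    return {
        "response": result.response,
        "selected_index": result.selected_index,
        "models": [
            {
                "terms": list(m.terms),
                "params": m.params,
                "pvalues": m.pvalues,
                "term_pvalues": m.term_pvalues,
                "adjusted_r2": m.adj_r2,
                "residual_se": m.resid_se,
                "f_statistic": m.f_stat,
                "f_df": list(m.f_df),
                "aic": m.aic,
                "observations": m.nobs,
                "max_cooks_distance": m.max_cooks,
            }
            for m in result.models
        ],
    }


def cohort_statistics(
    subjects: pd.DataFrame,
    medians: pd.DataFrame,
    removal_alpha: float = 0.05,
    bonferroni_alpha: float = 0.004,
) -> dict:
    """The full statistical battery over the cohort medians table.

    Covers the demographics comparisons (Welch t on age, chi-square on sex),
    the NAWM CoV table with the equality-of-CoVs test per group, Welch group
    comparisons of every measure in NAGM and NAWM gated at the Bonferroni
    threshold, the T1w/T2w vs sT1w/T2w correlation, and the backward
    stepwise covariate models (whole cohort and patients only).
    """
    joined = subjects.merge(medians, on="subject_id", validate="one_to_one")
    ms = joined[joined["group"] == "MS"]
    hc = joined[joined["group"] == "HC"]
    flags: list = []

    t, df_t, p_t = welch_t(hc["age"], ms["age"])
    sex_table = [
        [int((ms["sex"] == "F").sum()), int((ms["sex"] == "M").sum())],
        [int((hc["sex"] == "F").sum()), int((hc["sex"] == "M").sum())],
    ]
    chi2, chi2_df, chi2_p = chi_square_2x2(sex_table)
    demographics = {
        "age_welch": {"t": t, "df": df_t, "p": p_t, "group_order": "HC-MS"},
        "sex_chi2": {"statistic": chi2, "df": chi2_df, "p": chi2_p, "table": sex_table},
    }

    cov_section = {}
    for group, sub in (("MS", ms), ("HC", hc)):
        c_ratio = coefficient_of_variation(sub["t1t2_nawm"])
        c_st = coefficient_of_variation(sub["st1t2_nawm"])
        test = cov_equality_test(
            [c_ratio / 100.0, c_st / 100.0], [len(sub), len(sub)]
        )
        cov_section[group] = {
            "cov_t1t2_percent": c_ratio,
            "cov_st1t2_percent": c_st,
            "statistic": test.statistic,
            "df": test.df,
            "p": test.p_value,
            "n": len(sub),
        }

    group_tests = {}
    for measure in MEASURES:
        for region in GROUP_TEST_REGIONS:
            col = f"{measure}_{region}"
            t_g, df_g, p_g = welch_t(ms[col], hc[col])
            group_tests[col] = {
                "t": t_g,
                "df": df_g,
                "p": p_g,
                "significant": bool(p_g < bonferroni_alpha),
                "group_order": "MS-HC",
            }

    r, adj_r2 = pearson_with_adj_r2(joined["t1t2_nawm"], joined["st1t2_nawm"])
    correlation = {"pearson_r": r, "adjusted_r2": adj_r2, "n": len(joined)}

    design = _design_frame(joined)
    stepwise_cohort = {}
    stepwise_patients = {}
    for measure in MEASURES:
        response = f"{measure}_nawm"
        res_c = backward_stepwise_ols(design, response, COHORT_TERMS, removal_alpha)
        stepwise_cohort[response] = _stepwise_to_dict(res_c)
        res_p = backward_stepwise_ols(
            design[design["group"] == "MS"], response, PATIENT_TERMS, removal_alpha
        )
        stepwise_patients[response] = _stepwise_to_dict(res_p)
        for label, res in (("cohort", res_c), ("patients", res_p)):
            for i, m in enumerate(res.models):
                if m.max_cooks > 1.0:
                    flags.append(
                        f"stage=stats model={label}/{response}/{i} "
                        f"event=cooks_distance value={m.max_cooks:.3f}"
                    )

    return {
        "n_subjects": len(joined),
        "demographics": demographics,
        "cov_nawm": cov_section,
        "group_tests": group_tests,
        "bonferroni_alpha": bonferroni_alpha,
        "correlation_t1t2_vs_st1t2_nawm": correlation,
        "stepwise_cohort": stepwise_cohort,
        "stepwise_patients": stepwise_patients,
        "flags": flags,
    }


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages, writing artifacts under ``cfg.outdir``.

    Stage outputs: per-subject NIfTI volumes and ``subjects.tsv`` from
    simulate; corrected volumes from preprocess; ratio maps and
    ``medians.tsv`` from ratio; ``report.json`` and human-readable TSV
    tables from stats. Skipped stages are resumed from their artifacts.
    """
    cfg.validate()
    out = Path(cfg.outdir) if cfg.outdir else Path(".")
    out.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator
    stages = cfg.stages

    subjects = None
    if "simulate" in stages:
        subjects = generate_subject_table(gen)
        subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        for record in subjects.to_dict("records"):
            sid = record["subject_id"]
            masks = generate_label_volume(record, gen)
            t1w, t2w = render_intensity_volumes(masks, record, gen)
            masks.save_labels_nifti(out / f"{sid}_labels.nii.gz", gen.voxel_size_mm)
            t1w.save_nifti(out / f"{sid}_T1w.nii.gz")
            t2w.save_nifti(out / f"{sid}_T2w.nii.gz")
    elif {"preprocess", "ratio", "stats"} & set(stages):
        subjects = pd.read_csv(out / "subjects.tsv", sep="\t")

    if "preprocess" in stages:
        for record in subjects.to_dict("records"):
            sid = record["subject_id"]
            masks = TissueMaskSet.load_labels_nifti(out / f"{sid}_labels.nii.gz")
            masks = make_na_masks(masks)
            partition = [masks.csf, masks.nagm, masks.nawm, masks.lesion]
            for mod, name in (("t1w", "T1w"), ("t2w", "T2w")):
                vol = ImageVolume.load_nifti(out / f"{sid}_{name}.nii.gz", mod)
                fld = estimate_bias_field(
                    vol, masks.brain, cfg.bias_degree, tissue_masks=partition
                )
                corr = correct_bias(vol, fld, masks.brain)
                corr.save_nifti(out / f"{sid}_{name}_corr.nii.gz")

    if "ratio" in stages:
        rows = []
        for record in subjects.to_dict("records"):
            sid = record["subject_id"]
            masks = TissueMaskSet.load_labels_nifti(out / f"{sid}_labels.nii.gz")
            masks = make_na_masks(masks)
            t1c = ImageVolume.load_nifti(out / f"{sid}_T1w_corr.nii.gz", "t1w")
            t2c = ImageVolume.load_nifti(out / f"{sid}_T2w_corr.nii.gz", "t2w")
            maps = compute_ratio_maps(t1c, t2c, masks, eps_rel=cfg.eps_rel)
            voxel = t1c.voxel_size_mm
            ImageVolume(maps.t1t2, voxel, "ratio").save_nifti(out / f"{sid}_t1t2.nii.gz")
            ImageVolume(maps.st1t2, voxel, "st_ratio").save_nifti(out / f"{sid}_st1t2.nii.gz")
            rows.append(extract_tissue_medians(sid, t1c, t2c, maps, masks).to_row())
        pd.DataFrame(rows).to_csv(out / "medians.tsv", sep="\t", index=False)

    report = {}
    if "stats" in stages:
        medians = pd.read_csv(out / "medians.tsv", sep="\t")
        report = cohort_statistics(
            subjects, medians, cfg.removal_alpha, cfg.bonferroni_alpha
        )
        write_report(report, out / "report.json")
        _write_tables(report, out)
        for flag in report["flags"]:
            log.warning(flag)
    return report


def _write_tables(report: dict, out: Path) -> None:
    """Human-readable TSV analogs of the report sections (3-decimal p-values)."""
    cov_rows = []
    for group, d in report["cov_nawm"].items():
        cov_rows.append(
            {
                "group": group,
                "cov_t1t2": round(d["cov_t1t2_percent"], 2),
                "cov_st1t2": round(d["cov_st1t2_percent"], 2),
                "p": round(d["p"], 3),
            }
        )
    pd.DataFrame(cov_rows).to_csv(out / "table_cov.tsv", sep="\t", index=False)

    rows = []
    for col, d in report["group_tests"].items():
        rows.append(
            {
                "measure_region": col,
                "t": round(d["t"], 2),
                "df": round(d["df"], 2),
                "p": round(d["p"], 3),
                "significant": d["significant"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "table_group_tests.tsv", sep="\t", index=False)

    model_rows = []
    for scope_name, scope in (
        ("cohort", report["stepwise_cohort"]),
        ("patients", report["stepwise_patients"]),
    ):
        for response, res in scope.items():
            for i, m in enumerate(res["models"]):
                which = "selected" if i == res["selected_index"] else f"step{i}"
                for name, value in m["params"].items():
                    model_rows.append(
                        {
                            "scope": scope_name,
                            "response": response,
                            "model": which,
                            "term": name,
                            "coefficient": value,
                            "p": round(m["pvalues"][name], 4),
                            "aic": round(m["aic"], 2),
                            "adjusted_r2": round(m["adjusted_r2"], 3),
                            "observations": m["observations"],
                        }
                    )
    pd.DataFrame(model_rows).to_csv(out / "table_models.tsv", sep="\t", index=False)
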