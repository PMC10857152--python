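"""End-to-end evaluation: simulate -> register -> evaluate -> report.

Given a cohort of cases (synthetic or loaded from disk), this module fits
the rigid transform per case, computes the landmark metrics (FLE/TRE/FRE/FN)
and the lesion metrics (DSC/HD95 plus volume, depth, L2 norm), groups them
by surgical position (supine / prone / lateral, the two lateral sides
pooled), and produces the study-style summary tables:

* a landmark accuracy table (per-position mean +/- SD of FLE, TRE, FRE, FN
  with Kruskal–Wallis p-values),
* a lesion accuracy table (volume, depth, L2 norm, DSC, HD95 by position),
* a Spearman correlation table (DSC and HD95 against the three lesion
  characteristics), and
* a median-split subgroup table (DSC and HD95 between lesions above vs at-
  or-below the median of each characteristic).

Measured point sets are routed through the virtual-frame chain
(FEM -> HCM -> HCM^-1 -> REM) before metric computation, emulating the
platform's reporting path and exercising the frame/unit tags end to end;
the chain is the identity on coordinates by construction.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frames import (
    FiducialSet,
    SurgicalPosition,
    apply_transform,
    make_fem,
    make_hcm,
    make_rem,
)
from .io import RunConfig, write_fiducials_csv, write_fiducials_fcsv, write_mask, write_mesh
from .landmarks import CaseLandmarkSummary, summarize_landmarks
from .lesions import LesionAccuracy, evaluate_lesion
from .phantom import CaseRecord, NoiseModel, generate_cohort
from .registration import fit_rigid
from .stats import compare_positions, correlate, median_split
from .tables import write_fixture_tables

__all__ = [
    "through_platform",
    "evaluate_case",
    "evaluate_cohort",
    "cohort_report",
    "run_pipeline",
    "export_case_bundle",
]

#: position -> pooled group label used in the summary tables
POSITION_GROUP = {
    SurgicalPosition.SUPINE: "supine",
    SurgicalPosition.PRONE: "prone",
    SurgicalPosition.LEFT_LATERAL: "lateral",
    SurgicalPosition.RIGHT_LATERAL: "lateral",
}


def through_platform(
    fs: FiducialSet, position: SurgicalPosition, *, lateral_sign: int = +1
) -> FiducialSet:
    """Route a point set out to the virtual frame and back to analysis.

    RICS --FEM--> IVCS --HCM--> VCS --HCM^-1--> IVCS --REM--> ACS.  The
    round trip is the identity on coordinates (to numerical precision); it
    reproduces the platform's reporting path and validates the frame tags.
    """
    fem = make_fem(position, lateral_sign=lateral_sign)
    hcm = make_hcm()
    rem = make_rem(position, lateral_sign=lateral_sign)
    out = apply_transform(fem, fs)
    out = apply_transform(hcm, out)
    out = apply_transform(hcm.inverse(), out)
    out = apply_transform(rem, out)
    return out


def evaluate_case(
    case: CaseRecord,
    *,
    symmetric_hd95: bool = False,
    lateral_sign: int = +1,
) -> tuple[CaseLandmarkSummary, list[LesionAccuracy]]:
    """Fit the rigid transform and compute all metrics for one case."""
    c = case.fiducials_C
    v = through_platform(case.fiducials_V, case.position, lateral_sign=lateral_sign)
    p = through_platform(case.fiducials_P, case.position, lateral_sign=lateral_sign)
    fit = fit_rigid(c, p)
    landmark = summarize_landmarks(case.case_id, case.position, c, v, p, fit)
    lesions = [
        evaluate_lesion(
            gt,
            fit,
            case.skin,
            case_id=case.case_id,
            lesion_id=i + 1,
            symmetric_hd95=symmetric_hd95,
        )
        for i, gt in enumerate(case.lesions)
    ]
    return landmark, lesions


def evaluate_cohort(
    cases: list[CaseRecord], *, symmetric_hd95: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case landmark and per-lesion DataFrames for a cohort."""
    landmark_rows, lesion_rows = [], []
    for case in cases:
        summary, lesions = evaluate_case(case, symmetric_hd95=symmetric_hd95)
        row = summary.as_dict()
        row["group"] = POSITION_GROUP[case.position]
        landmark_rows.append(row)
        for acc in lesions:
            lrow = acc.as_dict()
            lrow["position"] = case.position.value
            lrow["group"] = POSITION_GROUP[case.position]
            lesion_rows.append(lrow)
    return pd.DataFrame(landmark_rows), pd.DataFrame(lesion_rows)


def _grouped_table(
    df: pd.DataFrame, columns: dict[str, str], group_col: str = "group"
) -> tuple[pd.DataFrame, dict]:
    """Overall + per-group mean/SD rows with Kruskal–Wallis p per metric."""
    order = ["supine", "prone", "lateral"]
    groups_present = [g for g in order if g in set(df[group_col])]
    rows = []
    comparisons = {}
    for label, subset in [("overall", df)] + [
        (g, df[df[group_col] == g]) for g in groups_present
    ]:
        row: dict = {"group": label, "n": len(subset)}
        for col, name in columns.items():
            row[f"{name}_mean"] = subset[col].mean()
            row[f"{name}_sd"] = subset[col].std(ddof=1)
        rows.append(row)
    if len(groups_present) >= 2 and all(
        (df[group_col] == g).sum() >= 2 for g in groups_present
    ):
        for col, name in columns.items():
            try:
                comp = compare_positions(
                    {
                        g: df.loc[df[group_col] == g, col].to_numpy()
                        for g in groups_present
                    },
                    metric=name,
                )
            except ValueError:
                # degenerate input (e.g. a zero-noise run where every value
                # is identical): the omnibus test is undefined, skip it
                continue
            comparisons[name] = comp
    return pd.DataFrame(rows), comparisons


def cohort_report(
    landmark_df: pd.DataFrame, lesion_df: pd.DataFrame
) -> dict:
    """Build the study-style summary tables from per-case/per-lesion frames."""
    landmark_table, landmark_tests = _grouped_table(
        landmark_df,
        {"mean_fle": "fle", "mean_tre": "tre", "mean_fre": "fre", "fn": "fn"},
    )
    lesion_table, lesion_tests = _grouped_table(
        lesion_df,
        {
            "volume_cm3": "volume",
            "depth_cm": "depth",
            "l2_norm_cm": "l2_norm",
            "dsc": "dsc",
            "hd95_mm": "hd95",
        },
    )

    characteristics = {
        "volume": "volume_cm3",
        "depth": "depth_cm",
        "l2_norm": "l2_norm_cm",
    }
    nan = float("nan")
    corr_rows, split_rows = [], []
    for metric_name, metric_col in [("dsc", "dsc"), ("hd95", "hd95_mm")]:
        for char_name, char_col in characteristics.items():
            try:
                res = correlate(
                    lesion_df[char_col],
                    lesion_df[metric_col],
                    pair=f"{metric_name}-{char_name}",
                )
                rho, p = res.rho, res.p_value
            except ValueError:  # constant metric, e.g. all-zero-noise DSC = 1
                rho, p = nan, nan
            corr_rows.append(
                {"pair": f"{metric_name}-{char_name}", "rho": rho, "p_value": p}
            )
            try:
                split = median_split(
                    lesion_df[metric_col],
                    lesion_df[char_col],
                    characteristic=char_name,
                    metric=metric_name,
                )
                row = {
                    "above_mean": split.above[0],
                    "above_sd": split.above[1],
                    "below_mean": split.below[0],
                    "below_sd": split.below[1],
                    "p_value": split.p_value,
                }
            except ValueError:
                row = {
                    "above_mean": nan,
                    "above_sd": nan,
                    "below_mean": nan,
                    "below_sd": nan,
                    "p_value": nan,
                }
            split_rows.append(
                {"characteristic": char_name, "metric": metric_name, **row}
            )

    return {
        "landmark_table": landmark_table,
        "lesion_table": lesion_table,
        "landmark_tests": landmark_tests,
        "lesion_tests": lesion_tests,
        "correlations": pd.DataFrame(corr_rows),
        "median_splits": pd.DataFrame(split_rows),
    }


def _tests_to_json(tests: dict) -> dict:
    return {
        name: {
            "omnibus_p": comp.omnibus_p,
            "alpha_adjusted": comp.alpha_adjusted,
            "pairwise": [
                {"groups": [a, b], "p": p} for a, b, p in comp.pairwise
            ],
        }
        for name, comp in tests.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a cohort, evaluate it, and write the full report to disk.

    Returns the report dict (DataFrames plus the demographics summary).
    Every run writes its resolved config, the package version, and the
    config hash next to the outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    noise = NoiseModel(
        sigma_probe=config.sigma_probe,
        rot_sigma_deg=config.rot_sigma_deg,
        trans_sigma=config.trans_sigma,
    )
    cases = generate_cohort(
        n_cases=config.n_cases,
        position_mix=tuple(config.position_mix),
        noise=noise,
        seed=config.seed,
    )
    landmark_df, lesion_df = evaluate_cohort(
        cases, symmetric_hd95=config.symmetric_hd95
    )
    report = cohort_report(landmark_df, lesion_df)

    demo_df = pd.DataFrame(
        {
            "case": [c.case_id for c in cases],
            "sex": [c.sex for c in cases],
            "age": [c.age for c in cases],
            "pathology": [c.pathology for c in cases],
            "position": [c.position.value for c in cases],
        }
    )
    from .stats import demographics_summary

    report["demographics"] = demographics_summary(demo_df)
    report["per_case_landmarks"] = landmark_df
    report["per_lesion"] = lesion_df

    # -- write everything -------------------------------------------------
    float_fmt = "%.6g"
    landmark_df.to_csv(outdir / "per_case_landmarks.csv", index=False,
                       float_format=float_fmt)
    lesion_df.to_csv(outdir / "per_lesion_metrics.csv", index=False,
                     float_format=float_fmt)
    report["landmark_table"].to_csv(outdir / "landmark_summary.csv", index=False,
                                    float_format=float_fmt)
    report["lesion_table"].to_csv(outdir / "lesion_summary.csv", index=False,
                                  float_format=float_fmt)
    report["correlations"].to_csv(outdir / "correlations.csv", index=False,
                                  float_format=float_fmt)
    report["median_splits"].to_csv(outdir / "median_splits.csv", index=False,
                                   float_format=float_fmt)
    demo_df.to_csv(outdir / "demographics.csv", index=False,
                   float_format=float_fmt)
    write_fixture_tables(outdir / "fixtures")

    summary_json = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "python": platform.python_version(),
        "demographics": report["demographics"],
        "statistical_tests": {
            "landmarks": _tests_to_json(report["landmark_tests"]),
            "lesions": _tests_to_json(report["lesion_tests"]),
        },
    }
    (outdir / "report.json").write_text(json.dumps(summary_json, indent=2, sort_keys=True))
    config.write(outdir / "config.yaml")
    return report


def export_case_bundle(case: CaseRecord, outdir: str | Path) -> None:
    """Write one case as a directory of standard-format files.

    Fiducials as CSV + FCSV, lesion masks as NRRD, the skin mesh as STL,
    and case metadata (including the true misregistration) as JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fs in [
        ("C", case.fiducials_C),
        ("V", case.fiducials_V),
        ("P", case.fiducials_P),
    ]:
        write_fiducials_csv(fs, outdir / f"fiducials_{name}.csv")
        write_fiducials_fcsv(fs, outdir / f"fiducials_{name}.fcsv")
    for i, lesion in enumerate(case.lesions, start=1):
        write_mask(lesion, outdir / f"lesion_{i:02d}.nrrd")
    write_mesh(case.skin, outdir / "skin.stl")
    meta = {
        "case_id": case.case_id,
        "sex": case.sex,
        "age": case.age,
        "pathology": case.pathology,
        "position": case.position.value,
        "seed": case.seed,
        "acquisition_order": list(case.acquisition_order),
        "true_misregistration_matrix": case.true_misregistration.matrix.tolist(),
        "noise": {
            "sigma_probe": case.noise.sigma_probe,
            "rot_sigma_deg": case.noise.rot_sigma_deg,
            "trans_sigma": case.noise.trans_sigma,
        },
        "package_version": __version__,
    }
    (outdir / "case.json").write_text(json.dumps(meta, indent=2))
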