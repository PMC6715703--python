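"""End-to-end orchestration of the threshold analysis.

`run_group_comparisons` reproduces the descriptive/group-comparison table
(HD medians and quartiles per group, Cliff's delta with bounded CI, null
and equivalence p-values, per stratum), plus the sex-ratio chi-square and
GMD outlier-proportion Fisher tests.  `run_regressions` runs the
three-step cumulative-probability-model hierarchy per modality, with
best-subset BIC selection and optional multiple imputation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import corr_tost, spearman
from .cpm import hierarchical_models, model_inference
from .effect_sizes import (
    chi_square_2x2,
    cliffs_delta,
    delta_tost,
    fisher_exact_2x2,
)
from .imputation import pmm_multiple_impute, pool_fits
from .thresholds import hd_quantile, summarize_cohort

log = logging.getLogger("thermolimits")

__all__ = ["AnalysisConfig", "run_group_comparisons", "run_regressions"]

ADULT_AGE_CUTOFF = 18.0   # children span 7.0-17.99 years

#: subject-level variables compared between groups, in reporting order
COMPARISON_VARIABLES = [
    "age", "viq", "piq", "fsiq", "srs_t", "srs_item42",
    "aasp_low_registration", "aasp_seeking", "aasp_sensitivity",
    "aasp_avoiding", "sp_low_registration", "sp_seeking",
    "sp_sensitivity", "sp_avoiding",
    "warm_threshold", "cool_threshold", "warm_gmd", "cool_gmd",
]


@dataclass
class AnalysisConfig:
    delta_bound: float = 0.33
    corr_bound: float = 0.30
    alpha: float = 0.05
    delta_ci_level: float = 0.90
    B: int = 10_000
    M: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("delta_bound", "corr_bound"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    def to_dict(self):
        return dataclasses.asdict(self)


def _strata(subjects: pd.DataFrame) -> dict:
    adult = subjects["age"] >= ADULT_AGE_CUTOFF
    return {
        "whole": subjects,
        "adults": subjects[adult],
        "children": subjects[~adult],
    }


def _describe(values: np.ndarray) -> tuple:
    mdn = hd_quantile(values, 0.5).estimate
    q1 = hd_quantile(values, 0.25).estimate
    q3 = hd_quantile(values, 0.75).estimate
    return mdn, q1, q3


def build_analysis_table(
    trials: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-subject threshold summaries onto the covariate table."""
    summary = summarize_cohort(trials, subjects)
    keep = [c for c in summary.columns if c not in ("diagnosis",)]
    return subjects.merge(summary[keep], on="subject_id", how="left")


def run_group_comparisons(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> dict:
    """ASD-vs-TD comparisons per variable and stratum.

    Returns a dict with the comparison table (one row per variable x
    stratum: group medians/quartiles, delta with CI, null and equivalence
    p-values), the sex-ratio contingency test, and GMD outlier-proportion
    Fisher tests.
    """
    config = config or AnalysisConfig()
    data = build_analysis_table(trials, subjects)
    rows = []
    for stratum, sub in _strata(data).items():
        asd = sub[sub["diagnosis"] == "ASD"]
        td = sub[sub["diagnosis"] == "TD"]
        for var in COMPARISON_VARIABLES:
            if var not in sub.columns:
                continue
            x = asd[var].dropna().to_numpy(dtype=float)
            y = td[var].dropna().to_numpy(dtype=float)
            row = {
                "variable": var, "stratum": stratum,
                "n_asd": len(x), "n_td": len(y),
            }
            if len(x) < 4 or len(y) < 4:
                row["computed"] = False
                rows.append(row)
                continue
            m1, q11, q31 = _describe(x)
            m2, q12, q32 = _describe(y)
            d = cliffs_delta(x, y, ci_level=config.delta_ci_level)
            eq = delta_tost(
                x, y, bound=config.delta_bound, alpha=config.alpha
            )
            row.update(
                computed=True,
                asd_mdn=m1, asd_q1=q11, asd_q3=q31,
                td_mdn=m2, td_q1=q12, td_q3=q32,
                delta=d.delta, ci_low=d.ci_low, ci_high=d.ci_high,
                p_h0=d.p_two_sided, p_equiv=eq.p_equiv,
            )
            rows.append(row)
    table = pd.DataFrame(rows)

    asd = data[data["diagnosis"] == "ASD"]
    td = data[data["diagnosis"] == "TD"]
    sex = chi_square_2x2(
        int((asd["sex"] == "M").sum()), int((asd["sex"] == "F").sum()),
        int((td["sex"] == "M").sum()), int((td["sex"] == "F").sum()),
    )
    outlier_tests = {}
    for col in ("outlier_warm_gmd", "outlier_cool_gmd",
                "outlier_warm", "outlier_cool"):
        if col not in data.columns:
            continue
        a = int(asd[col].sum())
        b = int((~asd[col].astype(bool)).sum())
        c = int(td[col].sum())
        dd = int((~td[col].astype(bool)).sum())
        outlier_tests[col] = {
            "asd_outliers": a, "td_outliers": c,
            "p_fisher": fisher_exact_2x2(a, b, c, dd),
        }
    return {
        "comparisons": table,
        "sex_ratio": {
            "chi2": sex.chi2, "df": sex.df, "p": sex.p, "phi": sex.phi,
        },
        "outlier_tests": outlier_tests,
    }


BASELINE_PREDICTORS = ["diagnosis_asd", "age", "sex_male", "warm_first"]
CANDIDATES_WHOLE = ["viq", "piq", "srs_t", "srs_item42"]


def _encode(data: pd.DataFrame) -> pd.DataFrame:
    out = data.copy()
    out["diagnosis_asd"] = (out["diagnosis"] == "ASD").astype(float)
    out["sex_male"] = (out["sex"] == "M").astype(float)
    out["warm_first"] = (out["counterbalance"] == "warm_first").astype(float)
    return out


def _subsample_plan(data: pd.DataFrame) -> dict:
    adult = data["age"] >= ADULT_AGE_CUTOFF
    plans = {
        "whole": (data, BASELINE_PREDICTORS, CANDIDATES_WHOLE),
        "adults": (
            data[adult],
            BASELINE_PREDICTORS,
            CANDIDATES_WHOLE
            + ["aasp_low_registration", "aasp_seeking", "aasp_sensitivity"],
        ),
        "children": (
            data[~adult],
            BASELINE_PREDICTORS,
            CANDIDATES_WHOLE
            + ["sp_low_registration", "sp_seeking", "sp_sensitivity"],
        ),
        "asd": (
            data[data["diagnosis"] == "ASD"],
            [p for p in BASELINE_PREDICTORS if p != "diagnosis_asd"],
            CANDIDATES_WHOLE + ["ados_css"],
        ),
    }
    return plans


def _fit_steps(sub, outcome, baseline, candidates, gmd_col):
    res = hierarchical_models(
        sub[outcome].to_numpy(dtype=float), sub, baseline, candidates, gmd_col
    )
    sel = res.selection.table.loc[res.selection.best_id]
    return {
        "chosen_subset": res.stats["chosen_subset"],
        "bic_weight_best": float(sel["bic_weight"]),
        "steps": {
            name: {
                "lr_chi2": st.lr_chi2, "df": st.df, "p": st.p,
                "nagelkerke_r2": st.nagelkerke_r2,
                "coefficients": st.coef_table.to_dict(orient="records"),
            }
            for name, st in (
                ("step1", res.stats["step1"]),
                ("step2", res.stats["step2"]),
                ("step3", res.stats["step3"]),
            )
        },
        "delta_r2_step2": res.stats["delta_r2_step2"],
        "delta_r2_step3": res.stats["delta_r2_step3"],
        "inclusion_probs": res.selection.inclusion_probs,
        "_result": res,
    }


def run_regressions(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    config: AnalysisConfig | None = None,
    samples=("whole",),
    impute: bool = True,
) -> dict:
    """Three-step CPM hierarchy per modality and subsample.

    Missing covariates are multiply imputed (PMM, M from the config); the
    step models are fit on each completed dataset, the best subset is the
    modal BIC choice across imputations, and step-3 slopes are pooled by
    Rubin's rules.  With ``impute=False`` a single complete-case-style fit
    is performed on mean-completed covariates.
    """
    config = config or AnalysisConfig()
    data = _encode(build_analysis_table(trials, subjects))
    results: dict = {}
    for sample in samples:
        plan = _subsample_plan(data)
        sub, baseline, candidates = plan[sample]
        results[sample] = {}
        for modality in ("warm", "cool"):
            outcome = f"{modality}_threshold"
            gmd_col = f"{modality}_gmd"
            cols = [outcome, gmd_col, *baseline, *candidates]
            frame = sub[["subject_id", *cols]].dropna(
                subset=[outcome, gmd_col]
            ).reset_index(drop=True)
            impute_vars = [
                c for c in candidates if frame[c].isna().any()
            ]
            if impute and impute_vars:
                imp = pmm_multiple_impute(
                    frame[cols], variables=impute_vars,
                    M=config.M, seed=config.seed,
                )
                per_imp = [
                    _fit_steps(d, outcome, baseline, candidates, gmd_col)
                    for d in imp.datasets
                ]
                # modal best subset across imputations
                subsets = [tuple(r["chosen_subset"]) for r in per_imp]
                modal = max(set(subsets), key=subsets.count)
                fits3 = [
                    r["_result"].step3 for r, s in zip(per_imp, subsets)
                    if s == modal
                ]
                pooled = (
                    pool_fits(fits3).table().to_dict(orient="records")
                    if len(fits3) >= 2 else None
                )
                rep = per_imp[subsets.index(modal)]
                rep = {k: v for k, v in rep.items() if k != "_result"}
                rep["chosen_subset"] = list(modal)
                rep["pooled_step3"] = pooled
                rep["n"] = len(frame)
                rep["M"] = config.M
                results[sample][modality] = rep
            else:
                filled = frame[cols].copy()
                for c in candidates:
                    if filled[c].isna().any():
                        filled[c] = filled[c].fillna(filled[c].mean())
                rep = _fit_steps(filled, outcome, baseline, candidates, gmd_col)
                rep = {k: v for k, v in rep.items() if k != "_result"}
                rep["n"] = len(frame)
                results[sample][modality] = rep
    return results


def threshold_gmd_correlations(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Zero-order Spearman correlations between thresholds and their GMDs."""
    config = config or AnalysisConfig()
    data = build_analysis_table(trials, subjects)
    rows = []
    for modality in ("warm", "cool"):
        sub = data[[f"{modality}_threshold", f"{modality}_gmd"]].dropna()
        r = spearman(sub.iloc[:, 0], sub.iloc[:, 1])
        res = corr_tost(r, len(sub), bound=config.corr_bound, alpha=config.alpha)
        rows.append(
            {
                "modality": modality, "n": len(sub), "r_s": r,
                "p": res.p_two_sided, "p_equiv": res.p_equiv,
            }
        )
    return pd.DataFrame(rows)
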