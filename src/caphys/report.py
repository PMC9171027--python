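"""Study-style report bundle: baseline table, matched comparison, MACE
effects, regression tables and ROC data from one seeded cohort run.

Percentages and rates are always computed from counts at report time and
never stored, so a report can't drift out of sync with its own counts.
Every output file carries the generating config hash and seed in a header
comment; ORs and CIs are rounded to 2 decimals in the human-readable
columns while full precision is kept in the numeric ones.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (
    EffectEstimate,
    compare_means,
    fit_logistic,
    propensity_match,
    roc_analysis,
    two_by_two_effects,
)
from .synthetic import CohortConfig, CohortTable, generate_cohort

__all__ = ["run_study", "StudyBundle"]

log = logging.getLogger("caphys")

BASELINE_CONTINUOUS = ["age", "sbp", "bmi", "lvef", "stob_hours", "dtob_minutes"]
BASELINE_BINARY = ["male"]
PSM_COVARIATES = ["age", "male", "sbp", "bmi"]
MACE_PREDICTORS = ["age", "male", "sbp", "bmi", "lvef", "stob_hours", "dtob_minutes",
                   "caimr_gt40", "dcb"]


class StudyBundle(dict):
    """Named DataFrames of one study run; write() emits provenance-stamped CSVs."""

    def __init__(self, artifacts: dict, config_hash: str, seed: int):
        super().__init__(artifacts)
        self.config_hash = config_hash
        self.seed = seed

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        try:
            for name, df in self.items():
                path = outdir / f"{name}.csv"
                with open(path, "w") as fh:
                    fh.write(f"# config_hash={self.config_hash} seed={self.seed}\n")
                    df.to_csv(fh, index=False)
                written.append(path)
        except Exception:
            for p in written:  # no partial bundles
                p.unlink(missing_ok=True)
            raise
        return written


def _effect_row(label: str, est: EffectEstimate, **extra) -> dict:
    row = {
        "label": label,
        "measure": est.measure,
        "point": est.point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "display": f"{est.point:.2f} ({est.ci_low:.2f}-{est.ci_high:.2f})",
        "statistic": est.statistic,
        "p_value": est.p_value,
        "n1": est.n1,
        "n2": est.n2,
    }
    row.update(extra)
    return row


def _baseline_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    g1 = df[df["dcb"] == 0]
    g2 = df[df["dcb"] == 1]
    for var in BASELINE_CONTINUOUS:
        est = compare_means(
            g1[var].mean(), g1[var].std(ddof=1), len(g1),
            g2[var].mean(), g2[var].std(ddof=1), len(g2),
        )
        rows.append(
            {
                "variable": var, "type": "continuous",
                "des_mean": g1[var].mean(), "des_sd": g1[var].std(ddof=1),
                "dcb_mean": g2[var].mean(), "dcb_sd": g2[var].std(ddof=1),
                "p_value": est.p_value,
            }
        )
    for var in BASELINE_BINARY:
        a, b = int(g1[var].sum()), int(len(g1) - g1[var].sum())
        c, d = int(g2[var].sum()), int(len(g2) - g2[var].sum())
        res = two_by_two_effects(a, b, c, d)
        rows.append(
            {
                "variable": var, "type": "binary",
                "des_mean": res.rate1, "des_sd": np.nan,
                "dcb_mean": res.rate2, "dcb_sd": np.nan,
                "p_value": res.chi2_p,
            }
        )
    return pd.DataFrame(rows)


def _mace_effects(df: pd.DataFrame, stage: str) -> list[dict]:
    g1 = df[df["dcb"] == 0]
    g2 = df[df["dcb"] == 1]
    rows = []
    for outcome in ["mace", "corh", "cv_death"]:
        a, b = int(g1[outcome].sum()), int(len(g1) - g1[outcome].sum())
        c, d = int(g2[outcome].sum()), int(len(g2) - g2[outcome].sum())
        try:
            res = two_by_two_effects(a, b, c, d)
        except ValueError:
            continue
        rows.append(
            _effect_row(f"{outcome} DES vs DCB", res.odds_ratio, stage=stage,
                        outcome=outcome, a=a, b=b, c=c, d=d)
        )
        rows.append(
            _effect_row(f"{outcome} DES vs DCB", res.risk_ratio, stage=stage,
                        outcome=outcome, a=a, b=b, c=c, d=d)
        )
    return rows


def run_study(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    cohort: CohortTable | None = None,
    univariate_alpha: float = 0.05,
) -> StudyBundle:
    """Run the full analysis skeleton on a (generated or supplied) cohort.

    Produces five artifacts: baseline comparison, caIMR comparison,
    MACE 2x2 effects before/after propensity matching, uni-/multivariate
    logistic odds-ratio table (multivariate predictors are those
    univariate-significant at ``univariate_alpha``), and ROC point lists
    with Youden statistics for the time predictors (MACE) and the caIMR>40
    score (CorH).
    """
    if cohort is None:
        log.info("generating cohort (seed=%d)", seed)
        cohort = generate_cohort(config, seed=seed)
    df = cohort.table
    log.info("cohort: %d patients (%d DES / %d DCB)", len(df),
             int((df["dcb"] == 0).sum()), int((df["dcb"] == 1).sum()))

    matched = propensity_match(df, covariates=PSM_COVARIATES, seed=seed)
    matched_df = df[df["id"].isin(matched.matched_ids())]
    log.info("propensity matching: %d pairs", matched.n_pairs)

    baseline = _baseline_table(df)

    # caIMR comparison (continuous and >40U grouping), pre and post matching
    caimr_rows = []
    for stage, d in [("pre_psm", df), ("post_psm", matched_df)]:
        g1, g2 = d[d["dcb"] == 0], d[d["dcb"] == 1]
        est = compare_means(
            g1["caimr"].mean(), g1["caimr"].std(ddof=1), len(g1),
            g2["caimr"].mean(), g2["caimr"].std(ddof=1), len(g2),
        )
        caimr_rows.append(_effect_row("caIMR DES vs DCB", est, stage=stage))
        a, b = int(g1["caimr_gt40"].sum()), int(len(g1) - g1["caimr_gt40"].sum())
        c, dd_ = int(g2["caimr_gt40"].sum()), int(len(g2) - g2["caimr_gt40"].sum())
        res = two_by_two_effects(a, b, c, dd_)
        caimr_rows.append(
            _effect_row("caIMR>40 DES vs DCB", res.odds_ratio, stage=stage,
                        a=a, b=b, c=c, d=dd_)
        )
    caimr_table = pd.DataFrame(caimr_rows)

    mace_rows = _mace_effects(df, "pre_psm") + _mace_effects(matched_df, "post_psm")
    mace_table = pd.DataFrame(mace_rows)

    # univariate then multivariate logistic for MACE
    uni_rows = []
    significant = []
    for pred in MACE_PREDICTORS:
        try:
            est = fit_logistic(df, "mace", [pred])[pred]
        except ValueError:
            continue
        uni_rows.append(_effect_row(pred, est, model="univariate"))
        if est.p_value < univariate_alpha:
            significant.append(pred)
    multi_preds = significant if significant else MACE_PREDICTORS
    multi = fit_logistic(df, "mace", multi_preds)
    multi_rows = [_effect_row(p, est, model="multivariate") for p, est in multi.items()]
    logistic_table = pd.DataFrame(uni_rows + multi_rows)

    # ROC: time predictors for MACE; caIMR for CorH
    roc_rows = []
    for score_col, outcome in [("stob_hours", "mace"), ("dtob_minutes", "mace"),
                               ("caimr", "corh")]:
        if df[outcome].nunique() < 2:
            continue
        roc = roc_analysis(df[score_col].to_numpy(), df[outcome].to_numpy())
        for t, se, sp_ in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            roc_rows.append(
                {
                    "score": score_col, "outcome": outcome, "threshold": t,
                    "sensitivity": se, "specificity": sp_, "auc": roc.auc,
                    "youden_threshold": roc.youden_threshold,
                    "youden_sensitivity": roc.youden_sensitivity,
                    "youden_specificity": roc.youden_specificity,
                }
            )
    roc_table = pd.DataFrame(roc_rows)

    smd_table = matched.smd.reset_index(names="covariate")

    return StudyBundle(
        {
            "baseline_table": baseline,
            "caimr_comparison": caimr_table,
            "mace_effects": mace_table,
            "logistic_or_table": logistic_table,
            "roc_points": roc_table,
            "psm_balance": smd_table,
        },
        config_hash=cohort.config_hash,
        seed=seed,
    )
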