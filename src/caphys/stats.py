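"""The study-style statistics pipeline.

Covers the analysis machinery of a matched observational comparison:
2x2 effect measures (odds ratio, risk ratio) with Woolf log-scale 95%
confidence intervals, pooled-variance t comparisons from summary
statistics, 1:1 greedy propensity-score matching with a caliper on the
propensity logit, uni-/multivariate logistic regression with Wald
intervals, and empirical ROC analysis with the Youden operating point.

Model fits go through statsmodels; the 2x2 measures and Woolf intervals
are implemented directly since they are part of the reproduced contract.
No multiple-testing correction is applied by default (mirroring common
single-study practice); Benjamini-Hochberg can be requested explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "EffectEstimate",
    "TwoByTwoResult",
    "MatchedCohort",
    "RocResult",
    "two_by_two_effects",
    "compare_means",
    "propensity_match",
    "fit_logistic",
    "roc_analysis",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with 95% CI, test statistic and p-value."""

    measure: str  # "OR" | "RR" | "mean_diff"
    point: float
    ci_low: float
    ci_high: float
    statistic: float
    p_value: float
    n1: int
    n2: int
    notes: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.point) and not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass(frozen=True)
class TwoByTwoResult:
    """Effect measures for a 2x2 events table.

    Layout: rows are groups, columns event / no-event:
    group 1 -> (a events, b non-events), group 2 -> (c, d).
    """

    odds_ratio: EffectEstimate
    risk_ratio: EffectEstimate
    chi2: float
    chi2_p: float
    rate1: float
    rate2: float


def two_by_two_effects(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """OR, RR and chi-square for a 2x2 table with Woolf 95% intervals.

    OR = (a d)/(b c), RR = [a/(a+b)] / [c/(c+d)]; intervals use the
    log-scale normal approximation with z = 1.96.  A 0.5 continuity
    correction is added to all four cells only when some cell is zero.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or not np.allclose(cells, np.round(cells)):
        raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("both group margins must be positive")
    rate1 = a / (a + b)
    rate2 = c / (c + d)

    corrected = cells + 0.5 if np.any(cells == 0) else cells
    aa, bb, cc, dd = corrected
    or_point = (aa * dd) / (bb * cc)
    se_log_or = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    rr_point = (aa / (aa + bb)) / (cc / (cc + dd))
    se_log_rr = np.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))

    chi2, chi2_p = np.nan, np.nan
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.all(table.sum(axis=0) > 0):
        chi2, chi2_p, _, _ = sps.chi2_contingency(table, correction=False)

    def _est(measure: str, point: float, se_log: float) -> EffectEstimate:
        zstat = np.log(point) / se_log if se_log > 0 else np.inf
        return EffectEstimate(
            measure=measure,
            point=float(point),
            ci_low=float(point * np.exp(-Z95 * se_log)),
            ci_high=float(point * np.exp(Z95 * se_log)),
            statistic=float(zstat),
            p_value=float(2 * sps.norm.sf(abs(zstat))),
            n1=int(a + b),
            n2=int(c + d),
            notes="Woolf log-normal CI" + (", 0.5 continuity correction" if np.any(cells == 0) else ""),
        )

    return TwoByTwoResult(
        odds_ratio=_est("OR", or_point, se_log_or),
        risk_ratio=_est("RR", rr_point, se_log_rr),
        chi2=float(chi2),
        chi2_p=float(chi2_p),
        rate1=float(rate1),
        rate2=float(rate2),
    )


def compare_means(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> EffectEstimate:
    """Two-sample mean difference with a pooled-variance t interval (95%).

    Operates on summary statistics, as needed when only published group
    means/SDs are available.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    diff = mean1 - mean2
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / dof
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    tcrit = sps.t.ppf(0.975, dof)
    tstat = diff / se if se > 0 else np.inf
    return EffectEstimate(
        measure="mean_diff",
        point=float(diff),
        ci_low=float(diff - tcrit * se),
        ci_high=float(diff + tcrit * se),
        statistic=float(tstat),
        p_value=float(2 * sps.t.sf(abs(tstat), dof)),
        n1=int(n1),
        n2=int(n2),
        notes="pooled-variance two-sample t",
    )


@dataclass(frozen=True)
class MatchedCohort:
    """Result of 1:1 propensity matching.

    ``pairs`` holds (treated_id, control_id) rows; ``smd`` holds the
    standardized mean difference per covariate before and after matching.
    """

    pairs: pd.DataFrame  # columns treated_id, control_id
    propensity: pd.Series  # propensity score per patient id
    smd: pd.DataFrame  # index covariate, columns pre / post
    caliper_logit: float
    seed: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> np.ndarray:
        return np.concatenate([self.pairs["treated_id"].values, self.pairs["control_id"].values])


def _smd(x1: np.ndarray, x0: np.ndarray) -> float:
    """Standardized mean difference with the pooled-variance denominator."""
    v = 0.5 * (np.var(x1, ddof=1) + np.var(x0, ddof=1))
    if v == 0:
        return 0.0
    return float((np.mean(x1) - np.mean(x0)) / np.sqrt(v))


def propensity_match(
    cohort: pd.DataFrame,
    covariates: list[str] = ["age", "male", "sbp", "bmi"],
    treatment_col: str = "dcb",
    id_col: str = "id",
    caliper: float = 0.2,
    seed: int = 0,
) -> MatchedCohort:
    """1:1 greedy nearest-neighbour propensity matching without replacement.

    The propensity is a logistic model of treatment on the listed
    covariates; matching is on the propensity *logit* with a caliper of
    ``caliper`` SDs of the logit, treated units processed in seeded random
    order.  Matching on the logit makes the pairing invariant to affine
    rescaling of any covariate.
    """
    for col in covariates + [treatment_col, id_col]:
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing column {col!r}")
    treat = cohort[treatment_col].to_numpy()
    if treat.sum() == 0 or treat.sum() == len(treat):
        raise ValueError("both treatment arms must be non-empty")

    x = sm.add_constant(cohort[covariates].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = sm.Logit(treat, x).fit(disp=0).predict(x)
    logit = np.log(ps / (1 - ps))
    cal = caliper * np.std(logit, ddof=1)

    rng = np.random.default_rng(seed)
    treated_idx = np.flatnonzero(treat == 1)
    control_idx = np.flatnonzero(treat == 0)
    order = rng.permutation(treated_idx)
    available = set(control_idx.tolist())
    pairs = []
    for ti in order:
        if not available:
            break
        cand = np.fromiter(available, dtype=int)
        dist = np.abs(logit[cand] - logit[ti])
        j = int(np.argmin(dist))
        if dist[j] <= cal:
            ci = int(cand[j])
            available.discard(ci)
            pairs.append((int(cohort[id_col].iloc[ti]), int(cohort[id_col].iloc[ci])))
    if not pairs:
        warnings.warn("no matches found within the caliper; result is empty", stacklevel=2)
    pairs_df = pd.DataFrame(pairs, columns=["treated_id", "control_id"])

    ids = cohort[id_col].to_numpy()
    smd_rows = {}
    for cov in covariates:
        v = cohort[cov].to_numpy(dtype=float)
        pre = _smd(v[treat == 1], v[treat == 0])
        if len(pairs_df):
            t_mask = np.isin(ids, pairs_df["treated_id"].values)
            c_mask = np.isin(ids, pairs_df["control_id"].values)
            post = _smd(v[t_mask], v[c_mask])
        else:
            post = np.nan
        smd_rows[cov] = {"pre": pre, "post": post}
    return MatchedCohort(
        pairs=pairs_df,
        propensity=pd.Series(ps, index=cohort[id_col].values, name="propensity"),
        smd=pd.DataFrame(smd_rows).T,
        caliper_logit=float(cal),
        seed=seed,
    )


def fit_logistic(
    table: pd.DataFrame, outcome: str, predictors: list[str]
) -> dict[str, EffectEstimate]:
    """Maximum-likelihood logistic regression; per-predictor odds ratios
    with Wald 95% intervals.

    Constant predictor columns are dropped with a warning; separation or
    non-convergence is flagged in the ``notes`` of each estimate rather
    than silently returned.
    """
    y = table[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    kept = []
    for p in predictors:
        if table[p].nunique() <= 1:
            warnings.warn(f"dropping constant predictor {p!r}", stacklevel=2)
        else:
            kept.append(p)
    if len(table) <= len(kept) + 1:
        raise ValueError("need more observations than predictors")
    if not kept:
        raise ValueError("no non-constant predictors remain")

    x = sm.add_constant(table[kept].to_numpy(dtype=float))
    flag = ""
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = sm.Logit(y, x)
        try:
            fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # separation raises in some statsmodels versions
            raise ValueError(f"logistic fit failed: {exc}") from exc
        if any("separation" in str(w.message).lower() for w in wlist):
            flag = "possible separation; "
    if not converged:
        flag += "did not converge; "

    out: dict[str, EffectEstimate] = {}
    params = fit.params[1:]
    bse = fit.bse[1:]
    for name, beta, se in zip(kept, params, bse):
        zstat = beta / se if se > 0 else np.inf
        out[name] = EffectEstimate(
            measure="OR",
            point=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            statistic=float(zstat),
            p_value=float(2 * sps.norm.sf(abs(zstat))),
            n1=int(y.sum()),
            n2=int(len(y) - y.sum()),
            notes=(flag + "Wald 95% CI").strip(),
        )
    return out


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC and the Youden-optimal threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC over all unique score thresholds.

    AUC is the trapezoidal area (equal to the rank-sum concordance
    statistic with tie correction); the reported operating point maximizes
    the Youden index sensitivity + specificity - 1.  Equal scores are
    treated as a single threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(int)

    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    youden = tpr - fpr
    j = int(np.argmax(youden))
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        youden_threshold=float(thr[j]),
        youden_sensitivity=float(tpr[j]),
        youden_specificity=float(1.0 - fpr[j]),
    )
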