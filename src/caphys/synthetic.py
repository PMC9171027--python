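"""Synthetic STEMI study data: physiology case fixtures and cohort tables.

Two generators make every downstream stage testable without any clinical
download:

``generate_case_fixture``
    Builds one vessel + pressure trace + contrast passage whose ground-truth
    physiology (MAP, diastolic window, Vdiastole, dP, caFFR, caIMR) is known
    by construction, so the full index pipeline can be checked by round trip.

``generate_cohort``
    Draws a patient table emulating the study population: 213 patients
    (129 drug-eluting stent, 84 drug-coated balloon), covariate marginals
    calibrated to the published baseline table, treatment assignment
    confounded through a propensity model (so matching has something to
    fix), and 1-year outcome flags from configured logistic models:
    MACE on standardized symptom-to-balloon and door-to-balloon times, and
    CV-death/heart-failure-readmission (CorH) on the caIMR > 40 U indicator.
    The CorH event-type allocation among MACE cases is calibrated in closed
    form so the *marginal* CorH odds ratio for caIMR > 40 equals the
    configured value.

Outcome timing is not modelled: flags are 1-year cumulative, matching the
binary analysis they feed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import Centerline, StenosisSpec, discretize, make_vessel
from .hemodynamics import FlowProblem, FluidProperties, solve_pressure_drop
from .physiology import (
    Constants,
    ContrastPassage,
    DiastoleWindow,
    PhysiologyResult,
    PressureTrace,
    hyperemic_aortic_pressure,
    run_case,
)

__all__ = [
    "CohortConfig",
    "CohortTable",
    "CaseFixture",
    "generate_cohort",
    "generate_case_fixture",
]


# ---------------------------------------------------------------------------
# physiology case fixtures


class CaseFixture(NamedTuple):
    centerline: Centerline
    trace: PressureTrace
    passage: ContrastPassage
    ground_truth: PhysiologyResult
    window: DiastoleWindow


def _aortic_waveform(phase: np.ndarray, notch_phase: float = 0.45) -> np.ndarray:
    """Normalized aortic pressure shape over one cycle, phase in [0, 1).

    Piecewise: systolic upstroke from 0.25 to the peak 1.0 at phase 0.3,
    decline to 0.55 at the dicrotic notch (``notch_phase``), a small
    dicrotic wave, then a linear diastolic decay back to 0.25.  The notch
    is a strict local minimum, which the detection heuristic targets.
    """
    peak, w_notch, w_end, bump = 0.3, 0.55, 0.25, 0.12
    bump_len = 0.18
    p = np.empty_like(phase)
    ph = np.mod(phase, 1.0)
    m = ph <= peak
    p[m] = w_end + (1.0 - w_end) * np.sin(0.5 * np.pi * ph[m] / peak)
    m = (ph > peak) & (ph <= notch_phase)
    p[m] = w_notch + (1.0 - w_notch) * np.cos(
        0.5 * np.pi * (ph[m] - peak) / (notch_phase - peak)
    )
    m = (ph > notch_phase) & (ph <= notch_phase + bump_len)
    p[m] = w_notch + bump * np.sin(np.pi * (ph[m] - notch_phase) / bump_len)
    m = ph > notch_phase + bump_len
    p[m] = w_notch + (w_end - w_notch) * (ph[m] - notch_phase - bump_len) / (
        1.0 - notch_phase - bump_len
    )
    return p


def generate_case_fixture(
    stenosis_severity: float = 0.5,
    map_mmHg: float = 100.0,
    v_diastole_target: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    constants: Constants = Constants(),
    fluid: FluidProperties = FluidProperties(),
    proximal_radius_mm: float = 1.75,
    cycle_period_s: float = 0.8,
    n_cycles: int = 5,
    sample_rate_hz: float = 200.0,
    n_cells: int = 400,
) -> CaseFixture:
    """One synthetic acquisition with analytically known ground truth.

    The pressure trace has exact mean ``map_mmHg`` over integer cycles and a
    planted dicrotic notch at 45% of the cycle; the contrast passage is
    constructed so the window-endpoint quotient equals ``v_diastole_target``
    exactly.  Gaussian noise of ``noise_sd`` mmHg perturbs the pressure
    samples only — the recorded ground truth is unchanged.
    """
    if not (0.0 <= stenosis_severity <= 0.9):
        raise ValueError("stenosis severity must be in [0, 0.9]")
    if map_mmHg <= 0:
        raise ValueError("MAP must be positive")
    if v_diastole_target <= 0:
        raise ValueError("v_diastole_target must be positive")
    rng = np.random.default_rng(seed)
    T = cycle_period_s
    # the notch sits on a cine-frame boundary (5/12 of the cycle at 15 fps
    # for the default 0.8 s period), so the piecewise-linear contrast front
    # has its velocity kink exactly at a frame and the window-endpoint
    # quotient reproduces v_diastole_target exactly
    notch_phase = 5.0 / 12.0

    # vessel long enough for the contrast front to stay inside during the
    # measured cycle (slow advance in systole, v_target in diastole)
    v_sys = 0.5 * v_diastole_target
    overrun_s = 0.15  # frames recorded past cycle end, front still advancing
    travel = v_sys * notch_phase * T + v_diastole_target * ((1 - notch_phase) * T + overrun_s)
    length = max(75.0, travel + 10.0)
    sten = (
        None
        if stenosis_severity == 0
        else StenosisSpec(center_s=0.45 * length, length=12.0, severity=stenosis_severity)
    )
    vessel = make_vessel(length, proximal_radius_mm, sten, tortuosity_amplitude_mm=1.5,
                         n_points=601)

    # pressure trace: n_cycles full cycles starting at a cycle boundary
    dt = 1.0 / sample_rate_hz
    t = np.arange(0.0, n_cycles * T, dt)
    w = _aortic_waveform(t / T, notch_phase)
    # exact MAP over one cycle
    ph = np.arange(0.0, 1.0, 1.0 / 4096)
    w_mean = float(np.mean(_aortic_waveform(ph, notch_phase)))
    amp = 40.0
    pressure = map_mmHg + amp * (w - w_mean)
    if noise_sd > 0:
        pressure = pressure + rng.normal(0.0, noise_sd, size=pressure.shape)
    trace = PressureTrace(time=t, pressure=pressure)

    # ground-truth diastolic window: notch to cycle end of the first *full*
    # detected cycle; detection finds minima between systolic peaks, so the
    # first detected cycle is the second generated one
    k = 1
    window = DiastoleWindow(t_start=(k + notch_phase) * T, t_end=(k + 1.0) * T)

    # contrast passage across the measured cycle at 15 fps
    frame_dt = 1.0 / 15.0
    ft = np.arange(k * T, (k + 1) * T + overrun_s, frame_dt)
    front = np.where(
        ft <= window.t_start,
        2.0 + v_sys * (ft - k * T),
        2.0 + v_sys * notch_phase * T + v_diastole_target * (ft - window.t_start),
    )
    passage = ContrastPassage(frame_time=ft, front_s=front)

    # analytic ground truth
    pa_hyp = hyperemic_aortic_pressure(map_mmHg)
    mesh = discretize(vessel, n_cells)
    v_hyp = constants.K * v_diastole_target
    drop = solve_pressure_drop(FlowProblem(mesh=mesh, inlet_velocity=v_hyp, fluid=fluid))
    pd_hyp = pa_hyp - drop.total_dp
    gt = PhysiologyResult(
        map_mmHg=map_mmHg,
        pa_hyp_mmHg=pa_hyp,
        v_diastole_mm_s=v_diastole_target,
        v_hyp_mm_s=v_hyp,
        dp_mmHg=drop.total_dp,
        pd_hyp_mmHg=pd_hyp,
        ca_ffr=pd_hyp / pa_hyp,
        ca_imr=pd_hyp * constants.L / (constants.K * v_diastole_target),
        abnormal=pd_hyp * constants.L / (constants.K * v_diastole_target)
        > constants.abnormal_threshold,
        provenance={"constructed": True, "seed": seed, "noise_sd": noise_sd},
    )
    return CaseFixture(vessel, trace, passage, gt, window)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Distributional and effect-structure parameters of the simulated cohort.

    Continuous covariates are normal, skewed biomarkers log-normal, binary
    traits Bernoulli — matching the summary types the baseline table
    reports.  Defaults reproduce the published marginals (total column) and
    the published effect estimates as generator settings.  Odds ratios for
    the time covariates are per SD (the published per-unit scaling is not
    stated).
    """

    n_total: int = 213
    n_des: int = 129
    n_dcb: int = 84

    age_mean: float = 58.34
    age_sd: float = 13.11
    male_frac: float = 0.8404
    sbp_mean: float = 126.26
    sbp_sd: float = 18.45
    bmi_mean: float = 25.59
    bmi_sd: float = 4.22
    lvef_mean: float = 52.05
    lvef_sd: float = 9.72
    ckmb_median: float = 88.79  # ng/L, log-normal
    ckmb_log_sd: float = 1.0
    stob_mean: float = 6.85  # symptom-to-balloon, hours
    stob_sd: float = 3.28
    dtob_mean: float = 67.13  # door-to-balloon, minutes
    dtob_sd: float = 15.59
    caimr_mean_des: float = 36.49
    caimr_sd_des: float = 21.04
    caimr_mean_dcb: float = 34.23
    caimr_sd_dcb: float = 23.91

    # treatment-assignment (propensity) log-odds on standardized covariates;
    # signs follow the observed arm imbalances: DCB patients older, higher
    # SBP, higher LVEF, lower BMI, slightly fewer males
    propensity_coefs: dict = field(
        default_factory=lambda: {
            "age": 0.6, "sbp": 0.6, "lvef": 0.6, "bmi": -0.6, "male": -1.0
        }
    )
    # scale of the logistic noise added to the assignment score; smaller
    # values make the configured confounding express more deterministically
    assignment_noise: float = 0.5

    # outcome structure
    mace_rate: float = 33.0 / 213.0
    or_stob: float = 2.08  # per SD
    or_dtob: float = 1.36  # per SD
    or_corh_caimr40: float = 4.07  # marginal, caIMR>40 vs <=40
    p_corh_given_mace_base: float = 0.2  # P(event type is CorH | MACE, caIMR<=40)
    p_cv_death_given_corh: float = 0.4  # else HF readmission
    followup_months: float = 12.0

    def __post_init__(self) -> None:
        if self.n_des + self.n_dcb != self.n_total:
            raise ValueError("arm sizes must sum to n_total")
        if min(self.n_des, self.n_dcb) <= 0:
            raise ValueError("both arms must be non-empty")
        for p in (self.male_frac, self.mace_rate, self.p_corh_given_mace_base,
                  self.p_cv_death_given_corh):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        for sd in (self.age_sd, self.sbp_sd, self.bmi_sd, self.lvef_sd,
                   self.stob_sd, self.dtob_sd, self.caimr_sd_des, self.caimr_sd_dcb):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass(frozen=True)
class CohortTable:
    """A generated patient table plus generation provenance."""

    table: pd.DataFrame
    config_hash: str
    seed: int

    @property
    def n(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path, with_sidecar: bool = True) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# config_hash={self.config_hash} seed={self.seed}\n")
            self.table.to_csv(fh, index=False)
        if with_sidecar:
            schema = {
                "columns": {c: str(t) for c, t in self.table.dtypes.items()},
                "config_hash": self.config_hash,
                "seed": self.seed,
            }
            path.with_suffix(path.suffix + ".json").write_text(json.dumps(schema, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(path, comment="#")
        return cls(table=df, config_hash=meta.get("config_hash", ""), seed=int(meta.get("seed", -1)))


def _calibrate_intercept(linpred: np.ndarray, target_rate: float) -> float:
    """Intercept b0 such that mean(expit(b0 + linpred)) == target_rate."""
    from scipy.optimize import brentq
    from scipy.special import expit

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + linpred))) - target_rate

    return float(brentq(f, -20.0, 20.0))


def _corh_allocation_probs(config: CohortConfig, mace_rate: float) -> tuple[float, float]:
    """P(CorH | MACE, caIMR<=40) and P(CorH | MACE, caIMR>40), calibrated so
    the marginal CorH odds ratio for caIMR>40 equals the configured value.

    With caIMR independent of the MACE predictors, the marginal probability
    of CorH given the caIMR group is mace_rate * P(CorH | MACE, group); the
    high-group allocation follows in closed form from the target odds ratio.
    """
    q0 = config.p_corh_given_mace_base
    p0 = mace_rate * q0
    odds1 = config.or_corh_caimr40 * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    q1 = p1 / mace_rate
    if q1 >= 1.0:
        raise ValueError(
            "configured CorH odds ratio is infeasible: P(CorH|MACE, caIMR>40) "
            f"would be {q1:.2f} >= 1; lower p_corh_given_mace_base or the odds ratio"
        )
    return q0, q1


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    caimr_via_pipeline: bool = False,
) -> CohortTable:
    """Draw a synthetic STEMI cohort table.

    Covariates are drawn from the configured marginals; treatment is
    assigned by the confounded propensity model and then rebalanced to the
    exact arm sizes (highest propensity-plus-logistic-noise scores go to
    the DCB arm, preserving confounding); outcomes follow the configured
    logistic models.  Deterministic under (config, seed).

    With ``caimr_via_pipeline`` the per-patient caIMR is produced by running
    the full physiology pipeline on a per-patient case fixture (slow path)
    instead of being drawn from the configured arm distributions.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    n = config.n_total

    age = rng.normal(config.age_mean, config.age_sd, n)
    male = (rng.random(n) < config.male_frac).astype(int)
    sbp = rng.normal(config.sbp_mean, config.sbp_sd, n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    lvef = rng.normal(config.lvef_mean, config.lvef_sd, n)
    ckmb = np.exp(rng.normal(np.log(config.ckmb_median), config.ckmb_log_sd, n))
    stob = np.clip(rng.normal(config.stob_mean, config.stob_sd, n), 0.5, None)
    dtob = np.clip(rng.normal(config.dtob_mean, config.dtob_sd, n), 10.0, None)

    # confounded treatment assignment, rebalanced to exact arm sizes
    z = lambda x, m, s: (x - m) / s if s > 0 else np.zeros_like(x)
    standardized = {
        "age": z(age, config.age_mean, config.age_sd),
        "sbp": z(sbp, config.sbp_mean, config.sbp_sd),
        "lvef": z(lvef, config.lvef_mean, config.lvef_sd),
        "bmi": z(bmi, config.bmi_mean, config.bmi_sd),
        "male": male - config.male_frac,
        "stob": z(stob, config.stob_mean, config.stob_sd),
    }
    unknown = set(config.propensity_coefs) - set(standardized)
    if unknown:
        raise ValueError(f"unknown propensity covariates: {sorted(unknown)}")
    logit_ps = sum(
        coef * standardized[name] for name, coef in config.propensity_coefs.items()
    )
    logit_ps = np.asarray(logit_ps, dtype=float)
    score = logit_ps + rng.logistic(0.0, config.assignment_noise, n)
    dcb = np.zeros(n, dtype=int)
    dcb[np.argsort(score)[-config.n_dcb:]] = 1

    # caIMR per arm
    if caimr_via_pipeline:
        caimr = np.empty(n)
        for i in range(n):
            mu = config.caimr_mean_dcb if dcb[i] else config.caimr_mean_des
            sev = float(np.clip(rng.uniform(0.1, 0.7), 0, 0.9))
            vd = float(np.clip(rng.normal(150.0 - mu, 20.0), 40.0, 300.0))
            fx = generate_case_fixture(
                stenosis_severity=sev,
                map_mmHg=float(np.clip(rng.normal(100, 12), 70, 150)),
                v_diastole_target=vd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            caimr[i] = run_case(fx.centerline, fx.trace, fx.passage).ca_imr
    else:
        mu = np.where(dcb == 1, config.caimr_mean_dcb, config.caimr_mean_des)
        sd = np.where(dcb == 1, config.caimr_sd_dcb, config.caimr_sd_des)
        caimr = np.clip(rng.normal(mu, sd), 1.0, None)
    caimr_gt40 = (caimr > 40.0).astype(int)

    # MACE from the configured logistic on standardized times
    linpred = np.log(config.or_stob) * z(stob, config.stob_mean, config.stob_sd) + np.log(
        config.or_dtob
    ) * z(dtob, config.dtob_mean, config.dtob_sd)
    b0 = _calibrate_intercept(linpred, config.mace_rate)
    p_mace = expit(b0 + linpred)
    mace = (rng.random(n) < p_mace).astype(int)

    # event-type allocation among MACE cases, calibrated for the marginal
    # CorH odds ratio on caIMR>40
    q0, q1 = _corh_allocation_probs(config, float(np.mean(p_mace)))
    p_corh = np.where(caimr_gt40 == 1, q1, q0)
    corh = np.where((mace == 1) & (rng.random(n) < p_corh), 1, 0)

    cv_death = np.zeros(n, dtype=int)
    hf_readmission = np.zeros(n, dtype=int)
    is_corh = corh == 1
    cv_draw = rng.random(n) < config.p_cv_death_given_corh
    cv_death[is_corh & cv_draw] = 1
    hf_readmission[is_corh & ~cv_draw] = 1

    # remaining MACE cases get one of the other component events
    other = (mace == 1) & ~is_corh
    kinds = rng.choice(4, size=n, p=[0.25, 0.35, 0.3, 0.1])
    nonfatal_mi = (other & (kinds == 0)).astype(int)
    revasc = (other & (kinds == 1)).astype(int)
    recurrent_ua = (other & (kinds == 2)).astype(int)
    non_cv_death = (other & (kinds == 3)).astype(int)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": np.where(dcb == 1, "DCB", "DES"),
            "dcb": dcb,
            "age": age,
            "male": male,
            "sbp": sbp,
            "bmi": bmi,
            "lvef": lvef,
            "ckmb": ckmb,
            "stob_hours": stob,
            "dtob_minutes": dtob,
            "caimr": caimr,
            "caimr_gt40": caimr_gt40,
            "mace": mace,
            "cv_death": cv_death,
            "non_cv_death": non_cv_death,
            "nonfatal_mi": nonfatal_mi,
            "revascularization": revasc,
            "hf_readmission": hf_readmission,
            "recurrent_ua": recurrent_ua,
            "corh": corh,
            "followup_months": config.followup_months,
        }
    )
    # invariant: MACE is the union of its components
    comp = df[
        ["cv_death", "non_cv_death", "nonfatal_mi", "revascularization",
         "hf_readmission", "recurrent_ua"]
    ].max(axis=1)
    assert (df["mace"] == comp).all()
    return CohortTable(table=df, config_hash=config.config_hash, seed=seed)
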