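"""Synthetic Phase-IIa-like trial generator.

Generates SOFA datasets and PK concentration profiles with the
statistical structure the analysis assumes, so the whole pipeline is
testable without patient data.  The default design reproduces the
published trial summaries: 10 placebo subjects (baseline SOFA
12.10 +/- 4.36) and 24 drug subjects split 6/9/9 across the 0.06, 0.12
and 0.24 mg/kg arms (baselines 9.25 +/- 2.22, 9.56 +/- 3.09,
10.09 +/- 3.86; AUC0-8h 295.21 +/- 47.16, 827.85 +/- 334.10,
1482.51 +/- 378.34 h*ng/mL), SOFA observed pre-dose and daily for 8
days, q8h 1-hour infusions for 7 days with PK sampling at the protocol
times (pre-dose and 0.5, 1, 2, 6, 8 h after the first dose; pre-dose
and 0.5, 1, 2, 6, 12 h after the last).

Baselines are drawn from a normal truncated to [3, 24] and rounded to
integers; the normal's location is bias-corrected so that the mean of
the truncated-rounded draw matches the arm target.  AUCs are drawn from
a moment-matched lognormal (positivity).  Day-0 DV equals the baseline
exactly (it is the baseline measurement); later days get
predict + epsilon and are left continuous by default so sigma recovery
is unbiased (an integer-DV mode clips to [0, 24] and rounds, for
realism studies only).

The PK profile generator uses a one-compartment constant-rate-infusion
superposition model.  Its clearance calibration targets the
protocol-time trapezoidal NCA average of the first- and last-dose
AUC0-8h — i.e. the quantity the trial actually measured and summarised
— rather than the analytic steady-state dose/CL; the analytic mode is
available as ``calibration="analytic"``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import ConcentrationProfile, ObservationRecord, SubjectRecord, TrialDataset
from .estimation import VarianceParams
from .model import StructuralParams, predict_sofa

__all__ = [
    "ArmDesign",
    "TrialDesign",
    "TruthParams",
    "PKParams",
    "default_design",
    "default_truth",
    "generate_trial",
    "generate_pk_profiles",
    "dropout_hazard_for_target",
    "draw_baselines",
    "draw_aucs",
    "steady_state_concentration",
]

#: q8h regimen: infusion duration and interval (hours), 7 days of dosing.
INFUSION_HOURS = 1.0
DOSING_INTERVAL_HOURS = 8.0
N_DOSES = 21  # 3 per day for 7 days

_BASELINE_RANGE = (3.0, 24.0)

_DOSE_MG_PER_KG = {"0.06": 0.06, "0.12": 0.12, "0.24": 0.24}


@dataclass(frozen=True)
class ArmDesign:
    """One arm: label, size, and baseline/AUC summary statistics."""

    label: str
    n: int
    base_mean: float
    base_sd: float
    auc_mean: float
    auc_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"arm {self.label}: n must be >= 1")
        if self.base_sd < 0 or self.auc_sd < 0:
            raise ValueError(f"arm {self.label}: SDs must be >= 0")
        if (self.label == "placebo") != (self.auc_mean == 0.0):
            raise ValueError(f"arm {self.label}: placebo iff AUC mean 0")


@dataclass(frozen=True)
class TrialDesign:
    """Trial layout: arms, observation days, dropout, PK sampling times."""

    arms: tuple[ArmDesign, ...]
    days: tuple[float, ...] = tuple(float(d) for d in range(9))
    dropout_hazard: float = 0.0
    pk_times_first: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 6.0, 8.0)
    pk_times_last: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 6.0, 12.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        if not (0.0 <= self.dropout_hazard < 1.0):
            raise ValueError("dropout_hazard must lie in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return sum(a.n for a in self.arms)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth fixed and random effects for generation."""

    structural: StructuralParams
    variance: VarianceParams


@dataclass(frozen=True)
class PKParams:
    """One-compartment infusion PK used only to exercise the NCA stage.

    ``half_life_h`` sets the elimination rate; no PK model was reported
    for the compound, so a mid-single-digit-hour half-life consistent
    with quantifiable concentrations 12 h after the last dose is used.
    ``calibration`` chooses whether clearance targets the protocol-time
    NCA average ("nca", default — what the trial measured) or the
    analytic steady-state dose/CL ("analytic").
    """

    half_life_h: float = 3.0
    body_weight_kg: float = 70.0
    calibration: str = "nca"

    def __post_init__(self) -> None:
        if self.half_life_h <= 0 or self.body_weight_kg <= 0:
            raise ValueError("PK parameters must be positive")
        if self.calibration not in ("nca", "analytic"):
            raise ValueError("calibration must be 'nca' or 'analytic'")


def default_design() -> TrialDesign:
    """The published Phase IIa analyzable set: 10 placebo + 6/9/9 drug subjects."""
    return TrialDesign(
        arms=(
            ArmDesign("placebo", 10, 12.10, 4.36, 0.0, 0.0),
            ArmDesign("0.06", 6, 9.25, 2.22, 295.21, 47.16),
            ArmDesign("0.12", 9, 9.56, 3.09, 827.85, 334.10),
            ArmDesign("0.24", 9, 10.09, 3.86, 1482.51, 378.34),
        )
    )


def default_truth(iiv_as_cv: bool = True) -> TruthParams:
    """Final published estimates as generating truth.

    The reported IIV of 30.2 on k is read as a CV%, giving
    omega = 0.302 * k; set ``iiv_as_cv=False`` to read it as the SD
    itself (0.302 /day).
    """
    sp = StructuralParams(f_placebo=0.792, k=0.263, kin=0.0569, eauc50=1320.0)
    omega = 0.302 * sp.k if iiv_as_cv else 0.302
    return TruthParams(structural=sp, variance=VarianceParams(omega=omega, sigma=1.96))


# ---------------------------------------------------------------------------
# distribution helpers (shared with the simulation module)


def _truncnorm_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))


def _bias_corrected_mu(target: float, sd: float, lo: float, hi: float) -> float:
    """Location such that the truncated normal's mean equals ``target``.

    Rounding to integers adds O(1e-3) bias at these SDs, far below the
    0.05 tolerance, so only the truncation is corrected analytically.
    """
    if sd == 0:
        return target
    f = lambda mu: _truncnorm_mean(mu, sd, lo, hi) - target
    span = 6.0 * sd
    if f(target - span) > 0 or f(target + span) < 0:
        raise ValueError(f"target mean {target} infeasible within [{lo}, {hi}] at sd={sd}")
    return float(optimize.brentq(f, target - span, target + span, xtol=1e-10))


def draw_baselines(rng: np.random.Generator, n: int, mean: float, sd: float,
                   integer: bool = True) -> np.ndarray:
    """Baseline SOFA draws: truncated normal on [3, 24], bias-corrected, rounded."""
    lo, hi = _BASELINE_RANGE
    if sd == 0:
        values = np.full(n, mean)
    else:
        mu = _bias_corrected_mu(mean, sd, lo, hi)
        a, b = (lo - mu) / sd, (hi - mu) / sd
        values = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    return np.round(values) if integer else values


def draw_aucs(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Exposure draws: lognormal moment-matched to (mean, sd); 0 for placebo."""
    if mean == 0:
        return np.zeros(n)
    if sd == 0:
        return np.full(n, mean)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n)


# ---------------------------------------------------------------------------
# SOFA dataset generation


def dropout_hazard_for_target(n_target_obs: int = 245,
                              design: TrialDesign | None = None) -> float:
    """Per-day dropout hazard whose *expected* observation count hits the target.

    With hazard p, a subject contributes the day-0 row plus day d with
    probability (1-p)^d; solve E[obs] = n_target for p.  The default 245
    matches the number of measurable SOFA scores in the published
    analyzable set (out of 34*9 = 306 possible).
    """
    design = design or default_design()
    n_sub = design.n_subjects
    post_days = [d for d in design.days if d > 0]

    def expected(p: float) -> float:
        q = 1.0 - p
        return n_sub * (1.0 + sum(q**d for d in post_days))

    if not (n_sub <= n_target_obs <= n_sub * len(design.days)):
        raise ValueError(f"target {n_target_obs} outside the feasible range")
    return float(optimize.brentq(lambda p: expected(p) - n_target_obs, 0.0, 0.999999))


def generate_trial(design: TrialDesign, truth: TruthParams, seed: int,
                   integer_dv: bool = False) -> TrialDataset:
    """Draw one synthetic trial; fully reproducible given ``seed``.

    Per subject: baseline ~ rounded truncated normal, AUC ~ lognormal
    (0 for placebo), eta_k ~ N(0, omega^2); the day-0 DV equals the
    baseline and later DVs are predict + N(0, sigma^2).  A positive
    ``dropout_hazard`` truncates each subject's follow-up geometrically.
    """
    rng = np.random.default_rng(seed)
    sp, vp = truth.structural, truth.variance
    subjects = []
    counter = 0
    for arm in design.arms:
        bases = draw_baselines(rng, arm.n, arm.base_mean, arm.base_sd)
        aucs = draw_aucs(rng, arm.n, arm.auc_mean, arm.auc_sd)
        etas = rng.normal(0.0, vp.omega, size=arm.n) if vp.omega > 0 else np.zeros(arm.n)
        for base, auc, eta in zip(bases, aucs, etas):
            counter += 1
            sid = f"S{counter:03d}"
            last_day = np.inf
            if design.dropout_hazard > 0:
                # geometric time-to-dropout in days
                last_day = rng.geometric(design.dropout_hazard) - 1
            obs = []
            for day in design.days:
                if day > last_day:
                    break
                if day == 0:
                    dv = float(base)
                else:
                    dv = float(predict_sofa(day, base, auc, sp, eta_k=eta)
                               + rng.normal(0.0, vp.sigma))
                    if integer_dv:
                        dv = float(np.clip(np.round(dv), 0.0, 24.0))
                obs.append(ObservationRecord(day=float(day), sofa=dv))
            subjects.append(
                SubjectRecord(id=sid, arm=arm.label, base=float(base),
                              auc=float(auc), observations=tuple(obs))
            )
    return TrialDataset(subjects=tuple(subjects))


# ---------------------------------------------------------------------------
# PK profile generation


def steady_state_concentration(t_after_dose: np.ndarray, dose_ng: float,
                               cl_ml_h: float, ke_per_h: float,
                               n_prior_doses: int) -> np.ndarray:
    """Concentration (ng/mL) at times after the start of a dose, by
    superposition of ``n_prior_doses`` earlier q8h 1-h infusions plus
    the current one."""
    t = np.asarray(t_after_dose, dtype=float)
    rate = dose_ng / INFUSION_HOURS
    v_ml = cl_ml_h / ke_per_h
    conc = np.zeros_like(t)
    for d in range(n_prior_doses + 1):
        t0 = -d * DOSING_INTERVAL_HOURS  # start time of dose d before current
        dt = t - t0
        during = (dt >= 0) & (dt <= INFUSION_HOURS)
        after = dt > INFUSION_HOURS
        conc[during] += rate / cl_ml_h * (1.0 - np.exp(-ke_per_h * dt[during]))
        conc[after] += (rate / cl_ml_h * (1.0 - np.exp(-ke_per_h * INFUSION_HOURS))
                        * np.exp(-ke_per_h * (dt[after] - INFUSION_HOURS)))
    return conc


def _shape_factor(design: TrialDesign, dose_ng: float, ke: float) -> float:
    """Average of first- and last-dose protocol-time trapezoid AUC0-8h
    at unit clearance; concentrations scale as 1/CL so the NCA output
    for clearance CL is dose_ng * phi / CL with phi this factor / dose."""
    from .nca import auc_0_8  # local import: nca must stay importable alone

    first = ConcentrationProfile(
        id="_cal", occasion="first_dose",
        samples=tuple(zip(design.pk_times_first,
                          steady_state_concentration(np.asarray(design.pk_times_first),
                                                     dose_ng, 1.0, ke, 0))),
    )
    last = ConcentrationProfile(
        id="_cal", occasion="last_dose",
        samples=tuple(zip(design.pk_times_last,
                          steady_state_concentration(np.asarray(design.pk_times_last),
                                                     dose_ng, 1.0, ke, N_DOSES - 1))),
    )
    return 0.5 * (auc_0_8(first) + auc_0_8(last))


def generate_pk_profiles(design: TrialDesign, pk_params: PKParams | None = None,
                         seed: int = 0) -> list[ConcentrationProfile]:
    """First- and last-dose concentration profiles for every drug subject.

    Per-subject clearance is set so the subject's exposure measure (the
    averaged protocol-time NCA, or the analytic dose/CL under
    ``calibration="analytic"``) equals an AUC drawn from the arm's
    moment-matched lognormal — i.e. between-subject variability enters
    through clearance and reproduces the arm AUC distribution.
    """
    pk = pk_params or PKParams()
    rng = np.random.default_rng(seed)
    ke = np.log(2.0) / pk.half_life_h
    profiles: list[ConcentrationProfile] = []
    counter = 0
    for arm in design.arms:
        if arm.label == "placebo":
            counter += arm.n
            continue
        dose_ng = _DOSE_MG_PER_KG[arm.label] * pk.body_weight_kg * 1e6  # mg -> ng
        if pk.calibration == "nca":
            unit_cl_auc = _shape_factor(design, dose_ng, ke)
        else:
            unit_cl_auc = dose_ng  # analytic steady-state AUC0-8 = dose/CL
        target_aucs = draw_aucs(rng, arm.n, arm.auc_mean, arm.auc_sd)
        for auc in target_aucs:
            counter += 1
            sid = f"S{counter:03d}"
            cl = unit_cl_auc / auc
            t_first = np.asarray(design.pk_times_first)
            t_last = np.asarray(design.pk_times_last)
            c_first = steady_state_concentration(t_first, dose_ng, cl, ke, 0)
            c_last = steady_state_concentration(t_last, dose_ng, cl, ke, N_DOSES - 1)
            profiles.append(ConcentrationProfile(
                id=sid, occasion="first_dose", samples=tuple(zip(t_first, c_first))))
            profiles.append(ConcentrationProfile(
                id=sid, occasion="last_dose", samples=tuple(zip(t_last, c_last))))
    return profiles
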