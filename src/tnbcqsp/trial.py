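"""In-silico clinical trials on virtual patient populations.

Workflow: sample parameter sets by Latin-hypercube sampling from the
shipped (or user) distributions; grow each patient's tumor from a small
seed until it first crosses the sampled pre-treatment diameter (patients
that never reach it are eliminated); filter on physiologically reasonable
pre-treatment characteristics; then simulate 400 days of treatment with
tumor diameter recorded every 8 weeks, classify response per RECIST 1.1
or irRC, and summarize ORR and duration of response with bootstrap
confidence intervals.

A virtual patient with a tumor below 2 mm is a complete responder; stable
disease requires a minimum duration of 8 weeks.  New-lesion events are
not modeled, so classification uses size only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .framework import IntegrationError, ODESystem, simulate
from .model import build_spec, default_parameters
from .params import ParameterDistribution, ParameterSet, distributions_from_csv
from .pharmacology import regimen_doses
from .stats import BootstrapSummary, bootstrap_ci, km_median, latin_hypercube
from .units import DAYS_PER_MONTH

MEASUREMENT_INTERVAL = 56.0  # days between tumor-size measurements (8 weeks)
CR_DIAMETER_CM = 0.2  # < 2 mm counts as complete response
TRIAL_HORIZON = 400.0  # days of treatment simulated per patient


def default_distributions() -> dict[str, ParameterDistribution]:
    """The shipped virtual-patient parameter distributions."""
    with resources.files("tnbcqsp.data").joinpath("distributions.csv").open() as fh:
        return distributions_from_csv(fh)


def default_plausibility_ranges() -> dict[str, tuple[float, float]]:
    """Measured pre-treatment ranges used as the plausibility filter
    (3-D cellular densities in cell/mL, cytokines in pg/mL)."""
    return {
        "CD8_density": (7.6e4, 3.4e9),
        "CD4_density": (6.1e4, 1.2e10),
        "Treg_density": (5.8e4, 1.7e9),
        "Mac_density": (3.2e4, 1.3e8),
        "MDSC_density": (4.3e2, 5.3e7),
        "M1_M2_ratio": (0.0, 26.0),
    }


@dataclass
class PatientRecord:
    pid: int
    params: ParameterSet
    target_diameter: float  # cm
    status: str = "sampled"  # sampled|initialized|eliminated|filtered_out|completed|unevaluable
    reason: str = ""
    baseline_state: np.ndarray | None = None
    baseline_day: float | None = None
    pre_treatment: dict[str, float] = field(default_factory=dict)
    measurements: np.ndarray | None = None  # diameters (cm) on the visit grid
    visit_days: np.ndarray | None = None


@dataclass
class ResponseAssessment:
    criteria: str
    visit_categories: list[str]  # per post-baseline visit: CR|PR|SD|PD|NE
    best_overall: str
    response_onset_day: float | None
    progression_day: float | None

    @property
    def responder(self) -> bool:
        return self.best_overall in ("CR", "PR")


@dataclass
class TrialResult:
    regimen: str
    criteria: str
    patients: pd.DataFrame  # one row per evaluable patient
    orr: float
    orr_ci: BootstrapSummary
    dor_months: np.ndarray
    dor_censored: np.ndarray
    dor_median: float
    dor_median_ci: BootstrapSummary | None


# ------------------------------------------------------------- population
def generate_population(
    distributions: dict[str, ParameterDistribution],
    n: int,
    seed: int,
    base_params: ParameterSet | None = None,
) -> list[PatientRecord]:
    """LHS-stratified virtual patients; reproducible under ``seed``."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    base = base_params or default_parameters()
    names = sorted(distributions)
    rng = np.random.default_rng(seed)
    u = latin_hypercube(n, len(names), rng)
    patients = []
    for i in range(n):
        p = base.copy()
        for j, name in enumerate(names):
            p.set(name, float(distributions[name].ppf(u[i, j])))
        patients.append(
            PatientRecord(pid=i, params=p, target_diameter=p["D_T0"])
        )
    return patients


def _patient_system(record: PatientRecord) -> ODESystem:
    return build_spec(record.params).assemble()


def characteristics(system: ODESystem, y: np.ndarray) -> dict[str, float]:
    """Pre-treatment population characteristics from one state vector."""
    idx = system.state_index
    p = system.spec.params
    v_t = system.rule_value("V_T", y)
    get = lambda n: float(y[idx[n]])  # noqa: E731
    m1, m2 = get("Mac_M1"), get("Mac_M2")
    return {
        "CD8_density": get("Teff_T") / v_t,
        "CD4_density": (get("Th_T") + get("Treg_T")) / v_t,
        "Th_density": get("Th_T") / v_t,
        "Treg_density": get("Treg_T") / v_t,
        "CD8_Treg_ratio": get("Teff_T") / max(get("Treg_T"), 1e-9),
        "CD4_Treg_ratio": (get("Th_T") + get("Treg_T")) / max(get("Treg_T"), 1e-9),
        "Mac_density": (m1 + m2) / v_t,
        "M1_density": m1 / v_t,
        "M2_density": m2 / v_t,
        "M1_M2_ratio": m1 / max(m2, 1e-9),
        "MDSC_density": get("MDSC") / v_t,
        "naive_CD4_density": p["div_CD4"] * get("nT_Th_C") / p["V_C"],
        "naive_CD8_density": p["div_CD8"] * get("nT_Teff_C") / p["V_C"],
        "IL10": get("IL10_T"),
        "IFNg": get("IFNg_T"),
        "CCL2": get("CCL2_T"),
        "PDL1_density": p["PDL1_dens_C"],
        "PDL2_density": p["r_PDL2"] * p["PDL1_dens_C"],
        "PD1_M_density": p["PD1_dens_M"],
        "SIRPa_density": p["SIRPa_dens_M"],
        "tumor_diameter": system.rule_value("D_T", y),
    }


def initialize_patient(
    record: PatientRecord, horizon: float = 3000.0
) -> PatientRecord:
    """Grow the tumor from the seed until the target diameter is crossed.

    The state at the crossing is frozen as the pre-treatment baseline; a
    patient whose tumor never reaches the target within ``horizon`` days
    is eliminated.
    """
    record.params.set("D_T0", record.target_diameter)
    system = _patient_system(record)
    try:
        traj = simulate(
            system,
            (0.0, horizon),
            record_grid=horizon,  # only endpoints; the event does the work
            stop_when=("D_T", record.target_diameter, +1),
        )
    except IntegrationError as exc:
        record.status = "eliminated"
        record.reason = f"integration failure at t={exc.time}"
        return record
    if traj.stopped_at is None:
        record.status = "eliminated"
        record.reason = "pre-treatment size not reached"
        return record
    record.baseline_day = traj.stopped_at
    record.baseline_state = traj.states.iloc[-1].to_numpy()
    record.pre_treatment = characteristics(system, record.baseline_state)
    record.status = "initialized"
    return record


def apply_plausibility_filter(
    record: PatientRecord,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> PatientRecord:
    """Drop a patient whose pre-treatment characteristics leave the
    physiologically reasonable ranges; reasons are logged on the record."""
    if record.status != "initialized":
        return record
    ranges = default_plausibility_ranges() if ranges is None else ranges
    reasons = []
    for name, (lo, hi) in ranges.items():
        value = record.pre_treatment.get(name)
        if value is not None and not (lo <= value <= hi):
            reasons.append(f"{name}={value:.3g} outside [{lo:.3g}, {hi:.3g}]")
    if reasons:
        record.status = "filtered_out"
        record.reason = "; ".join(reasons)
    return record


# ------------------------------------------------------------ classification
def classify_response(
    measurements: np.ndarray,
    criteria: str = "RECIST1_1",
    visit_days: np.ndarray | None = None,
    unit: str = "cm",
    require_absolute_increase: bool = True,
) -> ResponseAssessment:
    """Classify a diameter series (baseline at index 0) per visit.

    RECIST 1.1: PR at <= -30% vs baseline, PD at >= +20% vs nadir (plus a
    5 mm absolute increase when ``require_absolute_increase``), CR below
    2 mm; SD otherwise once at least 8 weeks from baseline.  irRC: PR at
    <= -50% vs baseline, PD at >= +25% vs nadir, same CR rule.
    """
    if criteria not in ("RECIST1_1", "irRC"):
        raise ValueError(f"unknown criteria {criteria!r}")
    scale = {"cm": 1.0, "mm": 0.1}[unit]
    d = np.asarray(measurements, dtype=float) * scale
    if d.ndim != 1 or d.size < 2:
        return ResponseAssessment(criteria, [], "NE", None, None)
    days = (
        np.asarray(visit_days, dtype=float)
        if visit_days is not None
        else np.arange(d.size) * MEASUREMENT_INTERVAL
    )
    baseline = d[0]
    if baseline <= 0:
        raise ValueError("baseline diameter must be positive")
    pr_threshold = -30.0 if criteria == "RECIST1_1" else -50.0
    pd_threshold = 20.0 if criteria == "RECIST1_1" else 25.0

    cats: list[str] = []
    onset = progression = None
    nadir = baseline
    for k in range(1, d.size):
        perc = (d[k] - baseline) / baseline * 100.0
        vs_nadir = (d[k] - nadir) / nadir * 100.0
        absolute_ok = (
            d[k] - nadir >= 0.5 or not require_absolute_increase
            if criteria == "RECIST1_1"
            else True
        )
        if d[k] < CR_DIAMETER_CM:
            cat = "CR"
        elif vs_nadir >= pd_threshold and absolute_ok:
            cat = "PD"  # progression takes precedence over response
        elif perc <= pr_threshold:
            cat = "PR"
        elif days[k] - days[0] >= MEASUREMENT_INTERVAL:
            cat = "SD"
        else:
            cat = "NE"
        cats.append(cat)
        nadir = min(nadir, d[k])
        if cat in ("CR", "PR") and onset is None:
            onset = float(days[k])
        if cat == "PD" and progression is None:
            progression = float(days[k])

    order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3, "NE": 4}
    best = min(cats, key=lambda c: order[c]) if cats else "NE"
    return ResponseAssessment(criteria, cats, best, onset, progression)


def duration_of_response(
    assessment: ResponseAssessment, horizon: float = TRIAL_HORIZON
) -> tuple[float, bool]:
    """Months from response onset to progression; censored at the horizon
    when no progression follows the response.  Undefined (ValueError) for
    non-responders."""
    if assessment.response_onset_day is None:
        raise ValueError("duration of response is defined only for responders")
    if (
        assessment.progression_day is not None
        and assessment.progression_day > assessment.response_onset_day
    ):
        days = assessment.progression_day - assessment.response_onset_day
        return days / DAYS_PER_MONTH, False
    return (horizon - assessment.response_onset_day) / DAYS_PER_MONTH, True


# ------------------------------------------------------------------- trial
def run_trial(
    population: list[PatientRecord],
    regimen: str,
    criteria: str = "RECIST1_1",
    horizon: float = TRIAL_HORIZON,
    trial_n: int | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> TrialResult:
    """Simulate treatment for every initialized patient and summarize.

    ``trial_n`` is the bootstrap resample size (defaults to the number of
    evaluable virtual patients; set it to the enrolled size of the
    clinical study being matched).
    """
    rows = []
    visit_days = np.arange(0.0, horizon + 1e-9, MEASUREMENT_INTERVAL)
    for rec in population:
        if rec.status not in ("initialized", "completed"):
            continue
        system = _patient_system(rec)
        doses = regimen_doses(regimen, rec.params, horizon)
        try:
            traj = simulate(
                system, (0.0, horizon), doses=doses,
                record_grid=visit_days, y0=rec.baseline_state,
            )
        except (IntegrationError, RuntimeError) as exc:
            rec.status = "unevaluable"
            rec.reason = str(exc)
            continue
        d_series = np.interp(visit_days, traj.t, traj.value("D_T"))
        rec.measurements = d_series
        rec.visit_days = visit_days
        rec.status = "completed"
        assessment = classify_response(d_series, criteria, visit_days)
        row = {
            "pid": rec.pid,
            "baseline_cm": d_series[0],
            "best_overall": assessment.best_overall,
            "responder": assessment.responder,
            "onset_day": assessment.response_onset_day,
            "progression_day": assessment.progression_day,
        }
        if assessment.responder:
            dor, censored = duration_of_response(assessment, horizon)
            row["dor_months"], row["dor_censored"] = dor, censored
        else:
            row["dor_months"], row["dor_censored"] = math.nan, True
        row.update(rec.pre_treatment)
        rows.append(row)

    patients = pd.DataFrame(rows)
    if patients.empty:
        raise ValueError("no evaluable patients in the population")
    responders = patients["responder"].to_numpy(dtype=float)
    resample = trial_n or len(patients)
    orr_ci = bootstrap_ci(
        responders, lambda a: 100.0 * a.mean(), resample, n_boot, seed,
        name=f"ORR({regimen})",
    )
    dor = patients.loc[patients.responder, "dor_months"].to_numpy(dtype=float)
    cens = patients.loc[patients.responder, "dor_censored"].to_numpy(dtype=bool)
    dor_median = km_median(dor, cens) if dor.size else math.nan
    dor_ci = None
    if dor.size >= 3:
        paired = np.column_stack([dor, cens.astype(float)])

        def med(sample_idx):
            s = paired[np.asarray(sample_idx, dtype=int)]
            return km_median(s[:, 0], s[:, 1].astype(bool))

        rng = np.random.default_rng(seed + 1)
        draws = rng.integers(0, len(paired), size=(min(n_boot, 1000), len(paired)))
        meds = np.array([med(ix) for ix in draws])
        lo, mid, hi = np.nanpercentile(meds, [2.5, 50.0, 97.5])
        dor_ci = BootstrapSummary("DOR median", float(mid), float(lo),
                                  float(hi), len(paired),
                                  min(n_boot, 1000), seed + 1)
    return TrialResult(
        regimen=regimen, criteria=criteria, patients=patients,
        orr=100.0 * float(responders.mean()), orr_ci=orr_ci,
        dor_months=dor, dor_censored=cens,
        dor_median=dor_median, dor_median_ci=dor_ci,
    )


def subgroup_orr(
    result: TrialResult,
    variable: str,
    scheme: str = "median_split",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """ORR (with bootstrap CIs) across subgroups of a pre-treatment variable.

    ``median_split`` yields two groups; ``quintiles`` sorts ascending and
    splits into five equal subgroups.
    """
    if variable not in result.patients.columns:
        raise KeyError(f"unknown pre-treatment variable {variable!r}")
    frame = result.patients.sort_values(variable).reset_index(drop=True)
    if scheme == "median_split":
        cut = frame[variable].median()
        groups = [("low", frame[frame[variable] <= cut]),
                  ("high", frame[frame[variable] > cut])]
    elif scheme == "quintiles":
        parts = np.array_split(frame, 5)
        groups = [(f"Q{k + 1}", part) for k, part in enumerate(parts)]
    else:
        raise ValueError(f"unknown subgroup scheme {scheme!r}")
    rows = []
    for label, part in groups:
        if len(part) == 0:
            rows.append({"subgroup": label, "n": 0, "orr": math.nan,
                         "ci_low": math.nan, "ci_high": math.nan,
                         "median_level": math.nan})
            continue
        ci = bootstrap_ci(
            part["responder"].to_numpy(dtype=float),
            lambda a: 100.0 * a.mean(), len(part), n_boot, seed, name=label,
        )
        rows.append({
            "subgroup": label, "n": len(part),
            "orr": 100.0 * part["responder"].mean(),
            "ci_low": ci.ci_low, "ci_high": ci.ci_high,
            "median_level": part[variable].median(),
        })
    return pd.DataFrame(rows)
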