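"""Global sensitivity (LHS-PRCC), bootstrap intervals, Kaplan-Meier,
and derivative-free least-squares fitting.

PRCC: all columns are rank-transformed; each parameter's partial
correlation with the output controls for every other parameter by linear
regression on the ranks, with two-sided p-values from the t-statistic on
n - p - 2 degrees of freedom.  Bootstrap intervals resample per-patient
outcomes with a resample size matching the clinical trial being compared
against, reporting the median and 2.5/97.5 percentiles of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


# --------------------------------------------------------------------- LHS
def latin_hypercube(n: int, dims: int, rng: np.random.Generator) -> np.ndarray:
    """n-by-dims Latin hypercube: per column, exactly one sample in each of
    the n equal-probability strata, uniformly placed within its stratum."""
    if n < 1 or dims < 1:
        raise ValueError("n and dims must be >= 1")
    u = (rng.random((n, dims)) + np.arange(n)[:, None]) / n
    for j in range(dims):
        u[:, j] = u[rng.permutation(n), j]
    return u


# -------------------------------------------------------------------- PRCC
@dataclass
class SensitivityResult:
    parameters: list[str]
    prcc: np.ndarray
    p_values: np.ndarray
    output: str = "output"

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"parameter": self.parameters, "prcc": self.prcc,
             "p_value": self.p_values}
        )
        return frame.reindex(frame.prcc.abs().sort_values(ascending=False).index)


def prcc(
    samples: np.ndarray,
    output: np.ndarray,
    names: Sequence[str] | None = None,
    output_name: str = "output",
) -> SensitivityResult:
    """Partial rank correlation of each column of ``samples`` with ``output``.

    Requires n > p + 2.  Constant columns are flagged with NaN coefficients
    (their PRCC is undefined).
    """
    x = np.asarray(samples, dtype=float)
    y = np.asarray(output, dtype=float)
    n, p = x.shape
    if y.shape != (n,):
        raise ValueError("output length must match the sample count")
    if n <= p + 2:
        raise ValueError("need more samples than parameters + 2")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]

    xr = np.apply_along_axis(sps.rankdata, 0, x)
    yr = sps.rankdata(y)
    coeffs = np.full(p, np.nan)
    pvals = np.full(p, np.nan)
    dof = n - p - 2
    for j in range(p):
        if np.ptp(x[:, j]) == 0:
            continue
        others = np.column_stack(
            [np.ones(n), np.delete(xr, j, axis=1)]
        )
        res_x = xr[:, j] - others @ np.linalg.lstsq(others, xr[:, j], rcond=None)[0]
        res_y = yr - others @ np.linalg.lstsq(others, yr, rcond=None)[0]
        denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
        if denom == 0:
            continue
        r = float(np.clip(res_x @ res_y / denom, -1.0, 1.0))
        coeffs[j] = r
        if abs(r) < 1.0:
            tstat = r * np.sqrt(dof / (1.0 - r * r))
            pvals[j] = 2.0 * sps.t.sf(abs(tstat), dof)
        else:
            pvals[j] = 0.0
    return SensitivityResult(names, coeffs, pvals, output_name)


# --------------------------------------------------------------- bootstrap
@dataclass
class BootstrapSummary:
    statistic: str
    median: float
    ci_low: float
    ci_high: float
    resample_size: int
    n_boot: int
    seed: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def bootstrap_ci(
    outcomes: Sequence[float],
    statistic: Callable[[np.ndarray], float],
    trial_n: int,
    n_boot: int = 10_000,
    seed: int = 0,
    name: str = "statistic",
) -> BootstrapSummary:
    """Percentile bootstrap of ``statistic`` over resamples of size
    ``trial_n`` (the enrolled size of the clinical study being matched)."""
    arr = np.asarray(outcomes, dtype=float)
    if arr.size == 0:
        raise ValueError("outcomes must be nonempty")
    if trial_n < 1:
        raise ValueError("trial_n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, arr.size, size=(n_boot, trial_n))
    values = np.array([statistic(arr[idx]) for idx in draws])
    lo, med, hi = np.nanpercentile(values, [2.5, 50.0, 97.5])
    return BootstrapSummary(name, float(med), float(lo), float(hi),
                            trial_n, n_boot, seed)


# ----------------------------------------------------------- Kaplan-Meier
def km_curve(durations: Sequence[float], censored: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival table with the median read at S(t) = 0.5.

    ``censored[i]`` is True when patient i had not progressed by the end of
    follow-up.  Returns a frame with columns (time, survival); the median
    is exposed via :func:`km_median`.
    """
    from lifelines import KaplanMeierFitter

    durations = np.asarray(durations, dtype=float)
    if (durations < 0).any():
        raise ValueError("durations must be >= 0")
    events = ~np.asarray(censored, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.survival_function_.reset_index()
    table.columns = ["time", "survival"]
    return table


def km_median(durations: Sequence[float], censored: Sequence[bool]) -> float:
    """Median survival time; NaN when not reached (all censored or S > 0.5)."""
    from lifelines import KaplanMeierFitter

    events = ~np.asarray(censored, dtype=bool)
    if not events.any():
        return float("nan")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(durations, dtype=float), event_observed=events)
    med = kmf.median_survival_time_
    return float(med) if np.isfinite(med) else float("nan")


# ------------------------------------------------------------------ fitting
@dataclass
class FitResult:
    values: dict[str, float]
    mse: float
    converged: bool
    n_iter: int


def fit_parameters(
    predict: Callable[[dict[str, float]], np.ndarray],
    observed: np.ndarray,
    init: dict[str, float],
    max_iter: int = 2000,
) -> FitResult:
    """Nelder-Mead simplex minimization of the mean squared difference
    between observed values and ``predict(params)`` (same length/grid).

    ``predict`` maps a parameter dict to the model's predicted series;
    non-convergence returns the best values found with ``converged=False``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("observed data must be nonempty")
    if not init:
        raise ValueError("at least one free parameter is required")
    names = list(init)
    x0 = np.array([init[k] for k in names], dtype=float)

    def loss(x: np.ndarray) -> float:
        pred = predict(dict(zip(names, x)))
        return float(np.mean((np.asarray(pred) - observed) ** 2))

    res = optimize.minimize(
        loss, x0, method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-12},
    )
    return FitResult(dict(zip(names, res.x)), float(res.fun),
                     bool(res.success), int(res.nit))
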