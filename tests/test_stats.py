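"""LHS-PRCC, bootstrap intervals, Kaplan-Meier, and simplex fitting."""

import numpy as np
import pytest
from scipy import stats as sps

import tnbcqsp as q
from tnbcqsp.stats import (
    bootstrap_ci,
    fit_parameters,
    km_curve,
    km_median,
    latin_hypercube,
    prcc,
)


# -------------------------------------------------------------------- PRCC
def _prcc_precision_oracle(x, y):
    """Independent construction: partial correlations from the inverse of
    the rank correlation matrix of [X, y]."""
    ranks = np.column_stack(
        [np.apply_along_axis(sps.rankdata, 0, x), sps.rankdata(y)]
    )
    prec = np.linalg.inv(np.corrcoef(ranks, rowvar=False))
    k = x.shape[1]
    return np.array(
        [-prec[j, k] / np.sqrt(prec[j, j] * prec[k, k]) for j in range(k)]
    )


def test_prcc_matches_precision_matrix_oracle():
    rng = np.random.default_rng(3)
    x = rng.random((20, 3))
    y = 2.0 * x[:, 0] - x[:, 1] + 0.3 * rng.random(20)
    res = prcc(x, y)
    oracle = _prcc_precision_oracle(x, y)
    np.testing.assert_allclose(res.prcc, oracle, atol=1e-10)
    assert (np.abs(res.prcc) <= 1.0).all()


def test_prcc_finds_monotone_driver():
    rng = np.random.default_rng(1)
    x = rng.random((400, 4))
    y = np.exp(3 * x[:, 1]) + 0.01 * rng.random(400)
    res = prcc(x, y)
    assert res.prcc[1] > 0.99
    assert np.abs(res.prcc[[0, 2, 3]]).max() < 0.2
    assert res.p_values[1] < 1e-10


def test_prcc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(5)
    x = rng.random((100, 3))
    y = x[:, 0] + 0.5 * rng.random(100)
    base = prcc(x, y).prcc
    x2 = x.copy()
    x2[:, 0] = np.exp(5 * x2[:, 0])         # strictly increasing transform
    transformed = prcc(x2, np.log1p(y)).prcc
    np.testing.assert_allclose(base, transformed, atol=1e-10)


def test_prcc_flags_constant_column():
    rng = np.random.default_rng(2)
    x = rng.random((30, 3))
    x[:, 2] = 1.0
    res = prcc(x, x[:, 0])
    assert np.isnan(res.prcc[2])
    assert not np.isnan(res.prcc[0])


def test_prcc_needs_enough_samples():
    with pytest.raises(ValueError):
        prcc(np.random.default_rng(0).random((5, 4)), np.arange(5.0))


# --------------------------------------------------------------- bootstrap
def test_bootstrap_all_responders_is_degenerate():
    s = bootstrap_ci([1.0] * 20, lambda a: 100.0 * a.mean(), 20, 500, seed=1)
    assert (s.median, s.ci_low, s.ci_high) == (100.0, 100.0, 100.0)


def test_bootstrap_binomial_median():
    outcomes = [1.0] * 10 + [0.0] * 10
    s = bootstrap_ci(outcomes, lambda a: 100.0 * a.mean(), 20, 4000, seed=2)
    assert s.median == pytest.approx(50.0, abs=5.0)
    assert s.ci_low <= s.median <= s.ci_high


def test_bootstrap_deterministic_under_seed():
    outcomes = [1, 0, 1, 1, 0, 0, 1]
    a = bootstrap_ci(outcomes, np.mean, 7, 300, seed=9)
    b = bootstrap_ci(outcomes, np.mean, 7, 300, seed=9)
    assert (a.median, a.ci_low, a.ci_high) == (b.median, b.ci_low, b.ci_high)


def test_bootstrap_ci_narrows_with_trial_size():
    rng = np.random.default_rng(4)
    outcomes = (rng.random(400) < 0.4).astype(float)
    widths = []
    for n in (25, 100, 400):
        s = bootstrap_ci(outcomes, np.mean, n, 2000, seed=0)
        widths.append(s.ci_high - s.ci_low)
    assert widths[0] > widths[1] > widths[2]
    # ~1/sqrt(n) scaling within 35%
    assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.35)


# ------------------------------------------------------------ Kaplan-Meier
def test_km_no_censoring_matches_empirical_median():
    times = [2.0, 5.0, 7.0, 11.0, 13.0]
    assert km_median(times, [False] * 5) == 7.0


def test_km_single_event_steps_to_zero():
    table = km_curve([4.0], [False])
    assert table.survival.iloc[0] == 1.0
    assert table.survival.iloc[-1] == 0.0


def test_km_textbook_censored_example():
    """Six subjects, events at 3, 5, 9 and censoring at 4, 7, 10:
    S(3)=5/6, S(5)=5/6*3/4, S(9)=5/6*3/4*1/2."""
    durations = [3.0, 4.0, 5.0, 7.0, 9.0, 10.0]
    censored = [False, True, False, True, False, True]
    table = km_curve(durations, censored).set_index("time").survival
    assert table.loc[3.0] == pytest.approx(5 / 6)
    assert table.loc[5.0] == pytest.approx(5 / 6 * 3 / 4)
    assert table.loc[9.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)


def test_km_all_censored_median_not_reached():
    assert np.isnan(km_median([5.0, 8.0], [True, True]))


# ------------------------------------------------------------------ fitting
def test_fit_recovers_fixed_point():
    predict = lambda p: p["a"] * np.arange(5.0)  # noqa: E731
    observed = 2.0 * np.arange(5.0)
    res = fit_parameters(predict, observed, {"a": 2.0})
    assert res.values["a"] == pytest.approx(2.0, abs=1e-8)
    assert res.mse < 1e-16


def test_fit_rejects_empty_data():
    with pytest.raises(ValueError):
        fit_parameters(lambda p: np.array([]), np.array([]), {"a": 1.0})


def test_fit_recovers_gompertz_growth_rate(default_params):
    """Simplex fit recovers k_C_growth within 1% from noiseless synthetic
    tumor growth data generated by the model itself."""
    p = default_params.copy()
    p.update({"C_init": 1e4})
    truth = p["k_C_growth"]
    t_grid = np.arange(0.0, 201.0, 20.0)

    def predict(free):
        pi = p.copy()
        pi.set("k_C_growth", abs(free["k_C_growth"]))
        system = q.assemble_model(pi, modules={"cancer_vasculature"})
        traj = q.simulate(system, (0, 200), record_grid=t_grid)
        return np.log10(traj.value("C_total"))

    observed = predict({"k_C_growth": truth})
    res = fit_parameters(predict, observed, {"k_C_growth": truth * 1.7},
                         max_iter=60)
    assert res.values["k_C_growth"] == pytest.approx(truth, rel=0.01)
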