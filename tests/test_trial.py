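"""Virtual-patient generation, response classification, and trial summaries."""

import numpy as np
import pytest

from tnbcqsp.params import ParameterDistribution
from tnbcqsp import trial as T


# ----------------------------------------------------------- population
def test_lhs_stratification_exactness():
    from tnbcqsp.stats import latin_hypercube

    rng = np.random.default_rng(0)
    u = latin_hypercube(10, 3, rng)
    for j in range(3):
        strata = np.floor(u[:, j] * 10).astype(int)
        assert sorted(strata) == list(range(10))


def test_fixed_distributions_give_identical_patients(default_params):
    dists = {"k_C_growth": ParameterDistribution("k_C_growth", "fixed", 0.02)}
    pop = T.generate_population(dists, 5, seed=0, base_params=default_params)
    values = {r.params["k_C_growth"] for r in pop}
    assert values == {0.02}


def test_population_is_reproducible_under_seed(default_params):
    dists = T.default_distributions()
    a = T.generate_population(dists, 8, seed=42, base_params=default_params)
    b = T.generate_population(dists, 8, seed=42, base_params=default_params)
    c = T.generate_population(dists, 8, seed=43, base_params=default_params)
    for ra, rb in zip(a, b):
        assert all(ra.params[k] == rb.params[k] for k in dists)
    assert any(
        any(ra.params[k] != rc.params[k] for k in dists) for ra, rc in zip(a, c)
    )


def test_sampled_values_respect_bounds(default_params):
    dists = T.default_distributions()
    pop = T.generate_population(dists, 40, seed=5, base_params=default_params)
    for rec in pop:
        for name, dist in dists.items():
            assert dist.lower <= rec.params[name] <= dist.upper


def test_invalid_distribution_rejected():
    with pytest.raises(ValueError):
        ParameterDistribution("x", "weibull", 1.0)
    with pytest.raises(ValueError):
        ParameterDistribution("x", "uniform", 1.0, lower=2.0, upper=1.0)


# ------------------------------------------------------- classification
def _diam(*percent_changes, baseline=5.0):
    return np.array([baseline] + [baseline * (1 + p / 100.0)
                                  for p in percent_changes])


def test_recist_partial_response():
    a = T.classify_response(_diam(-10, -40, -35))
    assert a.visit_categories == ["SD", "PR", "PR"]
    assert a.best_overall == "PR"
    assert a.response_onset_day == 112.0


def test_complete_response_below_2mm():
    a = T.classify_response(np.array([5.0, 2.0, 0.19]), unit="mm")
    assert a.visit_categories[-1] == "CR"
    assert a.best_overall == "CR"


def test_recist_progression_vs_nadir():
    # drops to 3 cm (nadir), then 3.8 cm: +27% vs nadir and +8 mm absolute
    a = T.classify_response(np.array([5.0, 3.0, 3.8]))
    assert a.visit_categories == ["PR", "PD"]
    assert a.progression_day == 112.0


def test_recist_absolute_increase_guard():
    # +25% vs nadir but only +2.5 mm absolute: not PD under full RECIST 1.1
    a = T.classify_response(np.array([3.0, 1.0, 1.25]))
    assert a.visit_categories[-1] != "PD"
    b = T.classify_response(np.array([3.0, 1.0, 1.25]),
                            require_absolute_increase=False)
    assert b.visit_categories[-1] == "PD"


def test_irrc_requires_50_percent_shrinkage():
    measurements = _diam(-40, -40)
    recist = T.classify_response(measurements, "RECIST1_1")
    irrc = T.classify_response(measurements, "irRC")
    assert recist.best_overall == "PR"
    assert irrc.best_overall == "SD"


def test_classification_unit_invariance():
    cm = np.array([5.0, 3.2, 2.8, 3.9])
    a = T.classify_response(cm, "RECIST1_1", unit="cm")
    b = T.classify_response(cm * 10.0, "RECIST1_1", unit="mm")
    assert a.visit_categories == b.visit_categories


def test_orr_recist_at_least_irrc_on_shrinkage_trajectories():
    rng = np.random.default_rng(7)
    recist_resp = irrc_resp = 0
    for _ in range(200):
        changes = np.cumsum(rng.normal(-8, 15, size=5))
        m = _diam(*np.maximum(changes, -99.0))
        recist_resp += T.classify_response(m, "RECIST1_1").responder
        irrc_resp += T.classify_response(m, "irRC").responder
    assert recist_resp >= irrc_resp


def test_single_measurement_is_unevaluable():
    a = T.classify_response(np.array([5.0]))
    assert a.best_overall == "NE"


# ------------------------------------------------------------------ DOR
def test_duration_of_response_cases():
    a = T.classify_response(_diam(-35, -40, -35, 30))
    months, censored = T.duration_of_response(a, horizon=400.0)
    assert not censored
    assert months == pytest.approx((224.0 - 56.0) / 30.0)

    b = T.classify_response(_diam(-35, -40, -45))
    months, censored = T.duration_of_response(b, horizon=400.0)
    assert censored
    assert months == pytest.approx((400.0 - 56.0) / 30.0)

    c = T.classify_response(_diam(40, 80))  # progression, never responds
    with pytest.raises(ValueError):
        T.duration_of_response(c)


# ----------------------------------------------------------- subgroups
def _fake_result(responders, variable):
    import pandas as pd
    from tnbcqsp.stats import BootstrapSummary

    patients = pd.DataFrame({
        "pid": range(len(responders)),
        "responder": responders,
        "marker": variable,
    })
    return T.TrialResult(
        regimen="combination", criteria="RECIST1_1", patients=patients,
        orr=100.0 * np.mean(responders),
        orr_ci=BootstrapSummary("orr", 0, 0, 0, len(responders), 10, 0),
        dor_months=np.array([]), dor_censored=np.array([]),
        dor_median=float("nan"), dor_median_ci=None,
    )


def test_median_split_with_perfectly_predictive_marker():
    res = _fake_result([False] * 10 + [True] * 10, list(range(20)))
    table = T.subgroup_orr(res, "marker", "median_split", n_boot=50)
    assert table.loc[table.subgroup == "low", "orr"].iloc[0] == 0.0
    assert table.loc[table.subgroup == "high", "orr"].iloc[0] == 100.0


def test_quintiles_partition_arithmetic():
    res = _fake_result([True] * 100, list(range(100)))
    table = T.subgroup_orr(res, "marker", "quintiles", n_boot=50)
    assert list(table.n) == [20] * 5
    assert (table.orr == 100.0).all()


def test_constant_marker_median_split_degenerates():
    res = _fake_result([True, False] * 10, [1.0] * 20)
    table = T.subgroup_orr(res, "marker", "median_split", n_boot=50)
    low = table.loc[table.subgroup == "low"].iloc[0]
    assert low.n == 20
    assert table.loc[table.subgroup == "high", "n"].iloc[0] == 0


def test_unknown_variable_rejected():
    res = _fake_result([True] * 4, [1, 2, 3, 4])
    with pytest.raises(KeyError):
        T.subgroup_orr(res, "nonexistent")


# -------------------------------------------------------- plausibility
def test_plausibility_filter_drops_out_of_range(default_params):
    rec = T.PatientRecord(0, default_params.copy(), 3.0, status="initialized")
    rec.pre_treatment = {"Mac_density": 1e12, "CD8_density": 1e7}
    T.apply_plausibility_filter(rec)
    assert rec.status == "filtered_out"
    assert "Mac_density" in rec.reason


def test_plausibility_filter_keeps_in_range(default_params):
    rec = T.PatientRecord(0, default_params.copy(), 3.0, status="initialized")
    rec.pre_treatment = {"Mac_density": 2.1e6, "CD8_density": 1.2e8}
    T.apply_plausibility_filter(rec)
    assert rec.status == "initialized"


def test_empty_filter_keeps_everything(default_params):
    rec = T.PatientRecord(0, default_params.copy(), 3.0, status="initialized")
    rec.pre_treatment = {"Mac_density": 1e12}
    T.apply_plausibility_filter(rec, ranges={})
    assert rec.status == "initialized"
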