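"""Model-assembly framework: Hill/scaling utilities, registry assembly,
integration contracts, and the toy parameter fixture."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tnbcqsp as q
from tnbcqsp.framework import Dose, HillSpec, ModelSpec, hill
from tnbcqsp.params import MissingParameterError, ParameterSet


# ------------------------------------------------------------------- hill
@pytest.mark.parametrize(
    "value, spec, expected",
    [
        (5.0, HillSpec(5.0, 1.0), 0.5),       # half-saturation point
        (5.0, HillSpec(5.0, 3.7), 0.5),       # ... for any exponent
        (0.0, HillSpec(2.0), 0.0),
        (3.0, HillSpec(1.0, 2.0), 0.9),       # 9/(9+1)
    ],
)
def test_hill_values(value, spec, expected):
    assert hill(value, spec) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=200, deadline=None)
@given(
    value=st.floats(0.0, 1e12),
    a50=st.floats(1e-9, 1e9),
    n=st.floats(1.0, 6.0),
)
def test_hill_bounded_and_monotone(value, a50, n):
    spec = HillSpec(a50, n)
    h = hill(value, spec)
    assert 0.0 <= h <= 1.0
    assert hill(value * 2 + 1e-9, spec) >= h - 1e-12


def test_hill_rejects_bad_arguments():
    with pytest.raises(ValueError):
        hill(-1.0, HillSpec(1.0))
    with pytest.raises(ValueError):
        HillSpec(0.0)
    with pytest.raises(ValueError):
        HillSpec(1.0, 0.5)


# -------------------------------------------------------------- allometry
def test_allometric_scaling():
    assert q.allometric_scale(0.3, 70.0, 70.0) == pytest.approx(0.3)
    assert q.allometric_scale(1.0, 16.0, 1.0) == pytest.approx(0.5)
    # mouse (20 g) to human (70 kg): (3500)^-0.25
    assert q.allometric_scale(1.0, 70.0, 0.02) == pytest.approx(
        3500.0**-0.25, rel=1e-12
    )
    assert q.allometric_scale(1.0, 70.0, 0.02) == pytest.approx(0.1300, abs=5e-5)
    with pytest.raises(ValueError):
        q.allometric_scale(1.0, -1.0, 1.0)


# --------------------------------------------------------------- assembly
def test_assembly_is_deterministic(default_params):
    a = q.assemble_model(default_params)
    b = q.assemble_model(default_params)
    assert list(a.state_index) == list(b.state_index)
    assert a.rule_names == b.rule_names
    np.testing.assert_array_equal(a.y0, b.y0)


def test_empty_module_set_is_invalid(default_params):
    from tnbcqsp.model import InvalidConfigError

    with pytest.raises(InvalidConfigError):
        q.assemble_model(default_params, modules=set())
    with pytest.raises(InvalidConfigError):
        q.assemble_model(default_params, modules={"not_a_module"})


def test_missing_parameter_is_named(default_params):
    broken = ParameterSet(
        {k: v for k, v in default_params.params.items() if k != "k_C_growth"}
    )
    with pytest.raises(MissingParameterError, match="k_C_growth"):
        q.assemble_model(broken)


def test_rule_cycles_are_rejected():
    ps = ParameterSet()
    spec = ModelSpec(ps)
    spec.add_compartment("box", 1.0)
    spec.add_species("x", "box", 1.0)
    spec.add_rule("a", "b + x")
    spec.add_rule("b", "a + 1.0")
    with pytest.raises(ValueError, match="cyclic"):
        spec.assemble()


def test_cancer_only_config_counts(default_params):
    system = q.assemble_model(default_params, modules={"cancer_vasculature"})
    # two clones, two dead pools, carrying capacity, angiogenic factor
    assert system.n_odes == 6
    assert set(system.state_index) == {
        "C1", "C2", "C_x1", "C_x2", "C_max", "c_vas"
    }


# ------------------------------------------------------------- simulation
def _single_decay_system(k=0.3, x0=5.0):
    ps = ParameterSet()
    ps.set("k_dec", k)
    spec = ModelSpec(ps)
    spec.add_compartment("box", 1.0)
    spec.add_species("x", "box", x0)
    spec.add_reaction("decay", "k_dec*x", {"x": -1.0})
    return spec.assemble()


def test_zero_rates_give_constant_trajectory():
    system = _single_decay_system(k=0.0, x0=2.5)
    traj = q.simulate(system, (0, 50), record_grid=5.0)
    np.testing.assert_allclose(traj.value("x"), 2.5, rtol=1e-9)


def test_exponential_decay_matches_closed_form():
    system = _single_decay_system(k=0.3, x0=5.0)
    traj = q.simulate(system, (0, 20), record_grid=1.0, rtol=1e-9, atol=1e-12)
    expected = 5.0 * np.exp(-0.3 * traj.t)
    np.testing.assert_allclose(traj.value("x"), expected, rtol=1e-6, atol=1e-9)


def test_bolus_dose_mass_bookkeeping():
    system = _single_decay_system(k=0.0, x0=1.0)
    traj = q.simulate(
        system, (0, 20), doses=[Dose("x", start=10.0, amount=3.0)],
        record_grid=1.0,
    )
    assert traj.value("x")[traj.t < 10].max() == pytest.approx(1.0)
    assert traj.value("x")[-1] == pytest.approx(4.0, rel=1e-9)


def test_infusion_delivers_amount_over_duration():
    system = _single_decay_system(k=0.0, x0=0.0)
    traj = q.simulate(
        system, (0, 4), doses=[Dose("x", start=1.0, amount=2.0, duration=2.0)],
        record_grid=0.5,
    )
    x = dict(zip(traj.t, traj.value("x")))
    assert x[1.0] == pytest.approx(0.0, abs=1e-9)
    assert x[2.0] == pytest.approx(1.0, rel=1e-6)  # halfway through infusion
    assert x[4.0] == pytest.approx(2.0, rel=1e-6)


def test_dose_outside_span_rejected():
    system = _single_decay_system()
    with pytest.raises(ValueError):
        q.simulate(system, (0, 5), doses=[Dose("x", start=10.0, amount=1.0)])


# ----------------------------------------------------------- toy fixtures
def test_toy_parameters_are_deterministic_and_valid():
    a = q.generate_toy_parameters(3)
    b = q.generate_toy_parameters(3)
    c = q.generate_toy_parameters(4)
    assert {k: a[k] for k in a} == {k: b[k] for k in b}
    assert any(a[k] != c[k] for k in a)
    for name in a:
        if name.startswith(("k_", "q_", "K_")):
            assert a[name] >= 0
    system = q.assemble_model(a)  # no missing-parameter error
    assert system.n_odes == 152


def test_toy_parameters_simulate_quickly():
    system = q.assemble_model(q.generate_toy_parameters(1))
    traj = q.simulate(system, (0.0, 400.0), record_grid=50.0)
    assert math.isfinite(traj.final("V_T"))
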