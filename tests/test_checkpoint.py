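"""Immune-synapse binding networks and derived inhibition Hills."""

import numpy as np
import pytest

import tnbcqsp as q
from tnbcqsp.framework import ModelSpec
from tnbcqsp.modules.checkpoint import h_mac_c
from tnbcqsp.panel import _synapse_system, equilibrium_h_mac, phagocytosis_panel
from tnbcqsp.params import ParameterSet
from tnbcqsp.units import MOLAR_TO_PER_UM3


# ------------------------------------------------------------- H_Mac_C
@pytest.mark.parametrize(
    "h_sirpa, h_pd1, expected",
    [(0.0, 0.0, 0.0), (1.0, 0.3, 1.0), (0.5, 0.5, 0.75), (0.2, 0.7, 0.76)],
)
def test_h_mac_c_complement_product(h_sirpa, h_pd1, expected):
    assert h_mac_c(h_sirpa, h_pd1) == pytest.approx(expected)
    assert h_mac_c(h_pd1, h_sirpa) == pytest.approx(expected)  # symmetric


def test_h_mac_c_monotone():
    grid = np.linspace(0, 1, 11)
    for fixed in (0.0, 0.4, 0.9):
        vals = [h_mac_c(x, fixed) for x in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


# ------------------------------------------------- 2-D Langmuir oracle
def _pair_system(p0, l0, kon3d, koff, d_syn=3e-3):
    ps = ParameterSet()
    ps.update({"kon": kon3d, "koff": koff, "d_syn": d_syn})
    spec = ModelSpec(ps)
    spec.add_compartment("syn", 37.8, "um^2")
    spec.add_species("R", "syn", p0, "molecule/um^2")
    spec.add_species("L", "syn", l0, "molecule/um^2")
    spec.add_species("RL", "syn", 0.0, "molecule/um^2")
    kon2d = f"kon/(d_syn*{MOLAR_TO_PER_UM3!r})"
    spec.add_reaction("bind", f"({kon2d})*R*L", {"R": -1.0, "L": -1.0, "RL": 1.0})
    spec.add_reaction("unbind", "koff*RL", {"R": 1.0, "L": 1.0, "RL": -1.0})
    return spec.assemble()


def test_single_pair_reaches_langmuir_steady_state():
    """Steady state of one receptor-ligand pair matches the quadratic
    closed form C* with Kd2d = koff/kon2d."""
    p0, l0 = 25.0, 50.0
    kon3d, koff, d_syn = 8.64e9, 7.1e4, 3e-3
    system = _pair_system(p0, l0, kon3d, koff, d_syn)
    traj = q.simulate(system, (0, 0.5), record_grid=0.1, rtol=1e-10, atol=1e-12)
    kd2d = koff / (kon3d / (d_syn * MOLAR_TO_PER_UM3))
    s = p0 + l0 + kd2d
    c_star = 0.5 * (s - np.sqrt(s * s - 4 * p0 * l0))
    assert traj.final("RL") == pytest.approx(c_star, rel=1e-6)
    # totals conserved
    assert traj.final("R") + traj.final("RL") == pytest.approx(p0, rel=1e-8)
    assert traj.final("L") + traj.final("RL") == pytest.approx(l0, rel=1e-8)


# ------------------------------------------------- synapse conservation
def test_synapse_totals_conserved_with_valence_weights(default_params):
    """In the isolated macrophage-cancer synapse (no synthesis), each
    molecule's free + bound total is conserved to 1e-8 relative."""
    system = _synapse_system(default_params)
    traj = q.simulate(system, (0, 1.0), record_grid=0.25, rtol=1e-10, atol=1e-12)
    s = traj.states
    totals = {
        "PD1": s.syn_PD1 + s.syn_PD1_PDL1 + s.syn_PD1_PDL2,
        "PDL1": s.syn_PDL1 + s.syn_PD1_PDL1 + s.syn_PDL1_aPDL1
        + 2 * s.syn_PDL1_aPDL1_PDL1 + s.syn_PDL1_CD80,
        "CD80": s.syn_CD80m + 2 * s.syn_CD80d + s.syn_PDL1_CD80,
        "CD47": s.syn_CD47 + s.syn_CD47_SIRPa + s.syn_CD47_aCD47
        + 2 * s.syn_CD47_aCD47_CD47,
        "SIRPa": s.syn_SIRPa + s.syn_CD47_SIRPa,
    }
    for name, series in totals.items():
        arr = series.to_numpy()
        np.testing.assert_allclose(arr, arr[0], rtol=1e-8, err_msg=name)


def test_saturating_anti_pdl1_abolishes_pd1_engagement(default_params):
    system = _synapse_system(default_params)
    h_free = equilibrium_h_mac(system, {"CD47_dens_C": 0.0})
    h_blocked = equilibrium_h_mac(system, {"CD47_dens_C": 0.0}, apdl1=1e-5)
    assert h_free > 0.3
    assert h_blocked < 0.05 * h_free


def test_doubly_bound_antibody_requires_cross_arm(default_params):
    p = default_params.copy()
    p.set("chi_aPDL1", 0.0)
    system = _synapse_system(p)
    sys2 = system.with_updates(param_updates={"aPDL1_panel": 1e-7})
    traj = q.simulate(sys2, (0, 1.0), record_grid=0.5)
    assert traj.final("syn_PDL1_aPDL1_PDL1") == pytest.approx(0.0, abs=1e-12)
    assert traj.final("syn_PDL1_aPDL1") > 0.0


# --------------------------------------------------------------- panel
def test_panel_with_zero_densities_has_no_inhibition(default_params):
    system = _synapse_system(default_params)
    h = equilibrium_h_mac(
        system,
        {k: 0.0 for k in ("PD1_dens_M", "PDL1_dens_C", "CD80_dens_C",
                          "CD47_dens_C", "SIRPa_dens_M")},
    )
    assert h == pytest.approx(0.0, abs=1e-9)


def test_panel_requires_two_samples():
    with pytest.raises(ValueError):
        phagocytosis_panel(1, seed=0)


def test_panel_reports_all_conditions_and_pvalues(default_params):
    res = phagocytosis_panel(12, seed=3)
    assert set(res.summary.condition) == {
        "control", "anti_CD47", "anti_PDL1", "PD1_negative", "CD47_negative"
    }
    assert res.fold("control") == pytest.approx(1.0)
    noncontrol = res.summary[res.summary.condition != "control"]
    assert (noncontrol.fold_change > 1.0).all()
    assert ((noncontrol.p_value >= 0) & (noncontrol.p_value <= 1)).all()


def test_pdl1_induction_saturates_at_fold_limit(full_system, baseline_trajectory):
    """Total PD-L1 never exceeds r_PDL1_IFNg times baseline."""
    p = full_system.spec.params
    cap = p["r_PDL1_IFNg"] * p["PDL1_dens_C"]
    s = baseline_trajectory.states
    total = (
        s.syn_T_C1_PDL1 + s.syn_T_C1_PD1_PDL1 + s.syn_T_C1_PDL1_aPDL1
        + 2 * s.syn_T_C1_PDL1_aPDL1_PDL1 + s.syn_T_C1_PDL1_CD80
    ).to_numpy()
    assert (total <= cap * (1 + 1e-6)).all()
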