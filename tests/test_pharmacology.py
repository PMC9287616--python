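"""Antibody and chemotherapy PK/PD, dosing regimens, permeability helpers."""

import numpy as np
import pytest
from scipy.linalg import expm

import tnbcqsp as q
from tnbcqsp.pharmacology import (
    DoseRegimen,
    atezolizumab_q3w,
    nab_paclitaxel_q3_4w,
    nabp_hill,
    permeability_from_ps,
    regimen_doses,
    stokes_radius,
)
from tnbcqsp.units import mg_to_mol


# ------------------------------------------------------------ worked values
def test_stokes_radius_values():
    assert stokes_radius(145000.0) == pytest.approx(47.4, abs=0.05)
    assert stokes_radius(1.0) == pytest.approx(0.483)
    assert stokes_radius(60000.0) == pytest.approx(0.483 * 60000**0.386, rel=1e-12)
    assert stokes_radius(60000.0) == pytest.approx(33.7, abs=0.2)
    with pytest.raises(ValueError):
        stokes_radius(-5.0)


def test_permeability_from_ps_values():
    assert permeability_from_ps(1.5e-4, 70.0) == pytest.approx(2e-8)
    assert permeability_from_ps(1.5e-4, 28.4) == pytest.approx(5e-8)  # 1 sig fig
    assert permeability_from_ps(100.0, 1.0) == pytest.approx(1.0)


def test_mg_mol_conversion_invertible():
    mol = mg_to_mol(1200.0, 145000.0)
    assert mol * 145000.0 * 1e3 == pytest.approx(1200.0, rel=1e-12)


# ---------------------------------------------------------------- regimens
def test_q3w_schedule():
    times = atezolizumab_q3w().schedule(400.0)
    assert times[:3] == [0.0, 21.0, 42.0]
    assert len(times) == 20
    assert all(b > a for a, b in zip(times, times[1:]))


def test_day_1_8_15_q28_schedule():
    times = nab_paclitaxel_q3_4w().schedule(60.0)
    assert times == [0.0, 7.0, 14.0, 28.0, 35.0, 42.0, 56.0]


def test_dose_conversion_to_molar(default_params):
    doses = regimen_doses("atezolizumab-mono", default_params, 21.0)
    expected = mg_to_mol(1200.0, 145000.0) / (default_params["V_C"] * 1e-3)
    assert doses[0].amount == pytest.approx(expected, rel=1e-12)
    assert doses[0].duration == pytest.approx(1.0 / 24.0)


def test_bsa_scaled_dosing(default_params):
    p = default_params.copy()
    p.set("BSA", 2.0)
    d2 = regimen_doses("nab-paclitaxel-mono", p, 1.0)[0]
    p.set("BSA", 1.0)
    d1 = regimen_doses("nab-paclitaxel-mono", p, 1.0)[0]
    assert d2.amount == pytest.approx(2.0 * d1.amount, rel=1e-12)


def test_unknown_drug_rejected():
    with pytest.raises(ValueError):
        DoseRegimen("aspirin", 100.0)


# ---------------------------------------------------------------- dynamics
@pytest.fixture(scope="module")
def pk_system(default_params):
    return q.assemble_model(
        default_params, modules={"cancer_vasculature", "pharmacology"}
    )


def test_antibody_mass_conserved_without_clearance(default_params):
    # freeze tumor volume (closed subsystem): drug amounts are then conserved
    p = default_params.copy()
    p.update({"k_cl_Atezo": 0.0, "k_C_growth": 0.0, "k_C_death": 0.0})
    system = q.assemble_model(p, modules={"cancer_vasculature", "pharmacology"})
    doses = regimen_doses("atezolizumab-mono", p, 0.0)  # single dose at t=0
    traj = q.simulate(system, (0, 400), doses=doses, record_grid=20.0,
                      rtol=1e-10, atol=1e-14)
    v_t = traj.value("V_T")
    total = (
        traj.states.Atezo_C * p["V_C"] + traj.states.Atezo_P * p["V_P"]
        + traj.states.Atezo_LN * p["V_LN"] + traj.states.Atezo_T * v_t
    ).to_numpy()
    # amounts after the 1-h infusion completes are conserved
    np.testing.assert_allclose(total[1:], total[-1], rtol=1e-6)


def test_equal_free_concentrations_mean_no_exchange(pk_system, default_params):
    p = default_params
    y = np.zeros(pk_system.n_odes)
    idx = pk_system.state_index
    y[idx["C1"]] = 1e9  # fixes V_T
    for comp, gamma in (("C", "gamma_C"), ("P", "gamma_P"),
                        ("T", "gamma_T"), ("LN", "gamma_LN")):
        y[idx[f"Atezo_{comp}"]] = 1e-6 * p[gamma]
    dy = pk_system.rhs(0.0, y, np.zeros_like(y))
    # permeability exchange vanishes; only clearance and lymph flow act
    drain = p["Q_LD"] * 1e-6  # free-fraction flux through the lymph chain
    assert dy[idx["Atezo_P"]] == pytest.approx(0.0, abs=1e-18)
    assert dy[idx["Atezo_T"]] == pytest.approx(
        -drain / (1e9 * p["V_cell_C"] / p["f_vol_cell"]), rel=1e-6
    )


def test_pk_linearity_superposition(pk_system, default_params):
    doses1 = regimen_doses("atezolizumab-mono", default_params, 100.0)
    doses2 = [
        q.Dose(d.species, d.start, 2 * d.amount, d.duration) for d in doses1
    ]
    t1 = q.simulate(pk_system, (0, 100), doses=doses1, record_grid=5.0,
                    rtol=1e-9, atol=1e-14)
    t2 = q.simulate(pk_system, (0, 100), doses=doses2, record_grid=5.0,
                    rtol=1e-9, atol=1e-14)
    for sp in ("Atezo_C", "Atezo_P", "Atezo_T", "Atezo_LN"):
        np.testing.assert_allclose(
            2 * t1.value(sp)[1:], t2.value(sp)[1:], rtol=1e-4
        )


def test_single_dose_profile_matches_matrix_exponential(default_params):
    """Bolus antibody kinetics follow the linear ODE solution exp(At)."""
    p = default_params.copy()
    p.update({"k_C_growth": 0.0, "k_C_death": 0.0})  # freeze V_T
    system = q.assemble_model(p, modules={"cancer_vasculature", "pharmacology"})
    idx = system.state_index
    y0 = system.y0.copy()
    y0[idx["C1"]] = 1e9
    c0 = 1e-6
    y0[idx["Atezo_C"]] = c0
    v_t = 1e9 * p["V_cell_C"] / p["f_vol_cell"]
    vols = {"C": p["V_C"], "P": p["V_P"], "T": v_t, "LN": p["V_LN"]}
    gam = {k: p[f"gamma_{k}"] for k in vols}
    comps = ["C", "P", "T", "LN"]
    a = np.zeros((4, 4))
    for other, qq in (("P", p["Q_P_ab"]), ("T", p["Q_T_ab"]), ("LN", p["Q_LN_ab"])):
        i, j = comps.index("C"), comps.index(other)
        a[i, j] += qq / (vols["C"] * gam[other])
        a[i, i] -= qq / (vols["C"] * gam["C"])
        a[j, i] += qq / (vols[other] * gam["C"])
        a[j, j] -= qq / (vols[other] * gam[other])
    a[comps.index("T"), comps.index("T")] -= p["Q_LD"] / (v_t * gam["T"])
    a[comps.index("LN"), comps.index("T")] += p["Q_LD"] / (vols["LN"] * gam["T"])
    a[comps.index("LN"), comps.index("LN")] -= p["Q_LD"] / (vols["LN"] * gam["LN"])
    a[comps.index("C"), comps.index("LN")] += p["Q_LD"] / (vols["C"] * gam["LN"])
    a[comps.index("C"), comps.index("C")] -= p["k_cl_Atezo"] / vols["C"]

    # tumor growth changes V_T slowly; freeze it by removing cancer dynamics
    traj = q.simulate(system, (0, 2.0), record_grid=0.5, y0=y0,
                      rtol=1e-10, atol=1e-14)
    for t_obs in (0.5, 1.0, 2.0):
        expected = expm(a * t_obs) @ np.array([c0, 0, 0, 0])
        k = np.argmin(np.abs(traj.t - t_obs))
        got = np.array([traj.value(f"Atezo_{c}")[k] for c in comps])
        np.testing.assert_allclose(got, expected, rtol=5e-3, atol=1e-15)


def test_nabp_effect_ordering(default_params):
    ec50 = default_params["EC50_nabp_C1"]
    assert nabp_hill(ec50, ec50) == pytest.approx(0.5)
    assert nabp_hill(ec50, 100 * ec50) < 0.01  # resistant clone barely touched
    assert nabp_hill(0.0, ec50) == 0.0
    with pytest.raises(ValueError):
        nabp_hill(1.0, 0.0)


def test_resistance_flux_gated_by_tgfb(full_system, derivative_probe):
    d_off = derivative_probe(full_system, {"C1": 1e8, "C_max": 1e9})
    p = full_system.spec.params
    d_on = derivative_probe(
        full_system, {"C1": 1e8, "C_max": 1e9, "TGFb_T": p["TGFb_50"]}
    )
    flux_off = d_off["C2"]
    flux_on = d_on["C2"]
    assert flux_off == pytest.approx(0.0, abs=1e-9)
    assert flux_on == pytest.approx(0.5 * p["k_C_resist"] * 1e8, rel=1e-9)
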