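"""Cancer-clone growth/death dynamics and angiogenesis-driven capacity.

Each cancer clone follows modified-Gompertzian growth toward a dynamic
carrying capacity C_max set by the tumor vasculature, and dies through
apoptosis, nab-paclitaxel cytotoxicity, phagocytosis by M1 macrophages,
and effector-T-cell killing.  The angiogenic factor c_vas (calibrated as
VEGF-A, pg/mL) is secreted by cancer cells and M2 macrophages and induced
by low-dose chemotherapy.  Dead cells from apoptosis/chemo/T-cell killing
accumulate in per-clone dead pools (phagocytosed cells are engulfed and
do not leave debris) and are cleared first-order; dead cells still occupy
tumor volume.
"""

from __future__ import annotations

from ..framework import ModelSpec

#: 3/(4*pi), for the sphere-equivalent diameter
_SPHERE = 0.23873241463784303
_EPS = "1e-06"


def _death_terms(i: int, has: set[str]) -> list[str]:
    """Per-cell death rate expressions for clone i (apoptosis, chemo,
    phagocytosis, Teff kill), matching availability of coupled modules."""
    terms = [f"k_C_death*C{i}"]
    if "pharmacology" in has:
        terms.append(
            f"k_C_nabp*H_nabp_C{i}*min(C_total,K_C_nabp)/max(C_total,{_EPS})*C{i}"
        )
    if "myeloid" in has:
        hmac = f"(1.0-H_Mac_C{i})" if "checkpoint_synapse" in has else "1.0"
        terms.append(
            f"k_M1_phago*Mac_M1/(Mac_M1+K_Mac_C*C{i}+{_EPS})"
            f"*{hmac}*(1.0-H_IL10_phago)*C{i}"
        )
    if "lymphocytes" in has:
        hpd1 = f"(1.0-H_PD1_C{i})" if "checkpoint_synapse" in has else "1.0"
        hmdsc = "(1.0-H_MDSC)" if "myeloid" in has else "1.0"
        htgfb = "(1.0-H_TGFb_Teff)" if "myeloid" in has else "1.0"
        terms.append(
            f"k_C_Teff*Teff_T/(Teff_T+K_T_C*C{i}+{_EPS})"
            f"*Teff_T/(Teff_T+K_T_Treg*Treg_T+{_EPS})"
            f"*{htgfb}*{hpd1}*{hmdsc}*C{i}"
        )
    return terms


def build(spec: ModelSpec, has: set[str], n_clones: int = 2) -> None:
    p = spec.params
    clones = range(1, n_clones + 1)

    for i in clones:
        init = p["C_init"] if i == 1 else 0.0
        spec.add_species(f"C{i}", "tumor", init, "cell", f"cancer clone {i}")
        spec.add_species(f"C_x{i}", "tumor", 0.0, "cell", f"dead cells, clone {i}")
    spec.add_species("C_max", "tumor", p["C_max_init"], "cell", "carrying capacity")
    spec.add_species("c_vas", "tumor", 0.0, "pg/mL", "angiogenic factor")

    spec.add_rule("C_total", " + ".join(f"C{i}" for i in clones), "cell")
    spec.add_rule("C_x_total", " + ".join(f"C_x{i}" for i in clones), "cell")

    # ------------------------------------------------------- clone dynamics
    for i in clones:
        spec.add_reaction(
            f"growth_C{i}",
            f"k_C_growth*C{i}*log(max(C_max,{_EPS})/max(C_total,{_EPS}))",
            {f"C{i}": 1.0},
        )
        apoptosis, *rest = _death_terms(i, has)
        spec.add_reaction(f"apoptosis_C{i}", apoptosis, {f"C{i}": -1.0, f"C_x{i}": 1.0})
        for term in rest:
            kind = "chemo" if "nabp" in term else ("phago" if "phago" in term else "teff")
            fate = {f"C{i}": -1.0} if kind == "phago" else {f"C{i}": -1.0, f"C_x{i}": 1.0}
            spec.add_reaction(f"{kind}_kill_C{i}", term, fate)
        spec.add_reaction(f"clear_Cx{i}", f"k_Cx_clear*C_x{i}", {f"C_x{i}": -1.0})

    if n_clones >= 2 and "pharmacology" in has and "myeloid" in has:
        # TGF-beta-gated induction of the chemo-resistant clone from clone 1
        spec.add_reaction(
            "resistance_induction",
            "k_C_resist*C1*H_TGFb",
            {"C1": -1.0, "C2": 1.0},
        )

    # total cancer-death flux: drives antigen release (deposition rate is
    # assumed equal to the rate of cancer cell death)
    all_death = []
    for i in clones:
        all_death.extend(_death_terms(i, has))
    spec.add_rule("R_cancer_death", " + ".join(all_death), "cell/day")

    # ------------------------------------------------------ carrying capacity
    spec.add_reaction(
        "vasculature_growth",
        "k_K_g*C_total*c_vas/(c_vas+c_vas50)",
        {"C_max": 1.0},
    )
    spec.add_reaction(
        "vasculature_inhibition",
        "k_K_d*C_max*(C_total*V_cell_C)**0.6666666666666666",
        {"C_max": -1.0},
    )
    if "pharmacology" in has:
        spec.add_reaction(
            "vasculature_chemo_kill", "k_K_nabp*C_max*NabP_T", {"C_max": -1.0}
        )

    # ------------------------------------------------------ angiogenic factor
    sec = "k_vas_Csec*C_total"
    if "myeloid" in has:
        sec += " + k_vas_Msec*Mac_M2"
    if "pharmacology" in has:
        sec += " + k_vas_nabp*C_total*H_nabp_vas"
    spec.add_reaction("cvas_secretion", f"({sec})/V_T", {"c_vas": 1.0})
    spec.add_reaction("cvas_degradation", "k_vas_deg*c_vas", {"c_vas": -1.0})

    # -------------------------------------------------------- volume bookkeeping
    vol = "V_cell_C*(C_total+C_x_total)"
    if "lymphocytes" in has:
        vol += " + V_cell_T*(T_total_T+T_exh)"
    if "myeloid" in has:
        vol += " + V_cell_Mac*M_total"
    spec.add_rule("V_T", f"max(({vol})/f_vol_cell, V_T_min)", "mL",
                  "tumor volume from cellular content / intracellular fraction")
    spec.add_rule("D_T", f"2.0*({_SPHERE}*V_T)**0.3333333333333333", "cm",
                  "sphere-equivalent tumor diameter")
    spec.add_rule("D_T_perc", "(D_T-D_T0)/max(D_T0,1e-09)*100.0", "%",
                  "percent diameter change from baseline")

    if "pharmacology" in has:
        for i in clones:
            spec.add_rule(
                f"H_nabp_C{i}",
                f"NabP_T/(NabP_T+EC50_nabp_C{i})",
                "",
                f"nab-paclitaxel effect on clone {i}",
            )
        spec.add_rule("H_nabp_vas", "NabP_T/(NabP_T+EC50_nabp_vas)")


def tumor_diameter(v_t: float) -> float:
    """Sphere-equivalent diameter (cm) of a tumor of volume v_t (mL)."""
    if v_t < 0:
        raise ValueError("tumor volume must be >= 0")
    return 2.0 * (_SPHERE * v_t) ** (1.0 / 3.0)


def percent_change(d: float, d0: float) -> float:
    """Percent diameter change from baseline d0."""
    if d0 <= 0:
        raise ValueError("baseline diameter must be positive")
    return (d - d0) / d0 * 100.0


def tumor_volume(
    cancer: float,
    dead_cancer: float,
    t_cells: float,
    exhausted_t: float,
    macrophages: float,
    v_cell_c: float,
    v_cell_t: float,
    v_cell_mac: float,
    f_vol_cell: float,
) -> float:
    """Tumor volume (mL) from cell counts; f_vol_cell is the intracellular
    volume fraction (0.37 for breast tumors: ~2% vascular, ~61% interstitial)."""
    if not 0 < f_vol_cell < 1:
        raise ValueError("intracellular volume fraction must be in (0,1)")
    counts = (cancer, dead_cancer, t_cells, exhausted_t, macrophages)
    if any(c < 0 for c in counts):
        raise ValueError("cell counts must be >= 0")
    return (
        v_cell_c * (cancer + dead_cancer)
        + v_cell_t * (t_cells + exhausted_t)
        + v_cell_mac * macrophages
    ) / f_vol_cell
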