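"""Antigen release, processing, MHC presentation, and TCR activation.

Two aggregated antigen channels are carried by default — tumor
neoantigens and tumor-associated self-antigens — each with an average
binding affinity representing all clones of that class (clone counts
enter only as multipliers).  Antigens are deposited into the tumor
interstitium at a rate equal to the cancer-cell death flux, taken up by
APCs into endosomes, degraded to peptides, loaded onto that channel's
MHC pool, and exocytosed to the APC surface.  Surface pMHC drives TCR
engagement through a binding quadratic and a kinetic-proofreading factor,
yielding the activation Hill H_Ag.

Units: extracellular/endosomal antigen and peptide in molar; MHC and pMHC
as surface densities (molecule/um^2) on the endosomal membrane (A_e) and
APC surface (A_s).  MHC is conserved per channel when synthesis and
degradation are off (the shipped model has neither).
"""

from __future__ import annotations

import math

from ..framework import ModelSpec
from ..units import N_AVOGADRO

CHANNELS = ("neo", "self")


def build(spec: ModelSpec, has: set[str]) -> None:
    p = spec.params
    vt = "V_T" if "cancer_vasculature" in has else "V_T_min"
    # mol <-> molecule/area/volume conversion factors used in stoichiometry
    pep_per_area = "A_endo_APC/(V_endo_APC*0.001)/N_AV"  # M per (molecule/um^2)

    for ch in CHANNELS:
        spec.add_species(f"P_T_{ch}", "tumor", 0.0, "M", f"extracellular {ch}-antigen")
        spec.add_species(f"P_e_{ch}", "APC_endosome", 0.0, "M",
                         f"endosomal {ch}-antigen (per-APC average)")
        spec.add_species(f"p_e_{ch}", "APC_endosome", 0.0, "M",
                         f"endosomal {ch}-peptide")
        spec.add_species(f"Mp_e_{ch}", "APC_endosome_membrane", 0.0,
                         "molecule/um^2", f"endosomal {ch}-pMHC")
        spec.add_species(f"Mp_s_{ch}", "APC_surface", 0.0,
                         "molecule/um^2", f"surface {ch}-pMHC")
        spec.add_species(f"M_e_{ch}", "APC_endosome_membrane",
                         p["M_endo_init"], "molecule/um^2",
                         f"free MHC, endosome ({ch} channel pool)")
        spec.add_species(f"M_s_{ch}", "APC_surface", 0.0, "molecule/um^2",
                         f"free MHC, surface ({ch} channel pool)")

        # extracellular pool: deposition from dying cancer cells, degradation,
        # uptake by all tumor APCs
        if "cancer_vasculature" in has:
            spec.add_reaction(
                f"antigen_deposition_{ch}",
                f"n_ag_per_cell_{ch}*R_cancer_death/N_AV/({vt}*0.001)",
                {f"P_T_{ch}": 1.0},
            )
        spec.add_reaction(
            f"antigen_ext_degradation_{ch}", f"k_xP_deg*P_T_{ch}", {f"P_T_{ch}": -1.0}
        )
        apc = "APC_T" if "antigen_presentation" in has else "0.0"
        spec.add_reaction(
            f"antigen_uptake_{ch}",
            f"k_up*P_T_{ch}",
            # per-APC endosomal gain of k_up*P_T; total tumor loss scales
            # with APC count and the endosome/tumor volume ratio
            {f"P_e_{ch}": 1.0, f"P_T_{ch}": f"-({apc})*V_endo_APC/{vt}"},
        )
        spec.add_reaction(
            f"antigen_processing_{ch}", f"k_P_deg*P_e_{ch}",
            {f"P_e_{ch}": -1.0, f"p_e_{ch}": 1.0},
        )
        spec.add_reaction(
            f"peptide_degradation_{ch}", f"k_p_deg*p_e_{ch}", {f"p_e_{ch}": -1.0}
        )
        # peptide-MHC loading on the endosomal membrane
        spec.add_reaction(
            f"pMHC_binding_{ch}", f"k_P_on*p_e_{ch}*M_e_{ch}",
            {f"Mp_e_{ch}": 1.0, f"M_e_{ch}": -1.0, f"p_e_{ch}": f"-({pep_per_area})"},
        )
        spec.add_reaction(
            f"pMHC_unbinding_{ch}", f"k_P_off_{ch}*Mp_e_{ch}",
            {f"Mp_e_{ch}": -1.0, f"M_e_{ch}": 1.0, f"p_e_{ch}": f"({pep_per_area})"},
        )
        spec.add_reaction(
            f"pMHC_exocytosis_{ch}", f"k_out_MHC*Mp_e_{ch}",
            {f"Mp_e_{ch}": -1.0, f"Mp_s_{ch}": "A_endo_APC/A_surf_APC"},
        )
        # surface pMHC dissociation loses the peptide, frees surface MHC
        spec.add_reaction(
            f"surface_pMHC_decay_{ch}", f"k_P_off_{ch}*Mp_s_{ch}",
            {f"Mp_s_{ch}": -1.0, f"M_s_{ch}": 1.0},
        )
        spec.add_reaction(
            f"MHC_exocytosis_{ch}", f"k_out_MHC*M_e_{ch}",
            {f"M_e_{ch}": -1.0, f"M_s_{ch}": "A_endo_APC/A_surf_APC"},
        )
        spec.add_reaction(
            f"MHC_internalization_{ch}", f"k_in_MHC*M_s_{ch}",
            {f"M_s_{ch}": -1.0, f"M_e_{ch}": "A_surf_APC/A_endo_APC"},
        )

        # kinetic-proofreading TCR activation (counts per T-cell:APC contact)
        pm = f"Mp_s_{ch}*A_surf_APC/n_T_clones_{ch}"
        s = f"({pm} + TCR_tot + K_D_TCR)"
        spec.add_rule(
            f"TCR_active_{ch}",
            f"k_off_TCR/(k_off_TCR+phi_TCR)"
            f"*(k_p_TCR/(k_p_TCR+k_off_TCR))**N_TCR_steps"
            f"*0.5*({s} - sqrt(max({s}**2 - 4.0*({pm})*TCR_tot, 0.0)))",
            "molecule",
            f"signaling-competent TCRs engaged by {ch}-pMHC",
        )
        spec.add_rule(
            f"H_Ag_{ch}", f"TCR_active_{ch}/(TCR_active_{ch}+K_p_TCR_act)", "",
            f"antigen-strength Hill for {ch}-specific activation",
        )


# ----------------------------------------------------------------- functions
def tcr_complexes(pmhc_per_clone: float, tcr_tot: float, kd: float) -> float:
    """Total TCR:pMHC complexes: smaller root of the binding quadratic."""
    if min(pmhc_per_clone, tcr_tot, kd) < 0:
        raise ValueError("inputs must be non-negative")
    s = pmhc_per_clone + tcr_tot + kd
    disc = s * s - 4.0 * pmhc_per_clone * tcr_tot
    if disc < -1e-9 * s * s:
        raise ArithmeticError("negative discriminant in TCR binding quadratic")
    return 0.5 * (s - math.sqrt(max(disc, 0.0)))


def tcr_activation(
    pmhc_density: float,
    a_surface: float,
    n_clones: float,
    tcr_tot: float,
    kd: float,
    k_off: float,
    phi: float,
    k_p: float,
    n_steps: float,
    k_half: float,
) -> tuple[float, float]:
    """Active TCR count and activation Hill H_Ag for one antigen channel.

    The proofreading factor k_off/(k_off+phi) * (k_p/(k_p+k_off))^N lies in
    (0, 1) and decreases with the number of modification steps N.
    """
    per_clone = pmhc_density * a_surface / n_clones
    total = tcr_complexes(per_clone, tcr_tot, kd)
    active = k_off / (k_off + phi) * (k_p / (k_p + k_off)) ** n_steps * total
    return active, active / (active + k_half)


MOLAR_PER_DENSITY = 1.0 / N_AVOGADRO  # documentation helper
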