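"""T lymphocyte dynamics: naive homeostasis, activation, and tumor fate.

Three lineages are tracked, each with its own naive clonotype-average pool
in the central, peripheral, and lymph-node compartments: CD8 cells that
become effector T cells (Teff, neoantigen-specific), CD4 cells that become
helper T cells (Th, neoantigen-specific), and CD4 cells that become
regulatory T cells (Treg, self-antigen-specific).  Naive cells are
maintained by zero-order thymic export (divided by clonotype diversity)
and saturating peripheral self-renewal; in the lymph node they are
consumed by APC- and antigen-gated activation.  Activated cells go through
a proliferation program of N_aT divisions (2^N_aT-fold amplification),
egress, recirculate, and infiltrate the tumor at a rate saturating with
the cancer-cell number.  Intratumoral Teff suffer additional Treg- and
cancer-contact-mediated death; Th differentiate into Treg under TGF-beta
and arginase-I.  All tumor-resident death fluxes feed one exhausted/dead
pool that still occupies volume until cleared.
"""

from __future__ import annotations

from ..framework import ModelSpec

_EPS = "1e-06"

#: lineage -> (antigen channel, naive diversity parameter)
LINEAGES = {
    "Teff": ("neo", "div_CD8"),
    "Th": ("neo", "div_CD4"),
    "Treg": ("self", "div_CD4"),
}


def build(spec: ModelSpec, has: set[str]) -> None:
    p = spec.params
    rec = f"C_total**2/(C_total**2+K_C_rec)" if "cancer_vasculature" in has else "1.0"
    clear = (
        f"k_cell_clear*K_C_rec/(C_total**2+K_C_rec)"
        if "cancer_vasculature" in has
        else "0.0"
    )

    for lin, (channel, div) in LINEAGES.items():
        # ------------------------------------------------- naive pools S6-S8
        for comp in ("C", "P", "LN"):
            spec.add_species(
                f"nT_{lin}_{comp}",
                {"C": "central", "P": "peripheral", "LN": "lymph_node"}[comp],
                p[f"nT_{lin}_{comp}_init"],
                "cell",
                f"naive {lin}-fated cells per clonotype, {comp}",
            )
        spec.add_reaction(
            f"thymic_export_{lin}", f"Q_nT_thym_{lin}/{div}", {f"nT_{lin}_C": 1.0}
        )
        spec.add_reaction(
            f"nT_{lin}_to_P", f"q_nT_P_in*nT_{lin}_C",
            {f"nT_{lin}_C": -1.0, f"nT_{lin}_P": 1.0},
        )
        spec.add_reaction(
            f"nT_{lin}_from_P", f"q_nT_P_out*nT_{lin}_P",
            {f"nT_{lin}_P": -1.0, f"nT_{lin}_C": 1.0},
        )
        spec.add_reaction(
            f"nT_{lin}_to_LN", f"q_nT_LN_in*nT_{lin}_C",
            {f"nT_{lin}_C": -1.0, f"nT_{lin}_LN": 1.0},
        )
        spec.add_reaction(
            f"nT_{lin}_from_LN", f"q_nT_LN_out*nT_{lin}_LN",
            {f"nT_{lin}_LN": -1.0, f"nT_{lin}_C": 1.0},
        )
        for comp in ("C", "P", "LN"):
            spec.add_reaction(
                f"nT_{lin}_{comp}_death", f"k_nT_death*nT_{lin}_{comp}",
                {f"nT_{lin}_{comp}": -1.0},
            )
        for comp in ("P", "LN"):
            spec.add_reaction(
                f"nT_{lin}_{comp}_selfrenewal",
                f"k_nT_pro_{lin}/{div}*nT_{lin}_{comp}"
                f"/(nT_{lin}_{comp}+K_nT_pro_{lin}/{div}+{_EPS})",
                {f"nT_{lin}_{comp}": 1.0},
            )

        # ------------------------------------- activation + program S9-S11
        spec.add_species(f"aT_{lin}_LN", "lymph_node", 0.0, "cell",
                         f"proliferating activated {lin}")
        for comp in ("LN", "C", "P", "T"):
            spec.add_species(
                f"{lin}_{comp}",
                {"LN": "lymph_node", "C": "central", "P": "peripheral", "T": "tumor"}[comp],
                0.0,
                "cell",
                f"mature {lin}, {comp}",
            )
        n_div = "N_aT_CD8" if lin == "Teff" else "N_aT_CD4"
        if "antigen_presentation" in has:
            act_gate = f"H_APC_{lin}*H_Ag_{channel}"
        else:
            act_gate = "1.0"
        k_act = "k_T_act_CD8" if lin == "Teff" else "k_T_act"
        spec.add_reaction(
            f"activation_{lin}",
            f"{k_act}*{act_gate}*nT_{lin}_LN",
            {f"nT_{lin}_LN": -1.0, f"aT_{lin}_LN": f"n_T_clones_{channel}"},
        )
        spec.add_reaction(
            f"maturation_{lin}",
            f"k_T_pro/max({n_div},1.0)*aT_{lin}_LN",
            {f"aT_{lin}_LN": -1.0, f"{lin}_LN": f"2.0**{n_div}"},
        )

        # ----------------------------------------- trafficking S10, S12-S13
        spec.add_reaction(
            f"{lin}_LN_egress", f"q_T_LN_out*{lin}_LN",
            {f"{lin}_LN": -1.0, f"{lin}_C": 1.0},
        )
        spec.add_reaction(
            f"{lin}_to_P", f"q_T_P_in*{lin}_C", {f"{lin}_C": -1.0, f"{lin}_P": 1.0}
        )
        spec.add_reaction(
            f"{lin}_from_P", f"q_T_P_out*{lin}_P", {f"{lin}_P": -1.0, f"{lin}_C": 1.0}
        )
        spec.add_reaction(
            f"{lin}_infiltration", f"q_T_T_in*{lin}_C*{rec}",
            {f"{lin}_C": -1.0, f"{lin}_T": 1.0},
        )
        for comp in ("LN", "C", "P"):
            spec.add_reaction(
                f"{lin}_{comp}_death", f"k_T_death*{lin}_{comp}", {f"{lin}_{comp}": -1.0}
            )
        spec.add_reaction(
            f"{lin}_T_death", f"k_T_death_{lin}*{lin}_T",
            {f"{lin}_T": -1.0, "T_exh": 1.0},
        )
        spec.add_reaction(
            f"{lin}_T_clearance", f"({clear})*{lin}_T", {f"{lin}_T": -1.0}
        )

    spec.add_species("T_exh", "tumor", 0.0, "cell", "exhausted/dead T cells")
    spec.add_reaction("T_exh_clearance", "k_Tx_clear*T_exh", {"T_exh": -1.0})

    # ------------------------------------------------ intratumoral fates S14-S16
    hil10 = "H_IL10" if "myeloid" in has else "1.0"
    hpd1 = "H_PD1_C" if "checkpoint_synapse" in has else "1.0"
    spec.add_reaction(
        "Teff_inhibition_by_Treg",
        f"k_Teff_Treg*Treg_T/(Teff_T+Treg_T+{_EPS})*{hil10}*Teff_T",
        {"Teff_T": -1.0, "T_exh": 1.0},
    )
    if "cancer_vasculature" in has:
        spec.add_reaction(
            "Teff_inhibition_by_cancer",
            f"k_Teff_C*C_total/(C_total+Teff_T+{_EPS})*{hpd1}*Teff_T",
            {"Teff_T": -1.0, "T_exh": 1.0},
        )
    if "myeloid" in has:
        # TGF-beta- and arginase-I-driven Th -> Treg differentiation; the
        # flux is first-order in the Th pool so the pair conserves Th+Treg
        spec.add_reaction(
            "Th_to_Treg_differentiation",
            "k_Th_Treg*H_TGFb*H_ArgI_Treg*Th_T",
            {"Th_T": -1.0, "Treg_T": 1.0},
        )

    spec.add_rule("T_total_T", "Teff_T + Treg_T + Th_T", "cell")
    h_cd28 = "H_CD28" if "checkpoint_synapse" in has else "0.0"
    h_il2 = "H_IL2" if "myeloid" in has else "0.0"
    spec.add_rule("N_aT_CD8", f"N_TCR_div + N_costim_div*{h_cd28} + N_IL2_div*{h_il2}",
                  "", "divisions of an activated CD8 cell")
    spec.add_rule("N_aT_CD4", f"N_TCR_div + N_costim_div*{h_cd28} + N_IL2_div*{h_il2}",
                  "", "divisions of an activated CD4 cell")

    # cytokine output of activated T cells (balance equations live in myeloid)
    if "myeloid" in has:
        vt = "V_T" if "cancer_vasculature" in has else "V_T_min"
        spec.add_reaction(
            "IFNg_secretion",
            f"(k_IFNg_sec_Teff*Teff_T + k_IFNg_sec_Th*Th_T)/{vt}",
            {"IFNg_T": 1.0},
        )
        spec.add_reaction(
            "IL2_secretion", "k_IL2_sec_Th*Th_LN/V_LN", {"IL2_LN": 1.0}
        )


def division_number(n_tcr: float, n_costim: float, n_il2: float,
                    h_cd28: float, h_il2: float) -> float:
    """Total divisions of an activated T cell: linear sum of the TCR,
    costimulatory, and IL-2 signal components."""
    if not (0 <= h_cd28 <= 1 and 0 <= h_il2 <= 1):
        raise ValueError("Hill inputs must be in [0, 1]")
    return n_tcr + n_costim * h_cd28 + n_il2 * h_il2
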