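"""Macrophages, MDSCs, and the shared cytokine balance machinery.

Monocyte recruitment and differentiation are collapsed into direct
CCL2-driven recruitment of M1-like macrophages.  Recruited TAMs polarize
reversibly between the M1 and M2 extremes: M2->M1 under IL-12 and IFNg,
M1->M2 under TGF-beta and IL-10 (polarization conserves the total).
MDSCs are recruited by CCL2 and secrete arginase-I and NO, which inhibit
Teff cytotoxicity (combined as H_MDSC = 1-(1-H_ArgI)(1-H_NO), mirroring
the phagocytosis-checkpoint composition); arginase-I additionally
promotes Th->Treg differentiation.

Every soluble mediator follows one balance pattern,
V*dc/dt = sum_i k_sec_i * N_i - k_deg * c * V, with a per-cytokine source
map.  Units: cytokines pg/mL, arginase-I mU/mL, NO molar.
"""

from __future__ import annotations

from ..framework import ModelSpec

#: cytokine -> (compartment volume, unit, [(secretion-rate param, cell species)])
#: secretion rates are pg/cell/day except NO (mol/cell/day, converted below)
#: and arginase-I (mU*mL/cell/day).
SOURCE_MAP = {
    "IL12_T": ("V_T", "pg/mL", [("k_IL12_sec_M1", "Mac_M1")]),
    "IL10_T": ("V_T", "pg/mL", [("k_IL10_sec_M2", "Mac_M2"),
                                ("k_IL10_sec_Treg", "Treg_T")]),
    "TGFb_T": ("V_T", "pg/mL", [("k_TGFb_sec_M2", "Mac_M2"),
                                ("k_TGFb_sec_C", "C_total")]),
    "CCL2_T": ("V_T", "pg/mL", [("k_CCL2_sec_C", "C_total")]),
    "ArgI_T": ("V_T", "mU/mL", [("k_ArgI_sec", "MDSC")]),
}


def build(spec: ModelSpec, has: set[str]) -> None:
    has_cancer = "cancer_vasculature" in has
    has_lymph = "lymphocytes" in has
    vt = "V_T" if has_cancer else "V_T_min"
    clear = (
        "k_cell_clear*K_C_rec/(C_total**2+K_C_rec)" if has_cancer else "0.0"
    )

    spec.add_species("Mac_M1", "tumor", 0.0, "cell", "M1-like macrophages")
    spec.add_species("Mac_M2", "tumor", 0.0, "cell", "M2-like macrophages")
    spec.add_species("MDSC", "tumor", 0.0, "cell", "myeloid-derived suppressors")
    for name, unit in (
        ("IL12_T", "pg/mL"), ("IL10_T", "pg/mL"), ("TGFb_T", "pg/mL"),
        ("IFNg_T", "pg/mL"), ("CCL2_T", "pg/mL"), ("NO_T", "M"),
        ("ArgI_T", "mU/mL"),
    ):
        spec.add_species(name, "tumor", 0.0, unit, name.split("_")[0])
    spec.add_species("IL2_LN", "lymph_node", 0.0, "pg/mL", "IL-2, lymph node")

    # ------------------------------------------------- macrophages S50-S51
    spec.add_reaction(
        "Mac_recruitment", f"k_Mac_mig*{vt}*H_CCL2", {"Mac_M1": 1.0}
    )
    spec.add_reaction(
        "M2_to_M1_polarization", "k_M1_pol*(H_IL12+H_IFNg)*Mac_M2",
        {"Mac_M2": -1.0, "Mac_M1": 1.0},
    )
    spec.add_reaction(
        "M1_to_M2_polarization", "k_M2_pol*(H_TGFb+H_IL10)*Mac_M1",
        {"Mac_M1": -1.0, "Mac_M2": 1.0},
    )
    for m in ("Mac_M1", "Mac_M2"):
        spec.add_reaction(f"{m}_death", f"k_Mac_death*{m}", {m: -1.0})
        spec.add_reaction(f"{m}_clearance", f"({clear})*{m}", {m: -1.0})

    # ------------------------------------------------------------ MDSC S49
    spec.add_reaction("MDSC_recruitment", f"k_MDSC_mig*{vt}*H_CCL2", {"MDSC": 1.0})
    spec.add_reaction("MDSC_death", "k_MDSC_death*MDSC", {"MDSC": -1.0})
    spec.add_reaction("MDSC_clearance", f"({clear})*MDSC", {"MDSC": -1.0})

    # --------------------------------------------------- cytokine balances
    for name, (vol, _unit, sources) in SOURCE_MAP.items():
        terms = [
            f"{k}*{cell}"
            for k, cell in sources
            if cell in ("Mac_M1", "Mac_M2", "MDSC")
            or (cell == "C_total" and has_cancer)
            or (cell == "Treg_T" and has_lymph)
        ]
        if terms:
            spec.add_reaction(
                f"{name}_secretion",
                f"({' + '.join(terms)})/{vol if has_cancer else 'V_T_min'}",
                {name: 1.0},
            )
        spec.add_reaction(
            f"{name}_degradation", f"k_cyt_deg_{name.split('_')[0]}*{name}",
            {name: -1.0},
        )
    # NO: secretion in mol/cell/day -> molar in the tumor water volume
    spec.add_reaction(
        "NO_T_secretion", f"k_NO_sec*MDSC/({vt}*0.001)", {"NO_T": 1.0}
    )
    spec.add_reaction("NO_T_degradation", "k_cyt_deg_NO*NO_T", {"NO_T": -1.0})
    spec.add_reaction("IL2_LN_degradation", "k_cyt_deg_IL2*IL2_LN", {"IL2_LN": -1.0})
    # IFNg sources (activated T cells) are registered by the lymphocyte module
    spec.add_reaction(
        "IFNg_T_degradation", "k_cyt_deg_IFNg*IFNg_T", {"IFNg_T": -1.0}
    )

    spec.add_rule("M_total", "Mac_M1 + Mac_M2", "cell")
    # cytokine response Hills (first-order saturation)
    for rule, conc, k50 in (
        ("H_CCL2", "CCL2_T", "CCL2_50"),
        ("H_IL10", "IL10_T", "IL10_50"),
        ("H_IL10_phago", "IL10_T", "IL10_50_phago"),
        ("H_IL12", "IL12_T", "IL12_50"),
        ("H_IFNg", "IFNg_T", "IFNg_50"),
        ("H_TGFb", "TGFb_T", "TGFb_50"),
        ("H_TGFb_Teff", "TGFb_T", "TGFb_50_Teff"),
        ("H_IL2", "IL2_LN", "IL2_50"),
        ("H_ArgI", "ArgI_T", "ArgI_50"),
        ("H_ArgI_Treg", "ArgI_T", "ArgI_50_Treg"),
        ("H_NO", "NO_T", "NO_50"),
    ):
        spec.add_rule(rule, f"{conc}/({conc}+{k50})")
    spec.add_rule("H_MDSC", "1.0 - (1.0-H_ArgI)*(1.0-H_NO)", "",
                  "combined MDSC inhibition of Teff killing")
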