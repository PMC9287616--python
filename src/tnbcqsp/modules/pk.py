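"""Antibody and nab-paclitaxel pharmacokinetics.

Antibodies (atezolizumab dosed by default; anti-CD47 and anti-CTLA-4
carried dormant for perturbation studies) follow a four-compartment model
with permeability-derived volumetric exchange on free-fraction
concentrations [A]_i/gamma_i, a lymphatic drainage chain
tumor -> lymph node -> central at rate Q_LD, and linear clearance from
the central compartment.  Nab-paclitaxel follows a linear three-
compartment plasma model; its intratumoral concentration is approximated
by a tumor-to-plasma partition ratio (repeated-assignment rule, not a
state).

States are concentrations (molar); exchange reactions scale by 1/V_i so
that total drug amount is conserved when clearance is off.  The slow
dilution of tumor drug by tumor-volume growth is neglected.
"""

from __future__ import annotations

from ..framework import ModelSpec

#: antibody tag -> (clearance param, dosed by default)
ANTIBODIES = ("Atezo", "aCD47Ab", "aCTLA4Ab")


def _antibody_pk(spec: ModelSpec, tag: str, vt: str) -> None:
    k_cl = f"k_cl_{tag}"
    spec.add_species(f"{tag}_C", "central", 0.0, "M", f"{tag}, central")
    spec.add_species(f"{tag}_P", "peripheral", 0.0, "M", f"{tag}, peripheral")
    spec.add_species(f"{tag}_T", "tumor", 0.0, "M", f"{tag}, tumor")
    spec.add_species(f"{tag}_LN", "lymph_node", 0.0, "M", f"{tag}, lymph node")
    spec.add_reaction(
        f"{tag}_exchange_P",
        f"Q_P_ab*({tag}_P/gamma_P - {tag}_C/gamma_C)",
        {f"{tag}_C": "1.0/V_C", f"{tag}_P": "-1.0/V_P"},
    )
    spec.add_reaction(
        f"{tag}_exchange_T",
        f"Q_T_ab*({tag}_T/gamma_T - {tag}_C/gamma_C)",
        {f"{tag}_C": "1.0/V_C", f"{tag}_T": f"-1.0/{vt}"},
    )
    spec.add_reaction(
        f"{tag}_exchange_LN",
        f"Q_LN_ab*({tag}_LN/gamma_LN - {tag}_C/gamma_C)",
        {f"{tag}_C": "1.0/V_C", f"{tag}_LN": "-1.0/V_LN"},
    )
    spec.add_reaction(
        f"{tag}_lymph_drain_T",
        f"Q_LD*{tag}_T/gamma_T",
        {f"{tag}_T": f"-1.0/{vt}", f"{tag}_LN": "1.0/V_LN"},
    )
    spec.add_reaction(
        f"{tag}_lymph_drain_LN",
        f"Q_LD*{tag}_LN/gamma_LN",
        {f"{tag}_LN": "-1.0/V_LN", f"{tag}_C": "1.0/V_C"},
    )
    spec.add_reaction(
        f"{tag}_clearance", f"{k_cl}*{tag}_C", {f"{tag}_C": "-1.0/V_C"}
    )


def build(spec: ModelSpec, has: set[str]) -> None:
    vt = "V_T" if "cancer_vasculature" in has else "V_T_min"
    for tag in ANTIBODIES:
        _antibody_pk(spec, tag, vt)

    # free interstitial antibody concentrations seen by tumor synapses
    spec.add_rule("aPDL1_T_free", "Atezo_T/gamma_T", "M",
                  "free atezolizumab in tumor interstitium")
    spec.add_rule("aCD47_T_free", "aCD47Ab_T/gamma_T", "M")
    spec.add_rule("aCTLA4_LN_free", "aCTLA4Ab_LN/gamma_LN", "M")

    # nab-paclitaxel: linear 3-compartment plasma PK
    spec.add_species("NabP_C", "central", 0.0, "M", "nab-paclitaxel, plasma")
    spec.add_species("NabP_P1", "peripheral", 0.0, "M",
                     "nab-paclitaxel, shallow tissue")
    spec.add_species("NabP_P2", "peripheral", 0.0, "M",
                     "nab-paclitaxel, deep tissue")
    for a, b, q in (("C", "P1", "Q12_nabp"), ("C", "P2", "Q13_nabp")):
        va = "V1_nabp" if a == "C" else f"V{a[1]}_nabp"
        vb = f"V{int(b[1]) + 1}_nabp"
        spec.add_reaction(
            f"nabp_{a}_to_{b}", f"{q}*NabP_{a}",
            {f"NabP_{a}": f"-1.0/{va}", f"NabP_{b}": f"1.0/{vb}"},
        )
        spec.add_reaction(
            f"nabp_{b}_to_{a}", f"{q}*NabP_{b}",
            {f"NabP_{b}": f"-1.0/{vb}", f"NabP_{a}": f"1.0/{va}"},
        )
    spec.add_reaction(
        "nabp_elimination", "CL_nabp*NabP_C", {"NabP_C": "-1.0/V1_nabp"}
    )
    spec.add_rule("NabP_T", "r_nabp_tumor_plasma*NabP_C", "M",
                  "intratumoral nab-paclitaxel (partition approximation)")
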