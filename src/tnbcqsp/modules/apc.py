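"""Antigen-presenting cells: recruitment, maturation, migration.

Immature APCs relax toward a density-proportional baseline in the tumor
and lymph node; in the tumor they mature under IL-12 with IL-10
inhibition, and mature APCs migrate to the draining lymph node where they
activate naive T cells.  H_APC is the saturating fraction of naive T
cells that can engage a mature APC, computed per T-cell lineage with the
lineage's antigen-clone count.
"""

from __future__ import annotations

from ..framework import ModelSpec

_EPS = "1e-09"


def build(spec: ModelSpec, has: set[str]) -> None:
    p = spec.params
    spec.add_species("APC_T", "tumor", 0.0, "cell", "immature APC, tumor")
    spec.add_species("APC_LN", "lymph_node", p["rho_APC"] * p["V_LN"], "cell",
                     "immature APC, lymph node")
    spec.add_species("mAPC_T", "tumor", 0.0, "cell", "mature APC, tumor")
    spec.add_species("mAPC_LN", "lymph_node", 0.0, "cell", "mature APC, lymph node")

    vt = "V_T" if "cancer_vasculature" in has else "V_T_min"
    spec.add_reaction(
        "APC_T_turnover", f"k_APC_death*(rho_APC*{vt} - APC_T)", {"APC_T": 1.0}
    )
    spec.add_reaction(
        "APC_LN_turnover", "k_APC_death*(rho_APC*V_LN - APC_LN)", {"APC_LN": 1.0}
    )
    gate = "H_IL12*(1.0-H_IL10)" if "myeloid" in has else "1.0"
    spec.add_reaction(
        "APC_maturation", f"k_APC_mat*APC_T*{gate}", {"APC_T": -1.0, "mAPC_T": 1.0}
    )
    spec.add_reaction(
        "mAPC_migration", "k_APC_mig*mAPC_T", {"mAPC_T": -1.0, "mAPC_LN": 1.0}
    )
    spec.add_reaction("mAPC_T_death", "k_mAPC_death*mAPC_T", {"mAPC_T": -1.0})
    spec.add_reaction("mAPC_LN_death", "k_mAPC_death*mAPC_LN", {"mAPC_LN": -1.0})

    if "lymphocytes" in has:
        for lin, channel in (("Teff", "neo"), ("Th", "neo"), ("Treg", "self")):
            spec.add_rule(
                f"H_APC_{lin}",
                f"n_sites_APC*mAPC_LN/"
                f"(n_sites_APC*mAPC_LN + n_T_clones_{channel}*nT_{lin}_LN + {_EPS})",
                "",
                f"mature-APC availability for {lin} activation",
            )

    if "myeloid" in has:
        # mature APCs secrete IL-12 upon antigen stimulation, ~10x the
        # macrophage rate (k_IL12_sec_mAPC is stored as the full rate)
        spec.add_reaction(
            "IL12_secretion_mAPC", "k_IL12_sec_mAPC*mAPC_T/V_T", {"IL12_T": 1.0}
        )


def h_apc(mapc_ln: float, nt_ln: float, n_sites: float, n_clones: float) -> float:
    """Fraction of naive T cells that can simultaneously engage mature APCs."""
    if min(mapc_ln, nt_ln, n_sites, n_clones) < 0:
        raise ValueError("inputs must be non-negative")
    denom = n_sites * mapc_ln + n_clones * nt_ln
    if denom == 0:
        return 0.0
    return n_sites * mapc_ln / denom
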