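"""Immune-synapse checkpoint binding networks and derived inhibition Hills.

Five synapse sub-compartments are carried by the default model, one per
interacting cell-pair class (checkpoint densities are averages over all
cells of a type, so one synapse per class suffices):

* ``syn_T_C1``/``syn_T_C2`` — effector T cell vs. cancer clone: PD-1 vs.
  PD-L1/PD-L2 with bivalent anti-PD-L1, and cis PD-L1:CD80 on the cancer
  surface.  Yields H_PD1_C (inhibition of Teff killing).
* ``syn_M_C1``/``syn_M_C2`` — M1 macrophage vs. cancer clone: the PD-1
  network plus trans CD47:SIRPalpha with bivalent anti-CD47.  Yields
  H_PD1_M, H_SIRPa and the combined phagocytosis inhibition
  H_Mac_C = 1 - (1-H_SIRPa)(1-H_PD1_M).
* ``syn_T_APC`` — naive T cell vs. mature APC in the lymph node: the PD-1
  network plus the CD28/CTLA-4 vs. CD80/CD86 competition (CD80 and CTLA-4
  bivalent, zipper-like multivalent complexes; cis PD-L1:CD80 frees CD80
  for CD28 but weakens CTLA-4 binding) with bivalent anti-CTLA-4 support.
  Yields H_CD28 (costimulatory divisions).

All species are 2-D densities (molecule/um^2).  3-D association constants
are converted to 2-D by the synapse confinement thickness d_syn; the
synapse contact area is widened by a fixed factor of 3 standing in for
diffusive entry of surface molecules.  Bivalent binders use the standard
stoichiometric corrections: 2*kon for the first arm, chi*kon/(d_syn*N_A)
for the cross-arm, 2*koff off the doubly-bound complex.
"""

from __future__ import annotations

from ..framework import ModelSpec
from ..units import MOLAR_TO_PER_UM3

_EPS = "1e-09"


def _kon2d(kon: str) -> str:
    """3-D association constant (1/(M*day)) -> 2-D (um^2/molecule/day)."""
    return f"({kon}/(d_syn*{MOLAR_TO_PER_UM3!r}))"


def _hill2(x: str, k50: str, n: str = "n_checkpoint") -> str:
    return f"({x})**{n}/(({x})**{n} + {k50}**{n})"


def add_pd1_network(
    spec: ModelSpec,
    syn: str,
    pd1_dens: str,
    pdl1_dens: str,
    apdl1_conc: str,
    with_ifng: bool,
    with_cis_cd80: str | None = None,
) -> None:
    """PD-1 vs PD-L1/PD-L2 binding with bivalent anti-PD-L1 and
    IFNg-driven, saturating PD-L1/2 synthesis.  ``with_cis_cd80`` names the
    CD80 density parameter when the ligand side carries CD80 (cancer cells
    and APCs); cis PD-L1:CD80 binding then competes with trans PD-1."""
    p = spec.params
    S = lambda n: f"{syn}_{n}"  # noqa: E731

    spec.add_species(S("PD1"), syn, p[pd1_dens], "molecule/um^2", "free PD-1")
    spec.add_species(S("PDL1"), syn, p[pdl1_dens], "molecule/um^2", "free PD-L1")
    spec.add_species(S("PDL2"), syn, p["r_PDL2"] * p[pdl1_dens],
                     "molecule/um^2", "free PD-L2")
    for c in ("PD1_PDL1", "PD1_PDL2", "PDL1_aPDL1", "PDL1_aPDL1_PDL1"):
        spec.add_species(S(c), syn, 0.0, "molecule/um^2", c.replace("_", ":"))

    spec.add_binding(
        S("PD1_PDL1"), S("PD1"), S("PDL1"), S("PD1_PDL1"),
        _kon2d("kon_PD1_PDL1"), "koff_PD1_PDL1",
    )
    spec.add_binding(
        S("PD1_PDL2"), S("PD1"), S("PDL2"), S("PD1_PDL2"),
        _kon2d("kon_PD1_PDL2"), "koff_PD1_PDL2",
    )
    # bivalent anti-PD-L1: first arm from solution, cross-arm on the surface
    spec.add_reaction(
        f"{S('PDL1_aPDL1')}_on",
        f"2.0*kon_PDL1_aPDL1*{S('PDL1')}*({apdl1_conc})",
        {S("PDL1"): -1.0, S("PDL1_aPDL1"): 1.0},
    )
    spec.add_reaction(
        f"{S('PDL1_aPDL1')}_off",
        f"koff_PDL1_aPDL1*{S('PDL1_aPDL1')}",
        {S("PDL1"): 1.0, S("PDL1_aPDL1"): -1.0},
    )
    spec.add_reaction(
        f"{S('PDL1_aPDL1_PDL1')}_on",
        f"chi_aPDL1*{_kon2d('kon_PDL1_aPDL1')}*{S('PDL1_aPDL1')}*{S('PDL1')}",
        {S("PDL1"): -1.0, S("PDL1_aPDL1"): -1.0, S("PDL1_aPDL1_PDL1"): 1.0},
    )
    spec.add_reaction(
        f"{S('PDL1_aPDL1_PDL1')}_off",
        f"2.0*koff_PDL1_aPDL1*{S('PDL1_aPDL1_PDL1')}",
        {S("PDL1"): 1.0, S("PDL1_aPDL1"): 1.0, S("PDL1_aPDL1_PDL1"): -1.0},
    )

    pdl1_complexes = [S("PD1_PDL1"), S("PDL1_aPDL1"), f"2.0*{S('PDL1_aPDL1_PDL1')}"]
    if with_cis_cd80 is not None:
        spec.add_species(S("CD80m"), syn, p[with_cis_cd80], "molecule/um^2",
                         "monomeric CD80")
        spec.add_species(S("CD80d"), syn, 0.0, "molecule/um^2", "CD80 homodimer")
        spec.add_species(S("PDL1_CD80"), syn, 0.0, "molecule/um^2",
                         "cis PD-L1:CD80 heterodimer")
        spec.add_reaction(
            f"{S('CD80d')}_on",
            f"{_kon2d('kon_CD80_CD80')}*{S('CD80m')}*{S('CD80m')}",
            {S("CD80m"): -2.0, S("CD80d"): 1.0},
        )
        spec.add_reaction(
            f"{S('CD80d')}_off", f"koff_CD80_CD80*{S('CD80d')}",
            {S("CD80m"): 2.0, S("CD80d"): -1.0},
        )
        # only monomeric CD80 engages PD-L1 in cis
        spec.add_binding(
            S("PDL1_CD80"), S("PDL1"), S("CD80m"), S("PDL1_CD80"),
            _kon2d("kon_CD80_PDL1"), "koff_CD80_PDL1",
        )
        pdl1_complexes.append(S("PDL1_CD80"))

    if with_ifng:
        total1 = " + ".join([S("PDL1")] + pdl1_complexes)
        total2 = f"{S('PDL2')} + {S('PD1_PDL2')}"
        hifng = "IFNg_T/(IFNg_T+IFNg50_PDL1)"
        spec.add_reaction(
            f"{S('PDL1')}_synthesis",
            f"k_out_PDL1*{hifng}*(1.0-({total1})/(r_PDL1_IFNg*{pdl1_dens}))",
            {S("PDL1"): 1.0},
        )
        spec.add_reaction(
            f"{S('PDL1')}_internalization",
            f"k_in_PDL1*({pdl1_dens}-({total1}))",
            {S("PDL1"): 1.0},
        )
        spec.add_reaction(
            f"{S('PDL2')}_synthesis",
            f"r_PDL2*k_out_PDL1*{hifng}"
            f"*(1.0-({total2})/(r_PDL1_IFNg*r_PDL2*{pdl1_dens}))",
            {S("PDL2"): 1.0},
        )
        spec.add_reaction(
            f"{S('PDL2')}_internalization",
            f"k_in_PDL1*(r_PDL2*{pdl1_dens}-({total2}))",
            {S("PDL2"): 1.0},
        )


def add_cd47_block(spec: ModelSpec, syn: str, acd47_conc: str) -> None:
    """Trans CD47:SIRPalpha binding with bivalent anti-CD47 support."""
    p = spec.params
    S = lambda n: f"{syn}_{n}"  # noqa: E731
    spec.add_species(S("CD47"), syn, p["CD47_dens_C"], "molecule/um^2", "free CD47")
    spec.add_species(S("SIRPa"), syn, p["SIRPa_dens_M"], "molecule/um^2",
                     "free SIRPalpha")
    for c in ("CD47_SIRPa", "CD47_aCD47", "CD47_aCD47_CD47"):
        spec.add_species(S(c), syn, 0.0, "molecule/um^2", c.replace("_", ":"))
    spec.add_binding(
        S("CD47_SIRPa"), S("CD47"), S("SIRPa"), S("CD47_SIRPa"),
        _kon2d("kon_CD47_SIRPa"), "koff_CD47_SIRPa",
    )
    spec.add_reaction(
        f"{S('CD47_aCD47')}_on",
        f"2.0*kon_CD47_aCD47*{S('CD47')}*({acd47_conc})",
        {S("CD47"): -1.0, S("CD47_aCD47"): 1.0},
    )
    spec.add_reaction(
        f"{S('CD47_aCD47')}_off", f"koff_CD47_aCD47*{S('CD47_aCD47')}",
        {S("CD47"): 1.0, S("CD47_aCD47"): -1.0},
    )
    spec.add_reaction(
        f"{S('CD47_aCD47_CD47')}_on",
        f"chi_aCD47*{_kon2d('kon_CD47_aCD47')}*{S('CD47_aCD47')}*{S('CD47')}",
        {S("CD47"): -1.0, S("CD47_aCD47"): -1.0, S("CD47_aCD47_CD47"): 1.0},
    )
    spec.add_reaction(
        f"{S('CD47_aCD47_CD47')}_off",
        f"2.0*koff_CD47_aCD47*{S('CD47_aCD47_CD47')}",
        {S("CD47"): 1.0, S("CD47_aCD47"): 1.0, S("CD47_aCD47_CD47"): -1.0},
    )


def add_costim_block(spec: ModelSpec, syn: str, actla4_conc: str) -> None:
    """CD28/CTLA-4 vs CD80/CD86 competition on the naive T-APC synapse.

    CD28 and monomeric CD86 are monovalent; CD80 (homodimer) and CTLA-4
    are bivalent, allowing zipper-like multivalent complexes; CD86 also
    homodimerizes, giving CTLA-4:CD86:CTLA-4.  The cis PD-L1:CD80
    heterodimer still binds CD28 with full affinity but CTLA-4 only with a
    weakening factor f_cis_CTLA4.
    """
    p = spec.params
    S = lambda n: f"{syn}_{n}"  # noqa: E731

    spec.add_species(S("CD28"), syn, p["CD28_dens_T"], "molecule/um^2", "free CD28")
    spec.add_species(S("CTLA4"), syn, p["CTLA4_dens_T"], "molecule/um^2",
                     "free CTLA-4")
    spec.add_species(S("CD86m"), syn, p["CD86_dens_APC"], "molecule/um^2",
                     "monomeric CD86")
    spec.add_species(S("CD86d"), syn, 0.0, "molecule/um^2", "CD86 homodimer")
    complexes = (
        "CD28_CD80", "CD28_CD80_CD28", "CD28_CD86",
        "CTLA4_CD80", "CTLA4_CD80_CTLA4", "CD80_CTLA4_CD80",
        "CTLA4_CD80_CTLA4_CD80", "CTLA4_CD86", "CTLA4_CD86_CTLA4",
        "PDL1_CD80_CD28", "PDL1_CD80_CTLA4",
        "CTLA4_aCTLA4", "CTLA4_aCTLA4_CTLA4",
    )
    for c in complexes:
        spec.add_species(S(c), syn, 0.0, "molecule/um^2", c.replace("_", ":"))

    spec.add_reaction(
        f"{S('CD86d')}_on", f"{_kon2d('kon_CD86_CD86')}*{S('CD86m')}*{S('CD86m')}",
        {S("CD86m"): -2.0, S("CD86d"): 1.0},
    )
    spec.add_reaction(
        f"{S('CD86d')}_off", f"koff_CD86_CD86*{S('CD86d')}",
        {S("CD86m"): 2.0, S("CD86d"): -1.0},
    )
    k28_80 = _kon2d("kon_CD28_CD80")
    k4_80 = _kon2d("kon_CTLA4_CD80")
    spec.add_reaction(
        f"{S('CD28_CD80')}_on", f"2.0*{k28_80}*{S('CD28')}*{S('CD80d')}",
        {S("CD28"): -1.0, S("CD80d"): -1.0, S("CD28_CD80"): 1.0},
    )
    spec.add_reaction(
        f"{S('CD28_CD80')}_off", f"koff_CD28_CD80*{S('CD28_CD80')}",
        {S("CD28"): 1.0, S("CD80d"): 1.0, S("CD28_CD80"): -1.0},
    )
    spec.add_reaction(
        f"{S('CD28_CD80_CD28')}_on", f"{k28_80}*{S('CD28_CD80')}*{S('CD28')}",
        {S("CD28"): -1.0, S("CD28_CD80"): -1.0, S("CD28_CD80_CD28"): 1.0},
    )
    spec.add_reaction(
        f"{S('CD28_CD80_CD28')}_off",
        f"2.0*koff_CD28_CD80*{S('CD28_CD80_CD28')}",
        {S("CD28"): 1.0, S("CD28_CD80"): 1.0, S("CD28_CD80_CD28"): -1.0},
    )
    spec.add_binding(
        S("CD28_CD86"), S("CD28"), S("CD86m"), S("CD28_CD86"),
        _kon2d("kon_CD28_CD86"), "koff_CD28_CD86",
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80')}_on", f"2.0*{k4_80}*{S('CTLA4')}*{S('CD80d')}",
        {S("CTLA4"): -1.0, S("CD80d"): -1.0, S("CTLA4_CD80"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80')}_off", f"koff_CTLA4_CD80*{S('CTLA4_CD80')}",
        {S("CTLA4"): 1.0, S("CD80d"): 1.0, S("CTLA4_CD80"): -1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80_CTLA4')}_on", f"{k4_80}*{S('CTLA4_CD80')}*{S('CTLA4')}",
        {S("CTLA4"): -1.0, S("CTLA4_CD80"): -1.0, S("CTLA4_CD80_CTLA4"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80_CTLA4')}_off",
        f"2.0*koff_CTLA4_CD80*{S('CTLA4_CD80_CTLA4')}",
        {S("CTLA4"): 1.0, S("CTLA4_CD80"): 1.0, S("CTLA4_CD80_CTLA4"): -1.0},
    )
    spec.add_reaction(
        f"{S('CD80_CTLA4_CD80')}_on", f"{k4_80}*{S('CTLA4_CD80')}*{S('CD80d')}",
        {S("CD80d"): -1.0, S("CTLA4_CD80"): -1.0, S("CD80_CTLA4_CD80"): 1.0},
    )
    spec.add_reaction(
        f"{S('CD80_CTLA4_CD80')}_off",
        f"2.0*koff_CTLA4_CD80*{S('CD80_CTLA4_CD80')}",
        {S("CD80d"): 1.0, S("CTLA4_CD80"): 1.0, S("CD80_CTLA4_CD80"): -1.0},
    )
    # closure of the 2:2 zipper from either side
    spec.add_reaction(
        f"{S('CTLA4_CD80_CTLA4_CD80')}_on_a",
        f"{k4_80}*{S('CTLA4_CD80_CTLA4')}*{S('CD80d')}",
        {S("CD80d"): -1.0, S("CTLA4_CD80_CTLA4"): -1.0,
         S("CTLA4_CD80_CTLA4_CD80"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80_CTLA4_CD80')}_on_b",
        f"{k4_80}*{S('CD80_CTLA4_CD80')}*{S('CTLA4')}",
        {S("CTLA4"): -1.0, S("CD80_CTLA4_CD80"): -1.0,
         S("CTLA4_CD80_CTLA4_CD80"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80_CTLA4_CD80')}_off_a",
        f"koff_CTLA4_CD80*{S('CTLA4_CD80_CTLA4_CD80')}",
        {S("CD80d"): 1.0, S("CTLA4_CD80_CTLA4"): 1.0,
         S("CTLA4_CD80_CTLA4_CD80"): -1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD80_CTLA4_CD80')}_off_b",
        f"koff_CTLA4_CD80*{S('CTLA4_CD80_CTLA4_CD80')}",
        {S("CTLA4"): 1.0, S("CD80_CTLA4_CD80"): 1.0,
         S("CTLA4_CD80_CTLA4_CD80"): -1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD86')}_on",
        f"2.0*{_kon2d('kon_CTLA4_CD86')}*{S('CTLA4')}*{S('CD86d')}",
        {S("CTLA4"): -1.0, S("CD86d"): -1.0, S("CTLA4_CD86"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD86')}_off", f"koff_CTLA4_CD86*{S('CTLA4_CD86')}",
        {S("CTLA4"): 1.0, S("CD86d"): 1.0, S("CTLA4_CD86"): -1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD86_CTLA4')}_on",
        f"{_kon2d('kon_CTLA4_CD86')}*{S('CTLA4_CD86')}*{S('CTLA4')}",
        {S("CTLA4"): -1.0, S("CTLA4_CD86"): -1.0, S("CTLA4_CD86_CTLA4"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_CD86_CTLA4')}_off",
        f"2.0*koff_CTLA4_CD86*{S('CTLA4_CD86_CTLA4')}",
        {S("CTLA4"): 1.0, S("CTLA4_CD86"): 1.0, S("CTLA4_CD86_CTLA4"): -1.0},
    )
    spec.add_binding(
        S("PDL1_CD80_CD28"), S("PDL1_CD80"), S("CD28"), S("PDL1_CD80_CD28"),
        k28_80, "koff_CD28_CD80",
    )
    spec.add_binding(
        S("PDL1_CD80_CTLA4"), S("PDL1_CD80"), S("CTLA4"), S("PDL1_CD80_CTLA4"),
        f"(f_cis_CTLA4*{k4_80})", "koff_CTLA4_CD80",
    )
    # bivalent anti-CTLA-4 (dormant by default: no regimen doses it)
    spec.add_reaction(
        f"{S('CTLA4_aCTLA4')}_on",
        f"2.0*kon_CTLA4_aCTLA4*{S('CTLA4')}*({actla4_conc})",
        {S("CTLA4"): -1.0, S("CTLA4_aCTLA4"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_aCTLA4')}_off", f"koff_CTLA4_aCTLA4*{S('CTLA4_aCTLA4')}",
        {S("CTLA4"): 1.0, S("CTLA4_aCTLA4"): -1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_aCTLA4_CTLA4')}_on",
        f"chi_aCTLA4*{_kon2d('kon_CTLA4_aCTLA4')}*{S('CTLA4_aCTLA4')}*{S('CTLA4')}",
        {S("CTLA4"): -1.0, S("CTLA4_aCTLA4"): -1.0, S("CTLA4_aCTLA4_CTLA4"): 1.0},
    )
    spec.add_reaction(
        f"{S('CTLA4_aCTLA4_CTLA4')}_off",
        f"2.0*koff_CTLA4_aCTLA4*{S('CTLA4_aCTLA4_CTLA4')}",
        {S("CTLA4"): 1.0, S("CTLA4_aCTLA4"): 1.0, S("CTLA4_aCTLA4_CTLA4"): -1.0},
    )


def build(spec: ModelSpec, has: set[str], n_clones: int = 2) -> None:
    p = spec.params
    has_pk = "pharmacology" in has
    has_myeloid = "myeloid" in has
    apdl1_t = "aPDL1_T_free" if has_pk else "0.0"
    apdl1_ln = "Atezo_LN/gamma_LN" if has_pk else "0.0"
    acd47_t = "aCD47_T_free" if has_pk else "0.0"
    actla4_ln = "aCTLA4_LN_free" if has_pk else "0.0"

    a_syn = p["A_syn_contact"] * p["f_syn_diffusion"]
    clones = range(1, n_clones + 1)

    # ------------------------------------------- Teff vs cancer, per clone
    for i in clones:
        syn = f"syn_T_C{i}"
        spec.add_compartment(syn, a_syn, "um^2")
        add_pd1_network(spec, syn, "PD1_dens_T", "PDL1_dens_C", apdl1_t,
                        has_myeloid, with_cis_cd80="CD80_dens_C")
        spec.add_rule(
            f"H_PD1_C{i}",
            _hill2(f"{syn}_PD1_PDL1 + {syn}_PD1_PDL2", "PD1_50_T"),
            "", f"PD-1 inhibition of Teff killing, clone {i}",
        )
    weighted = " + ".join(f"C{i}*H_PD1_C{i}" for i in clones)
    spec.add_rule("H_PD1_C", f"({weighted})/max(C_total,{_EPS})", "",
                  "clone-abundance-weighted PD-1 inhibition of Teff")

    # -------------------------------------- macrophage vs cancer, per clone
    for i in clones:
        syn = f"syn_M_C{i}"
        spec.add_compartment(syn, a_syn, "um^2")
        add_pd1_network(spec, syn, "PD1_dens_M", "PDL1_dens_C", apdl1_t,
                        has_myeloid, with_cis_cd80="CD80_dens_C")
        add_cd47_block(spec, syn, acd47_t)
        spec.add_rule(
            f"H_PD1_M{i}",
            _hill2(f"{syn}_PD1_PDL1 + {syn}_PD1_PDL2", "PD1_50_M"),
            "", f"PD-1 inhibition of phagocytosis, clone {i}",
        )
        h_sirpa = _hill2(f"{syn}_CD47_SIRPa", "SIRPa_50")
        spec.add_rule(
            f"H_Mac_C{i}",
            f"1.0 - (1.0-{h_sirpa})*(1.0-H_PD1_M{i})",
            "", f"combined checkpoint inhibition of phagocytosis, clone {i}",
        )

    # ------------------------------------------- naive T vs mAPC (lymph node)
    syn = "syn_T_APC"
    spec.add_compartment(syn, a_syn, "um^2")
    add_pd1_network(spec, syn, "PD1_dens_T", "PDL1_dens_APC", apdl1_ln,
                    has_myeloid, with_cis_cd80="CD80_dens_APC")
    add_costim_block(spec, syn, actla4_ln)
    spec.add_rule(
        "CD28bound",
        f"{syn}_CD28_CD80 + {syn}_CD28_CD86 + 2.0*{syn}_CD28_CD80_CD28"
        f" + {syn}_PDL1_CD80_CD28",
        "molecule/um^2", "bound CD28 density",
    )
    spec.add_rule("H_CD28", _hill2("CD28bound", "CD28_50"), "",
                  "costimulatory signal Hill")


def h_mac_c(h_sirpa: float, h_pd1_m: float) -> float:
    """Combined phagocytosis inhibition 1-(1-H_SIRPa)(1-H_PD1); commutative,
    monotone nondecreasing in both inputs."""
    if not (0 <= h_sirpa <= 1 and 0 <= h_pd1_m <= 1):
        raise ValueError("Hill inputs must lie in [0, 1]")
    return 1.0 - (1.0 - h_sirpa) * (1.0 - h_pd1_m)
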