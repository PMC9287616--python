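"""Default model assembly: module selection, parameters, toy fixtures.

The full default configuration couples six biological modules —
cancer/vasculature (two clones: nab-paclitaxel-sensitive and an induced
resistant clone with 100x EC50), lymphocytes, antigen presentation,
checkpoint synapses, myeloid cells, and pharmacology — into one stiff ODE
system.  Modules can be assembled in subsets; coupling terms to absent
modules are dropped (dependencies that cannot be dropped are enforced).
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .framework import ModelSpec, ODESystem
from .params import ParameterSet
from .modules import antigen, apc, cancer, checkpoint, myeloid, pk, tcell

#: biological modules selectable in a model configuration
BIOLOGICAL_MODULES = (
    "cancer_vasculature",
    "lymphocytes",
    "antigen_presentation",
    "checkpoint_synapse",
    "myeloid",
    "pharmacology",
)

_DEPENDENCIES = {
    "checkpoint_synapse": {"cancer_vasculature"},
}


class InvalidConfigError(ValueError):
    pass


def _derive_naive_t_steady_state(p) -> None:
    """Fill per-lineage naive-pool initials and self-renewal constants so
    each parameter set (e.g. a virtual patient's sampled thymic export)
    starts at its own healthy steady state.  Explicitly provided values
    are kept."""
    from .modules.tcell import LINEAGES

    kd, q_pi, q_po = p["k_nT_death"], p["q_nT_P_in"], p["q_nT_P_out"]
    q_li, q_lo = p["q_nT_LN_in"], p["q_nT_LN_out"]
    r_p, r_ln = p["ratio_nT_P"], p["ratio_nT_LN"]
    # clamped so perturbed (e.g. toy-jittered) rate sets stay admissible
    thym_per_c = max((q_pi + q_li + kd) - q_po * r_p - q_lo * r_ln, 1e-09)
    renewal_per_c = max((q_po + kd) * r_p - q_pi, 0.0)
    for lin, (_ch, div_name) in LINEAGES.items():
        div = p[div_name]
        c_star = p[f"Q_nT_thym_{lin}"] / (div * thym_per_c)
        defaults = {
            f"nT_{lin}_C_init": c_star,
            f"nT_{lin}_P_init": r_p * c_star,
            f"nT_{lin}_LN_init": r_ln * c_star,
            f"k_nT_pro_{lin}": 2.0 * renewal_per_c * c_star * div,
            f"K_nT_pro_{lin}": r_p * c_star * div,
        }
        for name, value in defaults.items():
            if name not in p:
                p.set(name, value, units="cell",
                      description="derived naive-T steady state")


def default_parameters() -> ParameterSet:
    """The shipped human TNBC parameter set (canonical units)."""
    with resources.files("tnbcqsp.data").joinpath("parameters.csv").open() as fh:
        return ParameterSet.from_csv(fh)


def build_spec(
    params: ParameterSet | None = None,
    modules: set[str] | None = None,
    n_cancer_clones: int = 2,
) -> ModelSpec:
    """Populate (but do not compile) the model registry."""
    has = set(BIOLOGICAL_MODULES if modules is None else modules)
    if not has:
        raise InvalidConfigError("empty module set")
    unknown = has - set(BIOLOGICAL_MODULES)
    if unknown:
        raise InvalidConfigError(f"unknown modules: {sorted(unknown)}")
    for mod, needs in _DEPENDENCIES.items():
        if mod in has and not needs <= has:
            raise InvalidConfigError(f"module {mod!r} requires {sorted(needs)}")
    if n_cancer_clones < 1:
        raise InvalidConfigError("need at least one cancer clone")

    p = (params or default_parameters()).copy()
    if "lymphocytes" in has:
        _derive_naive_t_steady_state(p)
    # the induced resistant clone carries a 100x EC50 at creation
    for i in range(2, n_cancer_clones + 1):
        if f"EC50_nabp_C{i}" not in p:
            p.set(
                f"EC50_nabp_C{i}",
                p["EC50_nabp_C1"] * p["r_EC50_resist"],
                units="M",
                provenance="reported",
                description=f"nab-paclitaxel EC50, resistant clone {i}",
            )

    spec = ModelSpec(p)
    spec.add_compartment("central", p["V_C"], "mL")
    spec.add_compartment("peripheral", p["V_P"], "mL")
    spec.add_compartment("lymph_node", p["V_LN"], "mL")
    spec.add_compartment(
        "tumor", "V_T" if "cancer_vasculature" in has else p["V_T_min"], "mL"
    )
    if "antigen_presentation" in has:
        spec.add_compartment("APC_endosome", p["V_endo_APC"], "mL")
        spec.add_compartment("APC_endosome_membrane", p["A_endo_APC"], "um^2")
        spec.add_compartment("APC_surface", p["A_surf_APC"], "um^2")

    if "cancer_vasculature" in has:
        cancer.build(spec, has, n_cancer_clones)
    if "lymphocytes" in has:
        tcell.build(spec, has)
    if "antigen_presentation" in has:
        apc.build(spec, has)
        antigen.build(spec, has)
    if "checkpoint_synapse" in has:
        checkpoint.build(spec, has, n_cancer_clones)
    if "myeloid" in has:
        myeloid.build(spec, has)
    if "pharmacology" in has:
        pk.build(spec, has)
    return spec


def assemble_model(
    params: ParameterSet | None = None,
    modules: set[str] | None = None,
    n_cancer_clones: int = 2,
) -> ODESystem:
    """Compile the selected configuration into an integrable system."""
    return build_spec(params, modules, n_cancer_clones).assemble()


#: parameters a toy fixture may jitter without breaking structure
_TOY_JITTER_EXCLUDE = (
    "V_C", "V_P", "V_LN", "V_T_min", "N_AV", "MW_atezo", "MW_nabp",
    "r_EC50_resist", "f_vol_cell", "f_syn_diffusion", "n_checkpoint",
    "D_T0", "gamma_C", "gamma_P", "gamma_T", "gamma_LN",
)


def generate_toy_parameters(seed: int) -> ParameterSet:
    """Deterministic, unit-consistent small parameter set for testing.

    Starts from the shipped defaults and applies a mild multiplicative
    lognormal jitter to rates/densities, so every assembled configuration
    keeps its invariants (non-negative rates, Hill exponents >= 1, volume
    fractions in (0, 1]) and a full 400-day simulation stays fast.
    """
    rng = np.random.default_rng(seed)
    p = default_parameters().copy()
    for name in sorted(p):
        rec = p.get_param(name)
        if name in _TOY_JITTER_EXCLUDE or name.startswith(("n_T_clones", "div_")):
            continue
        if name.startswith(("gamma_", "f_vol_")):
            continue
        factor = float(np.exp(rng.normal(0.0, 0.1)))
        p.set(name, rec.value * factor)
    return p
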