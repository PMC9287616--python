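"""LHS-PRCC global sensitivity harnesses for the two shipped analyses.

Both sample parameters by Latin-hypercube over log-uniform ranges spanning
(by default) a factor of `span` around the shipped value, evaluate the
model output per sample, and report partial rank correlation coefficients
with two-sided p-values.
"""

from __future__ import annotations

import numpy as np

from .model import default_parameters
from .panel import _synapse_system, equilibrium_h_mac
from .params import ParameterSet
from .framework import simulate
from .stats import SensitivityResult, latin_hypercube, prcc

#: parameters probed in the phagocytosis-submodule analysis
PHAGOCYTOSIS_PARAMS = (
    "PD1_dens_M", "SIRPa_dens_M", "CD47_dens_C", "PDL1_dens_C",
    "CD80_dens_C", "PD1_50_M", "SIRPa_50", "koff_PD1_PDL1",
    "koff_CD47_SIRPa",
)

#: parameters probed in the macrophage-module / tumor-volume analysis
MACROPHAGE_PARAMS = (
    "k_Mac_mig", "k_M1_pol", "k_M2_pol", "k_Mac_death", "k_M1_phago",
    "K_Mac_C", "k_IL10_sec_M2", "k_IL12_sec_M1", "k_TGFb_sec_M2",
    "IL10_50_phago",
)


def _lhs_values(
    params: ParameterSet, names: tuple[str, ...], n: int,
    rng: np.random.Generator, span: float,
) -> np.ndarray:
    u = latin_hypercube(n, len(names), rng)
    lo = np.array([params[p] / span for p in names])
    hi = np.array([params[p] * span for p in names])
    return lo * (hi / lo) ** u  # log-uniform within [default/span, default*span]


def sensitivity_phagocytosis(
    n: int = 1000, seed: int = 0, span: float = 3.0,
    params: ParameterSet | None = None,
) -> SensitivityResult:
    """PRCC of the combined phagocytosis inhibition H_Mac_C against the
    checkpoint densities and Hill constants of the submodule."""
    base = params or default_parameters()
    rng = np.random.default_rng(seed)
    x = _lhs_values(base, PHAGOCYTOSIS_PARAMS, n, rng, span)
    system = _synapse_system(base)
    out = np.empty(n)
    density_names = {"PD1_dens_M", "SIRPa_dens_M", "CD47_dens_C",
                     "PDL1_dens_C", "CD80_dens_C"}
    for i in range(n):
        sample = dict(zip(PHAGOCYTOSIS_PARAMS, x[i]))
        densities = {k: v for k, v in sample.items() if k in density_names}
        others = {k: v for k, v in sample.items() if k not in density_names}
        sys_i = system.with_updates(param_updates=others)
        out[i] = equilibrium_h_mac(sys_i, densities)
    return prcc(x, out, names=list(PHAGOCYTOSIS_PARAMS), output_name="H_Mac_C")


def sensitivity_tumor_volume(
    n: int = 200, seed: int = 0, span: float = 3.0, t_final: float = 400.0,
    params: ParameterSet | None = None,
) -> SensitivityResult:
    """PRCC of untreated tumor volume at ``t_final`` days against
    macrophage-module parameters (recruitment, polarization, phagocytosis,
    cytokine output)."""
    from .model import assemble_model

    base = params or default_parameters()
    rng = np.random.default_rng(seed)
    x = _lhs_values(base, MACROPHAGE_PARAMS, n, rng, span)
    reference = assemble_model(base)
    out = np.empty(n)
    for i in range(n):
        sys_i = reference.with_updates(
            param_updates=dict(zip(MACROPHAGE_PARAMS, x[i]))
        )
        traj = simulate(sys_i, (0.0, t_final), record_grid=t_final)
        out[i] = traj.final("V_T")
    return prcc(x, out, names=list(MACROPHAGE_PARAMS),
                output_name="tumor_volume_day400")
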