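"""Phagocytosis checkpoint panel: sampled inhibitory effect of CD47/PD-1.

Randomly samples the densities of the checkpoint molecules engaged in the
macrophage-cancer synapse (PD-1 on TAMs, PD-L1/CD80/CD47 on cancer cells,
SIRPalpha on TAMs), brings each sampled synapse to binding equilibrium
with the same mass-action kinetics the full model uses, and reports the
phagocytosis activity factor 1 - H_Mac_C under blockade/knockout
conditions.  Negative checkpoint status is simulated by setting the
corresponding density to zero; antibody blockade by a saturating free
antibody concentration.  Fold-changes are means relative to the untreated
control on paired density draws; significance uses the rank-based
two-sample (Wilcoxon) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .framework import ModelSpec, ODESystem, simulate
from .model import default_parameters
from .modules.checkpoint import _hill2, add_cd47_block, add_pd1_network
from .params import ParameterDistribution, ParameterSet

CONDITIONS = ("control", "anti_CD47", "anti_PDL1", "PD1_negative", "CD47_negative")

#: density parameters sampled by the panel and their synapse state names
_SAMPLED = {
    "PD1_dens_M": "syn_PD1",
    "PDL1_dens_C": "syn_PDL1",
    "CD80_dens_C": "syn_CD80m",
    "CD47_dens_C": "syn_CD47",
    "SIRPa_dens_M": "syn_SIRPa",
}
_BLOCKING_CONC = 6.7e-7  # M, saturating antibody (~100 ug/mL IgG)


@dataclass
class PanelResult:
    samples: pd.DataFrame  # condition, sample, one_minus_h
    summary: pd.DataFrame  # condition, fold_change, p_value

    def fold(self, condition: str) -> float:
        row = self.summary.loc[self.summary.condition == condition]
        return float(row.fold_change.iloc[0])


def _synapse_system(params: ParameterSet) -> ODESystem:
    """A macrophage-cancer synapse in isolation (no cytokine drive)."""
    p = params.copy()
    p.set("aPDL1_panel", 0.0, units="M")
    p.set("aCD47_panel", 0.0, units="M")
    spec = ModelSpec(p)
    spec.add_compartment("syn", p["A_syn_contact"] * p["f_syn_diffusion"], "um^2")
    add_pd1_network(spec, "syn", "PD1_dens_M", "PDL1_dens_C", "aPDL1_panel",
                    with_ifng=False, with_cis_cd80="CD80_dens_C")
    add_cd47_block(spec, "syn", "aCD47_panel")
    spec.add_rule("H_PD1_M", _hill2("syn_PD1_PDL1 + syn_PD1_PDL2", "PD1_50_M"))
    h_sirpa = _hill2("syn_CD47_SIRPa", "SIRPa_50")
    spec.add_rule("H_Mac_C", f"1.0 - (1.0-{h_sirpa})*(1.0-H_PD1_M)")
    return spec.assemble()


def equilibrium_h_mac(
    system: ODESystem,
    densities: dict[str, float],
    apdl1: float = 0.0,
    acd47: float = 0.0,
) -> float:
    """H_Mac_C at binding equilibrium for one sampled density set."""
    sys2 = system.with_updates(
        param_updates={"aPDL1_panel": apdl1, "aCD47_panel": acd47,
                       **{k: v for k, v in densities.items()}},
        state_updates={_SAMPLED[k]: v for k, v in densities.items()},
    )
    # PD-L2 baseline tracks the sampled PD-L1
    sys2 = sys2.with_updates(
        state_updates={
            "syn_PDL2": densities.get("PDL1_dens_C", 0.0)
            * system.spec.params["r_PDL2"]
        }
    )
    traj = simulate(sys2, (0.0, 1.0), record_grid=1.0)
    return traj.final("H_Mac_C")


def phagocytosis_panel(
    n_samples: int,
    seed: int,
    distributions: dict[str, ParameterDistribution] | None = None,
    params: ParameterSet | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> PanelResult:
    """Sampled 1 - H_Mac_C under checkpoint blockade/knockout conditions."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    unknown = set(conditions) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions: {sorted(unknown)}")
    params = params or default_parameters()
    if distributions is None:
        from .trial import default_distributions

        dists = default_distributions()
        distributions = {k: dists[k] for k in _SAMPLED if k in dists}
    system = _synapse_system(params)

    rng = np.random.default_rng(seed)
    draws = {
        name: (
            distributions[name].ppf(rng.random(n_samples))
            if name in distributions
            else np.full(n_samples, params[name])
        )
        for name in _SAMPLED
    }

    rows = []
    for i in range(n_samples):
        base = {k: float(v[i]) for k, v in draws.items()}
        for cond in conditions:
            dens = dict(base)
            apdl1 = acd47 = 0.0
            if cond == "anti_CD47":
                acd47 = _BLOCKING_CONC
            elif cond == "anti_PDL1":
                apdl1 = _BLOCKING_CONC
            elif cond == "PD1_negative":
                dens["PD1_dens_M"] = 0.0
            elif cond == "CD47_negative":
                dens["CD47_dens_C"] = 0.0
            h = equilibrium_h_mac(system, dens, apdl1, acd47)
            rows.append(
                {"condition": cond, "sample": i, "one_minus_h": 1.0 - h}
            )
    samples = pd.DataFrame(rows)

    control = samples.loc[samples.condition == "control", "one_minus_h"]
    summary_rows = []
    for cond in conditions:
        vals = samples.loc[samples.condition == cond, "one_minus_h"]
        fold = float(vals.mean() / control.mean())
        p = (
            float(sps.ranksums(vals, control).pvalue)
            if cond != "control"
            else float("nan")
        )
        summary_rows.append(
            {"condition": cond, "fold_change": fold, "p_value": p,
             "mean_one_minus_h": float(vals.mean())}
        )
    return PanelResult(samples=samples, summary=pd.DataFrame(summary_rows))
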