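"""Dosing regimens, permeability estimates, and chemo PD helpers.

The antibody transport parameters derive from the Stokes-Einstein radius
of the molecule (empirical power law a_e = 0.483 * MW^0.386) and the
permeability-surface-area product per capillary area; both helpers are
exposed because the shipped transport rates were derived with them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .framework import Dose
from .params import ParameterSet
from .units import mg_to_mol

#: regimen drug name -> (central species, molecular-weight param)
DRUG_SPECIES = {
    "atezolizumab": ("Atezo_C", "MW_atezo"),
    "anti-CD47": ("aCD47Ab_C", "MW_atezo"),
    "anti-CTLA4": ("aCTLA4Ab_C", "MW_atezo"),
    "nab-paclitaxel": ("NabP_C", "MW_nabp"),
}


def stokes_radius(mw: float) -> float:
    """Stokes-Einstein radius (angstrom) of a protein of MW daltons."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return 0.483 * mw**0.386


def permeability_from_ps(ps_product: float, specific_area: float) -> float:
    """Capillary permeability (cm/s) from a permeability-surface-area
    product (mL/(s*100 g)) and a capillary surface area per tissue mass
    (cm^2/g); reported at one significant figure, matching its use as a
    starting value for PK fitting."""
    if ps_product <= 0 or specific_area <= 0:
        raise ValueError("inputs must be positive")
    perm = ps_product / 100.0 / specific_area
    return float(f"{perm:.0e}")


@dataclass(frozen=True)
class DoseRegimen:
    """Drug, amount, infusion and schedule description.

    ``amount`` is mg (unit="mg") or mg per m^2 body surface area
    (unit="mg/m2").  The schedule is either a regular (start, interval,
    count) sequence or per-cycle day offsets repeated every
    ``cycle_days`` for ``n_cycles`` (e.g. days 0/7/14 per 28-day cycle).
    """

    drug: str
    amount: float
    unit: str = "mg"
    infusion_h: float = 1.0
    start_day: float = 0.0
    interval_days: float | None = None
    n_doses: int | None = None
    cycle_offsets: tuple[float, ...] = field(default=())
    cycle_days: float | None = None
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.drug not in DRUG_SPECIES:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.unit not in ("mg", "mg/m2"):
            raise ValueError(f"unsupported dose unit {self.unit!r}")

    def schedule(self, horizon: float) -> list[float]:
        """Strictly increasing administration times (days) within horizon."""
        times: list[float] = []
        if self.cycle_offsets:
            n_cycles = self.n_cycles or math.ceil(horizon / (self.cycle_days or 1))
            for c in range(n_cycles):
                for off in self.cycle_offsets:
                    times.append(self.start_day + c * float(self.cycle_days) + off)
        else:
            interval = self.interval_days or horizon + 1
            n = self.n_doses or (int(horizon // interval) + 1)
            times = [self.start_day + k * interval for k in range(n)]
        times = sorted(t for t in times if t <= horizon)
        if any(b - a <= 0 for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        return times

    def to_doses(self, params: ParameterSet, horizon: float) -> list[Dose]:
        species, mw_param = DRUG_SPECIES[self.drug]
        mg = self.amount
        if self.unit == "mg/m2":
            mg *= params["BSA"]
        mol = mg_to_mol(mg, params[mw_param])
        v_central = params["V_C"] if species != "NabP_C" else params["V1_nabp"]
        delta = mol / (v_central * 1.0e-3)  # molar increment in central volume
        return [
            Dose(species=species, start=t, amount=delta,
                 duration=self.infusion_h / 24.0)
            for t in self.schedule(horizon)
        ]


# -------------------------------------------------------- standard regimens
def atezolizumab_q3w() -> DoseRegimen:
    """1200 mg atezolizumab every 3 weeks (monotherapy arm)."""
    return DoseRegimen("atezolizumab", 1200.0, "mg", infusion_h=1.0,
                       interval_days=21.0)


def atezolizumab_q2w() -> DoseRegimen:
    """800 mg atezolizumab every 2 weeks (combination arm)."""
    return DoseRegimen("atezolizumab", 800.0, "mg", infusion_h=1.0,
                       interval_days=14.0)


def nab_paclitaxel_q3_4w() -> DoseRegimen:
    """100 mg/m^2 nab-paclitaxel on days 1, 8, 15 of a 28-day cycle."""
    return DoseRegimen("nab-paclitaxel", 100.0, "mg/m2", infusion_h=0.5,
                       cycle_offsets=(0.0, 7.0, 14.0), cycle_days=28.0)


REGIMENS = {
    "atezolizumab-mono": (atezolizumab_q3w,),
    "nab-paclitaxel-mono": (nab_paclitaxel_q3_4w,),
    "combination": (atezolizumab_q2w, nab_paclitaxel_q3_4w),
    "none": (),
}


def regimen_doses(name: str, params: ParameterSet, horizon: float) -> list[Dose]:
    """All doses of a named trial arm within the horizon."""
    if name not in REGIMENS:
        raise ValueError(f"unknown regimen {name!r}; options: {sorted(REGIMENS)}")
    doses: list[Dose] = []
    for factory in REGIMENS[name]:
        doses.extend(factory().to_doses(params, horizon))
    return doses


def nabp_hill(concentration: float, ec50: float) -> float:
    """Fractional nab-paclitaxel effect at a tumor concentration (molar)."""
    if ec50 <= 0:
        raise ValueError("EC50 must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return concentration / (concentration + ec50)
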