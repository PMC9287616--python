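"""Minimal unit normalization for model input tables.

Canonical internal units: time in days, volumes in mL, lengths in cm
(synapse geometry in um/um^2), cell populations as counts, drug and NO
concentrations in molar (M), cytokines in pg/mL, arginase-I in mU/mL,
surface densities in molecule/um^2.  Parameter files may use the common
laboratory units below; :func:`to_canonical` rescales them at load time.
"""

from __future__ import annotations

#: molecules per mole
N_AVOGADRO = 6.02214076e23
#: molecules per um^3 at 1 M (1 L = 1e15 um^3)
MOLAR_TO_PER_UM3 = N_AVOGADRO / 1.0e15
#: days per month used when reporting trial durations (calendar convention
#: of the response-duration tables this model is compared against)
DAYS_PER_MONTH = 30.0

# unit string -> (canonical unit, multiplicative factor)
_CONVERSIONS: dict[str, tuple[str, float]] = {
    # time
    "day": ("day", 1.0),
    "hour": ("day", 1.0 / 24.0),
    "minute": ("day", 1.0 / 1440.0),
    "second": ("day", 1.0 / 86400.0),
    "1/day": ("1/day", 1.0),
    "1/hour": ("1/day", 24.0),
    "1/minute": ("1/day", 1440.0),
    "1/second": ("1/day", 86400.0),
    # volume
    "mL": ("mL", 1.0),
    "L": ("mL", 1.0e3),
    "uL": ("mL", 1.0e-3),
    # length
    "cm": ("cm", 1.0),
    "mm": ("cm", 0.1),
    "um": ("um", 1.0),
    # concentration (molar)
    "M": ("M", 1.0),
    "mM": ("M", 1.0e-3),
    "uM": ("M", 1.0e-6),
    "nM": ("M", 1.0e-9),
    "pM": ("M", 1.0e-12),
    # association rates
    "1/(M*day)": ("1/(M*day)", 1.0),
    "1/(M*second)": ("1/(M*day)", 86400.0),
    "1/(uM*second)": ("1/(M*day)", 86400.0 * 1.0e6),
    "1/(nM*day)": ("1/(M*day)", 1.0e9),
    # cytokines
    "pg/mL": ("pg/mL", 1.0),
    "ng/mL": ("pg/mL", 1.0e3),
    # densities
    "molecule/um^2": ("molecule/um^2", 1.0),
    "cell/mL": ("cell/mL", 1.0),
    "cell/uL": ("cell/mL", 1.0e3),
}


def to_canonical(value: float, unit: str) -> tuple[float, str]:
    """Convert ``value`` with unit string ``unit`` to canonical units.

    Unknown unit strings are passed through unchanged: compound model-specific
    units (e.g. secretion rates already expressed per day) are stored
    canonically in the shipped tables.
    """
    if unit in _CONVERSIONS:
        canon, factor = _CONVERSIONS[unit]
        return value * factor, canon
    return value, unit


def mg_to_mol(mg: float, mw_daltons: float) -> float:
    """Convert a dose in mg to moles given a molecular weight in g/mol."""
    if mw_daltons <= 0:
        raise ValueError("molecular weight must be positive")
    return mg * 1.0e-3 / mw_daltons
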