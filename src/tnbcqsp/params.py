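"""Named parameter sets with units and provenance.

A :class:`ParameterSet` is the single source of every rate constant,
density, Hill constant, volume, and geometry factor in the model.  Values
are stored in the package's canonical units (see :mod:`tnbcqsp.units`);
delimited files in other supported units are rescaled at load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .units import to_canonical


class MissingParameterError(KeyError):
    """A model component referenced a parameter that is not in the set."""


@dataclass(frozen=True)
class Param:
    name: str
    value: float
    units: str = ""
    provenance: str = ""  # reported | literature | calibrated | assumed
    description: str = ""


@dataclass
class ParameterSet:
    """Mapping from parameter name to :class:`Param`.

    ``ps[name]`` returns the float value; ``ps.get_param(name)`` the full
    record.  Invariants enforced on construction/update: rate constants
    (``k_*``/``q_*`` prefixes) are non-negative, Hill exponents (``n_*``)
    at least 1, and volume fractions (``gamma_*``, ``f_vol_*``) in (0, 1].
    """

    params: dict[str, Param] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        try:
            return self.params[name].value
        except KeyError:
            raise MissingParameterError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def __len__(self) -> int:
        return len(self.params)

    def __iter__(self) -> Iterator[str]:
        return iter(self.params)

    def get_param(self, name: str) -> Param:
        try:
            return self.params[name]
        except KeyError:
            raise MissingParameterError(name) from None

    def set(
        self,
        name: str,
        value: float,
        units: str = "",
        provenance: str = "",
        description: str = "",
    ) -> None:
        self._validate(name, value)
        old = self.params.get(name)
        if old is not None:
            units = units or old.units
            provenance = provenance or old.provenance
            description = description or old.description
        self.params[name] = Param(name, float(value), units, provenance, description)

    def update(self, values: Mapping[str, float]) -> "ParameterSet":
        for name, value in values.items():
            self.set(name, value)
        return self

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.params))

    def require(self, names: Iterable[str]) -> None:
        missing = sorted(n for n in names if n not in self.params)
        if missing:
            raise MissingParameterError(
                "missing model parameters: " + ", ".join(missing)
            )

    @staticmethod
    def _validate(name: str, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
        if name.startswith(("k_", "q_", "Q_", "rho_", "K_")) and value < 0:
            raise ValueError(f"rate/threshold parameter {name!r} must be >= 0")
        if name.startswith("n_hill") and value < 1:
            raise ValueError(f"Hill exponent {name!r} must be >= 1")
        if name.startswith(("gamma_", "f_vol_")) and not (0 < value <= 1):
            raise ValueError(f"volume fraction {name!r} must be in (0, 1]")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParameterSet":
        ps = cls()
        for row in frame.itertuples(index=False):
            value, units = to_canonical(float(row.value), str(row.units))
            ps.set(
                str(row.name),
                value,
                units=units,
                provenance=str(getattr(row, "provenance", "") or ""),
                description=str(getattr(row, "description", "") or ""),
            )
        return ps

    @classmethod
    def from_csv(cls, path) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "value": p.value,
                    "units": p.units,
                    "provenance": p.provenance,
                    "description": p.description,
                }
                for p in self.params.values()
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling specification for one virtual-patient parameter.

    ``kind`` is one of ``lognormal`` (median + geometric sd), ``normal``
    (median = mean + sd), ``uniform`` (lower/upper), or ``fixed``.  Sampled
    values are truncated to [lower, upper] when bounds are given.
    """

    name: str
    kind: str
    median: float
    lower: float = float("-inf")
    upper: float = float("inf")
    sd: float = 0.0  # sd of log-value for lognormal, of value for normal

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "normal", "uniform", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not self.lower <= self.upper:
            raise ValueError(f"bounds of {self.name!r} are out of order")
        if self.kind == "lognormal" and self.median <= 0:
            raise ValueError(f"lognormal {self.name!r} needs a positive median")

    def ppf(self, q) -> float:
        """Quantile function (vectorized over ``q``), truncated to bounds."""
        import numpy as np
        from scipy import stats

        q = np.asarray(q, dtype=float)
        if self.kind == "fixed":
            out = np.full_like(q, self.median)
        elif self.kind == "uniform":
            lo = self.lower if math.isfinite(self.lower) else self.median
            hi = self.upper if math.isfinite(self.upper) else self.median
            out = lo + q * (hi - lo)
        elif self.kind == "normal":
            out = stats.norm.ppf(q, loc=self.median, scale=max(self.sd, 0.0))
        else:  # lognormal
            out = self.median * np.exp(
                stats.norm.ppf(q) * max(self.sd, 0.0)
            )
        return np.clip(out, self.lower, self.upper)


def distributions_from_csv(path) -> dict[str, ParameterDistribution]:
    frame = pd.read_csv(path, comment="#")
    out: dict[str, ParameterDistribution] = {}
    for row in frame.itertuples(index=False):
        out[str(row.name)] = ParameterDistribution(
            name=str(row.name),
            kind=str(row.distribution_type),
            median=float(row.median),
            lower=float(row.lower) if not pd.isna(row.lower) else float("-inf"),
            upper=float(row.upper) if not pd.isna(row.upper) else float("inf"),
            sd=float(row.sd) if not pd.isna(row.sd) else 0.0,
        )
    return out
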