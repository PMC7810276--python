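"""Crystalloid NaCl infusate definitions and unit conversions.

An infusate is characterised by its NaCl mass-percent (g per 100 mL), from
which the sodium concentration (mmol/L) and the tonicity (effective osmolar
concentration, mmol/L) follow.  Full dissociation of NaCl into two osmotically
active particles is assumed, so tonicity is exactly twice the sodium
concentration; potassium-containing fluids are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from natremia.errors import InvalidInputError

#: molar mass of NaCl, g/mol
NACL_MOLAR_MASS = 58.44


@dataclass(frozen=True)
class InfusateSpec:
    """A crystalloid NaCl fluid.

    Attributes
    ----------
    label : str
        Human-readable name, e.g. ``"0.9%-NaCl"``.
    nacl_percent : float
        NaCl mass fraction in g per 100 mL.
    na_conc : float
        Sodium concentration in mmol/L.
    tonicity : float
        Effective osmolar concentration in mmol/L (2 x ``na_conc``).
    """

    label: str
    nacl_percent: float
    na_conc: float
    tonicity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.nacl_percent) and self.nacl_percent > 0):
            raise InvalidInputError(
                f"nacl_percent must be positive and finite, got {self.nacl_percent!r}"
            )
        if self.tonicity != 2 * self.na_conc:
            raise InvalidInputError(
                f"tonicity ({self.tonicity}) must equal 2 x na_conc ({self.na_conc})"
            )
        expected = self.nacl_percent * 10 * 1000 / NACL_MOLAR_MASS
        if abs(self.na_conc - expected) > 1.0:
            raise InvalidInputError(
                f"na_conc {self.na_conc} inconsistent with {self.nacl_percent}% NaCl "
                f"(expected about {expected:.1f} mmol/L)"
            )


def infusate_from_percent(nacl_percent: float, label: str | None = None) -> InfusateSpec:
    """Build an :class:`InfusateSpec` from an NaCl mass-percent.

    The sodium concentration is ``percent x 10 x 1000 / 58.44`` rounded to the
    nearest integer mmol/L, and the tonicity is twice that.  0.9% gives
    154 / 308 mmol/L; 2.5% gives 428 / 856 mmol/L.

    Raises
    ------
    InvalidInputError
        If ``nacl_percent`` is not a positive finite number.
    """
    try:
        nacl_percent = float(nacl_percent)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"nacl_percent is not numeric: {nacl_percent!r}") from exc
    if not (math.isfinite(nacl_percent) and nacl_percent > 0):
        raise InvalidInputError(
            f"nacl_percent must be positive and finite, got {nacl_percent!r}"
        )
    na_conc = round(nacl_percent * 10 * 1000 / NACL_MOLAR_MASS)
    return InfusateSpec(
        label=label or f"{nacl_percent:g}%-NaCl",
        nacl_percent=nacl_percent,
        na_conc=float(na_conc),
        tonicity=float(2 * na_conc),
    )


#: built-in fluids used by the bundled validation cohort
REGISTRY: dict[str, InfusateSpec] = {
    "0.9%-NaCl": infusate_from_percent(0.9),
    "2.5%-NaCl": infusate_from_percent(2.5),
}


def get_infusate(key: str | float) -> InfusateSpec:
    """Resolve a registry label or a mass-percent to an :class:`InfusateSpec`."""
    if isinstance(key, str) and key in REGISTRY:
        return REGISTRY[key]
    return infusate_from_percent(key)  # type: ignore[arg-type]


def load_infusate_config(path: str | Path) -> dict[str, InfusateSpec]:
    """Load extra infusate definitions from a YAML mapping of label -> percent.

    Example file::

        3%-NaCl: 3.0
        half-normal: 0.45
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise InvalidInputError(f"infusate config {path} must be a mapping of label -> percent")
    return {
        str(label): infusate_from_percent(percent, label=str(label))
        for label, percent in raw.items()
    }
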