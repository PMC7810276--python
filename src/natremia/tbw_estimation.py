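"""Total-body-water estimation from sex and weight.

Uses the standard adult fractions (0.6 x weight for men, 0.5 x weight for
women) with an explicit override.  A directly measured or chart-supplied TBW
always takes precedence over this estimate; the bundled validation cohort
carries TBW verbatim and never goes through the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from natremia.errors import InvalidInputError

Sex = Literal["male", "female"]

TBW_FRACTION: dict[str, float] = {"male": 0.6, "female": 0.5}


@dataclass(frozen=True)
class Anthropometrics:
    sex: str
    age: float
    weight: float

    def __post_init__(self) -> None:
        if self.sex not in TBW_FRACTION:
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise InvalidInputError(f"weight must be positive, got {self.weight!r}")
        if not (math.isfinite(self.age) and self.age >= 0):
            raise InvalidInputError(f"age must be non-negative, got {self.age!r}")


def estimate_tbw(anthro: Anthropometrics, fraction_override: float | None = None) -> float:
    """Estimate total body water in litres, rounded to whole litres.

    ``fraction_override``, if given, replaces the sex-based default and must
    lie strictly in (0, 1).
    """
    if fraction_override is not None:
        if not (0 < fraction_override < 1):
            raise InvalidInputError(
                f"fraction_override must be in (0, 1), got {fraction_override!r}"
            )
        fraction = fraction_override
    else:
        fraction = TBW_FRACTION[anthro.sex]
    return float(round(fraction * anthro.weight))
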