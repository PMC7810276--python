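"""Closed-form predictors of the plasma sodium change after a saline bolus.

Two models are implemented:

* ``voets_delta_na`` — an electrolyte-free-water-balance model that accounts
  for both the infusate and the (osmolality-fixed) urine output::

      delta = [Na+]p * Vi / TBW * (factor * Oi / Ou - 1)

  where ``Oi`` is the infusate tonicity, ``Ou`` the urine osmolality and
  ``factor`` (default 1.7) converts urine osmolality to an effective urine
  tonicity.  The prediction changes sign at ``Ou = factor * Oi``.

* ``adrogue_madias_delta_na`` — the volume-generalised redistribution model::

      delta = Vi * ([Na+]i - [Na+]p) / (TBW + Vi)

  which ignores urine output entirely.  ``adrogue_madias_original`` is the
  classic per-litre special case ``([Na+]i - [Na+]p) / (TBW + 1)``.

Both models describe a single bolus processed to steady state; there is no
time dimension.  Repeated boluses are modelled by repeated calls with an
updated patient state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

from natremia.errors import InvalidInputError
from natremia.infusates import InfusateSpec

ModelName = Literal["voets", "adrogue_madias"]

#: default osmolality-to-tonicity conversion factor for urine
DEFAULT_TONICITY_FACTOR = 1.7

MODEL_NAMES: tuple[str, ...] = ("voets", "adrogue_madias")


@dataclass(frozen=True)
class PatientState:
    """Physiological inputs of the predictors.

    Attributes
    ----------
    tbw : float
        Total body water in litres.
    na_plasma : float
        Pre-infusion plasma sodium in mmol/L.
    urine_osm : float
        Urine osmolality in mOsmol/L.
    """

    tbw: float
    na_plasma: float
    urine_osm: float

    def __post_init__(self) -> None:
        for name in ("tbw", "na_plasma", "urine_osm"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidInputError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class InfusionEvent:
    """One administered bolus: volume in litres plus the fluid given."""

    volume: float
    infusate: InfusateSpec

    def __post_init__(self) -> None:
        if not (isinstance(self.volume, (int, float)) and math.isfinite(self.volume) and self.volume > 0):
            raise InvalidInputError(f"volume must be positive and finite, got {self.volume!r}")


@dataclass(frozen=True)
class PredictionResult:
    """Per-model predicted sodium change and resulting final sodium."""

    model: str
    delta_na: float
    na_final: float


def voets_delta_na(
    state: PatientState,
    infusion: InfusionEvent,
    tonicity_factor: float = DEFAULT_TONICITY_FACTOR,
) -> float:
    """Predicted plasma sodium change (mmol/L), free-water-balance model.

    Returns ``[Na+]p * Vi / TBW * (factor * Oi / Ou - 1)``, unrounded.  The
    result is positive iff the urine osmolality is below ``factor * Oi``
    (see :func:`critical_urine_osmolality`): more dilute urine means the
    kidneys excrete net free water and saline raises the plasma sodium.
    """
    if tonicity_factor <= 0 or not math.isfinite(tonicity_factor):
        raise InvalidInputError(f"tonicity_factor must be positive, got {tonicity_factor!r}")
    oi = infusion.infusate.tonicity
    return (
        state.na_plasma
        * infusion.volume
        / state.tbw
        * (tonicity_factor * oi / state.urine_osm - 1.0)
    )


def adrogue_madias_delta_na(state: PatientState, infusion: InfusionEvent) -> float:
    """Predicted plasma sodium change (mmol/L), redistribution model.

    Returns ``Vi * ([Na+]i - [Na+]p) / (TBW + Vi)``, unrounded.  Equivalent to
    mixing ``Vi`` litres of infusate into the body-water compartment:
    ``(TBW*[Na+]p + Vi*[Na+]i) / (TBW + Vi) - [Na+]p``.  Urine output is
    ignored, so the sign equals the sign of ``[Na+]i - [Na+]p``.
    """
    return (
        infusion.volume
        * (infusion.infusate.na_conc - state.na_plasma)
        / (state.tbw + infusion.volume)
    )


def adrogue_madias_original(state: PatientState, infusate: InfusateSpec) -> float:
    """Classic fixed-volume form: sodium change per 1 L of infusate.

    Exactly equals :func:`adrogue_madias_delta_na` with ``Vi = 1``.
    """
    return (infusate.na_conc - state.na_plasma) / (state.tbw + 1.0)


def critical_urine_osmolality(
    infusate: InfusateSpec,
    tonicity_factor: float = DEFAULT_TONICITY_FACTOR,
) -> float:
    """Urine osmolality (mOsmol/L) at which the free-water-balance prediction
    changes sign for the given infusate.

    Above this threshold the infusate *lowers* the plasma sodium.  For normal
    saline (tonicity 308 mmol/L) the threshold is 1.7 x 308 = 523.6 mOsmol/L.
    """
    if tonicity_factor <= 0 or not math.isfinite(tonicity_factor):
        raise InvalidInputError(f"tonicity_factor must be positive, got {tonicity_factor!r}")
    return tonicity_factor * infusate.tonicity


def round_display(delta: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for printed predictions.

    Python's built-in ``round`` is banker's rounding; printed clinical values
    round 0.25 -> 0.3 and -0.25 -> -0.3 instead.
    """
    scale = 10**ndigits
    return math.copysign(math.floor(abs(delta) * scale + 0.5) / scale, delta)


def predict(
    state: PatientState,
    infusion: InfusionEvent,
    model: str,
    tonicity_factor: float = DEFAULT_TONICITY_FACTOR,
) -> PredictionResult:
    """Dispatch to a model and package the unrounded delta and final sodium.

    Parameters
    ----------
    model : {"voets", "adrogue_madias"}
        Which predictor to apply.

    Notes
    -----
    A negative predicted final sodium is physically meaningless but can arise
    from extreme inputs; it is returned with a warning rather than clamped,
    since silently altering the output would hide model misuse.
    """
    if model == "voets":
        delta = voets_delta_na(state, infusion, tonicity_factor=tonicity_factor)
    elif model == "adrogue_madias":
        delta = adrogue_madias_delta_na(state, infusion)
    else:
        raise InvalidInputError(
            f"unknown model {model!r}; expected one of {MODEL_NAMES}"
        )
    na_final = state.na_plasma + delta
    if na_final <= 0:
        warnings.warn(
            f"predicted final sodium {na_final:.1f} mmol/L is non-physical; "
            "the first-order model is outside its domain of validity",
            RuntimeWarning,
            stacklevel=2,
        )
    return PredictionResult(model=model, delta_na=delta, na_final=na_final)
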