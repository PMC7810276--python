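"""Cohort validation statistics and correlation-based sample-size calculation.

For each cohort record the selected model's *unrounded* prediction is paired
with the measured sodium change; the report carries the Pearson correlation,
its two-sided p-value (t distribution, n-2 df), per-pair residuals and
residual summaries.  Display rounding is never applied before the statistics
are computed — rounding first visibly shifts r in the second decimal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from natremia.cohort import Cohort
from natremia.errors import InvalidInputError, UndefinedStatisticError
from natremia.infusates import infusate_from_percent
from natremia.sodium_models import (
    DEFAULT_TONICITY_FACTOR,
    InfusionEvent,
    PatientState,
    predict,
)


@dataclass
class ValidationReport:
    """Paired measured/predicted sodium changes and their agreement stats."""

    model: str
    pairs: list[tuple[float, float]]  # (measured, predicted) mmol/L
    pearson_r: float
    p_value: float
    n: int
    residuals: list[float] = field(default_factory=list)  # predicted - measured

    @property
    def mean_absolute_error(self) -> float:
        return float(np.mean(np.abs(self.residuals)))

    @property
    def bias(self) -> float:
        """Mean signed residual; positive means systematic over-prediction."""
        return float(np.mean(self.residuals))

    def scatter_data(self) -> list[dict[str, float]]:
        """Per-pair rows for external plotting (measured vs predicted)."""
        return [
            {"measured": m, "predicted": p, "model": self.model}  # type: ignore[dict-item]
            for m, p in self.pairs
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "n": self.n,
                "pearson_r": self.pearson_r,
                "p_value": self.p_value,
                "mean_absolute_error": self.mean_absolute_error,
                "bias": self.bias,
                "pairs": [{"measured": m, "predicted": p} for m, p in self.pairs],
                "residuals": self.residuals,
            },
            indent=2,
        )


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Raises
    ------
    UndefinedStatisticError
        If either vector is constant.
    InvalidInputError
        On length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError(f"expected equal-length 1-d vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise InvalidInputError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation is undefined for a constant vector")
    return float(_sps.pearsonr(x, y).statistic)


def pearson_p_two_sided(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the exact t test.

    Uses ``t = r * sqrt(n - 2) / sqrt(1 - r**2)`` against a t distribution
    with ``n - 2`` degrees of freedom.  ``|r| == 1`` returns 0 (exact fit).
    """
    if n < 3:
        raise InvalidInputError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise InvalidInputError(f"correlation must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * _sps.t.sf(abs(t), df))


def sample_size_for_correlation(
    r_target: float,
    alpha: float = 0.05,
    power: float = 0.80,
    *,
    return_raw: bool = False,
):
    """Required n to detect a correlation by the Fisher z method.

    Computes ``C = atanh(|r|)`` and ``n_raw = ((z_{1-alpha/2} + z_power) / C)**2
    + 3``, then rounds to the *nearest* integer.  (For r = 0.70, alpha = 0.05,
    power = 0.80 the raw value is 13.43, conventionally reported as
    "approximately 13"; a conservative user wanting a guaranteed-power n
    should take ``ceil`` of the raw value returned with ``return_raw=True``.)
    """
    if not 0 < abs(r_target) < 1:
        raise InvalidInputError(f"r_target must satisfy 0 < |r| < 1, got {r_target!r}")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise InvalidInputError("alpha and power must lie strictly in (0, 1)")
    c = math.atanh(abs(r_target))
    z_alpha = _sps.norm.ppf(1 - alpha / 2)
    z_power = _sps.norm.ppf(power)
    n_raw = ((z_alpha + z_power) / c) ** 2 + 3
    n = int(round(n_raw))
    return (n, n_raw) if return_raw else n


def validate_cohort(
    cohort: Cohort,
    model: str,
    tonicity_factor: float = DEFAULT_TONICITY_FACTOR,
) -> ValidationReport:
    """Predict every record with ``model`` and correlate against measured.

    Predictions are unrounded.  Records that violate model preconditions are
    collected and reported together; any failure aborts the report.
    """
    if len(cohort) == 0:
        raise InvalidInputError("cohort is empty")
    measured: list[float] = []
    predicted: list[float] = []
    errors: list[str] = []
    for record in cohort:
        try:
            state = PatientState(
                tbw=record.tbw_l,
                na_plasma=record.na_initial_mmol_l,
                urine_osm=record.urine_osm_mosm_l,
            )
            infusion = InfusionEvent(
                volume=record.infusate_volume_l,
                infusate=infusate_from_percent(record.infusate_percent_nacl),
            )
            result = predict(state, infusion, model, tonicity_factor=tonicity_factor)
        except InvalidInputError as exc:
            errors.append(f"record {record.record_id}: {exc}")
            continue
        measured.append(record.measured_delta)
        predicted.append(result.delta_na)
    if errors:
        raise InvalidInputError("validation aborted:\n" + "\n".join(errors))
    r = pearson_r(measured, predicted)
    p = pearson_p_two_sided(r, len(measured))
    residuals = [pred - meas for meas, pred in zip(measured, predicted)]
    return ValidationReport(
        model=model,
        pairs=list(zip(measured, predicted)),
        pearson_r=r,
        p_value=p,
        n=len(measured),
        residuals=residuals,
    )
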