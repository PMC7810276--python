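"""Seeded generator of synthetic SIADH measurement cohorts.

Patient states are drawn uniformly from configurable ranges whose defaults
match the spans of the bundled validation cohort.  The "measured" post-
infusion sodium is the chosen ground-truth model's prediction plus Gaussian
measurement noise, optionally rounded to whole mmol/L to mimic laboratory
reporting.  One seed controls all randomness, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from natremia.cohort import Cohort, MeasurementRecord
from natremia.errors import InvalidInputError
from natremia.infusates import infusate_from_percent
from natremia.sodium_models import (
    DEFAULT_TONICITY_FACTOR,
    InfusionEvent,
    MODEL_NAMES,
    PatientState,
    predict,
)
from natremia.tbw_estimation import TBW_FRACTION


@dataclass
class SynthConfig:
    """Configuration of the synthetic-cohort generator.

    Range defaults follow the bundled cohort: volumes 0.10-1.5 L, NaCl
    percents {0.9, 2.5}, urine osmolality 336-890 mOsmol/L.
    """

    n_records: int = 50
    seed: int = 0
    tbw_range: tuple[float, float] = (25.0, 60.0)
    na_range: tuple[float, float] = (106.0, 133.0)
    ou_range: tuple[float, float] = (336.0, 890.0)
    volume_range: tuple[float, float] = (0.10, 1.5)
    percent_choices: tuple[float, ...] = (0.9, 2.5)
    noise_sd: float = 0.0
    round_measured: bool = True

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise InvalidInputError(f"n_records must be >= 0, got {self.n_records}")
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("tbw_range", "na_range", "ou_range", "volume_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise InvalidInputError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if not self.percent_choices or any(p <= 0 for p in self.percent_choices):
            raise InvalidInputError("percent_choices must be non-empty and positive")


def generate_cohort(
    config: SynthConfig,
    ground_truth_model: str = "voets",
    tonicity_factor: float = DEFAULT_TONICITY_FACTOR,
) -> Cohort:
    """Draw a synthetic cohort whose measured responses follow one model.

    Deterministic for a fixed ``config.seed``.  An ``n_records`` of zero
    yields an empty cohort.
    """
    if ground_truth_model not in MODEL_NAMES:
        raise InvalidInputError(
            f"unknown ground_truth_model {ground_truth_model!r}; expected one of {MODEL_NAMES}"
        )
    rng = np.random.default_rng(config.seed)
    records: list[MeasurementRecord] = []
    for i in range(config.n_records):
        # draws are rounded before prediction so stored records are exactly
        # self-consistent with the ground-truth model in the noiseless case
        tbw = round(rng.uniform(*config.tbw_range), 2)
        na0 = round(rng.uniform(*config.na_range), 2)
        ou = round(rng.uniform(*config.ou_range), 1)
        volume = round(rng.uniform(*config.volume_range), 3)
        percent = float(rng.choice(config.percent_choices))
        sex = "male" if rng.random() < 0.5 else "female"
        age = float(rng.integers(50, 90))
        weight = tbw / TBW_FRACTION[sex]

        state = PatientState(tbw=tbw, na_plasma=na0, urine_osm=ou)
        infusion = InfusionEvent(volume=volume, infusate=infusate_from_percent(percent))
        true_delta = predict(
            state, infusion, ground_truth_model, tonicity_factor=tonicity_factor
        ).delta_na
        na_final = na0 + true_delta + rng.normal(0.0, config.noise_sd)
        if config.round_measured:
            na_final = float(round(na_final))
        records.append(
            MeasurementRecord(
                record_id=i + 1,
                sex=sex,
                age_y=age,
                weight_kg=round(weight, 1),
                tbw_l=tbw,
                infusate_volume_l=volume,
                infusate_percent_nacl=percent,
                na_initial_mmol_l=na0,
                na_final_mmol_l=na_final,
                urine_osm_mosm_l=ou,
                causative_condition="synthetic",
            )
        )
    return Cohort(
        records=records,
        provenance=f"synthetic (seed={config.seed}, ground_truth={ground_truth_model})",
    )
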