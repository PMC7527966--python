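"""Quantification arithmetic for precipitation and biocement assays.

Two small calculations: the mass of CaCO3 precipitate recovered on a filter
(gravimetric difference) and the percent gain in biocement compressive
strength over an uninoculated control.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PrecipitateWeights",
    "StrengthRecord",
    "precipitate_weight",
    "strength_gain",
]


def precipitate_weight(w_total: float, w_paper: float) -> float:
    """Precipitate mass (g): filter paper + precipitate minus the empty paper."""
    if w_total < w_paper:
        raise ValueError(
            f"total weight {w_total} g below empty-paper weight {w_paper} g; "
            "measurements are in the wrong order"
        )
    return w_total - w_paper


def strength_gain(treatment_mpa: float, control_mpa: float, ndigits: int | None = 1) -> float:
    """Percent increase in compressive strength over the control.

    Reported to one decimal (banker's rounding) by default; pass
    ``ndigits=None`` for the unrounded value.
    """
    if control_mpa <= 0 or treatment_mpa <= 0:
        raise ValueError("strengths must be positive")
    gain = 100.0 * (treatment_mpa - control_mpa) / control_mpa
    return gain if ndigits is None else round(gain, ndigits)


@dataclass(frozen=True)
class PrecipitateWeights:
    """Gravimetric record: total and empty filter-paper weights in grams."""

    w_total: float
    w_paper: float

    @property
    def w_precipitates(self) -> float:
        return precipitate_weight(self.w_total, self.w_paper)


@dataclass(frozen=True)
class StrengthRecord:
    """Paired compressive strengths (MPa): treated cube versus control."""

    treatment_mpa: float
    control_mpa: float

    @property
    def gain_percent(self) -> float:
        return strength_gain(self.treatment_mpa, self.control_mpa)
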