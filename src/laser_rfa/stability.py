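"""ISQ <-> resonance-frequency mapping and correlation-strength classes.

The dental magnetic-RFA device reports an implant stability quotient (ISQ) on
a 0–100 scale; its published anchor points are roughly 3000 Hz at ISQ 0 and
8000 Hz at ISQ 100. We fix those anchors as exact defaults of an affine map
(configurable; whether the proprietary map is truly affine is not established,
but two anchors define nothing more elaborate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "IsqMap",
    "StrengthClass",
    "isq_to_rf",
    "rf_to_isq",
    "classify_strength",
    "STRENGTH_THRESHOLDS",
]

#: |R| breakpoints separating weak / moderate / strong correlation.
STRENGTH_THRESHOLDS: tuple[float, float] = (0.3, 0.7)


@dataclass(frozen=True)
class IsqMap:
    """Affine ISQ->RF map defined by its two anchor frequencies (Hz)."""

    rf_at_isq0: float = 3000.0
    rf_at_isq100: float = 8000.0

    def __post_init__(self) -> None:
        if not self.rf_at_isq100 > self.rf_at_isq0:
            raise ValueError("rf_at_isq100 must exceed rf_at_isq0")


@dataclass(frozen=True)
class StrengthClass:
    """Correlation-strength label: weak (<0.3), moderate (0.3–0.7), strong (>0.7)."""

    label: str
    thresholds: tuple[float, float] = STRENGTH_THRESHOLDS

    def __post_init__(self) -> None:
        if self.label not in ("weak", "moderate", "strong"):
            raise ValueError(f"unknown strength label {self.label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def isq_to_rf(isq: float, isq_map: IsqMap | None = None) -> float:
    """Resonance frequency (Hz) for a stability quotient in [0, 100].

    Affine interpolation between the two anchors:
    ``rf_at_isq0 + (isq/100) * (rf_at_isq100 - rf_at_isq0)``.
    """
    isq_map = isq_map or IsqMap()
    if not 0 <= isq <= 100:
        raise ValueError(f"ISQ must lie in [0, 100], got {isq}")
    return isq_map.rf_at_isq0 + (isq / 100.0) * (
        isq_map.rf_at_isq100 - isq_map.rf_at_isq0
    )


def rf_to_isq(rf: float, isq_map: IsqMap | None = None) -> float:
    """Stability quotient for a resonance frequency; exact inverse on range.

    Frequencies outside [rf_at_isq0, rf_at_isq100] are clamped to 0 or 100
    with a warning rather than rejected — poorly fixed screws can resonate
    below the ISQ-0 anchor.
    """
    isq_map = isq_map or IsqMap()
    span = isq_map.rf_at_isq100 - isq_map.rf_at_isq0
    isq = 100.0 * (rf - isq_map.rf_at_isq0) / span
    if isq < 0 or isq > 100:
        clamped = min(max(isq, 0.0), 100.0)
        warnings.warn(
            f"RF {rf:g} Hz outside the ISQ map range "
            f"[{isq_map.rf_at_isq0:g}, {isq_map.rf_at_isq100:g}] Hz; "
            f"ISQ clamped to {clamped:g}",
            stacklevel=2,
        )
        return clamped
    return isq


def classify_strength(r: float) -> StrengthClass:
    """Classify a correlation coefficient by |r|.

    |r| < 0.3 is weak, 0.3 <= |r| <= 0.7 moderate (boundaries inclusive,
    following the interval notation "0.3–0.7"), |r| > 0.7 strong.
    """
    if abs(r) > 1:
        raise ValueError(f"correlation coefficient must lie in [-1, 1], got {r}")
    a = abs(r)
    lo, hi = STRENGTH_THRESHOLDS
    if a < lo:
        label = "weak"
    elif a <= hi:
        label = "moderate"
    else:
        label = "strong"
    return StrengthClass(label=label)
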