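"""Ideal-mixing calculators for osmotic and thermal challenges.

Experimental shocks are delivered by adding an aliquot of medium at a
different osmolarity or temperature; assuming volume additivity and ideal
mixing, the resulting osmolarity is the volume-weighted mean, and the
resulting temperature is the heat-capacity-weighted mean

    t = (m1*c1*t1 + m2*c2*t2) / (m1*c1 + m2*c2).

Values are kept at full precision in the API; rounding to the nearest mOsm
is a display-level concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SolutionAliquot", "ThermalAliquot", "mix_osmolarity", "mix_temperature"]


@dataclass(frozen=True)
class SolutionAliquot:
    """A volume (µl) of medium at a given osmolarity (mOsm/l)."""

    volume: float
    osmolarity: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.osmolarity < 0:
            raise ValueError("osmolarity must be nonnegative")


@dataclass(frozen=True)
class ThermalAliquot:
    """A mass (kg) with specific heat (kJ kg⁻¹ °C⁻¹) at temperature (°C)."""

    mass: float
    specific_heat: float
    temperature: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.specific_heat <= 0:
            raise ValueError("specific heat must be positive")


def mix_osmolarity(parts: Sequence[SolutionAliquot]) -> float:
    """Volume-weighted mean osmolarity of >= 2 mixed aliquots (mOsm/l)."""
    if len(parts) < 2:
        raise ValueError("mixing requires at least two parts")
    total_v = sum(p.volume for p in parts)
    return sum(p.volume * p.osmolarity for p in parts) / total_v


def mix_delta(parts: Sequence[SolutionAliquot]) -> float:
    """Osmolarity change relative to the first (pre-shock) part."""
    return mix_osmolarity(parts) - parts[0].osmolarity


def mix_temperature(parts: Sequence[ThermalAliquot]) -> float:
    """Heat-capacity-weighted mean temperature of >= 2 mixed aliquots (°C)."""
    if len(parts) < 2:
        raise ValueError("mixing requires at least two parts")
    denom = sum(p.mass * p.specific_heat for p in parts)
    return sum(p.mass * p.specific_heat * p.temperature for p in parts) / denom
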