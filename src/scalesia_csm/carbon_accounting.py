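"""Archipelago-scale carbon accounting.

Scales a per-hectare carbon projection to the ~723 ha of coffee cultivated in
Galapagos and expresses the stored carbon, converted to CO2 by the molecular
mass ratio 44/12, as a percentage of the archipelago's annual CO2 footprint
(~523,000 Mg/year, dominated by tourism) accumulated over the projection
horizon.  Reductions are reported as negative percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OffsetInputs", "total_storage", "footprint_reduction"]

#: Molecular mass ratio of CO2 to elemental carbon.
CO2_PER_C = 44.0 / 12.0


@dataclass(frozen=True)
class OffsetInputs:
    """Inputs of the footprint-offset calculation.

    ``per_ha_carbon`` is the carbon accumulated per hectare over the horizon
    (Mg C/ha), typically the projection's horizon-end mean.
    """

    per_ha_carbon: float
    area: float = 723.0
    annual_footprint: float = 523_000.0
    horizon: float = 10.0
    co2_per_c: float = CO2_PER_C

    def __post_init__(self) -> None:
        for name in ("per_ha_carbon", "area", "annual_footprint", "horizon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.co2_per_c < 1.0:
            raise ValueError("co2_per_c must be >= 1 (CO2 is heavier than C)")


def total_storage(per_ha_carbon: float, area: float) -> float:
    """Total carbon stored over the horizon (Mg C) across the planted area."""
    if per_ha_carbon < 0 or area < 0:
        raise ValueError("inputs must be >= 0")
    return float(per_ha_carbon * area)


def footprint_reduction(inputs: OffsetInputs) -> float:
    """Stored CO2-equivalent as a percentage of the cumulated footprint.

    Returns ``-100 * (per_ha_carbon * co2_per_c * area) / (annual_footprint *
    horizon)``; negative values are reductions.
    """
    if inputs.annual_footprint == 0 or inputs.horizon == 0:
        raise ZeroDivisionError("annual footprint and horizon must be > 0")
    stored_co2 = inputs.per_ha_carbon * inputs.co2_per_c * inputs.area
    return float(-100.0 * stored_co2 / (inputs.annual_footprint * inputs.horizon))
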