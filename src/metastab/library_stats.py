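"""Selection-experiment bookkeeping: plated-library capability estimates.

A transformed culture's library capability (number of independent
transformants) is extrapolated from plated colony counts:

    capability = (CFU / plated volume in uL) * 1000 uL/mL * culture volume in mL

The exact arithmetic result is reported together with an order-of-magnitude
rendering, since capabilities are conventionally quoted to one significant
power of ten.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from metastab.errors import ValidationError


@dataclass(frozen=True)
class PlatingObservation:
    """One plate: colonies counted from a known volume of a known culture."""

    cfu: int
    plated_volume_ul: float
    culture_volume_ml: float

    def __post_init__(self) -> None:
        if self.cfu < 0 or int(self.cfu) != self.cfu:
            raise ValidationError(f"cfu must be a non-negative integer, got {self.cfu}")
        if self.plated_volume_ul <= 0:
            raise ValidationError(f"plated volume must be positive, got {self.plated_volume_ul}")
        if self.culture_volume_ml <= 0:
            raise ValidationError(f"culture volume must be positive, got {self.culture_volume_ml}")


def library_capability(obs: PlatingObservation) -> float:
    """Exact transformant-count estimate from one plating observation."""
    return (obs.cfu / obs.plated_volume_ul) * 1000.0 * obs.culture_volume_ml


def order_of_magnitude(value: float) -> float:
    """Round to one significant power of ten (0 stays 0)."""
    if value == 0:
        return 0.0
    return float(10 ** round(math.log10(abs(value)))) * (1 if value > 0 else -1)


def dilution_series_estimate(observations) -> dict:
    """Pool per-plate capability estimates from a dilution series.

    Reports each plate's estimate, their mean, and the range (max - min)
    as a consistency check across dilutions.
    """
    observations = list(observations)
    if not observations:
        raise ValidationError("at least one plating observation is required")
    estimates = [library_capability(o) for o in observations]
    mean = sum(estimates) / len(estimates)
    return {
        "per_plate": estimates,
        "mean": mean,
        "range": max(estimates) - min(estimates),
        "order_of_magnitude": order_of_magnitude(mean),
    }
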