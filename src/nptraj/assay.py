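"""Worked-example statistics for the accompanying wet-lab readouts.

Small closed-form quantities: ELISA binding rate (bound fraction of total
growth factor), MTT-style viability normalisation, and the percent
inhibition used to summarise migration and tube-formation assays. Rounding
is half-away-from-zero to the nearest integer percent, which reproduces all
printed percentages computable from their underlying group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ConfigError
from .hbond import round_half_away

__all__ = [
    "BindingAssay",
    "GroupSummary",
    "binding_rate",
    "viability",
    "percent_inhibition",
]


@dataclass(frozen=True)
class BindingAssay:
    """Total and unbound concentrations (same units, e.g. ng/mL)."""

    total: float
    unbound: float

    def __post_init__(self):
        if self.total <= 0:
            raise ConfigError("total concentration must be positive")
        if self.unbound < 0:
            raise ConfigError("unbound concentration cannot be negative")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD of one treatment group (units: cells/field, µm, ...)."""

    label: str
    mean: float
    sd: float
    n: int | None = None
    units: str = ""

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigError("SD cannot be negative")


def binding_rate(assay: BindingAssay) -> float:
    """Fraction of growth factor bound: (total - unbound) / total.

    Measurement noise can push unbound above total; the rate is then
    clipped to 0 with a warning rather than reported negative.
    """
    rate = (assay.total - assay.unbound) / assay.total
    if rate < 0:
        warnings.warn("unbound exceeds total; binding rate clipped to 0",
                      RuntimeWarning)
        return 0.0
    return rate


def viability(od_sample: float, od_blank: float, od_nc: float) -> float:
    """Percent viability: (OD_sample - OD_blank) / (OD_NC - OD_blank) x 100."""
    if od_nc <= od_blank:
        raise ConfigError("negative-control OD must exceed blank OD")
    return (od_sample - od_blank) / (od_nc - od_blank) * 100.0


def percent_inhibition(treated: GroupSummary, control: GroupSummary,
                       rounded: bool = True) -> float:
    """Percent reduction of the treated group mean relative to control.

    100 x (control - treated) / control; negative values signal enhancement
    rather than inhibition and are reported with their sign.
    """
    if control.mean <= 0:
        raise ConfigError("control mean must be positive")
    pct = 100.0 * (control.mean - treated.mean) / control.mean
    return float(round_half_away(pct)) if rounded else pct
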