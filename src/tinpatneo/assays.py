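"""Positivity criteria for T-cell assays and cytotoxicity normalization.

These encode the explicit evaluation rules of the wet-lab readouts:
tetramer-based priming calls, IFN-γ ELISpot calls, and live-cell
cytotoxicity curves normalized to their t = 0 measurement.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FOLD = 3.0  # "three-fold higher" read inclusively (>= 3x)


@dataclass(frozen=True)
class PrimingMeasurement:
    """Tetramer-positive frequencies (% of viable CD8+ T cells)."""

    freq_specific: float
    freq_negative_control: float

    def __post_init__(self):
        for v in (self.freq_specific, self.freq_negative_control):
            if not 0 <= v <= 100:
                raise ValueError("frequencies must be percentages in [0, 100]")


@dataclass(frozen=True)
class ElispotMeasurement:
    """Spot counts per 500,000 cells."""

    spots: float
    negative_mean: float

    def __post_init__(self):
        if self.spots < 0 or self.negative_mean < 0:
            raise ValueError("spot counts must be >= 0")


def priming_call(m: PrimingMeasurement, min_freq: float = 0.1, fold: float = FOLD) -> bool:
    """Positive iff the peptide-specific frequency is >= 0.1% of CD8+ T cells
    and at least three-fold the negative control (a zero control counts as an
    infinite fold change)."""
    if m.freq_negative_control == 0:
        return m.freq_specific >= min_freq
    # tiny slack keeps the inclusive >= 3x boundary robust to float rounding
    return (
        m.freq_specific >= min_freq
        and m.freq_specific >= fold * m.freq_negative_control - 1e-9
    )


def elispot_call(m: ElispotMeasurement, min_spots: float = 10.0, fold: float = FOLD) -> bool:
    """Positive iff > 10 spots/500,000 cells and at least three-fold the mean
    negative-control spot count."""
    return m.spots > min_spots and m.spots >= fold * m.negative_mean - 1e-9


def cytotox_normalize(area_timeseries) -> np.ndarray:
    """Divide a fluorescence-area time series by its t = 0 value."""
    series = np.asarray(area_timeseries, dtype=float)
    if series.size == 0:
        raise ValueError("empty time series")
    if series[0] <= 0:
        raise ValueError("t = 0 measurement must be > 0")
    return series / series[0]
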