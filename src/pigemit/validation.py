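"""Measurement-side emission computation and model-validation statistics.

The reference measurement converts a concentration difference over the
house and a ventilation rate into an annual per-pig-place emission:

    E = (C_out - C_in) * rho * V * 24 * 365 / 1e6     (kg / yr / pig place)

with concentrations in ppm, ``rho`` the ppm -> mg/m3 gas density factor
(0.667 for CH4, 0.71 for NH3) and ``V`` the ventilation flow in m3/h per
pig place.  A vacancy factor (default 3% downtime between production
cycles) scales the annual figure.  Agreement between measured and
predicted series is summarized by MAE, RMSE and R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_DENSITY",
    "MeasurementRecord",
    "PairedSeries",
    "measured_emission",
    "mae",
    "rmse",
    "r2",
    "reduction_percent",
]

#: ppm -> mg/m3 conversion densities (kg/m3).
GAS_DENSITY = {"CH4": 0.667, "NH3": 0.71}

DEFAULT_VACANCY = 0.03


@dataclass(frozen=True)
class MeasurementRecord:
    """One reference-method measurement (concentrations in ppm)."""

    C_out: float
    C_in: float
    density: float  # kg/m3, ppm -> mg/m3 factor for the gas
    vent: float  # m3/h per pig place

    def __post_init__(self) -> None:
        if self.vent < 0:
            raise ValueError(f"vent must be >= 0, got {self.vent}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.C_out < self.C_in:
            warnings.warn(
                f"negative concentration difference ({self.C_out} < {self.C_in} "
                "ppm); record retained",
                stacklevel=2,
            )


def measured_emission(rec: MeasurementRecord, vacancy: float = DEFAULT_VACANCY) -> float:
    """Annual emission (kg per pig place per year) from one measurement."""
    e = (rec.C_out - rec.C_in) * rec.density * rec.vent * 24.0 * 365.0 / 1e6
    return e * (1.0 - vacancy)


@dataclass(frozen=True)
class PairedSeries:
    """Measured and predicted values paired on the same days."""

    measured: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if m.shape != p.shape or m.ndim != 1:
            raise ValueError("measured and predicted must be 1-D of equal length")
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "predicted", p)

    @property
    def n(self) -> int:
        return self.measured.size


def mae(p: PairedSeries) -> float:
    """Mean absolute error, in the units of the series."""
    if p.n < 1:
        raise ValueError("need at least one pair")
    return float(np.mean(np.abs(p.measured - p.predicted)))


def rmse(p: PairedSeries) -> float:
    """Root mean square error, in the units of the series."""
    if p.n < 1:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((p.measured - p.predicted) ** 2)))


def r2(p: PairedSeries) -> float:
    """Coefficient of determination about the measured mean.

    May be negative when the predictions do worse than the mean of the
    measurements.  Undefined (raises) for a zero-variance measured series.
    """
    if p.n < 2:
        raise ValueError("need at least two pairs for R2")
    ss_tot = float(np.sum((p.measured - p.measured.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R2 undefined: measured series has zero variance")
    ss_res = float(np.sum((p.measured - p.predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def reduction_percent(reference_mean: float, treatment_mean: float) -> float:
    """Emission reduction of a treatment relative to a reference, in %."""
    if reference_mean <= 0:
        raise ValueError(f"reference_mean must be > 0, got {reference_mean}")
    return 100.0 * (1.0 - treatment_mean / reference_mean)
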