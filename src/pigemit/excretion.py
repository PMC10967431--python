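"""Excretion mass balances: from daily intake and growth to slurry.

Converts one day of feed, water and weight gain of the average pig into
excreted dry matter, organic matter (volatile solids), nitrogen fractions,
the ammoniacal-nitrogen precursor (urinary urea-N) and the water reaching
the manure pit.  All balances are per pig per day.

Nitrogen bookkeeping: N intake = crude protein / 6.25; faecal N is the
undigested share; retained N follows body-protein deposition (protein is
16% N); urinary N closes the balance.  Dry matter combines undigested
faecal organic matter, net ash and urinary solids (urea plus minerals).
Slurry mass subtracts a small gas correction for hydrolysis losses (biogas
from organic matter, CO2 from urea).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "DietSpec",
    "ExcretionParams",
    "ExcretionDay",
    "nitrogen_balance",
    "solids_balance",
    "water_balance",
    "tan_potential",
    "excrete_day",
    "saturation_vapor_pressure",
]

#: kg N per kg crude protein (Kjeldahl convention).
N_PER_PROTEIN = 1.0 / 6.25


@dataclass(frozen=True)
class DietSpec:
    """Feed composition and digestibility, all as mass fractions of feed
    (as-fed) except the digestibilities and retention, which are fractions
    of the respective intake."""

    dry_matter_frac: float = 0.88
    crude_protein_frac: float = 0.165
    ash_frac: float = 0.055
    digestibility_OM: float = 0.80
    digestibility_CP: float = 0.80
    ash_retention_frac: float = 0.35

    def __post_init__(self) -> None:
        for name in (
            "dry_matter_frac",
            "crude_protein_frac",
            "ash_frac",
            "digestibility_OM",
            "digestibility_CP",
            "ash_retention_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.crude_protein_frac + self.ash_frac > self.dry_matter_frac:
            raise ValueError(
                "crude_protein_frac + ash_frac exceeds dry_matter_frac "
                f"({self.crude_protein_frac} + {self.ash_frac} > "
                f"{self.dry_matter_frac})"
            )

    @property
    def organic_matter_frac(self) -> float:
        """Organic matter as fraction of feed: DM minus ash."""
        return self.dry_matter_frac - self.ash_frac


@dataclass(frozen=True)
class ExcretionParams:
    """Coefficients of the excretion balances.

    body_protein_per_gain : kg body protein deposited per kg weight gain.
    protein_N_frac        : kg N per kg body protein.
    urea_fraction         : share of urinary N excreted as urea
                            (the ammonia precursor).
    urinary_solids_per_N  : kg urinary solids per kg urinary N
                            (urea stoichiometry 60/28 = 2.14, plus minerals).
    urinary_organic_frac  : organic share of urinary solids.
    biogas_frac_OM        : share of excreted OM lost as hydrolysis gas.
    urea_co2_per_N        : kg CO2 per kg urea-N hydrolysed (44/(2*28)).
    metabolic_water_per_DM: L metabolic water per kg digested dry matter.
    body_water_per_gain   : L water retained per kg weight gain.
    respiratory_frac      : share of liquid water intake lost as vapour.
    evap_rate_ref         : floor evaporation, L per m2 wetted floor per h
                            at the 20 degC / 60% RH reference climate.
    """

    body_protein_per_gain: float = 0.16
    protein_N_frac: float = 0.16
    urea_fraction: float = 0.75
    urinary_solids_per_N: float = 2.14
    urinary_organic_frac: float = 0.70
    biogas_frac_OM: float = 0.05
    urea_co2_per_N: float = 0.733
    metabolic_water_per_DM: float = 0.4
    body_water_per_gain: float = 0.70
    respiratory_frac: float = 0.25
    evap_rate_ref: float = 0.05


@dataclass(frozen=True)
class ExcretionDay:
    """One day's excretion of the average pig (kg or L per day)."""

    faecal_DM: float
    urinary_solids: float
    DM_exc: float
    OM_exc: float  # volatile solids, the methane substrate
    ash_exc: float
    N_total: float
    N_urinary: float
    N_faecal: float
    TAN_potential: float  # urea-N, hydrolysing to ammoniacal N
    water_to_pit: float
    slurry_mass: float
    gas_correction: float
    meta: dict = field(default_factory=dict, compare=False)


def nitrogen_balance(
    feed_kg: float,
    diet: DietSpec,
    weight_gain: float,
    body_protein_per_gain: float = 0.16,
    protein_N_frac: float = 0.16,
) -> tuple[float, float, float]:
    """Partition nitrogen intake into urinary, faecal and retained N.

    Returns ``(N_urinary, N_faecal, N_retained)`` in kg N per day.
    Retention is capped at digestible N; urinary N is clamped at zero
    (with a warning) if retention plus faecal N would exceed intake.
    """
    if feed_kg < 0 or weight_gain < 0:
        raise ValueError("feed_kg and weight_gain must be >= 0")
    n_intake = feed_kg * diet.crude_protein_frac * N_PER_PROTEIN
    n_faecal = (1.0 - diet.digestibility_CP) * n_intake
    digestible = n_intake - n_faecal
    n_retained = min(weight_gain * body_protein_per_gain * protein_N_frac, digestible)
    n_urinary = n_intake - n_faecal - n_retained
    if n_urinary < 0:
        warnings.warn(
            f"urinary N clamped to 0 (balance gave {n_urinary:.3g} kg N/d)",
            stacklevel=2,
        )
        n_urinary = 0.0
    return n_urinary, n_faecal, n_retained


def solids_balance(
    feed_kg: float,
    diet: DietSpec,
    urinary_N: float,
    params: ExcretionParams = ExcretionParams(),
) -> tuple[float, float, float, float, float]:
    """Excreted solids from undigested feed and urinary urea/minerals.

    Returns ``(faecal_DM, OM_exc, ash_exc, urinary_solids, DM_exc)``.
    ``OM_exc`` is the volatile-solids output consumed by the methane
    module (faecal organic matter plus the organic share of urinary
    solids); ``DM_exc`` adds the net ash.
    """
    if feed_kg < 0 or urinary_N < 0:
        raise ValueError("inputs must be >= 0")
    faecal_om = (1.0 - diet.digestibility_OM) * feed_kg * diet.organic_matter_frac
    ash_exc = (1.0 - diet.ash_retention_frac) * feed_kg * diet.ash_frac
    urinary_solids = params.urinary_solids_per_N * urinary_N
    om_exc = faecal_om + params.urinary_organic_frac * urinary_solids
    faecal_dm = faecal_om + ash_exc
    dm_exc = faecal_om + ash_exc + urinary_solids
    return faecal_dm, om_exc, ash_exc, urinary_solids, dm_exc


def saturation_vapor_pressure(T_c: float) -> float:
    """Magnus saturation vapour pressure (kPa) over water at ``T_c`` degC."""
    import math

    return 0.6108 * math.exp(17.27 * T_c / (T_c + 237.3))


def floor_evaporation(
    wetted_area_m2: float,
    T_c: float,
    RH_pct: float,
    evap_rate_ref: float = 0.05,
) -> float:
    """Daily evaporation (L/d) from wetted floor, scaled by the saturation
    deficit relative to the 20 degC / 60% RH reference."""
    ref_deficit = saturation_vapor_pressure(20.0) * 0.40
    deficit = saturation_vapor_pressure(T_c) * max(0.0, 1.0 - RH_pct / 100.0)
    return evap_rate_ref * (deficit / ref_deficit) * wetted_area_m2 * 24.0


def water_balance(
    water_L: float,
    feed_kg: float,
    diet: DietSpec,
    weight_gain: float,
    evap_floor: float = 0.0,
    params: ExcretionParams = ExcretionParams(),
) -> float:
    """Water reaching the pit (L/d): drinking water plus feed moisture and
    metabolic water, minus body retention, respiratory loss and floor
    evaporation.  Clamped at zero with a warning."""
    if min(water_L, feed_kg, weight_gain, evap_floor) < 0:
        raise ValueError("inputs must be >= 0")
    feed_moisture = feed_kg * (1.0 - diet.dry_matter_frac)
    digested_dm = (
        diet.digestibility_OM * feed_kg * diet.organic_matter_frac
        + diet.ash_retention_frac * feed_kg * diet.ash_frac
    )
    metabolic = params.metabolic_water_per_DM * digested_dm
    body = params.body_water_per_gain * weight_gain
    respiratory = params.respiratory_frac * (water_L + feed_moisture)
    out = water_L + feed_moisture + metabolic - body - respiratory - evap_floor
    if out < 0:
        warnings.warn(
            f"water to pit clamped to 0 (balance gave {out:.3g} L/d)", stacklevel=2
        )
        out = 0.0
    return out


def tan_potential(N_urinary: float, urea_fraction: float = 0.75) -> float:
    """Urea-N excreted in urine (kg N/d), the precursor of ammoniacal N."""
    if not 0.0 <= urea_fraction <= 1.0:
        raise ValueError(f"urea_fraction must be in [0, 1], got {urea_fraction}")
    return urea_fraction * N_urinary


def excrete_day(
    feed_kg: float,
    water_L: float,
    weight_gain: float,
    diet: DietSpec,
    params: ExcretionParams = ExcretionParams(),
    evap_floor: float = 0.0,
) -> ExcretionDay:
    """Full excretion balance for one pig-day."""
    n_urinary, n_faecal, n_retained = nitrogen_balance(
        feed_kg, diet, weight_gain, params.body_protein_per_gain, params.protein_N_frac
    )
    faecal_dm, om_exc, ash_exc, urinary_solids, dm_exc = solids_balance(
        feed_kg, diet, n_urinary, params
    )
    water = water_balance(water_L, feed_kg, diet, weight_gain, evap_floor, params)
    tan = tan_potential(n_urinary, params.urea_fraction)
    gas = params.biogas_frac_OM * om_exc + params.urea_co2_per_N * tan
    slurry = max(dm_exc + water - gas, 0.0)
    return ExcretionDay(
        faecal_DM=faecal_dm,
        urinary_solids=urinary_solids,
        DM_exc=dm_exc,
        OM_exc=om_exc,
        ash_exc=ash_exc,
        N_total=n_urinary + n_faecal,
        N_urinary=n_urinary,
        N_faecal=n_faecal,
        TAN_potential=tan,
        water_to_pit=water,
        slurry_mass=slurry,
        gas_correction=gas,
        meta={"N_retained": n_retained},
    )
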