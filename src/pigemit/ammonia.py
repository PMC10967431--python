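"""Ammonia volatilization from liquid surfaces in the pig house.

Each emitting surface (pit manure surface, urine puddles on solid or
slatted floor) releases ammonia by convective mass transfer:

    E_NH3 = k * A * f * [TAN] / H          (mol NH3 / s)

with ``k`` the mass-transfer coefficient (m/s, a power law in air velocity
and temperature), ``A`` the emitting area (m2), ``f`` the unionized
fraction of total ammoniacal nitrogen (pH/temperature equilibrium of
NH4+/NH3), ``[TAN]`` the ammoniacal-N concentration (mol/m3) and ``H`` the
dimensionless liquid/gas Henry coefficient.  Room emission is the sum over
sources; annualization converts to kg NH3 per pig place per year.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "NH3Params",
    "SurfaceSource",
    "FloorFouling",
    "mass_transfer_coefficient",
    "fraction_unionized",
    "henry_dimensionless",
    "nh3_flux",
    "flux_to_kgN_per_day",
    "room_nh3",
    "KG_N_PER_MOL",
    "KG_NH3_PER_MOL",
    "SECONDS_PER_YEAR",
]

KG_N_PER_MOL = 0.014
KG_NH3_PER_MOL = 0.017
SECONDS_PER_YEAR = 3.1536e7
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class NH3Params:
    """Coefficients of the volatilization model (all configurable; the
    mass-transfer and dissociation relations are standard boundary-layer
    and equilibrium forms)."""

    k_ref: float = 2.0e-3  # m/s at the reference velocity and temperature
    v_ref: float = 0.15  # m/s
    v_exponent: float = 0.8  # boundary-layer velocity exponent
    T_ref: float = 293.15  # K
    T_exponent: float = 1.0
    pKa_intercept: float = 0.09018
    pKa_slope_over_T: float = 2729.92  # K
    henry_ref: float = 1431.0  # dimensionless at henry_T_ref
    henry_base: float = 1.053
    henry_T_ref: float = 293.0  # K
    surface_pH_offset: float = 0.5  # surface pH minus bulk slurry pH


@dataclass(frozen=True)
class SurfaceSource:
    """One emitting surface with its local conditions."""

    area: float  # m2
    TAN_conc: float  # mol/m3
    surface_pH: float
    surface_T: float  # K
    air_velocity: float  # m/s
    kind: str = "pit"  # pit | solid_floor | slatted_concrete | slatted_metal

    def __post_init__(self) -> None:
        if self.area < 0 or self.TAN_conc < 0:
            raise ValueError("area and TAN_conc must be >= 0")
        if not 0.0 < self.surface_pH < 14.0:
            raise ValueError(f"surface_pH must be in (0, 14), got {self.surface_pH}")


@dataclass(frozen=True)
class FloorFouling:
    """Urine-fouled floor shares.  The per-m2 flux of fouled concrete
    slatted floor is taken equal to that of the solid floor; emission from
    soiled pigs and pen partitions is folded into the solid-floor term."""

    solid_floor_area: float  # m2
    slatted_concrete_area: float  # m2, front of the pen
    slatted_metal_area: float  # m2, triangular slats at the back
    fouled_fraction_solid: float = 0.10
    fouled_fraction_slatted_front: float = 0.05
    fouled_fraction_slatted_back: float = 0.05
    puddle_pH: float = 7.8  # urine puddle after urea hydrolysis

    def __post_init__(self) -> None:
        for name in (
            "fouled_fraction_solid",
            "fouled_fraction_slatted_front",
            "fouled_fraction_slatted_back",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def mass_transfer_coefficient(
    v: float, T: float, params: NH3Params = NH3Params()
) -> float:
    """Mass-transfer coefficient k (m/s) at air velocity ``v`` (m/s) and
    surface temperature ``T`` (K)."""
    if v < 0 or T <= 0:
        raise ValueError("need v >= 0 and T > 0")
    return (
        params.k_ref
        * (v / params.v_ref) ** params.v_exponent
        * (T / params.T_ref) ** params.T_exponent
    )


def fraction_unionized(pH: float, T: float, params: NH3Params = NH3Params()) -> float:
    """Unionized (volatile) share of TAN at ``pH`` and ``T`` (K):
    f = 1 / (1 + 10^(pKa(T) - pH)), pKa(T) = 0.09018 + 2729.92/T."""
    if T <= 0:
        raise ValueError("T must be > 0")
    pKa = params.pKa_intercept + params.pKa_slope_over_T / T
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def henry_dimensionless(T: float, params: NH3Params = NH3Params()) -> float:
    """Dimensionless liquid/gas Henry coefficient of NH3 at ``T`` (K),
    H = 1431 * 1.053^(293 - T); decreasing in temperature."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return params.henry_ref * params.henry_base ** (params.henry_T_ref - T)


def nh3_flux(source: SurfaceSource, params: NH3Params = NH3Params()) -> float:
    """Ammonia emission of one surface, mol NH3 per second."""
    k = mass_transfer_coefficient(source.air_velocity, source.surface_T, params)
    f = fraction_unionized(source.surface_pH, source.surface_T, params)
    h = henry_dimensionless(source.surface_T, params)
    return k * source.area * f * source.TAN_conc / h


def flux_to_kgN_per_day(flux_mol_s: float) -> float:
    """Convert a molar flux to kg N per day (for TAN-pool depletion)."""
    return flux_mol_s * SECONDS_PER_DAY * KG_N_PER_MOL


def flux_to_kgNH3_per_day(flux_mol_s: float) -> float:
    return flux_mol_s * SECONDS_PER_DAY * KG_NH3_PER_MOL


def room_nh3(
    pit_sources: list[SurfaceSource],
    floor_sources: list[SurfaceSource],
    params: NH3Params = NH3Params(),
) -> dict[str, float]:
    """Itemized room emission in kg NH3 per day.

    Returns ``{"pit": ..., "floor": ..., "total": ...}``; the total is the
    exact sum of the itemized sources.  Fluxes per source are also exposed
    under ``"flux_mol_s"`` keys for pool bookkeeping by the driver.
    """
    pit = sum(nh3_flux(s, params) for s in pit_sources)
    floor = sum(nh3_flux(s, params) for s in floor_sources)
    return {
        "pit": flux_to_kgNH3_per_day(pit),
        "floor": flux_to_kgNH3_per_day(floor),
        "total": flux_to_kgNH3_per_day(pit) + flux_to_kgNH3_per_day(floor),
        "pit_flux_mol_s": pit,
        "floor_flux_mol_s": floor,
    }
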