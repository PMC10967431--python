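"""Manure-pit geometry, storage bookkeeping, removal schedules and the
indoor-climate submodel.

A pit channel is a trapezoidal prism: a rectangular footprint whose side
walls may slope inward (0, 1 or 2 sloped walls at a common angle).  With
sloped walls the emitting surface shrinks as the manure level drops, which
is the geometric mechanism behind the short-storage (SS) pen design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PitGeometry",
    "RemovalSchedule",
    "PitState",
    "ClimateDay",
    "ClimateParams",
    "pit_volume",
    "height_from_volume",
    "emitting_area",
    "pit_influx",
    "apply_removal",
    "remove_to_height",
    "indoor_climate",
]


@dataclass(frozen=True)
class PitGeometry:
    """One pit channel (per pen).  ``wall_slope_deg`` is measured from the
    horizontal; 90 degrees means straight (vertical) walls."""

    length: float  # m
    top_width: float  # m
    depth: float  # m
    wall_slope_deg: float = 90.0
    n_sloped_walls: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.wall_slope_deg <= 90.0:
            raise ValueError(f"wall_slope_deg must be in (0, 90], got {self.wall_slope_deg}")
        if self.n_sloped_walls not in (0, 1, 2):
            raise ValueError(f"n_sloped_walls must be 0, 1 or 2, got {self.n_sloped_walls}")
        if min(self.length, self.top_width, self.depth) <= 0:
            raise ValueError("length, top_width and depth must be > 0")
        if self.bottom_width <= 0:
            raise ValueError(
                f"sloped walls meet above the pit floor (bottom width "
                f"{self.bottom_width:.4g} m <= 0); reduce depth or slope"
            )

    @property
    def _inv_tan(self) -> float:
        # horizontal run per metre of rise on each sloped wall
        return 1.0 / math.tan(math.radians(self.wall_slope_deg))

    @property
    def bottom_width(self) -> float:
        return self.top_width - self.n_sloped_walls * self.depth * self._inv_tan

    @property
    def capacity(self) -> float:
        """Volume (m3) at a manure height equal to the pit depth."""
        return pit_volume(self, self.depth)


def pit_volume(geom: PitGeometry, height: float) -> float:
    """Stored volume (m3) at manure ``height`` (m): trapezoidal prism."""
    if not 0.0 <= height <= geom.depth + 1e-12:
        raise ValueError(f"height {height} outside [0, {geom.depth}]")
    w_b = geom.bottom_width
    return geom.length * (
        w_b * height + geom.n_sloped_walls * geom._inv_tan * height**2 / 2.0
    )


def height_from_volume(geom: PitGeometry, volume: float) -> float:
    """Manure height (m) holding ``volume`` m3: inverse of :func:`pit_volume`.

    Straight walls reduce to a division; sloped walls solve the quadratic
    ``(n/(2 tan)) L h^2 + L w_b h = V`` for the positive root.

    Raises
    ------
    ValueError
        If ``volume`` exceeds the pit capacity (overflow) or is negative.
    """
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    cap = geom.capacity
    if volume > cap * (1.0 + 1e-9):
        raise ValueError(
            f"pit overflow: volume {volume:.6g} m3 exceeds capacity {cap:.6g} m3"
        )
    volume = min(volume, cap)
    if geom.n_sloped_walls == 0 or geom.wall_slope_deg == 90.0:
        return volume / (geom.length * geom.top_width)
    a = geom.length * geom.n_sloped_walls * geom._inv_tan / 2.0
    b = geom.length * geom.bottom_width
    # positive root of a h^2 + b h - V = 0 (a > 0, b > 0)
    h = (-b + math.sqrt(b * b + 4.0 * a * volume)) / (2.0 * a)
    return min(max(h, 0.0), geom.depth)


def emitting_area(
    geom: PitGeometry, height: float, empty_floor_wetted: bool = True
) -> float:
    """Emitting surface (m2) of the stored manure at ``height``.

    Straight walls: the full footprint (length x top width) whenever manure
    is present.  Sloped walls: the liquid surface grows with height from
    the bottom width to the top width.  At zero height the pit floor is
    assumed wetted (configurable off).
    """
    if not 0.0 <= height <= geom.depth + 1e-12:
        raise ValueError(f"height {height} outside [0, {geom.depth}]")
    if height == 0.0:
        return geom.length * geom.bottom_width if empty_floor_wetted else 0.0
    if geom.n_sloped_walls == 0 or geom.wall_slope_deg == 90.0:
        return geom.length * geom.top_width
    return geom.length * (
        geom.bottom_width + geom.n_sloped_walls * geom._inv_tan * height
    )


@dataclass(frozen=True)
class RemovalSchedule:
    """When and how far a channel is emptied.

    ``interval_days`` of 45 gives long-storage emptying on period days
    45, 90, ...; 1 gives daily flushing.  ``empty_days`` adds explicit
    extra emptying days (1-based day of the growing period; the sentinel
    -1 means the last day of the period), used for the SS front water
    channel which is emptied once per period.
    """

    interval_days: int | None = None
    residual_height: float = 0.0
    empty_days: tuple[int, ...] = ()
    dilution_water: float = 0.0  # L per pig per day added to this channel

    def __post_init__(self) -> None:
        if self.interval_days is not None and self.interval_days < 1:
            raise ValueError(f"interval_days must be >= 1, got {self.interval_days}")
        if self.residual_height < 0:
            raise ValueError("residual_height must be >= 0")

    def is_removal_day(self, day: int, period_length: int | None = None) -> bool:
        """``day`` is the 1-based day of the growing period."""
        if self.interval_days is not None and day % self.interval_days == 0:
            return True
        if day in self.empty_days:
            return True
        return period_length is not None and day == period_length and -1 in self.empty_days


@dataclass
class PitState:
    """Evolving content of one pit channel (aggregated over its pens).

    Masses are totals for the channel; ``volume`` in m3, VS pools and TAN
    in kg.  Concentrations follow from the well-mixed assumption.
    """

    volume: float = 0.0
    VS_deg: float = 0.0  # fast-degradable volatile solids, kg
    VS_nondeg: float = 0.0  # slowly degradable volatile solids, kg
    TAN_mass: float = 0.0  # ammoniacal N, kg N
    manure_T: float = 15.0  # degC

    @property
    def VS_mass(self) -> float:
        return self.VS_deg + self.VS_nondeg

    @property
    def TAN_conc(self) -> float:
        """kg N per m3 of stored slurry (0 when empty)."""
        return self.TAN_mass / self.volume if self.volume > 0 else 0.0

    @property
    def VS_conc(self) -> float:
        """kg VS per m3 of stored slurry (0 when empty)."""
        return self.VS_mass / self.volume if self.volume > 0 else 0.0


def pit_influx(
    state: PitState,
    volume_m3: float,
    vs_kg: float,
    tan_kg: float,
    vs_degradable_frac: float = 0.83,
) -> PitState:
    """Add one day's slurry to the channel (fresh VS split into pools)."""
    if min(volume_m3, vs_kg, tan_kg) < 0:
        raise ValueError("influx quantities must be >= 0")
    state.volume += volume_m3
    state.VS_deg += vs_kg * vs_degradable_frac
    state.VS_nondeg += vs_kg * (1.0 - vs_degradable_frac)
    state.TAN_mass += tan_kg
    return state


@dataclass(frozen=True)
class Removed:
    """Material taken out of a channel by one emptying event."""

    volume: float
    VS: float
    TAN: float


def remove_to_height(
    state: PitState, geom: PitGeometry, residual_height: float, n_units: int = 1
) -> tuple[PitState, Removed]:
    """Empty the channel down to ``residual_height``, removing VS and TAN
    in proportion to the volume removed (well-mixed slurry).

    ``n_units`` is the number of identical pens sharing the aggregated
    state.  A no-op when the level is already at or below the residual.
    """
    v_res = pit_volume(geom, residual_height) * n_units
    if state.volume <= v_res:
        return state, Removed(0.0, 0.0, 0.0)
    frac_removed = (state.volume - v_res) / state.volume
    rem = Removed(
        volume=state.volume - v_res,
        VS=state.VS_mass * frac_removed,
        TAN=state.TAN_mass * frac_removed,
    )
    state.VS_deg *= 1.0 - frac_removed
    state.VS_nondeg *= 1.0 - frac_removed
    state.TAN_mass *= 1.0 - frac_removed
    state.volume = v_res
    return state, rem


def apply_removal(
    state: PitState,
    geom: PitGeometry,
    sched: RemovalSchedule,
    day: int,
    n_units: int = 1,
    period_length: int | None = None,
) -> tuple[PitState, Removed]:
    """Apply the removal schedule at the end of period day ``day`` (1-based)."""
    if sched.is_removal_day(day, period_length):
        return remove_to_height(state, geom, sched.residual_height, n_units)
    return state, Removed(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Indoor climate


@dataclass(frozen=True)
class ClimateParams:
    """Coefficients of the indoor-climate submodel.

    Mechanical ventilation holds the room near a setpoint in cold weather;
    in warm weather the room tracks the outside temperature plus a
    ventilation offset.  Manure temperature follows the room linearly and
    sits below it (slurry mass and the pit floor buffer it).
    """

    T_set_min: float = 20.0  # degC, minimum room temperature
    dT_vent: float = 3.0  # degC, room warming over outside air
    manure_T_intercept: float = 0.0  # degC
    manure_T_slope: float = 0.88  # per degC of room temperature
    air_velocity_surface: float = 0.15  # m/s, constant over emitting surfaces
    rh_factor: float = 0.75  # room RH as a share of outside RH
    rh_min: float = 30.0
    rh_max: float = 90.0


@dataclass(frozen=True)
class ClimateDay:
    outside_T: float
    outside_RH: float
    room_T: float
    room_RH: float
    manure_T: float
    air_velocity_surface: float


def indoor_climate(
    outside_T: float, outside_RH: float, params: ClimateParams = ClimateParams()
) -> ClimateDay:
    """Room, manure and surface conditions for one day of outside weather."""
    if not (math.isfinite(outside_T) and math.isfinite(outside_RH)):
        raise ValueError("weather values must be finite")
    room_T = max(params.T_set_min, outside_T + params.dT_vent)
    room_RH = min(max(outside_RH * params.rh_factor, params.rh_min), params.rh_max)
    manure_T = params.manure_T_intercept + params.manure_T_slope * room_T
    return ClimateDay(
        outside_T=outside_T,
        outside_RH=outside_RH,
        room_T=room_T,
        room_RH=room_RH,
        manure_T=manure_T,
        air_velocity_surface=params.air_velocity_surface,
    )
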