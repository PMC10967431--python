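"""Scenario configuration: room layout, herd, diet, pit channels, schedules.

Ships two presets mirroring the experimental fattening-pig rooms:

``LS`` (long storage)
    54 places, 6 pens of 5.10 x 1.88 m, deep pit (1.20 m) with straight
    walls under the slatted floor (60/40 slatted/solid), emptied every
    45 days.

``SS`` (short storage)
    78 places, 6 pens of 5.22 x 2.59 m, shallow pit (0.50 m) with 45
    degree sloped walls split into a back manure channel (flushed daily,
    2 cm residual film) and a front water channel (receives dilution
    water and part of the manure, emptied once per growing period),
    38/62 slatted/solid floor.

Scenarios can also be loaded from / saved to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import yaml

from .excretion import DietSpec, ExcretionParams
from .housing import ClimateParams, PitGeometry, RemovalSchedule
from .ammonia import NH3Params
from .methane import MethaneParams

__all__ = [
    "ChannelSpec",
    "Scenario",
    "ls_preset",
    "ss_preset",
    "load_scenario",
    "save_scenario",
    "DEFAULT_GP_CALENDAR",
]

#: Growing-period calendar of the simulated year: (start offset in days
#: from 8 October, length in days).  Stocking dates 8 Oct, 21 Jan, 27 Apr,
#: 27 Jul; delivery 12 Jan, 20 Apr, 21 Jul, 21 Oct.
DEFAULT_GP_CALENDAR: tuple[tuple[int, int], ...] = (
    (0, 96),
    (105, 89),
    (201, 85),
    (292, 86),
)


@dataclass(frozen=True)
class ChannelSpec:
    """One pit channel: per-pen geometry, schedule and its share of the
    excreted manure."""

    name: str
    geometry: PitGeometry
    schedule: RemovalSchedule
    manure_fraction: float = 1.0
    n_units: int = 1  # identical pens sharing the channel

    def __post_init__(self) -> None:
        if not 0.0 <= self.manure_fraction <= 1.0:
            raise ValueError(
                f"channel {self.name}: manure_fraction must be in [0, 1], "
                f"got {self.manure_fraction}"
            )
        if self.n_units < 1:
            raise ValueError(f"channel {self.name}: n_units must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """Complete description of one pig room and its management."""

    name: str
    n_places: int
    n_pens: int
    room_length: float  # m
    room_width: float  # m
    start_weight_kg: float
    end_weight_kg: float
    period_days: int
    total_feed_kg: float  # per pig over the period
    total_water_L: float  # per pig over the period
    slatted_frac: float  # share of floor area that is slatted
    slatted_front_share: float = 0.5  # concrete share of the slatted floor
    bulk_slurry_pH: float = 7.0  # measured input
    puddle_pH: float = 7.8  # urine puddle on the floor after urea hydrolysis
    urine_water_frac: float = 0.55  # urine volume / drinking water
    urea_hydrolysis_frac: float = 1.0  # share hydrolysed in floor puddles
    fouled_fraction_solid: float = 0.10
    fouled_fraction_slatted_front: float = 0.05
    fouled_fraction_slatted_back: float = 0.05
    vacancy: float = 0.03
    empty_floor_wetted: bool = True
    diet: DietSpec = field(default_factory=DietSpec)
    excretion: ExcretionParams = field(default_factory=ExcretionParams)
    climate: ClimateParams = field(default_factory=ClimateParams)
    nh3: NH3Params = field(default_factory=NH3Params)
    ch4: MethaneParams = field(default_factory=MethaneParams)
    channels: tuple[ChannelSpec, ...] = ()
    gp_calendar: tuple[tuple[int, int], ...] = DEFAULT_GP_CALENDAR

    def __post_init__(self) -> None:
        if self.n_places < 0:
            raise ValueError(f"n_places must be >= 0, got {self.n_places}")
        if self.n_pens < 1:
            raise ValueError(f"n_pens must be >= 1, got {self.n_pens}")
        if not 0 < self.start_weight_kg < self.end_weight_kg:
            raise ValueError(
                "need 0 < start_weight_kg < end_weight_kg, got "
                f"{self.start_weight_kg}, {self.end_weight_kg}"
            )
        if self.period_days < 1:
            raise ValueError(f"period_days must be >= 1, got {self.period_days}")
        if min(self.total_feed_kg, self.total_water_L) <= 0:
            raise ValueError("total_feed_kg and total_water_L must be > 0")
        if not 0.0 <= self.slatted_frac <= 1.0:
            raise ValueError(f"slatted_frac must be in [0, 1], got {self.slatted_frac}")
        if not 0.0 <= self.vacancy < 1.0:
            raise ValueError(f"vacancy must be in [0, 1), got {self.vacancy}")
        if not self.channels:
            raise ValueError("scenario needs at least one pit channel")
        tot = sum(c.manure_fraction for c in self.channels)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(
                f"channel manure_fractions must sum to 1, got {tot:.6g}"
            )
        starts = [s for s, _ in self.gp_calendar]
        ends = [s + l for s, l in self.gp_calendar]
        for (s, e_prev) in zip(starts[1:], ends[:-1]):
            if s < e_prev:
                raise ValueError("gp_calendar periods overlap")

    # -- derived floor areas ------------------------------------------------
    @property
    def room_area(self) -> float:
        return self.room_length * self.room_width

    @property
    def solid_floor_area(self) -> float:
        return self.room_area * (1.0 - self.slatted_frac)

    @property
    def slatted_concrete_area(self) -> float:
        return self.room_area * self.slatted_frac * self.slatted_front_share

    @property
    def slatted_metal_area(self) -> float:
        return self.room_area * self.slatted_frac * (1.0 - self.slatted_front_share)

    def replace(self, **kw) -> "Scenario":
        return dc_replace(self, **kw)


def ls_preset(**overrides) -> Scenario:
    """Long-storage room: deep straight-walled pit, 45-day emptying."""
    geom = PitGeometry(length=5.10, top_width=1.88, depth=1.20)
    chan = ChannelSpec(
        name="pit",
        geometry=geom,
        schedule=RemovalSchedule(interval_days=45, residual_height=0.05),
        manure_fraction=1.0,
        n_units=6,
    )
    sc = Scenario(
        name="LS",
        n_places=54,
        n_pens=6,
        room_length=11.28,
        room_width=5.90,
        start_weight_kg=23.6,
        end_weight_kg=115.6,
        period_days=96,
        total_feed_kg=240.0,
        total_water_L=560.0,
        slatted_frac=0.60,
        channels=(chan,),
    )
    return sc.replace(**overrides) if overrides else sc


def ss_preset(**overrides) -> Scenario:
    """Short-storage room: shallow 45-degree sloped channels, daily flush
    of the back manure channel, diluted front water channel emptied once
    per growing period."""
    back = ChannelSpec(
        name="back",
        geometry=PitGeometry(
            length=5.22, top_width=1.30, depth=0.50, wall_slope_deg=45.0, n_sloped_walls=2
        ),
        schedule=RemovalSchedule(interval_days=1, residual_height=0.02),
        manure_fraction=0.8,
        n_units=6,
    )
    front = ChannelSpec(
        name="front",
        geometry=PitGeometry(
            length=5.22, top_width=1.29, depth=0.50, wall_slope_deg=45.0, n_sloped_walls=1
        ),
        schedule=RemovalSchedule(
            interval_days=None,
            residual_height=0.0,
            empty_days=(-1,),
            dilution_water=0.75,
        ),
        manure_fraction=0.2,
        n_units=6,
    )
    sc = Scenario(
        name="SS",
        n_places=78,
        n_pens=6,
        room_length=15.55,
        room_width=6.00,
        start_weight_kg=22.6,
        end_weight_kg=114.0,
        period_days=96,
        total_feed_kg=240.0,
        total_water_L=560.0,
        slatted_frac=0.38,
        channels=(back, front),
    )
    return sc.replace(**overrides) if overrides else sc


PRESETS = {"LS": ls_preset, "SS": ss_preset}


# ---------------------------------------------------------------------------
# YAML round trip


def _scenario_to_dict(sc: Scenario) -> dict:
    d = asdict(sc)
    d["gp_calendar"] = [list(x) for x in sc.gp_calendar]
    for ch, spec in zip(d["channels"], sc.channels):
        ch["schedule"]["empty_days"] = list(spec.schedule.empty_days)
    d["channels"] = list(d["channels"])
    return d


def save_scenario(sc: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(_scenario_to_dict(sc), sort_keys=False))


def _build(cls, data: dict, context: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValueError(f"invalid {context} config: {exc}") from None


def load_scenario(path) -> Scenario:
    """Load a scenario YAML, with field-level validation errors."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario file must be a mapping")
    channels = []
    for ch in data.pop("channels", []):
        geom = _build(PitGeometry, ch.pop("geometry"), "geometry")
        sched = ch.pop("schedule")
        sched["empty_days"] = tuple(sched.get("empty_days", ()))
        schedule = _build(RemovalSchedule, sched, "schedule")
        channels.append(
            _build(ChannelSpec, {**ch, "geometry": geom, "schedule": schedule}, "channel")
        )
    for key, cls in (
        ("diet", DietSpec),
        ("excretion", ExcretionParams),
        ("climate", ClimateParams),
        ("nh3", NH3Params),
        ("ch4", MethaneParams),
    ):
        if key in data:
            data[key] = _build(cls, data[key], key)
    if "gp_calendar" in data:
        data["gp_calendar"] = tuple(tuple(x) for x in data["gp_calendar"])
    return _build(Scenario, {**data, "channels": tuple(channels)}, "scenario")
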