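"""Daily simulation loop for one growing period or a full production year.

Each simulated day runs, in order: indoor climate, growth and intake,
excretion, pit influx, emission fluxes (NH3 per surface, CH4 per channel
plus enteric) and end-of-day manure removal.  Between growing periods the
room is empty but the pit keeps emitting from the stored manure.

The driver keeps conservation ledgers (volume, volatile solids,
ammoniacal N) so that everything excreted is accounted for as removed,
still stored, degraded to methane, or volatilized as ammonia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ammonia, methane
from .ammonia import NH3Params, SurfaceSource, nh3_flux
from .excretion import excrete_day, floor_evaporation
from .growth import build_trajectory
from .housing import (
    ClimateDay,
    PitState,
    apply_removal,
    emitting_area,
    height_from_volume,
    indoor_climate,
)
from .scenario import Scenario

__all__ = ["run_growing_period", "run_year", "annualize", "annualize_outputs", "SimResult"]

CELSIUS_TO_K = 273.15


@dataclass
class Ledger:
    """Cumulative mass bookkeeping for conservation checks."""

    volume_in: float = 0.0  # m3, slurry + dilution water
    volume_removed: float = 0.0
    vs_in: float = 0.0  # kg
    vs_removed: float = 0.0
    vs_degraded: float = 0.0  # kg VS converted to CH4 carbon
    tan_in: float = 0.0  # kg N
    tan_removed: float = 0.0
    tan_volatilized: float = 0.0


@dataclass
class SimResult:
    daily: pd.DataFrame
    states: dict[str, PitState]
    ledger: Ledger
    scenario: Scenario

    def final_storage(self) -> dict[str, float]:
        return {
            "volume": sum(s.volume for s in self.states.values()),
            "VS": sum(s.VS_mass for s in self.states.values()),
            "TAN": sum(s.TAN_mass for s in self.states.values()),
        }


def _fresh_states(scenario: Scenario) -> dict[str, PitState]:
    return {c.name: PitState() for c in scenario.channels}


def _pit_sources(
    scenario: Scenario, states: dict[str, PitState], clim: ClimateDay
) -> dict[str, SurfaceSource]:
    """Per-channel emitting surfaces at the current manure level."""
    sources = {}
    for chan in scenario.channels:
        st = states[chan.name]
        h = height_from_volume(chan.geometry, st.volume / chan.n_units)
        area = (
            emitting_area(chan.geometry, h, scenario.empty_floor_wetted) * chan.n_units
        )
        sources[chan.name] = SurfaceSource(
            area=area,
            TAN_conc=st.TAN_conc / ammonia.KG_N_PER_MOL,
            surface_pH=scenario.bulk_slurry_pH + scenario.nh3.surface_pH_offset,
            surface_T=st.manure_T + CELSIUS_TO_K,
            air_velocity=clim.air_velocity_surface,
            kind="pit",
        )
    return sources


def _floor_sources(
    scenario: Scenario, puddle_tan_mol_m3: float, clim: ClimateDay
) -> list[SurfaceSource]:
    if puddle_tan_mol_m3 <= 0:
        return []
    layout = [
        (scenario.solid_floor_area, scenario.fouled_fraction_solid, "solid_floor"),
        (
            scenario.slatted_concrete_area,
            scenario.fouled_fraction_slatted_front,
            "slatted_concrete",
        ),
        (
            scenario.slatted_metal_area,
            scenario.fouled_fraction_slatted_back,
            "slatted_metal",
        ),
    ]
    return [
        SurfaceSource(
            area=area * frac,
            TAN_conc=puddle_tan_mol_m3,
            surface_pH=scenario.puddle_pH,
            surface_T=clim.room_T + CELSIUS_TO_K,
            air_velocity=clim.air_velocity_surface,
            kind=kind,
        )
        for area, frac, kind in layout
        if area * frac > 0
    ]


def _emission_day(
    scenario: Scenario,
    states: dict[str, PitState],
    clim: ClimateDay,
    puddle_tan_mol_m3: float,
    headcount: float,
    ledger: Ledger,
) -> dict[str, float]:
    """NH3 and CH4 fluxes for one day; depletes pit TAN and VS pools."""
    nh3p: NH3Params = scenario.nh3
    pit_kg = 0.0
    pit_sources = _pit_sources(scenario, states, clim)
    for chan in scenario.channels:
        flux = nh3_flux(pit_sources[chan.name], nh3p)
        st = states[chan.name]
        n_loss = min(ammonia.flux_to_kgN_per_day(flux), st.TAN_mass)
        st.TAN_mass -= n_loss
        ledger.tan_volatilized += n_loss
        pit_kg += n_loss * (ammonia.KG_NH3_PER_MOL / ammonia.KG_N_PER_MOL)
    floor_kg = 0.0
    if headcount > 0:
        for src in _floor_sources(scenario, puddle_tan_mol_m3, clim):
            floor_kg += ammonia.flux_to_kgNH3_per_day(nh3_flux(src, nh3p))

    ch4_pit = 0.0
    for chan in scenario.channels:
        st = states[chan.name]
        vs_before = st.VS_mass
        ch4_pit += methane.pit_ch4_day(st, scenario.ch4)
        ledger.vs_degraded += vs_before - st.VS_mass
    ch4_enteric = methane.enteric_ch4_day(headcount, scenario.ch4)
    return {
        "nh3_pit_kg": pit_kg,
        "nh3_floor_kg": floor_kg,
        "nh3_total_kg": pit_kg + floor_kg,
        "ch4_pit_kg": ch4_pit,
        "ch4_enteric_kg": ch4_enteric,
        "ch4_total_kg": ch4_pit + ch4_enteric,
    }


def _require_weather(weather: pd.DataFrame, n_needed: int) -> None:
    if len(weather) < n_needed:
        raise ValueError(
            f"weather series has {len(weather)} days but the simulation "
            f"calendar needs {n_needed}"
        )


def run_growing_period(
    scenario: Scenario,
    weather: pd.DataFrame,
    start_offset: int = 0,
    length: int | None = None,
    gp_index: int = 0,
    states: dict[str, PitState] | None = None,
    ledger: Ledger | None = None,
) -> SimResult:
    """Simulate one growing period.

    ``weather`` must cover days ``start_offset .. start_offset+length-1``
    (columns ``T_out_C``, ``RH_out_pct``).  ``states`` carries pit content
    in from a previous period (fresh empty pits by default).  The run is
    deterministic given its inputs.
    """
    length = scenario.period_days if length is None else int(length)
    _require_weather(weather, start_offset + length)
    states = _fresh_states(scenario) if states is None else states
    ledger = Ledger() if ledger is None else ledger

    traj = build_trajectory(
        scenario.start_weight_kg,
        scenario.end_weight_kg,
        length,
        scenario.total_feed_kg,
        scenario.total_water_L,
    )
    t_out = weather["T_out_C"].to_numpy()
    rh_out = weather["RH_out_pct"].to_numpy()
    n = scenario.n_places
    rows = []
    for d in range(length):
        abs_day = start_offset + d
        clim = indoor_climate(t_out[abs_day], rh_out[abs_day], scenario.climate)
        for st in states.values():
            st.manure_T = clim.manure_T

        puddle_tan = 0.0
        exc = None
        if n > 0:
            feed = float(traj.daily_feed[d])
            water = float(traj.daily_water[d])
            gain = max(float(traj.daily_gain[d]), 0.0)
            wetted = scenario.solid_floor_area * scenario.fouled_fraction_solid
            evap = (
                floor_evaporation(
                    wetted, clim.room_T, clim.room_RH, scenario.excretion.evap_rate_ref
                )
                / n
            )
            exc = excrete_day(feed, water, gain, scenario.diet, scenario.excretion, evap)
            urine_L = scenario.urine_water_frac * water
            if urine_L > 0:
                conc_kg_m3 = (
                    exc.TAN_potential * scenario.urea_hydrolysis_frac / urine_L * 1000.0
                )
                puddle_tan = conc_kg_m3 / ammonia.KG_N_PER_MOL
            for chan in scenario.channels:
                sched = chan.schedule
                vol = (
                    exc.slurry_mass * n * chan.manure_fraction
                    + sched.dilution_water * n
                ) / 1000.0
                vs = exc.OM_exc * n * chan.manure_fraction
                tan = exc.TAN_potential * n * chan.manure_fraction
                st = states[chan.name]
                st.volume += vol
                st.VS_deg += vs * scenario.ch4.VS_d_frac
                st.VS_nondeg += vs * (1.0 - scenario.ch4.VS_d_frac)
                st.TAN_mass += tan
                ledger.volume_in += vol
                ledger.vs_in += vs
                ledger.tan_in += tan

        em = _emission_day(scenario, states, clim, puddle_tan, n, ledger)

        removed_vol = 0.0
        for chan in scenario.channels:
            states[chan.name], rem = apply_removal(
                states[chan.name],
                chan.geometry,
                chan.schedule,
                d + 1,
                chan.n_units,
                period_length=length,
            )
            removed_vol += rem.volume
            ledger.volume_removed += rem.volume
            ledger.vs_removed += rem.VS
            ledger.tan_removed += rem.TAN

        first = scenario.channels[0]
        rows.append(
            {
                "day": abs_day,
                "gp": gp_index,
                "day_of_gp": d + 1,
                "headcount": n,
                "weight_kg": float(traj.daily_weight[d]) if n > 0 else np.nan,
                "feed_kg": float(traj.daily_feed[d]) if n > 0 else 0.0,
                "water_L": float(traj.daily_water[d]) if n > 0 else 0.0,
                "slurry_kg_per_pig": exc.slurry_mass if exc else 0.0,
                "pit_volume_m3": sum(s.volume for s in states.values()),
                "pit_height_m": height_from_volume(
                    first.geometry, states[first.name].volume / first.n_units
                ),
                "removed_volume_m3": removed_vol,
                "outside_T_C": clim.outside_T,
                "room_T_C": clim.room_T,
                "manure_T_C": clim.manure_T,
                **em,
            }
        )
    return SimResult(pd.DataFrame(rows), states, ledger, scenario)


def run_year(scenario: Scenario, weather: pd.DataFrame) -> SimResult:
    """Simulate the full growing-period calendar of one production year.

    Pit state carries across periods; on vacancy days between periods the
    room holds no pigs but stored manure keeps emitting.
    """
    calendar = scenario.gp_calendar
    n_needed = calendar[-1][0] + calendar[-1][1]
    _require_weather(weather, n_needed)
    t_out = weather["T_out_C"].to_numpy()
    rh_out = weather["RH_out_pct"].to_numpy()

    states = _fresh_states(scenario)
    ledger = Ledger()
    frames = []
    prev_end = 0
    for gp_index, (start, length) in enumerate(calendar):
        for abs_day in range(prev_end, start):  # vacancy days
            clim = indoor_climate(t_out[abs_day], rh_out[abs_day], scenario.climate)
            for st in states.values():
                st.manure_T = clim.manure_T
            em = _emission_day(scenario, states, clim, 0.0, 0, ledger)
            first = scenario.channels[0]
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "day": abs_day,
                            "gp": -1,
                            "day_of_gp": 0,
                            "headcount": 0,
                            "weight_kg": np.nan,
                            "feed_kg": 0.0,
                            "water_L": 0.0,
                            "slurry_kg_per_pig": 0.0,
                            "pit_volume_m3": sum(s.volume for s in states.values()),
                            "pit_height_m": height_from_volume(
                                first.geometry,
                                states[first.name].volume / first.n_units,
                            ),
                            "removed_volume_m3": 0.0,
                            "outside_T_C": clim.outside_T,
                            "room_T_C": clim.room_T,
                            "manure_T_C": clim.manure_T,
                            **em,
                        }
                    ]
                )
            )
        res = run_growing_period(
            scenario, weather, start, length, gp_index, states, ledger
        )
        frames.append(res.daily)
        states, ledger = res.states, res.ledger
        prev_end = start + length
    daily = pd.concat(frames, ignore_index=True)
    return SimResult(daily, states, ledger, scenario)


def annualize(
    daily_emission_kg: np.ndarray | pd.Series,
    headcount: float,
    vacancy: float = 0.03,
) -> float:
    """Annual emission per pig place (kg/yr/place) from a daily room series:
    mean daily emission x 365 / headcount x (1 - vacancy)."""
    arr = np.asarray(daily_emission_kg, dtype=float)
    if arr.size == 0:
        raise ValueError("empty emission series")
    if headcount <= 0:
        raise ValueError(f"headcount must be > 0, got {headcount}")
    return float(arr.mean() * 365.0 / headcount * (1.0 - vacancy))


def annualize_outputs(result: SimResult) -> dict[str, float]:
    """Annualized per-pig-place emissions of a simulation, by gas and source."""
    sc = result.scenario
    df = result.daily
    out = {}
    for col in (
        "nh3_pit_kg",
        "nh3_floor_kg",
        "nh3_total_kg",
        "ch4_pit_kg",
        "ch4_enteric_kg",
        "ch4_total_kg",
    ):
        out[col.replace("_kg", "_kg_yr_place")] = annualize(
            df[col], sc.n_places, sc.vacancy
        )
    return out
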