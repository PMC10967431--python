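"""Methane production from stored slurry and enteric fermentation.

The specific methanogenesis rate of slurry follows an Arrhenius law on
volatile solids (VS), with the slowly degradable pool contributing at 1%
of the weight of the fast pool:

    F_t = (VS_d + 0.01 * VS_nd) * exp(lnA - Ea / (R * T))

in g CH4 per kg VS per hour, with T the manure temperature in kelvin.
Daily pit emission is F_t applied to the stored VS mass, so emission
scales linearly with the stored manure volume at fixed composition.
Enteric methane from the pigs themselves is a constant per-head rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .housing import PitState

__all__ = [
    "MethaneParams",
    "specific_ch4_rate",
    "pit_ch4_day",
    "enteric_ch4_day",
    "CARBON_FRAC_CH4",
]

#: kg C per kg CH4 (12/16): converts emitted CH4 mass to VS carbon removed.
CARBON_FRAC_CH4 = 12.0 / 16.0

CELSIUS_TO_K = 273.15


@dataclass(frozen=True)
class MethaneParams:
    """Arrhenius parameters for slurry methanogenesis plus the enteric rate.

    ``VS_d_frac`` splits fresh VS into fast/slowly degradable pools;
    ``lnA`` (g CH4 / kg VS / h) and ``Ea`` (kJ/mol) are literature values
    for pig slurry; ``R`` is the gas constant in kJ/(mol K).
    ``deplete_pool`` removes emitted CH4 carbon from the fast pool.
    """

    VS_d_frac: float = 0.83
    lnA: float = 31.3
    Ea: float = 81.0
    R: float = 0.0083145
    enteric_rate: float = 1.5  # kg CH4 per pig per year
    deplete_pool: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.VS_d_frac <= 1.0:
            raise ValueError(f"VS_d_frac must be in [0, 1], got {self.VS_d_frac}")
        if self.Ea <= 0:
            raise ValueError(f"Ea must be > 0, got {self.Ea}")


def specific_ch4_rate(params: MethaneParams, T: float) -> float:
    """Specific methane production rate (g CH4 / kg VS / h) at ``T`` (K),
    for slurry whose VS carries the default degradable split."""
    if T <= 0:
        raise ValueError("T must be > 0 K")
    weight = params.VS_d_frac + 0.01 * (1.0 - params.VS_d_frac)
    return weight * math.exp(params.lnA - params.Ea / (params.R * T))


def _arrhenius(params: MethaneParams, T: float) -> float:
    return math.exp(params.lnA - params.Ea / (params.R * T))


def pit_ch4_day(state: PitState, params: MethaneParams = MethaneParams()) -> float:
    """One day's methane emission (kg CH4) from a pit channel.

    Applies the Arrhenius rate to the channel's actual VS pools (the
    slowly degradable pool at 1% weight) at the manure temperature, and
    optionally depletes the fast pool by the emitted CH4 carbon.
    """
    if state.VS_mass <= 0:
        return 0.0
    rate = _arrhenius(params, state.manure_T + CELSIUS_TO_K)  # g/kg VS/h
    effective_vs = state.VS_deg + 0.01 * state.VS_nondeg
    emission_kg = rate * effective_vs * 24.0 / 1000.0
    if params.deplete_pool:
        loss = min(emission_kg * CARBON_FRAC_CH4, state.VS_deg)
        state.VS_deg -= loss
    return emission_kg


def enteric_ch4_day(headcount: float, params: MethaneParams = MethaneParams()) -> float:
    """Enteric (hindgut) methane of the herd, kg CH4 per day."""
    if headcount < 0:
        raise ValueError("headcount must be >= 0")
    return headcount * params.enteric_rate / 365.0
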