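# Methods

This note documents the model equations, the parameter choices behind the
shipped defaults, what the synthetic inputs emulate, and the numerical
decisions — in enough detail that a user can judge what a simulation (or a
passing test) does and does not show.

## Model structure

One simulated day runs, in fixed order: indoor climate → growth/intake →
excretion → pit influx → emission fluxes (NH₃ per surface, CH₄ per channel
+ enteric) → end-of-day removal. A production year chains four growing
periods (stocking 8 Oct, 21 Jan, 27 Apr, 27 Jul) with pit state carried
across the vacancy days between them; empty-room days keep emitting from
stored manure but add nothing. The pen is one average pig multiplied by
headcount — no between-animal variation.

## Growth and intake

Weight, cumulative feed and cumulative water follow the Gompertz form
`A + M·exp(−exp(−B(t − t*)))` with breed-default shape parameters
(weight: A=0, B=0.0146 d⁻¹, t*=110.4 d; feed: A=−41.9, B=0.0111,
t*=154.7; water: A=−149, B=0.0103, t*=147.4; asymptotes 164.2 kg, 608 kg,
1432 L). Only the asymptote is refitted per period: weight to the
(start, end) pair, feed/water so the cumulative increase equals the input
totals, with the entry age taken from the weight fit. The curve is
analytically invertible in `t`, so the endpoint fit reduces to a 1-D
Brent root-find on the asymptote (residual < 10⁻⁸). The asymptote is
capped at 3× the breed default: without the cap, an arbitrarily fast
endpoint pair can always be "fitted" by a multi-tonne mature weight, so
the cap is what turns biologically absurd inputs into an error. The
negative feed/water offsets can make very early cumulative values
negative; daily intakes are first differences and are clamped at ≥ 0.

## Excretion defaults

Unpublished empirical relations are replaced by configurable
parameterizations; defaults were chosen once from standard pig-nutrition
values and magnitude checks against typical Dutch fattening rooms
(slurry 4–5 kg pig⁻¹ d⁻¹, slurry TAN 3–6 kg N m⁻³, VS 60–110 g kg⁻¹):

| parameter | default | basis |
|---|---|---|
| diet DM / CP / ash | 0.88 / 0.165 / 0.055 | typical finisher diet |
| digestibility OM / CP | 0.80 / 0.80 | commercial feeds |
| ash retention | 0.35 | mineral retention in growing pigs |
| body protein per kg gain | 0.16 (16 % N) | pig growth composition |
| urea fraction of urinary N | 0.75 | pig urine composition |
| urinary solids per kg urea-N | 2.14 (70 % organic) | urea stoichiometry 60/28 |
| gas correction | 5 % of OM + 0.733 kg CO₂/kg urea-N | hydrolysis losses |
| metabolic water | 0.4 L per kg digested DM | oxidation water |
| body water retention | 0.70 L per kg gain | body composition |
| respiratory loss | 25 % of liquid intake | house vapour balance |
| floor evaporation | 0.05 L m⁻² h⁻¹ at 20 °C/60 % RH, scaled by saturation deficit (Magnus) | evaporation from wetted concrete |
| total feed / water per pig | 240 kg / 560 L per period | feed conversion ≈ 2.6, water:feed ≈ 2.3 |

Nitrogen is conserved exactly (intake = faecal + urinary + retained)
before a defensive non-negativity clamp that only engages for
inconsistent inputs.

## Pit geometry, removal, climate

Channels are trapezoidal prisms (0/1/2 sloped walls); volume↔height is a
quadratic with closed-form positive root, and the emitting surface grows
from bottom to top width with the manure level (straight walls always
expose the full footprint). Removal empties to a residual height, taking
VS and TAN in proportion to volume (well-mixed slurry; depth
stratification is a known omission). Presets: LS pit 5.10 × 1.88 × 1.20 m
straight, 45-day interval, 5 cm residual; SS back channel 5.22 × 1.30 ×
0.50 m with two 45° walls, flushed daily to a 2 cm film, receiving 80 %
of the manure; SS front water channel 5.22 × 1.29 × 0.50 m with one
sloped wall (the outer room wall is vertical), receiving 20 % of the
manure plus 0.75 L pig⁻¹ d⁻¹ dilution water (spoiled drinking + cleaning
water), emptied on the last day of each period. A two-sloped-wall front
channel with more dilution would overflow before the once-per-period
emptying, which fixed these two choices; both are configurable.

Indoor climate: room T = max(20 °C, outside + 3 °C) — mechanically
ventilated rooms sit at the setpoint in winter and track outside air in
summer; manure T = 0.88 × room T (slurry sits below air temperature, as
field measurements of deep pits show); room RH = 0.75 × outside RH
(clipped 30–90 %); air velocity over emitting surfaces constant at
0.15 m s⁻¹. All coefficients are config fields.

## Ammonia

Flux per surface `E = k·A·f·[TAN]/H` with
`k = 2×10⁻³·(v/0.15)^0.8·(T/293.15)` m s⁻¹ (boundary-layer velocity
exponent; reference value set so pit fluxes land in the observed
kg yr⁻¹ place⁻¹ range), `pKa(T) = 0.09018 + 2729.92/T`,
`H = 1431·1.053^(293−T)`. Pit TAN accumulates from urinary urea-N
(hydrolysis assumed complete within a day — urease is in excess on fouled
surfaces) and is depleted by volatilization and removal. Surface pH =
bulk slurry pH (measured input, default 7.0) + 0.5 offset — the offset
stands in for an unpublished bulk→surface regression and is the most
uncertain NH₃ parameter. Floor puddles: fouled fractions 0.10 (solid) /
0.05 / 0.05 (concrete, metal slats), puddle TAN from urea-N divided by
urine volume (55 % of drinking water), puddle pH 7.8 after hydrolysis.
Fouled concrete slats emit per m² like the solid floor; pig and
pen-partition soiling is folded into the solid-floor term. Floor-puddle
N is not debited from the pit ledger (urine is counted once into the pit
and the puddle term is a source-strength model); at ~0.5–0.8 kg NH₃
place⁻¹ yr⁻¹ the double count is ≈ 2 % of excreted N.

## Methane

`F_t = (VS_d + 0.01·VS_nd)·exp(lnA − E_a/(R·T))` in g CH₄ kg⁻¹ VS h⁻¹
(VS_d = 0.83, lnA = 31.3, E_a = 81.0 kJ mol⁻¹, R = 0.0083145), applied to
the channel's VS pools at manure temperature — manure rather than air
temperature because methanogenesis happens in the slurry. Fresh VS is
split 0.83/0.17 into fast/slow pools; emitted CH₄ carbon (12/16 of mass)
is debited from the fast pool (config flag; the effect is small at
45-day storage). Enteric methane is 1.5 kg pig⁻¹ yr⁻¹ spread uniformly
over occupied days. No lag-phase kinetics: inoculum enters only through
residual manure, which is why the LS residual height (5 cm default, not
reported for the real rooms) matters for the emission level.

## Annualization and validation

Annual per-pig-place emission = pooled daily mean × 365 / places ×
(1 − 0.03 vacancy). Pooling daily data (rather than averaging per-period
figures) was an open choice; vacancy days therefore already dilute the
mean and the 3 % factor is applied on top, mirroring the reference
method's convention. Reference-method emission:
`(C_out − C_in)·ρ·V·24·365/10⁶` with ρ = 0.667 (CH₄) / 0.71 (NH₃);
negative concentration differences are retained with a warning. MAE,
RMSE and R² are computed on whatever paired series is supplied; R²
raises on a zero-variance measured series.

## Synthetic weather

`weather_fixture` draws T = 10.5 + 7·sin(seasonal) + N(0, 3²) °C and
RH = 80 − 10·sin(seasonal) + N(0, 5²) % (clipped), phased so the maximum
falls in late July and day 0 is 8 October. It reproduces the Dutch
seasonal cycle and day-to-day scatter but not autocorrelated weather
(fronts, heat waves), diurnal cycles, or ventilation-driven indoor
dynamics. Passing directional tests on this fixture therefore shows the
model's mechanisms (storage time, geometry, temperature response) behave
correctly — not that absolute levels on a specific farm would be
reproduced, which also depends on measured pH, fouling and feed records.

## Problem sizes and determinism

A full paired LS/SS year (2 × 378 daily steps) runs in well under a
second; tests and the acceptance script use exactly these sizes. All
stochastic inputs flow through a single integer seed; simulations are
bitwise deterministic given scenario + weather.

## Known limitations

Well-mixed pits (no depth stratification of T or VS); constant surface
air velocity; no hourly urination dynamics; pH is an input, not
predicted; no outside-storage emissions after removal; one average pig
per pen. These mirror the stated scope: the model ranks management
systems and predicts seasonal/within-period dynamics, not absolute
single-farm levels without farm records.
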