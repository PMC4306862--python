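# Methods

## Model

`puffbox` implements a single-room mass-balance ("box") model for an
intermittent indoor point source. The classic one-box model assumes the
whole room is instantly well mixed, which systematically underestimates the
near-field peak a bystander experiences shortly after each emission. The
model here instead applies the well-mixed assumption at *low scale*: each
exhalation fills an expanding cuboid that is internally uniform, and only
when the cuboid has grown to the room volume does the model coincide with
the ordinary one-box description.

A single puff emitted at time 0 produces, at an observer a distance `d`
from the source:

- **Phase 1 — not yet exposed.** `C = 0` for `t < t_arrival`, where
  `t_arrival = min(t_front, t_fill)`: `t_front` solves
  `L0/2 + s_x t = d` (the cuboid face nearest the observer starts half an
  edge from the source) and `t_fill` is when the cuboid volume reaches the
  room volume. Taking the minimum avoids the geometric contradiction of a
  "full" room with an unreached observer: once the room is full, everyone
  in it is exposed.
- **Phases 2–3 — dilution.** `C(t) = M / V(t)` with
  `V(t) = min(Π_i (L0 + 2 s_i t), V_room)`. The cuboid volume is a cubic
  polynomial in `t`, strictly increasing whenever any front speed is
  positive, so fill and onset times are unique roots (found with
  `numpy.roots`; the smallest non-negative real root is taken).
- **Phase 4 — removal.** From the extraction-onset time `t_init` (when the
  aerosol fills the onset fraction, 0.8 by default, of the room) the
  concentration acquires the factor `exp(−a (t − t_init))` with
  `a = (Q_extract + Q_dep)/V_room`. After `t_fill` the dilution factor
  freezes at `M/V_room` and only the exponential remains — exactly the
  one-box solution. The profile is continuous everywhere after arrival.

The recycling term in `Q_extract = (ACH/60) V_room (1 − RRA/100)` treats
the recycled-air rate `RRA` as a percentage reducing the effective
extraction flow; `RRA = 0` leaves the full ventilation flow
`ACH·V_room/60`, and `RRA = 100` (closed-loop recirculation) removes
nothing.

Puffs superpose linearly: the room volume is constant, removal is
first-order, and re-emission by the bystander is neglected, so every
concentration, exposure integral and dose is exactly homogeneous of degree
one in the emitted mass. This linearity is load-bearing — several headline
results (the 3-fold exposure scaling, the 66.7 % emission impact in the
sweep) follow from it identically, independent of every other parameter.

## Parameters

| Parameter | Units | Default | Notes |
|---|---|---|---|
| inhaled mass per puff | µg | 60 (office) | upper-bound nicotine delivery per puff |
| retention rate | % | 50 (office), 0 (machine) | fraction kept by the user's body |
| exhaled puff volume | L | 0.5 | typical single exhalation; affects only the brief pre-arrival geometry, since every built-in scenario fills the room within minutes |
| front speed `s` | m/min | 0.6 (office), 2 (chamber) | fills 37.5 m³ in ~3 min, 39 m³ in ~1 min respectively |
| deposition velocity `v_d` | m/min | 0.06 | net flux to surfaces / air concentration |
| `ACH` | 1/h | 1.33 (office) | 50 m³/h in the 37.5 m³ office |
| `RRA` | % | 0 | recycled fraction of extracted air |
| deposition surface `S_dep` | m² | box surface | see below |
| extraction-onset fraction | — | 0.8 | fill fraction at which removal starts |
| bystander distance | m | 2 (office), 1 (chamber) | along the first propagation axis |
| breathing rate | L/min | 8–16 | resting to light activity |
| reporting grid step | min | 0.01 | see numerics |

**Deposition surface.** The deposition flow needs a surface area that room
descriptions rarely supply. The default is the full interior surface of a
rectangular box of the given volume: floor + ceiling + four walls, with a
2.5 m height and a square floor plan unless the floor area is given
(68.7 m² for the 15 m² office; 70.7 m² for the 39 m³ chamber). It is an
explicit field on `Room`, so an effective (smaller) surface — e.g. floor
only, for a heavy, fast-settling aerosol — can be substituted directly.

**Removal onset.** Extraction and deposition both switch on at the 80 %
fill time of each puff's cuboid. A consequence worth knowing: slower
propagation delays removal onset, which can slightly *raise* long-window
average concentrations even though it delays the bystander's first
exposure. Setting the onset fraction near zero makes removal act from the
start of each puff instead.

## Scenario builders

- `office_day_scenario`: 8-h working day (t = 0–480 min), one puff every
  5 min except during the 60-min lunch break (t = 180–240) — 84 puffs of
  30 µg — bystander present outside lunch (420 min). Reports the peak, the
  8-h average, the exposure integral and the inhaled dose at 8 and
  16 L/min.
- `machine_release_scenario`: a smoking machine in a 39 m³ chamber emits
  `n` puffs at 10-s spacing, repeating the pattern once at t = 30 min, with
  0 % retention; the response is the 1-h average at 1 m. The "high"
  emission pattern uses 15 puffs (the machine-study description is
  ambiguous between 14 and 15; 15 is the default and `n_puffs` is a free
  argument).
- `one_at_a_time`: single-puff sensitivity runs around a mid-level base
  (distance 1.5 m, 20 µg exhaled, 1 m/min, v_d 0.03 m/min, ACH 2,
  1-h window).
- `parameter_sweep` / `parameter_impact`: the 3^5 factorial design over
  distance (1/1.5/2 m), front speed (0.5/1/2 m/min), exhaled mass
  (10/20/30 µg), ACH (1/2/3 h⁻¹) and v_d (0.01/0.03/0.06 m/min), response
  = average 8-h bystander concentration; the impact of a parameter is the
  difference between its high-group and low-group maxima relative to the
  larger of the two. Relative-to-the-larger is chosen so that a pure ×3
  emission scaling reads as +66.7 % rather than +200 %, matching how such
  factorial impacts are customarily quoted.

## Numerics

- All profiles are evaluated per phase in closed form; there is no ODE
  solver and no randomness anywhere.
- Integrals (exposure, averages, doses) use trapezoidal quadrature on the
  reporting grid, with window endpoints interpolated onto the grid so
  integrals are exactly additive over adjacent windows. Profiles are
  piecewise smooth exponentials, so the trapezoid rule converges fast:
  refining the grid from 0.01 to 0.002 min moves the 8-h office exposure
  integral by well under 0.2 %.
- Default grid step 0.01 min everywhere; the full 243-scenario sweep at
  that resolution runs in about half a minute on one CPU. Structural tests
  use coarser grids (0.1–1 min) since exact linearity and level-pattern
  properties hold at any resolution.
- Degenerate inputs return well-defined values rather than errors: zero
  front speeds leave the aerosol volume constant (arrival time +inf for a
  distant observer — a sentinel, not an exception), zero breathing gives
  zero dose, an empty schedule gives an all-zero series. Genuinely invalid
  inputs (negative masses, retention outside 0–100 %, inverted windows)
  raise `ValueError`.
- CSV output uses six significant digits, enough for stable golden-file
  diffs while keeping files small.

## What the built-in scenarios do and do not emulate

The scenario builders encode idealised study conditions: perfectly periodic
puffing, a stationary user and bystander, constant ventilation, a single
constituent treated as a passive scalar. Real exhaled aerosol undergoes
coagulation, droplet evaporation and gas-particle partitioning, all of
which change the effective deposition velocity over time; surfaces can also
re-emit sorbed material. None of that is modelled — removal is a single
constant first-order sink — so passing tests demonstrate internal
consistency of the mass balance and faithful reproduction of the idealised
scenarios, not predictive accuracy for a specific real room. The model is
also strictly single-zone: coupled multi-room buildings would require a
compartment model with inter-zone flows.

## Known limitations

- The exhaled puff volume and the deposition surface are defaults, not
  measurements; both are exposed as configuration and the deposition
  surface in particular sets the absolute scale of long-window averages.
- Concentration is resolved along the source–observer axis only; there is
  no full spatial field.
- Deposition-onset timing couples propagation speed to removal (see above),
  which makes long-window averages only weakly — and sometimes inversely —
  sensitive to propagation speed and distance.
- Multiple simultaneous users are supported by linear superposition of
  schedules but no dedicated builder is provided.
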