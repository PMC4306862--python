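"""Indoor-air-quality box model for intermittent exhaled-aerosol sources.

``puffbox`` predicts the airborne concentration of an exhaled aerosol
constituent (nicotine is the canonical example) at a bystander's position in
a single room, following e-cigarette use.  The model is deliberately simple
and fully closed-form:

1.  **Emission** — each puff releases a constituent mass equal to the mass
    inhaled minus the fraction retained by the user; the exhaled air volume
    sets the initial concentration.
2.  **Propagation / dilution** — the exhaled volume is idealised as a cube
    whose edges grow at fixed front speeds, so the aerosol occupies an
    expanding cuboid that is internally well mixed (a "low-scale" well-mixed
    assumption).  The cuboid volume is capped at the room volume.
3.  **Removal** — once the aerosol fills a set fraction of the room
    (80 % by default), ventilation extraction and surface deposition act as
    first-order sinks, giving exponential decay with rate
    ``a = (Q_extract + Q_dep) / V_room``.
4.  **Exposure** — puffs superpose linearly; exposure is the time integral
    of concentration at the observer, and inhaled dose is that integral
    times the breathing flow over the presence intervals.

Everything is deterministic: identical inputs give identical outputs, with
no random number generator anywhere in the package.

Units throughout: minutes, metres, cubic metres, micrograms; breathing
rates are accepted in L/min and converted internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    # domain types
    "Constituent",
    "Puff",
    "Room",
    "TransportParams",
    "Observer",
    "RemovalRates",
    "PuffSchedule",
    "ConcentrationSeries",
    "ExposureSummary",
    "ScenarioSpec",
    # puff physics
    "exhaled_mass",
    "initial_concentration",
    "aerosol_volume",
    "removal_rates",
    "arrival_time",
    "fill_time",
    "extraction_start_time",
    "single_puff_concentration",
    # exposure accounting
    "superpose",
    "exposure_integral",
    "peak_concentration",
    "average_concentration",
    "bystander_dose",
    "user_total_inhaled",
    # scenario builders
    "box_surface_area",
    "office_day_scenario",
    "machine_release_scenario",
    "one_at_a_time",
    "parameter_sweep",
    "parameter_impact",
    "SWEEP_LEVELS",
    # configuration
    "RunConfig",
    "load_config",
    "run_cli",
]

logger = logging.getLogger("puffbox")

# ---------------------------------------------------------------------------
# Package-wide defaults
# ---------------------------------------------------------------------------

#: Default volume of air exhaled in a single puff (m^3).  A typical single
#: exhalation is ~0.5 L; this only affects the brief pre-arrival geometry
#: because every realistic scenario fills the room within a few minutes.
DEFAULT_EXHALED_VOLUME = 0.5e-3

#: Default room height (m) used to derive a deposition surface when none is
#: supplied: a rectangular box with a square floor plan of the given volume.
DEFAULT_ROOM_HEIGHT = 2.5

#: Fraction of the room volume the aerosol must fill before extraction and
#: deposition start to act.
DEFAULT_EXTRACTION_START_FRACTION = 0.8

#: Default reporting grid step (min).
DEFAULT_GRID_STEP = 0.01

#: Numeric output format for CSV files: six significant digits gives stable,
#: diff-friendly golden files.
CSV_FLOAT_FORMAT = "%.6g"

_INF = math.inf


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constituent:
    """An aerosol chemical constituent and its per-puff emission behaviour.

    Parameters
    ----------
    name:
        Label, e.g. ``"nicotine"``.
    inhaled_mass_per_puff:
        Mass of the constituent taken in by the user in one puff (µg).
    retention_rate:
        Percentage of the inhaled mass retained by the user's body and not
        exhaled (0–100).  A smoking machine corresponds to 0 % retention.
    """

    name: str
    inhaled_mass_per_puff: float
    retention_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.inhaled_mass_per_puff < 0:
            raise ValueError("inhaled_mass_per_puff must be >= 0")
        if not 0.0 <= self.retention_rate <= 100.0:
            raise ValueError("retention_rate must be in [0, 100]")

    @property
    def exhaled_mass_per_puff(self) -> float:
        """Mass exhaled back into the room per puff (µg)."""
        return exhaled_mass(self.inhaled_mass_per_puff, self.retention_rate)


@dataclass(frozen=True)
class Puff:
    """A single exhalation event.

    ``constituents`` maps constituent name to the exhaled mass (µg) carried
    by this puff.
    """

    time: float
    exhaled_volume: float = DEFAULT_EXHALED_VOLUME
    constituents: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.exhaled_volume <= 0:
            raise ValueError("exhaled_volume must be > 0")
        if self.time < 0:
            raise ValueError("puff time must be >= 0")
        for name, mass in self.constituents:
            if mass < 0:
                raise ValueError(f"exhaled mass of {name!r} must be >= 0")

    def mass_of(self, constituent: "Constituent | str") -> float:
        name = constituent if isinstance(constituent, str) else constituent.name
        for cname, mass in self.constituents:
            if cname == name:
                return mass
        raise KeyError(f"puff carries no constituent named {name!r}")

    @classmethod
    def from_constituent(
        cls,
        time: float,
        constituent: Constituent,
        exhaled_volume: float = DEFAULT_EXHALED_VOLUME,
    ) -> "Puff":
        """Build a puff whose exhaled mass follows the retention balance."""
        return cls(
            time=time,
            exhaled_volume=exhaled_volume,
            constituents=((constituent.name, constituent.exhaled_mass_per_puff),),
        )


@dataclass(frozen=True)
class Room:
    """The enclosure: volume, ventilation and deposition surface.

    ``deposition_surface`` defaults to the total interior surface of a
    rectangular box with the given volume and height (floor + ceiling + four
    walls, square floor plan unless ``floor_area`` is given).
    """

    volume: float
    ach: float
    recycling_rate: float = 0.0
    deposition_surface: float | None = None
    height: float = DEFAULT_ROOM_HEIGHT
    floor_area: float | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("room volume must be > 0")
        if self.ach < 0:
            raise ValueError("ach must be >= 0")
        if not 0.0 <= self.recycling_rate <= 100.0:
            raise ValueError("recycling_rate must be in [0, 100]")
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.deposition_surface is None:
            surface = box_surface_area(self.volume, self.height, self.floor_area)
            object.__setattr__(self, "deposition_surface", surface)
        if self.deposition_surface < 0:
            raise ValueError("deposition_surface must be >= 0")


@dataclass(frozen=True)
class TransportParams:
    """Aerosol transport: propagation front speeds and deposition velocity.

    ``front_speed`` may be an isotropic scalar or a per-axis triple
    (m/min); each cuboid axis grows by twice the front speed because both
    opposite faces advance.  The observer sits along the first axis.
    """

    front_speed: float | tuple[float, float, float]
    deposition_velocity: float = 0.0
    extraction_start_fraction: float = DEFAULT_EXTRACTION_START_FRACTION

    def __post_init__(self) -> None:
        speeds = self.speeds
        if any(s < 0 for s in speeds):
            raise ValueError("front speeds must be >= 0")
        if self.deposition_velocity < 0:
            raise ValueError("deposition_velocity must be >= 0")
        if not 0.0 < self.extraction_start_fraction <= 1.0:
            raise ValueError("extraction_start_fraction must be in (0, 1]")

    @property
    def speeds(self) -> tuple[float, float, float]:
        s = self.front_speed
        if isinstance(s, (int, float)):
            return (float(s),) * 3
        sx, sy, sz = s
        return (float(sx), float(sy), float(sz))


@dataclass(frozen=True)
class Observer:
    """A person at a fixed distance from the source.

    ``presence`` is a tuple of disjoint, ordered ``(start, end)`` intervals
    (min) during which the person is in the room; ``None`` means always
    present.  ``breathing_rate`` is in L/min.
    """

    distance: float
    breathing_rate: float = 0.0
    presence: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if self.breathing_rate < 0:
            raise ValueError("breathing_rate must be >= 0")
        if self.presence is not None:
            last_end = -_INF
            for start, end in self.presence:
                if start >= end:
                    raise ValueError("presence intervals must have start < end")
                if start < last_end:
                    raise ValueError("presence intervals must be disjoint and ordered")
                last_end = end

    @property
    def breathing_flow(self) -> float:
        """Breathing flow in m^3/min."""
        return self.breathing_rate / 1000.0


@dataclass(frozen=True)
class RemovalRates:
    """First-order removal flows and the resulting decay coefficient."""

    q_extract: float
    q_dep: float
    a: float


@dataclass(frozen=True)
class PuffSchedule:
    """An ordered sequence of puffs sharing a constituent set."""

    puffs: tuple[Puff, ...]
    description: str = ""

    def __post_init__(self) -> None:
        times = [p.time for p in self.puffs]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("puff times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.puffs)

    @classmethod
    def regular(
        cls,
        constituent: Constituent,
        times: Iterable[float],
        exhaled_volume: float = DEFAULT_EXHALED_VOLUME,
        description: str = "",
    ) -> "PuffSchedule":
        puffs = tuple(
            Puff.from_constituent(t, constituent, exhaled_volume) for t in times
        )
        return cls(puffs=puffs, description=description)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Constituent concentration versus time at a fixed observer position."""

    times: np.ndarray
    values: np.ndarray
    observer: Observer
    constituent: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "conc_ug_m3": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


@dataclass(frozen=True)
class ExposureSummary:
    """Exposure metrics over a stated window.

    ``exposure_integral`` is the concentration–time integral (µg·min/m³),
    ``peak`` and ``mean`` are µg/m³, and ``inhaled_mass`` (µg) is the dose —
    the exposure integral times the breathing flow over presence.
    """

    exposure_integral: float
    peak: float
    mean: float
    window: tuple[float, float]
    inhaled_mass: float = 0.0

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "metric": [
                    "exposure_integral_ug_min_m3",
                    "peak_ug_m3",
                    "mean_ug_m3",
                    "window_start_min",
                    "window_end_min",
                    "inhaled_mass_ug",
                ],
                "value": [
                    self.exposure_integral,
                    self.peak,
                    self.mean,
                    self.window[0],
                    self.window[1],
                    self.inhaled_mass,
                ],
            }
        )
        frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete simulation scenario: who puffs what, where, and when."""

    room: Room
    transport: TransportParams
    constituent: Constituent
    schedule: PuffSchedule
    observer: Observer
    window: tuple[float, float]

    def __post_init__(self) -> None:
        start, end = self.window
        if start >= end:
            raise ValueError("window must have start < end")


# ---------------------------------------------------------------------------
# Single-puff physics
# ---------------------------------------------------------------------------

def exhaled_mass(inhaled_mass: float, retention_rate: float) -> float:
    """Mass exhaled into the room: inhaled mass minus the retained fraction.

    Parameters are the inhaled mass (µg) and the retention rate (percent,
    0–100).  A 0 % retention (machine-generated aerosol) releases the full
    inhaled mass; 100 % retention releases nothing.
    """
    if inhaled_mass < 0:
        raise ValueError("inhaled_mass must be >= 0")
    if not 0.0 <= retention_rate <= 100.0:
        raise ValueError("retention_rate must be in [0, 100]")
    return inhaled_mass * (1.0 - retention_rate / 100.0)


def initial_concentration(mass: float, exhaled_volume: float) -> float:
    """Concentration in the freshly exhaled air: mass over exhaled volume."""
    if exhaled_volume <= 0:
        raise ValueError("exhaled_volume must be > 0")
    if mass < 0:
        raise ValueError("mass must be >= 0")
    return mass / exhaled_volume


def _edge_lengths(exhaled_volume: float) -> float:
    return exhaled_volume ** (1.0 / 3.0)


def aerosol_volume(
    t, puff: Puff, transport: TransportParams, room: Room
):
    """Volume occupied by the aerosol ``t`` minutes after exhalation (m³).

    The initial cube of edge ``V_exh^(1/3)`` grows into a cuboid whose axis
    ``i`` has length ``L0 + 2 s_i t`` (both faces advance at the front speed
    ``s_i``); the product of the axis lengths is capped at the room volume.
    Accepts scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    L0 = _edge_lengths(puff.exhaled_volume)
    vol = np.ones_like(t_arr)
    for s in transport.speeds:
        vol = vol * (L0 + 2.0 * s * t_arr)
    vol = np.minimum(vol, room.volume)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(vol)
    return vol


def _time_to_volume(
    puff: Puff, transport: TransportParams, target_volume: float
) -> float:
    """Earliest t at which the (uncapped) cuboid volume reaches ``target``.

    The cuboid volume is a cubic polynomial in t, strictly increasing when
    any front speed is positive, so the crossing is unique.  Returns +inf
    when the target is never reached (all speeds zero) and 0 when the
    exhaled volume already meets it.
    """
    if puff.exhaled_volume >= target_volume:
        return 0.0
    speeds = transport.speeds
    if all(s == 0 for s in speeds):
        return _INF
    L0 = _edge_lengths(puff.exhaled_volume)
    poly = np.poly1d([1.0])
    for s in speeds:
        poly = poly * np.poly1d([2.0 * s, L0])
    roots = (poly - target_volume).roots
    real = roots[np.isreal(roots)].real
    candidates = real[real >= 0]
    if candidates.size == 0:  # pragma: no cover - monotone growth guarantees a root
        return _INF
    return float(candidates.min())


def fill_time(puff: Puff, transport: TransportParams, room: Room) -> float:
    """Earliest t at which the aerosol fills the whole room (min)."""
    return _time_to_volume(puff, transport, room.volume)


def extraction_start_time(
    puff: Puff, transport: TransportParams, room: Room
) -> float:
    """Earliest t at which the aerosol fills the extraction-start fraction
    of the room — the moment ventilation and deposition switch on."""
    target = transport.extraction_start_fraction * room.volume
    return _time_to_volume(puff, transport, target)


def removal_rates(room: Room, transport: TransportParams) -> RemovalRates:
    """Extraction and deposition flows and the first-order decay rate.

    ``Q_extract = (ACH/60) * V_room * (1 - RRA/100)`` (m³/min): the
    ventilation flow, reduced by the recycled fraction of extracted air.
    ``Q_dep = S_dep * v_d`` (m³/min): the equivalent deposition flow.
    ``a = (Q_extract + Q_dep) / V_room`` (1/min).
    """
    q_extract = (room.ach / 60.0) * room.volume * (1.0 - room.recycling_rate / 100.0)
    q_dep = room.deposition_surface * transport.deposition_velocity
    a = (q_extract + q_dep) / room.volume
    return RemovalRates(q_extract=q_extract, q_dep=q_dep, a=a)


def arrival_time(
    puff: Puff, transport: TransportParams, room: Room, observer: Observer
) -> float:
    """Time after exhalation at which the observer is first exposed (min).

    The observer is reached either when the propagation front travels the
    source–observer distance (``L0/2 + s*t = d`` along the observer axis) or
    when the aerosol fills the whole room, whichever comes first — once the
    room is full, the well-mixed assumption exposes every position.
    Returns +inf if neither ever happens.
    """
    L0 = _edge_lengths(puff.exhaled_volume)
    d = observer.distance
    s_axis = transport.speeds[0]
    if d <= L0 / 2.0:
        t_front = 0.0
    elif s_axis > 0:
        t_front = (d - L0 / 2.0) / s_axis
    else:
        t_front = _INF
    return min(t_front, fill_time(puff, transport, room))


def _puff_kernel(
    tau: np.ndarray,
    mass: float,
    puff: Puff,
    room: Room,
    transport: TransportParams,
    observer: Observer,
) -> np.ndarray:
    """Concentration at the observer, tau minutes after one exhalation.

    Four phases: (1) zero before the aerosol arrives; (2–3) pure dilution
    ``M / V(tau)`` while the cuboid expands; from the extraction-start time
    onward the same dilution times ``exp(-a (tau - t_init))``; after the
    room is full the dilution factor freezes at ``M / V_room`` and only the
    exponential decay remains.  Continuous for tau >= arrival.
    """
    arrival = arrival_time(puff, transport, room, observer)
    t_init = extraction_start_time(puff, transport, room)
    a = removal_rates(room, transport).a
    conc = np.zeros_like(tau)
    live = tau >= arrival
    if arrival == _INF or not np.any(live):
        return conc
    vol = aerosol_volume(tau[live], puff, transport, room)
    c = mass / vol
    if math.isfinite(t_init) and a > 0:
        decaying = tau[live] >= t_init
        c = np.where(decaying, c * np.exp(-a * (tau[live] - t_init)), c)
    conc[live] = c
    return conc


def single_puff_concentration(
    t,
    puff: Puff,
    constituent: Constituent | str,
    room: Room,
    transport: TransportParams,
    observer: Observer,
):
    """Constituent concentration (µg/m³) at the observer at absolute time t.

    ``t`` (scalar or array, min since simulation start) must not precede the
    puff's emission time.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < puff.time):
        raise ValueError("t must be >= the puff emission time")
    mass = puff.mass_of(constituent)
    conc = _puff_kernel(
        np.atleast_1d(t_arr - puff.time), mass, puff, room, transport, observer
    )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(conc[0])
    return conc


# ---------------------------------------------------------------------------
# Superposition and exposure accounting
# ---------------------------------------------------------------------------

def superpose(
    schedule: PuffSchedule,
    constituent: Constituent | str,
    room: Room,
    transport: TransportParams,
    observer: Observer,
    grid: np.ndarray,
) -> ConcentrationSeries:
    """Total concentration on ``grid``: the linear sum over all puffs.

    Each puff contributes its single-puff profile shifted to its emission
    time; puffs not yet emitted contribute zero.  An empty schedule yields
    an all-zero series.
    """
    grid = np.asarray(grid, dtype=float)
    name = constituent if isinstance(constituent, str) else constituent.name
    total = np.zeros_like(grid)
    for puff in schedule.puffs:
        mass = puff.mass_of(name)
        if mass == 0:
            continue
        tau = grid - puff.time
        emitted = tau >= 0
        if not np.any(emitted):
            continue
        total[emitted] += _puff_kernel(
            tau[emitted], mass, puff, room, transport, observer
        )
    return ConcentrationSeries(
        times=grid, values=total, observer=observer, constituent=name
    )


def _window_slice(
    series: ConcentrationSeries, window: tuple[float, float] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Grid restricted to a window, with interpolated endpoint samples."""
    if window is None:
        return series.times, series.values
    start, end = window
    if start > end:
        raise ValueError("window must have start <= end")
    t, v = series.times, series.values
    if start < t[0] or end > t[-1]:
        raise ValueError("window must lie within the series grid")
    inside = (t > start) & (t < end)
    times = np.concatenate(([start], t[inside], [end]))
    values = np.concatenate(
        ([np.interp(start, t, v)], v[inside], [np.interp(end, t, v)])
    )
    return times, values


def exposure_integral(
    series: ConcentrationSeries, window: tuple[float, float] | None = None
) -> float:
    """Concentration–time integral over the window (µg·min/m³).

    Trapezoidal quadrature on the reporting grid; additive over disjoint
    windows.
    """
    times, values = _window_slice(series, window)
    return float(np.trapezoid(values, times))


def peak_concentration(
    series: ConcentrationSeries, window: tuple[float, float] | None = None
) -> float:
    """Maximum concentration over the window (µg/m³)."""
    times, values = _window_slice(series, window)
    if times.size == 0:
        raise ValueError("empty window")
    return float(values.max())


def average_concentration(
    series: ConcentrationSeries, window: tuple[float, float] | None = None
) -> float:
    """Time-average concentration over the window (µg/m³)."""
    times, values = _window_slice(series, window)
    length = times[-1] - times[0]
    if length <= 0:
        raise ValueError("window must have positive length")
    return float(np.trapezoid(values, times) / length)


def _presence_intervals(
    series: ConcentrationSeries, observer: Observer
) -> tuple[tuple[float, float], ...]:
    if observer.presence is None:
        return ((float(series.times[0]), float(series.times[-1])),)
    return observer.presence


def bystander_dose(series: ConcentrationSeries, observer: Observer) -> float:
    """Total constituent mass inhaled by the bystander (µg).

    Integrates concentration times the breathing flow over the presence
    intervals; re-emission by the bystander is neglected.
    """
    flow = observer.breathing_flow
    if flow == 0:
        return 0.0
    return flow * sum(
        exposure_integral(series, interval)
        for interval in _presence_intervals(series, observer)
    )


def user_total_inhaled(
    schedule: PuffSchedule,
    constituent: Constituent,
    user_series: ConcentrationSeries,
    observer: Observer,
) -> float:
    """Total constituent mass inhaled by the user (µg).

    The per-puff inhaled mass summed over the schedule, plus the ambient
    mass breathed between puffs at the user's own position (``user_series``
    must be evaluated at distance 0).
    """
    direct = len(schedule) * constituent.inhaled_mass_per_puff
    ambient = bystander_dose(user_series, observer)
    return direct + ambient


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def box_surface_area(
    volume: float, height: float = DEFAULT_ROOM_HEIGHT, floor_area: float | None = None
) -> float:
    """Interior surface of a rectangular room: floor + ceiling + four walls.

    The floor plan is square unless ``floor_area`` is given, in which case
    a square plan of that area is used.  This is the default deposition
    surface — the model needs one and room dimensions are rarely reported.
    """
    if volume <= 0 or height <= 0:
        raise ValueError("volume and height must be > 0")
    area = floor_area if floor_area is not None else volume / height
    if area <= 0:
        raise ValueError("floor_area must be > 0")
    perimeter = 4.0 * math.sqrt(area)
    return 2.0 * area + perimeter * height


def _grid(end: float, step: float) -> np.ndarray:
    n = int(round(end / step))
    return np.linspace(0.0, end, n + 1)


#: Factorial-sweep level values: low / medium / high for each of the five
#: varied parameters of the 8-h office scenario.
SWEEP_LEVELS: dict[str, tuple[float, float, float]] = {
    "distance": (1.0, 1.5, 2.0),
    "propagation_speed": (0.5, 1.0, 2.0),
    "exhaled_mass": (10.0, 20.0, 30.0),
    "ach": (1.0, 2.0, 3.0),
    "deposition_velocity": (0.01, 0.03, 0.06),
}

_SWEEP_PARAMETERS = tuple(SWEEP_LEVELS)
_LEVEL_CODES = ("L", "M", "H")


def _office_puff_times(
    day_minutes: float = 480.0,
    puff_interval: float = 5.0,
    lunch: tuple[float, float] = (180.0, 240.0),
) -> list[float]:
    """Puff once per interval over the working day, pausing over lunch."""
    times: list[float] = []
    t = 0.0
    while t < day_minutes:
        if not (lunch[0] <= t < lunch[1]):
            times.append(t)
        t += puff_interval
    return times


def office_day_spec(
    room_volume: float = 37.5,
    floor_area: float = 15.0,
    ach: float = 1.33,
    inhaled_mass: float = 60.0,
    retention_rate: float = 50.0,
    propagation_speed: float = 0.6,
    deposition_velocity: float = 0.06,
    distance: float = 2.0,
    breathing_rate: float = 8.0,
    puff_interval: float = 5.0,
    day_minutes: float = 480.0,
    lunch: tuple[float, float] = (180.0, 240.0),
    exhaled_mass_override: float | None = None,
    exhaled_volume: float = DEFAULT_EXHALED_VOLUME,
) -> ScenarioSpec:
    """The 8-h shared-office scenario as a :class:`ScenarioSpec`.

    Two colleagues share a 37.5 m³ office from 09:00 to 17:00 (t = 0 to
    480 min) with a one-hour lunch break (t = 180–240) during which nobody
    puffs and the bystander is out of the room.  The user puffs once every
    5 min, inhaling 60 µg nicotine and retaining 50 %, so each puff exhales
    30 µg.  ``exhaled_mass_override`` sets the exhaled mass directly
    (retention bookkeeping is bypassed), which is how the sweep varies the
    emitted quantity.
    """
    if exhaled_mass_override is not None:
        constituent = Constituent(
            "nicotine",
            inhaled_mass_per_puff=exhaled_mass_override,
            retention_rate=0.0,
        )
    else:
        constituent = Constituent(
            "nicotine",
            inhaled_mass_per_puff=inhaled_mass,
            retention_rate=retention_rate,
        )
    room = Room(volume=room_volume, ach=ach, floor_area=floor_area)
    transport = TransportParams(
        front_speed=propagation_speed, deposition_velocity=deposition_velocity
    )
    times = _office_puff_times(day_minutes, puff_interval, lunch)
    schedule = PuffSchedule.regular(
        constituent, times, exhaled_volume, description="office day"
    )
    presence = ((0.0, lunch[0]), (lunch[1], day_minutes))
    observer = Observer(
        distance=distance, breathing_rate=breathing_rate, presence=presence
    )
    return ScenarioSpec(
        room=room,
        transport=transport,
        constituent=constituent,
        schedule=schedule,
        observer=observer,
        window=(0.0, day_minutes),
    )


@dataclass(frozen=True)
class OfficeDayResult:
    """Bystander series plus the headline office-day numbers."""

    series: ConcentrationSeries
    summary: ExposureSummary
    dose_low: float
    dose_high: float


def office_day_scenario(
    grid_step: float = DEFAULT_GRID_STEP,
    breathing_rate_low: float = 8.0,
    breathing_rate_high: float = 16.0,
    **overrides,
) -> OfficeDayResult:
    """Simulate the 8-h office day and summarise bystander exposure.

    Returns the bystander concentration series over the 480-min day, an
    :class:`ExposureSummary` (peak, 8-h mean, exposure integral, dose at
    the low breathing rate) and the inhaled dose at the low and high
    breathing rates (defaults 8 and 16 L/min over the 420 min of presence).
    Keyword ``overrides`` are forwarded to :func:`office_day_spec`.
    """
    spec = office_day_spec(**overrides)
    logger.info(
        "office day: V=%.3g m3, ACH=%.3g, v_d=%.3g m/min, %d puffs",
        spec.room.volume,
        spec.room.ach,
        spec.transport.deposition_velocity,
        len(spec.schedule),
    )
    grid = _grid(spec.window[1], grid_step)
    series = superpose(
        spec.schedule, spec.constituent, spec.room, spec.transport,
        spec.observer, grid,
    )
    integral = exposure_integral(series, spec.window)
    peak = peak_concentration(series, spec.window)
    mean = average_concentration(series, spec.window)
    obs_low = replace(spec.observer, breathing_rate=breathing_rate_low)
    obs_high = replace(spec.observer, breathing_rate=breathing_rate_high)
    dose_low = bystander_dose(series, obs_low)
    dose_high = bystander_dose(series, obs_high)
    summary = ExposureSummary(
        exposure_integral=integral,
        peak=peak,
        mean=mean,
        window=spec.window,
        inhaled_mass=dose_low,
    )
    return OfficeDayResult(
        series=series, summary=summary, dose_low=dose_low, dose_high=dose_high
    )


def machine_release_scenario(
    nicotine_per_puff: float,
    n_puffs: int,
    ach: float,
    room_volume: float = 39.0,
    propagation_speed: float = 2.0,
    deposition_velocity: float = 0.06,
    distance: float = 1.0,
    puff_spacing: float = 10.0 / 60.0,
    session_interval: float = 30.0,
    window: tuple[float, float] = (0.0, 60.0),
    grid_step: float = DEFAULT_GRID_STEP,
) -> ExposureSummary:
    """A smoking-machine chamber release and its 1-h average concentration.

    ``n_puffs`` puffs are emitted every 10 s starting at t = 0, and the
    whole emission pattern repeats once after 30 min.  The machine retains
    nothing (0 % retention), the aerosol propagates at 2 m/min (the chamber
    air is fan-mixed, filling the 39 m³ room in about a minute) and deposits
    at 0.06 m/min.  The summary is taken at 1 m from the machine over the
    first hour.
    """
    if n_puffs < 0:
        raise ValueError("n_puffs must be >= 0")
    constituent = Constituent(
        "nicotine", inhaled_mass_per_puff=nicotine_per_puff, retention_rate=0.0
    )
    room = Room(volume=room_volume, ach=ach)
    transport = TransportParams(
        front_speed=propagation_speed, deposition_velocity=deposition_velocity
    )
    times = [
        session_start + i * puff_spacing
        for session_start in (0.0, session_interval)
        for i in range(n_puffs)
    ]
    schedule = PuffSchedule.regular(
        constituent, sorted(times), description="machine release"
    )
    observer = Observer(distance=distance)
    grid = _grid(window[1], grid_step)
    series = superpose(schedule, constituent, room, transport, observer, grid)
    return ExposureSummary(
        exposure_integral=exposure_integral(series, window),
        peak=peak_concentration(series, window),
        mean=average_concentration(series, window),
        window=window,
    )


def _apply_parameter(spec: ScenarioSpec, parameter: str, value: float) -> ScenarioSpec:
    """Return a copy of ``spec`` with one named parameter replaced."""
    if parameter == "distance":
        return replace(spec, observer=replace(spec.observer, distance=value))
    if parameter == "propagation_speed":
        return replace(spec, transport=replace(spec.transport, front_speed=value))
    if parameter == "deposition_velocity":
        return replace(
            spec, transport=replace(spec.transport, deposition_velocity=value)
        )
    if parameter == "ach":
        return replace(spec, room=replace(spec.room, ach=value))
    if parameter == "exhaled_mass":
        constituent = Constituent(
            spec.constituent.name, inhaled_mass_per_puff=value, retention_rate=0.0
        )
        schedule = PuffSchedule.regular(
            constituent,
            [p.time for p in spec.schedule.puffs],
            spec.schedule.puffs[0].exhaled_volume
            if spec.schedule.puffs
            else DEFAULT_EXHALED_VOLUME,
            description=spec.schedule.description,
        )
        return replace(spec, constituent=constituent, schedule=schedule)
    raise ValueError(f"unknown parameter {parameter!r}")


def single_puff_spec(
    distance: float = 1.5,
    exhaled_mass_per_puff: float = 20.0,
    propagation_speed: float = 1.0,
    deposition_velocity: float = 0.03,
    ach: float = 2.0,
    room_volume: float = 37.5,
    floor_area: float = 15.0,
    window: tuple[float, float] = (0.0, 60.0),
) -> ScenarioSpec:
    """One exhaled puff at t = 0 with the mid-level parameter values.

    This is the base configuration for one-at-a-time sensitivity runs:
    every parameter sits at its medium sweep level and summaries are taken
    over one hour.
    """
    constituent = Constituent(
        "nicotine", inhaled_mass_per_puff=exhaled_mass_per_puff, retention_rate=0.0
    )
    room = Room(volume=room_volume, ach=ach, floor_area=floor_area)
    transport = TransportParams(
        front_speed=propagation_speed, deposition_velocity=deposition_velocity
    )
    schedule = PuffSchedule.regular(constituent, [0.0], description="single puff")
    observer = Observer(distance=distance)
    return ScenarioSpec(
        room=room,
        transport=transport,
        constituent=constituent,
        schedule=schedule,
        observer=observer,
        window=window,
    )


def one_at_a_time(
    base: ScenarioSpec,
    parameter: str,
    values: Sequence[float],
    grid_step: float = DEFAULT_GRID_STEP,
) -> list[tuple[float, ConcentrationSeries, ExposureSummary]]:
    """Vary one parameter while all others stay at their base values.

    ``parameter`` is one of ``distance``, ``propagation_speed``,
    ``deposition_velocity``, ``ach`` or ``exhaled_mass``.  Each run returns
    the bystander series and an exposure summary over the base window.
    """
    results = []
    for value in values:
        spec = _apply_parameter(base, parameter, value)
        grid = _grid(spec.window[1], grid_step)
        series = superpose(
            spec.schedule, spec.constituent, spec.room, spec.transport,
            spec.observer, grid,
        )
        summary = ExposureSummary(
            exposure_integral=exposure_integral(series, spec.window),
            peak=peak_concentration(series, spec.window),
            mean=average_concentration(series, spec.window),
            window=spec.window,
        )
        results.append((value, series, summary))
    return results


def parameter_sweep(
    levels: dict[str, tuple[float, float, float]] | None = None,
    base: ScenarioSpec | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> pd.DataFrame:
    """Run the full 3^5 factorial sweep over the office-day scenario.

    Five parameters (distance, propagation speed, exhaled mass, ACH,
    deposition velocity) each take a low / medium / high value, giving 243
    scenarios.  The response is the average 8-h concentration at the
    bystander.  Returns a DataFrame with one row per scenario: a level code
    (L/M/H) and numeric value per parameter plus ``mean_8h_ug_m3``.
    """
    if levels is None:
        levels = SWEEP_LEVELS
    if set(levels) != set(_SWEEP_PARAMETERS):
        raise ValueError(f"levels must cover exactly {_SWEEP_PARAMETERS}")
    for name, vals in levels.items():
        if len(vals) != 3:
            raise ValueError(f"parameter {name!r} needs exactly 3 level values")
    if base is None:
        base = office_day_spec()
    grid = _grid(base.window[1], grid_step)
    rows = []
    index_grid = np.ndindex(*(3 for _ in _SWEEP_PARAMETERS))
    for combo in index_grid:
        spec = base
        row: dict[str, object] = {}
        for parameter, level_idx in zip(_SWEEP_PARAMETERS, combo):
            value = levels[parameter][level_idx]
            spec = _apply_parameter(spec, parameter, value)
            row[f"{parameter}_level"] = _LEVEL_CODES[level_idx]
            row[f"{parameter}_value"] = value
        series = superpose(
            spec.schedule, spec.constituent, spec.room, spec.transport,
            spec.observer, grid,
        )
        row["mean_8h_ug_m3"] = average_concentration(series, spec.window)
        rows.append(row)
    table = pd.DataFrame(rows)
    logger.info("parameter sweep complete: %d scenarios", len(table))
    return table


def parameter_impact(table: pd.DataFrame, parameter: str) -> float:
    """Signed impact (%) of one parameter on the maximum sweep response.

    The 243 scenarios are grouped by the parameter's level; the impact is
    the difference between the high-group and low-group maxima of the
    average 8-h concentration, relative to the larger of the two maxima:
    positive when raising the parameter raises the achievable maximum,
    negative when it lowers it.  (Relative to the larger maximum, a
    three-fold emission increase reads as +66.7 %, matching how such
    sensitivity results are usually quoted.)
    """
    level_col = f"{parameter}_level"
    if level_col not in table.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    max_low = table.loc[table[level_col] == "L", "mean_8h_ug_m3"].max()
    max_high = table.loc[table[level_col] == "H", "mean_8h_ug_m3"].max()
    larger = max(max_low, max_high)
    if larger == 0:
        return 0.0
    return float((max_high - max_low) / larger * 100.0)


# ---------------------------------------------------------------------------
# Configuration and command-line interface
# ---------------------------------------------------------------------------

_KNOWN_SCENARIOS = ("office_day", "machine_release", "sweep", "one_at_a_time", "custom")


@dataclass(frozen=True)
class RunConfig:
    """A validated run description loaded from a YAML config file."""

    scenario: str
    grid_step: float = DEFAULT_GRID_STEP
    out_prefix: str = "puffbox"
    log_level: str = "INFO"
    parameter: str | None = None
    values: tuple[float, ...] | None = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in _KNOWN_SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {_KNOWN_SCENARIOS}"
            )
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log_level {self.log_level!r}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected; numeric invariants (positive grid step,
    non-negative rates in overrides) are checked by constructing the
    corresponding scenario objects.
    """
    import yaml

    try:
        with open(path) as handle:
            raw = yaml.safe_load(handle)
    except FileNotFoundError:
        raise
    except yaml.YAMLError as exc:
        raise ValueError(f"could not parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    allowed = {
        "scenario", "grid_step", "out_prefix", "log_level",
        "parameter", "values", "overrides",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "values" in raw and raw["values"] is not None:
        raw["values"] = tuple(float(v) for v in raw["values"])
    config = RunConfig(**raw)
    _validate_overrides(config)
    return config


def _validate_overrides(config: RunConfig) -> None:
    """Construct the configured scenario once so bad values fail early."""
    if config.scenario == "office_day":
        office_day_spec(**config.overrides)
    elif config.scenario == "machine_release":
        required = {"nicotine_per_puff", "n_puffs", "ach"}
        missing = required - set(config.overrides)
        if missing:
            raise ValueError(f"machine_release requires overrides: {sorted(missing)}")


def save_config(config: RunConfig, path) -> None:
    """Write a RunConfig back to YAML (round-trips through load_config)."""
    import yaml

    payload = {
        "scenario": config.scenario,
        "grid_step": config.grid_step,
        "out_prefix": config.out_prefix,
        "log_level": config.log_level,
        "overrides": dict(config.overrides),
    }
    if config.parameter is not None:
        payload["parameter"] = config.parameter
    if config.values is not None:
        payload["values"] = list(config.values)
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle)


def _parse_set_overrides(pairs: Sequence[str]) -> dict:
    overrides: dict = {}
    for pair in pairs:
        if "=" not in pair:
            raise ValueError(f"--set expects key=value, got {pair!r}")
        key, _, value = pair.partition("=")
        try:
            overrides[key] = float(value)
        except ValueError:
            overrides[key] = value
    return overrides


def _cmd_simulate(config: RunConfig) -> int:
    prefix = config.out_prefix
    if config.scenario == "office_day":
        result = office_day_scenario(grid_step=config.grid_step, **config.overrides)
        result.series.to_csv(f"{prefix}_series.csv")
        result.summary.to_csv(f"{prefix}_summary.csv")
        logger.info(
            "office day: peak %.3g ug/m3, 8-h mean %.3g ug/m3, dose %.3g-%.3g ug",
            result.summary.peak, result.summary.mean,
            result.dose_low, result.dose_high,
        )
    elif config.scenario == "machine_release":
        overrides = dict(config.overrides)
        overrides["n_puffs"] = int(overrides["n_puffs"])
        summary = machine_release_scenario(grid_step=config.grid_step, **overrides)
        summary.to_csv(f"{prefix}_summary.csv")
        logger.info("machine release: 1-h mean %.3g ug/m3", summary.mean)
    elif config.scenario == "one_at_a_time":
        if config.parameter is None or config.values is None:
            raise ValueError("one_at_a_time requires 'parameter' and 'values'")
        base = single_puff_spec()
        runs = one_at_a_time(
            base, config.parameter, config.values, grid_step=config.grid_step
        )
        for value, series, summary in runs:
            tag = f"{config.parameter}_{value:g}"
            series.to_csv(f"{prefix}_{tag}_series.csv")
            summary.to_csv(f"{prefix}_{tag}_summary.csv")
    else:
        raise ValueError(f"scenario {config.scenario!r} is not simulatable here")
    return 0


def _cmd_sweep(config: RunConfig) -> int:
    table = parameter_sweep(grid_step=config.grid_step)
    path = f"{config.out_prefix}_sweep.csv"
    table.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    logger.info("wrote %d sweep rows to %s", len(table), path)
    return 0


def _cmd_impact(config: RunConfig) -> int:
    if config.parameter is None:
        raise ValueError("impact requires --parameter")
    table = parameter_sweep(grid_step=config.grid_step)
    impact = parameter_impact(table, config.parameter)
    print(f"{config.parameter}: {impact:+.1f} %")
    return 0


def run_cli(argv: Sequence[str] | None = None) -> int:
    """Command-line entry point: ``simulate``, ``sweep`` and ``impact``.

    Returns the process exit code; argparse itself exits with code 2 on
    bad flags.
    """
    import argparse

    parser = argparse.ArgumentParser(
        prog="puffbox",
        description="Indoor-air box model for exhaled e-cigarette aerosol.",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    def add_common(p):
        p.add_argument("--config", help="YAML run configuration")
        p.add_argument("--grid-step", type=float, default=None,
                       help="reporting grid step in minutes")
        p.add_argument("--out-prefix", default=None, help="output file prefix")
        p.add_argument("--set", action="append", default=[], metavar="KEY=VALUE",
                       dest="overrides", help="override a scenario parameter")

    p_sim = sub.add_parser("simulate", help="run a named scenario")
    add_common(p_sim)
    p_sim.add_argument("--scenario", default=None, choices=_KNOWN_SCENARIOS)

    p_sweep = sub.add_parser("sweep", help="run the 243-scenario factorial sweep")
    add_common(p_sweep)

    p_imp = sub.add_parser("impact", help="parameter impact from the sweep")
    add_common(p_imp)
    p_imp.add_argument("--parameter", required=True, choices=_SWEEP_PARAMETERS)

    args = parser.parse_args(argv)

    try:
        if args.config:
            config = load_config(args.config)
        else:
            scenario = getattr(args, "scenario", None) or (
                "sweep" if args.command in ("sweep", "impact") else "office_day"
            )
            config = RunConfig(scenario=scenario)
        updates: dict = {}
        if args.grid_step is not None:
            updates["grid_step"] = args.grid_step
        if args.out_prefix is not None:
            updates["out_prefix"] = args.out_prefix
        if getattr(args, "scenario", None):
            updates["scenario"] = args.scenario
        if getattr(args, "parameter", None):
            updates["parameter"] = args.parameter
        if args.overrides:
            merged = dict(config.overrides)
            merged.update(_parse_set_overrides(args.overrides))
            updates["overrides"] = merged
        if updates:
            config = replace(config, **updates)

        logging.basicConfig(level=config.log_level.upper())
        logger.info("run: command=%s scenario=%s grid_step=%g",
                    args.command, config.scenario, config.grid_step)

        if args.command == "simulate":
            return _cmd_simulate(config)
        if args.command == "sweep":
            return _cmd_sweep(config)
        if args.command == "impact":
            return _cmd_impact(config)
        raise ValueError(f"unknown command {args.command!r}")
    except (ValueError, KeyError, FileNotFoundError) as exc:
        print(f"puffbox: error: {exc}", flush=True)
        return 1
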