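"""Dose regimens, instantaneous events, and inhalation forcings.

Doses are instantaneous additions to a target state variable (oral ->
gut lumen, iv -> venous blood); inhalation exposure is a piecewise-
constant forcing time series of air concentrations.  Dosing times are
inserted into the solver grid automatically — the requested output times
only need to cover where predictions are wanted.  Time is in days
internally; amounts are converted to µmol at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..units import Quantity, UnitContext, convert_units, scale_dosing
from .registry import ModelInfo

__all__ = ["DoseRegimen", "EventTable", "build_event_schedule", "ForcingFunction"]


@dataclass(frozen=True)
class DoseRegimen:
    """A dosing scenario for one simulation.

    initial_dose / daily_dose are interpreted in ``input_units`` (per-kg
    units are body-weight-scaled); dosing_matrix is explicit (time d,
    amount) pairs; forcing_series is (time d, value, unit) steps for
    inhalation exposure, held constant until the next step.
    """

    route: str = "oral"
    initial_dose: float | None = None
    doses_per_day: int | None = None
    daily_dose: float | None = None
    dosing_matrix: tuple[tuple[float, float], ...] = ()
    forcing_series: tuple[tuple[float, float, str], ...] = ()
    input_units: str = "mg/kg"

    def __post_init__(self) -> None:
        for t, a in self.dosing_matrix:
            if a < 0:
                raise ValueError("dose amounts must be non-negative")
        times = [t for t, _ in self.dosing_matrix]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("dosing_matrix times must be non-decreasing")
        if self.initial_dose is not None and self.initial_dose < 0:
            raise ValueError("initial_dose must be non-negative")
        if self.daily_dose is not None and self.daily_dose < 0:
            raise ValueError("daily_dose must be non-negative")


@dataclass
class EventTable:
    """Instantaneous state changes: rows of (variable, time d, value µmol, method)."""

    rows: list = field(default_factory=list)  # (var, time, value, method)

    def add(self, var: str, time: float, value: float, method: str = "add") -> None:
        if method not in ("add", "replace"):
            raise ValueError(f"unknown event method {method!r}")
        self.rows.append((var, float(time), float(value), method))
        self.rows.sort(key=lambda r: r[1])

    def times(self) -> list[float]:
        return sorted({r[1] for r in self.rows})

    def apply_at(self, time: float, state: np.ndarray, state_index: dict) -> np.ndarray:
        out = state.copy()
        for var, t, value, method in self.rows:
            if t == time:
                i = state_index[var]
                out[i] = out[i] + value if method == "add" else value
        return out


class ForcingFunction:
    """Piecewise-constant forcing: value of the last step at or before t."""

    def __init__(self, name: str, steps: list[tuple[float, float]]):
        self.name = name
        steps = sorted(steps)
        self._times = np.array([s[0] for s in steps]) if steps else np.array([])
        self._values = np.array([s[1] for s in steps]) if steps else np.array([])

    def __call__(self, t: float) -> float:
        if self._times.size == 0:
            return 0.0
        i = np.searchsorted(self._times, t, side="right") - 1
        return float(self._values[i]) if i >= 0 else 0.0

    def step_times(self) -> list[float]:
        return list(self._times)


def _dose_to_umol(amount: float, unit: str, BW: float, MW: float) -> float:
    q = Quantity(amount, unit)
    if "/kg" in unit:
        q = scale_dosing(q, BW)
    ctx = UnitContext(MW=MW)
    return convert_units(q, "umol", ctx).value


def build_event_schedule(
    regimen: DoseRegimen,
    model: ModelInfo,
    BW: float,
    MW: float,
    times: np.ndarray,
    air_temperature: float = 298.15,
) -> tuple[EventTable, ForcingFunction, np.ndarray]:
    """Expand a DoseRegimen into events, a forcing function, and the solver grid.

    Per-kg doses are body-weight scaled then converted to µmol;
    ``doses_per_day`` splits the daily dose into equally spaced events
    (0, 1/n, 2/n, ... of each day).  Every event/forcing-step time is
    inserted into the solver grid; the returned results are still reported
    only at the requested times.
    """
    if regimen.route not in model.routes:
        raise ValueError(
            f"model {model.name!r} does not support route {regimen.route!r}; "
            f"supported: {sorted(model.routes)}"
        )
    times = np.asarray(times, dtype=float)
    events = EventTable()
    t0, t_end = float(times[0]), float(times[-1])

    target = model.dose_targets.get(regimen.route)
    unit = regimen.input_units

    if regimen.route in ("oral", "iv"):
        if regimen.initial_dose:
            events.add(target, t0, _dose_to_umol(regimen.initial_dose, unit, BW, MW))
        if regimen.daily_dose:
            n_per_day = regimen.doses_per_day or 1
            per_dose = regimen.daily_dose / n_per_day
            rate_unit = unit[: -len("/day")] if unit.endswith("/day") else unit
            day = np.floor(t0)
            k = 0
            while True:
                t = day + k / n_per_day  # integer steps avoid float drift
                if t > t_end:
                    break
                if t >= t0:
                    events.add(target, t, _dose_to_umol(per_dose, rate_unit, BW, MW))
                k += 1
        for t, amount in regimen.dosing_matrix:
            events.add(target, t, _dose_to_umol(amount, unit, BW, MW))

    steps: list[tuple[float, float]] = []
    if regimen.forcing_series:
        if "inhalation" not in model.routes:
            raise ValueError(f"model {model.name!r} does not support inhalation forcing")
        for t, value, funit in regimen.forcing_series:
            ctx = UnitContext(MW=MW, temperature=air_temperature, state="gas")
            uM = convert_units(Quantity(value, funit), "uM", ctx).value
            steps.append((float(t), uM))
    forcing_name = model.input_var_names[0] if model.input_var_names else "Cinh"
    forcing = ForcingFunction(forcing_name, steps)

    grid = np.unique(
        np.concatenate(
            [times, np.array(events.times()), np.array(forcing.step_times())]
        )
    )
    grid = grid[(grid >= t0) & (grid <= t_end)]
    return events, forcing, grid
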