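"""Scoring parameter sets against scaled experimental time courses.

Immunoblot-style training data carry no absolute units, so both the measured
series and the simulated readout are min-max scaled independently within each
objective — the lowest band maps to 0 and the highest to 1 — and the squared
error is summed over the measured points.  The model is therefore trained on
the relative change in band intensity over time or over conditions, never on
absolute intensities.

An objective's points may all come from one condition (a time course) or span
several conditions at fixed times (a bar-chart comparison); both shapes share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .network import ParameterVector, ReactionNetwork
from .simulate import Condition, Trajectory, simulate_protocol

__all__ = [
    "ExperimentalSeries",
    "ObjectiveResult",
    "minmax_scale",
    "scaled_error",
    "evaluate_objectives",
    "Evaluator",
    "load_objectives",
    "save_objectives",
]


@dataclass(frozen=True)
class ExperimentalSeries:
    """One training dataset: a readout, measured points and their conditions.

    ``readout`` lists the model species whose sum maps to the measured band.
    ``conditions`` holds one condition name per measured point; a plain time
    course uses the same name throughout, while a condition-comparison bar
    set mixes names.
    """

    objective_id: str
    readout: tuple[str, ...]
    conditions: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "readout",
                           (self.readout,) if isinstance(self.readout, str)
                           else tuple(self.readout))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        conds = self.conditions
        if isinstance(conds, str):
            conds = (conds,) * self.times.size
        object.__setattr__(self, "conditions", tuple(conds))
        if not (len(self.conditions) == self.times.size == self.values.size):
            raise ValueError(
                f"objective {self.objective_id!r}: conditions, times and "
                "values must have equal length"
            )
        if self.times.size == 0:
            raise ValueError(f"objective {self.objective_id!r}: empty series")

    @property
    def condition_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c)
        return tuple(seen)

    @classmethod
    def timecourse(cls, objective_id, readout, condition: str, times, values):
        return cls(objective_id, readout, (condition,) * len(times), times, values)


@dataclass(frozen=True)
class ObjectiveResult:
    objective_id: str
    squared_error: float
    scaled_sim: np.ndarray
    scaled_data: np.ndarray


def minmax_scale(series: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]: (v − min)/(max − min); a constant series maps to all
    zeros (basal no-stimulus controls are legitimately flat)."""
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("cannot scale an empty series")
    lo, hi = v.min(), v.max()
    # a numerically constant series (range below solver noise) must not be
    # blown up to a full-range shape by the normalisation
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def scaled_error(
    series: ExperimentalSeries,
    trajectories: Mapping[str, Trajectory] | Trajectory,
) -> ObjectiveResult:
    """Squared error between independently min-max-scaled data and simulation.

    ``trajectories`` maps condition names to simulated trajectories (or is a
    single trajectory for single-condition series).  The simulated readout is
    the sum of the mapped species, linearly interpolated to the measured
    times.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = {c: trajectories for c in series.condition_names}
    sim = np.empty(series.times.size)
    for i, (cond, t) in enumerate(zip(series.conditions, series.times)):
        traj = trajectories[cond]
        missing = [s for s in series.readout if s not in traj.species_ids]
        if missing:
            raise KeyError(
                f"objective {series.objective_id!r}: readout species "
                f"{missing} absent from model"
            )
        sim[i] = traj.at(series.readout, np.array([t]))[0]
    scaled_sim = minmax_scale(sim)
    scaled_data = minmax_scale(series.values)
    err = float(np.sum((scaled_data - scaled_sim) ** 2))
    return ObjectiveResult(series.objective_id, err, scaled_sim, scaled_data)


class Evaluator:
    """Evaluate all objectives for a parameter set, simulating each unique
    condition once per call.

    Basal steady states are warm-started from the previous call's solution,
    which greatly reduces the window count during ensemble estimation where
    successive candidates differ by small perturbations.  Simulation failures
    flag the affected objectives with ``inf`` and the run continues.
    """

    def __init__(
        self,
        net: ReactionNetwork,
        objectives: Sequence[ExperimentalSeries],
        conditions: Mapping[str, Condition],
        *,
        solver_options: Mapping | None = None,
    ):
        self.net = net
        self.objectives = list(objectives)
        self.conditions = dict(conditions)
        self.solver_options = dict(solver_options or {})
        missing = {
            c for obj in self.objectives for c in obj.condition_names
        } - self.conditions.keys()
        if missing:
            raise KeyError(f"objectives reference undefined conditions: {sorted(missing)}")
        self._warm: dict[str, np.ndarray] = {}

    def simulate_condition(self, name: str, params: ParameterVector) -> Trajectory:
        cond = self.conditions[name]
        net, p = cond.apply(self.net, params)
        from .simulate import find_steady_state

        ss_keys = {k: v for k, v in self.solver_options.items()
                   if k in ("dt", "eps", "max_windows", "norm", "rtol", "atol", "method")}
        ss = find_steady_state(net, p, x0=self._warm.get(name), **ss_keys)
        self._warm[name] = ss.state
        ivp = {k: v for k, v in self.solver_options.items()
               if k in ("rtol", "atol", "method")}
        return simulate_protocol(net, p, cond.protocol, steady_state=ss.state, **ivp)

    def __call__(self, params: ParameterVector) -> np.ndarray:
        needed: dict[str, None] = {}
        for obj in self.objectives:
            for c in obj.condition_names:
                needed.setdefault(c)
        trajs: dict[str, Trajectory] = {}
        failed: set[str] = set()
        for name in needed:
            try:
                trajs[name] = self.simulate_condition(name, params)
            except Exception:
                failed.add(name)
                self._warm.pop(name, None)
        errors = np.empty(len(self.objectives))
        for i, obj in enumerate(self.objectives):
            if set(obj.condition_names) & failed:
                errors[i] = np.inf
            else:
                errors[i] = scaled_error(obj, trajs).squared_error
        return errors


def evaluate_objectives(
    net: ReactionNetwork,
    params: ParameterVector,
    objectives: Sequence[ExperimentalSeries],
    conditions: Mapping[str, Condition],
    **solver_options,
) -> np.ndarray:
    """One squared error per objective (see :class:`Evaluator`)."""
    return Evaluator(net, objectives, conditions, solver_options=solver_options)(params)


# ---------------------------------------------------------------------------
# on-disk objective definitions: YAML index + CSV data tables
# ---------------------------------------------------------------------------


def save_objectives(
    objectives: Sequence[ExperimentalSeries], directory: str | Path
) -> Path:
    """Write an objective set as a YAML index plus one CSV per objective."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for obj in objectives:
        csv_name = f"{obj.objective_id}.csv"
        pd.DataFrame(
            {"condition": obj.conditions, "time": obj.times, "value": obj.values}
        ).to_csv(directory / csv_name, index=False)
        index.append(
            {
                "id": obj.objective_id,
                "readout": list(obj.readout),
                "data": csv_name,
            }
        )
    path = directory / "objectives.yaml"
    path.write_text(yaml.safe_dump({"objectives": index}, sort_keys=False))
    return path


def load_objectives(path: str | Path) -> list[ExperimentalSeries]:
    path = Path(path)
    spec = yaml.safe_load(path.read_text())
    out = []
    for entry in spec["objectives"]:
        df = pd.read_csv(path.parent / entry["data"])
        out.append(
            ExperimentalSeries(
                objective_id=entry["id"],
                readout=tuple(entry["readout"]),
                conditions=tuple(df["condition"].astype(str)),
                times=df["time"].to_numpy(),
                values=df["value"].to_numpy(),
            )
        )
    return out
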