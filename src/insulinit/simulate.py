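"""Stiff ODE integration, steady-state detection, stimulus protocols and
in-silico knockdowns.

Simulation protocols follow the two-phase scheme used for hormone-stimulation
experiments: the network is first relaxed to its pre-stimulus steady state,
the stimulus species is then incremented, and the response is recorded over a
fixed horizon (100 min by default).  The steady state is detected numerically
by integrating over successive windows of length ``dt`` and declaring
convergence when the norm of the difference between successive window
endpoints drops below ``eps`` (0.001 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ParameterVector, Reaction, ReactionNetwork

__all__ = [
    "Trajectory",
    "StimulusProtocol",
    "Condition",
    "IntegrationError",
    "SteadyStateError",
    "SteadyStateResult",
    "integrate",
    "find_steady_state",
    "simulate_protocol",
    "knockdown",
]

#: negative excursions beyond this (relative to the trajectory scale) are
#: treated as integrator failure; smaller ones are clipped to zero on output
TOL_NEG = 1e-4


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time t={last_time:g})")
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge within the window budget."""


@dataclass
class Trajectory:
    """Time-stamped concentration matrix from one simulation protocol."""

    times: np.ndarray
    states: np.ndarray  # n_times x n_species, clipped at 0 on output
    species_ids: list[str]
    protocol_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def readout(self, species: str | Iterable[str]) -> np.ndarray:
        """Concentration time course of one species, or the sum of several
        (a phospho-band may pool multiple complexes)."""
        if isinstance(species, str):
            species = [species]
        idx = [self.species_ids.index(s) for s in species]
        return self.states[:, idx].sum(axis=1)

    def at(self, species: str | Iterable[str], times: np.ndarray) -> np.ndarray:
        """Readout linearly interpolated at arbitrary times."""
        return np.interp(np.asarray(times, float), self.times, self.readout(species))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form frame (time, species, value, protocol)."""
        frames = []
        for i, sid in enumerate(self.species_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "species": sid,
                        "value": self.states[:, i],
                        "protocol": self.protocol_label,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class StimulusProtocol:
    """Add ``stimulus_amount`` of each stimulus species after the pre-stimulus
    steady state, then record ``horizon`` minutes of response.

    The stimulus is added to (not clamped at) the steady-state concentration:
    ligand consumption by receptor binding is part of the model.
    """

    stimulus_species: tuple[str, ...] = ()
    stimulus_amount: float = 0.0
    stimulus_time: float = 0.0
    horizon: float = 100.0

    def __post_init__(self) -> None:
        if isinstance(self.stimulus_species, str):
            object.__setattr__(self, "stimulus_species", (self.stimulus_species,))
        else:
            object.__setattr__(self, "stimulus_species", tuple(self.stimulus_species))
        if self.horizon <= 0:
            raise ValueError("protocol horizon must be > 0")
        if self.stimulus_amount < 0:
            raise ValueError("stimulus amount must be >= 0")


@dataclass(frozen=True)
class Condition:
    """An experimental condition: a stimulus protocol plus structural or
    operational modifications (inhibitors as rate multipliers, knockdowns)."""

    name: str
    protocol: StimulusProtocol
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    knockdowns: tuple[str, ...] = ()

    def apply(
        self, net: ReactionNetwork, params: ParameterVector
    ) -> tuple[ReactionNetwork, ParameterVector]:
        """Return the modified network/parameters this condition simulates."""
        k = params.rate_constants.copy()
        for rid, factor in self.rate_multipliers.items():
            try:
                j = net.reaction_ids.index(rid)
            except ValueError:
                raise KeyError(f"condition {self.name!r}: unknown reaction {rid!r}")
            k[j] *= factor
        out_net, out_params = net, ParameterVector(k, params.initial_conditions.copy())
        if self.knockdowns:
            out_net, out_params = knockdown(out_net, out_params, self.knockdowns)
        return out_net, out_params


def _solve(
    net: ReactionNetwork,
    k: np.ndarray,
    x0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None,
    rtol: float,
    atol: float,
    method: str,
):
    sol = solve_ivp(
        lambda t, x: net.rhs(x, k),
        t_span,
        x0,
        method=method,
        t_eval=t_eval,
        jac=lambda t, x: net.jacobian(x, k),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t_span[0]
        raise IntegrationError(f"integration failed: {sol.message}", last)
    return sol


def integrate(
    net: ReactionNetwork,
    params: ParameterVector,
    t_grid: np.ndarray,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
    x0: np.ndarray | None = None,
    protocol_label: str = "",
) -> Trajectory:
    """Integrate dx/dt = S·r(x,k) on ``t_grid`` with a stiff-capable solver.

    The analytical Jacobian is supplied to the solver.  Tiny negative
    excursions (within ``TOL_NEG``) are clipped to zero on output.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if x0 is None:
        x0 = params.initial_conditions
    x0 = np.asarray(x0, dtype=float)
    sol = _solve(
        net, params.rate_constants, x0,
        (float(t_grid[0]), float(t_grid[-1])), t_grid, rtol, atol, method,
    )
    states = sol.y.T
    if states.min() < -TOL_NEG * max(1.0, abs(states).max()):
        worst = float(states.min())
        raise IntegrationError(
            f"integration produced a negative concentration ({worst:g})",
            float(sol.t[int(np.argmin(states.min(axis=1)))]),
        )
    return Trajectory(t_grid, np.maximum(states, 0.0), net.species_ids, protocol_label)


@dataclass
class SteadyStateResult:
    state: np.ndarray
    windows: int
    residual: float  # ||x(t+dt) - x(t)|| at convergence

    def __iter__(self):  # allow tuple-unpacking (state, info)
        yield self.state
        yield self


def find_steady_state(
    net: ReactionNetwork,
    params: ParameterVector,
    *,
    dt: float = 1.0,
    eps: float = 1e-3,
    max_windows: int = 1000,
    norm: str = "euclidean",
    x0: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> SteadyStateResult:
    """Relax to steady state by repeated integration over windows of ``dt``.

    Convergence is declared at the first state where the norm of the
    difference between successive window endpoints falls below ``eps``.
    Windows are integrated in chunks to amortise solver start-up.  ``x0``
    (warm start) defaults to the parameter vector's initial conditions.
    """
    if norm not in ("euclidean", "max"):
        raise ValueError(f"unknown norm {norm!r}")
    ord_ = None if norm == "euclidean" else np.inf
    x = np.asarray(params.initial_conditions if x0 is None else x0, dtype=float)
    k = params.rate_constants
    chunk = 32
    done = 0
    prev = x
    while done < max_windows:
        n_win = min(chunk, max_windows - done)
        t_eval = dt * np.arange(1, n_win + 1)
        sol = _solve(net, k, prev, (0.0, float(t_eval[-1])), t_eval, rtol, atol, method)
        pts = np.concatenate([prev[None, :], sol.y.T], axis=0)
        diffs = np.linalg.norm(np.diff(pts, axis=0), ord=ord_, axis=1)
        hit = np.nonzero(diffs < eps)[0]
        if hit.size:
            i = int(hit[0])
            return SteadyStateResult(
                np.maximum(pts[i + 1], 0.0), done + i + 1, float(diffs[i])
            )
        prev = pts[-1]
        done += n_win
    drift = np.abs(net.rhs(np.maximum(prev, 0.0), k))
    worst = net.species_ids[int(np.argmax(drift))]
    raise SteadyStateError(
        f"no steady state within {max_windows} windows of dt={dt}; largest "
        f"residual species {worst!r} (|dx/dt|={drift.max():g})"
    )


def simulate_protocol(
    net: ReactionNetwork,
    params: ParameterVector,
    protocol: StimulusProtocol,
    *,
    t_grid: np.ndarray | None = None,
    steady_state: np.ndarray | None = None,
    n_points: int = 201,
    **solver_kwargs,
) -> Trajectory:
    """Run the two-phase stimulus protocol.

    Phase 1 relaxes the network (stimulus species at basal initial values) to
    steady state; phase 2 adds the stimulus and records the response.  A
    precomputed ``steady_state`` may be supplied to skip phase 1 (used when
    many protocols share the same basal state).
    """
    for sid in protocol.stimulus_species:
        if sid not in net.index:
            raise KeyError(f"stimulus species {sid!r} not in network")
    ss_keys = {k: v for k, v in solver_kwargs.items()
               if k in ("dt", "eps", "max_windows", "norm")}
    ivp_keys = {k: v for k, v in solver_kwargs.items()
                if k in ("rtol", "atol", "method")}
    if steady_state is None:
        steady_state = find_steady_state(net, params, **ss_keys, **ivp_keys).state
    x0 = np.asarray(steady_state, dtype=float).copy()
    for sid in protocol.stimulus_species:
        x0[net.index[sid]] += protocol.stimulus_amount
    if t_grid is None:
        t_grid = np.linspace(0.0, protocol.horizon, n_points)
    return integrate(
        net, params, t_grid, x0=x0,
        protocol_label=",".join(protocol.stimulus_species) or "basal",
        **ivp_keys,
    )


def knockdown(
    net: ReactionNetwork,
    params: ParameterVector,
    target: str | Iterable[str],
) -> tuple[ReactionNetwork, ParameterVector]:
    """Remove one or more species from the stoichiometric matrix.

    Every reaction in which a target participates (as reactant or product) is
    removed and the target's initial condition is set to zero; remaining
    species and their ordering are unchanged.  Removing reactions (rather
    than just zeroing the species) prevents regeneration through synthesis
    steps.  Idempotent.
    """
    targets = {target} if isinstance(target, str) else set(target)
    unknown = targets - net.index.keys()
    if unknown:
        raise KeyError(f"unknown knockdown target(s): {sorted(unknown)}")
    keep = [
        (rxn, kj)
        for rxn, kj in zip(net.reactions, params.rate_constants)
        if not (rxn.species_ids & targets)
    ]
    new_net = net.with_reactions([rxn for rxn, _ in keep])
    x0 = params.initial_conditions.copy()
    for sid in targets:
        x0[net.index[sid]] = 0.0
    new_params = ParameterVector(np.array([kj for _, kj in keep]), x0)
    return new_net, new_params
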