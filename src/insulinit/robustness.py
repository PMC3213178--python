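"""Knockdown screening over an ensemble with robustness coefficients.

The robustness coefficient of a perturbation is the ratio of the
time-integrated concentration of a network marker (by default the assembled
80S ribosomal complex, the model's readout of translation initiation) in the
perturbed simulation over the nominal one:

    value > 1  — the perturbation increased the integrated marker,
    value = 1  — no influence,
    value < 1  — the perturbation decreased it.

The screen runs every (ensemble member × knockdown target × condition) cell,
aggregates the member coefficients into a four-way effect category from the
member median, and reports sub-population splits for targets whose direction
of effect differs across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ParameterVector, ReactionNetwork
from .simulate import Condition, Trajectory, knockdown, simulate_protocol, find_steady_state

__all__ = [
    "RobustnessCoefficient",
    "ScreenResult",
    "robustness_coefficient",
    "knockdown_screen",
    "classify_effect",
    "subpopulation_report",
    "convergence_report",
]

CATEGORIES = ("increase", "none", "moderate_decrease", "severe_decrease", "undetermined")


@dataclass(frozen=True)
class RobustnessCoefficient:
    marker: str
    perturbation: str
    condition: str
    value: float


def _integrated(traj: Trajectory, marker: str | Iterable[str], t0: float, tf: float) -> float:
    if not (traj.times[0] <= t0 and tf <= traj.times[-1]):
        raise ValueError(
            f"trajectory span [{traj.times[0]}, {traj.times[-1]}] does not "
            f"cover window [{t0}, {tf}]"
        )
    mask = (traj.times > t0) & (traj.times < tf)
    times = np.concatenate([[t0], traj.times[mask], [tf]])
    values = traj.at(marker, times)
    return float(np.trapezoid(values, times))


def robustness_coefficient(
    traj_perturbed: Trajectory,
    traj_nominal: Trajectory,
    marker: str | Iterable[str],
    t0: float,
    tf: float,
) -> float:
    """Trapezoid integral of the marker in the perturbed run over the same
    integral in the nominal run."""
    denom = _integrated(traj_nominal, marker, t0, tf)
    if denom <= 0:
        raise ValueError(
            f"marker {marker!r} never produced in the nominal run "
            "(zero denominator integral)"
        )
    return _integrated(traj_perturbed, marker, t0, tf) / denom


@dataclass
class ScreenResult:
    """Coefficient matrices (targets × members) per condition plus settings."""

    coefficients: dict[str, np.ndarray]  # condition -> n_targets x n_members
    targets: list[str]
    conditions: list[str]
    marker: str | tuple[str, ...]
    window: tuple[float, float]
    delta: float = 0.1
    c_severe: float = 0.25

    @property
    def n_members(self) -> int:
        return next(iter(self.coefficients.values())).shape[1]

    def member_coefficients(self, target: str, condition: str) -> np.ndarray:
        return self.coefficients[condition][self.targets.index(target)]

    def category(self, target: str, condition: str) -> str:
        return classify_effect(
            self.member_coefficients(target, condition),
            delta=self.delta,
            c_severe=self.c_severe,
        )

    def median(self, target: str, condition: str) -> float:
        c = self.member_coefficients(target, condition)
        finite = c[np.isfinite(c)]
        return float(np.median(finite)) if finite.size else np.nan

    def failed_cells(self) -> int:
        return int(sum(np.sum(~np.isfinite(m)) for m in self.coefficients.values()))

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: member, target, condition, coefficient."""
        rows = []
        for cond, mat in self.coefficients.items():
            for i, target in enumerate(self.targets):
                for m in range(mat.shape[1]):
                    rows.append((m, target, cond, mat[i, m]))
        return pd.DataFrame(rows, columns=["member", "target", "condition", "coefficient"])

    def summary(self) -> pd.DataFrame:
        """Per (target, condition): category, median and sub-population counts.
        The classification thresholds are included on every row."""
        rows = []
        for cond in self.conditions:
            for target in self.targets:
                rep = subpopulation_report(self, target, cond)
                rows.append(
                    {
                        "target": target,
                        "condition": cond,
                        "category": self.category(target, cond),
                        "median": self.median(target, cond),
                        "n_increase": rep["n_above_1"],
                        "n_decrease": rep["n_below_1"],
                        "n_twofold_up": rep["n_twofold_up"],
                        "n_twofold_down": rep["n_twofold_down"],
                        "n_failed": rep["n_failed"],
                        "delta": self.delta,
                        "c_severe": self.c_severe,
                    }
                )
        return pd.DataFrame(rows)

    def histogram(self, target: str, condition: str, bins: int = 20) -> pd.DataFrame:
        """Fold-change histogram of member coefficients for one cell."""
        c = self.member_coefficients(target, condition)
        c = c[np.isfinite(c)]
        counts, edges = np.histogram(c, bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def classify_effect(
    member_coefficients: np.ndarray,
    *,
    delta: float = 0.1,
    c_severe: float = 0.25,
) -> str:
    """Four-way effect category from the member-median coefficient m:
    increase (m > 1+δ), none (|m−1| ≤ δ), moderate decrease
    (c_sev < m < 1−δ) or severe decrease (m ≤ c_sev, closed boundary).
    All cells failed → "undetermined"."""
    c = np.asarray(member_coefficients, dtype=float)
    finite = c[np.isfinite(c)]
    if finite.size == 0:
        return "undetermined"
    m = float(np.median(finite))
    if m > 1 + delta:
        return "increase"
    if abs(m - 1) <= delta:
        return "none"
    if m <= c_severe:
        return "severe_decrease"
    return "moderate_decrease"


def knockdown_screen(
    net: ReactionNetwork,
    ensemble: Sequence[ParameterVector],
    targets: Sequence[str | tuple[str, ...]],
    conditions: Sequence[Condition],
    *,
    marker: str | tuple[str, ...] = "R80S",
    window: tuple[float, float] | None = None,
    delta: float = 0.1,
    c_severe: float = 0.25,
    solver_options: Mapping | None = None,
) -> ScreenResult:
    """Screen knockdowns over the ensemble under each condition.

    For every (member, target, condition) cell the nominal and knocked-down
    protocols are simulated and the marker's robustness coefficient computed
    over ``window`` (default: the full protocol horizon).  A target may be a
    single species or a tuple knocked down together (e.g. both nucleotide
    states of a GTPase).  Per-cell simulation failures are flagged NaN and
    excluded from aggregates, with the count reported.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    solver_options = dict(solver_options or {})
    ivp = {k: v for k, v in solver_options.items() if k in ("rtol", "atol", "method")}
    ss = {k: v for k, v in solver_options.items()
          if k in ("dt", "eps", "max_windows", "norm")}
    target_labels = [t if isinstance(t, str) else "+".join(t) for t in targets]
    for t in targets:
        for sid in ((t,) if isinstance(t, str) else t):
            if sid not in net.index:
                raise KeyError(f"knockdown target {sid!r} not in network")
    coefficients: dict[str, np.ndarray] = {}
    horizon = max(c.protocol.horizon for c in conditions)
    win = window or (0.0, horizon)
    for cond in conditions:
        mat = np.full((len(targets), len(ensemble)), np.nan)
        for m, params in enumerate(ensemble):
            base_net, base_params = cond.apply(net, params)
            try:
                nominal = simulate_protocol(
                    base_net, base_params, cond.protocol, **ss, **ivp
                )
            except Exception:
                continue  # whole member fails under this condition
            for i, t in enumerate(targets):
                tset = (t,) if isinstance(t, str) else t
                try:
                    kd_net, kd_params = knockdown(base_net, base_params, tset)
                    perturbed = simulate_protocol(
                        kd_net, kd_params, cond.protocol, **ss, **ivp
                    )
                    mat[i, m] = robustness_coefficient(
                        perturbed, nominal, marker, *win
                    )
                except Exception:
                    pass  # flagged NaN, excluded from aggregates
        coefficients[cond.name] = mat
    return ScreenResult(
        coefficients=coefficients,
        targets=target_labels,
        conditions=[c.name for c in conditions],
        marker=marker,
        window=win,
        delta=delta,
        c_severe=c_severe,
    )


def subpopulation_report(
    screen: ScreenResult, target: str, condition: str | None = None
) -> dict:
    """Counts of members by effect direction and fold change for one target.

    Reports how many members increased (> 1) or decreased (< 1) the marker,
    how many changed at least two-fold in either direction, the member ids in
    each group, and how many cells failed.  Counts of the direction split sum
    to the number of non-failed members.
    """
    if condition is None:
        condition = screen.conditions[0]
    c = screen.member_coefficients(target, condition)
    finite_mask = np.isfinite(c)
    ids = np.arange(c.size)
    above = ids[finite_mask & (c > 1)]
    below = ids[finite_mask & (c < 1)]
    at_one = ids[finite_mask & (c == 1)]
    return {
        "target": target,
        "condition": condition,
        "n_members": int(c.size),
        "n_failed": int((~finite_mask).sum()),
        "n_above_1": int(above.size),
        "n_below_1": int(below.size),
        "n_at_1": int(at_one.size),
        "n_twofold_up": int(np.sum(finite_mask & (c >= 2.0))),
        "n_twofold_down": int(np.sum(finite_mask & (c <= 0.5))),
        "members_above_1": above.tolist(),
        "members_below_1": below.tolist(),
    }


def convergence_report(
    screen: ScreenResult, sizes: Sequence[int] = (50, 100, 200)
) -> pd.DataFrame:
    """Category stability across nested member subsample sizes.

    For each (target, condition) the effect category is recomputed over the
    first n members for each requested n (plus the full ensemble) and targets
    whose category flips between sizes are flagged — the screen-size
    convergence check for ensemble robustness analyses.
    """
    all_sizes = sorted({min(s, screen.n_members) for s in sizes} | {screen.n_members})
    rows = []
    for cond in screen.conditions:
        for target in screen.targets:
            c = screen.member_coefficients(target, cond)
            cats = {
                n: classify_effect(c[:n], delta=screen.delta, c_severe=screen.c_severe)
                for n in all_sizes
            }
            rows.append(
                {
                    "target": target,
                    "condition": cond,
                    **{f"category_n{n}": cat for n, cat in cats.items()},
                    "stable": len(set(cats.values())) == 1,
                }
            )
    return pd.DataFrame(rows)
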