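"""Forward kinetic sensitivity analysis and SVD-based fragility ranking.

First-order sensitivities s_j(t) = ∂x/∂k_j are computed by integrating the
augmented system

    ds_j/dt = J(x)·s_j + B_j(x),    s_j(0) = 0

alongside the states, where J is the analytical Jacobian and B_j the j-th
column of the analytical parameter-derivative matrix.  The coefficients are
made dimensionless with the log-sensitivity scaling (k_j/x_i)·∂x_i/∂k_j,
time-averaged with the trapezoid rule over a window of the response, arranged
into an array across ensemble members, and decomposed by SVD.  A species (or
parameter) is scored by the fraction of the leading singular vectors in which
its coefficient exceeds a magnitude threshold: high scores mark fragile
network elements, low scores robust ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ParameterVector, ReactionNetwork
from .simulate import Condition, StimulusProtocol, find_steady_state

__all__ = [
    "SensitivityField",
    "SensitivityArray",
    "FragilityRanking",
    "solve_sensitivities",
    "scale_and_time_average",
    "svd_rank",
    "ranking_comparison",
    "ensemble_species_scores",
]

#: concentration guard for the log-sensitivity scaling
X_GUARD = 1e-6


@dataclass
class SensitivityField:
    """∂x_i/∂k_j over time, together with the state trajectory it rides on."""

    times: np.ndarray
    states: np.ndarray  # n_times x n_species
    s: np.ndarray  # n_times x n_species x n_params
    species_ids: list[str]
    param_indices: np.ndarray  # indices into the rate-constant vector
    rate_constants: np.ndarray  # full rate-constant vector


def solve_sensitivities(
    net: ReactionNetwork,
    params: ParameterVector,
    protocol: StimulusProtocol | None = None,
    param_subset: Sequence[int] | None = None,
    *,
    t_grid: np.ndarray | None = None,
    steady_state: np.ndarray | None = None,
    rate_multipliers: Mapping[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
    n_points: int = 101,
    **ss_kwargs,
) -> SensitivityField:
    """Integrate the kinetic-sensitivity equations for a stimulus protocol.

    Sensitivities are taken over the response phase: the network is relaxed
    to steady state, the stimulus applied, and the augmented system solved
    from s(0) = 0.  ``param_subset`` selects rate-constant indices (default:
    all).  ``rate_multipliers`` lets inhibitor conditions reuse this path.
    """
    k = params.rate_constants.copy()
    if rate_multipliers:
        for rid, f in rate_multipliers.items():
            k[net.reaction_ids.index(rid)] *= f
    run_params = ParameterVector(k, params.initial_conditions)
    if param_subset is None:
        param_subset = np.arange(net.n_reactions)
    sub = np.asarray(param_subset, dtype=int)
    n, p = net.n_species, sub.size

    if protocol is None:
        protocol = StimulusProtocol()
    if steady_state is None:
        steady_state = find_steady_state(net, run_params, **ss_kwargs).state
    x0 = np.asarray(steady_state, float).copy()
    for sid in protocol.stimulus_species:
        x0[net.index[sid]] += protocol.stimulus_amount
    if t_grid is None:
        t_grid = np.linspace(0.0, protocol.horizon, n_points)
    t_grid = np.asarray(t_grid, float)

    def rhs_aug(t: float, y: np.ndarray) -> np.ndarray:
        x = np.maximum(y[:n], 0.0)
        S = y[n:].reshape(n, p)
        J = net.jacobian(x, k)
        B = net.dfdk(x, k)[:, sub]
        return np.concatenate([net.rhs(x, k), (J @ S + B).ravel()])

    y0 = np.concatenate([x0, np.zeros(n * p)])
    sol = solve_ivp(
        rhs_aug, (float(t_grid[0]), float(t_grid[-1])), y0,
        method=method, t_eval=t_grid, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"sensitivity integration failed for parameter subset "
            f"{sub.tolist()}: {sol.message}"
        )
    states = np.maximum(sol.y[:n].T, 0.0)
    s = sol.y[n:].T.reshape(t_grid.size, n, p)
    return SensitivityField(t_grid, states, s, net.species_ids, sub, k)


def scale_and_time_average(
    field: SensitivityField, window: tuple[float, float]
) -> np.ndarray:
    """Dimensionless, trapezoid-time-averaged sensitivities.

    Each s_ij is scaled to (k_j/x_i(t))·∂x_i/∂k_j with x_i guarded by
    ``X_GUARD``, integrated over the window with the trapezoid rule and
    divided by the window length.  Returns n_species × n_params.
    """
    t0, tf = window
    if not tf > t0:
        raise ValueError(f"zero-width or inverted window {window}")
    if t0 < field.times[0] - 1e-12 or tf > field.times[-1] + 1e-12:
        raise ValueError(f"window {window} outside simulated span")
    mask = (field.times >= t0) & (field.times <= tf)
    times = field.times[mask]
    # include interpolated endpoints if the grid does not hit them exactly
    def interp_at(t: float) -> tuple[np.ndarray, np.ndarray]:
        xi = np.array(
            [np.interp(t, field.times, field.states[:, i])
             for i in range(field.states.shape[1])]
        )
        si = np.array(
            [[np.interp(t, field.times, field.s[:, i, j])
              for j in range(field.s.shape[2])]
             for i in range(field.s.shape[1])]
        )
        return xi, si

    xs = field.states[mask]
    ss = field.s[mask]
    if times.size == 0 or times[0] > t0 + 1e-12:
        xi, si = interp_at(t0)
        times = np.concatenate([[t0], times])
        xs = np.concatenate([xi[None], xs], axis=0)
        ss = np.concatenate([si[None], ss], axis=0)
    if times[-1] < tf - 1e-12:
        xi, si = interp_at(tf)
        times = np.concatenate([times, [tf]])
        xs = np.concatenate([xs, xi[None]], axis=0)
        ss = np.concatenate([ss, si[None]], axis=0)

    kj = field.rate_constants[field.param_indices]
    scaled = ss * kj[None, None, :] / np.maximum(xs, X_GUARD)[:, :, None]
    avg = np.trapezoid(scaled, times, axis=0) / (tf - t0)
    return avg


@dataclass
class SensitivityArray:
    """Scaled, time-averaged coefficients across an ensemble.

    ``A`` is n_params × (n_members · n_species) with column blocks aligned to
    ensemble members (member m's species i sits at column m·n_species + i).
    """

    A: np.ndarray
    species_ids: list[str]
    n_members: int

    @classmethod
    def from_member_matrices(
        cls, matrices: Sequence[np.ndarray], species_ids: Sequence[str]
    ) -> "SensitivityArray":
        """Stack per-member (n_species × n_params) matrices column-wise."""
        blocks = [m.T for m in matrices]  # each n_params x n_species
        return cls(np.hstack(blocks), list(species_ids), len(matrices))

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclass
class FragilityRanking:
    """Occurrence-fraction scores from the leading singular vectors."""

    species_scores: np.ndarray  # in [0, 1], one per species
    param_scores: np.ndarray  # in [0, 1], one per parameter (reaction)
    species_ids: list[str]
    k_used: int
    threshold: float
    window: tuple[float, float] | None = None
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species_ids,
                "condition": self.condition,
                "window_start": self.window[0] if self.window else np.nan,
                "window_end": self.window[1] if self.window else np.nan,
                "score": self.species_scores,
            }
        )


def svd_rank(
    array: SensitivityArray | np.ndarray,
    k_vectors: int | None = None,
    threshold: float = 0.001,
    *,
    energy: float = 0.95,
    species_ids: Sequence[str] | None = None,
    n_members: int = 1,
    window: tuple[float, float] | None = None,
    condition: str = "",
) -> FragilityRanking:
    """Fragility ranking by SVD of the sensitivity array.

    The left singular vectors (parameter axis) and right singular vectors
    (member·species axis) of the ``k_vectors`` largest singular values are
    thresholded at ``threshold``; an index's score is the fraction of those
    vectors in which its coefficient magnitude exceeds the threshold.  Species
    scores aggregate over member blocks (a species is marked in a vector if
    any of its member entries passes).  If ``k_vectors`` is omitted it is the
    number of singular values capturing ``energy`` of the spectral energy.
    """
    if isinstance(array, SensitivityArray):
        A = array.A
        species_ids = array.species_ids
        n_members = array.n_members
    else:
        A = np.asarray(array, dtype=float)
        if species_ids is None:
            species_ids = [f"s{i}" for i in range(A.shape[1] // n_members)]
    if not np.all(np.isfinite(A)):
        raise ValueError("sensitivity array contains non-finite entries")
    n_species = len(species_ids)
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size and sv[0] > 0 else 0
    if k_vectors is None:
        if sv.sum() > 0:
            frac = np.cumsum(sv**2) / np.sum(sv**2)
            k_vectors = int(np.searchsorted(frac, energy) + 1)
        else:
            k_vectors = 1
    if k_vectors > max(rank, 1):
        warnings.warn(
            f"k_vectors={k_vectors} exceeds matrix rank {rank}; clamping"
        )
        k_vectors = max(rank, 1)

    marked_params = np.abs(U[:, :k_vectors]) > threshold  # n_params x k
    param_scores = marked_params.sum(axis=1) / k_vectors

    V = Vt[:k_vectors].T  # (n_members*n_species) x k
    marked_species = np.zeros((n_species, k_vectors), dtype=bool)
    for m in range(n_members):
        block = np.abs(V[m * n_species : (m + 1) * n_species]) > threshold
        marked_species |= block
    species_scores = marked_species.sum(axis=1) / k_vectors

    return FragilityRanking(
        species_scores=species_scores,
        param_scores=param_scores,
        species_ids=list(species_ids),
        k_used=k_vectors,
        threshold=threshold,
        window=window,
        condition=condition,
    )


def ranking_comparison(
    rank_a: FragilityRanking, rank_b: FragilityRanking
) -> pd.DataFrame:
    """Paired per-species scores for two conditions/windows (scatter-plot
    table for ±stimulus, ±feedback or early-vs-late comparisons)."""
    if rank_a.species_ids != rank_b.species_ids:
        raise ValueError("rankings cover different species universes")
    return pd.DataFrame(
        {
            "species": rank_a.species_ids,
            "score_a": rank_a.species_scores,
            "score_b": rank_b.species_scores,
        }
    )


def ensemble_species_scores(
    net: ReactionNetwork,
    members: Sequence[ParameterVector],
    condition: Condition,
    window: tuple[float, float],
    *,
    k_vectors: int | None = None,
    threshold: float = 0.001,
    param_subset: Sequence[int] | None = None,
    solver_options: Mapping | None = None,
) -> pd.DataFrame:
    """Per-species fragility scores over an ensemble, with standard errors.

    Each member's scaled, time-averaged sensitivity matrix is ranked by SVD
    separately; the table reports the mean score and one standard error
    across members, plus the pooled-array score (all members stacked into a
    single array before decomposition).
    """
    solver_options = dict(solver_options or {})
    per_member = []
    matrices = []
    for params in members:
        c_net, c_params = condition.apply(net, params)
        field = solve_sensitivities(
            c_net, c_params, condition.protocol, param_subset, **solver_options
        )
        M = scale_and_time_average(field, window)
        matrices.append(M)
        r = svd_rank(
            SensitivityArray.from_member_matrices([M], net.species_ids),
            k_vectors,
            threshold,
            window=window,
            condition=condition.name,
        )
        per_member.append(r.species_scores)
    per_member = np.array(per_member)
    pooled = svd_rank(
        SensitivityArray.from_member_matrices(matrices, net.species_ids),
        k_vectors,
        threshold,
        window=window,
        condition=condition.name,
    )
    n = len(members)
    stderr = per_member.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(
        net.n_species
    )
    return pd.DataFrame(
        {
            "species": net.species_ids,
            "condition": condition.name,
            "window_start": window[0],
            "window_end": window[1],
            "score": per_member.mean(axis=0),
            "stderr": stderr,
            "pooled_score": pooled.species_scores,
        }
    )
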