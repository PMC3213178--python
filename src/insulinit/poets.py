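"""Pareto Optimal Ensemble Technique (POETs): multiobjective simulated
annealing with Pareto-rank fitness, interleaved pattern search, leave-three-out
cross-validation and sub-ensemble selection.

A candidate parameter set is scored by one squared error per training
objective.  Its fitness is the Fonseca–Fleming Pareto rank — the number of
archived parameter sets whose error vectors dominate it — and it is accepted
with probability exp(−rank/T), so nondominated candidates (rank 0) are always
accepted.  The annealing temperature is discretised into 10 quanta and cooled
geometrically; the epoch counter advances after every ``epoch_size`` additions
to the archive.  The outcome is not a single best fit but an experimentally
constrained population of models whose spread quantifies parametric
uncertainty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ParameterVector

__all__ = [
    "ArchiveEntry",
    "AnnealingState",
    "CVFold",
    "EnsembleArchive",
    "POETSConfig",
    "dominates",
    "pareto_rank",
    "acceptance_probability",
    "perturb",
    "pattern_search",
    "run_poets",
    "make_cv_folds",
    "select_subensemble",
    "parameter_cv",
    "random_control_parameters",
]


def dominates(e1: np.ndarray, e2: np.ndarray) -> bool:
    """True iff e1 ≤ e2 elementwise with strict inequality somewhere."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError(f"error vectors differ in length: {e1.shape} vs {e2.shape}")
    return bool(np.all(e1 <= e2) and np.any(e1 < e2))


def pareto_rank(candidate_errors: np.ndarray, archive_errors: np.ndarray) -> int:
    """Fonseca–Fleming rank: how many archived error vectors dominate the
    candidate.  Rank 0 means nondominated."""
    cand = np.asarray(candidate_errors, dtype=float)
    arch = np.asarray(archive_errors, dtype=float)
    if arch.size == 0:
        return 0
    arch = arch.reshape(-1, cand.size)
    le = arch <= cand
    lt = arch < cand
    return int(np.sum(le.all(axis=1) & lt.any(axis=1)))


def acceptance_probability(rank: int, T: float) -> float:
    """exp(−rank/T); exactly 1 for rank 0."""
    if T <= 0:
        raise ValueError(f"annealing temperature must be > 0, got {T}")
    if rank < 0:
        raise ValueError("Pareto rank must be >= 0")
    return float(np.exp(-rank / T))


def perturb(
    params: ParameterVector,
    magnitude: float,
    rng: np.random.Generator,
    *,
    perturb_initial_conditions: bool = True,
) -> ParameterVector:
    """Multiply each parameter by a factor drawn uniformly from
    [1−magnitude, 1+magnitude]; nonnegativity is preserved by construction."""
    if not 0 < magnitude < 1:
        raise ValueError("perturbation magnitude must lie in (0, 1)")
    k = params.rate_constants * rng.uniform(
        1 - magnitude, 1 + magnitude, params.rate_constants.size
    )
    if perturb_initial_conditions:
        x0 = params.initial_conditions * rng.uniform(
            1 - magnitude, 1 + magnitude, params.initial_conditions.size
        )
    else:
        x0 = params.initial_conditions.copy()
    return ParameterVector(k, x0)


def pattern_search(
    params: ParameterVector,
    objective_index: int,
    evaluate: Callable[[ParameterVector], np.ndarray],
    *,
    steps: int = 20,
    step_factor: float = 1.5,
    shrink: float = 0.5,
    min_factor: float = 1.00005,
    perturb_initial_conditions: bool = True,
) -> ParameterVector:
    """Local coordinate polling on a single objective's residual.

    Each poll multiplies/divides one parameter by ``step_factor`` and keeps
    the move only if the selected objective's error decreases; a full sweep
    without improvement shrinks the step toward 1.  The result never has a
    larger error on the selected objective than the input.
    """
    best = params.copy()
    best_err = float(evaluate(best)[objective_index])
    n_k = best.rate_constants.size
    n_x = best.initial_conditions.size if perturb_initial_conditions else 0
    factor = step_factor
    polls = 0
    while polls < steps and factor > min_factor:
        improved = False
        for i in range(n_k + n_x):
            if polls >= steps:
                break
            for f in (factor, 1.0 / factor):
                trial = best.copy()
                if i < n_k:
                    trial.rate_constants[i] *= f
                else:
                    trial.initial_conditions[i - n_k] *= f
                err = float(evaluate(trial)[objective_index])
                polls += 1
                if err < best_err:
                    best, best_err = trial, err
                    improved = True
                    break
                if polls >= steps:
                    break
        if not improved:
            factor = 1.0 + (factor - 1.0) * shrink
    return best


@dataclass
class ArchiveEntry:
    """One accepted parameter set with its per-objective errors and rank."""

    params: ParameterVector
    errors: np.ndarray
    rank: int = 0
    iteration: int = 0
    fold_id: int = -1

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)


@dataclass
class AnnealingState:
    """Bookkeeping for the discretised cooling schedule."""

    T: float
    quantum_index: int = 0
    epoch: int = 0
    members_added: int = 0


@dataclass(frozen=True)
class CVFold:
    fold_id: int
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]


@dataclass
class POETSConfig:
    """Free constants of the POETs schedule, all explicit and logged.

    The schedule *structure* (10 temperature quanta, epoch advance per fixed
    number of archive additions, a terminal temperature) is part of the
    method; the numeric defaults below are tunable configuration.
    """

    iterations: int = 2000
    perturbation_magnitude: float = 0.25
    pattern_search_interval: int = 10  # accepted steps between local searches
    pattern_search_steps: int = 20
    n_quanta: int = 10
    t0_multiplier: float = 10.0
    t_final: float = 0.1
    epoch_size: int = 100
    perturb_initial_conditions: bool = True
    rerank_each_epoch: bool = True

    def temperature_ladder(self, initial_max_error: float) -> np.ndarray:
        t0 = max(self.t0_multiplier * max(initial_max_error, 0.0), self.t_final * 1.0001)
        # geometric descent over n_quanta quanta from t0 to t_final
        ratio = (self.t_final / t0) ** (1.0 / (self.n_quanta - 1))
        return t0 * ratio ** np.arange(self.n_quanta)


class EnsembleArchive:
    """Accepted parameter sets with per-objective errors and Pareto ranks."""

    def __init__(
        self,
        entries: Sequence[ArchiveEntry] | None = None,
        *,
        seed: int | None = None,
        config: Mapping | None = None,
        trace: list[dict] | None = None,
        n_reactions: int | None = None,
    ):
        self.entries: list[ArchiveEntry] = list(entries or [])
        self.seed = seed
        self.config = dict(config or {})
        self.trace = list(trace or [])
        self.n_reactions = n_reactions
        self.mean_pairwise_correlation: float | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def errors_matrix(self) -> np.ndarray:
        return np.array([e.errors for e in self.entries])

    def params_matrix(self) -> np.ndarray:
        """Flat parameter matrix, one row per member ([rates, initials])."""
        return np.array([e.params.as_array() for e in self.entries])

    def rate_constant_matrix(self) -> np.ndarray:
        return np.array([e.params.rate_constants for e in self.entries])

    def recompute_ranks(self) -> None:
        """Exact Fonseca–Fleming re-ranking of every entry over the archive."""
        errs = self.errors_matrix()
        for i, entry in enumerate(self.entries):
            others = np.delete(errs, i, axis=0)
            entry.rank = pareto_rank(entry.errors, others)

    def rank_zero(self) -> list[ArchiveEntry]:
        return [e for e in self.entries if e.rank == 0]

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """CSV matrix (members × parameters) + JSON sidecar (ranks, errors,
        seed, config)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.params_matrix()).to_csv(
            directory / "ensemble_parameters.csv", index=False
        )
        sidecar = {
            "seed": self.seed,
            "config": self.config,
            "n_reactions": self.n_reactions,
            "ranks": [int(e.rank) for e in self.entries],
            "iterations": [int(e.iteration) for e in self.entries],
            "fold_ids": [int(e.fold_id) for e in self.entries],
            "errors": [list(map(float, e.errors)) for e in self.entries],
            "mean_pairwise_correlation": self.mean_pairwise_correlation,
        }
        (directory / "ensemble_meta.json").write_text(json.dumps(sidecar, indent=1))
        if self.trace:
            pd.DataFrame(self.trace).to_csv(directory / "acceptance_trace.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleArchive":
        directory = Path(directory)
        mat = pd.read_csv(directory / "ensemble_parameters.csv").to_numpy()
        meta = json.loads((directory / "ensemble_meta.json").read_text())
        n_r = meta["n_reactions"]
        entries = [
            ArchiveEntry(
                ParameterVector.from_array(row, n_r),
                np.asarray(err),
                rank=rank,
                iteration=it,
                fold_id=fid,
            )
            for row, err, rank, it, fid in zip(
                mat, meta["errors"], meta["ranks"], meta["iterations"], meta["fold_ids"]
            )
        ]
        out = cls(entries, seed=meta["seed"], config=meta["config"], n_reactions=n_r)
        out.mean_pairwise_correlation = meta.get("mean_pairwise_correlation")
        return out

    @classmethod
    def load_flat_files(
        cls, paths: Iterable[str | Path], n_reactions: int
    ) -> "EnsembleArchive":
        """Ingest a directory of flat parameter files (one whitespace- or
        newline-separated vector per file), the layout used by published
        POETs ensembles."""
        entries = []
        for p in sorted(Path(p) for p in paths):
            vec = np.loadtxt(p).ravel()
            entries.append(
                ArchiveEntry(ParameterVector.from_array(vec, n_reactions), np.array([]))
            )
        return cls(entries, n_reactions=n_reactions)


def run_poets(
    evaluate: Callable[[ParameterVector], np.ndarray],
    initial_params: ParameterVector,
    config: POETSConfig,
    rng: np.random.Generator,
    *,
    fold_id: int = -1,
    seed: int | None = None,
    n_reactions: int | None = None,
) -> EnsembleArchive:
    """Run the annealing loop and return the ensemble archive.

    ``evaluate`` maps a parameter vector to the training-objective error
    vector (``inf`` entries flag simulation failures; such candidates are
    rejected and logged).  Per iteration: perturb the current point, score
    it, Pareto-rank it against the archive, accept with exp(−rank/T); the
    pattern search refines the current point on one randomly chosen objective
    every ``pattern_search_interval`` accepted steps.
    """
    initial_errors = np.asarray(evaluate(initial_params), dtype=float)
    if not np.all(np.isfinite(initial_errors)):
        raise RuntimeError("initial parameter set does not simulate without error")
    ladder = config.temperature_ladder(float(initial_errors.max()))
    state = AnnealingState(T=float(ladder[0]))
    archive = EnsembleArchive(
        [ArchiveEntry(initial_params.copy(), initial_errors, iteration=0, fold_id=fold_id)],
        seed=seed,
        config=asdict(config),
        n_reactions=n_reactions
        if n_reactions is not None
        else initial_params.rate_constants.size,
    )
    arch_errs = [initial_errors]
    current = initial_params.copy()

    def add(entry: ArchiveEntry) -> None:
        archive.entries.append(entry)
        arch_errs.append(entry.errors)
        state.members_added += 1
        if state.members_added % config.epoch_size == 0:
            state.epoch += 1
            state.quantum_index = min(state.epoch, config.n_quanta - 1)
            state.T = float(ladder[state.quantum_index])
            if config.rerank_each_epoch:
                archive.recompute_ranks()

    for it in range(1, config.iterations + 1):
        candidate = perturb(
            current,
            config.perturbation_magnitude,
            rng,
            perturb_initial_conditions=config.perturb_initial_conditions,
        )
        errors = np.asarray(evaluate(candidate), dtype=float)
        if not np.all(np.isfinite(errors)):
            archive.trace.append(
                {"iteration": it, "rank": -1, "T": state.T, "accepted": False,
                 "failed": True}
            )
            continue
        rank = pareto_rank(errors, np.array(arch_errs))
        p = acceptance_probability(rank, state.T)
        accepted = rank == 0 or rng.random() <= p
        archive.trace.append(
            {"iteration": it, "rank": rank, "T": state.T, "accepted": bool(accepted),
             "failed": False}
        )
        if not accepted:
            continue
        add(ArchiveEntry(candidate, errors, rank=rank, iteration=it, fold_id=fold_id))
        current = candidate
        if (
            config.pattern_search_interval > 0
            and state.members_added % config.pattern_search_interval == 0
        ):
            obj_idx = int(rng.integers(errors.size))
            refined = pattern_search(
                current,
                obj_idx,
                evaluate,
                steps=config.pattern_search_steps,
                perturb_initial_conditions=config.perturb_initial_conditions,
            )
            ref_errors = np.asarray(evaluate(refined), dtype=float)
            if np.all(np.isfinite(ref_errors)):
                ref_rank = pareto_rank(ref_errors, np.array(arch_errs))
                add(
                    ArchiveEntry(
                        refined, ref_errors, rank=ref_rank, iteration=it, fold_id=fold_id
                    )
                )
                current = refined

    archive.recompute_ranks()
    return archive


def make_cv_folds(
    objective_ids: Sequence[str],
    rng: np.random.Generator,
    *,
    holdout_size: int = 3,
) -> list[CVFold]:
    """Leave-``holdout_size``-out partition: disjoint validation triples
    covering every objective exactly once (24 objectives → 8 folds of
    21 train / 3 validation)."""
    ids = list(objective_ids)
    if len(ids) % holdout_size != 0:
        raise ValueError(
            f"{len(ids)} objectives not divisible by holdout size {holdout_size}"
        )
    order = list(rng.permutation(len(ids)))
    folds = []
    n_folds = len(ids) // holdout_size
    for f in range(n_folds):
        val = tuple(ids[i] for i in order[f * holdout_size : (f + 1) * holdout_size])
        train = tuple(i for i in ids if i not in val)
        folds.append(CVFold(fold_id=f, train_ids=train, validation_ids=val))
    return folds


def _log_params(mat: np.ndarray) -> np.ndarray:
    return np.log10(np.maximum(mat, 1e-12))


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two members' log rate-constant vectors;
    degenerate (zero-variance) vectors count as perfectly correlated."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


def mean_pairwise_correlation(rate_matrix: np.ndarray) -> float:
    """Mean signed Pearson correlation over member pairs (log rates)."""
    lm = _log_params(rate_matrix)
    n = lm.shape[0]
    if n < 2:
        return 1.0
    vals = [
        _pairwise_corr(lm[i], lm[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def select_subensemble(
    archives: Sequence[EnsembleArchive],
    n_per_fold: int,
    rng: np.random.Generator,
    *,
    candidate_pool: int = 32,
) -> EnsembleArchive:
    """Iteratively select low-correlation, low-error rank-0 models per fold.

    Starting from the rank-0 entry nearest the origin in error space, each
    step samples candidates from the remaining rank-0 pool and keeps the one
    minimising the sum of its mean signed Pearson correlation (log rate
    constants) with the members already selected and its error-vector norm
    scaled by the pool median — balancing low correlation against short
    distance to the origin.  The achieved mean pairwise correlation is
    reported on the result.
    """
    if not archives:
        raise ValueError("no archives to select from")
    selected: list[ArchiveEntry] = []
    for arch in archives:
        arch.recompute_ranks()
        pool = arch.rank_zero()
        if len(pool) < n_per_fold:
            warnings.warn(
                f"fold {pool[0].fold_id if pool else '?'}: only {len(pool)} "
                f"rank-0 entries for a request of {n_per_fold}; selecting all"
            )
            selected.extend(pool)
            continue
        norms = np.array([np.linalg.norm(e.errors) for e in pool])
        norm_scale = max(float(np.median(norms)), 1e-12)
        picked = [int(np.argmin(norms))]
        while len(picked) < n_per_fold:
            remaining = [i for i in range(len(pool)) if i not in picked]
            cand = rng.choice(
                remaining, size=min(candidate_pool, len(remaining)), replace=False
            )
            sel_logs = _log_params(
                np.array([pool[i].params.rate_constants for i in picked])
            )
            best_i, best_key = None, None
            for i in cand:
                cl = _log_params(pool[int(i)].params.rate_constants[None, :])[0]
                corr = float(
                    np.mean([_pairwise_corr(cl, s) for s in sel_logs])
                )
                key = corr + norms[int(i)] / norm_scale
                if best_key is None or key < best_key:
                    best_i, best_key = int(i), key
            picked.append(best_i)
        selected.extend(pool[i] for i in picked)
    out = EnsembleArchive(
        [ArchiveEntry(e.params.copy(), e.errors.copy(), e.rank, e.iteration, e.fold_id)
         for e in selected],
        n_reactions=archives[0].n_reactions,
    )
    out.mean_pairwise_correlation = mean_pairwise_correlation(
        out.rate_constant_matrix()
    )
    return out


def parameter_cv(ensemble: EnsembleArchive) -> np.ndarray:
    """Per-rate-constant coefficient of variation (sample std / mean) across
    ensemble members — the spread statistic used to judge how strongly the
    training data constrain each parameter."""
    if len(ensemble) < 2:
        raise ValueError("parameter CV needs at least two ensemble members")
    mat = ensemble.rate_constant_matrix()
    mean = mat.mean(axis=0)
    std = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, std / mean, 0.0)
    return cv


def random_control_parameters(
    nominal: ParameterVector,
    rng: np.random.Generator,
    *,
    decades: float = 1.0,
    randomize_initial_conditions: bool = False,
) -> ParameterVector:
    """Random-parameter control: rate constants drawn log-uniformly within
    ±``decades`` of nominal (the baseline against which trained errors are
    judged)."""
    k = nominal.rate_constants * 10.0 ** rng.uniform(
        -decades, decades, nominal.rate_constants.size
    )
    if randomize_initial_conditions:
        x0 = nominal.initial_conditions * 10.0 ** rng.uniform(
            -decades, decades, nominal.initial_conditions.size
        )
    else:
        x0 = nominal.initial_conditions.copy()
    return ParameterVector(k, x0)
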