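"""Synthetic study system: a reduced insulin→translation-initiation network,
frozen ground-truth parameters, pseudo-immunoblot training objectives and
random networks for property tests.

The toy network (29 species, 32 mass-action reactions) preserves the signal
flow of the full insulin-initiation pathway: ligand–receptor binding, IRS-1
adaptor assembly, PI3K activation, PIP2→PIP3 conversion opposed by PTEN, Akt
activation, Akt inhibition of the TSC1/2 GAP, Rheb-GDP/GTP cycling, mTORC1
and mTORC2 activation, S6K1 activation, 4E-BP1 phosphorylation releasing
eIF4E, and eIF4E-dependent 80S assembly that consumes GTP.  GTP is an
explicit finite species consumed by both Rheb loading and 80S assembly, so
GTP limitation under strong Rheb–GTP association is representable.  S6K1
feedback on the IRS-1 adaptor is a removable switch.

Inhibitor analogues (wortmannin, rapamycin) zero the target activation rates
rather than introducing new species.  Pseudo-immunoblot objectives carry
multiplicative lognormal noise standing in for blot quantitation error.

The ground-truth rate constants are a hand-tuned, frozen fixture: the
qualitative behaviour of the system (basal initiation restrained by PTEN,
inducible initiation through PI3K, GTP-limited outlier regime) depends on
the kinetic regime, not on any particular published constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import ParameterVector, Reaction, ReactionNetwork, Species, write_network
from .objectives import Evaluator, ExperimentalSeries, save_objectives
from .poets import (
    EnsembleArchive,
    POETSConfig,
    make_cv_folds,
    perturb,
    random_control_parameters,
    run_poets,
    select_subensemble,
)
from .simulate import Condition, StimulusProtocol, knockdown, simulate_protocol
from .robustness import robustness_coefficient

__all__ = [
    "ToyModelBundle",
    "NoiseModel",
    "build_toy_insulin_network",
    "toy_conditions",
    "build_toy_bundle",
    "generate_objectives",
    "random_network",
    "recovery_experiment",
    "PI3K_AXIS",
    "MARKER",
]

#: the translation-activity marker: the assembled 80S complex proxy
MARKER = "R80S"

#: PI3K/Akt signalling-axis species used in feedback-sensitivity comparisons
PI3K_AXIS = ("PI3K", "PI3Ka", "PIP3", "Akt", "Akta")

# frozen ground-truth rate constants [1/min in appropriate composite units]
_TRUTH_K: dict[str, float] = {
    "r01": 1.0,    # Ins + IR -> IRa              ligand binding/activation
    "r02": 0.05,   # IRa -> IR                    receptor deactivation
    "r03": 1.0,    # IRa + IRS1 -> IRIRS          adaptor assembly
    "r04": 0.2,    # IRIRS -> IRa + IRS1          adaptor disassembly
    "r05": 2.0,    # IRIRS + PI3K -> IRIRS + PI3Ka
    "r06": 0.01,   # PI3K -> PI3Ka                basal activation
    "r07": 1.0,    # PI3Ka -> PI3K
    "r08": 0.5,    # PI3Ka + PIP2 -> PI3Ka + PIP3
    "r09": 2.0,    # PTEN + PIP3 -> PTEN + PIP2
    "r10": 1.0,    # PIP3 + Akt -> PIP3 + Akta    (PDK1 implicit)
    "r11": 1.0,    # Akta -> Akt
    "r12": 2.0,    # Akta + TSC -> Akta + TSCi
    "r13": 0.5,    # TSCi -> TSC
    "r14": 0.1,    # RhebGDP + GTP -> RhebGTP     nucleotide loading
    "r15": 2.0,    # TSC + RhebGTP -> TSC + RhebGDP   GAP hydrolysis
    "r16": 0.1,    # RhebGTP -> RhebGDP           intrinsic hydrolysis
    "r17": 2.0,    # RhebGTP + mTORC1 -> RhebGTP + mTORC1a
    "r18": 1.0,    # mTORC1a -> mTORC1
    "r19": 0.5,    # PIP3 + mTORC2 -> PIP3 + mTORC2a
    "r20": 0.5,    # mTORC2a -> mTORC2
    "r21": 0.5,    # mTORC2a + Akt -> mTORC2a + Akta
    "r22": 2.0,    # mTORC1a + S6K1 -> mTORC1a + S6K1a
    "r23": 1.0,    # S6K1a -> S6K1
    "r24": 2.0,    # mTORC1a + BP1_4E -> mTORC1a + BP1p + eIF4E
    "r25": 0.5,    # BP1p -> BP1                  dephosphorylation
    "r26": 2.0,    # BP1 + eIF4E -> BP1_4E        re-sequestration
    "r27": 0.1,    # eIF4E + GTP -> eIF4E + R80S  GTP-dependent 80S assembly
    "r28": 0.2,    # R80S -> 0                    ribosome recycling
    "r29": 0.5,    # 0 -> GTP                     nucleotide supply
    "r30": 0.05,   # GTP -> 0                     nucleotide turnover
    "r31": 1.0,    # S6K1a + IRIRS -> S6K1a + IRa + IRS1i   IRS-1 feedback
    "r32": 0.2,    # IRS1i -> IRS1                IRS-1 recovery
    "r33": 0.03,   # BP1_4E -> BP1p + eIF4E       slow basal eIF4E release
}

_TRUTH_X0: dict[str, float] = {
    "Ins": 0.0, "IR": 2.0, "IRa": 0.0, "IRS1": 1.0, "IRS1i": 0.0, "IRIRS": 0.0,
    "PI3K": 1.0, "PI3Ka": 0.0, "PIP2": 5.0, "PIP3": 0.0, "PTEN": 1.0,
    "Akt": 1.0, "Akta": 0.0, "TSC": 1.0, "TSCi": 0.0,
    "RhebGDP": 1.0, "RhebGTP": 0.0, "mTORC1": 1.0, "mTORC1a": 0.0,
    "mTORC2": 1.0, "mTORC2a": 0.0, "S6K1": 1.0, "S6K1a": 0.0,
    "BP1_4E": 1.0, "BP1p": 0.0, "BP1": 0.0, "eIF4E": 0.0,
    "GTP": 5.0, "R80S": 0.0,
}

_REACTIONS: list[tuple[str, str, str]] = [
    ("r01", "Ins + IR", "IRa"),
    ("r02", "IRa", "IR"),
    ("r03", "IRa + IRS1", "IRIRS"),
    ("r04", "IRIRS", "IRa + IRS1"),
    ("r05", "IRIRS + PI3K", "IRIRS + PI3Ka"),
    ("r06", "PI3K", "PI3Ka"),
    ("r07", "PI3Ka", "PI3K"),
    ("r08", "PI3Ka + PIP2", "PI3Ka + PIP3"),
    ("r09", "PTEN + PIP3", "PTEN + PIP2"),
    ("r10", "PIP3 + Akt", "PIP3 + Akta"),
    ("r11", "Akta", "Akt"),
    ("r12", "Akta + TSC", "Akta + TSCi"),
    ("r13", "TSCi", "TSC"),
    ("r14", "RhebGDP + GTP", "RhebGTP"),
    ("r15", "TSC + RhebGTP", "TSC + RhebGDP"),
    ("r16", "RhebGTP", "RhebGDP"),
    ("r17", "RhebGTP + mTORC1", "RhebGTP + mTORC1a"),
    ("r18", "mTORC1a", "mTORC1"),
    ("r19", "PIP3 + mTORC2", "PIP3 + mTORC2a"),
    ("r20", "mTORC2a", "mTORC2"),
    ("r21", "mTORC2a + Akt", "mTORC2a + Akta"),
    ("r22", "mTORC1a + S6K1", "mTORC1a + S6K1a"),
    ("r23", "S6K1a", "S6K1"),
    ("r24", "mTORC1a + BP1_4E", "mTORC1a + BP1p + eIF4E"),
    ("r25", "BP1p", "BP1"),
    ("r26", "BP1 + eIF4E", "BP1_4E"),
    ("r27", "eIF4E + GTP", "eIF4E + R80S"),
    ("r28", "R80S", ""),
    ("r29", "", "GTP"),
    ("r30", "GTP", ""),
    ("r31", "S6K1a + IRIRS", "S6K1a + IRa + IRS1i"),
    ("r32", "IRS1i", "IRS1"),
    ("r33", "BP1_4E", "BP1p + eIF4E"),
]

#: rate-constant overrides defining the strong Rheb–GTP association variant,
#: the regime in which GTP limitation makes a Rheb knockdown pro-initiation
STRONG_RHEB_OVERRIDES: dict[str, float] = {"r14": 10.0, "r29": 0.2}


def _parse_terms(text: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for term in text.split("+"):
        term = term.strip()
        if "*" in term:
            coef, sid = term.split("*")
            out.append((sid.strip(), int(coef)))
        else:
            out.append((term, 1))
    return tuple(out)


def build_toy_insulin_network(strong_rheb: bool = False) -> ReactionNetwork:
    """Deterministic reduced insulin-initiation network with truth constants.

    ``strong_rheb=True`` returns the variant with strong Rheb–GTP association
    and restricted nucleotide supply (the GTP-limited outlier regime).
    """
    k = dict(_TRUTH_K)
    if strong_rheb:
        k.update(STRONG_RHEB_OVERRIDES)
    species = [Species(sid, sid, x0) for sid, x0 in _TRUTH_X0.items()]
    reactions = [
        Reaction(rid, _parse_terms(lhs), _parse_terms(rhs), k[rid])
        for rid, lhs, rhs in _REACTIONS
    ]
    return ReactionNetwork(species, reactions)


#: default insulin stimulus (added to the basal receptor-ligand pool)
INSULIN_DOSE = 2.0


def toy_conditions(horizon: float = 100.0) -> dict[str, Condition]:
    """The study conditions: ±insulin, inhibitor analogues, feedback off."""
    ins = StimulusProtocol("Ins", INSULIN_DOSE, horizon=horizon)
    none = StimulusProtocol((), 0.0, horizon=horizon)
    return {
        "basal": Condition("basal", none),
        "insulin": Condition("insulin", ins),
        # wortmannin analogue: PI3K activation rates zeroed
        "wortmannin": Condition(
            "wortmannin", ins, rate_multipliers={"r05": 0.0, "r06": 0.0}
        ),
        # rapamycin analogue: mTORC1 catalytic rates zeroed
        "rapamycin": Condition(
            "rapamycin", ins, rate_multipliers={"r22": 0.0, "r24": 0.0}
        ),
        "feedback_off": Condition("feedback_off", ins, rate_multipliers={"r31": 0.0}),
        "basal_feedback_off": Condition(
            "basal_feedback_off", none, rate_multipliers={"r31": 0.0}
        ),
    }


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise emulating blot quantitation error.

    Raw value = simulated readout × LN(1, cv); zero cv reproduces the
    simulation exactly.
    """

    multiplicative_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValueError("noise cv must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.multiplicative_cv == 0:
            return np.asarray(values, float).copy()
        sigma = np.sqrt(np.log1p(self.multiplicative_cv**2))
        factors = rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(values))
        return np.asarray(values, float) * factors


# the 24 pseudo-immunoblot objectives: (id, readout species, shape)
_TIMECOURSE_TIMES = (0.0, 2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 100.0)
_OBJECTIVE_PLAN: list[tuple[str, tuple[str, ...], list[tuple[str, float]]]] = (
    [
        ("O01", ("Akta",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O02", ("Akta",), [("rapamycin", t) for t in _TIMECOURSE_TIMES]),
        ("O03", ("S6K1a",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O04", ("RhebGTP",), [("rapamycin", t) for t in _TIMECOURSE_TIMES]),
        ("O05", ("BP1p",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O06", ("R80S",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O07", ("PIP3",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O08", ("RhebGTP",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O09", ("Akta",), [("feedback_off", t) for t in _TIMECOURSE_TIMES]),
        ("O10", ("S6K1a",), [("feedback_off", t) for t in _TIMECOURSE_TIMES]),
        ("O11", ("IRIRS",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O12", ("R80S",), [("feedback_off", t) for t in _TIMECOURSE_TIMES]),
        ("O13", ("mTORC1a",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O14", ("TSCi",), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        # phospho-band pooling: both unbound 4E-BP1 forms map to one band
        ("O15", ("BP1p", "BP1"), [("insulin", t) for t in _TIMECOURSE_TIMES]),
        ("O16", ("R80S",), [("rapamycin", t) for t in _TIMECOURSE_TIMES]),
        # condition-comparison bar sets at a single sampling time
        ("O17", ("Akta",), [("basal", 20.0), ("insulin", 20.0), ("wortmannin", 20.0)]),
        ("O18", ("S6K1a",), [("basal", 15.0), ("insulin", 15.0), ("rapamycin", 15.0)]),
        ("O19", ("R80S",), [("basal", 60.0), ("insulin", 60.0), ("wortmannin", 60.0)]),
        ("O20", ("PIP3",), [("basal", 10.0), ("insulin", 10.0), ("wortmannin", 10.0)]),
        ("O21", ("BP1p",), [("basal", 20.0), ("insulin", 20.0), ("rapamycin", 20.0)]),
        ("O22", ("RhebGTP",), [("basal", 30.0), ("insulin", 30.0), ("rapamycin", 30.0)]),
        ("O23", ("Akta",), [("basal", 40.0), ("insulin", 40.0), ("feedback_off", 40.0)]),
        ("O24", ("S6K1a",), [("basal", 40.0), ("insulin", 40.0), ("feedback_off", 40.0)]),
    ]
)


def generate_objectives(
    net: ReactionNetwork,
    params: ParameterVector,
    conditions: Mapping[str, Condition],
    noise: NoiseModel = NoiseModel(),
    *,
    solver_options: Mapping | None = None,
) -> list[ExperimentalSeries]:
    """Simulate the truth model and emit the 24 pseudo-immunoblot objectives.

    Each objective samples a readout (sum of mapped species) at its plan's
    (condition, time) points and multiplies by lognormal noise.  Zero noise
    gives exact self-consistency: the truth parameters score an error of
    zero on every objective.
    """
    rng = np.random.default_rng(noise.seed)
    solver_options = dict(solver_options or {})
    ivp = {k: v for k, v in solver_options.items() if k in ("rtol", "atol", "method")}
    ss = {k: v for k, v in solver_options.items()
          if k in ("dt", "eps", "max_windows", "norm")}
    needed = {c for _, _, pts in _OBJECTIVE_PLAN for c, _ in pts}
    trajs = {}
    for name in needed:
        cond = conditions[name]
        c_net, c_params = cond.apply(net, params)
        trajs[name] = simulate_protocol(c_net, c_params, cond.protocol, **ss, **ivp)
    out = []
    for oid, readout, pts in _OBJECTIVE_PLAN:
        conds = tuple(c for c, _ in pts)
        times = np.array([t for _, t in pts])
        raw = np.array(
            [trajs[c].at(readout, np.array([t]))[0] for c, t in pts]
        )
        out.append(
            ExperimentalSeries(oid, readout, conds, times, noise.apply(raw, rng))
        )
    return out


@dataclass
class ToyModelBundle:
    """The complete synthetic study system the pipeline trains on."""

    network: ReactionNetwork
    truth_params: ParameterVector
    objectives: list[ExperimentalSeries]
    conditions: dict[str, Condition]
    noise: NoiseModel
    seed: int

    def evaluator(self, **solver_options) -> Evaluator:
        return Evaluator(
            self.network, self.objectives, self.conditions,
            solver_options=solver_options,
        )

    def write(self, directory: str | Path) -> Path:
        """Write the bundle in the exact formats the pipeline consumes:
        network text file + SBML, truth-parameter CSV, objective YAML+CSVs."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_network(self.network, directory / "network.txt", format="text")
        write_network(self.network, directory / "network.xml", format="sbml")
        pd.DataFrame(
            {
                "name": self.network.reaction_ids + self.network.species_ids,
                "kind": ["rate"] * self.network.n_reactions
                + ["initial"] * self.network.n_species,
                "value": self.truth_params.as_array(),
            }
        ).to_csv(directory / "truth_parameters.csv", index=False)
        save_objectives(self.objectives, directory / "objectives")
        return directory


def build_toy_bundle(
    seed: int = 0,
    noise_cv: float = 0.1,
    *,
    strong_rheb: bool = False,
    horizon: float = 100.0,
    solver_options: Mapping | None = None,
) -> ToyModelBundle:
    """Assemble the toy network, truth parameters, conditions and noisy
    objectives.  Fully seeded and reproducible."""
    net = build_toy_insulin_network(strong_rheb=strong_rheb)
    truth = net.nominal_parameters()
    conditions = toy_conditions(horizon=horizon)
    noise = NoiseModel(noise_cv, seed)
    objectives = generate_objectives(
        net, truth, conditions, noise, solver_options=solver_options
    )
    return ToyModelBundle(net, truth, objectives, conditions, noise, seed)


def random_network(
    n_species: int,
    n_reactions: int,
    seed: int,
    *,
    closed: bool = False,
) -> ReactionNetwork:
    """Connected random mass-action network for property tests.

    A uni-molecular chain backbone guarantees connectivity; remaining
    reactions are random uni- or bimolecular conversions.  In ``closed``
    mode every reaction conserves molecule count (A→B or A+B→C+D), so all
    stoichiometric-matrix columns sum to zero and total mass is invariant.
    """
    if n_species < 2:
        raise ValueError("random network needs at least 2 species")
    if n_reactions < n_species - 1:
        raise ValueError(
            f"{n_reactions} reactions cannot connect {n_species} species"
        )
    rng = np.random.default_rng(seed)
    ids = [f"X{i}" for i in range(n_species)]
    species = [
        Species(sid, sid, float(rng.uniform(0.2, 2.0))) for sid in ids
    ]
    reactions: list[Reaction] = []

    def k() -> float:
        return float(rng.lognormal(-0.5, 0.7))

    order = rng.permutation(n_species)
    for i in range(n_species - 1):  # connectivity backbone
        a, b = ids[order[i]], ids[order[i + 1]]
        reactions.append(Reaction(f"R{len(reactions)}", ((a, 1),), ((b, 1),), k()))
    while len(reactions) < n_reactions:
        if closed:
            if rng.random() < 0.5:
                a, b = rng.choice(n_species, 2, replace=False)
                r = Reaction(
                    f"R{len(reactions)}", ((ids[a], 1),), ((ids[b], 1),), k()
                )
            else:
                a, b, c, d = rng.choice(n_species, 4, replace=False)
                r = Reaction(
                    f"R{len(reactions)}",
                    ((ids[a], 1), (ids[b], 1)),
                    ((ids[c], 1), (ids[d], 1)),
                    k(),
                )
        else:
            kind = rng.random()
            if kind < 0.4:
                a, b = rng.choice(n_species, 2, replace=False)
                r = Reaction(f"R{len(reactions)}", ((ids[a], 1),), ((ids[b], 1),), k())
            elif kind < 0.8:
                a, b, c = rng.choice(n_species, 3, replace=False)
                r = Reaction(
                    f"R{len(reactions)}",
                    ((ids[a], 1), (ids[b], 1)),
                    ((ids[c], 1),),
                    k(),
                )
            else:  # degradation keeps random open networks bounded
                a = int(rng.integers(n_species))
                r = Reaction(f"R{len(reactions)}", ((ids[a], 1),), (), k())
        reactions.append(r)
    return ReactionNetwork(species, reactions)


def recovery_experiment(
    bundle: ToyModelBundle,
    config: POETSConfig,
    rng: np.random.Generator,
    *,
    n_folds: int = 1,
    n_select: int = 25,
    initial_jitter: float = 0.3,
    n_random_controls: int = 10,
    solver_options: Mapping | None = None,
) -> dict:
    """End-to-end pipeline harness: POETs on noisy objectives from truth.

    Runs ``n_folds`` leave-three-out folds of POETs (each from a jittered
    copy of the truth parameters, emulating an initial best-fit set), selects
    a low-correlation sub-ensemble, and reports: per-parameter truth coverage
    by the [5, 95] percentile interval of the sub-ensemble, held-out
    validation errors per fold, trained-vs-random errors per objective, and
    the toy knockdown switch table (PTEN basal / PI3K induced).
    """
    solver_options = dict(solver_options or {})
    ids = [o.objective_id for o in bundle.objectives]
    folds = make_cv_folds(ids, rng)
    by_id = {o.objective_id: o for o in bundle.objectives}
    archives = []
    validation_errors = {}
    trained_by_fold: dict[int, set[str]] = {}
    for fold in folds[:n_folds]:
        trained_by_fold[fold.fold_id] = set(fold.train_ids)
        train = [by_id[i] for i in fold.train_ids]
        ev = Evaluator(
            bundle.network, train, bundle.conditions, solver_options=solver_options
        )
        initial = perturb(bundle.truth_params, initial_jitter, rng)
        arch = run_poets(
            ev, initial, config, rng, fold_id=fold.fold_id,
            n_reactions=bundle.network.n_reactions,
        )
        archives.append(arch)
        val = [by_id[i] for i in fold.validation_ids]
        ev_val = Evaluator(
            bundle.network, val, bundle.conditions, solver_options=solver_options
        )
        arch.recompute_ranks()
        members = arch.rank_zero() or arch.entries
        val_errs = np.array([ev_val(e.params) for e in members[: min(20, len(members))]])
        validation_errors[fold.fold_id] = {
            "objective_ids": list(fold.validation_ids),
            "mean": val_errs.mean(axis=0).tolist(),
            "finite": bool(np.all(np.isfinite(val_errs))),
        }

    sub = select_subensemble(archives, n_select, rng)
    rates = sub.rate_constant_matrix()
    lo = np.percentile(rates, 5, axis=0)
    hi = np.percentile(rates, 95, axis=0)
    truth_k = bundle.truth_params.rate_constants
    covered = (truth_k >= lo) & (truth_k <= hi)
    coverage = float(covered.mean())

    # trained vs random-control errors, per objective
    ev_all = Evaluator(
        bundle.network, bundle.objectives, bundle.conditions,
        solver_options=solver_options,
    )
    members = sub.entries[: min(len(sub), 40)]
    trained = np.array([ev_all(e.params) for e in members])
    randoms = np.array(
        [
            ev_all(
                random_control_parameters(
                    bundle.truth_params, rng, randomize_initial_conditions=True
                )
            )
            for _ in range(n_random_controls)
        ]
    )
    # an objective's training error comes from the members of folds that
    # trained it; members whose simulation fails under a condition are
    # excluded from that objective's aggregate, with the count reported
    trained_cells = np.where(np.isfinite(trained), trained, np.nan)
    for j, oid in enumerate(ids):
        for i, e in enumerate(members):
            if oid not in trained_by_fold.get(e.fold_id, set()):
                trained_cells[i, j] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        trained_mean = np.nanmean(trained_cells, axis=0)
        random_mean = np.nanmean(
            np.where(np.isfinite(randoms), randoms, np.nan), axis=0
        )
    n_failed_cells = int(np.sum(~np.isfinite(trained)))
    comparable = np.isfinite(trained_mean) & np.isfinite(random_mean)

    return {
        "n_folds_run": n_folds,
        "sub_ensemble_size": len(sub),
        "mean_pairwise_correlation": sub.mean_pairwise_correlation,
        "coverage_5_95": coverage,
        "covered_parameters": covered.tolist(),
        "validation": validation_errors,
        "objective_ids": ids,
        "n_failed_trained_cells": n_failed_cells,
        "trained_mean_errors": trained_mean.tolist(),
        "random_mean_errors": random_mean.tolist(),
        "n_compared_objectives": int(comparable.sum()),
        "trained_beats_random": bool(
            comparable.any()
            and np.all(trained_mean[comparable] < random_mean[comparable])
        ),
        "knockdown_switch": knockdown_switch_table(solver_options=solver_options),
    }


def knockdown_switch_table(*, solver_options: Mapping | None = None) -> dict:
    """The qualitative knockdown switch of the toy model at truth parameters.

    PTEN knockdown without stimulus raises integrated 80S (basal initiation
    restrained by PTEN); PI3K knockdown with stimulus lowers it without
    abolishing it (inducible initiation through PI3K, basal through Rheb);
    in the strong Rheb–GTP variant a Rheb knockdown raises it (GTP
    limitation relieved).
    """
    # structural knockdowns can relax slowly; keep the full window budget
    solver_options = {
        k: v for k, v in dict(solver_options or {}).items() if k != "max_windows"
    }
    conds = toy_conditions()

    def coef(strong: bool, cond_name: str, targets: tuple[str, ...]) -> float:
        net = build_toy_insulin_network(strong_rheb=strong)
        params = net.nominal_parameters()
        cond = conds[cond_name]
        c_net, c_params = cond.apply(net, params)
        nominal = simulate_protocol(c_net, c_params, cond.protocol, **solver_options)
        kd_net, kd_params = knockdown(c_net, c_params, targets)
        perturbed = simulate_protocol(kd_net, kd_params, cond.protocol, **solver_options)
        return robustness_coefficient(
            perturbed, nominal, MARKER, 0.0, cond.protocol.horizon
        )

    return {
        "pten_kd_basal": coef(False, "basal", ("PTEN",)),
        "pi3k_kd_insulin": coef(False, "insulin", ("PI3K", "PI3Ka")),
        "rheb_kd_insulin": coef(False, "insulin", ("RhebGDP", "RhebGTP")),
        "rheb_kd_insulin_strong_variant": coef(
            True, "insulin", ("RhebGDP", "RhebGTP")
        ),
    }
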