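"""Reaction networks and their mass-action ODE compilation.

A :class:`ReactionNetwork` is an ordered list of species and irreversible (or
reversible, pre-split) mass-action reactions together with the stoichiometric
matrix ``S``.  The network compiles into the right-hand side of the coupled
ODE system

    dx/dt = S · r(x, k),        r_j(x, k) = k_j · Π_{s ∈ reactants(j)} x_s^σ_sj

with analytical Jacobian ``J = ∂(S·r)/∂x`` and parameter-derivative matrix
``B = ∂(S·r)/∂k``, which downstream modules use for stiff integration and for
the forward (kinetic) sensitivity equations.

Two on-disk formats are supported: a plain-text reaction list for desk-scale
authoring, and a minimal SBML Level-2 subset (species, reactions with a
kinetic law reducible to a single rate constant, reversible flags).  Anything
outside the subset raises rather than being silently skipped.
"""

from __future__ import annotations

import csv
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ParameterVector",
    "NetworkParseError",
    "UnsupportedConstructError",
    "parse_network",
    "parse_text",
    "parse_sbml",
    "write_network",
    "write_text",
    "write_sbml",
    "split_reversible",
    "massaction_rate",
    "rhs",
    "jacobian_and_dfdk",
    "export_summary",
]


class NetworkParseError(ValueError):
    """Malformed network file; the message names the offending element."""


class UnsupportedConstructError(NetworkParseError):
    """SBML construct outside the supported subset (events, rules, ...)."""


@dataclass(frozen=True)
class Species:
    """One chemical species (protein, lipid, mRNA or complex)."""

    id: str
    name: str = ""
    initial_amount: float = 0.0
    compartment: str = "cell"

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise ValueError(f"species {self.id!r}: initial_amount must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction.

    ``reactants``/``products`` are tuples of ``(species_id, coefficient)``
    with positive integer coefficients.  A reaction may have an empty reactant
    list (zeroth-order source) or empty product list (sink).  ``reversible``
    reactions carry an independent ``reverse_rate_constant`` and exist only
    before :func:`split_reversible`.
    """

    id: str
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    rate_constant: float = 1.0
    reversible: bool = False
    reverse_rate_constant: float = 0.0

    def __post_init__(self) -> None:
        for sid, coef in (*self.reactants, *self.products):
            if coef < 1 or int(coef) != coef:
                raise ValueError(
                    f"reaction {self.id!r}: coefficient for {sid!r} must be a "
                    f"positive integer, got {coef}"
                )
        if self.rate_constant < 0 or self.reverse_rate_constant < 0:
            raise ValueError(f"reaction {self.id!r}: rate constants must be >= 0")

    @property
    def species_ids(self) -> set[str]:
        return {sid for sid, _ in self.reactants} | {sid for sid, _ in self.products}


class ReactionNetwork:
    """Ordered species + reactions with the stoichiometric matrix ``S``.

    ``S`` is n_species × n_reactions with signed integer entries: negative
    where a species is consumed, positive where produced, zero where
    uninvolved.  Species order follows the file/constructor order and fixes
    the indexing of every downstream vector (states, initial conditions).
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        ids = [s.id for s in species]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids: {dup}")
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.index: dict[str, int] = {s.id: i for i, s in enumerate(self.species)}
        for rxn in self.reactions:
            missing = rxn.species_ids - self.index.keys()
            if missing:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown species {sorted(missing)}"
                )
        self.S = self._build_S()
        self._compiled: _Compiled | None = None

    # -- structure -------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def _build_S(self) -> np.ndarray:
        S = np.zeros((self.n_species, self.n_reactions), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for sid, coef in rxn.reactants:
                S[self.index[sid], j] -= coef
            for sid, coef in rxn.products:
                S[self.index[sid], j] += coef
        return S

    @property
    def rate_constants(self) -> np.ndarray:
        return np.array([r.rate_constant for r in self.reactions], dtype=float)

    @property
    def initial_conditions(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def nominal_parameters(self) -> "ParameterVector":
        return ParameterVector(self.rate_constants, self.initial_conditions)

    def with_reactions(self, reactions: Sequence[Reaction]) -> "ReactionNetwork":
        return ReactionNetwork(self.species, reactions)

    # -- compiled mass-action kinetics ----------------------------------

    def _compile(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled

    def rates(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Mass-action rate vector r(x, k); tiny negative x clipped to 0."""
        return self._compile().rates(np.maximum(np.asarray(x, float), 0.0), k)

    def rhs(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(x, k)

    def jacobian(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self._compile().jacobian(np.maximum(np.asarray(x, float), 0.0), k)

    def dfdk(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self._compile().dfdk(np.maximum(np.asarray(x, float), 0.0), k)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ReactionNetwork {self.n_species} species, "
            f"{self.n_reactions} reactions>"
        )


class _Compiled:
    """Flat (reaction, species, exponent) triples for vectorised kinetics.

    The reactant structure is stored as parallel index arrays so rates,
    Jacobian and parameter derivatives evaluate without Python loops over
    reactions — the hot path of every integration.
    """

    def __init__(self, net: ReactionNetwork):
        self.S = net.S.astype(float)
        self.n_s = net.n_species
        self.n_r = net.n_reactions
        rj, si, ex = [], [], []
        for j, rxn in enumerate(net.reactions):
            for sid, coef in rxn.reactants:
                rj.append(j)
                si.append(net.index[sid])
                ex.append(int(coef))
        self.rj = np.array(rj, dtype=int)
        self.si = np.array(si, dtype=int)
        self.ex = np.array(ex, dtype=float)

    def monomials(self, x: np.ndarray) -> np.ndarray:
        """Π x^σ per reaction (the rate without the constant)."""
        m = np.ones(self.n_r)
        if self.rj.size:
            np.multiply.at(m, self.rj, x[self.si] ** self.ex)
        return m

    def rates(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return np.asarray(k, float) * self.monomials(x)

    def drdx(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        d = np.zeros((self.n_r, self.n_s))
        if not self.rj.size:
            return d
        tv = x[self.si] ** self.ex  # per-triple term value
        m = np.ones(self.n_r)
        np.multiply.at(m, self.rj, tv)
        zero = tv == 0.0
        n_zero = np.zeros(self.n_r)
        np.add.at(n_zero, self.rj, zero.astype(float))
        pnz = np.ones(self.n_r)  # product of the nonzero terms per reaction
        np.multiply.at(pnz, self.rj[~zero], tv[~zero])
        # product of the *other* terms of the same reaction, per triple
        other = np.zeros(tv.size)
        nz = ~zero
        other[nz] = np.where(n_zero[self.rj[nz]] == 0, m[self.rj[nz]] / tv[nz], 0.0)
        other[zero] = np.where(n_zero[self.rj[zero]] == 1, pnz[self.rj[zero]], 0.0)
        g = k[self.rj] * self.ex * x[self.si] ** (self.ex - 1.0) * other
        np.add.at(d, (self.rj, self.si), g)
        return d

    def jacobian(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.S @ self.drdx(x, np.asarray(k, float))

    def dfdk(self, x: np.ndarray, k: np.ndarray) -> np.ndarray:
        # dr_j/dk_j is the bare monomial; B[:, j] = S[:, j] * monomial_j
        return self.S * self.monomials(x)[None, :]


@dataclass
class ParameterVector:
    """Rate constants (aligned to reactions) + initial conditions (species).

    The flat layout is ``[rate_constants, initial_conditions]`` — the
    reproducible indexing used by ensemble files.
    """

    rate_constants: np.ndarray
    initial_conditions: np.ndarray

    def __post_init__(self) -> None:
        self.rate_constants = np.asarray(self.rate_constants, dtype=float)
        self.initial_conditions = np.asarray(self.initial_conditions, dtype=float)
        if (self.rate_constants < 0).any() or (self.initial_conditions < 0).any():
            raise ValueError("parameter vector entries must be >= 0")

    @property
    def n(self) -> int:
        return self.rate_constants.size + self.initial_conditions.size

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.rate_constants, self.initial_conditions])

    @classmethod
    def from_array(cls, arr: np.ndarray, n_reactions: int) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[:n_reactions], arr[n_reactions:])

    def copy(self) -> "ParameterVector":
        return ParameterVector(
            self.rate_constants.copy(), self.initial_conditions.copy()
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def split_reversible(net: ReactionNetwork) -> ReactionNetwork:
    """Replace every reversible reaction by two irreversible steps.

    The forward step keeps the forward constant; the reverse step swaps
    reactants and products and takes the reverse constant.  Irreversible
    reactions pass through unchanged, so the operation is idempotent.
    """
    out: list[Reaction] = []
    for rxn in net.reactions:
        if not rxn.reversible:
            out.append(rxn)
            continue
        out.append(
            Reaction(
                id=f"{rxn.id}_f",
                reactants=rxn.reactants,
                products=rxn.products,
                rate_constant=rxn.rate_constant,
            )
        )
        out.append(
            Reaction(
                id=f"{rxn.id}_r",
                reactants=rxn.products,
                products=rxn.reactants,
                rate_constant=rxn.reverse_rate_constant,
            )
        )
    return net.with_reactions(out)


def massaction_rate(
    rxn: Reaction, x: np.ndarray, index: Mapping[str, int]
) -> float:
    """Mass-action rate k_j · Π x_s^σ for one reaction.

    ``index`` maps species ids to positions in ``x``.  A zeroth-order source
    returns the bare rate constant.  Negative concentrations are rejected
    (they signal an integrator failure upstream).
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        bad = int(np.argmin(x))
        raise ValueError(f"negative concentration at index {bad}: {x[bad]}")
    rate = rxn.rate_constant
    for sid, coef in rxn.reactants:
        rate *= x[index[sid]] ** coef
    return float(rate)


def rhs(net: ReactionNetwork, x: np.ndarray, k: np.ndarray) -> np.ndarray:
    """dx/dt = S · r(x, k)."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    if x.shape != (net.n_species,):
        raise ValueError(f"x has shape {x.shape}, expected ({net.n_species},)")
    if k.shape != (net.n_reactions,):
        raise ValueError(f"k has shape {k.shape}, expected ({net.n_reactions},)")
    return net.rhs(x, k)


def jacobian_and_dfdk(
    net: ReactionNetwork, x: np.ndarray, k: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytical J = ∂(S·r)/∂x (n×n) and B = ∂(S·r)/∂k (n×p)."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    if x.shape != (net.n_species,) or k.shape != (net.n_reactions,):
        raise ValueError("dimension mismatch between network, x and k")
    return net.jacobian(x, k), net.dfdk(x, k)


# ---------------------------------------------------------------------------
# plain-text format
# ---------------------------------------------------------------------------
#
#   # comment
#   A = 1.0                      (initial amount; unlisted species start at 0)
#   R1: A + 2*B -> C ; k=0.1
#   R2: C <-> D ; kf=1, kr=2

_TERM_RE = re.compile(r"^(?:(\d+)\s*\*\s*)?([A-Za-z_][\w:\-]*)$")


def _parse_side(side: str, line: str) -> tuple[tuple[str, int], ...]:
    side = side.strip()
    if not side or side in ("0", "∅"):
        return ()
    out = []
    for term in side.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise NetworkParseError(f"cannot parse species term {term.strip()!r} in line {line!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        out.append((m.group(2), coef))
    return tuple(out)


def _parse_kv(text: str, line: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise NetworkParseError(f"expected key=value, got {part!r} in line {line!r}")
        key, val = (p.strip() for p in part.split("=", 1))
        try:
            out[key] = float(val)
        except ValueError as exc:
            raise NetworkParseError(f"bad numeric value {val!r} in line {line!r}") from exc
    return out


def parse_text(path: str | Path) -> ReactionNetwork:
    """Parse the plain-text reaction-list format."""
    path = Path(path)
    species_order: list[str] = []
    initials: dict[str, float] = {}
    reactions: list[Reaction] = []

    def see(sid: str) -> None:
        if sid not in initials:
            species_order.append(sid)
            initials[sid] = 0.0

    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            if "=" not in line:
                raise NetworkParseError(f"cannot parse line {line!r} in {path}")
            sid, val = (p.strip() for p in line.split("=", 1))
            try:
                amount = float(val)
            except ValueError as exc:
                raise NetworkParseError(f"bad initial amount in line {line!r}") from exc
            see(sid)
            initials[sid] = amount
            continue
        if ":" in line.split("->", 1)[0] and ":" in line:
            rid, body = (p.strip() for p in line.split(":", 1))
        else:
            rid, body = f"R{len(reactions) + 1}", line
        if ";" in body:
            eqn, params = (p.strip() for p in body.split(";", 1))
            kv = _parse_kv(params, line)
        else:
            eqn, kv = body, {}
        reversible = "<->" in eqn
        arrow = "<->" if reversible else "->"
        lhs, rhs_ = eqn.split(arrow, 1)
        reactants = _parse_side(lhs, line)
        products = _parse_side(rhs_, line)
        for sid, _ in (*reactants, *products):
            see(sid)
        if reversible:
            if "kf" not in kv or "kr" not in kv:
                raise NetworkParseError(f"reversible reaction {rid!r} needs kf= and kr=")
            rxn = Reaction(rid, reactants, products, kv["kf"], True, kv["kr"])
        else:
            rxn = Reaction(rid, reactants, products, kv.get("k", 1.0))
        reactions.append(rxn)

    species = [Species(sid, sid, initials[sid]) for sid in species_order]
    return ReactionNetwork(species, reactions)


def write_text(net: ReactionNetwork, path: str | Path) -> None:
    path = Path(path)
    lines = []
    for s in net.species:
        lines.append(f"{s.id} = {s.initial_amount!r}")
    for r in net.reactions:
        def side(terms: tuple[tuple[str, int], ...]) -> str:
            if not terms:
                return "0"
            return " + ".join(f"{c}*{sid}" if c > 1 else sid for sid, c in terms)
        if r.reversible:
            lines.append(
                f"{r.id}: {side(r.reactants)} <-> {side(r.products)} ; "
                f"kf={r.rate_constant!r}, kr={r.reverse_rate_constant!r}"
            )
        else:
            lines.append(
                f"{r.id}: {side(r.reactants)} -> {side(r.products)} ; k={r.rate_constant!r}"
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML Level-2 subset
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level2"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_UNSUPPORTED = (
    "listOfEvents",
    "listOfRules",
    "listOfFunctionDefinitions",
    "listOfConstraints",
    "listOfInitialAssignments",
)


def _tag(el: ET.Element) -> str:
    return el.tag.rsplit("}", 1)[-1]


def parse_sbml(path: str | Path) -> ReactionNetwork:
    """Parse the supported SBML Level-2 subset.

    Supported: compartments (treated as unit volume), species with
    ``initialAmount``/``initialConcentration``, reactions with reactant and
    product speciesReferences and a kinetic law whose listOfParameters holds a
    single rate constant (or ``kf``/``kr`` for reversible reactions).  Events,
    rules, function definitions, constraints and initial assignments raise
    :class:`UnsupportedConstructError`.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise NetworkParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if _tag(root) != "sbml":
        raise NetworkParseError(f"{path}: root element is {_tag(root)!r}, expected 'sbml'")
    model = next((el for el in root if _tag(el) == "model"), None)
    if model is None:
        raise NetworkParseError(f"{path}: no <model> element")

    for el in model:
        if _tag(el) in _UNSUPPORTED:
            raise UnsupportedConstructError(
                f"{path}: unsupported SBML construct <{_tag(el)}>"
            )

    species: list[Species] = []
    for el in model.iter():
        if _tag(el) != "species":
            continue
        sid = el.get("id")
        if not sid:
            raise NetworkParseError(f"{path}: <species> without id")
        amount = el.get("initialAmount", el.get("initialConcentration", "0"))
        species.append(
            Species(
                id=sid,
                name=el.get("name", sid),
                initial_amount=float(amount),
                compartment=el.get("compartment", "cell"),
            )
        )

    reactions: list[Reaction] = []
    for el in model.iter():
        if _tag(el) != "reaction":
            continue
        rid = el.get("id")
        if not rid:
            raise NetworkParseError(f"{path}: <reaction> without id")
        reversible = el.get("reversible", "true").lower() == "true"
        reactants: list[tuple[str, int]] = []
        products: list[tuple[str, int]] = []
        params: dict[str, float] = {}
        for child in el:
            tag = _tag(child)
            if tag in ("listOfReactants", "listOfProducts"):
                target = reactants if tag == "listOfReactants" else products
                for ref in child:
                    if _tag(ref) != "speciesReference":
                        raise UnsupportedConstructError(
                            f"{path}: reaction {rid!r}: unsupported <{_tag(ref)}>"
                        )
                    stoich = float(ref.get("stoichiometry", "1"))
                    if stoich != int(stoich):
                        raise NetworkParseError(
                            f"{path}: reaction {rid!r}: non-integer stoichiometry {stoich}"
                        )
                    target.append((ref.get("species"), int(stoich)))
            elif tag == "listOfModifiers":
                raise UnsupportedConstructError(
                    f"{path}: reaction {rid!r}: modifiers are outside the "
                    "mass-action subset"
                )
            elif tag == "kineticLaw":
                for sub in child.iter():
                    if _tag(sub) == "parameter":
                        params[sub.get("id", sub.get("name", "k"))] = float(
                            sub.get("value", "nan")
                        )
        if reversible:
            if set(params) >= {"kf", "kr"}:
                kf, kr = params["kf"], params["kr"]
            else:
                raise NetworkParseError(
                    f"{path}: reversible reaction {rid!r} needs kf and kr "
                    f"kinetic-law parameters, got {sorted(params)}"
                )
            rxn = Reaction(rid, tuple(reactants), tuple(products), kf, True, kr)
        else:
            if len(params) != 1:
                raise NetworkParseError(
                    f"{path}: reaction {rid!r}: kinetic law must carry exactly "
                    f"one rate constant, got {sorted(params)}"
                )
            (k,) = params.values()
            rxn = Reaction(rid, tuple(reactants), tuple(products), k)
        reactions.append(rxn)

    return ReactionNetwork(species, reactions)


def write_sbml(net: ReactionNetwork, path: str | Path) -> None:
    """Write the network in the same SBML Level-2 subset the parser reads."""
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "2", "version": "4"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": "network"})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    for cid in sorted({s.compartment for s in net.species}):
        ET.SubElement(comps, f"{{{_SBML_NS}}}compartment", {"id": cid, "size": "1"})
    lsp = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in net.species:
        ET.SubElement(
            lsp,
            f"{{{_SBML_NS}}}species",
            {
                "id": s.id,
                "name": s.name or s.id,
                "compartment": s.compartment,
                "initialAmount": repr(s.initial_amount),
            },
        )
    lrx = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in net.reactions:
        rel = ET.SubElement(
            lrx,
            f"{{{_SBML_NS}}}reaction",
            {"id": r.id, "reversible": "true" if r.reversible else "false"},
        )
        for tag, terms in (
            ("listOfReactants", r.reactants),
            ("listOfProducts", r.products),
        ):
            if terms:
                lst = ET.SubElement(rel, f"{{{_SBML_NS}}}{tag}")
                for sid, coef in terms:
                    ET.SubElement(
                        lst,
                        f"{{{_SBML_NS}}}speciesReference",
                        {"species": sid, "stoichiometry": str(coef)},
                    )
        kl = ET.SubElement(rel, f"{{{_SBML_NS}}}kineticLaw")
        lp = ET.SubElement(kl, f"{{{_SBML_NS}}}listOfParameters")
        if r.reversible:
            ET.SubElement(lp, f"{{{_SBML_NS}}}parameter", {"id": "kf", "value": repr(r.rate_constant)})
            ET.SubElement(lp, f"{{{_SBML_NS}}}parameter", {"id": "kr", "value": repr(r.reverse_rate_constant)})
        else:
            ET.SubElement(lp, f"{{{_SBML_NS}}}parameter", {"id": "k", "value": repr(r.rate_constant)})
    ET.indent(root)
    Path(path).write_bytes(ET.tostring(root, xml_declaration=True, encoding="utf-8"))


def parse_network(path: str | Path, format: str | None = None) -> ReactionNetwork:
    """Read a network from disk; format inferred from the suffix if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "text"
    if format == "sbml":
        return parse_sbml(path)
    if format == "text":
        return parse_text(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: ReactionNetwork, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "text"
    if format == "sbml":
        write_sbml(net, path)
    elif format == "text":
        write_text(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def export_summary(net: ReactionNetwork, directory: str | Path) -> tuple[Path, Path]:
    """Write species and reaction tables as CSV; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp_path = directory / "species.csv"
    rx_path = directory / "reactions.csv"
    with sp_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "initial_amount", "compartment"])
        for s in net.species:
            w.writerow([s.id, s.name, s.initial_amount, s.compartment])
    with rx_path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "reactants", "products", "rate_constant", "reversible", "reverse_rate_constant"])
        for r in net.reactions:
            fmt = lambda terms: " + ".join(
                f"{c}*{sid}" if c > 1 else sid for sid, c in terms
            ) or "0"
            w.writerow([r.id, fmt(r.reactants), fmt(r.products), r.rate_constant, r.reversible, r.reverse_rate_constant])
    return sp_path, rx_path
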