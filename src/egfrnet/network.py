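"""Reaction-network core: domain types, the tabular model dialect, validation
and stoichiometric analysis.

A :class:`Model` is a list of :class:`Species` plus a list of mass-action
:class:`Reaction` rows.  Concentrations are in nM and time in minutes
throughout.  Complex species are named by joining their constituent tokens
with ``":"`` (sorted, so ``EGF:EGFR`` not ``EGFR:EGF``); phosphorylated forms
carry a ``p-`` prefix on the token (``p-ERK``).  This grammar is load-bearing:
readout totals and moiety bookkeeping parse it.

The on-disk dialect is a pair of TSV tables, ``reactions.tsv`` with columns
``id, equation, law, kf, kr, K, kcat, tags, source`` and ``initials.tsv``
with columns ``species, compartment, amount_nM, source``.  Rate-constant
cells are either a bare number (the parameter is then named
``<reaction id>.<role>``) or ``name=value`` so that one named parameter can
be shared by several reactions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy

__all__ = [
    "Law",
    "Param",
    "Species",
    "Reaction",
    "Model",
    "ConservationLaw",
    "ModelError",
    "ParseError",
    "complex_name",
    "species_tokens",
    "moiety_count",
    "parse_reaction_table",
    "write_reaction_table",
    "validate_model",
    "conserved_moieties",
    "expand_enzymatic",
]

_TOKEN_RE = re.compile(r"^(p-)?[A-Za-z][A-Za-z0-9_]*$")
_EMPTY_SIDE = "-"


class ModelError(ValueError):
    """A structural problem with a model or one of its members."""


class ParseError(ModelError):
    """Raised by the table parser; carries the offending table row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class Law(str, Enum):
    MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
    MASS_ACTION_REVERSIBLE = "mass_action_reversible"
    ENZYMATIC_TWO_STEP = "enzymatic_two_step"


#: rate-constant roles each law requires
_LAW_ROLES = {
    Law.MASS_ACTION_IRREVERSIBLE: ("kf",),
    Law.MASS_ACTION_REVERSIBLE: ("kf", "kr"),
    Law.ENZYMATIC_TWO_STEP: ("K", "kcat"),
}


@dataclass(frozen=True)
class Param:
    """A named, strictly positive rate constant.

    Units follow molecularity: second-order constants (``kf`` of a bimolecular
    step, ``K``) are 1/(nM·min); first-order constants (``kr``, ``kcat``,
    unimolecular ``kf``) are 1/min.
    """

    name: str
    value: float

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value <= 0:
            raise ModelError(f"rate constant {self.name!r} must be finite and > 0, got {self.value}")


def complex_name(*parts: str) -> str:
    """Canonical name of a complex: constituent tokens sorted, ``":"``-joined.

    Arguments may themselves be complex names; their tokens are merged, so
    ``complex_name("EGF:EGFR", "Shc") == complex_name("Shc", "EGF", "EGFR")``.
    """
    tokens: list[str] = []
    for part in parts:
        tokens.extend(part.split(":"))
    return ":".join(sorted(tokens))


def species_tokens(name: str) -> list[str]:
    """Constituent tokens of a (possibly complex) species name."""
    return name.split(":")


def moiety_count(name: str, *base_tokens: str) -> int:
    """How many of the species' tokens carry any of the given base tokens.

    A base token matches itself and its ``p-`` phospho form, so
    ``moiety_count("EGF:EGF:p-EGFR:p-EGFR", "EGFR") == 2``.
    """
    hits = set(base_tokens) | {f"p-{t}" for t in base_tokens}
    return sum(1 for t in species_tokens(name) if t in hits)


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str = "cytosol"
    initial_amount: float = 0.0
    role_tags: frozenset[str] = frozenset()

    def __post_init__(self):
        for tok in species_tokens(self.name):
            if not _TOKEN_RE.match(tok):
                raise ModelError(f"species name {self.name!r}: bad token {tok!r}")
        if self.compartment not in ("membrane", "cytosol"):
            raise ModelError(f"species {self.name}: unknown compartment {self.compartment!r}")
        if not np.isfinite(self.initial_amount) or self.initial_amount < 0:
            raise ModelError(f"species {self.name}: initial amount must be finite and >= 0")


@dataclass(frozen=True)
class Reaction:
    """One reaction row.

    ``reactants``/``products`` are multisets (tuples, possibly with repeats);
    molecularity of each side is at most two.  ``constants`` maps the role
    required by ``law`` (``kf``/``kr`` or ``K``/``kcat``) to a :class:`Param`.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    law: Law
    constants: Mapping[str, Param]
    tags: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "constants", dict(self.constants))
        object.__setattr__(self, "tags", frozenset(self.tags))
        if len(self.reactants) > 2 or len(self.products) > 2:
            raise ModelError(f"reaction {self.id}: molecularity of each side is limited to 2")
        if self.law is Law.ENZYMATIC_TWO_STEP and len(self.reactants) != 2:
            raise ModelError(f"reaction {self.id}: enzymatic_two_step needs enzyme + substrate")
        missing = [r for r in _LAW_ROLES[self.law] if r not in self.constants]
        if missing:
            raise ModelError(f"reaction {self.id}: missing rate constant(s) {missing}")

    @property
    def equation(self) -> str:
        lhs = " + ".join(self.reactants) if self.reactants else _EMPTY_SIDE
        rhs = " + ".join(self.products) if self.products else _EMPTY_SIDE
        arrow = "<->" if self.law is Law.MASS_ACTION_REVERSIBLE else "->"
        return f"{lhs} {arrow} {rhs}"

    def net_stoichiometry(self) -> dict[str, int]:
        st: dict[str, int] = {}
        for s in self.reactants:
            st[s] = st.get(s, 0) - 1
        for s in self.products:
            st[s] = st.get(s, 0) + 1
        return {s: c for s, c in st.items() if c != 0}


@dataclass
class ConservationLaw:
    """Integer left-null vector of the stoichiometry matrix."""

    coefficients: dict[str, int]
    description: str = ""

    @property
    def support(self) -> frozenset[str]:
        return frozenset(s for s, c in self.coefficients.items() if c != 0)


@dataclass
class Model:
    """A validated reaction network.

    Invariants (checked by :func:`validate_model`): species names unique,
    every species referenced by a reaction is declared, rate constants are
    positive, parameter names shared across reactions agree on their value.
    """

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- bookkeeping ------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def parameters(self) -> dict[str, float]:
        """Distinct named rate constants of the model."""
        out: dict[str, float] = {}
        for rxn in self.reactions:
            for p in rxn.constants.values():
                if p.name in out and out[p.name] != p.value:
                    raise ModelError(
                        f"parameter {p.name!r} bound to conflicting values "
                        f"{out[p.name]} and {p.value}"
                    )
                out[p.name] = p.value
        return out

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def nonzero_initial_species(self) -> list[str]:
        return [s.name for s in self.species if s.initial_amount > 0]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (n_species, n_reactions), integer entries."""
        idx = self.species_index
        S = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for name, c in rxn.net_stoichiometry().items():
                S[idx[name], j] += c
        return S

    def with_parameters(self, updates: Mapping[str, float]) -> "Model":
        """Copy of the model with named rate constants replaced."""
        new_rxns = []
        for rxn in self.reactions:
            consts = {
                role: (Param(p.name, updates[p.name]) if p.name in updates else p)
                for role, p in rxn.constants.items()
            }
            new_rxns.append(replace(rxn, constants=consts))
        return Model(list(self.species), new_rxns, dict(self.metadata))

    def copy(self) -> "Model":
        return Model(list(self.species), list(self.reactions), dict(self.metadata))

    def structurally_equal(self, other: "Model") -> bool:
        def key(m: "Model"):
            sp = sorted((s.name, s.compartment, round(s.initial_amount, 12), tuple(sorted(s.role_tags)))
                        for s in m.species)
            rx = sorted(
                (r.id, tuple(sorted(r.reactants)), tuple(sorted(r.products)), r.law.value,
                 tuple(sorted((role, p.name, round(p.value, 12)) for role, p in r.constants.items())),
                 tuple(sorted(r.tags)))
                for r in m.reactions)
            return sp, rx

        return key(self) == key(other)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: Model) -> list[str]:
    """Structural validation report; an empty list means the model is valid."""
    report: list[str] = []
    names = model.species_names
    seen: set[str] = set()
    for n in names:
        if n in seen:
            report.append(f"duplicate species name {n!r}")
        seen.add(n)
    referenced: set[str] = set()
    rids: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in rids:
            report.append(f"duplicate reaction id {rxn.id!r}")
        rids.add(rxn.id)
        for s in (*rxn.reactants, *rxn.products):
            referenced.add(s)
            if s not in seen:
                report.append(f"reaction {rxn.id} references undeclared species {s!r}")
        for role, p in rxn.constants.items():
            if p.value <= 0 or not np.isfinite(p.value):
                report.append(f"reaction {rxn.id}: non-positive {role}")
    for s in model.species:
        if s.name not in referenced:
            report.append(f"orphan species {s.name!r} (referenced by no reaction)")
        if s.initial_amount < 0:
            report.append(f"species {s.name}: negative initial amount")
    try:
        model.parameters
    except ModelError as exc:
        report.append(str(exc))
    return report


# ---------------------------------------------------------------------------
# enzymatic expansion
# ---------------------------------------------------------------------------

def expand_enzymatic(model: Model, unbinding_kd_nm: float = 10.0) -> Model:
    """Expand ``enzymatic_two_step`` rows into elementary steps.

    ``E + S -> E + P`` with binding constant K (1/(nM·min)) and turnover kcat
    (1/min) becomes ``E + S <-> E:S`` (kf = K, kr = K·Kd) followed by
    ``E:S -> E + P`` (kcat).  ``unbinding_kd_nm`` sets the dissociation
    constant of the intermediate; the resulting Michaelis constant is
    Kd + kcat/K.
    """
    species = list(model.species)
    have = set(model.species_names)
    out: list[Reaction] = []
    for rxn in model.reactions:
        if rxn.law is not Law.ENZYMATIC_TWO_STEP:
            out.append(rxn)
            continue
        enzyme, substrate = rxn.reactants
        if enzyme not in rxn.products:
            # convention: the enzyme is the reactant that reappears in products
            if substrate in rxn.products:
                enzyme, substrate = substrate, enzyme
            else:
                raise ModelError(f"reaction {rxn.id}: enzyme must reappear among products")
        products = list(rxn.products)
        products.remove(enzyme)
        K = rxn.constants["K"]
        kcat = rxn.constants["kcat"]
        inter = complex_name(enzyme, substrate)
        if inter not in have:
            species.append(Species(inter, compartment="cytosol"))
            have.add(inter)
        out.append(Reaction(
            f"{rxn.id}.bind", (enzyme, substrate), (inter,), Law.MASS_ACTION_REVERSIBLE,
            {"kf": K, "kr": Param(f"{K.name}.unbind", K.value * unbinding_kd_nm)},
            tags=rxn.tags, source=rxn.source))
        out.append(Reaction(
            f"{rxn.id}.cat", (inter,), (enzyme, *products), Law.MASS_ACTION_IRREVERSIBLE,
            {"kf": kcat}, tags=rxn.tags, source=rxn.source))
    return Model(species, out, dict(model.metadata))


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = ["id", "equation", "law", "kf", "kr", "K", "kcat", "tags", "source"]
_INITIAL_COLUMNS = ["species", "compartment", "amount_nM", "source"]


def _parse_side(text: str, row: int) -> tuple[str, ...]:
    text = text.strip()
    if text in ("", _EMPTY_SIDE):
        return ()
    parts = [p.strip() for p in text.split("+")]
    if any(not p for p in parts):
        raise ParseError(f"malformed reaction side {text!r}", row)
    return tuple(parts)


def _parse_const(cell, rxn_id: str, role: str, row: int) -> Param | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    if "=" in text:
        name, _, val = text.partition("=")
        name = name.strip()
    else:
        name, val = f"{rxn_id}.{role}", text
    try:
        value = float(val)
    except ValueError:
        raise ParseError(f"bad rate constant {text!r} for {role}", row) from None
    if value <= 0:
        raise ParseError(f"non-positive rate constant {role}={value} in reaction {rxn_id!r}", row)
    return Param(name, value)


def parse_reaction_table(reaction_rows: str, initial_rows: str,
                         expand: bool = True) -> Model:
    """Parse the two-table model dialect into a validated :class:`Model`.

    Parameters
    ----------
    reaction_rows, initial_rows
        TSV text for the reaction and initial-condition tables.
    expand
        Expand ``enzymatic_two_step`` rows into elementary steps (default).

    Raises
    ------
    ParseError
        With the offending row number, on any malformed cell, unknown
        species, duplicate id or non-positive rate constant.
    """
    rdf = pd.read_csv(io.StringIO(reaction_rows), sep="\t", dtype=str, keep_default_na=False)
    idf = pd.read_csv(io.StringIO(initial_rows), sep="\t", dtype=str, keep_default_na=False)
    for col in _REACTION_COLUMNS:
        if col not in rdf.columns:
            raise ParseError(f"reactions table missing column {col!r}")
    for col in _INITIAL_COLUMNS:
        if col not in idf.columns:
            raise ParseError(f"initials table missing column {col!r}")

    species: list[Species] = []
    declared: set[str] = set()
    for i, row in idf.iterrows():
        name = row["species"].strip()
        try:
            amount = float(row["amount_nM"]) if row["amount_nM"].strip() else 0.0
        except ValueError:
            raise ParseError(f"bad amount {row['amount_nM']!r} for {name}", i) from None
        if name in declared:
            raise ParseError(f"duplicate species {name!r}", i)
        raw_tags = row["tags"] if "tags" in idf.columns else ""
        tags = frozenset(t.strip() for t in raw_tags.split(",") if t.strip())
        try:
            species.append(Species(name, row["compartment"].strip() or "cytosol", amount, tags))
        except ModelError as exc:
            raise ParseError(str(exc), i) from None
        declared.add(name)

    reactions: list[Reaction] = []
    rids: set[str] = set()
    for i, row in rdf.iterrows():
        rid = row["id"].strip()
        if not rid:
            raise ParseError("empty reaction id", i)
        if rid in rids:
            raise ParseError(f"duplicate reaction id {rid!r}", i)
        rids.add(rid)
        eq = row["equation"]
        if "<->" in eq:
            lhs, _, rhs = eq.partition("<->")
        elif "->" in eq:
            lhs, _, rhs = eq.partition("->")
        else:
            raise ParseError(f"malformed equation {eq!r}", i)
        try:
            law = Law(row["law"].strip())
        except ValueError:
            raise ParseError(f"unknown law {row['law']!r}", i) from None
        reactants = _parse_side(lhs, i)
        products = _parse_side(rhs, i)
        consts = {}
        for role in ("kf", "kr", "K", "kcat"):
            p = _parse_const(row[role], rid, role, i)
            if p is not None:
                consts[role] = p
        for s in (*reactants, *products):
            if s not in declared:
                raise ParseError(f"reaction {rid} references unknown species {s!r}", i)
        tags = frozenset(t.strip() for t in row["tags"].split(",") if t.strip())
        try:
            reactions.append(Reaction(rid, reactants, products, law, consts, tags,
                                      row["source"].strip()))
        except ModelError as exc:
            raise ParseError(str(exc), i) from None

    model = Model(species, reactions)
    if expand:
        model = expand_enzymatic(model)
    report = validate_model(model)
    if report:
        raise ParseError("; ".join(report))
    return model


def _format_const(rxn: Reaction, role: str) -> str:
    p = rxn.constants.get(role)
    if p is None:
        return ""
    default_name = f"{rxn.id}.{role}"
    return repr(p.value) if p.name == default_name else f"{p.name}={p.value!r}"


def write_reaction_table(model: Model) -> tuple[str, str]:
    """Serialize a model to (reactions.tsv, initials.tsv) text.

    Deterministic: reactions sorted by id, species by name; two writes of the
    same model are byte-identical.
    """
    rrows = []
    for rxn in sorted(model.reactions, key=lambda r: r.id):
        rrows.append({
            "id": rxn.id,
            "equation": rxn.equation,
            "law": rxn.law.value,
            "kf": _format_const(rxn, "kf"),
            "kr": _format_const(rxn, "kr"),
            "K": _format_const(rxn, "K"),
            "kcat": _format_const(rxn, "kcat"),
            "tags": ",".join(sorted(rxn.tags)),
            "source": rxn.source,
        })
    irows = []
    for sp in sorted(model.species, key=lambda s: s.name):
        irows.append({
            "species": sp.name,
            "compartment": sp.compartment,
            "amount_nM": repr(sp.initial_amount),
            "source": "",
            "tags": ",".join(sorted(sp.role_tags)),
        })
    rdf = pd.DataFrame(rrows, columns=_REACTION_COLUMNS)
    idf = pd.DataFrame(irows, columns=_INITIAL_COLUMNS + ["tags"])
    return (rdf.to_csv(sep="\t", index=False), idf.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# conserved moieties
# ---------------------------------------------------------------------------

def conserved_moieties(model: Model, within: Iterable[str] | None = None,
                       ) -> list[ConservationLaw]:
    """Integer basis of the left null space of the stoichiometry matrix.

    Every returned vector v satisfies v·S = 0 exactly (integer arithmetic),
    i.e. the weighted total it describes is invariant under the reaction
    stoichiometry.  ``within`` restricts the search to laws supported on the
    given species subset (the remaining coefficients are zero) — useful on
    large models where the full rational null space is expensive.
    """
    names = model.species_names
    S = model.stoichiometry_matrix()
    if within is not None:
        keep = [i for i, n in enumerate(names) if n in set(within)]
    else:
        keep = list(range(len(names)))
    sub = sympy.Matrix(S[keep, :]).T
    laws: list[ConservationLaw] = []
    for vec in sub.nullspace():
        denoms = [Fraction(sympy.Rational(x).p, sympy.Rational(x).q).denominator for x in vec]
        scale = int(np.lcm.reduce([int(d) for d in denoms])) if denoms else 1
        ints = [int(x * scale) for x in vec]
        g = int(np.gcd.reduce([abs(v) for v in ints if v != 0] or [1]))
        ints = [v // g for v in ints]
        if sum(v > 0 for v in ints) < sum(v < 0 for v in ints):
            ints = [-v for v in ints]
        coeffs = {names[keep[i]]: ints[i] for i in range(len(keep)) if ints[i] != 0}
        if coeffs:
            laws.append(ConservationLaw(coeffs))
    return laws


def conservation_values(model: Model, laws: Sequence[ConservationLaw],
                        state: np.ndarray) -> np.ndarray:
    """Value of each conservation law at a state vector."""
    idx = model.species_index
    return np.array([sum(c * state[idx[s]] for s, c in law.coefficients.items())
                     for law in laws])
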