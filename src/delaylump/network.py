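"""Reaction-network representation, structural classification and generators.

A network is a list of species (whose declaration order fixes the chain
ordering S_1 ... S_n of the chain members), a list of reactions, and a set of
species of interest (SOIs).  Reactions are classified relative to the chain:

* ``chain_forward`` / ``chain_backward`` -- unimolecular 1-to-1 conversions
  between chain neighbours (forward = towards larger chain index);
* ``bypass_forward`` / ``bypass_backward`` -- unimolecular 1-to-1 conversions
  S_j -> S_i with |i - j| > 1;
* ``degradation`` -- a chain species is consumed and leaves the chain; the
  products (possibly empty) are emitted outside the chain.  All such killing
  channels can be lumped into a common absorbing state;
* ``synthesis`` -- zero-order production of a single species;
* ``boundary_bimolecular`` -- a reaction with two reactant units (two distinct
  species, or one species twice) feeding the chain; it never enters any
  generator matrix and is carried over explicitly during abridgement.

Generator matrices follow the column convention dp/dt = K p: entry (i, j) for
i != j is the total rate of reactions S_j -> S_i, the diagonal is minus the
total outflow of S_j, and columns of absorbing species are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Species", "Reaction", "ReactionKind", "ReactionNetwork",
    "StructureReport", "GeneratorMatrix", "NetworkError",
    "classify_reactions", "build_generator", "inner_rate_matrix",
]


class NetworkError(ValueError):
    """Raised for malformed or unsupported network topologies."""


class ReactionKind(str, Enum):
    CHAIN_FORWARD = "chain_forward"
    CHAIN_BACKWARD = "chain_backward"
    BYPASS_FORWARD = "bypass_forward"
    BYPASS_BACKWARD = "bypass_backward"
    DEGRADATION = "degradation"
    SYNTHESIS = "synthesis"
    BOUNDARY_BIMOLECULAR = "boundary_bimolecular"


@dataclass(frozen=True)
class Species:
    """A chemical species; ``index`` is its 1-based chain position (or 0 for
    species outside the chain, e.g. partners of boundary bimolecular
    reactions)."""

    name: str
    index: int = 0


@dataclass
class Reaction:
    """A reaction with integer stoichiometries.

    ``reactants``/``products`` are lists of (species name, stoichiometry).
    ``rate_constant`` is per-time for unimolecular reactions and
    per-time-per-pair for bimolecular ones.  ``propensity`` optionally names a
    non-mass-action propensity law as ``(kind, params)``; the only built-in
    law is ``("hill_repression", {"vmax", "threshold", "exponent"})`` used by
    the glycolysis example.
    """

    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    rate_constant: float
    kind: ReactionKind | None = None
    propensity: tuple[str, dict] | None = None

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise NetworkError(f"negative rate constant {self.rate_constant}")
        for sp, st in list(self.reactants) + list(self.products):
            if st <= 0:
                raise NetworkError(f"non-positive stoichiometry for {sp}")

    # -- structural predicates -------------------------------------------
    @property
    def reactant_units(self) -> int:
        return sum(st for _, st in self.reactants)

    @property
    def is_unimolecular(self) -> bool:
        return len(self.reactants) == 1 and self.reactants[0][1] == 1

    @property
    def is_conversion(self) -> bool:
        """One stoichiometry-1 reactant into one stoichiometry-1 product."""
        return (self.is_unimolecular and len(self.products) == 1
                and self.products[0][1] == 1
                and self.products[0][0] != self.reactants[0][0])

    def label(self) -> str:
        lhs = " + ".join(f"{st if st > 1 else ''}{sp}" for sp, st in self.reactants) or "0"
        rhs = " + ".join(f"{st if st > 1 else ''}{sp}" for sp, st in self.products) or "0"
        return f"{lhs} -> {rhs}"


@dataclass
class ReactionNetwork:
    """Species (declaration order = chain order for chain members), reactions
    and the SOI set.  ``initial_state`` maps species names to molecule
    counts."""

    species: list[Species]
    reactions: list[Reaction]
    sois: list[str] = field(default_factory=list)
    initial_state: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkError("species names are not unique")
        declared = set(names)
        for r in self.reactions:
            for sp, _ in list(r.reactants) + list(r.products):
                if sp not in declared:
                    raise NetworkError(f"reaction {r.label()} references undeclared species {sp!r}")
            if r.is_unimolecular and r.products == [(r.reactants[0][0], 1)]:
                raise NetworkError(f"self-loop reaction {r.label()} is not allowed in a full model")
        for s in self.sois:
            if s not in declared:
                raise NetworkError(f"SOI {s!r} is not a declared species")
        for sp in self.initial_state:
            if sp not in declared:
                raise NetworkError(f"initial state references undeclared species {sp!r}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}


@dataclass
class StructureReport:
    """Classification of a network's reactions relative to the chain order."""

    chain_order: list[str]
    chain_reactions: list[Reaction]
    bypasses: list[Reaction]
    degradations: list[Reaction]
    syntheses: list[Reaction]
    boundary_bimolecular: list[Reaction]
    soi_positions: list[int]            # 1-based positions of chain SOIs
    has_bypass: bool = False
    has_degradation: bool = False
    bypass_produces_soi: bool = False
    bypass_consumes_soi: bool = False
    uni_directional: bool = False

    def chain_position(self, name: str) -> int:
        """1-based chain position of a chain species."""
        return self.chain_order.index(name) + 1


@dataclass
class GeneratorMatrix:
    """Column-convention generator over an ordered state list.

    ``ordering`` maps state labels (species names, plus optional absorbing
    pseudo-state labels) to 0-based row/column indices.
    """

    matrix: np.ndarray
    ordering: dict[str, int]
    convention: str = "column"

    def index(self, name: str) -> int:
        return self.ordering[name]


ABSORBED = "@absorbed"  # label of the lumped degradation state


def classify_reactions(network: ReactionNetwork, sois: list[str] | None = None) -> StructureReport:
    """Classify every reaction and infer the chain structure.

    Chain members are the species that take part in a unimolecular 1-to-1
    conversion; their relative declaration order in ``network.species`` is the
    chain order S_1 ... S_n.  Raises :class:`NetworkError` for unsupported
    topologies (disconnected chains, contradictory declared kinds).
    """
    sois = list(network.sois if sois is None else sois)
    conversions = [r for r in network.reactions if r.is_conversion]
    chain_members: set[str] = set()
    for r in conversions:
        chain_members.add(r.reactants[0][0])
        chain_members.add(r.products[0][0])
    chain_order = [s.name for s in network.species if s.name in chain_members]
    pos = {name: i + 1 for i, name in enumerate(chain_order)}

    chain_rx: list[Reaction] = []
    bypass_rx: list[Reaction] = []
    degr_rx: list[Reaction] = []
    synth_rx: list[Reaction] = []
    bimol_rx: list[Reaction] = []
    for r in network.reactions:
        if r.is_conversion:
            i, j = pos[r.reactants[0][0]], pos[r.products[0][0]]
            if abs(i - j) == 1:
                kind = ReactionKind.CHAIN_FORWARD if j > i else ReactionKind.CHAIN_BACKWARD
                chain_rx.append(r)
            else:
                kind = ReactionKind.BYPASS_FORWARD if j > i else ReactionKind.BYPASS_BACKWARD
                bypass_rx.append(r)
        elif not r.reactants:
            if len(r.products) != 1 or r.products[0][1] != 1:
                raise NetworkError(f"synthesis {r.label()} must produce exactly one molecule")
            kind = ReactionKind.SYNTHESIS
            synth_rx.append(r)
        elif r.is_unimolecular:
            # consumed chain species leaving the chain, products emitted outside
            sp = r.reactants[0][0]
            for p, _ in r.products:
                if p in chain_members and p != sp:
                    # a 1->k conversion into the chain is not monomolecular
                    if len(r.products) == 1 and r.products[0][1] > 1:
                        raise NetworkError(
                            f"unsupported reaction {r.label()}: non-unit stoichiometry within the chain")
            kind = ReactionKind.DEGRADATION
            degr_rx.append(r)
        elif r.reactant_units == 2:
            kind = ReactionKind.BOUNDARY_BIMOLECULAR
            bimol_rx.append(r)
        else:
            raise NetworkError(f"unsupported reaction {r.label()}: more than two reactant units")
        if r.kind is not None and r.kind != kind:
            raise NetworkError(
                f"declared kind {r.kind.value} contradicts inferred {kind.value} for {r.label()}")
        r.kind = kind

    # connectivity: every adjacent chain pair must be linked by some conversion
    linked: set[tuple[int, int]] = set()
    for r in conversions:
        i, j = pos[r.reactants[0][0]], pos[r.products[0][0]]
        linked.add((min(i, j), max(i, j)))
    for i in range(1, len(chain_order)):
        if not any(a <= i < i + 1 <= b for a, b in linked):
            raise NetworkError(
                f"not a linear chain: no reaction links {chain_order[i-1]} and {chain_order[i]}")

    soi_chain = [s for s in sois if s in pos]
    bypass_prod_soi = any(r.products[0][0] in sois for r in bypass_rx)
    bypass_cons_soi = any(r.reactants[0][0] in sois for r in bypass_rx)
    uni = not any(r.kind is ReactionKind.CHAIN_BACKWARD for r in chain_rx) and not bypass_rx
    return StructureReport(
        chain_order=chain_order,
        chain_reactions=chain_rx,
        bypasses=bypass_rx,
        degradations=degr_rx,
        syntheses=synth_rx,
        boundary_bimolecular=bimol_rx,
        soi_positions=[pos[s] for s in soi_chain],
        has_bypass=bool(bypass_rx),
        has_degradation=bool(degr_rx),
        bypass_produces_soi=bypass_prod_soi,
        bypass_consumes_soi=bypass_cons_soi,
        uni_directional=uni,
    )


def build_generator(network: ReactionNetwork, absorbing: set[str] | list[str] = (),
                    lump_degradation: bool = False) -> GeneratorMatrix:
    """Column-convention generator over the chain species.

    Boundary bimolecular reactions and syntheses are excluded (they are not
    single-molecule transitions).  Columns of ``absorbing`` species are
    zeroed.  With ``lump_degradation`` an extra row/column collects every
    degradation channel into one common absorbing state labelled
    ``"@absorbed"``.
    """
    report = classify_reactions(network, network.sois or None)
    states = list(report.chain_order)
    absorbing = set(absorbing)
    for a in absorbing:
        if a not in states:
            raise NetworkError(f"absorbing species {a!r} is not a chain species")
    n = len(states)
    m = n + 1 if lump_degradation else n
    idx = {s: i for i, s in enumerate(states)}
    K = np.zeros((m, m))
    for r in report.chain_reactions + report.bypasses:
        j = idx[r.reactants[0][0]]
        if states[j] in absorbing:
            continue
        K[j, j] -= r.rate_constant
        i = idx[r.products[0][0]]
        K[i, j] += r.rate_constant
    for r in report.degradations:
        sp = r.reactants[0][0]
        if sp not in idx:
            continue  # degradation of a non-chain species (e.g. an SOI outside the chain)
        j = idx[sp]
        if states[j] in absorbing:
            continue
        K[j, j] -= r.rate_constant
        if lump_degradation:
            K[n, j] += r.rate_constant
    ordering = dict(idx)
    if lump_degradation:
        ordering[ABSORBED] = n
    return GeneratorMatrix(matrix=K, ordering=ordering)


def inner_rate_matrix(network: ReactionNetwork, sois: list[str] | None = None) -> np.ndarray:
    """Generator restricted to the intermediates between two boundary SOIs.

    Requires the SOIs to be exactly the two chain ends; outflow to the
    boundaries and to degradation appears only through the diagonal.  Raises
    ``NetworkError("no intermediates")`` for chains of length < 3 (nothing to
    lump).
    """
    sois = list(network.sois if sois is None else sois)
    report = classify_reactions(network, sois)
    chain = report.chain_order
    if len(sois) != 2 or set(sois) != {chain[0], chain[-1]}:
        raise NetworkError("inner_rate_matrix requires the two SOIs to be the chain ends")
    if len(chain) < 3:
        raise NetworkError("no intermediates")
    gen = build_generator(network, absorbing=set(sois), lump_degradation=False)
    inner = [gen.index(s) for s in chain[1:-1]]
    return gen.matrix[np.ix_(inner, inner)]
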