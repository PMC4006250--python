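"""Construction of the abridged delayed-reaction model.

Every intermediate species between the SOIs is removed; each reaction that
injects a molecule into the intermediate block (an SOI's outgoing
conversion, a boundary bimolecular reaction, or a synthesis) is replaced by
one consuming delayed reaction per possible fate of the injected walker:

* arrival at an SOI ``T`` -- a delayed reaction producing ``T`` (a *loop*
  with a first-return delay when ``T`` is the reactant itself, a *link* with
  a first-arrival delay otherwise), at the original rate weighted by the
  arrival probability;
* a killing event -- a delayed *loss* reaction carrying the killing
  channel's emitted products (empty for pure degradation), so reactant
  removal still happens at initiation and the walker semantics of
  degradation are conserved.

Rates out of every SOI are conserved exactly: the weighted branch rates sum
to the original outgoing rate.  Reactions entirely between retained species
are carried over unchanged.  Probability-zero branches are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    NetworkError,
    Reaction,
    ReactionKind,
    ReactionNetwork,
    Species,
    classify_reactions,
)
from .passage import (
    DelayDistribution,
    PassagePortfolio,
    PassageProbabilities,
    arrival_return_probabilities,
    first_passage_analysis,
)
from .simulate import PendingUpdate

__all__ = ["DelayedReaction", "AbridgedModel", "HistoryDraw",
           "abridge", "attach_synthesis", "build_initial_history"]


@dataclass
class DelayedReaction:
    """A consuming delayed reaction: reactants are removed when the reaction
    fires, products appear a random delay later.

    ``rate_constant`` is the probability-weighted rate (for reactions with a
    declared non-mass-action propensity it is the probability weight applied
    to the propensity law).  ``label`` records the walker scenario the delay
    represents.
    """

    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    rate_constant: float
    delay: DelayDistribution
    label: str  # first_return | first_arrival | synthesis_arrival | loss
    consuming: bool = True
    propensity: tuple[str, dict] | None = None

    def reaction_view(self) -> Reaction:
        return Reaction(reactants=list(self.reactants), products=list(self.products),
                        rate_constant=self.rate_constant, propensity=self.propensity)


@dataclass
class AbridgedModel:
    """SOIs plus delayed reactions, with carried-over immediate reactions."""

    species: list[Species]                  # retained species, chain order kept
    sois: list[str]
    delayed_reactions: list[DelayedReaction]
    immediate_reactions: list[Reaction]
    probabilities: PassageProbabilities | None = None
    initial_state: dict[str, int] = field(default_factory=dict)
    synthesis_attached: bool = False

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def outgoing_rate(self, name: str) -> float:
        """Total rate constant out of a species, delayed plus immediate
        (mass-action unimolecular reactions only)."""
        total = 0.0
        for r in self.delayed_reactions:
            if r.propensity is None and r.reactants == [(name, 1)]:
                total += r.rate_constant
        for r in self.immediate_reactions:
            if r.propensity is None and r.is_unimolecular and r.reactants[0][0] == name:
                total += r.rate_constant
        return total


@dataclass
class HistoryDraw:
    """Pre-drawn delayed updates representing the non-SOI molecules of the
    full model's initial condition."""

    pending: list[PendingUpdate]
    discarded: int
    initial_state: dict[str, int]


def _portfolio_cache(network: ReactionNetwork, sois: list[str]):
    cache: dict[str, PassagePortfolio] = {}

    def get(start: str) -> PassagePortfolio:
        if start not in cache:
            cache[start] = first_passage_analysis(network, start, sois)
        return cache[start]

    return get


def _branch_reactions(reaction: Reaction, portfolio: PassagePortfolio,
                      label_for_target) -> list[DelayedReaction]:
    out = []
    for o in portfolio.outcomes:
        if o.target is None and not o.products:
            label = "loss"
        elif o.target is None:
            label = "loss"
        else:
            label = label_for_target(o.target)
        if not o.products and label == "loss":
            # pure degradation still removes the reactant at initiation
            pass
        out.append(DelayedReaction(
            reactants=list(reaction.reactants),
            products=list(o.products),
            rate_constant=reaction.rate_constant * o.probability,
            delay=o.distribution,
            label=label,
            propensity=reaction.propensity,
        ))
    return out


def abridge(network: ReactionNetwork, sois: list[str] | None = None,
            mode: str | None = None, rewire_synthesis: bool = True) -> AbridgedModel:
    """Build the abridged delayed-reaction model for the chosen SOI set.

    ``mode`` may assert the intended scheme (``"two_soi"``: both chain ends
    are SOIs; ``"single_soi"``: one SOI, first-return loops only); by default
    it is inferred.  Bypass reactions consuming an SOI are not supported and
    raise :class:`NetworkError`.
    """
    sois = list(network.sois if sois is None else sois)
    if not sois:
        raise NetworkError("at least one SOI is required for abridgement")
    report = classify_reactions(network, sois)
    if report.bypass_consumes_soi:
        raise NetworkError("unsupported configuration: a bypass reaction consumes an SOI "
                           "(requires the extended abridgement scheme)")
    chain_sois = [s for s in report.chain_order if s in sois]
    if mode == "two_soi" and len(chain_sois) != 2:
        raise NetworkError("two_soi mode needs two chain SOIs")
    if mode == "single_soi" and len(chain_sois) != 1:
        raise NetworkError("single_soi mode needs exactly one chain SOI")
    intermediates = {s for s in report.chain_order if s not in sois}
    retained = [sp for sp in network.species if sp.name not in intermediates]
    initial = {k: v for k, v in network.initial_state.items() if k not in intermediates}

    if not intermediates:
        # nothing to lump: the abridged model is the original model
        return AbridgedModel(species=retained, sois=sois, delayed_reactions=[],
                             immediate_reactions=list(network.reactions),
                             probabilities=None, initial_state=initial,
                             synthesis_attached=True)

    probabilities = None
    if len(chain_sois) == 2 and chain_sois[0] == report.chain_order[0] \
            and chain_sois[1] == report.chain_order[-1]:
        probabilities = arrival_return_probabilities(network, sois)

    portfolio = _portfolio_cache(network, sois)
    delayed: list[DelayedReaction] = []
    immediate: list[Reaction] = []
    deferred_syntheses: list[Reaction] = []
    for r in network.reactions:
        touches_block_reactant = any(sp in intermediates for sp, _ in r.reactants)
        if touches_block_reactant:
            continue  # internal to the lumped block
        inter_products = [(sp, st) for sp, st in r.products if sp in intermediates]
        if not inter_products:
            immediate.append(r)
            continue
        if r.kind is ReactionKind.SYNTHESIS:
            deferred_syntheses.append(r)
            continue
        if len(inter_products) > 1 or inter_products[0][1] != 1:
            raise NetworkError(f"cannot abridge {r.label()}: more than one molecule "
                               "injected into the lumped block per firing")
        start = inter_products[0][0]
        if r.is_unimolecular and r.reactants[0][0] in sois:
            src = r.reactants[0][0]
            delayed.extend(_branch_reactions(
                r, portfolio(start),
                lambda t, src=src: "first_return" if t == src else "first_arrival"))
        else:
            # boundary bimolecular (or other retained-reactant) feeder
            delayed.extend(_branch_reactions(r, portfolio(start),
                                             lambda t: "first_arrival"))

    model = AbridgedModel(species=retained, sois=sois, delayed_reactions=delayed,
                          immediate_reactions=immediate, probabilities=probabilities,
                          initial_state=initial)
    if rewire_synthesis:
        model = attach_synthesis(network, model, _syntheses=deferred_syntheses)
    elif deferred_syntheses:
        model._pending_syntheses = deferred_syntheses  # type: ignore[attr-defined]
    return model


def attach_synthesis(network: ReactionNetwork, abridged: AbridgedModel,
                     _syntheses: list[Reaction] | None = None) -> AbridgedModel:
    """Rewire synthesis reactions producing intermediates into delayed
    syntheses of the reachable SOIs; SOI-producing syntheses are carried over
    verbatim (they already are, by :func:`abridge`)."""
    if abridged.synthesis_attached:
        return abridged
    if _syntheses is None:
        _syntheses = getattr(abridged, "_pending_syntheses", None)
        if _syntheses is None:
            report = classify_reactions(network, abridged.sois)
            retained = set(abridged.species_names)
            _syntheses = [r for r in report.syntheses
                          if r.products[0][0] not in retained]
    portfolio = _portfolio_cache(network, abridged.sois)
    for r in _syntheses:
        start = r.products[0][0]
        for o in portfolio(start).outcomes:
            if not o.products:
                continue  # degradation-absorbed fraction emits nothing
            abridged.delayed_reactions.append(DelayedReaction(
                reactants=[], products=list(o.products),
                rate_constant=r.rate_constant * o.probability,
                delay=o.distribution, label="synthesis_arrival",
                propensity=r.propensity,
            ))
    abridged.synthesis_attached = True
    return abridged


def build_initial_history(network: ReactionNetwork, abridged: AbridgedModel,
                          full_initial_state: dict[str, int],
                          rng: np.random.Generator) -> HistoryDraw:
    """Translate a full-model initial condition into an abridged one.

    SOI (and other retained-species) counts are copied; each molecule of a
    lumped intermediate is represented by a pre-drawn delayed update: an
    arrival fate is drawn from its first-passage probabilities and a
    completion time from the corresponding conditional delay distribution.
    Molecules fated to pure degradation are discarded (counted).
    """
    retained = set(abridged.species_names)
    initial = {sp: 0 for sp in abridged.species_names}
    portfolio = _portfolio_cache(network, abridged.sois)
    pending: list[PendingUpdate] = []
    discarded = 0
    chain = {s.name for s in network.species}
    for sp, count in full_initial_state.items():
        if sp not in chain:
            raise NetworkError(f"initial molecules of unknown species {sp!r}")
        if count < 0:
            raise NetworkError(f"negative initial count for {sp!r}")
        if sp in retained:
            initial[sp] = initial.get(sp, 0) + count
            continue
        pf = portfolio(sp)
        probs = np.array([o.probability for o in pf.outcomes])
        draws = rng.multinomial(count, probs / probs.sum())
        for o, k in zip(pf.outcomes, draws):
            if k == 0:
                continue
            if not o.products:
                discarded += int(k)
                continue
            times = np.atleast_1d(o.distribution.sample(rng, size=int(k)))
            for t in times:
                pending.append(PendingUpdate(completion_time=float(t),
                                             increment=dict(o.products)))
    pending.sort(key=lambda p: p.completion_time)
    return HistoryDraw(pending=pending, discarded=discarded, initial_state=initial)
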