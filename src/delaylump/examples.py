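"""Synthetic chain generation and the worked biological systems.

Three families of fixtures:

* :func:`random_chain` -- seeded bi-directional chains with optional bypass,
  degradation and synthesis reactions, the workhorse of the validation
  suite;
* :func:`example_bidirectional_chain` -- a 10-species fully bi-directional
  chain S0 ... S9 with two uni-directional bypass reactions and SOIs
  {S0, S9}.  The reference rate set shipped here is synthetic (documented
  defaults chosen in the mid-range of order-one kinetics); the reduction and
  all of its checks are rate-agnostic;
* :func:`example_glycolysis` and :func:`example_proofreading` -- a minimal
  autocatalytic glycolysis model (ATP = Y drives its own production through
  a chain of lower-glycolysis intermediates, with ATP-inhibited
  phosphofructokinase kinetics) and McKeithan-style kinetic proofreading of
  T-cell receptor signalling (receptor T and peptide M bind and the complex
  matures through N phosphorylation steps to the active form C_N, each step
  racing against dissociation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abridge import AbridgedModel, abridge
from .network import NetworkError, Reaction, ReactionNetwork, Species

__all__ = [
    "ChainSpecParams", "GlycolysisParams", "ProofreadingParams",
    "random_chain", "example_bidirectional_chain",
    "example_glycolysis", "example_proofreading",
]


# ---------------------------------------------------------------------------
# synthetic chains
# ---------------------------------------------------------------------------

@dataclass
class ChainSpecParams:
    """Parameters of a synthetic bi-directional chain S1 ... Sn.

    ``forward``/``backward`` may be explicit rate lists (length n-1) or None
    to sample uniformly from ``rate_range`` with ``seed``.  Bypasses,
    degradations and syntheses are given as (from, to, rate), (species, rate)
    and (species, rate) tuples over 1-based chain positions.
    """

    n: int
    forward: list[float] | None = None
    backward: list[float] | None = None
    rate_range: tuple[float, float] = (0.5, 5.0)
    bypasses: list[tuple[int, int, float]] = field(default_factory=list)
    degradations: list[tuple[int, float]] = field(default_factory=list)
    syntheses: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise NetworkError("a chain needs at least two species")
        for i, j, _ in self.bypasses:
            if not (1 <= i <= self.n and 1 <= j <= self.n and abs(i - j) > 1):
                raise NetworkError(f"invalid bypass endpoints ({i}, {j}) for n={self.n}")


def random_chain(params: ChainSpecParams) -> ReactionNetwork:
    """Reproducible chain network from a parameter set; SOIs default to the
    two chain ends."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    lo, hi = params.rate_range
    fwd = params.forward if params.forward is not None else rng.uniform(lo, hi, n - 1)
    bwd = params.backward if params.backward is not None else rng.uniform(lo, hi, n - 1)
    if len(fwd) != n - 1 or len(bwd) != n - 1:
        raise NetworkError("need n-1 forward and n-1 backward rates")
    name = [f"S{i}" for i in range(1, n + 1)]
    species = [Species(nm, i + 1) for i, nm in enumerate(name)]
    reactions = []
    for i in range(n - 1):
        if fwd[i] > 0:
            reactions.append(Reaction([(name[i], 1)], [(name[i + 1], 1)], float(fwd[i])))
        if bwd[i] > 0:
            reactions.append(Reaction([(name[i + 1], 1)], [(name[i], 1)], float(bwd[i])))
    for i, j, c in params.bypasses:
        reactions.append(Reaction([(name[i - 1], 1)], [(name[j - 1], 1)], float(c)))
    for i, c in params.degradations:
        reactions.append(Reaction([(name[i - 1], 1)], [], float(c)))
    for i, c in params.syntheses:
        reactions.append(Reaction([], [(name[i - 1], 1)], float(c)))
    return ReactionNetwork(species=species, reactions=reactions,
                           sois=[name[0], name[-1]])


def example_bidirectional_chain(forward: float = 1.5, backward: float = 1.0,
                                bypass_rates: tuple[float, float] = (0.5, 0.4),
                                s9_initial: int = 200) -> ReactionNetwork:
    """The 10-species fully bi-directional chain S0 ... S9 with two
    uni-directional bypass reactions (S2 -> S6 forward, S7 -> S3 backward)
    and SOIs {S0, S9}.  Rates are documented synthetic defaults."""
    name = [f"S{i}" for i in range(10)]
    species = [Species(nm, i + 1) for i, nm in enumerate(name)]
    reactions = []
    for i in range(9):
        reactions.append(Reaction([(name[i], 1)], [(name[i + 1], 1)], forward))
        reactions.append(Reaction([(name[i + 1], 1)], [(name[i], 1)], backward))
    reactions.append(Reaction([("S2", 1)], [("S6", 1)], bypass_rates[0]))
    reactions.append(Reaction([("S7", 1)], [("S3", 1)], bypass_rates[1]))
    return ReactionNetwork(species=species, reactions=reactions,
                           sois=["S0", "S9"],
                           initial_state={"S9": s9_initial})


# ---------------------------------------------------------------------------
# glycolysis
# ---------------------------------------------------------------------------

@dataclass
class GlycolysisParams:
    """Minimal autocatalytic glycolysis model.

    Y denotes ATP.  The phosphofructokinase (PFK) step invests ``q`` ATP and
    feeds the intermediate chain X1 -> ... -> X4; the final step returns
    ``2q`` ATP (gross glycolytic yield, net gain q).  PFK activity is
    ATP-inhibited with a Hill law of maximal rate V, threshold phi*V and
    exponent h; ATP is consumed by a non-specific demand at rate gamma*Y.
    ``h_i`` are the degradation rates of the intermediates in the
    degradation-extended variant (disabled in the minimal scheme); ``g_y``
    is a basal ATP synthesis likewise excluded from the minimal scheme, so
    that the abridged model has exactly one delayed and one non-delayed
    reaction.
    """

    V: float = 500.0
    phi: float = 0.5
    q: int = 2
    h: float = 5.0
    gamma: float = 2.0
    g: tuple[float, float, float, float] = (2.0, 2.0, 2.0, 2.0)
    g_y: float = 0.5
    h_i: tuple[float, float, float] = (1.0, 1.0, 1.0)   # X2..X4 degradation rates
    Y0: int = 100

    def __post_init__(self) -> None:
        if min(self.V, self.phi, self.h, self.gamma, self.g_y, *self.g) <= 0 \
                or self.q < 1:
            raise NetworkError("glycolysis parameters must be positive")


def glycolysis_network(params: GlycolysisParams | None = None,
                       include_intermediate_degradation: bool = False,
                       include_basal_synthesis: bool = False) -> ReactionNetwork:
    p = params or GlycolysisParams()
    xs = [f"X{i}" for i in range(1, 5)]
    species = [Species(x, i + 1) for i, x in enumerate(xs)] + [Species("Y")]
    pfk = Reaction(
        reactants=[("Y", p.q)], products=[("X1", 1)], rate_constant=1.0,
        propensity=("hill_repression",
                    {"vmax": p.V, "threshold": p.phi * p.V,
                     "exponent": p.h, "min_count": p.q}),
    )
    reactions = [pfk]
    for i in range(3):
        reactions.append(Reaction([(xs[i], 1)], [(xs[i + 1], 1)], p.g[i]))
    reactions.append(Reaction([("X4", 1)], [("Y", 2 * p.q)], p.g[3]))
    reactions.append(Reaction([("Y", 1)], [], p.gamma))
    if include_basal_synthesis:
        reactions.append(Reaction([], [("Y", 1)], p.g_y))
    if include_intermediate_degradation:
        for x, d in zip(xs[1:], p.h_i):
            reactions.append(Reaction([(x, 1)], [], d))
    return ReactionNetwork(species=species, reactions=reactions, sois=["Y"],
                           initial_state={"Y": p.Y0})


def example_glycolysis(params: GlycolysisParams | None = None
                       ) -> tuple[ReactionNetwork, AbridgedModel]:
    """Full network and its abridgement: the four-stage intermediate chain is
    replaced by a single delayed PFK reaction (q Y -> 2q Y after a delay that
    is the convolution of the four stage exponentials) next to the
    non-delayed ATP demand."""
    network = glycolysis_network(params)
    return network, abridge(network)


# ---------------------------------------------------------------------------
# kinetic proofreading
# ---------------------------------------------------------------------------

@dataclass
class ProofreadingParams:
    """McKeithan-style kinetic proofreading of T-cell receptor signalling.

    T (receptor) + M (peptide) bind at ``k1`` into the nascent complex C0,
    which matures through N phosphorylation steps at ``kp``, each racing
    against dissociation back to T + M at ``k_minus1``; C_N is the active
    complex.  The completion probability from C0 is
    p = (kp / (kp + k_minus1))^N and the conditional completion time the
    N-fold convolution of Exp(kp + k_minus1) stages.
    """

    k1: float = 1.0
    k_minus1: float = 0.25
    kp: float = 5.0
    N: int = 6
    T0: int = 200
    M0: int = 200

    def __post_init__(self) -> None:
        if min(self.k1, self.k_minus1, self.kp) <= 0 or self.N < 1:
            raise NetworkError("proofreading parameters must be positive, N >= 1")

    @property
    def completion_probability(self) -> float:
        return (self.kp / (self.kp + self.k_minus1)) ** self.N


def proofreading_network(params: ProofreadingParams | None = None) -> ReactionNetwork:
    p = params or ProofreadingParams()
    cs = [f"C{i}" for i in range(p.N + 1)]
    species = [Species(c, i + 1) for i, c in enumerate(cs)] + [Species("T"), Species("M")]
    reactions = [Reaction([("T", 1), ("M", 1)], [("C0", 1)], p.k1)]
    for i in range(p.N):
        reactions.append(Reaction([(cs[i], 1)], [(cs[i + 1], 1)], p.kp))
        reactions.append(Reaction([(cs[i], 1)], [("T", 1), ("M", 1)], p.k_minus1))
    return ReactionNetwork(species=species, reactions=reactions,
                           sois=["C0", cs[-1], "T", "M"],
                           initial_state={"T": p.T0, "M": p.M0})


def example_proofreading(params: ProofreadingParams | None = None
                         ) -> tuple[ReactionNetwork, AbridgedModel]:
    """Full network and its abridgement: the intermediate complexes C1..C5
    are replaced by two delayed reactions out of C0 -- delayed production of
    the active complex and delayed regeneration of T + M -- next to the
    carried-over binding and first-step dissociation."""
    network = proofreading_network(params)
    return network, abridge(network)
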