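"""Exact stochastic simulation: direct-method SSA and rejection-method DSSA.

Full models are simulated with Gillespie's direct method.  Abridged models
contain consuming delayed reactions and are simulated with the rejection
DSSA: a tentative next-reaction time is drawn from the total propensity; if
a queued product update completes earlier, the tentative firing is rejected,
the completion is applied and the waiting time redrawn (valid because
exponential waiting times are memoryless).  When a delayed reaction fires,
its reactants are removed immediately and its products are scheduled at
``t + tau`` with ``tau`` drawn from the reaction's delay distribution.
Queued completions that would land beyond the simulation horizon are
discarded from the reported trajectory (molecules still "in transit" are
invisible to the SOI marginals by construction).

One seeded generator per run drives, in order: the initial-condition delay
history (drawn before the main loop), then the alternating firing-time /
reaction-selection / delay draws of the main loop.

Ensemble runs are delegated to compiled kernels (:mod:`delaylump._kernels`)
that implement the identical algorithms with fixed-grid state recording.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkError, Reaction, ReactionNetwork

__all__ = [
    "PendingUpdate", "Trajectory", "EnsembleResult", "ModelProgram",
    "compile_network", "compile_abridged", "ssa_direct", "dssa_rejection",
    "sample_delay", "run_ssa_ensemble", "run_dssa_ensemble", "simulate_abridged_run",
]

#: probability grid used to tabulate inverse CDFs for kernel delay sampling
_INV_U = np.linspace(0.0, 1.0 - 1e-7, 4097)


@dataclass(order=True)
class PendingUpdate:
    """A scheduled product update in the DSSA queue."""

    completion_time: float
    increment: dict[str, int] = field(compare=False)


@dataclass
class Trajectory:
    """Event-resolution trajectory: state after every state change."""

    times: np.ndarray            # nondecreasing, first entry 0
    states: np.ndarray           # (n_events+1, n_species) counts
    species: list[str]
    seed: int | None = None
    model_id: str = ""

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(i, 0)]

    def resample(self, grid) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        idx = np.clip(np.searchsorted(self.times, grid, side="right") - 1, 0, None)
        return self.states[idx]

    def counts(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]


@dataclass
class EnsembleResult:
    """Fixed-grid ensemble: counts[r, g, s] for run r, grid point g, species s."""

    grid: np.ndarray
    counts: np.ndarray
    species: list[str]

    @property
    def n_runs(self) -> int:
        return self.counts.shape[0]

    def mean(self, name: str | None = None) -> np.ndarray:
        m = self.counts.mean(axis=0)
        return m if name is None else m[:, self.species.index(name)]

    def sem(self, name: str | None = None) -> np.ndarray:
        s = self.counts.std(axis=0, ddof=1) / math.sqrt(self.n_runs)
        return s if name is None else s[:, self.species.index(name)]

    def terminal(self, name: str) -> np.ndarray:
        return self.counts[:, -1, self.species.index(name)]


# ---------------------------------------------------------------------------
# model compilation
# ---------------------------------------------------------------------------

@dataclass
class ModelProgram:
    """A reaction model flattened into arrays for the simulation loops."""

    species: list[str]
    kind: np.ndarray
    rate: np.ndarray
    r0: np.ndarray
    r1: np.ndarray
    hill: np.ndarray
    delta: np.ndarray
    delayed: np.ndarray
    prod_row: np.ndarray
    prod_rows: np.ndarray
    delay_kind: np.ndarray
    stage_start: np.ndarray
    stage_end: np.ndarray
    stage_rates: np.ndarray
    table_row: np.ndarray
    tables: np.ndarray
    delays: list            # DelayDistribution or None, per reaction
    labels: list[str]

    @property
    def n_reactions(self) -> int:
        return self.kind.size

    def index(self, name: str) -> int:
        return self.species.index(name)

    def state_vector(self, x0: dict[str, int]) -> np.ndarray:
        x = np.zeros(len(self.species), dtype=np.int64)
        for sp, c in x0.items():
            if sp not in self.species:
                raise NetworkError(f"initial count for unknown species {sp!r}")
            x[self.index(sp)] = c
        return x

    def propensity(self, k: int, x: np.ndarray) -> float:
        kd = self.kind[k]
        c = self.rate[k]
        if kd == 0:
            return c * x[self.r0[k]]
        if kd == 1:
            return c * x[self.r0[k]] * x[self.r1[k]]
        if kd == 2:
            return c * x[self.r0[k]] * (x[self.r0[k]] - 1)
        if kd == 3:
            return c
        y = x[self.r0[k]]
        if y < self.hill[k, 3]:
            return 0.0
        return c * self.hill[k, 0] / (1.0 + (y / self.hill[k, 1]) ** self.hill[k, 2])

    def propensities(self, x: np.ndarray) -> np.ndarray:
        return np.array([self.propensity(k, x) for k in range(self.n_reactions)])


def _encode_propensity(reactants, propensity):
    """Map a reactant pattern (and optional law) to a (kind, r0, r1, hill) row."""
    hill = (0.0, 1.0, 1.0, 0.0)
    if propensity is not None:
        law, params = propensity
        if law != "hill_repression":
            raise NetworkError(f"unknown propensity law {law!r}")
        if len(reactants) != 1:
            raise NetworkError("hill_repression expects a single reactant species")
        hill = (params["vmax"], params["threshold"], params["exponent"],
                params.get("min_count", reactants[0][1]))
        return 4, 0, -1, hill
    if not reactants:
        return 3, -1, -1, hill
    if len(reactants) == 1 and reactants[0][1] == 1:
        return 0, 0, -1, hill
    if len(reactants) == 2 and all(st == 1 for _, st in reactants):
        return 1, 0, 1, hill
    if len(reactants) == 1 and reactants[0][1] == 2:
        return 2, 0, -1, hill
    raise NetworkError(f"unsupported reactant pattern {reactants}")


def _compile(species: list[str], immediate: list[Reaction], delayed_rx) -> ModelProgram:
    sidx = {s: i for i, s in enumerate(species)}
    n_s = len(species)
    rows = []
    stage_rates: list[float] = []
    tables: list[np.ndarray] = []
    delays: list = []
    labels: list[str] = []
    from .passage import StageConvolution  # local import to avoid a cycle

    for r in immediate:
        kd, p0, p1, hill = _encode_propensity(r.reactants, r.propensity)
        delta = np.zeros(n_s, dtype=np.int64)
        for sp, st in r.reactants:
            delta[sidx[sp]] -= st
        for sp, st in r.products:
            delta[sidx[sp]] += st
        rows.append(dict(kind=kd, rate=r.rate_constant,
                         r0=sidx[r.reactants[p0][0]] if p0 >= 0 else -1,
                         r1=sidx[r.reactants[p1][0]] if p1 >= 0 else -1,
                         hill=hill, delta=delta, delayed=False,
                         prod=None, dk=-1, ss=0, se=0, trow=-1))
        delays.append(None)
        labels.append(r.label())
    for r in delayed_rx:
        kd, p0, p1, hill = _encode_propensity(r.reactants, r.propensity)
        delta = np.zeros(n_s, dtype=np.int64)
        for sp, st in r.reactants:
            delta[sidx[sp]] -= st
        prod = np.zeros(n_s, dtype=np.int64)
        for sp, st in r.products:
            prod[sidx[sp]] += st
        if isinstance(r.delay, StageConvolution):
            ss = len(stage_rates)
            stage_rates.extend(float(v) for v in r.delay.stage_rates)
            dk, se, trow = 0, len(stage_rates), -1
        else:
            trow = len(tables)
            tables.append(r.delay.inverse_cdf_table(_INV_U))
            dk, ss, se = 1, 0, 0
        rows.append(dict(kind=kd, rate=r.rate_constant,
                         r0=sidx[r.reactants[p0][0]] if p0 >= 0 else -1,
                         r1=sidx[r.reactants[p1][0]] if p1 >= 0 else -1,
                         hill=hill, delta=delta, delayed=True,
                         prod=prod, dk=dk, ss=ss, se=se, trow=trow))
        delays.append(r.delay)
        labels.append(f"{r.label}:{'+'.join(sp for sp, _ in r.reactants) or '0'}")
    n_k = len(rows)
    prod_rows = [row["prod"] for row in rows if row["prod"] is not None]
    prod_map = {}
    j = 0
    for i, row in enumerate(rows):
        if row["prod"] is not None:
            prod_map[i] = j
            j += 1
    return ModelProgram(
        species=species,
        kind=np.array([r["kind"] for r in rows], dtype=np.int64),
        rate=np.array([r["rate"] for r in rows], dtype=np.float64),
        r0=np.array([r["r0"] for r in rows], dtype=np.int64),
        r1=np.array([r["r1"] for r in rows], dtype=np.int64),
        hill=np.array([r["hill"] for r in rows], dtype=np.float64).reshape(n_k, 4),
        delta=np.array([r["delta"] for r in rows], dtype=np.int64).reshape(n_k, n_s),
        delayed=np.array([r["delayed"] for r in rows], dtype=np.bool_),
        prod_row=np.array([prod_map.get(i, -1) for i in range(n_k)], dtype=np.int64),
        prod_rows=(np.array(prod_rows, dtype=np.int64).reshape(len(prod_rows), n_s)
                   if prod_rows else np.zeros((0, n_s), dtype=np.int64)),
        delay_kind=np.array([r["dk"] for r in rows], dtype=np.int64),
        stage_start=np.array([r["ss"] for r in rows], dtype=np.int64),
        stage_end=np.array([r["se"] for r in rows], dtype=np.int64),
        stage_rates=np.array(stage_rates, dtype=np.float64),
        table_row=np.array([r["trow"] for r in rows], dtype=np.int64),
        tables=(np.array(tables, dtype=np.float64).reshape(len(tables), _INV_U.size)
                if tables else np.zeros((0, _INV_U.size), dtype=np.float64)),
        delays=delays,
        labels=labels,
    )


def compile_network(network: ReactionNetwork) -> ModelProgram:
    return _compile([s.name for s in network.species], list(network.reactions), [])


def compile_abridged(abridged) -> ModelProgram:
    return _compile(abridged.species_names, list(abridged.immediate_reactions),
                    list(abridged.delayed_reactions))


# ---------------------------------------------------------------------------
# reference (event-recording) simulators
# ---------------------------------------------------------------------------

def sample_delay(d, rng: np.random.Generator) -> float:
    """One positive delay draw: exact stage sums for convolution forms,
    inverse-CDF otherwise."""
    return float(d.sample(rng))


def ssa_direct(network: ReactionNetwork | ModelProgram, x0: dict[str, int],
               t_end: float, rng: np.random.Generator,
               max_events: int = 10_000_000, model_id: str = "full") -> Trajectory:
    """Statistically exact direct-method trajectory of a full model."""
    prog = network if isinstance(network, ModelProgram) else compile_network(network)
    x = prog.state_vector(x0)
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    for _ in range(max_events):
        a = prog.propensities(x)
        total = float(a.sum())
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        k = min(int(np.searchsorted(np.cumsum(a), rng.random() * total)),
                prog.n_reactions - 1)
        x = x + prog.delta[k]
        if np.any(x < 0):
            raise RuntimeError(f"negative count after reaction {prog.labels[k]}")
        times.append(t)
        states.append(x.copy())
    return Trajectory(times=np.array(times), states=np.array(states),
                      species=prog.species, model_id=model_id)


def dssa_rejection(abridged, x0: dict[str, int], history, t_end: float,
                   rng: np.random.Generator, max_events: int = 10_000_000,
                   model_id: str = "abridged") -> Trajectory:
    """Rejection-method DSSA trajectory of an abridged model.

    ``history`` is a :class:`delaylump.abridge.HistoryDraw` (or None); its
    pending updates seed the completion queue.
    """
    prog = abridged if isinstance(abridged, ModelProgram) else compile_abridged(abridged)
    for k, d in enumerate(prog.delays):
        if d is not None and float(d.cdf(d._time_scale() * 200.0)) < 0.999:
            raise NetworkError(f"delay of reaction {prog.labels[k]} is not sampleable "
                               "(CDF does not approach 1)")
    x = prog.state_vector(x0)
    queue: list[tuple[float, int, np.ndarray]] = []
    counter = 0
    if history is not None:
        for p in sorted(history.pending, key=lambda q: q.completion_time):
            inc = np.zeros(len(prog.species), dtype=np.int64)
            for sp, st in p.increment.items():
                inc[prog.index(sp)] += st
            heapq.heappush(queue, (p.completion_time, counter, inc))
            counter += 1
    times = [0.0]
    states = [x.copy()]
    t = 0.0
    for _ in range(max_events):
        a = prog.propensities(x)
        total = float(a.sum())
        t_next = t + rng.exponential(1.0 / total) if total > 0 else math.inf
        t_comp = queue[0][0] if queue else math.inf
        if t_comp <= t_next:           # completion wins ties
            if t_comp > t_end:
                break
            _, _, inc = heapq.heappop(queue)
            x = x + inc
            t = t_comp
        else:
            if t_next > t_end or not math.isfinite(t_next):
                break
            k = min(int(np.searchsorted(np.cumsum(a), rng.random() * total)),
                    prog.n_reactions - 1)
            x = x + prog.delta[k]
            t = t_next
            if prog.delayed[k]:
                tau = sample_delay(prog.delays[k], rng)
                heapq.heappush(queue, (t + tau, counter, prog.prod_rows[prog.prod_row[k]]))
                counter += 1
        if np.any(x < 0):
            raise RuntimeError("negative count in DSSA update")
        times.append(t)
        states.append(x.copy())
    return Trajectory(times=np.array(times), states=np.array(states),
                      species=prog.species, model_id=model_id)


# ---------------------------------------------------------------------------
# ensemble runners (compiled kernels)
# ---------------------------------------------------------------------------

def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs, dtype=np.int64)


def run_ssa_ensemble(network: ReactionNetwork | ModelProgram, x0: dict[str, int],
                     t_end: float, grid, n_runs: int, seed: int) -> EnsembleResult:
    """n_runs independent SSA trajectories recorded on a fixed grid."""
    from ._kernels import ssa_kernel
    prog = network if isinstance(network, ModelProgram) else compile_network(network)
    grid = np.asarray(grid, dtype=float)
    xv = prog.state_vector(x0)
    seeds = _run_seeds(seed, n_runs)
    counts = np.empty((n_runs, grid.size, len(prog.species)), dtype=np.int64)
    for r in range(n_runs):
        counts[r] = ssa_kernel(seeds[r], xv, float(t_end), grid, prog.kind, prog.rate,
                               prog.r0, prog.r1, prog.hill, prog.delta)
    return EnsembleResult(grid=grid, counts=counts, species=prog.species)


def run_dssa_ensemble(network: ReactionNetwork | None, abridged, full_x0: dict[str, int],
                      t_end: float, grid, n_runs: int, seed: int) -> EnsembleResult:
    """n_runs independent rejection-DSSA trajectories of an abridged model.

    When ``full_x0`` places molecules on lumped intermediates, a fresh
    initial-condition delay history is drawn for every run from the run's own
    generator (``network`` is then required for the first-passage analysis).
    """
    from ._kernels import dssa_kernel
    from .abridge import build_initial_history
    prog = compile_abridged(abridged)
    grid = np.asarray(grid, dtype=float)
    retained = set(prog.species)
    needs_history = any(sp not in retained and c > 0 for sp, c in full_x0.items())
    seeds = _run_seeds(seed, n_runs)
    counts = np.empty((n_runs, grid.size, len(prog.species)), dtype=np.int64)
    n_base = prog.prod_rows.shape[0]
    for r in range(n_runs):
        rng = np.random.default_rng(int(seeds[r]))
        if needs_history:
            if network is None:
                raise NetworkError("full-model network required to draw the delay history")
            hist = build_initial_history(network, abridged, full_x0, rng)
            x0 = hist.initial_state
            extra_rows = []
            hist_t = np.empty(len(hist.pending))
            hist_row = np.empty(len(hist.pending), dtype=np.int64)
            for i, p in enumerate(hist.pending):
                inc = np.zeros(len(prog.species), dtype=np.int64)
                for sp, st in p.increment.items():
                    inc[prog.index(sp)] += st
                extra_rows.append(inc)
                hist_t[i] = p.completion_time
                hist_row[i] = n_base + i
            prows = (np.vstack([prog.prod_rows] + extra_rows)
                     if extra_rows else prog.prod_rows)
        else:
            x0 = {sp: c for sp, c in full_x0.items() if sp in retained}
            hist_t = np.empty(0)
            hist_row = np.empty(0, dtype=np.int64)
            prows = prog.prod_rows
        xv = prog.state_vector(x0)
        counts[r] = dssa_kernel(int(rng.integers(0, 2**31 - 1)), xv, float(t_end), grid,
                                prog.kind, prog.rate, prog.r0, prog.r1, prog.hill,
                                prog.delta, prog.delayed, prog.prod_row, prows,
                                prog.delay_kind, prog.stage_start, prog.stage_end,
                                prog.stage_rates, prog.table_row, prog.tables, _INV_U,
                                hist_t, hist_row)
    return EnsembleResult(grid=grid, counts=counts, species=prog.species)


def simulate_abridged_run(network: ReactionNetwork, abridged, full_x0: dict[str, int],
                          t_end: float, rng: np.random.Generator) -> Trajectory:
    """One reference DSSA run including history construction, in the
    documented generator-consumption order (history first)."""
    from .abridge import build_initial_history
    hist = build_initial_history(network, abridged, full_x0, rng)
    return dssa_rejection(abridged, hist.initial_state, hist, t_end, rng)
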