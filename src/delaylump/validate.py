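"""Brute-force oracles and statistical comparisons.

Single-molecule walker sampling and ensemble comparison machinery used to
triangulate every closed-form distribution and the exactness of the
reduction: closed forms are checked against (i) the matrix-exponential
tabulation and (ii) empirical first-passage samples (KS test, binomial
confidence intervals on event frequencies); SSA ensembles of full models are
checked against DSSA ensembles of abridged models via per-checkpoint
z-scores of the means and chi-square tests on terminal histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import ABSORBED, NetworkError, ReactionNetwork, build_generator
from .simulate import EnsembleResult

__all__ = [
    "FirstPassageSample", "KSReport", "EnsembleComparison",
    "walker_first_passage_sample", "ks_compare", "compare_ensembles",
    "binomial_ci",
]

DEGRADED = "degradation"


@dataclass
class FirstPassageSample:
    """Per-walker outcome labels and event times."""

    outcomes: np.ndarray      # array of str labels: stop-species name or "degradation"
    times: np.ndarray
    start: str
    n_walkers: int
    seed: int | None = None

    def times_for(self, label: str) -> np.ndarray:
        return self.times[self.outcomes == label]

    def frequency(self, label: str) -> float:
        return float(np.mean(self.outcomes == label))


def walker_first_passage_sample(network: ReactionNetwork, start: str,
                                stop_set, n_walkers: int,
                                rng: np.random.Generator,
                                max_steps: int = 1_000_000) -> FirstPassageSample:
    """Simulate ``n_walkers`` independent single-molecule jump chains until
    each hits a stop species or degrades; vectorized over walkers."""
    stop_set = list(stop_set)
    gen = build_generator(network, absorbing=stop_set, lump_degradation=True)
    K = gen.matrix
    n = K.shape[0]
    labels = [None] * n
    for name, i in gen.ordering.items():
        labels[i] = name if name != ABSORBED else DEGRADED
    if start not in gen.ordering or start in stop_set:
        raise NetworkError("start must be a non-stop chain species")
    exit_rate = -np.diag(K).copy()
    absorbing = exit_rate <= 0.0
    # mass-leak check: from the start, some absorbing state must be reachable
    reach = {gen.ordering[start]}
    frontier = [gen.ordering[start]]
    while frontier:
        j = frontier.pop()
        for i in np.nonzero(K[:, j] > 0)[0]:
            if i not in reach:
                reach.add(int(i))
                frontier.append(int(i))
    valid = {gen.ordering[s] for s in stop_set} | \
            ({gen.ordering[ABSORBED]} if ABSORBED in gen.ordering else set())
    reachable_sinks = {i for i in reach if absorbing[i]}
    if not reachable_sinks & valid or reachable_sinks - valid:
        raise NetworkError("walker can neither reach a stop state nor degrade "
                           "(dead-end state in the block)")
    # embedded jump probabilities, cumulative per column
    P = np.zeros((n, n))
    for j in range(n):
        if not absorbing[j]:
            P[:, j] = K[:, j].clip(min=0.0) / exit_rate[j]
    cum = np.cumsum(P, axis=0)

    state = np.full(n_walkers, gen.ordering[start], dtype=np.int64)
    time = np.zeros(n_walkers)
    active = ~absorbing[state]
    steps = 0
    while np.any(active):
        idx = np.nonzero(active)[0]
        s = state[idx]
        time[idx] += rng.exponential(1.0, size=idx.size) / exit_rate[s]
        u = rng.random(idx.size)
        nxt = (cum[:, s] < u).sum(axis=0)
        state[idx] = nxt
        active[idx] = ~absorbing[nxt]
        steps += 1
        if steps > max_steps:
            raise RuntimeError("walker simulation exceeded the step budget")
    outcomes = np.array([labels[s] for s in state])
    return FirstPassageSample(outcomes=outcomes, times=time, start=start,
                              n_walkers=n_walkers)


@dataclass
class KSReport:
    statistic: float
    pvalue: float
    critical: float
    alpha: float
    passed: bool


def ks_compare(sample_times, distribution, alpha: float = 0.01) -> KSReport:
    """One-sample Kolmogorov-Smirnov test of sampled times against a delay
    distribution's CDF; passes iff the statistic is below the asymptotic
    critical value at ``alpha``."""
    sample = np.asarray(sample_times, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_1samp(sample, lambda t: np.asarray(distribution.cdf(t), dtype=float))
    critical = stats.kstwobign.isf(alpha) / math.sqrt(sample.size)
    return KSReport(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    critical=float(critical), alpha=alpha,
                    passed=bool(res.statistic < critical))


def binomial_ci(p: float, n: int, alpha: float = 0.01) -> tuple[float, float]:
    """Normal-approximation (1-alpha) confidence band for an empirical
    frequency around probability ``p``."""
    z = stats.norm.isf(alpha / 2.0)
    half = z * math.sqrt(max(p * (1.0 - p), 1e-12) / n)
    return p - half, p + half


@dataclass
class EnsembleComparison:
    checkpoints: np.ndarray
    species: list[str]
    z_scores: np.ndarray          # (n_checkpoints, n_species)
    max_abs_z: float
    chisq_pvalues: dict[str, float]
    alpha: float
    z_threshold: float

    @property
    def passed(self) -> bool:
        chis = [p for p in self.chisq_pvalues.values() if not math.isnan(p)]
        return bool(self.max_abs_z < self.z_threshold
                    and all(p > self.alpha for p in chis))


def _merged_histogram(a: np.ndarray, b: np.ndarray, min_expected: float = 5.0):
    """Common binning of two count samples with adjacent bins merged until
    every pooled expected count reaches ``min_expected`` in both rows."""
    lo = int(min(a.min(), b.min()))
    hi = int(max(a.max(), b.max()))
    edges = np.arange(lo, hi + 2)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    ma, mb = [], []
    ca = cb = 0
    na, nb = a.size, b.size
    for i in range(ha.size):
        ca += ha[i]
        cb += hb[i]
        pooled = (ca + cb) / (na + nb)
        if min(na, nb) * pooled >= min_expected:
            ma.append(ca)
            mb.append(cb)
            ca = cb = 0
    if ca + cb > 0:
        if ma:
            ma[-1] += ca
            mb[-1] += cb
        else:
            ma, mb = [ca], [cb]
    return np.array(ma), np.array(mb)


def compare_ensembles(ens_a: EnsembleResult, ens_b: EnsembleResult,
                      checkpoints=None, species: list[str] | None = None,
                      alpha: float = 0.01, z_threshold: float = 3.0) -> EnsembleComparison:
    """Statistical comparison of two trajectory ensembles on a common grid.

    Mean differences are scored with z = Δmean / sqrt(se_a² + se_b²) at every
    checkpoint; terminal-time count histograms are compared with a two-sample
    chi-square after merging bins to expected counts ≥ 5.
    """
    if ens_a.n_runs < 2 or ens_b.n_runs < 2:
        raise ValueError("need at least 2 runs per ensemble")
    if species is None:
        species = [s for s in ens_a.species if s in ens_b.species]
    if checkpoints is None:
        checkpoints = ens_a.grid
    checkpoints = np.asarray(checkpoints, dtype=float)
    gi_a = np.searchsorted(ens_a.grid, checkpoints)
    gi_b = np.searchsorted(ens_b.grid, checkpoints)
    if not (np.allclose(ens_a.grid[gi_a], checkpoints) and
            np.allclose(ens_b.grid[gi_b], checkpoints)):
        raise ValueError("checkpoints must lie on both ensemble grids")
    z = np.zeros((checkpoints.size, len(species)))
    chis: dict[str, float] = {}
    for si, sp in enumerate(species):
        ia, ib = ens_a.species.index(sp), ens_b.species.index(sp)
        xa = ens_a.counts[:, gi_a, ia]
        xb = ens_b.counts[:, gi_b, ib]
        ma, mb = xa.mean(axis=0), xb.mean(axis=0)
        sa = xa.std(axis=0, ddof=1) / math.sqrt(xa.shape[0])
        sb = xb.std(axis=0, ddof=1) / math.sqrt(xb.shape[0])
        denom = np.sqrt(sa**2 + sb**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = np.where(denom > 0, (ma - mb) / denom, np.where(ma == mb, 0.0, np.inf))
        z[:, si] = zz
        ha, hb = _merged_histogram(xa[:, -1], xb[:, -1])
        if ha.size < 2:
            chis[sp] = float("nan")  # degenerate (e.g. constant) terminal counts
        else:
            chis[sp] = float(stats.chi2_contingency(np.vstack([ha, hb]))[1])
    return EnsembleComparison(checkpoints=checkpoints, species=species,
                              z_scores=z, max_abs_z=float(np.max(np.abs(z))),
                              chisq_pvalues=chis, alpha=alpha, z_threshold=z_threshold)
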