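"""SSA/DSSA correctness: exact laws, queue discipline, kernel agreement."""

import numpy as np
import pytest
from scipy.linalg import expm

from delaylump import (ChainSpecParams, abridge, dssa_rejection,
                       example_bidirectional_chain, random_chain, sample_delay,
                       run_dssa_ensemble, run_ssa_ensemble, ssa_direct,
                       compare_ensembles)
from delaylump.network import Reaction, ReactionNetwork, Species
from delaylump.passage import StageConvolution, TabulatedDistribution
from delaylump.simulate import EnsembleResult, compile_network
from delaylump.validate import ks_compare

from conftest import retry_stochastic


def _decay_net():
    return ReactionNetwork([Species("A", 1), Species("B", 2)],
                           [Reaction([("A", 1)], [("B", 1)], 1.0)])


class TestSSA:
    def test_no_reactions_constant_state(self, rng):
        net = ReactionNetwork([Species("A", 1)], [])
        tr = ssa_direct(net, {"A": 7}, 5.0, rng)
        assert tr.times.tolist() == [0.0]
        assert tr.states[0].tolist() == [7]

    def test_pure_decay_mean(self):
        def check(seed):
            rng = np.random.default_rng(seed)
            prog = compile_network(_decay_net())
            vals = [ssa_direct(prog, {"A": 1000}, 1.0, rng).state_at(1.0)[0]
                    for _ in range(300)]
            expected = 1000 * np.exp(-1.0)
            sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - expected) < 3 * sem
        retry_stochastic(check)

    def test_single_firing_time_exponential(self):
        def check(seed):
            rng = np.random.default_rng(seed)
            net = ReactionNetwork([Species("S1", 1), Species("S2", 2)],
                                  [Reaction([("S1", 1)], [("S2", 1)], 2.5)])
            times = []
            for _ in range(4000):
                tr = ssa_direct(net, {"S1": 1}, 50.0, rng)
                times.append(tr.times[1])
            assert ks_compare(np.array(times), StageConvolution([2.5])).passed
        retry_stochastic(check)

    def test_ensemble_mean_matches_master_equation(self):
        """Monomolecular ensemble means follow the matrix-exponential
        solution of the mean equations."""
        net = random_chain(ChainSpecParams(n=4, seed=6))
        from delaylump import build_generator
        K = build_generator(net).matrix
        x0 = np.array([120.0, 0.0, 0.0, 0.0])
        grid = np.array([0.5, 1.0, 2.0, 4.0])

        def check(seed):
            ens = run_ssa_ensemble(net, {"S1": 120}, 4.0, grid, 400, seed)
            for gi, t in enumerate(grid):
                exact = expm(K * t) @ x0
                mean = ens.counts[:, gi, :].mean(axis=0)
                sem = ens.counts[:, gi, :].std(axis=0, ddof=1) / np.sqrt(ens.n_runs)
                z = (mean - exact) / np.maximum(sem, 1e-9)
                assert np.max(np.abs(z)) < 4.0
        retry_stochastic(check)


class TestDSSA:
    def test_degenerates_to_ssa_without_delays(self):
        net = random_chain(ChainSpecParams(n=2, forward=[1.2], backward=[0.7]))
        ab = abridge(net)
        grid = np.linspace(0.0, 5.0, 6)

        def check(seed):
            e1 = run_ssa_ensemble(net, {"S1": 80}, 5.0, grid, 400, seed)
            e2 = run_dssa_ensemble(net, ab, {"S1": 80}, 5.0, grid, 400, seed + 7)
            rep = compare_ensembles(e1, e2, checkpoints=grid[1:])
            assert rep.passed
        retry_stochastic(check)

    def test_delayed_products_lag_by_delay_mean(self, rng):
        """A single delayed conversion with a narrow delay: products appear
        about one delay-mean after the reactants are removed."""
        from delaylump.abridge import AbridgedModel, DelayedReaction
        narrow = StageConvolution([100.0] * 50)   # mean 0.5, sd ~0.07
        ab = AbridgedModel(
            species=[Species("A", 1), Species("B", 2)], sois=["A", "B"],
            delayed_reactions=[DelayedReaction([("A", 1)], [("B", 1)], 3.0, narrow,
                                               "first_arrival")],
            immediate_reactions=[])
        tr = dssa_rejection(ab, {"A": 400}, None, 6.0, rng)
        a_idx, b_idx = tr.species.index("A"), tr.species.index("B")
        half_a = tr.times[np.argmax(tr.states[:, a_idx] <= 200)]
        half_b = tr.times[np.argmax(tr.states[:, b_idx] >= 200)]
        assert half_b - half_a == pytest.approx(0.5, abs=0.1)

    def test_queue_discipline_no_negative_counts(self, rng):
        net = example_bidirectional_chain(s9_initial=40)
        ab = abridge(net)
        tr = dssa_rejection(ab, {"S9": 40}, None, 8.0, rng)
        assert np.min(tr.states) >= 0

    def test_kernel_matches_reference_dssa(self):
        net = example_bidirectional_chain(s9_initial=50)
        ab = abridge(net)
        grid = np.linspace(0.0, 10.0, 11)

        def check(seed):
            rng = np.random.default_rng(seed)
            ref = np.zeros((150, 11, len(ab.species_names)), dtype=np.int64)
            for i in range(150):
                tr = dssa_rejection(ab, {"S9": 50}, None, 10.0,
                                    np.random.default_rng(rng.integers(2**31)))
                ref[i] = tr.resample(grid)
            kern = run_dssa_ensemble(net, ab, {"S9": 50}, 10.0, grid, 300, seed + 1)
            rep = compare_ensembles(
                EnsembleResult(grid=grid, counts=ref, species=ab.species_names),
                kern, checkpoints=grid[1:])
            assert rep.passed
        retry_stochastic(check)


class TestSampleDelay:
    def test_stage_sample_mean(self):
        def check(seed):
            rng = np.random.default_rng(seed)
            d = StageConvolution([1.0, 3.0])
            x = d.sample(rng, size=100_000)
            sem = x.std(ddof=1) / np.sqrt(x.size)
            assert abs(x.mean() - 4.0 / 3.0) < 3 * sem
        retry_stochastic(check)

    def test_single_stage_is_exponential(self):
        def check(seed):
            rng = np.random.default_rng(seed)
            d = StageConvolution([2.0])
            x = np.array([sample_delay(d, rng) for _ in range(5000)])
            assert ks_compare(x, d).passed
        retry_stochastic(check)

    def test_tabulated_matches_stage_sampler(self):
        def check(seed):
            rng = np.random.default_rng(seed)
            d = StageConvolution([1.0, 3.0])
            grid = np.linspace(0.0, 40.0, 2000)
            tab = TabulatedDistribution(grid, np.asarray(d.cdf(grid)))
            xs = d.sample(rng, size=50_000)
            xt = tab.sample(rng, size=50_000)
            se = np.sqrt(xs.var(ddof=1) / xs.size + xt.var(ddof=1) / xt.size)
            assert abs(xs.mean() - xt.mean()) < 3 * se
        retry_stochastic(check)
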