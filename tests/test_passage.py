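"""Closed-form first-passage laws against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delaylump import (ChainSpecParams, arrival_return_probabilities,
                       eigvals_inner, first_arrival_distribution,
                       first_return_distribution, inner_rate_matrix,
                       minor_eval, numeric_first_passage_cdf, random_chain,
                       build_generator)
from delaylump.network import NetworkError
from delaylump.passage import (MinorEvaluator, ResidueForm, StageConvolution,
                               TabulatedDistribution, _Block)


def _sup_vs_oracle(net, kind, direction_or_end):
    """Sup-norm between a closed-form conditional CDF and the
    matrix-exponential tabulation on its auto grid."""
    block = _Block(net, net.sois)
    chain = block.report.chain_order
    if kind == "arrival":
        d = first_arrival_distribution(net, direction_or_end)
        start, target = ((chain[1], chain[-1]) if direction_or_end == "toward_sn"
                         else (chain[-2], chain[0]))
    else:
        d = first_return_distribution(net, direction_or_end)
        target = direction_or_end
        start = chain[1] if target == chain[0] else chain[-2]
    num = block.numeric_cdf(block.index[start], block.soi_channels[target])
    return float(np.max(np.abs(np.asarray(d.cdf(num.grid)) - num.cdf_values))), d


class TestEigvals:
    def test_symmetric_2x2(self):
        eigs, simple = eigvals_inner(np.array([[-2.0, 1.0], [1.0, -2.0]]))
        assert simple
        assert np.allclose(sorted(eigs.real), [-3.0, -1.0])

    def test_unidirectional_repeated(self):
        K = np.diag([-2.0] * 4) + np.diag([2.0] * 3, -1)
        eigs, simple = eigvals_inner(K)
        assert not simple
        assert np.allclose(eigs.real, -2.0)

    def test_nonnegative_real_part_rejected(self):
        with pytest.raises(NetworkError, match="dissipative"):
            eigvals_inner(np.array([[0.0]]))


class TestMinors:
    def test_empty_minor_is_one(self):
        assert minor_eval(MinorEvaluator(np.array([[-3.0]]), 0, 0), 1.7) == 1.0

    def test_2x2_corner(self):
        K = np.array([[-2.0, 1.0], [1.0, -2.0]])
        assert minor_eval(MinorEvaluator(K, 0, 0), 0.5) == pytest.approx(2.5)

    @pytest.mark.parametrize("corner", [(0, 0), (4, 4)])
    def test_recurrence_matches_dense_determinant(self, corner):
        net = random_chain(ChainSpecParams(n=7, seed=5))
        K = inner_rate_matrix(net)
        ev = MinorEvaluator(K, *corner)
        assert ev.use_recurrence
        dense = MinorEvaluator(K, *corner)
        dense.use_recurrence = False
        for s in (0.7, -1.3, 2.0 + 1.5j):
            a, b = ev.evaluate(s), dense.evaluate(s)
            assert abs(a - b) <= 1e-10 * max(abs(b), 1.0)


class TestProbabilities:
    def test_n3_competing_exponentials(self, chain3):
        p = arrival_return_probabilities(chain3)
        assert p.p_a_n == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert p.p_r_1 == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert p.p_deg_1 == pytest.approx(0.0, abs=1e-12)

    def test_n3_with_degradation(self):
        net = random_chain(ChainSpecParams(n=3, forward=[1.0, 1.0], backward=[1.0, 1.0],
                                           degradations=[(2, 2.0)]))
        p = arrival_return_probabilities(net)
        assert p.p_a_n == pytest.approx(0.25, abs=1e-12)
        assert p.p_r_1 == pytest.approx(0.25, abs=1e-12)
        assert p.p_deg_1 == pytest.approx(0.5, abs=1e-12)

    def test_gamblers_ruin_symmetric(self, chain4_symmetric):
        p = arrival_return_probabilities(chain4_symmetric)
        assert p.p_a_n == pytest.approx(1.0 / 3.0, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(3, 12), st.integers(0, 10_000), st.booleans())
    def test_conservation(self, n, seed, with_deg):
        degr = [(max(2, n // 2), 0.9)] if with_deg and n >= 3 else []
        net = random_chain(ChainSpecParams(n=n, seed=seed, degradations=degr))
        p = arrival_return_probabilities(net)
        assert p.p_r_1 + p.p_a_n + p.p_deg_1 == pytest.approx(1.0, abs=1e-10)
        assert p.p_r_n + p.p_a_1 + p.p_deg_n == pytest.approx(1.0, abs=1e-10)


class TestArrival:
    def test_n3_single_stage(self, chain3):
        d = first_arrival_distribution(chain3, "toward_sn")
        assert isinstance(d, StageConvolution)
        assert d.cdf(np.log(2.0) / 3.0) == pytest.approx(0.5, abs=1e-12)

    def test_n4_symmetric_stages(self, chain4_symmetric):
        d = first_arrival_distribution(chain4_symmetric, "toward_sn")
        assert sorted(d.stage_rates) == pytest.approx([1.0, 3.0])
        assert d.mean() == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_direction_independence_no_bypass(self):
        net = random_chain(ChainSpecParams(n=8, seed=17))
        dn = first_arrival_distribution(net, "toward_sn")
        d1 = first_arrival_distribution(net, "toward_s1")
        grid = np.linspace(0.0, 50.0, 600)
        assert np.max(np.abs(np.asarray(dn.cdf(grid)) - np.asarray(d1.cdf(grid)))) < 1e-10

    def test_forward_bypass_matches_oracle(self):
        net = random_chain(ChainSpecParams(n=5, seed=23, bypasses=[(2, 4, 0.8)]))
        sup, d = _sup_vs_oracle(net, "arrival", "toward_sn")
        assert isinstance(d, ResidueForm)
        assert sup < 1e-8


class TestReturn:
    def test_n3_return_equals_arrival(self, chain3):
        d = first_return_distribution(chain3, "S1")
        assert d.cdf(np.log(2.0) / 3.0) == pytest.approx(0.5, abs=1e-12)

    def test_return_distributions_differ_on_asymmetric_chain(self):
        net = random_chain(ChainSpecParams(
            n=6, forward=[3.0, 2.5, 2.0, 1.5, 1.0], backward=[0.4, 0.5, 0.6, 0.8, 1.0]))
        r1 = first_return_distribution(net, "S1")
        rn = first_return_distribution(net, "S6")
        an = first_arrival_distribution(net, "toward_sn")
        a1 = first_arrival_distribution(net, "toward_s1")
        grid = np.linspace(0.0, 30.0, 500)
        gap = np.max(np.abs(np.asarray(r1.cdf(grid)) - np.asarray(rn.cdf(grid))))
        assert gap > 0.01
        assert np.max(np.abs(np.asarray(an.cdf(grid)) - np.asarray(a1.cdf(grid)))) < 1e-10

    def test_return_matches_oracle_with_bypass(self):
        net = random_chain(ChainSpecParams(n=6, seed=31, bypasses=[(5, 2, 0.7)]))
        sup, _ = _sup_vs_oracle(net, "return", "S1")
        assert sup < 1e-8


class TestNumericOracle:
    def test_n3_absorbed_mass_closed_form(self, chain3):
        gen = build_generator(chain3, absorbing={"S1", "S3"})
        grid = np.linspace(0.0, 5.0, 40)
        g, cdfs, probs = numeric_first_passage_cdf(gen, "S2", ["S1", "S3"], grid=grid)
        assert probs["S3"] == pytest.approx(1.0 / 3.0, abs=1e-10)
        expected = 1.0 - np.exp(-3.0 * grid)  # conditional CDF
        assert np.allclose(cdfs["S3"], expected, atol=1e-9)

    def test_gamblers_ruin_limits(self, chain4_symmetric):
        gen = build_generator(chain4_symmetric, absorbing={"S1", "S4"})
        _, _, probs = numeric_first_passage_cdf(gen, "S2", ["S1", "S4"])
        assert probs["S1"] == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert probs["S4"] == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_non_absorbing_target_rejected(self, chain3):
        gen = build_generator(chain3, absorbing={"S1"})
        with pytest.raises(NetworkError, match="absorbing"):
            numeric_first_passage_cdf(gen, "S2", ["S3"])


class TestDistributionObjects:
    def test_stage_mean_and_quantiles(self):
        d = StageConvolution([1.0, 3.0])
        assert d.mean() == pytest.approx(4.0 / 3.0)
        assert StageConvolution([3.0]).quantile(0.5) == pytest.approx(np.log(2.0) / 3.0,
                                                                      abs=1e-10)
        assert d.quantile(0.0) == 0.0

    def test_quantile_of_one_rejected(self):
        with pytest.raises(ValueError):
            StageConvolution([1.0]).quantile(1.0)

    def test_quantile_cdf_roundtrip(self):
        net = random_chain(ChainSpecParams(n=5, seed=2))
        d = first_return_distribution(net, "S1")
        for u in (0.05, 0.3, 0.77, 0.99):
            assert d.cdf(d.quantile(u)) == pytest.approx(u, abs=1e-9)

    def test_repeated_stage_rates_phase_type_path(self):
        d = StageConvolution([2.0, 2.0, 2.0])
        from scipy.stats import erlang
        grid = np.linspace(0.0, 5.0, 50)
        assert np.allclose(d.cdf(grid), erlang.cdf(grid, 3, scale=0.5), atol=1e-9)
        assert d.mean() == pytest.approx(1.5)

    def test_residue_form_invariants_complex_pairs(self):
        net = random_chain(ChainSpecParams(n=7, seed=41, bypasses=[(2, 6, 1.5)]))
        d = first_return_distribution(net, "S1")
        assert isinstance(d, ResidueForm)
        if np.max(np.abs(d.eigenvalues.imag)) > 0:
            conj = np.sort_complex(np.conj(d.eigenvalues))
            assert np.allclose(np.sort_complex(d.eigenvalues), conj)
        grid = np.linspace(0.0, 40.0, 400)
        vals = np.asarray(d.cdf(grid))
        assert d.max_imag(grid) < 1e-9
        assert abs(vals[0]) < 1e-9
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[-1] == pytest.approx(1.0, abs=1e-9)

    def test_tabulated_monotone_and_sampling(self, rng):
        grid = np.linspace(0.0, 10.0, 200)
        d = TabulatedDistribution(grid, 1.0 - np.exp(-grid))
        assert d.cdf(0.0) == 0.0
        x = d.sample(rng, size=5000)
        assert np.mean(x) == pytest.approx(1.0, abs=5 * 1.0 / np.sqrt(5000))
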