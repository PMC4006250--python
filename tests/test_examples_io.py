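"""Worked systems, synthetic generation, file round-trips and the CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from delaylump import (ChainSpecParams, GlycolysisParams, ProofreadingParams,
                       classify_reactions, example_bidirectional_chain,
                       example_glycolysis, example_proofreading,
                       first_passage_analysis, random_chain)
from delaylump.cli import main
from delaylump.modelio import (read_abridged, read_model, write_distribution,
                               write_model, write_trajectory)
from delaylump.network import NetworkError
from delaylump.passage import StageConvolution


class TestRandomChain:
    def test_reaction_counts(self):
        net = random_chain(ChainSpecParams(n=10, seed=12,
                                           bypasses=[(2, 6, 0.5), (8, 4, 0.4)]))
        rep = classify_reactions(net)
        assert len(rep.chain_reactions) == 18
        assert len(rep.bypasses) == 2

    def test_n2_has_no_intermediates(self):
        net = random_chain(ChainSpecParams(n=2, seed=1))
        rep = classify_reactions(net)
        assert set(rep.chain_order) == set(net.sois)

    def test_seed_determinism(self, tmp_path):
        p = ChainSpecParams(n=6, seed=99, degradations=[(3, 0.4)])
        write_model(random_chain(p), tmp_path / "a.yaml")
        write_model(random_chain(p), tmp_path / "b.yaml")
        assert (tmp_path / "a.yaml").read_bytes() == (tmp_path / "b.yaml").read_bytes()


class TestGlycolysis:
    def test_structure_and_delay(self):
        net, ab = example_glycolysis()
        rep = classify_reactions(net)
        assert rep.chain_order == ["X1", "X2", "X3", "X4"]
        assert rep.uni_directional
        assert len(ab.delayed_reactions) == 1
        assert len(ab.immediate_reactions) == 1
        (d,) = ab.delayed_reactions
        assert isinstance(d.delay, StageConvolution)
        assert list(d.delay.stage_rates) == [2.0, 2.0, 2.0, 2.0]
        assert d.delay.mean() == pytest.approx(sum(1.0 / g for g in (2, 2, 2, 2)))
        assert d.propensity is not None and d.propensity[0] == "hill_repression"

    def test_atp_stoichiometry(self):
        p = GlycolysisParams()
        _, ab = example_glycolysis(p)
        (d,) = ab.delayed_reactions
        assert d.reactants == [("Y", p.q)]
        assert d.products == [("Y", 2 * p.q)]


class TestProofreading:
    def test_completion_probability_and_delay(self):
        p = ProofreadingParams()
        net, _ = example_proofreading(p)
        pf = first_passage_analysis(net, "C0", sois=["T", "M", "C6"])
        oc = pf.outcome_for("C6")
        assert oc.probability == pytest.approx((p.kp / (p.kp + p.k_minus1)) ** 6,
                                               abs=1e-10)
        assert isinstance(oc.distribution, StageConvolution)
        assert np.allclose(oc.distribution.stage_rates, p.kp + p.k_minus1)
        assert len(oc.distribution.stage_rates) == 6

    def test_abridged_scheme_shape(self):
        net, ab = example_proofreading()
        labels = sorted(r.label for r in ab.delayed_reactions)
        assert labels == ["first_arrival", "loss"]
        loss = next(r for r in ab.delayed_reactions if r.label == "loss")
        assert sorted(loss.products) == [("M", 1), ("T", 1)]
        imm = sorted(r.label() for r in ab.immediate_reactions)
        assert imm == ["C0 -> T + M", "T + M -> C0"]

    def test_rate_split_conserves_outgoing_rate(self):
        p = ProofreadingParams()
        _, ab = example_proofreading(p)
        total = sum(r.rate_constant for r in ab.delayed_reactions)
        assert total == pytest.approx(p.kp, rel=1e-12)


class TestModelIO:
    def test_round_trip_proofreading(self, tmp_path):
        net, _ = example_proofreading()
        path = tmp_path / "m.yaml"
        write_model(net, path)
        back = read_model(path)
        assert back.species_names == net.species_names
        assert back.sois == net.sois
        assert len(back.reactions) == len(net.reactions)
        for a, b in zip(back.reactions, net.reactions):
            assert (a.reactants, a.products, a.rate_constant) == \
                   (b.reactants, b.products, b.rate_constant)

    def test_missing_rate_is_load_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("species: [A, B]\nreactions:\n  - reactants: {A: 1}\n"
                        "    products: {B: 1}\n")
        with pytest.raises(NetworkError, match="rate"):
            read_model(path)

    def test_trajectory_tsv_rows(self, tmp_path, rng):
        from delaylump import ssa_direct
        from delaylump.network import Reaction, ReactionNetwork, Species
        net = ReactionNetwork([Species("A", 1), Species("B", 2)],
                              [Reaction([("A", 1)], [("B", 1)], 5.0)])
        tr = ssa_direct(net, {"A": 3}, 100.0, rng)
        path = tmp_path / "t.tsv"
        write_trajectory(tr, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "time\tA\tB"
        assert len(lines) == 1 + 1 + 3  # header + initial + 3 events

    def test_abridged_round_trip_preserves_delays(self, tmp_path):
        net = example_bidirectional_chain()
        from delaylump import abridge
        ab = abridge(net)
        path = tmp_path / "ab.yaml"
        write_model(ab, path)
        back = read_abridged(path)
        assert len(back.delayed_reactions) == len(ab.delayed_reactions)
        g = np.linspace(0.0, 20.0, 100)
        for a, b in zip(back.delayed_reactions, ab.delayed_reactions):
            assert a.rate_constant == pytest.approx(b.rate_constant)
            assert np.allclose(np.asarray(a.delay.cdf(g)), np.asarray(b.delay.cdf(g)),
                               atol=1e-9)

    def test_distribution_export_matches_closed_form(self, tmp_path):
        d = StageConvolution([3.0])
        path = tmp_path / "d.tsv"
        write_distribution(d, path, name="first_arrival_to_S3")
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "# distribution: first_arrival_to_S3"
        data = np.loadtxt(lines[2:])
        assert np.allclose(data[:, 1], 1.0 - np.exp(-3.0 * data[:, 0]), atol=1e-9)


class TestCLI:
    def test_validate_reports_structure(self, tmp_path):
        write_model(example_bidirectional_chain(), tmp_path / "m.yaml")
        res = CliRunner().invoke(main, ["validate", str(tmp_path / "m.yaml")])
        assert res.exit_code == 0
        assert "bypasses: 2" in res.output

    def test_abridge_then_read(self, tmp_path):
        write_model(example_bidirectional_chain(), tmp_path / "m.yaml")
        res = CliRunner().invoke(main, ["abridge", str(tmp_path / "m.yaml"),
                                        str(tmp_path / "ab.yaml")])
        assert res.exit_code == 0
        assert len(read_abridged(tmp_path / "ab.yaml").delayed_reactions) == 4

    def test_dist_exports_expected_cdf(self, tmp_path, chain3):
        write_model(chain3, tmp_path / "m.yaml")
        res = CliRunner().invoke(
            main, ["dist", str(tmp_path / "m.yaml"),
                   "--out-prefix", str(tmp_path / "d")])
        assert res.exit_code == 0
        data = np.loadtxt(tmp_path / "d_first_arrival_to_S3.tsv", skiprows=2)
        assert np.allclose(data[:, 1], 1.0 - np.exp(-3.0 * data[:, 0]), atol=1e-9)

    def test_unknown_subcommand_errors(self):
        res = CliRunner().invoke(main, ["frobnicate"])
        assert res.exit_code != 0

    def test_demo_chain_smoke(self, tmp_path, monkeypatch):
        monkeypatch.chdir(tmp_path)
        res = CliRunner().invoke(main, ["demo", "chain", "--runs", "60", "--seed", "1"])
        assert res.exit_code in (0, 1)  # statistical verdict, but must complete
        assert (tmp_path / "chain_full.yaml").exists()
        assert (tmp_path / "chain_ssa.tsv").exists()
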