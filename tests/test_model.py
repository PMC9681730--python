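"""Architecture contracts: branch widths, weight sharing, permutation
invariance, ablations, whole-PROTAC variants."""

import numpy as np
import pytest

from protacdeg import nn
from protacdeg.chem_io import read_small_molecule
from protacdeg.featurize import TokenSequence, to_graph, tokenize
from protacdeg.model import (
    ALL_BRANCHES,
    ModelConfig,
    ablated_config,
    forward,
    forward_logits,
    gcn_branch,
    init_model,
    linker_branch,
    variant_config,
    variant_forward,
)


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig()


@pytest.fixture(scope="module")
def params(cfg):
    return init_model(cfg, seed=3)


@pytest.fixture(scope="module")
def graphs(tiny_samples):
    return tiny_samples[0].inputs


def _ligand_graph(smiles="CC(=O)Nc1ccccc1"):
    return to_graph(read_small_molecule(smiles), "ligand")


class TestInit:
    def test_same_seed_identical_checksum(self, cfg):
        assert init_model(cfg, 5).checksum() == init_model(cfg, 5).checksum()

    def test_different_seed_differs(self, cfg):
        assert init_model(cfg, 5).checksum() != init_model(cfg, 6).checksum()

    def test_pocket_branches_share_parameters(self, params):
        assert params.branch_group("poi_pocket") is params.branch_group("e3_pocket")

    def test_ligand_branches_share_parameters(self, params):
        assert params.branch_group("warhead") is params.branch_group("e3_ligand")

    def test_pocket_and_ligand_vocabularies_are_separate(self, params):
        assert params.branch_group("poi_pocket") is not params.branch_group("warhead")
        assert params.branch_group("poi_pocket")["embed"].data.shape[0] == 5
        assert params.branch_group("warhead")["embed"].data.shape[0] == 10


class TestGcnBranch:
    def test_output_dimension_64(self, params, cfg):
        out = gcn_branch(_ligand_graph(), params, cfg)
        assert out.data.shape == (64,)

    def test_single_node_graph_pooling_identity(self, params, cfg):
        from protacdeg.featurize import MolecularGraph

        g = MolecularGraph(kind="ligand", node_codes=[0], edges=[])
        out = gcn_branch(g, params, cfg)
        assert out.data.shape == (64,)
        assert np.all(np.isfinite(out.data))

    def test_out_of_range_node_code_rejected(self, params, cfg):
        from protacdeg.featurize import MolecularGraph

        g = MolecularGraph(kind="protein_pocket", node_codes=[7], edges=[])
        with pytest.raises(ValueError, match="out of range"):
            gcn_branch(g, params.groups["pocket_gcn"], cfg)

    @pytest.mark.parametrize("trial", range(10))
    def test_permutation_invariance(self, params, cfg, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 12))
        codes = rng.integers(0, 10, size=n).tolist()
        edges = []
        for i in range(n - 1):  # a random tree plus extras
            j = int(rng.integers(0, i + 1)) if i else 0
            t = int(rng.integers(1, 6))
            edges += [(i + 1, j, t), (j, i + 1, t)]
        from protacdeg.featurize import MolecularGraph

        g = MolecularGraph(kind="ligand", node_codes=codes, edges=edges)
        base = gcn_branch(g, params, cfg).data

        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g2 = MolecularGraph(
            kind="ligand",
            node_codes=[codes[inv[k]] for k in range(n)],
            edges=[(int(perm[i]), int(perm[j]), t) for i, j, t in edges],
        )
        np.testing.assert_allclose(gcn_branch(g2, params, cfg).data, base, atol=1e-10)

    def test_edge_list_order_irrelevant(self, params, cfg):
        g = _ligand_graph()
        from protacdeg.featurize import MolecularGraph

        g2 = MolecularGraph(g.kind, g.node_codes, list(reversed(g.edges)))
        np.testing.assert_allclose(
            gcn_branch(g2, params, cfg).data,
            gcn_branch(g, params, cfg).data,
            atol=1e-12,
        )

    def test_bond_encoding_changes_output(self, cfg):
        """With bond encoding on, relabeling an edge type changes the
        embedding; with it off, it cannot."""
        from dataclasses import replace
        from protacdeg.featurize import MolecularGraph

        g1 = MolecularGraph("ligand", [0, 0], [(0, 1, 1), (1, 0, 1)])
        g2 = MolecularGraph("ligand", [0, 0], [(0, 1, 3), (1, 0, 3)])
        p_on = init_model(cfg, 1)
        assert not np.allclose(
            gcn_branch(g1, p_on, cfg).data, gcn_branch(g2, p_on, cfg).data
        )
        cfg_off = replace(cfg, use_bond_encoding=False)
        p_off = init_model(cfg_off, 1)
        np.testing.assert_allclose(
            gcn_branch(g1, p_off, cfg_off).data, gcn_branch(g2, p_off, cfg_off).data
        )


class TestLinkerBranch:
    def test_output_dimension(self, params, cfg, encoding_table):
        seq = tokenize("CCOCCO", encoding_table, max_len=20)
        out = linker_branch(seq, params, cfg)
        assert out.data.shape == (1, 64)

    def test_all_pad_sequence_is_well_defined(self, params, cfg):
        seq = TokenSequence(codes=[0] * 10, true_length=0)
        out = linker_branch(seq, params, cfg)
        assert np.all(np.isfinite(out.data))

    def test_deterministic(self, params, cfg, encoding_table):
        seq = tokenize("CCCC", encoding_table, max_len=20)
        a = linker_branch(seq, params, cfg).data
        b = linker_branch(seq, params, cfg).data
        np.testing.assert_array_equal(a, b)

    def test_padding_does_not_change_output(self, params, cfg, encoding_table):
        a = linker_branch(tokenize("CCC", encoding_table, 10), params, cfg).data
        b = linker_branch(tokenize("CCC", encoding_table, 50), params, cfg).data
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestForward:
    def test_full_model_logits_and_probability(self, graphs, cfg, params):
        out = forward(params=params, config=cfg, **graphs)
        assert len(out.logits) == 2
        assert 0.0 <= out.prob_active <= 1.0
        assert out.label in ("active", "inactive")

    def test_probabilities_sum_to_one(self, graphs, cfg, params):
        out = forward(params=params, config=cfg, **graphs)
        probs = np.exp(out.logits) / np.exp(out.logits).sum()
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert out.prob_active == pytest.approx(probs[1], abs=1e-9)

    def test_concat_width_all_branches(self, cfg):
        assert cfg.concat_dim == 5 * 64 == 320

    def test_missing_branch_input_rejected(self, graphs, cfg, params):
        inputs = dict(graphs)
        inputs["linker"] = None
        with pytest.raises(ValueError, match="linker"):
            forward_logits(inputs, params, cfg)

    def test_single_branch_graceful_degradation(self, graphs):
        from dataclasses import replace

        for branch in ALL_BRANCHES:
            cfg1 = replace(ModelConfig(), active_branches=(branch,))
            p1 = init_model(cfg1, 0)
            logits = forward_logits(graphs, p1, cfg1)
            assert logits.data.shape == (1, 2)
            assert np.all(np.isfinite(logits.data))


class TestAblation:
    def test_item_1_keeps_all_branches(self):
        assert ablated_config(ModelConfig(), 1).active_branches == ALL_BRANCHES

    def test_item_6_removes_linker(self):
        cfg = ablated_config(ModelConfig(), 6)
        assert "linker" not in cfg.active_branches
        assert len(cfg.active_branches) == 4
        assert cfg.concat_dim == 256

    def test_item_7_keeps_poi_side_plus_linker(self):
        cfg = ablated_config(ModelConfig(), 7)
        assert set(cfg.active_branches) == {"poi_pocket", "warhead", "linker"}

    def test_item_8_keeps_e3_side_plus_linker(self):
        cfg = ablated_config(ModelConfig(), 8)
        assert set(cfg.active_branches) == {"e3_pocket", "e3_ligand", "linker"}

    @pytest.mark.parametrize("item,n_branches",
                             [(1, 5), (2, 4), (3, 4), (4, 4), (5, 4), (6, 4),
                              (7, 3), (8, 3)])
    def test_branch_counts(self, item, n_branches):
        assert len(ablated_config(ModelConfig(), item).active_branches) == n_branches

    def test_invalid_item_rejected(self):
        with pytest.raises(ValueError):
            ablated_config(ModelConfig(), 9)


class TestVariants:
    def test_whole_graph_concat_width(self):
        cfg = variant_config("whole_graph")
        assert cfg.concat_dim == 3 * 64 == 192

    def test_whole_smiles_head_contract(self, graphs, encoding_table):
        cfg = variant_config("whole_smiles")
        p = init_model(cfg, 0)
        protac_tokens = tokenize("c1ccccc1CCCCC1CCNCC1", encoding_table, 60)
        out = variant_forward(
            "whole_smiles", graphs["poi_pocket"], graphs["e3_pocket"],
            protac_tokens, params=p,
        )
        assert len(out.logits) == 2

    def test_whole_graph_forward(self, graphs):
        cfg = variant_config("whole_graph")
        p = init_model(cfg, 0)
        out = variant_forward(
            "whole_graph", graphs["poi_pocket"], graphs["e3_pocket"],
            _ligand_graph("c1ccccc1CCCC1CCNCC1"), params=p,
        )
        assert 0.0 <= out.prob_active <= 1.0

    def test_pocket_sharing_holds_in_variants(self):
        p = init_model(variant_config("whole_graph"), 0)
        assert p.branch_group("poi_pocket") is p.branch_group("e3_pocket")

    def test_mismatched_variant_params_rejected(self, graphs):
        p = init_model(variant_config("whole_graph"), 0)
        with pytest.raises(ValueError, match="protac_smiles"):
            variant_forward(
                "whole_smiles", graphs["poi_pocket"], graphs["e3_pocket"],
                TokenSequence([0] * 5, 0), params=p,
            )


class TestCheckpoint:
    def test_save_load_roundtrip(self, params, tmp_path, graphs, cfg):
        path = tmp_path / "ckpt.npz"
        params.save(path, metadata={"note": "test"})
        loaded = params.load(path)
        assert loaded.checksum() == params.checksum()
        a = forward(params=params, config=cfg, **graphs)
        b = forward(params=loaded, config=loaded.config, **graphs)
        assert a.logits == b.logits

    def test_sidecar_metadata(self, params, tmp_path):
        path = tmp_path / "ckpt.npz"
        params.save(path)
        import json

        sidecar = json.loads((tmp_path / "ckpt.npz.json").read_text())
        assert sidecar["seed"] == params.seed
        assert sidecar["checksum"] == params.checksum()
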