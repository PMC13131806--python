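"""Masked layers, assembly, gradients, and baseline architectures."""

import numpy as np
import pytest

from binnet.knowledge import (
    GeneMembership,
    Mask,
    MaskStack,
    PathwayHierarchy,
    build_layer_masks,
    count_connections,
)
from binnet.network import (
    ConfigError,
    DimensionError,
    ModelConfig,
    SparseNet,
    assemble_pnet,
    make_geneset_first_layer,
    make_random_sparse,
    masked_affine,
)


def _flat_hierarchy(n_pathways=1):
    names = [f"P{i}" for i in range(n_pathways)]
    return PathwayHierarchy(
        nodes=frozenset(names),
        edges=frozenset(),
        roots=frozenset(names),
        layer_of={n: 1 for n in names},
    )


def _stack_for(genes, pathway_of):
    gm = GeneMembership(
        genes=tuple(genes),
        member_of={g: frozenset({p}) for g, p in pathway_of.items()},
    )
    return build_layer_masks(
        _flat_hierarchy(len(set(pathway_of.values()))), gm, n_layers=1
    )


class TestMaskedAffine:
    def test_all_zero_mask_broadcasts_bias(self):
        x = np.ones((3, 2))
        out = masked_affine(x, np.ones((2, 2)), np.array([5.0, -1.0]),
                            np.zeros((2, 2)))
        assert np.allclose(out, [[5.0, -1.0]] * 3)

    def test_identity(self):
        x = np.arange(6.0).reshape(3, 2)
        out = masked_affine(x, np.eye(2), np.zeros(2), np.eye(2))
        assert np.allclose(out, x)

    def test_hand_2x2(self):
        x = np.array([[1.0, 2.0]])
        mask = np.array([[1, 0], [1, 1]])
        w = np.array([[3.0, 5.0], [7.0, 11.0]])
        out = masked_affine(x, w, np.zeros(2), mask)
        assert np.allclose(out, [[17.0, 22.0]])

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            masked_affine(np.ones((1, 3)), np.ones((2, 2)), np.zeros(2),
                          np.ones((2, 2)))


class TestAssembly:
    def test_gil_block_structure(self):
        stack = _stack_for(["a", "b", "c"], {"a": "P0", "b": "P0", "c": "P0"})
        net = assemble_pnet(stack, ModelConfig(n_layers=1, dropout_rate=0.0),
                            modalities=("m0", "m1"))
        gil = net.gil.mask
        assert gil.nnz == 6  # 2 modalities x 3 genes
        for i, row in enumerate(gil.row_index):
            g = row.split(":")[1]
            j = gil.col_index.index(g)
            assert gil.data[i, j] == 1 and gil.data[i].sum() == 1

    def test_head_count_without_regulatory(self):
        stack = _stack_for(["a", "b"], {"a": "P0", "b": "P0"})
        net = assemble_pnet(stack, ModelConfig(n_layers=1, dropout_rate=0.0))
        assert net.head_names == ("gene_input", "pathway_1")

    def test_regulatory_without_mask_is_config_error(self):
        stack = _stack_for(["a"], {"a": "P0"})
        with pytest.raises(ConfigError):
            assemble_pnet(stack, ModelConfig(use_regulatory=True, n_layers=1))

    def test_empty_regulon_equals_no_regulatory_model(self, diamond_hierarchy,
                                                      diamond_membership):
        from binnet.knowledge import RegulatoryNetwork

        empty = RegulatoryNetwork(tfs=frozenset(), edges=frozenset())
        with_reg = build_layer_masks(
            diamond_hierarchy, diamond_membership, regulon=empty, n_layers=2
        )
        without = build_layer_masks(diamond_hierarchy, diamond_membership,
                                    n_layers=2)
        cfg = dict(n_layers=2, dropout_rate=0.0, seed=5)
        net_r = assemble_pnet(with_reg, ModelConfig(use_regulatory=True, **cfg),
                              modalities=("m0",))
        net_p = assemble_pnet(without, ModelConfig(**cfg), modalities=("m0",))
        # copy the plain model's parameters into the regulatory variant
        state = net_r.get_state()
        for k, v in net_p.get_state().items():
            if not k.startswith(("regulatory", "head.regulatory")):
                state[k] = v
        state["alphas"] = np.array([0.0, -1e9, 0.0, 0.0])  # silence the dead head
        net_r.set_state(state)
        x = np.random.default_rng(0).standard_normal((4, len(net_p.genes)))
        pred_r = net_r.predict(x)
        pred_p = net_p.predict(x)
        names = ["gene_input", "pathway_1", "pathway_2"]
        idx_r = [net_r.head_names.index(n) for n in names]
        idx_p = [net_p.head_names.index(n) for n in names]
        assert np.allclose(pred_r.per_layer_logits[:, idx_r],
                           pred_p.per_layer_logits[:, idx_p])
        # regulatory output is the zero vector, so its head emits only bias 0
        i_reg = net_r.head_names.index("regulatory")
        assert np.allclose(pred_r.per_layer_logits[:, i_reg], 0.0)


class TestForward:
    def test_identical_head_logits_give_same_combined(self, small_net):
        x = np.zeros((2, 2 * len(small_net.genes)))
        # force every head to emit the same constant c
        state = small_net.get_state()
        for name in small_net.head_names:
            state[f"head.{name}.w"] = np.zeros_like(state[f"head.{name}.w"])
            state[f"head.{name}.b"] = np.array([1.7])
        small_net.set_state(state)
        pred = small_net.predict(x)
        assert np.allclose(pred.combined_logit, 1.7)
        assert np.allclose(pred.head_weights.sum(), 1.0)

    def test_hand_forward_linear(self):
        """2 genes feeding one pathway, unit weights, zero biases."""
        stack = _stack_for(["a", "b"], {"a": "P0", "b": "P0"})
        net = assemble_pnet(
            stack,
            ModelConfig(n_layers=1, activation="linear", dropout_rate=0.0),
            modalities=("m0",),
        )
        state = net.get_state()
        state["gene_input.W"] = np.eye(2)
        state["pathway_1.W"] = np.ones((2, 1))
        state["gene_input.b"] = np.zeros(2)
        state["pathway_1.b"] = np.zeros(1)
        state["head.gene_input.w"] = np.array([1.0, 2.0])
        state["head.gene_input.b"] = np.array([0.0])
        state["head.pathway_1.w"] = np.array([3.0])
        state["head.pathway_1.b"] = np.array([0.0])
        state["alphas"] = np.zeros(2)
        net.set_state(state)
        pred = net.predict(np.array([[1.0, -1.0]]))
        # genes h=[1,-1]; pathway = 0; heads: 1*1+2*(-1) = -1 and 3*0 = 0
        assert np.allclose(pred.per_layer_logits, [[-1.0, 0.0]])
        assert np.allclose(pred.combined_logit, [-0.5])  # uniform weights

    def test_wrong_width_raises(self, small_net):
        with pytest.raises(DimensionError):
            small_net.predict(np.zeros((1, 5)))


class TestGradients:
    def test_matches_finite_differences(self, small_net):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 2 * len(small_net.genes)))
        y = rng.integers(0, 2, 5)
        _, grads = small_net.loss_and_grads(x, y, training=False)
        params = small_net.param_dict()
        eps = 1e-6
        for key in ["gene_input.W", "regulatory.W", "pathway_1.W",
                    "pathway_2.b", "head.pathway_1.w", "alphas"]:
            p = params[key]
            flat = np.random.default_rng(2).choice(p.size, min(p.size, 6),
                                                   replace=False)
            for f in flat:
                idx = np.unravel_index(f, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = small_net.loss_and_grads(x, y, training=False)
                p[idx] = orig - eps
                lm, _ = small_net.loss_and_grads(x, y, training=False)
                p[idx] = orig
                assert np.isclose((lp - lm) / (2 * eps), grads[key][idx],
                                  rtol=1e-4, atol=1e-7), key

    def test_zero_mask_positions_have_zero_gradient(self, small_net):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 2 * len(small_net.genes)))
        y = rng.integers(0, 2, 5)
        _, grads = small_net.loss_and_grads(x, y, training=False)
        for lname, lay in small_net._layers().items():
            g = grads[f"{lname}.W"]
            assert np.all(g[~lay.pattern] == 0)
            assert np.all(g[lay.frozen] == 0)

    def test_signed_softplus_preserves_curated_signs(self, small_net):
        w_eff = small_net.reg.effective_weight()
        signs = np.sign(small_net.reg.mask.data)
        nz = signs != 0
        assert np.all(np.sign(w_eff[nz]) == signs[nz])


class TestDenseLimit:
    def test_all_ones_masks_match_plain_mlp(self):
        genes = ["a", "b", "c"]
        stack = MaskStack([
            Mask("pathway_1", np.ones((3, 4), dtype=np.int8),
                 tuple(genes), tuple("wxyz")),
            Mask("pathway_2", np.ones((4, 2), dtype=np.int8),
                 tuple("wxyz"), ("u", "v")),
        ])
        net = assemble_pnet(
            stack, ModelConfig(n_layers=2, activation="tanh", dropout_rate=0.0,
                               seed=9),
            modalities=("m0",),
        )
        x = np.random.default_rng(4).standard_normal((6, 3))
        pred = net.predict(x)
        # plain dense forward with the same parameters
        h = np.tanh(x @ net.gil.effective_weight() + net.gil.b)
        logits = [h @ net.heads["gene_input"].w + net.heads["gene_input"].b[0]]
        for lay in net.pathway_layers:
            h = np.tanh(h @ lay.W + lay.b)
            head = net.heads[lay.mask.name]
            logits.append(h @ head.w + head.b[0])
        dense = np.column_stack(logits)
        assert np.allclose(pred.per_layer_logits, dense)
        assert np.allclose(pred.combined_logit, dense @ net.head_weights())


class TestRandomSparse:
    def test_counts_preserved_across_seeds(self, diamond_stack):
        for seed in range(10):
            rnd = make_random_sparse(diamond_stack, seed=seed)
            assert count_connections(rnd) == count_connections(diamond_stack)

    def test_full_mask_unchanged(self):
        m = Mask("pathway_1", np.ones((3, 2), dtype=np.int8),
                 ("a", "b", "c"), ("p", "q"))
        rnd = make_random_sparse(MaskStack([m]), seed=0)
        assert np.array_equal(rnd.by_name("pathway_1").data, m.data)

    def test_seed_reproducible_and_seeds_differ(self):
        rng = np.random.default_rng(0)
        data = (rng.random((10, 10)) < 0.2).astype(np.int8)
        data.flat[:1] = 1  # ensure nonempty
        m = Mask("pathway_1", data,
                 tuple(f"r{i}" for i in range(10)),
                 tuple(f"c{i}" for i in range(10)))
        a = make_random_sparse(MaskStack([m]), seed=5)
        b = make_random_sparse(MaskStack([m]), seed=5)
        c = make_random_sparse(MaskStack([m]), seed=6)
        assert np.array_equal(a.by_name("pathway_1").data,
                              b.by_name("pathway_1").data)
        assert not np.array_equal(a.by_name("pathway_1").data,
                                  c.by_name("pathway_1").data)


class TestGenesetFirstLayer:
    def test_membership_first_mask(self, diamond_stack):
        gm = GeneMembership(
            genes=("g1", "g2"),
            member_of={"g1": frozenset({"S1"}), "g2": frozenset({"S1"})},
        )
        stack = make_geneset_first_layer(gm, diamond_stack, seed=0)
        first = stack.by_name("pathway_1")
        assert first.shape == (2, 1) and first.nnz == 2

    def test_every_gene_every_set_gives_all_ones(self, diamond_stack):
        gm = GeneMembership(
            genes=("g1", "g2"),
            member_of={"g1": frozenset({"S1", "S2"}),
                       "g2": frozenset({"S1", "S2"})},
        )
        stack = make_geneset_first_layer(gm, diamond_stack, seed=0)
        assert (stack.by_name("pathway_1").data == 1).all()

    def test_subsequent_counts_match_reference(self, diamond_stack):
        gm = GeneMembership(
            genes=("g1", "g2", "g3"),
            member_of={g: frozenset({"S1", "S2"}) for g in ("g1", "g2", "g3")},
        )
        stack = make_geneset_first_layer(gm, diamond_stack, seed=0)
        ref_counts = count_connections(diamond_stack)
        got = count_connections(stack)
        assert got["pathway_2"] == min(ref_counts["pathway_2"], 2 * 2)


class TestCheckpoint:
    def test_save_load_reproduces_forward(self, small_net, tmp_path):
        x = np.random.default_rng(0).standard_normal((3, 2 * len(small_net.genes)))
        before = small_net.predict(x)
        small_net.save(tmp_path / "ckpt")
        loaded = SparseNet.load(tmp_path / "ckpt")
        after = loaded.predict(x)
        assert np.array_equal(before.combined_logit, after.combined_logit)
        assert np.array_equal(before.per_layer_logits, after.per_layer_logits)
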