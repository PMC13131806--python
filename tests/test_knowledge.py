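"""Parsers, layer assignment and mask construction."""

import numpy as np
import pytest

from binnet.knowledge import (
    GeneMembership,
    GraphError,
    KnowledgeError,
    ParseError,
    RegulatoryNetwork,
    build_layer_masks,
    count_connections,
    licensed_pairs,
    load_mask_stack,
    parse_gene_sets,
    parse_pathway_relations,
    parse_regulatory_edges,
    save_mask_stack,
)

from util import oracle_licensed_pairs, random_hierarchy, random_membership


class TestParseRelations:
    def test_layers_by_longest_path_to_leaf(self, diamond_relations):
        h = parse_pathway_relations(diamond_relations)
        assert set(h.nodes) == {"R", "A", "B", "C"}
        assert set(h.roots) == {"R"}
        assert dict(h.layer_of) == {"C": 1, "B": 1, "A": 2, "R": 3}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        h = parse_pathway_relations(p)
        assert not h.nodes and not h.roots

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "cyc.tsv"
        p.write_text("A\tB\nB\tA\n")
        with pytest.raises(GraphError, match="cycle"):
            parse_pathway_relations(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("R\tA\nonly_one_field\n")
        with pytest.raises(ParseError, match=":2"):
            parse_pathway_relations(p)

    def test_every_edge_goes_strictly_up(self, diamond_relations):
        h = parse_pathway_relations(diamond_relations)
        for parent, child in h.edges:
            assert h.layer_of[parent] >= h.layer_of[child] + 1


class TestParseGeneSets:
    def test_membership_and_first_appearance_order(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tg1\tg2\nS2\td\tg2\tg3\n")
        gm = parse_gene_sets(p)
        assert gm.genes == ("g1", "g2", "g3")
        assert gm.member_of["g2"] == {"S1", "S2"}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("")
        gm = parse_gene_sets(p)
        assert gm.genes == ()

    def test_duplicate_gene_in_set_deduplicated(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S1\td\tg1\tg1\tg2\n")
        gm = parse_gene_sets(p)
        assert gm.genes == ("g1", "g2")
        assert gm.member_of["g1"] == {"S1"}

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "short.gmt"
        p.write_text("S1\tdescription_only\n")
        with pytest.raises(ParseError):
            parse_gene_sets(p)


class TestParseRegulon:
    def test_sign_collapse(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("source\ttarget\tweight\nt1\tg1\t0.8\nt1\tg2\t-0.3\n")
        net = parse_regulatory_edges(p)
        assert net.tfs == {"t1"}
        assert net.edges == {("t1", "g1", 1), ("t1", "g2", -1)}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("")
        net = parse_regulatory_edges(p)
        assert not net.tfs and not net.edges

    def test_conflicting_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("source\ttarget\tweight\nt1\tg1\t0.8\nt1\tg1\t-0.8\n")
        with pytest.raises(KnowledgeError, match="t1"):
            parse_regulatory_edges(p)

    def test_zero_sign_rejected(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("source\ttarget\tweight\nt1\tg1\t0\n")
        with pytest.raises(KnowledgeError, match="zero"):
            parse_regulatory_edges(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "reg.tsv"
        p.write_text("a\tb\tc\nt1\tg1\t1\n")
        with pytest.raises(ParseError):
            parse_regulatory_edges(p)


class TestBuildMasks:
    def test_diamond_example(self, diamond_hierarchy, diamond_membership):
        stack = build_layer_masks(diamond_hierarchy, diamond_membership, n_layers=2)
        assert stack.names == ["pathway_1", "pathway_2"]
        assert licensed_pairs(stack.by_name("pathway_1")) == {
            ("g1", "C"), ("g2", "C"), ("g3", "B"),
        }
        # C feeds its parent A; B (parent above the cut) is carried by a copy
        assert licensed_pairs(stack.by_name("pathway_2")) == {
            ("C", "A"), ("B", "B::copy@2"),
        }
        copy_mask = stack.by_name("pathway_2")
        j = copy_mask.col_index.index("B::copy@2")
        assert copy_mask.linear_cols_bool()[j]
        assert copy_mask.frozen_bool().sum() == 1

    def test_single_pathway_all_genes(self):
        h = _single_pathway_hierarchy()
        gm = GeneMembership(
            genes=("g1", "g2"),
            member_of={"g1": frozenset({"P"}), "g2": frozenset({"P"})},
        )
        stack = build_layer_masks(h, gm, n_layers=1)
        m = stack.by_name("pathway_1")
        assert m.shape == (2, 1)
        assert (m.data == 1).all()

    def test_regulatory_mask_nonzeros(self, diamond_hierarchy):
        gm = GeneMembership(
            genes=("g1", "g2", "t1"),
            member_of={g: frozenset({"C"}) for g in ("g1", "g2", "t1")},
        )
        reg = RegulatoryNetwork(
            tfs=frozenset({"t1"}),
            edges=frozenset({("t1", "g1", 1), ("t1", "g2", -1)}),
        )
        stack = build_layer_masks(diamond_hierarchy, gm, regulon=reg, n_layers=2)
        rm = stack.by_name("regulatory")
        nz = {
            (rm.row_index[i], rm.col_index[j], int(rm.data[i, j]))
            for i, j in zip(*np.nonzero(rm.data))
        }
        assert nz == {("g1", "t1", 1), ("g2", "t1", -1), ("t1", "t1", 1)}

    def test_gene_without_membership_dropped_or_error(self, diamond_hierarchy):
        gm = GeneMembership(
            genes=("g1", "orphan"),
            member_of={"g1": frozenset({"C"}), "orphan": frozenset()},
        )
        stack = build_layer_masks(diamond_hierarchy, gm, n_layers=2)
        assert stack.by_name("pathway_1").row_index == ("g1",)
        with pytest.raises(KnowledgeError, match="orphan"):
            build_layer_masks(
                diamond_hierarchy, gm, n_layers=2, on_unmapped_gene="error"
            )

    def test_deep_membership_enters_through_copy_chain(self, diamond_hierarchy):
        # gene attached only to A (layer 2) must enter at layer 1 via a copy
        gm = GeneMembership(genes=("gx",), member_of={"gx": frozenset({"A"})})
        stack = build_layer_masks(diamond_hierarchy, gm, n_layers=2)
        assert licensed_pairs(stack.by_name("pathway_1")) == {("gx", "A::copy@1")}
        assert ("A::copy@1", "A") in licensed_pairs(stack.by_name("pathway_2"))

    def test_count_connections(self, diamond_stack):
        counts = count_connections(diamond_stack)
        assert counts == {"pathway_1": 3, "pathway_2": 2}
        assert counts["pathway_1"] == diamond_stack.by_name("pathway_1").nnz


class TestMaskOracle:
    def test_nonzeros_subset_of_licensed_pairs(self):
        """Brute-force oracle over 25 random hierarchies (<= 50 pathways)."""
        rng = np.random.default_rng(42)
        for trial in range(25):
            n_nodes = int(rng.integers(4, 51))
            h = random_hierarchy(rng, n_nodes)
            gm = random_membership(rng, h, n_genes=int(rng.integers(3, 20)))
            n_layers = int(rng.integers(1, h.n_layers + 1))
            try:
                stack = build_layer_masks(h, gm, n_layers=n_layers)
            except KnowledgeError:
                continue  # all genes dropped for this draw
            for mask in stack:
                allowed = oracle_licensed_pairs(mask, h, gm, n_layers)
                assert licensed_pairs(mask) <= allowed, (trial, mask.name)

    def test_chaining_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            h = random_hierarchy(rng, 30)
            gm = random_membership(rng, h, 10)
            stack = build_layer_masks(h, gm, n_layers=min(3, h.n_layers))
            chain = stack.pathway_masks()
            for a, b in zip(chain, chain[1:]):
                assert a.col_index == b.row_index

    def test_counts_invariant_under_permutation(self, diamond_stack):
        rng = np.random.default_rng(0)
        for m in diamond_stack:
            perm_r = rng.permutation(m.shape[0])
            perm_c = rng.permutation(m.shape[1])
            assert int(np.count_nonzero(m.data[np.ix_(perm_r, perm_c)])) == m.nnz


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, diamond_hierarchy,
                                  diamond_membership, toy_regulon):
        stack = build_layer_masks(
            diamond_hierarchy, diamond_membership, regulon=toy_regulon, n_layers=2
        )
        save_mask_stack(stack, tmp_path / "masks")
        loaded = load_mask_stack(tmp_path / "masks")
        assert loaded.names == stack.names
        for a, b in zip(stack, loaded):
            assert a.row_index == b.row_index
            assert a.col_index == b.col_index
            assert np.array_equal(a.data, b.data)
            assert np.array_equal(a.frozen_bool(), b.frozen_bool())
            assert np.array_equal(a.linear_cols_bool(), b.linear_cols_bool())


def _single_pathway_hierarchy():
    from binnet.knowledge import PathwayHierarchy

    return PathwayHierarchy(
        nodes=frozenset({"P"}),
        edges=frozenset(),
        roots=frozenset({"P"}),
        layer_of={"P": 1},
    )
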