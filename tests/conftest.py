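import numpy as np
import pytest

from binnet.knowledge import (
    GeneMembership,
    PathwayHierarchy,
    RegulatoryNetwork,
    build_layer_masks,
)
from binnet.network import ModelConfig, assemble_pnet


@pytest.fixture
def diamond_relations(tmp_path):
    """The four-node hierarchy R -> {A, B}, A -> C."""
    p = tmp_path / "relations.tsv"
    p.write_text("R\tA\nR\tB\nA\tC\n")
    return p


@pytest.fixture
def diamond_hierarchy():
    return PathwayHierarchy(
        nodes=frozenset({"R", "A", "B", "C"}),
        edges=frozenset({("R", "A"), ("R", "B"), ("A", "C")}),
        roots=frozenset({"R"}),
        layer_of={"C": 1, "B": 1, "A": 2, "R": 3},
    )


@pytest.fixture
def diamond_membership():
    return GeneMembership(
        genes=("g1", "g2", "g3"),
        member_of={
            "g1": frozenset({"C"}),
            "g2": frozenset({"C"}),
            "g3": frozenset({"B"}),
        },
    )


@pytest.fixture
def toy_regulon():
    return RegulatoryNetwork(
        tfs=frozenset({"g3"}),
        edges=frozenset({("g3", "g1", 1), ("g3", "g2", -1)}),
    )


@pytest.fixture
def diamond_stack(diamond_hierarchy, diamond_membership):
    return build_layer_masks(diamond_hierarchy, diamond_membership, n_layers=2)


@pytest.fixture
def small_net(diamond_hierarchy, diamond_membership, toy_regulon):
    """3-gene, 2-layer network with a regulatory layer, 2 modalities."""
    stack = build_layer_masks(
        diamond_hierarchy, diamond_membership, regulon=toy_regulon, n_layers=2
    )
    cfg = ModelConfig(
        use_regulatory=True, n_layers=2, dropout_rate=0.0, seed=7
    )
    return assemble_pnet(stack, cfg, modalities=("m0", "m1"))
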