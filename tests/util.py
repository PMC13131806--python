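"""Shared helpers: random knowledge graphs and the brute-force
licensed-pair oracle used to validate mask construction."""

from __future__ import annotations

import numpy as np

from binnet.knowledge import (
    COPY_SEP,
    GeneMembership,
    Mask,
    MaskStack,
    PathwayHierarchy,
    copy_source,
    is_copy_node,
)


def random_hierarchy(
    rng: np.random.Generator, n_nodes: int, extra_edge_prob: float = 0.15
) -> PathwayHierarchy:
    """Random rooted DAG: each node gets one parent among its predecessors,
    plus occasional extra parents (multi-parent, layer-skipping edges)."""
    names = [f"P{i:02d}" for i in range(n_nodes)]
    edges: set[tuple[str, str]] = set()
    for i in range(1, n_nodes):
        parent = int(rng.integers(0, i))
        edges.add((names[parent], names[i]))
        if i >= 2 and rng.random() < extra_edge_prob:
            extra = int(rng.integers(0, i))
            if extra != parent:
                edges.add((names[extra], names[i]))
    # longest path to a leaf, computed straightforwardly
    children: dict[str, list[str]] = {n: [] for n in names}
    for p, c in edges:
        children[p].append(c)

    def depth(n: str) -> int:
        return 1 if not children[n] else 1 + max(depth(c) for c in children[n])

    layer = {n: depth(n) for n in names}
    parents_of = {c for _, c in edges}
    return PathwayHierarchy(
        nodes=frozenset(names),
        edges=frozenset(edges),
        roots=frozenset(n for n in names if n not in parents_of),
        layer_of=layer,
    )


def random_membership(
    rng: np.random.Generator, hierarchy: PathwayHierarchy, n_genes: int
) -> GeneMembership:
    """Genes attached to 1-3 random pathways anywhere in the hierarchy."""
    pathways = sorted(hierarchy.nodes)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    member = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        member[g] = frozenset(
            str(p) for p in rng.choice(pathways, size=min(k, len(pathways)), replace=False)
        )
    return GeneMembership(genes=tuple(genes), member_of=member)


def oracle_licensed_pairs(
    mask: Mask,
    hierarchy: PathwayHierarchy,
    membership: GeneMembership,
    n_layers: int,
) -> set[tuple[str, str]]:
    """Brute-force enumeration of the pairs a mask may connect.

    Derived directly from the hierarchy edge list, the layer map and the
    deepest-membership rule — independently of the mask builder:

    * gene -> layer-1 mask: a gene may reach pathway ``p`` (or a layer-1
      copy of ``p``) only if ``p`` is among its deepest usable memberships;
    * pathway masks: real-to-real pairs need a hierarchy edge with the
      parent exactly one layer up; copies chain their source pathway
      upward; a copy may feed a real parent only via a hierarchy edge of
      its source.
    """
    layer_of = hierarchy.layer_of
    edges = set(hierarchy.edges)
    licensed: set[tuple[str, str]] = set()
    k = int(mask.name.split("_")[1])
    if k == 1:
        for g in membership.genes:
            usable = {
                p for p in membership.member_of[g] if layer_of[p] <= n_layers
            }
            if not usable:
                continue
            deepest = min(layer_of[p] for p in usable)
            for p in usable:
                if layer_of[p] != deepest:
                    continue
                for col in mask.col_index:
                    if col == p or (is_copy_node(col) and copy_source(col) == p):
                        licensed.add((g, col))
        return licensed
    for row in mask.row_index:
        r_src = copy_source(row)
        for col in mask.col_index:
            c_src = copy_source(col)
            if is_copy_node(col) and c_src == r_src:
                licensed.add((row, col))  # chain continuation
            elif not is_copy_node(col):
                if (col, r_src) in edges and layer_of[col] == k:
                    licensed.add((row, col))  # (re-anchored) hierarchy edge
                elif is_copy_node(row) and col == r_src and layer_of[col] == k:
                    licensed.add((row, col))  # chain exit into its source
    return licensed
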