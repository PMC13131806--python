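"""Prior-knowledge graphs and the sparsity masks they license.

This module turns three kinds of curated biology into the connectivity
masks of a biologically informed neural network:

* a hierarchical pathway graph (Reactome-dialect ``parent<TAB>child``
  relation files), in which specific sub-processes sit below broader
  parent pathways;
* gene-set membership (GMT files) linking genes to pathways;
* a signed transcription-factor regulon (CollecTRI-dialect TSV) linking
  target genes to the factors that activate (+1) or repress (-1) them.

Pathways are assigned to layers by longest path to a leaf, so layer 1
holds the most specific pathways and each retained edge connects a child
at layer *k* to its parent at layer *k + 1*.  Edges that skip layers, and
genes whose most specific membership lies above layer 1, are re-anchored
through frozen identity "copy-through" nodes so the mask stack chains
cleanly layer by layer.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

COPY_SEP = "::copy@"  # marks frozen pass-through nodes, e.g. "P3::copy@2"


class KnowledgeError(ValueError):
    """Raised for malformed or inconsistent knowledge inputs."""


class ParseError(KnowledgeError):
    """Raised when an input file violates its dialect."""


class GraphError(KnowledgeError):
    """Raised when the pathway relation graph is not a rooted DAG."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayHierarchy:
    """Rooted DAG of pathways with a per-node layer assignment.

    ``layer_of`` maps each pathway to a positive integer; layer 1 is the
    most specific (deepest) level.  For every edge,
    ``layer_of[parent] >= layer_of[child] + 1``.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (parent, child)
    roots: frozenset[str]
    layer_of: Mapping[str, int]

    @property
    def n_layers(self) -> int:
        return max(self.layer_of.values(), default=0)

    def children(self, pathway: str) -> set[str]:
        return {c for p, c in self.edges if p == pathway}

    def parents(self, pathway: str) -> set[str]:
        return {p for p, c in self.edges if c == pathway}

    def ancestors(self, pathway: str) -> set[str]:
        """All pathways reachable by repeatedly following parent edges."""
        out: set[str] = set()
        frontier = {pathway}
        while frontier:
            nxt = set().union(*(self.parents(p) for p in frontier)) - out
            out |= nxt
            frontier = nxt
        return out


@dataclass(frozen=True)
class GeneMembership:
    """Ordered gene list plus gene -> pathway-set membership."""

    genes: tuple[str, ...]
    member_of: Mapping[str, frozenset[str]]

    def validate_against(self, hierarchy: PathwayHierarchy) -> None:
        unknown = set().union(*self.member_of.values(), frozenset()) - set(
            hierarchy.nodes
        )
        if unknown:
            raise KnowledgeError(
                f"membership references pathways absent from the hierarchy: "
                f"{sorted(unknown)[:5]}"
            )


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed TF -> target edges; sign +1 activation, -1 repression."""

    tfs: frozenset[str]
    edges: frozenset[tuple[str, str, int]]  # (tf, target, sign)

    def sign_of(self) -> dict[tuple[str, str], int]:
        return {(t, g): s for t, g, s in self.edges}


@dataclass
class Mask:
    """One connectivity matrix of the stack, with identifier indices.

    ``data`` holds entries in {-1, 0, +1}.  ``frozen`` flags positions whose
    effective weight is pinned at +1 (copy-through links); ``linear_cols``
    flags output nodes that are pure pass-throughs (no activation, no bias).
    """

    name: str
    data: np.ndarray
    row_index: tuple[str, ...]
    col_index: tuple[str, ...]
    frozen: np.ndarray | None = None
    linear_cols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape != (len(self.row_index), len(self.col_index)):
            raise KnowledgeError(
                f"mask {self.name}: data shape {self.data.shape} does not match "
                f"indices ({len(self.row_index)}, {len(self.col_index)})"
            )
        bad = set(np.unique(self.data)) - {-1, 0, 1}
        if bad:
            raise KnowledgeError(f"mask {self.name}: entries outside {{-1,0,1}}: {bad}")

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def frozen_bool(self) -> np.ndarray:
        if self.frozen is None:
            return np.zeros(self.data.shape, dtype=bool)
        return self.frozen.astype(bool)

    def linear_cols_bool(self) -> np.ndarray:
        if self.linear_cols is None:
            return np.zeros(len(self.col_index), dtype=bool)
        return self.linear_cols.astype(bool)


@dataclass
class MaskStack:
    """Ordered masks defining one sparse architecture.

    Pathway masks chain: ``masks[k].col_index == masks[k+1].row_index``.
    A square gene-indexed ``regulatory`` mask, when present, is exempt from
    chaining (it runs parallel to the first pathway mask).
    """

    masks: list[Mask]

    def __iter__(self):
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def by_name(self, name: str) -> Mask:
        for m in self.masks:
            if m.name == name:
                return m
        raise KeyError(f"no mask named {name!r}; have {[m.name for m in self.masks]}")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.masks]

    def pathway_masks(self) -> list[Mask]:
        return [m for m in self.masks if m.name != "regulatory"]

    def regulatory_mask(self) -> Mask | None:
        return next((m for m in self.masks if m.name == "regulatory"), None)

    def validate_chaining(self) -> None:
        chain = self.pathway_masks()
        for a, b in zip(chain, chain[1:]):
            if a.col_index != b.row_index:
                raise KnowledgeError(
                    f"mask chaining broken between {a.name} and {b.name}"
                )
        reg = self.regulatory_mask()
        if reg is not None:
            if reg.row_index != reg.col_index:
                raise KnowledgeError("regulatory mask must be square over genes")
            if chain and reg.row_index != chain[0].row_index:
                raise KnowledgeError(
                    "regulatory mask gene index must match the gene input mask"
                )


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def parse_pathway_relations(path: str | Path) -> PathwayHierarchy:
    """Parse a Reactome-dialect relation file (``parent<TAB>child`` lines).

    Layers are assigned by longest path to a leaf plus one, so leaves sit
    at layer 1 and every parent sits strictly above all of its children.

    Raises
    ------
    ParseError
        If a non-empty line does not have exactly two tab-separated fields.
    GraphError
        If the relation graph contains a directed cycle (one cycle is named).
    """
    path = Path(path)
    g = nx.DiGraph()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(
                f"{path.name}:{lineno}: expected 2 tab-separated fields, "
                f"got {len(fields)}: {line!r}"
            )
        parent, child = (f.strip() for f in fields)
        g.add_edge(parent, child)
    if g.number_of_nodes() == 0:
        return PathwayHierarchy(frozenset(), frozenset(), frozenset(), {})
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        loop = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
        raise GraphError(f"{path.name}: relation graph contains a cycle: {loop}")
    layer = _longest_path_to_leaf_layers(g)
    roots = frozenset(n for n in g.nodes if g.in_degree(n) == 0)
    return PathwayHierarchy(
        nodes=frozenset(g.nodes),
        edges=frozenset(g.edges),
        roots=roots,
        layer_of=layer,
    )


def _longest_path_to_leaf_layers(g: nx.DiGraph) -> dict[str, int]:
    """layer(n) = 1 + longest directed path from n down to any leaf."""
    layer: dict[str, int] = {}
    for n in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(n))
        layer[n] = 1 if not succ else 1 + max(layer[s] for s in succ)
    return layer


def parse_gene_sets(path: str | Path, dialect: str = "gmt") -> GeneMembership:
    """Parse a GMT file (``set-name<TAB>description<TAB>gene...``).

    Gene order is first-appearance order across the file; duplicate genes
    within a set line are deduplicated.
    """
    if dialect != "gmt":
        raise ValueError(f"unsupported gene-set dialect: {dialect!r}")
    path = Path(path)
    genes: list[str] = []
    member: dict[str, set[str]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path.name}:{lineno}: GMT line needs >= 3 fields "
                f"(name, description, genes...), got {len(fields)}"
            )
        set_name = fields[0].strip()
        for gene in fields[2:]:
            gene = gene.strip()
            if not gene:
                continue
            if gene not in member:
                member[gene] = set()
                genes.append(gene)
            member[gene].add(set_name)
    return GeneMembership(
        genes=tuple(genes),
        member_of={g: frozenset(s) for g, s in member.items()},
    )


def parse_regulatory_edges(path: str | Path) -> RegulatoryNetwork:
    """Parse a CollecTRI-dialect regulon TSV.

    Expects header columns ``source``, ``target`` and ``weight`` (or
    ``sign``); weights are collapsed to their sign.  A zero weight, or a
    duplicated (tf, target) pair with conflicting signs, is a validation
    error.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        return RegulatoryNetwork(frozenset(), frozenset())
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        i_src = header.index("source")
        i_tgt = header.index("target")
    except ValueError as exc:
        raise ParseError(
            f"{path.name}: missing 'source'/'target' columns in header {header}"
        ) from exc
    if "weight" in header:
        i_w = header.index("weight")
    elif "sign" in header:
        i_w = header.index("sign")
    else:
        raise ParseError(f"{path.name}: need a 'weight' or 'sign' column")
    seen: dict[tuple[str, str], int] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        fields = raw.split("\t")
        if len(fields) <= max(i_src, i_tgt, i_w):
            raise ParseError(f"{path.name}:{lineno}: too few columns")
        tf, target = fields[i_src].strip(), fields[i_tgt].strip()
        try:
            w = float(fields[i_w])
        except ValueError as exc:
            raise ParseError(
                f"{path.name}:{lineno}: weight {fields[i_w]!r} is not numeric"
            ) from exc
        if w == 0:
            raise KnowledgeError(
                f"{path.name}:{lineno}: zero-valued sign for ({tf}, {target})"
            )
        sign = 1 if w > 0 else -1
        key = (tf, target)
        if key in seen:
            if seen[key] != sign:
                raise KnowledgeError(
                    f"{path.name}: conflicting signs for duplicated pair {key}"
                )
            continue
        seen[key] = sign
    return RegulatoryNetwork(
        tfs=frozenset(t for t, _ in seen),
        edges=frozenset((t, g, s) for (t, g), s in seen.items()),
    )


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------


def is_copy_node(name: str) -> bool:
    return COPY_SEP in name

def copy_source(name: str) -> str:
    """Original pathway a copy-through node stands in for."""
    return name.split(COPY_SEP, 1)[0]


def _copy_name(pathway: str, layer: int) -> str:
    return f"{pathway}{COPY_SEP}{layer}"


def build_layer_masks(
    hierarchy: PathwayHierarchy,
    membership: GeneMembership,
    regulon: RegulatoryNetwork | None = None,
    n_layers: int = 2,
    on_unmapped_gene: str = "drop",
) -> MaskStack:
    """Build the ordered mask stack for a pathway-structured network.

    Masks produced, in order: optional ``regulatory`` (square over genes),
    then ``pathway_1`` (genes x layer-1 nodes) through ``pathway_L``.  Each
    gene connects only to its deepest-layer (minimum layer index)
    memberships; a membership at layer l > 1 is reached through a frozen
    copy chain entering at layer 1.  Hierarchy edges that skip layers are
    re-anchored the same way, and children of truncated parents are carried
    up to layer ``n_layers`` so no retained branch dead-ends.

    Parameters
    ----------
    on_unmapped_gene:
        ``"drop"`` removes genes without any usable pathway membership with
        a logged warning; ``"error"`` raises instead.
    """
    if n_layers < 1:
        raise KnowledgeError("n_layers must be >= 1")
    if hierarchy.n_layers and n_layers > hierarchy.n_layers:
        raise KnowledgeError(
            f"n_layers={n_layers} exceeds hierarchy depth {hierarchy.n_layers}"
        )
    if on_unmapped_gene not in ("drop", "error"):
        raise ValueError("on_unmapped_gene must be 'drop' or 'error'")
    membership.validate_against(hierarchy)
    layer_of = dict(hierarchy.layer_of)

    # genes -> deepest-layer memberships reachable within the retained depth
    attach: dict[str, set[str]] = {}
    dropped: list[str] = []
    for gene in membership.genes:
        paths = membership.member_of.get(gene, frozenset())
        usable = {p for p in paths if layer_of[p] <= n_layers}
        if not usable:
            dropped.append(gene)
            continue
        deepest = min(layer_of[p] for p in usable)
        attach[gene] = {p for p in usable if layer_of[p] == deepest}
    if dropped:
        msg = (
            f"{len(dropped)} gene(s) have no pathway membership within "
            f"{n_layers} layer(s) and were dropped: {sorted(dropped)[:5]}"
        )
        if on_unmapped_gene == "error":
            raise KnowledgeError(msg)
        logger.warning(msg)
    genes = tuple(sorted(attach))
    if not genes:
        raise KnowledgeError("no genes remain after membership filtering")

    # layered node sets and flow edges (child-at-k -> parent-at-k+1)
    nodes_at: dict[int, set[str]] = {
        k: {p for p, l in layer_of.items() if l == k} for k in range(1, n_layers + 1)
    }
    flow_edges: set[tuple[str, str]] = set()  # (lower node, upper node)
    frozen_edges: set[tuple[str, str]] = set()  # edges into copy nodes

    def _chain(pathway: str, lo: int, hi: int, upward: bool) -> tuple[str, str]:
        """Insert copy nodes for ``pathway`` at layers lo..hi (inclusive).

        Returns (entry node at layer lo, exit node at layer hi).  ``upward``
        chains carry an existing lower node up; downward chains (gene
        attachment) carry signal from layer 1 up into the real node.
        Either way flow runs lower-layer -> higher-layer.
        """
        prev = None
        first = None
        for k in range(lo, hi + 1):
            cname = _copy_name(pathway, k)
            nodes_at[k].add(cname)
            if first is None:
                first = cname
            if prev is not None:
                flow_edges.add((prev, cname))
                frozen_edges.add((prev, cname))
            prev = cname
        return first, prev

    for parent, child in hierarchy.edges:
        lp, lc = layer_of[parent], layer_of[child]
        if lc > n_layers:
            continue
        top = min(lp - 1, n_layers)
        if top > lc:  # carry child upward through copies
            entry, exit_ = _chain(child, lc + 1, top, upward=True)
            flow_edges.add((child, entry))
            frozen_edges.add((child, entry))
            carrier = exit_
        else:
            carrier = child
        if lp <= n_layers:
            flow_edges.add((carrier, parent))

    # gene attachment: memberships above layer 1 enter through a copy chain
    gene_edges: set[tuple[str, str]] = set()  # (gene, layer-1 node)
    for gene, paths in attach.items():
        for p in paths:
            lp = layer_of[p]
            if lp == 1:
                gene_edges.add((gene, p))
            else:
                entry, exit_ = _chain(p, 1, lp - 1, upward=False)
                gene_edges.add((gene, entry))
                flow_edges.add((exit_, p))

    # materialize masks with lexicographically sorted indices
    masks: list[Mask] = []
    if regulon is not None:
        masks.append(_regulatory_mask(genes, regulon))
    col_ids = tuple(sorted(nodes_at[1]))
    data = np.zeros((len(genes), len(col_ids)), dtype=np.int8)
    gpos = {g: i for i, g in enumerate(genes)}
    cpos = {c: j for j, c in enumerate(col_ids)}
    for g, p in gene_edges:
        data[gpos[g], cpos[p]] = 1
    masks.append(
        Mask(
            name="pathway_1",
            data=data,
            row_index=genes,
            col_index=col_ids,
            linear_cols=np.array([is_copy_node(c) for c in col_ids], dtype=bool),
        )
    )
    for k in range(1, n_layers):
        row_ids = col_ids
        col_ids = tuple(sorted(nodes_at[k + 1]))
        rpos = {r: i for i, r in enumerate(row_ids)}
        cpos = {c: j for j, c in enumerate(col_ids)}
        data = np.zeros((len(row_ids), len(col_ids)), dtype=np.int8)
        frz = np.zeros_like(data, dtype=bool)
        for lo, hi in flow_edges:
            if lo in rpos and hi in cpos:
                data[rpos[lo], cpos[hi]] = 1
                if (lo, hi) in frozen_edges:
                    frz[rpos[lo], cpos[hi]] = True
        masks.append(
            Mask(
                name=f"pathway_{k + 1}",
                data=data,
                row_index=row_ids,
                col_index=col_ids,
                frozen=frz if frz.any() else None,
                linear_cols=np.array(
                    [is_copy_node(c) for c in col_ids], dtype=bool
                ),
            )
        )
    stack = MaskStack(masks)
    stack.validate_chaining()
    return stack


def _regulatory_mask(genes: tuple[str, ...], regulon: RegulatoryNetwork) -> Mask:
    """Square gene x gene mask: column t holds t's targets plus a self-link."""
    pos = {g: i for i, g in enumerate(genes)}
    data = np.zeros((len(genes), len(genes)), dtype=np.int8)
    skipped = 0
    for tf, target, sign in regulon.edges:
        if tf not in pos or target not in pos:
            skipped += 1
            continue
        data[pos[target], pos[tf]] = sign
    for tf in regulon.tfs:
        if tf in pos:
            data[pos[tf], pos[tf]] = 1
    if skipped:
        logger.warning(
            "regulatory mask: skipped %d edge(s) referencing genes outside "
            "the model gene list",
            skipped,
        )
    return Mask(name="regulatory", data=data, row_index=genes, col_index=genes)


def count_connections(stack: MaskStack) -> dict[str, int]:
    """Nonzero entries per mask; the sum is total model connectivity."""
    return {m.name: m.nnz for m in stack}


# ---------------------------------------------------------------------------
# licensed-pair enumeration (used by tests as the brute-force oracle surface)
# ---------------------------------------------------------------------------


def licensed_pairs(mask: Mask) -> set[tuple[str, str]]:
    """(row_id, col_id) pairs where the mask licenses a connection."""
    rows, cols = np.nonzero(mask.data)
    return {(mask.row_index[i], mask.col_index[j]) for i, j in zip(rows, cols)}


# ---------------------------------------------------------------------------
# serialization: sparse triplet CSV + JSON index sidecar, bit-exact round-trip
# ---------------------------------------------------------------------------


def save_mask_stack(stack: MaskStack, directory: str | Path) -> list[Path]:
    """Write each mask as ``<name>.triplets.csv`` plus ``<name>.index.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    order = []
    for m in stack:
        trip = directory / f"{m.name}.triplets.csv"
        with trip.open("w") as fh:
            fh.write("row_id,col_id,sign\n")
            rows, cols = np.nonzero(m.data)
            for i, j in zip(rows.tolist(), cols.tolist()):
                fh.write(f"{m.row_index[i]},{m.col_index[j]},{int(m.data[i, j])}\n")
        frz = m.frozen_bool()
        fi, fj = np.nonzero(frz)
        sidecar = {
            "name": m.name,
            "row_index": list(m.row_index),
            "col_index": list(m.col_index),
            "frozen": [[m.row_index[i], m.col_index[j]] for i, j in zip(fi, fj)],
            "linear_cols": [
                m.col_index[j] for j in np.nonzero(m.linear_cols_bool())[0]
            ],
        }
        idx = directory / f"{m.name}.index.json"
        idx.write_text(json.dumps(sidecar, indent=0, sort_keys=True))
        written += [trip, idx]
        order.append(m.name)
    (directory / "stack.json").write_text(json.dumps({"order": order}))
    written.append(directory / "stack.json")
    return written


def load_mask_stack(directory: str | Path) -> MaskStack:
    directory = Path(directory)
    order = json.loads((directory / "stack.json").read_text())["order"]
    masks = []
    for name in order:
        sidecar = json.loads((directory / f"{name}.index.json").read_text())
        rows = tuple(sidecar["row_index"])
        cols = tuple(sidecar["col_index"])
        rpos = {r: i for i, r in enumerate(rows)}
        cpos = {c: j for j, c in enumerate(cols)}
        data = np.zeros((len(rows), len(cols)), dtype=np.int8)
        trip = (directory / f"{name}.triplets.csv").read_text().splitlines()
        for line in trip[1:]:
            if not line.strip():
                continue
            # identifiers never contain commas in our dialects
            r, c, s = line.split(",")
            data[rpos[r], cpos[c]] = int(s)
        frozen = None
        if sidecar["frozen"]:
            frozen = np.zeros_like(data, dtype=bool)
            for r, c in sidecar["frozen"]:
                frozen[rpos[r], cpos[c]] = True
        linear = None
        if sidecar["linear_cols"]:
            linear = np.zeros(len(cols), dtype=bool)
            for c in sidecar["linear_cols"]:
                linear[cpos[c]] = True
        masks.append(
            Mask(
                name=name,
                data=data,
                row_index=rows,
                col_index=cols,
                frozen=frozen,
                linear_cols=linear,
            )
        )
    return MaskStack(masks)
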