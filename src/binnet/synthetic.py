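"""Synthetic knowledge graphs and cohorts with planted causal structure.

The generator emulates the three curated inputs the model consumes — a
rooted pathway hierarchy, gene-to-pathway membership, and a signed TF
regulon — plus a labeled multi-modality cohort whose binary outcome is
driven by the member genes of a small set of "causal" leaf pathways
through a logistic model.  Everything is a pure function of the seed, and
the emitted files use exactly the dialects the knowledge parsers read, so
every downstream module is testable end to end without external
databases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .knowledge import (
    GeneMembership,
    PathwayHierarchy,
    RegulatoryNetwork,
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    ``branching`` may be a single integer (balanced b-ary tree) or one
    integer per level, root first.  ``effect_size`` is the log-odds
    contribution of one unit of a causal gene's signal, applied through
    every modality.
    """

    n_genes: int = 200
    n_layers: int = 2
    branching: int | tuple[int, ...] = (5, 4)
    genes_per_leaf: int = 10
    n_tfs: int = 10
    targets_per_tf: int = 8
    n_samples: int = 600
    n_modalities: int = 2
    causal_pathway_count: int = 1
    effect_size: float = 1.5
    label_noise: float = 0.0
    binary_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_layers", "genes_per_leaf", "n_samples",
            "n_modalities", "causal_pathway_count",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_tfs < 0 or self.targets_per_tf < 0:
            raise ValueError("TF counts must be non-negative")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if isinstance(self.branching, int):
            self.branching = (self.branching,) * self.n_layers
        else:
            self.branching = tuple(self.branching)
        if len(self.branching) != self.n_layers:
            raise ValueError("branching needs one factor per layer")
        if any(b < 1 for b in self.branching):
            raise ValueError("branching factors must be positive")


@dataclass
class GroundTruth:
    causal_genes: frozenset[str]
    causal_pathways: frozenset[str]  # the planted leaves
    causal_lineage: frozenset[str]  # leaves plus all their ancestors
    beta: pd.Series  # per-gene log-odds effect

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "causal_genes": sorted(self.causal_genes),
                    "causal_pathways": sorted(self.causal_pathways),
                    "causal_lineage": sorted(self.causal_lineage),
                    "beta": {g: float(v) for g, v in self.beta.items()},
                },
                indent=1,
                sort_keys=True,
            )
        )


def _tree_nodes(branching: tuple[int, ...]) -> tuple[list[tuple[str, str]], list[str]]:
    """Edges (parent, child) and leaves of a rooted tree, root name 'P0'."""
    edges: list[tuple[str, str]] = []
    level = ["P0"]
    for depth, b in enumerate(branching, start=1):
        nxt = []
        for parent in level:
            for j in range(b):
                child = f"{parent}.{j}"
                edges.append((parent, child))
                nxt.append(child)
        level = nxt
    return edges, level


def simulate_hierarchy(
    cfg: SyntheticConfig,
) -> tuple[PathwayHierarchy, GeneMembership, RegulatoryNetwork]:
    """Balanced rooted tree of depth ``n_layers`` with genes on leaves.

    Every gene is dealt to at least one leaf; remaining leaf slots are
    filled by uniform draws (overlap).  ``n_tfs`` genes become TFs with
    ``targets_per_tf`` signed targets each, signs equiprobable.
    """
    rng = np.random.default_rng(cfg.seed)
    edges, leaves = _tree_nodes(cfg.branching)
    n_slots = len(leaves) * cfg.genes_per_leaf
    if cfg.n_genes > n_slots:
        raise ValueError(
            f"{cfg.n_genes} genes cannot fill {len(leaves)} leaves x "
            f"{cfg.genes_per_leaf} slots"
        )
    width = len(str(cfg.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]

    # deal every gene once, then fill leftover slots with uniform draws
    dealt = list(rng.permutation(genes))
    slots: list[list[str]] = [[] for _ in leaves]
    for i, g in enumerate(dealt):
        slots[i % len(leaves)].append(g)
    for leaf_i, members in enumerate(slots):
        while len(members) < cfg.genes_per_leaf:
            g = genes[rng.integers(cfg.n_genes)]
            if g not in members:
                members.append(g)

    member_of: dict[str, set[str]] = {g: set() for g in genes}
    for leaf, members in zip(leaves, slots):
        for g in members:
            member_of[g].add(leaf)
    membership = GeneMembership(
        genes=tuple(genes),
        member_of={g: frozenset(s) for g, s in member_of.items()},
    )

    nodes = {n for e in edges for n in e}
    layer_of: dict[str, int] = {}
    # balanced tree: layer = n_layers+1 - depth; compute from the leaves up
    depth_of = {"P0": 0}
    for parent, child in edges:
        depth_of[child] = depth_of[parent] + 1
    for n in nodes:
        layer_of[n] = cfg.n_layers + 1 - depth_of[n]
    hierarchy = PathwayHierarchy(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        roots=frozenset({"P0"}),
        layer_of=layer_of,
    )

    reg_edges: set[tuple[str, str, int]] = set()
    tfs: set[str] = set()
    if cfg.n_tfs > 0 and cfg.targets_per_tf > 0:
        tf_genes = rng.choice(genes, size=min(cfg.n_tfs, cfg.n_genes), replace=False)
        for tf in tf_genes:
            tfs.add(str(tf))
            candidates = [g for g in genes if g != tf]
            targets = rng.choice(
                candidates, size=min(cfg.targets_per_tf, len(candidates)),
                replace=False,
            )
            signs = rng.choice([-1, 1], size=len(targets))
            for g, s in zip(targets, signs):
                reg_edges.add((str(tf), str(g), int(s)))
    regulon = RegulatoryNetwork(tfs=frozenset(tfs), edges=frozenset(reg_edges))
    return hierarchy, membership, regulon


def simulate_cohort(
    hierarchy: PathwayHierarchy,
    membership: GeneMembership,
    cfg: SyntheticConfig,
) -> tuple[dict[str, pd.DataFrame], pd.Series, GroundTruth]:
    """Labeled cohort with planted causal leaves.

    Modalities: ``continuous`` ~ N(0,1) per gene; ``binary`` ~
    Bernoulli(binary_rate).  The label is Bernoulli of the logistic of
    ``beta @ x`` summed over modalities, then flipped with probability
    ``label_noise``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    leaves = sorted(
        n for n in hierarchy.nodes if hierarchy.layer_of[n] == 1
    )
    if cfg.causal_pathway_count > len(leaves):
        raise ValueError(
            f"causal_pathway_count={cfg.causal_pathway_count} exceeds "
            f"{len(leaves)} leaves"
        )
    causal_leaves = {
        str(p)
        for p in rng.choice(leaves, size=cfg.causal_pathway_count, replace=False)
    }
    genes = list(membership.genes)
    causal_genes = {
        g for g in genes if membership.member_of[g] & causal_leaves
    }
    beta = pd.Series(
        [cfg.effect_size if g in causal_genes else 0.0 for g in genes],
        index=genes,
        dtype=float,
    )
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    modality_names = _modality_names(cfg.n_modalities)
    mods: dict[str, pd.DataFrame] = {}
    logit = np.zeros(cfg.n_samples)
    for name in modality_names:
        if name.startswith("binary"):
            x = rng.binomial(1, cfg.binary_rate, size=(cfg.n_samples, len(genes))).astype(float)
        else:
            x = rng.standard_normal((cfg.n_samples, len(genes)))
        mods[name] = pd.DataFrame(x, index=sample_ids, columns=genes)
        logit += x @ beta.to_numpy()
    prob = 1.0 / (1.0 + np.exp(-logit))
    y = rng.binomial(1, prob)
    flips = rng.random(cfg.n_samples) < cfg.label_noise
    y = np.where(flips, 1 - y, y)
    labels = pd.Series(y, index=sample_ids, name="label", dtype=int)
    lineage = set(causal_leaves)
    for leaf in causal_leaves:
        lineage |= hierarchy.ancestors(leaf)
    truth = GroundTruth(
        causal_genes=frozenset(causal_genes),
        causal_pathways=frozenset(causal_leaves),
        causal_lineage=frozenset(lineage),
        beta=beta,
    )
    return mods, labels, truth


def _modality_names(n: int) -> list[str]:
    """Two defaults mirror mutation + expression inputs; extras numbered."""
    base = ["continuous", "binary"]
    if n <= 2:
        return base[:n]
    return base + [f"continuous_{i}" for i in range(2, n)]


# ---------------------------------------------------------------------------
# file emission in the exact parser dialects
# ---------------------------------------------------------------------------


def write_relations(hierarchy: PathwayHierarchy, path: str | Path) -> None:
    lines = [f"{p}\t{c}" for p, c in sorted(hierarchy.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_gmt(membership: GeneMembership, path: str | Path) -> None:
    by_set: dict[str, list[str]] = {}
    for g in membership.genes:
        for s in membership.member_of[g]:
            by_set.setdefault(s, []).append(g)
    lines = [
        "\t".join([s, "synthetic"] + sorted(members))
        for s, members in sorted(by_set.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_regulon(regulon: RegulatoryNetwork, path: str | Path) -> None:
    lines = ["source\ttarget\tweight"]
    for tf, g, s in sorted(regulon.edges):
        lines.append(f"{tf}\t{g}\t{s}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(
    mods: dict[str, pd.DataFrame], labels: pd.Series, directory: str | Path
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in mods.items():
        p = directory / f"{name}.csv"
        df.to_csv(p, index_label="sample_id")
        written.append(p)
    p = directory / "labels.csv"
    labels.to_frame().to_csv(p, index_label="sample_id")
    written.append(p)
    return written


def simulate_to_dir(cfg: SyntheticConfig, directory: str | Path) -> dict[str, Path]:
    """Full emission: relations TSV, GMT, regulon TSV, modality CSVs,
    labels CSV and truth JSON.  Byte-identical for identical config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hierarchy, membership, regulon = simulate_hierarchy(cfg)
    mods, labels, truth = simulate_cohort(hierarchy, membership, cfg)
    paths = {
        "relations": directory / "relations.tsv",
        "gmt": directory / "gene_sets.gmt",
        "regulon": directory / "regulon.tsv",
        "truth": directory / "truth.json",
    }
    write_relations(hierarchy, paths["relations"])
    write_gmt(membership, paths["gmt"])
    write_regulon(regulon, paths["regulon"])
    truth.to_json(paths["truth"])
    for p in write_cohort(mods, labels, directory):
        paths[p.stem] = p
    return paths
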