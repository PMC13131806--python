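"""Reproducibility statistics for importance scores across repeated runs.

Deep models trained from different random initializations can rank
features very differently.  Three statistics quantify how reproducible a
model's importance scores are:

* top-N Jaccard stability: the mean pairwise Jaccard index of the N
  highest-scoring node sets over all unordered pairs of runs (1 = the top
  sets are identical in every run);
* per-node signal-to-noise ratio SNR = mu / sigma, the mean of a node's
  importance across runs over its standard deviation (ddof 1);
* layerwise Z: each node's SNR standardized against the SNR distribution
  of its own layer, with a one-sided upper-tail normal p-value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    n_top: int
    jaccard_mean: float
    table: pd.DataFrame  # node_id, layer, mu, sigma, snr, z, p

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# n_top={self.n_top} jaccard_mean={self.jaccard_mean!r}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StabilityReport":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip()
            table = pd.read_csv(fh)
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        return cls(
            n_top=int(meta["n_top"]),
            jaccard_mean=float(meta["jaccard_mean"]),
            table=table,
        )


def _top_n_ids(run: pd.DataFrame, n: int) -> frozenset[str]:
    """Ties broken by score descending then node_id ascending."""
    if len(run) < n:
        raise ValueError(f"run has {len(run)} nodes, fewer than N={n}")
    ordered = run.sort_values(
        ["score", "node_id"], ascending=[False, True], kind="mergesort"
    )
    return frozenset(ordered["node_id"].head(n))


def topn_jaccard_stability(runs: Sequence[pd.DataFrame], n: int = 20) -> float:
    """Mean pairwise Jaccard index of the top-N node sets across runs."""
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    tops = [_top_n_ids(run, n) for run in runs]
    vals = [
        len(a & b) / len(a | b) for a, b in itertools.combinations(tops, 2)
    ]
    return float(np.mean(vals))


def snr(runs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-node (mu, sigma, snr) across runs; sigma uses ddof 1.

    Nodes with sigma == 0 get NaN snr (reported as missing, excluded from
    layerwise statistics).  Every node must be present in every run.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    has_layer = "layer" in runs[0].columns
    key = ["node_id", "layer"] if has_layer else ["node_id"]
    mats = []
    ref = None
    for run in runs:
        piv = run.set_index(key)
        if piv.index.has_duplicates:
            raise ValueError("duplicate node ids within one run")
        if ref is None:
            ref = piv.index
        elif not piv.index.sort_values().equals(ref.sort_values()):
            raise ValueError("runs do not share a common node index")
        mats.append(piv.loc[ref, "score"].to_numpy(dtype=float))
    scores = np.vstack(mats)  # runs x nodes
    mu = scores.mean(axis=0)
    sigma = scores.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sigma > 0, mu / np.where(sigma > 0, sigma, 1.0), np.nan)
    n_degenerate = int(np.sum(sigma == 0))
    if n_degenerate:
        logger.warning("%d node(s) have zero variance across runs", n_degenerate)
    out = pd.DataFrame(
        {"node_id": ref.get_level_values("node_id") if has_layer else ref,
         "mu": mu, "sigma": sigma, "snr": ratio}
    ).reset_index(drop=True)
    if has_layer:
        out.insert(1, "layer", ref.get_level_values("layer"))
    return out


def layerwise_z(snr_table: pd.DataFrame) -> pd.DataFrame:
    """Standardize SNR within each layer: z = (snr - mean) / sd (ddof 1).

    Layers with fewer than two defined SNR values, or zero SNR spread,
    raise; NaN-SNR rows keep NaN z.
    """
    if "layer" not in snr_table.columns:
        raise ValueError("snr table must carry a 'layer' column")
    out = snr_table.copy()
    out["z"] = np.nan
    for layer, grp in snr_table.groupby("layer", sort=False):
        vals = grp["snr"].dropna()
        if len(vals) < 2:
            raise ValueError(
                f"layer {layer!r} has {len(vals)} defined SNR value(s); need >= 2"
            )
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"layer {layer!r} has zero SNR spread")
        out.loc[vals.index, "z"] = (vals - vals.mean()) / sd
    return out


def z_to_pvalue(z):
    """One-sided upper-tail standard-normal probability of the Z score."""
    return norm.sf(z)


def stability_report(
    runs: Sequence[pd.DataFrame],
    n_top: int = 20,
    jaccard_layer: str | None = "gene_input",
) -> StabilityReport:
    """Full report from per-run importance tables.

    Each run is an ImportanceTable (columns ``run_id,node_id,layer,score``).
    The Jaccard statistic is computed on ``jaccard_layer`` (gene level by
    default, matching how importance stability is defined for genes); SNR,
    layerwise Z and p-values cover every node.
    """
    if jaccard_layer is not None and "layer" in runs[0].columns:
        jacc_runs = [r[r["layer"] == jaccard_layer] for r in runs]
        if any(len(r) == 0 for r in jacc_runs):
            jacc_runs = runs
    else:
        jacc_runs = runs
    jaccard = topn_jaccard_stability(jacc_runs, n=n_top)
    table = layerwise_z(snr(runs))
    table["p"] = z_to_pvalue(table["z"])
    cols = ["node_id", "layer", "mu", "sigma", "snr", "z", "p"]
    return StabilityReport(n_top=n_top, jaccard_mean=jaccard, table=table[cols])
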