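"""Path-integral gradient attribution for inputs and hidden nodes.

Integrated Gradients assigns each input feature the integral of its
partial derivative along the straight line from a baseline to the sample,
scaled by the input-baseline difference; the attributions of all features
sum to the change in the target output (completeness).  Layer conductance
extends this to hidden nodes: a node's score is the path integral of
(downstream gradient) x (directional derivative of the node along the
path), so the scores of any full cut through the network again sum to the
output change.

The default target is the model's combined logit and the default baseline
the all-zeros input (absence/reference encoding for mutation and
expression data).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd


def _quadrature(steps: int, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Points and weights for integrating over the path parameter in [0,1]."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if method == "riemann_mid":
        pts = (np.arange(steps) + 0.5) / steps
        wts = np.full(steps, 1.0 / steps)
    elif method == "gausslegendre":
        x, w = np.polynomial.legendre.leggauss(steps)
        pts = 0.5 * (x + 1.0)
        wts = 0.5 * w
    else:
        raise ValueError(f"unknown quadrature {method!r}")
    return pts, wts


def _grad_fn(model, target: str) -> Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    if hasattr(model, "value_and_input_grad"):
        return lambda x: model.value_and_input_grad(x, target=target)
    if callable(model):
        return model  # (value, grad) callable, used for closed-form oracles
    raise TypeError("model must expose value_and_input_grad or be callable")


def integrated_gradients(
    model,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 64,
    target: str = "combined",
    method: str = "riemann_mid",
) -> np.ndarray:
    """Per-input attributions of the target logit, one row per sample.

    ``model`` is a :class:`~binnet.network.SparseNet` (or any object with a
    ``value_and_input_grad(x, target=...)`` method, or a callable returning
    ``(value, grad)``).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.broadcast_to(
        np.atleast_2d(np.asarray(baseline, dtype=float)), x.shape
    )
    if baseline.shape != x.shape:
        raise ValueError("baseline shape must match x")
    fn = _grad_fn(model, target)
    pts, wts = _quadrature(steps, method)
    diff = x - baseline
    total = np.zeros_like(x)
    for a, w in zip(pts, wts):
        _, g = fn(baseline + a * diff)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient along the path")
        total += w * g
    return diff * total


def completeness_gap(
    model, x, attributions: np.ndarray, baseline=None, target: str = "combined"
) -> np.ndarray:
    """|sum(attr) - (F(x) - F(baseline))| per sample, for diagnostics."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if baseline is None:
        baseline = np.zeros_like(x)
    fn = _grad_fn(model, target)
    fx, _ = fn(x)
    fb, _ = fn(np.broadcast_to(np.atleast_2d(baseline), x.shape))
    return np.abs(attributions.sum(axis=1) - (fx - fb))


def layer_conductance(
    model,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    layer_name: str = "pathway_1",
    steps: int = 64,
    target: str = "combined",
    method: str = "riemann_mid",
) -> np.ndarray:
    """Per-node conductance of ``layer_name``, one row per sample.

    When the layer is a full cut between the inputs and the target (always
    true for ``gene_input``, and for any layer when targeting that layer's
    own downstream head), node conductances sum to F(x) - F(baseline) up
    to quadrature error.  With multiple prediction heads and the combined
    target, earlier heads bypass deeper layers, so a deep layer's
    conductances sum to the share of the output change routed through it.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if baseline is None:
        baseline = np.zeros_like(x)
    baseline = np.broadcast_to(
        np.atleast_2d(np.asarray(baseline, dtype=float)), x.shape
    )
    pts, wts = _quadrature(steps, method)
    diff = x - baseline
    total: np.ndarray | None = None
    for a, w in zip(pts, wts):
        _, g, u = model.layer_grad_and_tangent(
            baseline + a * diff, diff, layer_name, target=target
        )
        term = w * g * u
        total = term if total is None else total + term
    return total


def importance_table(
    model,
    x: np.ndarray,
    layers: Sequence[str] | None = None,
    baseline: np.ndarray | None = None,
    steps: int = 64,
    run_id: str | int = 0,
    target: str = "combined",
    method: str = "riemann_mid",
    aggregate: str = "mean_abs",
) -> pd.DataFrame:
    """One aggregated importance score per node for the requested layers.

    Gene-level scores are the conductances of the ``gene_input`` nodes;
    pathway-level scores the conductances of each pathway layer.  Columns:
    ``run_id, node_id, layer, score``.
    """
    layers = list(layers) if layers is not None else list(model.node_index)
    frames = []
    for layer in layers:
        cond = layer_conductance(
            model, x, baseline=baseline, layer_name=layer, steps=steps,
            target=target, method=method,
        )
        per_sample = pd.DataFrame(cond, columns=list(model.node_index[layer]))
        frames.append(
            aggregate_importance([per_sample], method=aggregate).assign(
                layer=layer
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "run_id", run_id)
    return out[["run_id", "node_id", "layer", "score"]]


def aggregate_importance(
    per_sample_tables: Iterable[pd.DataFrame],
    method: str = "mean_abs",
) -> pd.DataFrame:
    """Collapse per-sample attribution rows to one score per node.

    Each input table is samples x nodes (columns are node ids).  The
    default takes the mean of absolute per-sample scores, so consistently
    large attributions of either sign rank high.
    """
    tables = list(per_sample_tables)
    if not tables:
        raise ValueError("no attribution tables given")
    stacked = pd.concat(tables, axis=0, ignore_index=True)
    if stacked.empty:
        raise ValueError("attribution tables are empty")
    if method == "mean_abs":
        scores = stacked.abs().mean(axis=0)
    elif method == "mean":
        scores = stacked.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregation {method!r}")
    return pd.DataFrame({"node_id": scores.index, "score": scores.to_numpy()})
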