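"""Model / Results interface over the masked sparse network.

:class:`PathwayNet` is constructed from per-modality gene matrices, a
binary label vector and the prior-knowledge masks; ``fit()`` returns a
:class:`PathwayNetResults` carrying the trained parameters, loss history,
head weights, attribution methods and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import attribution as _attr
from .knowledge import (
    GeneMembership,
    MaskStack,
    PathwayHierarchy,
    RegulatoryNetwork,
    build_layer_masks,
    count_connections,
)
from .network import BatchPrediction, ModelConfig, SparseNet, assemble_pnet
from .training import FoldResult, TrainConfig, auc_roc, cross_validate, train_model


class AlignmentError(ValueError):
    """Input gene columns do not match the model's gene index."""


def _align(
    data: Mapping[str, pd.DataFrame], genes: Sequence[str], modalities: Sequence[str]
) -> np.ndarray:
    """Stack modality matrices into the flat network input (modality-major)."""
    blocks = []
    for mod in modalities:
        if mod not in data:
            raise AlignmentError(f"modality {mod!r} missing from input data")
        df = data[mod]
        unknown = set(df.columns) - set(genes)
        if unknown:
            raise AlignmentError(
                f"modality {mod!r} has {len(unknown)} unknown gene column(s), "
                f"e.g. {sorted(unknown)[:5]}"
            )
        missing = set(genes) - set(df.columns)
        if missing:
            raise AlignmentError(
                f"modality {mod!r} lacks {len(missing)} model gene(s), "
                f"e.g. {sorted(missing)[:5]}"
            )
        blocks.append(df.loc[:, list(genes)].to_numpy(dtype=float))
    return np.concatenate(blocks, axis=1)


class PathwayNet:
    """Biologically informed sparse classifier for a binary outcome.

    Parameters
    ----------
    data:
        Mapping modality name -> (samples x genes) DataFrame.  All
        modalities must cover the mask's gene list; samples must align.
    labels:
        Binary outcome per sample (Series or array aligned with the rows).
    masks:
        Knowledge-derived :class:`~binnet.knowledge.MaskStack` (regulatory
        mask included when the config asks for the regulatory layer).
    config:
        Architecture settings; defaults follow :class:`ModelConfig`.
    """

    def __init__(
        self,
        data: Mapping[str, pd.DataFrame],
        labels: pd.Series | np.ndarray,
        masks: MaskStack,
        config: ModelConfig | None = None,
    ):
        self.config = config or ModelConfig()
        self.masks = masks
        self.modalities = tuple(data.keys())
        self.net = assemble_pnet(masks, self.config, modalities=self.modalities)
        self.genes = self.net.genes
        self.data = {m: df for m, df in data.items()}
        self.exog = _align(self.data, self.genes, self.modalities)
        y = np.asarray(labels).ravel()
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.endog = y.astype(int)
        if len(self.endog) != self.exog.shape[0]:
            raise AlignmentError("label count does not match sample count")

    @classmethod
    def from_knowledge(
        cls,
        data: Mapping[str, pd.DataFrame],
        labels,
        hierarchy: PathwayHierarchy,
        membership: GeneMembership,
        regulon: RegulatoryNetwork | None = None,
        config: ModelConfig | None = None,
    ) -> "PathwayNet":
        """Build masks from parsed knowledge objects and construct the model."""
        config = config or ModelConfig()
        masks = build_layer_masks(
            hierarchy,
            membership,
            regulon=regulon if config.use_regulatory else None,
            n_layers=config.n_layers,
        )
        return cls(data, labels, masks, config)

    # ------------------------------------------------------------------

    def fit(self, train_config: TrainConfig | None = None) -> "PathwayNetResults":
        cfg = train_config or TrainConfig()
        history = train_model(self.net, self.exog, self.endog, cfg)
        return PathwayNetResults(self, cfg, history)

    def cross_validate(
        self, train_config: TrainConfig | None = None
    ) -> list[FoldResult]:
        """Stratified k-fold CV with a freshly initialized network per fold."""
        cfg = train_config or TrainConfig()

        def build(seed: int) -> SparseNet:
            sub = ModelConfig(**{**self.config.__dict__, "seed": seed})
            return assemble_pnet(self.masks, sub, modalities=self.modalities)

        return cross_validate(build, self.exog, self.endog, cfg)


@dataclass
class PathwayNetResults:
    """Fitted model: parameters, diagnostics, prediction and attribution."""

    model: PathwayNet
    train_config: TrainConfig
    loss_history: list[float]

    @property
    def net(self) -> SparseNet:
        return self.model.net

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.net.get_state()

    @property
    def head_weights(self) -> pd.Series:
        return pd.Series(self.net.head_weights(), index=self.net.head_names)

    # -- prediction ----------------------------------------------------

    def _exog_of(self, data) -> np.ndarray:
        if data is None:
            return self.model.exog
        if isinstance(data, np.ndarray):
            return data
        return _align(data, self.model.genes, self.model.modalities)

    def predict(self, data=None) -> np.ndarray:
        """Combined-head probability per sample."""
        return self.net.predict(self._exog_of(data)).combined_probability

    def predict_full(self, data=None) -> BatchPrediction:
        return self.net.predict(self._exog_of(data))

    def auc(self, data=None, labels=None) -> float:
        y = self.model.endog if labels is None else np.asarray(labels).ravel()
        return auc_roc(self.predict(data), y)

    # -- attribution ---------------------------------------------------

    def integrated_gradients(self, data=None, **kw) -> pd.DataFrame:
        """Per-input IG attributions (samples x modality:gene columns)."""
        x = self._exog_of(data)
        attr = _attr.integrated_gradients(self.net, x, **kw)
        cols = [f"{m}:{g}" for m in self.model.modalities for g in self.model.genes]
        return pd.DataFrame(attr, columns=cols)

    def layer_conductance(self, layer_name: str, data=None, **kw) -> pd.DataFrame:
        x = self._exog_of(data)
        cond = _attr.layer_conductance(self.net, x, layer_name=layer_name, **kw)
        return pd.DataFrame(cond, columns=list(self.net.node_index[layer_name]))

    def importance_table(
        self,
        data=None,
        layers: Sequence[str] | None = None,
        run_id: str | int = 0,
        **kw,
    ) -> pd.DataFrame:
        """Aggregated node importances (``run_id,node_id,layer,score``)."""
        return _attr.importance_table(
            self.net, self._exog_of(data), layers=layers, run_id=run_id, **kw
        )

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        net = self.net
        buf = io.StringIO()
        title = "Pathway-structured sparse network"
        buf.write(f"{title}\n{'=' * len(title)}\n")
        cfg = self.model.config
        buf.write(f"genes: {len(self.model.genes)}  ")
        buf.write(f"modalities: {', '.join(self.model.modalities)}\n")
        buf.write(
            f"pathway layers: {len(net.pathway_layers)}  "
            f"regulatory layer: {'yes' if net.reg is not None else 'no'}  "
            f"activation: {cfg.activation}  dropout: {cfg.dropout_rate}\n"
        )
        buf.write("\nconnections per mask\n--------------------\n")
        counts = count_connections(self.model.masks)
        counts["gene_input"] = net.gil.mask.nnz
        for name in ["gene_input"] + self.model.masks.names:
            buf.write(f"  {name:<14s} {counts[name]:>8d}\n")
        buf.write("\nhead weights (convex combination)\n")
        buf.write("---------------------------------\n")
        for name, w in self.head_weights.items():
            buf.write(f"  {name:<14s} {w:>8.4f}\n")
        if self.loss_history:
            buf.write(
                f"\nepochs run: {len(self.loss_history)}  "
                f"final loss: {self.loss_history[-1]:.4f}\n"
            )
        buf.write(f"training AUC: {self.auc():.4f}\n")
        return buf.getvalue()

    def save(self, directory: str | Path) -> None:
        self.net.save(directory)
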