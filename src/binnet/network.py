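"""Masked sparse feed-forward network with per-layer prediction heads.

The architecture: a Gene Input Layer (GIL) collapses the per-gene channels
of each data modality into one node per gene; an optional square
Regulatory Layer (TF self-links plus target-gene -> TF links, signed) is
applied to the gene representation and summed element-wise back onto it;
hierarchical pathway layers then follow the knowledge masks upward.  Every
maskable layer carries an affine prediction head producing one logit, and
the overall prediction is a learned convex (softmax-weighted) combination
of the head logits.

All forward and backward passes are explicit NumPy; gradients with respect
to raw weights at zero-mask positions are identically zero by
construction, so sparsity survives any number of optimization steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .knowledge import Mask, MaskStack, GeneMembership, load_mask_stack, save_mask_stack

logger = logging.getLogger(__name__)

_ACTIVATIONS = ("tanh", "relu", "linear")


class ConfigError(ValueError):
    pass


class DimensionError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``signed_mode`` controls how signed (regulatory) mask entries constrain
    learning: ``"softplus"`` keeps the effective weight's sign fixed at the
    curated sign (weight = sign * softplus(raw)); ``"free"`` uses the sign
    only to initialize an otherwise unconstrained weight.
    """

    use_regulatory: bool = False
    n_layers: int = 2
    activation: str = "tanh"
    dropout_rate: float = 0.1
    head_weighting: str = "softmax"  # or "linear_clamped"
    signed_mode: str = "softplus"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ConfigError(f"activation must be one of {_ACTIVATIONS}")
        if self.head_weighting not in ("softmax", "linear_clamped"):
            raise ConfigError("head_weighting must be softmax or linear_clamped")
        if self.signed_mode not in ("softplus", "free"):
            raise ConfigError("signed_mode must be softplus or free")


@dataclass
class BatchPrediction:
    per_layer_logits: np.ndarray  # samples x heads
    combined_logit: np.ndarray  # samples
    combined_probability: np.ndarray  # samples, in [0,1]
    head_names: tuple[str, ...]
    head_weights: np.ndarray  # convex weights, sum to 1


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    # inverse of softplus for y > 0
    return y + np.log1p(-np.exp(-y))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def masked_affine(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    mask: np.ndarray,
    signed_mode: str = "softplus",
) -> np.ndarray:
    """Affine map through a {-1,0,+1} mask: ``x @ W_eff + bias``.

    For binary masks ``W_eff = weights * |mask|``; where the mask carries a
    sign and ``signed_mode == "softplus"``, ``W_eff = sign * softplus(raw)``
    so the curated sign can never flip during training.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    mask = np.asarray(mask)
    if weights.shape != mask.shape:
        raise DimensionError(
            f"weights {weights.shape} and mask {mask.shape} differ in shape"
        )
    if x.shape[-1] != weights.shape[0]:
        raise DimensionError(
            f"input width {x.shape[-1]} does not match mask rows {weights.shape[0]}"
        )
    w_eff = effective_weight(weights, mask, frozen=None, signed_mode=signed_mode)
    return x @ w_eff + np.asarray(bias, dtype=float)


def effective_weight(
    raw: np.ndarray,
    mask: np.ndarray,
    frozen: np.ndarray | None,
    signed_mode: str,
) -> np.ndarray:
    """Raw parameters -> effective weights under mask / sign / frozen rules."""
    pattern = mask != 0
    if frozen is None:
        frozen = np.zeros_like(pattern)
    free = pattern & ~frozen
    if (mask < 0).any() and signed_mode == "softplus":
        w = np.where(free, np.sign(mask) * _softplus(raw), 0.0)
    else:
        w = np.where(free, raw, 0.0)
    return np.where(frozen, 1.0, w)


class MaskedLayer:
    """One masked affine + activation stage of the network.

    Copy-through output nodes (flagged by the mask's ``linear_cols``) skip
    the activation and have their bias frozen at zero, and their single
    incoming weight frozen at one, making them exact identities.
    """

    def __init__(
        self,
        mask: Mask,
        activation: str,
        signed_mode: str = "softplus",
        bias_only_on_fed_nodes: bool = False,
    ):
        self.mask = mask
        self.activation = activation
        self.pattern = mask.data != 0
        self.frozen = mask.frozen_bool()
        self.linear_cols = mask.linear_cols_bool()
        self.signed = bool((mask.data < 0).any())
        self.signed_mode = signed_mode
        fed = self.pattern.any(axis=0)
        self.bias_active = ~self.linear_cols
        if bias_only_on_fed_nodes:
            self.bias_active = self.bias_active & fed
        self.W = np.zeros(mask.data.shape, dtype=float)
        self.b = np.zeros(mask.data.shape[1], dtype=float)

    # -- initialization -----------------------------------------------------

    def initialize(self, rng: np.random.Generator) -> None:
        """Fan-in-scaled uniform init on nonzero mask positions only."""
        fan_in = np.maximum(self.pattern.sum(axis=0), 1)
        bound = 1.0 / np.sqrt(fan_in)  # per-column
        u = rng.uniform(-1.0, 1.0, size=self.W.shape) * bound[None, :]
        free = self.pattern & ~self.frozen
        if self.signed and self.signed_mode == "softplus":
            mag = np.maximum(np.abs(u), 1e-3)
            self.W = np.where(free, _softplus_inv(mag), 0.0)
        else:
            self.W = np.where(free, u, 0.0)
        self.b = np.zeros(self.W.shape[1], dtype=float)

    # -- forward / backward -------------------------------------------------

    def effective_weight(self) -> np.ndarray:
        return effective_weight(
            self.W, self.mask.data, self.frozen if self.frozen.any() else None,
            self.signed_mode,
        )

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
        if x.shape[-1] != self.W.shape[0]:
            raise DimensionError(
                f"layer {self.mask.name}: input width {x.shape[-1]} != "
                f"{self.W.shape[0]}"
            )
        w_eff = self.effective_weight()
        z = x @ w_eff + self.b * self.bias_active
        h = self._act(z)
        return z, h, {"x": x, "z": z, "w_eff": w_eff}

    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "linear":
            return z
        if self.activation == "tanh":
            h = np.tanh(z)
        elif self.activation == "relu":
            h = np.maximum(z, 0.0)
        else:  # pragma: no cover
            raise ConfigError(self.activation)
        if self.linear_cols.any():
            h = np.where(self.linear_cols[None, :], z, h)
        return h

    def _act_deriv(self, z: np.ndarray) -> np.ndarray:
        if self.activation == "linear":
            return np.ones_like(z)
        if self.activation == "tanh":
            d = 1.0 - np.tanh(z) ** 2
        else:
            d = (z > 0).astype(float)
        if self.linear_cols.any():
            d = np.where(self.linear_cols[None, :], 1.0, d)
        return d

    def backward(
        self, dh: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Given dL/dh, return (dL/dx, dL/dW_raw, dL/db)."""
        dz = dh * self._act_deriv(cache["z"])
        db = dz.sum(axis=0) * self.bias_active
        dw_eff = cache["x"].T @ dz
        free = self.pattern & ~self.frozen
        if self.signed and self.signed_mode == "softplus":
            jac = np.sign(self.mask.data) * _sigmoid(self.W)
            dW = np.where(free, dw_eff * jac, 0.0)
        else:
            dW = np.where(free, dw_eff, 0.0)
        dx = dz @ cache["w_eff"].T
        return dx, dW, db

    def tangent(self, u: np.ndarray, cache: dict) -> np.ndarray:
        """Forward-mode: directional derivative of h given that of x."""
        uz = u @ cache["w_eff"]
        return uz * self._act_deriv(cache["z"])


class Head:
    """Affine map from one layer's activations to a scalar logit."""

    def __init__(self, width: int):
        self.w = np.zeros(width, dtype=float)
        self.b = np.zeros(1, dtype=float)

    def initialize(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(max(len(self.w), 1))
        self.w = rng.uniform(-bound, bound, size=len(self.w))
        self.b = np.zeros(1, dtype=float)

    def forward(self, h: np.ndarray) -> np.ndarray:
        return h @ self.w + self.b[0]

    def backward(
        self, ds: np.ndarray, h: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dh = np.outer(ds, self.w)
        dw = h.T @ ds
        db = np.array([ds.sum()])
        return dh, dw, db


def _make_gil_mask(genes: Sequence[str], modalities: Sequence[str]) -> Mask:
    """Block mask collapsing modality channels onto one node per gene."""
    rows = tuple(f"{mod}:{g}" for mod in modalities for g in genes)
    data = np.zeros((len(rows), len(genes)), dtype=np.int8)
    for m_i in range(len(modalities)):
        for g_i in range(len(genes)):
            data[m_i * len(genes) + g_i, g_i] = 1
    return Mask(name="gene_input", data=data, row_index=rows, col_index=tuple(genes))


class SparseNet:
    """Assembled masked network (the trainable ModelSpec).

    Head order: ``gene_input``, then ``regulatory`` when present, then the
    pathway layers bottom-up.  ``head_weights()`` returns the convex
    combination weights applied to the head logits.
    """

    def __init__(
        self,
        masks: MaskStack,
        cfg: ModelConfig,
        modalities: Sequence[str] = ("modality_0",),
    ):
        masks.validate_chaining()
        self.cfg = cfg
        self.modalities = tuple(modalities)
        path_masks = masks.pathway_masks()
        if not path_masks:
            raise ConfigError("mask stack has no pathway masks")
        self.genes = path_masks[0].row_index
        reg_mask = masks.regulatory_mask()
        if cfg.use_regulatory and reg_mask is None:
            raise ConfigError("use_regulatory=True but the stack has no regulatory mask")
        self.masks = masks
        self.gil = MaskedLayer(
            _make_gil_mask(self.genes, self.modalities), cfg.activation
        )
        self.reg = (
            MaskedLayer(
                reg_mask,
                cfg.activation,
                signed_mode=cfg.signed_mode,
                bias_only_on_fed_nodes=True,
            )
            if cfg.use_regulatory and reg_mask is not None
            else None
        )
        self.pathway_layers = [
            MaskedLayer(m, cfg.activation) for m in path_masks
        ]
        self.head_names: tuple[str, ...] = tuple(
            ["gene_input"]
            + (["regulatory"] if self.reg is not None else [])
            + [m.name for m in path_masks]
        )
        widths = {"gene_input": len(self.genes)}
        if self.reg is not None:
            widths["regulatory"] = len(self.genes)
        for m in path_masks:
            widths[m.name] = len(m.col_index)
        self.heads = {name: Head(widths[name]) for name in self.head_names}
        self.alphas = np.zeros(len(self.head_names), dtype=float)
        self.node_index: dict[str, tuple[str, ...]] = {
            "gene_input": self.genes,
            **({"regulatory": self.genes} if self.reg is not None else {}),
            **{m.name: m.col_index for m in path_masks},
        }
        self.initialize(np.random.default_rng(cfg.seed))

    # -- parameters ---------------------------------------------------------

    def initialize(self, rng: np.random.Generator) -> None:
        self.gil.initialize(rng)
        if self.reg is not None:
            self.reg.initialize(rng)
        for lay in self.pathway_layers:
            lay.initialize(rng)
        for name in self.head_names:
            self.heads[name].initialize(rng)
        self.alphas = np.zeros(len(self.head_names), dtype=float)

    def _layers(self) -> dict[str, MaskedLayer]:
        out = {"gene_input": self.gil}
        if self.reg is not None:
            out["regulatory"] = self.reg
        for lay in self.pathway_layers:
            out[lay.mask.name] = lay
        return out

    def param_dict(self) -> dict[str, np.ndarray]:
        """Live parameter arrays keyed by path (views, not copies)."""
        params: dict[str, np.ndarray] = {}
        for lname, lay in self._layers().items():
            params[f"{lname}.W"] = lay.W
            params[f"{lname}.b"] = lay.b
        for name in self.head_names:
            params[f"head.{name}.w"] = self.heads[name].w
            params[f"head.{name}.b"] = self.heads[name].b
        params["alphas"] = self.alphas
        return params

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.param_dict().items()}

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        for lname, lay in self._layers().items():
            lay.W = np.array(state[f"{lname}.W"], dtype=float)
            lay.b = np.array(state[f"{lname}.b"], dtype=float)
        for name in self.head_names:
            self.heads[name].w = np.array(state[f"head.{name}.w"], dtype=float)
            self.heads[name].b = np.atleast_1d(
                np.array(state[f"head.{name}.b"], dtype=float)
            )
        self.alphas = np.array(state["alphas"], dtype=float)

    def head_weights(self) -> np.ndarray:
        if self.cfg.head_weighting == "softmax":
            a = self.alphas - self.alphas.max()
            e = np.exp(a)
            return e / e.sum()
        pos = np.maximum(self.alphas, 0.0)
        total = pos.sum()
        if total <= 0:  # degenerate: fall back to uniform
            return np.full(len(self.alphas), 1.0 / len(self.alphas))
        return pos / total

    # -- forward ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        want = len(self.modalities) * len(self.genes)
        if x.shape[1] != want:
            raise DimensionError(
                f"input width {x.shape[1]} != n_modalities*n_genes = {want}"
            )
        return x

    def _forward_full(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        x = self._check_input(x)
        caches: dict[str, dict] = {}
        outputs: dict[str, np.ndarray] = {}
        _, h_gene, caches["gene_input"] = self.gil.forward(x)
        outputs["gene_input"] = h_gene
        if self.reg is not None:
            _, r, caches["regulatory"] = self.reg.forward(h_gene)
            outputs["regulatory"] = r
            cur = h_gene + r
        else:
            cur = h_gene
        drop_masks: dict[str, np.ndarray] = {}
        p = self.cfg.dropout_rate
        for lay in self.pathway_layers:
            name = lay.mask.name
            _, h, caches[name] = lay.forward(cur)
            if training and p > 0.0 and rng is not None:
                keep = rng.random(h.shape) >= p
                h = h * keep / (1.0 - p)
                drop_masks[name] = keep
            outputs[name] = h
            cur = h
        logits = np.column_stack(
            [self.heads[name].forward(outputs[name]) for name in self.head_names]
        )
        omega = self.head_weights()
        combined = logits @ omega
        return {
            "x": x,
            "caches": caches,
            "outputs": outputs,
            "drop_masks": drop_masks,
            "logits": logits,
            "omega": omega,
            "combined": combined,
        }

    def predict(self, x: np.ndarray) -> BatchPrediction:
        fw = self._forward_full(x, training=False)
        return BatchPrediction(
            per_layer_logits=fw["logits"],
            combined_logit=fw["combined"],
            combined_probability=_sigmoid(fw["combined"]),
            head_names=self.head_names,
            head_weights=fw["omega"],
        )

    # -- backward -----------------------------------------------------------

    def _backward(
        self,
        fw: dict,
        d_logits: np.ndarray,
        d_combined: np.ndarray | None,
        want_param_grads: bool = True,
    ) -> dict:
        """Reverse pass from head-logit seeds.

        ``d_logits`` is samples x heads; ``d_combined`` (samples,) is folded
        into the head seeds through the combination weights and also drives
        the weighting-parameter gradient.  Returns a dict with ``dx``,
        per-output-layer gradients ``d_outputs`` (the total derivative of
        the objective w.r.t. each layer's activations), and parameter
        gradients when requested.
        """
        omega = fw["omega"]
        logits = fw["logits"]
        ds = d_logits.copy()
        d_alpha = np.zeros_like(self.alphas)
        if d_combined is not None:
            ds = ds + d_combined[:, None] * omega[None, :]
            d_omega = logits.T @ d_combined
            if self.cfg.head_weighting == "softmax":
                d_alpha = omega * (d_omega - float(d_omega @ omega))
            else:
                pos = self.alphas > 0
                total = np.maximum(self.alphas, 0.0).sum()
                if total > 0:
                    d_alpha = np.where(
                        pos, (d_omega - float(d_omega @ omega)) / total, 0.0
                    )
        grads: dict[str, np.ndarray] = {}
        d_out: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.head_names):
            dh, dw, db = self.heads[name].backward(ds[:, i], fw["outputs"][name])
            d_out[name] = dh
            if want_param_grads:
                grads[f"head.{name}.w"] = dw
                grads[f"head.{name}.b"] = np.array(db)
        if want_param_grads:
            grads["alphas"] = d_alpha

        p = self.cfg.dropout_rate
        dh_next: np.ndarray | None = None
        for lay in reversed(self.pathway_layers):
            name = lay.mask.name
            dh = d_out.get(name, 0.0)
            if dh_next is not None:
                dh = dh + dh_next
            if name in fw["drop_masks"]:
                dh = dh * fw["drop_masks"][name] / (1.0 - p)
            d_out[name] = dh  # total derivative w.r.t. this layer's output
            dx, dW, db = lay.backward(dh, fw["caches"][name])
            if want_param_grads:
                grads[f"{name}.W"] = dW
                grads[f"{name}.b"] = db
            dh_next = dx

        d_gene_stage = dh_next if dh_next is not None else 0.0
        dh_gene = d_out.get("gene_input", 0.0) + d_gene_stage
        if self.reg is not None:
            dr = d_out.get("regulatory", 0.0) + d_gene_stage
            d_out["regulatory"] = np.asarray(dr) if np.ndim(dr) else dr
            dxr, dWr, dbr = self.reg.backward(dr, fw["caches"]["regulatory"])
            if want_param_grads:
                grads["regulatory.W"] = dWr
                grads["regulatory.b"] = dbr
            dh_gene = dh_gene + dxr
        d_out["gene_input"] = dh_gene
        dx_in, dWg, dbg = self.gil.backward(dh_gene, fw["caches"]["gene_input"])
        if want_param_grads:
            grads["gene_input.W"] = dWg
            grads["gene_input.b"] = dbg
        return {"dx": dx_in, "d_outputs": d_out, "grads": grads}

    # -- losses -------------------------------------------------------------

    def loss_and_grads(
        self,
        x: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        training: bool = True,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean of per-head binary cross-entropies plus the combined-head BCE."""
        y = np.asarray(y, dtype=float).ravel()
        fw = self._forward_full(x, training=training, rng=rng)
        n = len(y)
        if sample_weight is None:
            sw = np.full(n, 1.0 / n)
        else:
            sw = np.asarray(sample_weight, dtype=float)
            sw = sw / sw.sum()
        n_heads = len(self.head_names)
        loss = 0.0
        d_logits = np.zeros_like(fw["logits"])
        for i in range(n_heads):
            s = fw["logits"][:, i]
            loss += float(sw @ _bce(s, y)) / n_heads
            d_logits[:, i] = sw * (_sigmoid(s) - y) / n_heads
        c = fw["combined"]
        loss += float(sw @ _bce(c, y))
        d_combined = sw * (_sigmoid(c) - y)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss; aborting")
        bw = self._backward(fw, d_logits, d_combined)
        return loss, bw["grads"]

    # -- derivatives for attribution -----------------------------------------

    def value_and_input_grad(
        self, x: np.ndarray, target: str = "combined"
    ) -> tuple[np.ndarray, np.ndarray]:
        """Target logit per sample and its gradient w.r.t. the flat input."""
        fw = self._forward_full(x, training=False)
        d_logits = np.zeros_like(fw["logits"])
        d_combined = None
        if target == "combined":
            value = fw["combined"]
            d_combined = np.ones_like(value)
        elif target in self.head_names:
            i = self.head_names.index(target)
            value = fw["logits"][:, i]
            d_logits[:, i] = 1.0
        else:
            raise KeyError(f"unknown attribution target {target!r}")
        bw = self._backward(fw, d_logits, d_combined, want_param_grads=False)
        return value, bw["dx"]

    def layer_grad_and_tangent(
        self,
        x: np.ndarray,
        direction: np.ndarray,
        layer_name: str,
        target: str = "combined",
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """For conductance: (target value, dF/dh_layer, dh_layer/dalpha).

        The tangent is the forward-mode directional derivative of the
        layer's activations along ``direction`` in input space.
        """
        if layer_name not in self.node_index:
            raise KeyError(
                f"unknown layer {layer_name!r}; have {sorted(self.node_index)}"
            )
        fw = self._forward_full(x, training=False)
        d_logits = np.zeros_like(fw["logits"])
        d_combined = None
        if target == "combined":
            value = fw["combined"]
            d_combined = np.ones_like(value)
        elif target in self.head_names:
            i = self.head_names.index(target)
            value = fw["logits"][:, i]
            d_logits[:, i] = 1.0
        else:
            raise KeyError(f"unknown attribution target {target!r}")
        bw = self._backward(fw, d_logits, d_combined, want_param_grads=False)
        g = np.asarray(bw["d_outputs"][layer_name])

        u = np.atleast_2d(np.asarray(direction, dtype=float))
        u_gene = self.gil.tangent(u, fw["caches"]["gene_input"])
        tangents = {"gene_input": u_gene}
        if self.reg is not None:
            u_r = self.reg.tangent(u_gene, fw["caches"]["regulatory"])
            tangents["regulatory"] = u_r
            cur = u_gene + u_r
        else:
            cur = u_gene
        for lay in self.pathway_layers:
            cur = lay.tangent(cur, fw["caches"][lay.mask.name])
            tangents[lay.mask.name] = cur
        return value, g, tangents[layer_name]

    # -- checkpointing ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_mask_stack(self.masks, directory / "masks")
        np.savez(directory / "params.npz", **self.get_state())
        cfg = asdict(self.cfg)
        cfg["modalities"] = list(self.modalities)
        (directory / "config.yaml").write_text(yaml.safe_dump(cfg))

    @classmethod
    def load(cls, directory: str | Path) -> "SparseNet":
        directory = Path(directory)
        raw = yaml.safe_load((directory / "config.yaml").read_text())
        modalities = raw.pop("modalities")
        cfg = ModelConfig(**raw)
        masks = load_mask_stack(directory / "masks")
        net = cls(masks, cfg, modalities=modalities)
        with np.load(directory / "params.npz") as npz:
            net.set_state({k: npz[k] for k in npz.files})
        return net


def _bce(logit: np.ndarray, y: np.ndarray) -> np.ndarray:
    # numerically stable binary cross-entropy from logits
    return np.logaddexp(0.0, logit) - y * logit


def assemble_pnet(
    masks: MaskStack,
    cfg: ModelConfig,
    modalities: Sequence[str] = ("modality_0", "modality_1"),
) -> SparseNet:
    """Build the full network from a knowledge mask stack."""
    return SparseNet(masks, cfg, modalities=modalities)


def forward_predict(model: SparseNet, x: np.ndarray) -> BatchPrediction:
    return model.predict(x)


# ---------------------------------------------------------------------------
# baseline architectures
# ---------------------------------------------------------------------------


def make_random_sparse(masks: MaskStack, seed: int) -> MaskStack:
    """Degree-matched random baseline: same shapes and per-mask nonzero
    counts, positions drawn uniformly without replacement, values permuted."""
    rng = np.random.default_rng(seed)
    out = []
    for m in masks:
        values = m.data[m.data != 0]
        flat = rng.choice(m.data.size, size=len(values), replace=False)
        data = np.zeros(m.data.size, dtype=np.int8)
        data[flat] = rng.permutation(values)
        out.append(
            Mask(
                name=m.name,
                data=data.reshape(m.data.shape),
                row_index=m.row_index,
                col_index=m.col_index,
            )
        )
    return MaskStack(out)


def make_geneset_first_layer(
    sets: GeneMembership,
    reference: MaskStack,
    seed: int,
) -> MaskStack:
    """Gene-set-first baseline: the first hidden layer bundles genes into
    curated sets; later layers are random sparse with per-layer connection
    counts matched to the reference stack."""
    if not sets.member_of:
        raise ValueError("gene sets are empty")
    genes = tuple(sorted(sets.genes))
    set_names = tuple(sorted({s for ss in sets.member_of.values() for s in ss}))
    data = np.zeros((len(genes), len(set_names)), dtype=np.int8)
    spos = {s: j for j, s in enumerate(set_names)}
    for i, g in enumerate(genes):
        for s in sets.member_of[g]:
            data[i, spos[s]] = 1
    masks = [
        Mask(name="pathway_1", data=data, row_index=genes, col_index=set_names)
    ]
    rng = np.random.default_rng(seed)
    ref_chain = reference.pathway_masks()
    prev_cols = set_names
    for k, ref in enumerate(ref_chain[1:], start=2):
        cols = tuple(f"rand{k}_{j}" for j in range(len(ref.col_index)))
        size = len(prev_cols) * len(cols)
        nnz = min(ref.nnz, size)
        flat = rng.choice(size, size=nnz, replace=False)
        d = np.zeros(size, dtype=np.int8)
        d[flat] = 1
        masks.append(
            Mask(
                name=f"pathway_{k}",
                data=d.reshape(len(prev_cols), len(cols)),
                row_index=prev_cols,
                col_index=cols,
            )
        )
        prev_cols = cols
    return MaskStack(masks)
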