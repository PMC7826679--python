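"""The relation-network core: label-wise feature aggregation (LFA),
squeeze-excitation activation/deactivation (ADA), attention-based relation
learning (ARL), feature fusion and the multilabel prediction head.

The pipeline, for a batch of backbone feature maps ``X ∈ R^{N×D×h×w}`` and a
vocabulary of C labels:

1. **LFA** — three conv–norm–ReLU layers (1×1→mid, 3×3→mid, 1×1→C) map X to a
   score map ``S ∈ R^{N×C×h×w}`` with one channel per label, and a spatial
   softmax normalizes each channel to a distribution over the h×w grid,
   giving the aggregated feature ``A``.
2. **ADA** — an SE block: per-channel global average pooling (squeeze), two
   C-dimensional fully connected layers with ReLU then logistic sigmoid
   (excite), and channel reweighting ``Ã_l = A_l · s_l``.
3. **ARL** — each label's channel, flattened to an h·w vector fA_l, attends
   over the other labels' channels with scaled dot-product attention:
   ``wS_ml = ⟨W_K fA_m, W_Q fA_l⟩ / scale`` and
   ``w_ml = softmax_{m≠l}(wS_ml)``, producing the correlation feature
   ``fR_l = Σ_{m≠l} w_ml (W_V fA_m)``.
4. **Fusion + head** — ``fM = Ã + fR``; per-channel spatial average pooling
   gives the logit, and a sigmoid the per-label confidence.

The scale defaults to √d_K (the scaled dot-product attention convention);
``scale="dk"`` divides by d_K instead.  The W_Q/W_K/W_V maps are shared
across query labels by default; ``per_label_params=True`` gives each of the C
relation submodules its own maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, build_backbone, _Backbone
from .nn import Tensor
from .nn.autograd import relu, sigmoid

__all__ = [
    "LFA",
    "SEGate",
    "ARLParams",
    "ARL",
    "FARNet",
    "spatial_softmax",
    "se_squeeze",
    "se_excite",
    "se_reweight",
    "relation_scores",
    "relation_weights",
    "relation_features",
    "fuse",
    "predict_head",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


# ----------------------------------------------------------------------- LFA


class LFA(nn.Module):
    """Label-wise feature aggregation convolutions: D → mid → mid → C.

    Kernel sizes are 1×1, 3×3 (same padding) and 1×1; each layer is followed
    by batch-norm (with affine scale) and ReLU, so spatial size is preserved
    and the last layer has exactly one output channel per label.  ``mid`` is
    1024 in the Inception configuration and scales down for tiny backbones.
    """

    def __init__(
        self,
        in_channels: int,
        n_labels: int,
        mid_channels: int = 1024,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if n_labels < 1:
            raise ValueError("n_labels must be positive")
        self.n_labels = n_labels
        self.block = nn.Sequential(
            nn.ConvBNReLU(in_channels, mid_channels, 1, rng=rng),
            nn.ConvBNReLU(mid_channels, mid_channels, 3, padding=1, rng=rng),
            nn.ConvBNReLU(mid_channels, n_labels, 1, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


def lfa_conv(x, params: LFA) -> Tensor:
    """Apply the LFA conv block; raises on channel mismatch via conv2d."""
    return params(_as_tensor(x))


def spatial_softmax(s) -> Tensor:
    """Normalize each label channel to a distribution over the spatial grid.

    ``A_l(i,j) = exp(S_l(i,j)) / Σ_{i,j} exp(S_l(i,j))`` — every channel of
    the result is nonnegative and sums to one over h×w.
    """
    s = _as_tensor(s)
    if not np.all(np.isfinite(s.data)):
        raise ValueError("spatial_softmax requires finite input")
    shift = Tensor(s.data.max(axis=(-2, -1), keepdims=True))  # constant: softmax shift invariance
    e = (s - shift).exp()
    return e / e.sum(axis=(-2, -1), keepdims=True)


# ----------------------------------------------------------------------- ADA


def se_squeeze(a) -> Tensor:
    """Squeeze: spatial mean of each channel, ``z_l = (1/hw) Σ_{i,j} A_l(i,j)``."""
    return _as_tensor(a).mean(axis=(-2, -1))


class SEGate(nn.Module):
    """Excitation: two C-dimensional FC layers, ReLU inner, sigmoid outer."""

    def __init__(self, n_labels: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.fc1 = nn.Linear(n_labels, n_labels, rng=rng)
        self.fc2 = nn.Linear(n_labels, n_labels, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        return sigmoid(self.fc2(relu(self.fc1(z))))


def se_excite(z, params: SEGate) -> Tensor:
    z = _as_tensor(z)
    n_labels = params.fc1.weight.shape[0]
    if z.shape[-1] != n_labels:
        raise ValueError(f"squeeze vector has length {z.shape[-1]}, gate expects {n_labels}")
    return params(z)


def se_reweight(a, s) -> Tensor:
    """Reweight: scale channel l of A by the scalar gate s_l."""
    a, s = _as_tensor(a), _as_tensor(s)
    if a.shape[-3] != s.shape[-1]:
        raise ValueError(
            f"gate length {s.shape[-1]} does not match channel count {a.shape[-3]}"
        )
    return a * s.reshape(*s.shape, 1, 1)


# ----------------------------------------------------------------------- ARL


@dataclass(frozen=True)
class ARLParams:
    dk: int = 64
    scale: str = "sqrt_dk"  # divide scores by √d_K (default) or by d_K
    per_label_params: bool = False

    def __post_init__(self) -> None:
        if self.dk <= 0:
            raise ValueError(f"d_K must be positive, got {self.dk}")
        if self.scale not in ("sqrt_dk", "dk"):
            raise ValueError("scale must be 'sqrt_dk' or 'dk'")

    @property
    def denominator(self) -> float:
        return float(np.sqrt(self.dk)) if self.scale == "sqrt_dk" else float(self.dk)


class ARL(nn.Module):
    """Attention-based relation learning over the C label channels.

    Each channel is flattened to an h·w vector; W_Q and W_K map h·w → d_K and
    W_V maps h·w → h·w (no biases, as in dot-product attention).  With
    ``per_label_params`` each query label owns its own three maps.
    """

    def __init__(
        self,
        hw: int,
        n_labels: int,
        params: ARLParams = ARLParams(),
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if n_labels < 2:
            raise ValueError("relation learning needs at least 2 labels")
        rng = rng or np.random.default_rng()
        self.hw = hw
        self.n_labels = n_labels
        self.params = params
        if params.per_label_params:
            shape_qk = (n_labels, hw, params.dk)
            shape_v = (n_labels, hw, hw)
        else:
            shape_qk = (hw, params.dk)
            shape_v = (hw, hw)
        # The attended vectors are spatially softmax-normalized maps (unit
        # mass over h·w cells), so their Euclidean norm is well below 1; the
        # query/key maps use unit-std entries to keep the initial dot-product
        # scores at a scale where the softmax over source labels can
        # differentiate, while W_V keeps the 1/√hw fan-in scale so the fused
        # features start commensurate with the gated maps.
        self.w_q = Tensor(rng.normal(0, 1.0, shape_qk), requires_grad=True)
        self.w_k = Tensor(rng.normal(0, 1.0, shape_qk), requires_grad=True)
        self.w_v = Tensor(rng.normal(0, 1.0 / np.sqrt(hw), shape_v), requires_grad=True)

    def forward(self, fa_flat: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """fa_flat (N, C, h·w) → (fR (N, C, h·w), w (N, C, C), wS (N, C, C)).

        Weight matrices are indexed ``[m, l]``: the influence of source label
        m on query label l; each column l sums to 1 over m ≠ l.
        """
        ws = relation_scores(fa_flat, self)
        w = relation_weights(ws)
        fr = relation_features(fa_flat, w, self)
        return fr, w, ws


def relation_scores(fa_flat, arl: ARL) -> Tensor:
    """Raw relevance scores ``wS_ml = ⟨W_K fA_m, W_Q fA_l⟩ / scale``, (N, m, l)."""
    fa = _as_tensor(fa_flat)
    p = arl.params
    if p.per_label_params:
        # (N,1,C_m,hw) @ (C_l,hw,dk) → (N, C_l, C_m, dk)
        k = fa.reshape(fa.shape[0], 1, fa.shape[1], fa.shape[2]) @ arl.w_k
        # (N,C_l,1,hw) @ (C_l,hw,dk) → (N, C_l, 1, dk)
        q = fa.reshape(fa.shape[0], fa.shape[1], 1, fa.shape[2]) @ arl.w_q
        ws_lm = (k * q).sum(axis=-1)  # (N, C_l, C_m)
        ws = ws_lm.transpose(0, 2, 1)
    else:
        k = fa @ arl.w_k  # (N, C, dk)
        q = fa @ arl.w_q
        ws = k @ q.transpose(0, 2, 1)  # (N, m, l)
    return ws * (1.0 / p.denominator)


def relation_weights(ws) -> Tensor:
    """Column-wise softmax over source labels m ≠ l; the diagonal is zero."""
    ws = _as_tensor(ws)
    c = ws.shape[-1]
    if c < 2:
        raise ValueError("relation weights need at least 2 labels")
    if not np.all(np.isfinite(ws.data)):
        raise ValueError("relation scores must be finite")
    off = 1.0 - np.eye(c)
    masked = ws * Tensor(off) + Tensor(-1e30 * np.eye(c))
    shift = Tensor(masked.data.max(axis=-2, keepdims=True))
    e = (masked - shift).exp()
    return e / e.sum(axis=-2, keepdims=True)


def relation_features(fa_flat, w, arl: ARL) -> Tensor:
    """Correlation features ``fR_l = Σ_{m≠l} w_ml · (W_V fA_m)``, (N, C, h·w)."""
    fa = _as_tensor(fa_flat)
    w = _as_tensor(w)
    if arl.params.per_label_params:
        # (N,1,C_m,hw) @ (C_l,hw,hw) → (N, C_l, C_m, hw)
        v = fa.reshape(fa.shape[0], 1, fa.shape[1], fa.shape[2]) @ arl.w_v
        w_lm = w.transpose(0, 2, 1)  # (N, C_l, C_m)
        return (v * w_lm.reshape(*w_lm.shape, 1)).sum(axis=2)
    v = fa @ arl.w_v  # (N, C_m, hw)
    return w.transpose(0, 2, 1) @ v  # (N, C_l, hw)


# --------------------------------------------------------------- fusion/head


def fuse(fa, fr) -> Tensor:
    """Elementwise fusion ``fM = fA + fR``."""
    fa, fr = _as_tensor(fa), _as_tensor(fr)
    if fa.shape != fr.shape:
        raise ValueError(f"cannot fuse shapes {fa.shape} and {fr.shape}")
    return fa + fr


def predict_head(fm) -> tuple[Tensor, Tensor]:
    """Spatial average pooling then sigmoid: returns (logits, confidences)."""
    fm = _as_tensor(fm)
    logits = fm.mean(axis=(-2, -1))
    return logits, sigmoid(logits)


# -------------------------------------------------------------------- FARNet


class FARNet(nn.Module):
    """The assembled relation network: backbone → LFA → ADA → ARL → fuse → head.

    Ablation flags bypass individual blocks: ``without_ada`` sets Ã := A,
    ``without_arl`` sets fM := Ã, and all three flags together reduce the
    model to the plain CNN baseline (backbone + global average pooling +
    C-way linear + sigmoid).  ``without_lfa`` alone is rejected — both ADA and
    ARL operate on label-wise channels, which only LFA provides.
    """

    def __init__(
        self,
        backbone: _Backbone | BackboneConfig,
        n_labels: int = 8,
        lfa_mid: int | None = None,
        arl_params: ARLParams = ARLParams(),
        without_lfa: bool = False,
        without_ada: bool = False,
        without_arl: bool = False,
        seed: int = 0,
    ) -> None:
        super().__init__()
        if without_lfa and not (without_ada and without_arl):
            raise ValueError(
                "without_lfa requires without_ada and without_arl: the ADA and ARL "
                "blocks operate on the label-wise channels produced by LFA"
            )
        rng = np.random.default_rng(seed)
        if isinstance(backbone, BackboneConfig):
            backbone = build_backbone(backbone, rng)
        self.backbone = backbone
        self.n_labels = n_labels
        self.without_lfa = without_lfa
        self.without_ada = without_ada
        self.without_arl = without_arl
        cfg = backbone.config
        h, w = cfg.out_spatial
        self.hw = h * w
        self.out_spatial = (h, w)
        # the backbone's own pooled C-way classifier (the "Linear" stage of the
        # Inception layout): the whole model when LFA/ADA/ARL are all ablated,
        # and the head through which stage-1 backbone fine-tuning runs
        self.baseline_head = nn.Linear(cfg.out_channels, n_labels, rng=rng)
        if without_lfa:
            self.lfa = None
            self.se = None
            self.arl = None
        else:
            mid = lfa_mid if lfa_mid is not None else max(32, cfg.out_channels // 2)
            self.lfa = LFA(cfg.out_channels, n_labels, mid_channels=mid, rng=rng)
            self.se = None if without_ada else SEGate(n_labels, rng=rng)
            self.arl = None if without_arl else ARL(self.hw, n_labels, arl_params, rng=rng)

    # parameter groups for the staged training protocol
    def module_groups(self) -> dict[str, list[Tensor]]:
        groups: dict[str, list[Tensor]] = {
            "backbone": self.backbone.parameters() + self.baseline_head.parameters()
        }
        if self.lfa is not None:
            groups["lfa"] = self.lfa.parameters()
        if self.se is not None:
            groups["ada"] = self.se.parameters()
        if self.arl is not None:
            groups["arl"] = self.arl.parameters()
        return groups

    def forward_baseline(self, images) -> Tensor:
        """Backbone + global average pooling + C-way linear head (logits)."""
        x = self.backbone(images)
        return self.baseline_head(x.mean(axis=(-2, -1)))

    def forward_full(self, images) -> dict[str, Tensor]:
        """Forward pass exposing every intermediate tensor by name."""
        x = self.backbone(images)
        out: dict[str, Tensor] = {"X": x}
        if self.without_lfa:
            logits = self.baseline_head(x.mean(axis=(-2, -1)))
            out["logits"] = logits
            out["confidence"] = sigmoid(logits)
            return out
        s_map = self.lfa(x)
        a = spatial_softmax(s_map)
        out["S"], out["A"] = s_map, a
        if self.without_ada:
            fa = a
        else:
            gate = self.se(se_squeeze(a))
            fa = se_reweight(a, gate)
            out["gate"] = gate
        out["fA"] = fa
        if self.without_arl:
            fm = fa
        else:
            n, c = fa.shape[0], fa.shape[1]
            fa_flat = fa.reshape(n, c, self.hw)
            fr_flat, w, ws = self.arl(fa_flat)
            fr = fr_flat.reshape(n, c, *self.out_spatial)
            fm = fuse(fa, fr)
            out["fR"], out["w"], out["wS"] = fr, w, ws
        out["fM"] = fm
        logits, conf = predict_head(fm)
        out["logits"], out["confidence"] = logits, conf
        return out

    def forward(self, images) -> Tensor:
        return self.forward_full(images)["logits"]

    def predict(self, images, batch_size: int = 32) -> np.ndarray:
        """Per-label confidences in inference mode (deterministic)."""
        was_training = self.training
        self.eval()
        try:
            images = np.asarray(images)
            if images.ndim == 3:
                images = images[None]
            chunks = [
                self.forward_full(images[i : i + batch_size])["confidence"].data
                for i in range(0, len(images), batch_size)
            ]
        finally:
            self.train(was_training)
        return np.concatenate(chunks, axis=0)

    def attention_weights(self, images, batch_size: int = 32) -> np.ndarray:
        """Mean C×C relation-weight matrix (rows m, columns l) over a batch."""
        if self.arl is None:
            raise ValueError("model has no ARL block (ablated)")
        was_training = self.training
        self.eval()
        try:
            images = np.asarray(images)
            if images.ndim == 3:
                images = images[None]
            mats = [
                self.forward_full(images[i : i + batch_size])["w"].data.sum(axis=0)
                for i in range(0, len(images), batch_size)
            ]
        finally:
            self.train(was_training)
        return np.sum(mats, axis=0) / len(images)
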