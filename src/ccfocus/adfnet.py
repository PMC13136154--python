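"""Anatomy-aware dual-stream fusion network.

Two residual CNN streams (one per ultrasound plane) exchange information
mid-network through a Cross-View Feature Interaction Module (CVFIM): each
stream's feature map is residually re-weighted by a sigmoid gate computed
from the *other* stream via an independent 1x1 convolution,

    F'_sag = F_sag + sigmoid(phi_s(F_cor)) * F_sag
    F'_cor = F_cor + sigmoid(phi_c(F_sag)) * F_cor.

After the remaining stages, each stream is globally average-pooled; a gating
network turns the concatenated pooled vectors into a per-case scalar
alpha in (0, 1) — the sagittal contribution coefficient — and the fused
vector alpha * v_sag + (1 - alpha) * v_cor feeds a 512-unit ReLU MLP head
with dropout and a softmax over {normal, agenesis}.

Class imbalance is handled by a class-weighted cross-entropy with
w_agenesis = N_normal / N_agenesis and w_normal = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

LABEL_TO_INDEX = {"normal": 0, "agenesis": 1}
INDEX_TO_LABEL = {v: k for k, v in LABEL_TO_INDEX.items()}

_BACKBONES = {
    # stem_width, stem_stride, stage_widths, stage_blocks, default input size
    "resnet18": dict(stem_width=64, stem_stride=2,
                     stage_widths=(64, 128, 256, 512),
                     stage_blocks=(2, 2, 2, 2), input_size=256),
    "tiny": dict(stem_width=16, stem_stride=2, stage_widths=(16, 32),
                 stage_blocks=(1, 1), input_size=64),
}


@dataclass(frozen=True)
class NetworkConfig:
    backbone: str = "tiny"
    pretrained: bool = False
    cvfim_stage: int | None = None  # default: penultimate stage (3 of 4 for resnet18)
    hidden_units: int = 512
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in _BACKBONES:
            raise ValueError(f"backbone must be one of {sorted(_BACKBONES)}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        n_stages = len(_BACKBONES[self.backbone]["stage_widths"])
        if self.cvfim_stage is not None and not 1 <= self.cvfim_stage <= n_stages:
            raise ValueError(f"cvfim_stage must lie in [1, {n_stages}]")

    @property
    def resolved_cvfim_stage(self) -> int:
        if self.cvfim_stage is not None:
            return self.cvfim_stage
        return max(1, len(_BACKBONES[self.backbone]["stage_widths"]) - 1)

    @property
    def resolved_input_size(self) -> int:
        return self.input_size or _BACKBONES[self.backbone]["input_size"]


@dataclass(frozen=True)
class FusionState:
    """Per-case learned sagittal contribution coefficient."""

    alpha: float

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def axial_weight(self) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class Prediction:
    prob_normal: float
    prob_agenesis: float
    predicted_label: str
    alpha_used: float

    def __post_init__(self):
        if abs(self.prob_normal + self.prob_agenesis - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass(frozen=True)
class ClassWeights:
    w_normal: float = 1.0
    w_agenesis: float = 1.0

    def __post_init__(self):
        if self.w_normal <= 0 or self.w_agenesis <= 0:
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_normal, self.w_agenesis], dtype=np.float64)


def compute_class_weights(n_normal: int, n_agenesis: int) -> ClassWeights:
    """Inverse-frequency weighting: w_agenesis = N_normal / N_agenesis."""
    if n_normal < 1:
        raise ValueError("n_normal must be >= 1")
    if n_agenesis < 1:
        raise ValueError("class weighting undefined with zero agenesis cases")
    return ClassWeights(1.0, n_normal / n_agenesis)


def weighted_ce_loss(probs: np.ndarray, labels: np.ndarray,
                     weights: ClassWeights, eps: float = 1e-12) -> float:
    """Batch class-weighted cross-entropy on softmax probabilities:
    sum_i w_{y_i} (-log p_{i,y_i}) / sum_i w_{y_i}."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels length mismatch")
    w = weights.as_array()[labels]
    py = np.clip(probs[np.arange(len(labels)), labels], eps, None)
    return float((-w * np.log(py)).sum() / w.sum())


class CVFIM(nn.Module):
    """Cross-view gating applied symmetrically with independent 1x1 convs.

    With `disabled=True` both gates are frozen at 0.5, so the residual form
    scales each feature map by exactly 1.5 — the ablation hook.
    """

    def __init__(self, rng, channels: int, disabled: bool = False):
        super().__init__()
        self.phi_sag = nn.Conv2d(rng, channels, channels, kernel=1, pad=0)
        self.phi_cor = nn.Conv2d(rng, channels, channels, kernel=1, pad=0)
        self.disabled = disabled

    def __call__(self, f_sag: Tensor, f_cor: Tensor) -> tuple[Tensor, Tensor]:
        if f_sag.shape != f_cor.shape:
            raise ValueError(f"feature shape mismatch {f_sag.shape} vs {f_cor.shape}")
        if self.disabled:
            half = np.full(f_sag.shape, 0.5, dtype=nn.DTYPE)
            return f_sag + f_sag * half, f_cor + f_cor * half
        gate_sag = nn.sigmoid(self.phi_sag(f_cor))
        gate_cor = nn.sigmoid(self.phi_cor(f_sag))
        return f_sag + gate_sag * f_sag, f_cor + gate_cor * f_cor


def fuse(v_sag: Tensor | np.ndarray, v_cor: Tensor | np.ndarray, alpha):
    """Convex combination alpha * v_sag + (1 - alpha) * v_cor.

    alpha may be a FusionState, a scalar, or an (N, 1) Tensor from the
    gating network (scalar per case, broadcast over channels).
    """
    if isinstance(alpha, FusionState):
        alpha = alpha.alpha
    v_sag_arr = v_sag.data if isinstance(v_sag, Tensor) else np.asarray(v_sag)
    v_cor_arr = v_cor.data if isinstance(v_cor, Tensor) else np.asarray(v_cor)
    if v_sag_arr.shape[-1] != v_cor_arr.shape[-1]:
        raise ValueError("pooled vectors must share length")
    if isinstance(alpha, Tensor):
        one_minus = (alpha * (-1.0)) + 1.0
        return v_sag * alpha + v_cor * one_minus
    if not 0.0 <= float(alpha) <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if isinstance(v_sag, Tensor) or isinstance(v_cor, Tensor):
        v_sag = v_sag if isinstance(v_sag, Tensor) else Tensor(v_sag)
        v_cor = v_cor if isinstance(v_cor, Tensor) else Tensor(v_cor)
        return v_sag * float(alpha) + v_cor * (1.0 - float(alpha))
    return float(alpha) * v_sag_arr + (1.0 - float(alpha)) * v_cor_arr


class ADFNet(nn.Module):
    """The dual-stream classifier. Label indices: 0 = normal, 1 = agenesis."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        self.config = config or NetworkConfig()
        if self.config.pretrained:
            raise NotImplementedError(
                "pretrained initialization requires a user-supplied weight "
                "file (no download hook in this environment); load one via "
                "load_state_dict instead")
        spec = _BACKBONES[self.config.backbone]
        rng = np.random.default_rng(self.config.seed)
        self.stream_sag = nn.ResidualBackbone(
            rng, in_ch=1, stem_width=spec["stem_width"],
            stem_stride=spec["stem_stride"], stage_widths=spec["stage_widths"],
            stage_blocks=spec["stage_blocks"])
        self.stream_cor = nn.ResidualBackbone(
            rng, in_ch=1, stem_width=spec["stem_width"],
            stem_stride=spec["stem_stride"], stage_widths=spec["stage_widths"],
            stage_blocks=spec["stage_blocks"])
        cvfim_channels = spec["stage_widths"][self.config.resolved_cvfim_stage - 1]
        self.cvfim = CVFIM(rng, cvfim_channels)
        out_ch = self.stream_sag.out_channels
        self.gate = nn.Linear(rng, 2 * out_ch, 1)
        self.fc1 = nn.Linear(rng, out_ch, self.config.hidden_units)
        self.dropout = nn.Dropout(self.config.dropout_rate)
        self.fc2 = nn.Linear(rng, self.config.hidden_units, self.config.n_classes)

    # -- forward ------------------------------------------------------------
    def compute_alpha(self, v_sag: Tensor, v_cor: Tensor) -> Tensor:
        """alpha = sigmoid(linear([v_sag ; v_cor])), shape (N, 1).

        The output is nudged just inside (0, 1): float32 sigmoid saturates
        to exactly 0/1 for large logits, which would break the strict-
        interior contract of the fusion coefficient.
        """
        alpha = nn.sigmoid(self.gate(nn.concat([v_sag, v_cor], axis=1)))
        eps = np.float32(1e-6)
        alpha.data = np.clip(alpha.data, eps, np.float32(1.0) - eps)
        return alpha

    def forward(self, x_sag, x_cor, rng: np.random.Generator | None = None,
                capture: dict | None = None) -> Tensor:
        """Returns the (N, n_classes) logits tensor.

        x_sag/x_cor: (N, H, W) or (N, 1, H, W) arrays on the [0, 255] scale;
        inputs are scaled to [0, 1] internally. `capture`, when given, is
        filled with intermediate tensors (final per-stream feature maps with
        retained gradients, pooled vectors, alpha) for Grad-CAM++ and for
        the alpha diagnostics.
        """
        f_sag = Tensor(self._prep(x_sag))
        f_cor = Tensor(self._prep(x_cor))
        h_sag = self.stream_sag.forward_stem(f_sag)
        h_cor = self.stream_cor.forward_stem(f_cor)
        k = self.config.resolved_cvfim_stage
        for stage in range(1, self.stream_sag.n_stages + 1):
            h_sag = self.stream_sag.forward_stage(h_sag, stage)
            h_cor = self.stream_cor.forward_stage(h_cor, stage)
            if stage == k:
                h_sag, h_cor = self.cvfim(h_sag, h_cor)
        if capture is not None:
            h_sag.retain_grad()
            h_cor.retain_grad()
            capture["feature_sagittal"] = h_sag
            capture["feature_axial"] = h_cor
        v_sag = nn.gap(h_sag)
        v_cor = nn.gap(h_cor)
        alpha = self.compute_alpha(v_sag, v_cor)
        fused = fuse(v_sag, v_cor, alpha)
        hidden = nn.relu(self.fc1(fused))
        hidden = self.dropout(hidden, rng)
        logits = self.fc2(hidden)
        if capture is not None:
            capture["alpha"] = alpha.data[:, 0].copy()
            capture["v_sagittal"] = v_sag
            capture["v_axial"] = v_cor
            capture["logits"] = logits
        return logits

    @staticmethod
    def _prep(x) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, H, W) or (N, 1, H, W), got {x.shape}")
        return x / 255.0

    def predict(self, x_sag, x_cor) -> list[Prediction]:
        """Eval-mode forward returning Prediction objects."""
        was_training = self.training
        self.eval()
        try:
            capture: dict = {}
            logits = self.forward(x_sag, x_cor, capture=capture)
            probs = nn.softmax(logits.data.astype(np.float64))
            alphas = capture["alpha"]
        finally:
            if was_training:
                self.train()
        out = []
        for p, a in zip(probs, alphas):
            idx = int(np.argmax(p))
            out.append(Prediction(prob_normal=float(p[0]),
                                  prob_agenesis=float(p[1]),
                                  predicted_label=INDEX_TO_LABEL[idx],
                                  alpha_used=float(a)))
        return out

    def cross_view_covariance(self, x_sag, x_cor) -> np.ndarray:
        """Diagnostic only: channel-wise covariance between the two pooled
        feature vectors over a batch (reported, never used in the forward
        pass — the gating equation is the authoritative mechanism)."""
        capture: dict = {}
        was_training = self.training
        self.eval()
        try:
            self.forward(x_sag, x_cor, capture=capture)
        finally:
            if was_training:
                self.train()
        vs = capture["v_sagittal"].data
        vc = capture["v_axial"].data
        vs = vs - vs.mean(axis=0, keepdims=True)
        vc = vc - vc.mean(axis=0, keepdims=True)
        return (vs.T @ vc) / max(1, vs.shape[0] - 1)
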