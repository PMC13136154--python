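"""Grad-CAM++ attribution, heatmap banding, and overlays.

The class activation map is computed per view over the stream's final
convolutional stage (pre-pooling, post cross-view interaction), then
rectified, bilinearly upsampled to the classifier input size, and min-max
normalized to the [0, 255] signal scale. Banding thresholds follow the
reported reading of those signal values: >220 decisive, 200-220 high,
100-200 perceptible, <80 background, with the unassigned [80, 100) gap kept
as a distinct "low" band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from . import nn
from .adfnet import ADFNet, LABEL_TO_INDEX

BANDS = ("background", "low", "perceptible", "high", "decisive")


@dataclass
class Heatmap:
    values: np.ndarray  # 2D, [0, 255]
    view: str
    target_class: str
    layer_name: str


def gradcam_pp_combine(activation: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """Grad-CAM++ channel weighting from first/second/third-order gradient
    terms of the class score w.r.t. a (C, H, W) activation.

    With dY/dA = g, the pixel weights are a = g^2 / (2 g^2 + sum(A) g^3)
    (zero where the denominator vanishes), the channel weights
    w_c = sum_ij a_ij relu(g_ij), and the map relu(sum_c w_c A_c).
    """
    a = np.asarray(activation, dtype=np.float64)
    g = np.asarray(grads, dtype=np.float64)
    if a.shape != g.shape or a.ndim != 3:
        raise ValueError("activation/gradient must both be (C, H, W)")
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + np.sum(a, axis=(1, 2), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1, denom), 0.0)
    weights = np.sum(alpha * np.maximum(g, 0.0), axis=(1, 2))
    cam = np.maximum(np.tensordot(weights, a, axes=(0, 0)), 0.0)
    return cam


def _normalize_255(cam: np.ndarray) -> np.ndarray:
    peak = cam.max()
    if peak <= 0:
        return np.zeros_like(cam)
    return cam * (255.0 / peak)


def grad_cam_pp(model: ADFNet, x_sag: np.ndarray, x_cor: np.ndarray,
                target_class: str | int | None = None,
                layer: str = "final") -> dict[str, Heatmap]:
    """Grad-CAM++ heatmaps for one case pair, one per view.

    target_class defaults to the predicted class. Only the streams' final
    convolutional stage is exposed ("final"); asking for another layer is an
    error. Returns maps upsampled to the input image size, normalized so the
    peak is 255 (an identically-zero rectified map stays all zero).
    """
    if layer != "final":
        raise ValueError(f"unknown attribution layer {layer!r}; only 'final' "
                         "(last convolutional stage per stream) is exposed")
    x_sag = np.asarray(x_sag, dtype=np.float32)
    x_cor = np.asarray(x_cor, dtype=np.float32)
    model.eval()
    capture: dict = {}
    logits = model.forward(x_sag[None], x_cor[None], capture=capture)
    probs = nn.softmax(logits.data.astype(np.float64))[0]
    if target_class is None:
        cls = int(probs.argmax())
    elif isinstance(target_class, str):
        cls = LABEL_TO_INDEX[target_class]
    else:
        cls = int(target_class)
    mask = np.zeros_like(logits.data)
    mask[:, cls] = 1.0
    score = nn.tsum(logits * mask)
    score.backward()
    class_name = {v: k for k, v in LABEL_TO_INDEX.items()}[cls]
    out = {}
    for view, key, img in (("sagittal", "feature_sagittal", x_sag),
                           ("axial", "feature_axial", x_cor)):
        feat = capture[key]
        cam = gradcam_pp_combine(feat.data[0], feat.grad[0])
        cam = sktransform.resize(cam, img.shape[:2], order=1,
                                 preserve_range=True)
        cam = np.maximum(cam, 0.0)
        out[view] = Heatmap(values=_normalize_255(cam), view=view,
                            target_class=class_name, layer_name="final")
    return out


def band(heatmap: Heatmap | np.ndarray) -> np.ndarray:
    """Per-pixel intensity band of a normalized heatmap.

    decisive > 220 >= high > 200 >= perceptible >= 100 > low >= 80 >
    background; returned as a string array over BANDS.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    out = np.full(values.shape, "background", dtype=object)
    out[(values >= 80) & (values < 100)] = "low"
    out[(values >= 100) & (values <= 200)] = "perceptible"
    out[(values > 200) & (values <= 220)] = "high"
    out[values > 220] = "decisive"
    return out


def band_fractions(heatmap: Heatmap | np.ndarray) -> dict[str, float]:
    b = band(heatmap)
    n = b.size
    return {name: float((b == name).sum()) / n for name in BANDS}


def overlay(heatmap: Heatmap | np.ndarray, image: np.ndarray,
            alpha: float = 0.4) -> np.ndarray:
    """Jet-colorized heatmap alpha-blended over the grayscale image (uint8 RGB)."""
    from matplotlib import colormaps

    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    image = np.asarray(image, dtype=np.float64)
    if values.shape != image.shape:
        raise ValueError("heatmap and image shapes must match")
    gray = np.clip(image, 0, 255) / 255.0
    base = np.stack([gray] * 3, axis=-1)
    colored = colormaps["jet"](np.clip(values, 0, 255) / 255.0)[..., :3]
    weight = alpha * (values > 0)[..., None]
    blended = base * (1.0 - weight) + colored * weight
    return (np.clip(blended, 0, 1) * 255).astype(np.uint8)


def top_decile_mass_in_regions(heatmap: Heatmap | np.ndarray,
                               region_masks: list[np.ndarray],
                               dilation_px: int = 5) -> float:
    """Fraction of the top-decile heatmap pixels inside the union of the
    given ground-truth regions, each dilated by `dilation_px`."""
    from scipy import ndimage

    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    union = np.zeros(values.shape, dtype=bool)
    struct = np.ones((2 * dilation_px + 1, 2 * dilation_px + 1), dtype=bool)
    for m in region_masks:
        union |= ndimage.binary_dilation(np.asarray(m, dtype=bool), struct)
    cutoff = np.quantile(values, 0.9)
    top = (values >= cutoff) & (values > 0)  # zero background never counts
    if top.sum() == 0:
        return 0.0
    return float((top & union).sum() / top.sum())
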