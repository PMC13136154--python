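"""Preprocessing: pose canonicalization, homomorphic speckle filtering,
aspect-preserving letterbox resize, training augmentation and TTA variants.

The canonicalization estimates a similarity transform from the bright skull
outline (largest connected bright component after light smoothing) via image
moments: centroid -> image center, major axis -> horizontal, major-axis
half-length -> a fixed target. Since the sagittal and axial planes are
orthogonal anatomical sections, "alignment across views" is realized as
per-view canonicalization to this shared frame convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage import transform as sktransform

from .roi import BoundingBox


class DetectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix mapping input (x, y, 1) pixel coordinates to output."""

    matrix: tuple  # ((a, b, tx), (c, d, ty))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def from_skimage(cls, tform: sktransform.ProjectiveTransform):
        m = np.asarray(tform.params, dtype=float)
        return cls(matrix=tuple(map(tuple, m[:2])))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def to_skimage(self) -> sktransform.AffineTransform:
        m = np.vstack([self.as_array(), [0.0, 0.0, 1.0]])
        return sktransform.AffineTransform(matrix=m)

    @property
    def rotation_deg(self) -> float:
        m = self.as_array()
        return float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        m = self.as_array()
        return pts @ m[:, :2].T + m[:, 2]

    def apply_to_image(self, image: np.ndarray, cval: float = 0.0) -> np.ndarray:
        tform = self.to_skimage()
        out = sktransform.warp(np.asarray(image, dtype=np.float64),
                               tform.inverse, order=1,
                               preserve_range=True, cval=cval)
        return out.astype(np.float32)

    def apply_to_box(self, box: BoundingBox,
                     image_shape: tuple[int, int]) -> BoundingBox | None:
        corners = np.array([[box.x_min, box.y_min], [box.x_max, box.y_min],
                            [box.x_min, box.y_max], [box.x_max, box.y_max]],
                           dtype=float)
        warped = self.apply_to_points(corners)
        h, w = image_shape[:2]
        x0 = int(np.clip(np.floor(warped[:, 0].min()), 0, w - 1))
        y0 = int(np.clip(np.floor(warped[:, 1].min()), 0, h - 1))
        x1 = int(np.clip(np.ceil(warped[:, 0].max()), x0 + 1, w))
        y1 = int(np.clip(np.ceil(warped[:, 1].max()), y0 + 1, h))
        return BoundingBox(x0, y0, x1, y1)


@dataclass(frozen=True)
class AugmentationParams:
    """Training/TTA augmentation strengths."""

    rotation_limit_deg: float = 15.0
    brightness_limit_frac: float = 0.10
    elastic_sigma: float = 8.0
    elastic_alpha: float = 32.0

    def __post_init__(self):
        if self.rotation_limit_deg < 0 or self.brightness_limit_frac < 0 \
                or self.elastic_alpha < 0:
            raise ValueError("augmentation limits must be >= 0")
        if self.elastic_sigma <= 0:
            raise ValueError("elastic_sigma must be > 0")


# ---------------------------------------------------------------------------

def homomorphic_filter(image: np.ndarray, low_gain: float = 0.5,
                       high_gain: float = 1.5, cutoff: float = 0.1,
                       eps: float = 1.0) -> np.ndarray:
    """Homomorphic speckle suppression.

    Works in the log domain, where multiplicative speckle becomes additive
    broadband noise: frequencies are weighted by a Gaussian transfer function
    that keeps full gain at DC and rolls off to low_gain/high_gain at high
    spatial frequency (cutoff is the Gaussian scale as a fraction of
    Nyquist). The filter is normalized to unit DC gain so overall brightness
    is preserved; output is clipped to [0, 255].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if not (low_gain <= 1.0 <= high_gain):
        raise ValueError("require low_gain <= 1 <= high_gain")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    log_img = np.log(image + eps)
    fy = np.fft.fftfreq(image.shape[0]) * 2.0  # Nyquist -> 1
    fx = np.fft.fftfreq(image.shape[1]) * 2.0
    d2 = fy[:, None] ** 2 + fx[None, :] ** 2
    h = low_gain + (high_gain - low_gain) * np.exp(-d2 / (2.0 * cutoff ** 2))
    h /= h[0, 0]  # unit DC gain: brightness-preserving
    filtered = np.fft.ifft2(np.fft.fft2(log_img) * h).real
    out = np.exp(filtered) - eps
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def estimate_canonical_transform(image: np.ndarray, threshold: float = 170.0,
                                 target_halfwidth: float = 107.0,
                                 smoothing_sigma: float = 1.5) -> AffineTransform:
    """Similarity transform mapping the detected skull outline to the
    canonical frame (centered, major axis horizontal, fixed half-width).

    The outline is the largest connected bright component after Gaussian
    smoothing; an algebraic ellipse fit to its pixels gives center,
    orientation and semi-major axis (sub-pixel / sub-degree on phantoms).
    The default target half-width matches what the fit reports for the
    default phantom skull in canonical pose, so the canonical-pose transform
    is the identity up to estimation noise.
    """
    image = np.asarray(image, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(image, smoothing_sigma)
    mask = smoothed >= threshold
    if not mask.any():
        raise DetectionError(
            f"no bright outline found at threshold {threshold}")
    labels = measure.label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    component = labels == counts.argmax()
    ys, xs = np.nonzero(component)
    if xs.size < 50:
        raise DetectionError(
            f"bright component too small at threshold {threshold}")
    fit = measure.EllipseModel.from_estimate(
        np.column_stack([xs, ys]).astype(float))
    if not fit:
        raise DetectionError(
            f"ellipse fit failed on outline at threshold {threshold}")
    mx, my = fit.center
    a_est, b_est = fit.axis_lengths
    theta = fit.theta
    if b_est > a_est:
        a_est, b_est = b_est, a_est
        theta += np.pi / 2.0
    theta = (theta + np.pi / 2.0) % np.pi - np.pi / 2.0  # wrap to (-90, 90]
    scale = target_halfwidth / a_est
    h, w = image.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    tform = (sktransform.SimilarityTransform(translation=(-mx, -my))
             + sktransform.SimilarityTransform(rotation=-theta, scale=scale)
             + sktransform.SimilarityTransform(translation=(cx, cy)))
    return AffineTransform.from_skimage(tform)


def resize_letterbox(image: np.ndarray, target: int = 256) -> np.ndarray:
    """Aspect-preserving resize into a target x target frame, zero-padded."""
    image = np.asarray(image, dtype=np.float32)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    if (h, w) == (target, target):
        return image.copy()
    scale = min(target / h, target / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    nh, nw = max(1, nh), max(1, nw)
    content = sktransform.resize(image.astype(np.float64), (nh, nw), order=1,
                                 preserve_range=True,
                                 anti_aliasing=scale < 1.0)
    out = np.zeros((target, target), dtype=np.float32)
    top, left = (target - nh) // 2, (target - nw) // 2
    out[top:top + nh, left:left + nw] = content
    return out


def draw_augmentation(params: AugmentationParams, rng: np.random.Generator,
                      shape: tuple[int, int]) -> dict:
    """Sample one augmentation realization (shared across paired views)."""
    angle = float(rng.uniform(-params.rotation_limit_deg,
                              params.rotation_limit_deg))
    factor = float(rng.uniform(1.0 - params.brightness_limit_frac,
                               1.0 + params.brightness_limit_frac))
    field = None
    if params.elastic_alpha > 0:
        noise_x = rng.uniform(-1.0, 1.0, size=shape)
        noise_y = rng.uniform(-1.0, 1.0, size=shape)
        dx = params.elastic_alpha * ndimage.gaussian_filter(
            noise_x, params.elastic_sigma, mode="reflect")
        dy = params.elastic_alpha * ndimage.gaussian_filter(
            noise_y, params.elastic_sigma, mode="reflect")
        field = (dy, dx)
    return {"angle_deg": angle, "brightness": factor, "elastic_field": field}


def apply_augmentation(image: np.ndarray, draws: dict) -> np.ndarray:
    """Rotation -> brightness -> elastic deformation, in that order."""
    out = np.asarray(image, dtype=np.float64)
    if draws["angle_deg"] != 0.0:
        out = sktransform.rotate(out, draws["angle_deg"], order=1,
                                 mode="constant", cval=0.0,
                                 preserve_range=True)
    if draws["brightness"] != 1.0:
        out = np.clip(out * draws["brightness"], 0.0, 255.0)
    if draws["elastic_field"] is not None:
        dy, dx = draws["elastic_field"]
        yy, xx = np.meshgrid(np.arange(out.shape[0]), np.arange(out.shape[1]),
                             indexing="ij")
        out = ndimage.map_coordinates(out, [yy + dy, xx + dx], order=1,
                                      mode="constant", cval=0.0)
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def augment(image: np.ndarray, params: AugmentationParams,
            rng: np.random.Generator) -> np.ndarray:
    draws = draw_augmentation(params, rng, np.asarray(image).shape[:2])
    return apply_augmentation(image, draws)


def make_tta_variants(image: np.ndarray, k: int = 5,
                      params: AugmentationParams | None = None,
                      rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """k augmented copies for test-time augmentation; input left untouched."""
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or AugmentationParams()
    rng = rng or np.random.default_rng(0)
    source = np.asarray(image)
    return [augment(source, params, rng) for _ in range(k)]


def preprocess_image(image: np.ndarray, target: int = 256,
                     filter_kwargs: dict | None = None,
                     threshold: float = 170.0,
                     adaptive: bool = True) -> tuple[np.ndarray, AffineTransform]:
    """Canonicalize -> homomorphic filter -> letterbox resize.

    "Adaptive" filtering scales the filter cutoff with the detected outline
    size, so apparent speckle grain (which scales with the rendered zoom) is
    suppressed at a matched spatial frequency.
    """
    tform = estimate_canonical_transform(image, threshold=threshold)
    canonical = tform.apply_to_image(image)
    kwargs = dict(filter_kwargs or {})
    if adaptive and "cutoff" not in kwargs:
        m = tform.as_array()
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        kwargs["cutoff"] = float(np.clip(0.1 * scale, 0.02, 0.5))
    filtered = homomorphic_filter(canonical, **kwargs)
    return resize_letterbox(filtered, target), tform


def preprocess_case(case, target: int = 256, threshold: float = 170.0,
                    filter_kwargs: dict | None = None):
    """Return a canonicalized copy of a CasePair with gt boxes mapped into
    the canonical frame (letterbox resize is the identity for same-size
    frames, so boxes only need the similarity transform)."""
    from .phantom import CasePair, _mask_bbox  # local import to avoid a cycle

    images, boxes = {}, {}
    for view in ("sagittal", "axial"):
        img = case.image(view)
        out, tform = preprocess_image(img, target=target, threshold=threshold,
                                      filter_kwargs=filter_kwargs)
        images[view] = out
        view_masks = (case.masks or {}).get(view)
        if view_masks:
            # exact: warp the structure masks and take tight bounds
            skt = tform.to_skimage()
            warped = {name: sktransform.warp(m.astype(np.float64), skt.inverse,
                                             order=0, preserve_range=True,
                                             output_shape=out.shape) > 0.5
                      for name, m in view_masks.items()}
            boxes[view] = {name: bb for name, m in warped.items()
                           if (bb := _mask_bbox(m)) is not None}
        else:
            # approximate: enclosing box of the transformed box corners
            boxes[view] = {name: tb
                           for name, bb in case.gt_boxes.get(view, {}).items()
                           if (tb := tform.apply_to_box(bb, out.shape)) is not None}
    return CasePair(case_id=case.case_id, sagittal_image=images["sagittal"],
                    axial_image=images["axial"], label=case.label,
                    gt_boxes=boxes,
                    provenance={**case.provenance, "preprocessed": True})
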