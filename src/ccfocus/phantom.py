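"""Seeded synthetic fetal cranial ultrasound phantoms.

Renders paired sagittal/axial B-mode-like frames of the fetal head with the
landmarks a corpus-callosum (CC) screen relies on: a bright skull ellipse, a
bright midline falx, the thin hypoechoic CC arch with the cavum septi
pellucidi beneath it, and the lateral ventricles. In agenesis cases the CC
arch is omitted, the third ventricle is displaced upward and rendered as a
hyperechoic triangle, and the lateral ventricles are dilated by a fixed
factor — the indirect signs a sonographer (and the classifier) keys on.

Speckle is modelled as multiplicative gamma noise with `speckle_looks`
playing the role of the number of incoherently averaged looks, the standard
fully-developed-speckle statistic for B-mode amplitude images. Each case is
drawn in a canonical pose and then perturbed by a small random similarity
transform per view, so the alignment stage of the preprocessing pipeline has
genuine work to do. Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw
from skimage import transform as sktransform

from .roi import BoundingBox

NORMAL = "normal"
AGENESIS = "agenesis"
LABELS = (NORMAL, AGENESIS)

# structure keys used in gt_boxes
CC = "cc"
CAVUM = "cavum_septi_pellucidi"
VENTRICLE = "lateral_ventricle_anterior_horn"
THIRD_VENTRICLE = "third_ventricle"


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise parameters of the phantom, in pixels/degrees.

    Intensities are on the 8-bit [0, 255] scale. Defaults satisfy
    cc_band_intensity < parenchyma_intensity < falx_intensity and keep every
    primitive inside the image.
    """

    image_height: int = 256
    image_width: int = 256
    speckle_looks: int = 16

    background_intensity: float = 12.0
    parenchyma_intensity: float = 120.0

    skull_center: tuple[float, float] = (128.0, 128.0)  # (x, y)
    skull_axes: tuple[float, float] = (105.0, 82.0)     # semi-axes (x, y)
    skull_angle_deg: float = 0.0
    skull_thickness: float = 5.0
    skull_intensity: float = 230.0

    falx_intensity: float = 240.0

    cc_center: tuple[float, float] = (128.0, 118.0)
    cc_axes: tuple[float, float] = (45.0, 30.0)
    cc_thickness: float = 6.0
    cc_intensity: float = 55.0

    cavum_axes: tuple[float, float] = (14.0, 7.0)
    cavum_intensity: float = 45.0

    ventricle_lumen_intensity: float = 40.0
    ventricle_wall_intensity: float = 185.0
    ventricle_dilation_factor: float = 1.5
    third_ventricle_shift: float = 25.0

    prevalence: float = 0.1
    pose_rotation_deg: float = 10.0   # max |rotation| of the per-view pose jitter
    pose_translation_px: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be a positive integer")
        if not (self.cc_intensity < self.parenchyma_intensity < self.falx_intensity):
            raise ValueError("require cc intensity < parenchyma < falx intensity")
        if self.ventricle_dilation_factor < 1.0:
            raise ValueError("ventricle_dilation_factor must be >= 1")
        cx, cy = self.skull_center
        ax, ay = self.skull_axes
        margin = self.skull_thickness + 1
        if (cx - ax - margin < 0 or cx + ax + margin > self.image_width
                or cy - ay - margin < 0 or cy + ay + margin > self.image_height):
            raise ValueError("skull ellipse (plus outline) exceeds image bounds")


@dataclass
class CasePair:
    """One case: paired sagittal/axial frames, label, and ground truth."""

    case_id: str
    sagittal_image: np.ndarray
    axial_image: np.ndarray
    label: str
    gt_boxes: dict[str, dict[str, BoundingBox]]
    provenance: dict = field(default_factory=dict)
    #: per-view structure masks (kept in memory only, not serialized); they
    #: let downstream stages recompute tight boxes after further warps
    masks: dict[str, dict[str, np.ndarray]] | None = None

    def image(self, view: str) -> np.ndarray:
        if view == "sagittal":
            return self.sagittal_image
        if view == "axial":
            return self.axial_image
        raise KeyError(f"unknown view {view!r}")


# ---------------------------------------------------------------------------
# drawing helpers (all operate on float images, y = rows, x = cols)

def _filled_ellipse(shape, center_xy, axes_xy, angle_deg=0.0):
    cx, cy = center_xy
    ax, ay = axes_xy
    rr, cc = skdraw.ellipse(cy, cx, ay, ax, shape=shape,
                            rotation=np.deg2rad(angle_deg))
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _ellipse_ring(shape, center_xy, axes_xy, thickness, angle_deg=0.0):
    outer = _filled_ellipse(shape, center_xy,
                            (axes_xy[0] + thickness, axes_xy[1] + thickness),
                            angle_deg)
    inner = _filled_ellipse(shape, center_xy, axes_xy, angle_deg)
    return outer & ~inner


def _triangle(shape, apex_xy, half_base, height):
    ax, ay = apex_xy
    rows = np.array([ay, ay + height, ay + height])
    cols = np.array([ax, ax - half_base, ax + half_base])
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def render_canonical(config: PhantomConfig, view: str, label: str):
    """Noise-free anatomy in canonical pose.

    Returns (image, masks) where masks maps structure name -> boolean mask.
    The axial rendering reuses the same latent geometry but lays the
    ventricular system out prominently and replaces the sagittal falx arc
    with the straight interhemispheric midline echo.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    shape = (config.image_height, config.image_width)
    cx, cy = config.skull_center
    img = np.full(shape, config.background_intensity, dtype=np.float64)
    masks: dict[str, np.ndarray] = {}

    brain = _filled_ellipse(shape, (cx, cy), config.skull_axes,
                            config.skull_angle_deg)
    img[brain] = config.parenchyma_intensity
    skull = _ellipse_ring(shape, (cx, cy), config.skull_axes,
                          config.skull_thickness, config.skull_angle_deg)
    img[skull] = config.skull_intensity

    dil = config.ventricle_dilation_factor if label == AGENESIS else 1.0

    if view == "sagittal":
        # falx: bright arc dorsal to the CC
        falx = _ellipse_ring(shape, (cx, cy), (78.0, 60.0), 3.0)
        yy = np.arange(shape[0])[:, None]
        falx &= yy < (cy - 20)
        img[falx] = config.falx_intensity

        # lateral ventricle (posterior horn region): dark lumen, bright wall
        v_axes = (22.0 * dil, 9.0 * dil)
        v_center = (cx + 42, cy - 23)
        v_lumen = _filled_ellipse(shape, v_center, v_axes, angle_deg=-25.0)
        v_wall = _ellipse_ring(shape, v_center, v_axes, 3.0, angle_deg=-25.0)
        img[v_lumen] = config.ventricle_lumen_intensity
        img[v_wall] = config.ventricle_wall_intensity
        masks[VENTRICLE] = v_lumen | v_wall

        if label == NORMAL:
            # the CC arch: thin hypoechoic band under the falx
            arch = _ellipse_ring(shape, config.cc_center, config.cc_axes,
                                 config.cc_thickness)
            arch &= yy <= config.cc_center[1]
            img[arch] = config.cc_intensity
            masks[CC] = arch

        # cavum septi pellucidi below the CC position
        cav = _filled_ellipse(shape, (cx, config.cc_center[1] + 18),
                              config.cavum_axes)
        img[cav] = config.cavum_intensity
        masks[CAVUM] = cav

        # third ventricle: inconspicuous dark slit when the CC is present;
        # in agenesis it is displaced upward and reads as a hyperechoic
        # triangle, the classic indirect sign.
        if label == NORMAL:
            tv = _filled_ellipse(shape, (cx, cy + 42), (5.0, 8.0))
            img[tv] = 70.0
        else:
            apex_y = cy + 42 - config.third_ventricle_shift - 12
            tv = _triangle(shape, (cx, apex_y), 12, 24)
            img[tv] = 195.0
        masks[THIRD_VENTRICLE] = tv

    elif view == "axial":
        # straight midline falx echo (no sagittal arc in this plane)
        falx = np.zeros(shape, dtype=bool)
        x0, x1 = int(cx - config.skull_axes[0] + 14), int(cx + config.skull_axes[0] - 14)
        falx[int(cy) - 1:int(cy) + 2, x0:x1] = True
        img[falx] = config.falx_intensity

        # paired lateral ventricles, parallel to the midline
        v_masks = []
        for side in (-1, 1):
            v_center = (cx + 24, cy + side * 27)
            v_axes = (34.0 * dil, 8.0 * dil)
            lumen = _filled_ellipse(shape, v_center, v_axes, angle_deg=side * 6.0)
            wall = _ellipse_ring(shape, v_center, v_axes, 3.0, angle_deg=side * 6.0)
            img[lumen] = config.ventricle_lumen_intensity
            img[wall] = config.ventricle_wall_intensity
            v_masks.append(lumen | wall)
        masks[VENTRICLE] = v_masks[0] | v_masks[1]

        # cavum: small anechoic box on the midline, anterior third
        cav = _filled_ellipse(shape, (cx - 52, cy),
                              (config.cavum_axes[1], config.cavum_axes[0]))
        img[cav] = config.cavum_intensity
        masks[CAVUM] = cav
    else:
        raise KeyError(f"unknown view {view!r}")

    return img, masks


def _pose_transform(config: PhantomConfig, rng: np.random.Generator):
    angle = np.deg2rad(rng.uniform(-config.pose_rotation_deg,
                                   config.pose_rotation_deg))
    tx = rng.uniform(-config.pose_translation_px, config.pose_translation_px)
    ty = rng.uniform(-config.pose_translation_px, config.pose_translation_px)
    cx, cy = config.skull_center
    center = sktransform.SimilarityTransform(translation=(-cx, -cy))
    rot = sktransform.SimilarityTransform(rotation=angle)
    back = sktransform.SimilarityTransform(translation=(cx + tx, cy + ty))
    return center + rot + back, np.rad2deg(angle), (tx, ty)


def _warp_image(img, tform, background):
    return sktransform.warp(img, tform.inverse, order=1, preserve_range=True,
                            cval=background)


def _mask_bbox(mask: np.ndarray) -> BoundingBox | None:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    return BoundingBox(int(cols.min()), int(rows.min()),
                       int(cols.max()) + 1, int(rows.max()) + 1)


def generate_case(config: PhantomConfig, label: str, seed: int,
                  case_id: str | None = None) -> CasePair:
    """Generate one paired-view case. Pure function of (config, label, seed)."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(seed)
    images, boxes, pose_log, all_masks = {}, {}, {}, {}
    for view in ("sagittal", "axial"):
        img, masks = render_canonical(config, view, label)
        if config.pose_rotation_deg > 0 or config.pose_translation_px > 0:
            tform, angle, shift = _pose_transform(config, rng)
            img = _warp_image(img, tform, config.background_intensity)
            masks = {k: sktransform.warp(m.astype(np.float64), tform.inverse,
                                         order=0, preserve_range=True) > 0.5
                     for k, m in masks.items()}
            pose_log[view] = {"rotation_deg": float(angle),
                              "translation_px": [float(shift[0]), float(shift[1])]}
        else:
            pose_log[view] = {"rotation_deg": 0.0, "translation_px": [0.0, 0.0]}
        speckle = rng.gamma(config.speckle_looks,
                            1.0 / config.speckle_looks, size=img.shape)
        img = np.clip(img * speckle, 0.0, 255.0).astype(np.float32)
        images[view] = img
        boxes[view] = {name: bb for name, m in masks.items()
                       if (bb := _mask_bbox(m)) is not None}
        all_masks[view] = masks
    if label == AGENESIS and CC in boxes["sagittal"]:
        raise AssertionError("agenesis case must not carry a cc box")
    return CasePair(
        case_id=case_id or f"case_{seed}",
        sagittal_image=images["sagittal"],
        axial_image=images["axial"],
        label=label,
        gt_boxes=boxes,
        provenance={"config": dataclasses.asdict(config), "seed": int(seed),
                    "pose": pose_log},
        masks=all_masks,
    )


def generate_dataset(config: PhantomConfig, n_cases: int, seed: int):
    """Generate n_cases with round(prevalence * n) agenesis cases.

    Returns (cases, manifest) where the manifest is a JSON-serializable list
    of per-case records (no file paths until the set is saved to disk).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    n_agenesis = int(round(config.prevalence * n_cases))
    labels = np.array([AGENESIS] * n_agenesis + [NORMAL] * (n_cases - n_agenesis))
    ss = np.random.SeedSequence(seed)
    np.random.default_rng(ss.spawn(1)[0]).shuffle(labels)
    case_seeds = ss.generate_state(n_cases + 1)[1:] % (2 ** 31)
    cases = []
    for i, (label, cs) in enumerate(zip(labels, case_seeds)):
        cases.append(generate_case(config, str(label), int(cs),
                                   case_id=f"case_{i:04d}"))
    manifest = [_case_record(c) for c in cases]
    return cases, manifest


def _case_record(case: CasePair) -> dict:
    return {
        "case_id": case.case_id,
        "label": case.label,
        "boxes": {view: {name: list(bb.as_tuple())
                         for name, bb in view_boxes.items()}
                  for view, view_boxes in case.gt_boxes.items()},
        "seed": case.provenance.get("seed"),
    }


def save_dataset(cases: list[CasePair], out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs, a JSON manifest and a CSV summary."""
    from imageio.v3 import imwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for case in cases:
        rec = _case_record(case)
        for view in ("sagittal", "axial"):
            path = out / f"{case.case_id}_{view}.png"
            imwrite(path, np.clip(case.image(view), 0, 255).astype(np.uint8))
            rec[f"{view}_path"] = path.name
        records.append(rec)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(records, indent=2))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label", "sagittal_path", "axial_path"])
        for rec in records:
            writer.writerow([rec["case_id"], rec["label"],
                             rec["sagittal_path"], rec["axial_path"]])
    return manifest_path


def load_dataset(manifest_path: str | Path) -> list[CasePair]:
    """Load a saved phantom set back into CasePair objects."""
    from imageio.v3 import imread

    manifest_path = Path(manifest_path)
    records = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    cases = []
    for rec in records:
        boxes = {view: {name: BoundingBox(*vals)
                        for name, vals in view_boxes.items()}
                 for view, view_boxes in rec.get("boxes", {}).items()}
        cases.append(CasePair(
            case_id=rec["case_id"],
            sagittal_image=imread(base / rec["sagittal_path"]).astype(np.float32),
            axial_image=imread(base / rec["axial_path"]).astype(np.float32),
            label=rec["label"],
            gt_boxes=boxes,
            provenance={"seed": rec.get("seed")},
        ))
    return cases


def cc_matched_filter_score(image: np.ndarray, config: PhantomConfig) -> float:
    """Fixed matched-filter statistic for CC presence on a canonical-pose
    sagittal image: mean intensity of the surrounding ring minus the mean
    inside the canonical CC-band mask (positive when the dark band exists).
    """
    shape = (config.image_height, config.image_width)
    yy = np.arange(shape[0])[:, None]
    band = _ellipse_ring(shape, config.cc_center, config.cc_axes,
                         config.cc_thickness)
    band &= yy <= config.cc_center[1]
    ring = _ellipse_ring(shape, config.cc_center,
                         (config.cc_axes[0] - 6, config.cc_axes[1] - 6),
                         config.cc_thickness + 12)
    ring &= yy <= config.cc_center[1]
    ring &= ~band
    return float(image[ring].mean() - image[band].mean())
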