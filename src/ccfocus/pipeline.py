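"""End-to-end plumbing: phantom cases -> preprocessing -> ROI extraction ->
classifier arrays, plus the full demo pipeline used by the CLI `run` command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from . import phantom as ph
from .adfnet import ADFNet, NetworkConfig, compute_class_weights
from .preprocessing import preprocess_case, resize_letterbox
from .roi import BoundingBox, Detection, MatchedFilterDetector, crop_roi, iou
from .training import (ArrayDataset, TrainConfig, labels_to_indices,
                       predict_tta, split_patient_level, train)
from .evaluation import evaluate_predictions


def default_detectors(config: ph.PhantomConfig | None = None):
    cfg = dataclasses.replace(config or ph.PhantomConfig(),
                              pose_rotation_deg=0.0, pose_translation_px=0.0)
    return {"sagittal": MatchedFilterDetector("sagittal", cfg),
            "axial": MatchedFilterDetector("axial", cfg)}


def extract_roi_pair(case: ph.CasePair, detectors: dict,
                     expansion: int | str = "auto") -> dict:
    """Detect structures on a preprocessed case and crop one ROI per view.

    Sagittal: the CC detection window (fallback: the canonical expected CC
    window — the correct behaviour in agenesis, where no CC is found).
    Axial: the union of the detected landmark boxes (cavum + ventricles).
    Returns {"sagittal": ROI, "axial": ROI, "detections": {view: [...]}}.
    """
    out = {"detections": {}}
    for view in ("sagittal", "axial"):
        image = case.image(view)
        detections = detectors[view].detect(image)
        out["detections"][view] = detections
        if view == "sagittal":
            cc = [d for d in detections if d.structure == ph.CC]
            if cc:
                chosen = cc[0]
            else:
                window = detectors[view].expected_cc_window(image.shape)
                chosen = Detection(window, 0.0, ph.CC)
        else:
            if detections:
                x0 = min(d.box.x_min for d in detections)
                y0 = min(d.box.y_min for d in detections)
                x1 = max(d.box.x_max for d in detections)
                y1 = max(d.box.y_max for d in detections)
                chosen = Detection(BoundingBox(x0, y0, x1, y1),
                                   min(d.confidence for d in detections),
                                   "axial_landmarks")
            else:
                h, w = image.shape[:2]
                chosen = Detection(BoundingBox(w // 4, h // 4,
                                               3 * w // 4, 3 * h // 4),
                                   0.0, "axial_landmarks")
        out[view] = crop_roi(image, chosen, expansion, view=view,
                             case_id=case.case_id)
    return out


def roi_region_masks(case: ph.CasePair, roi, structures,
                     out_size: int) -> list[np.ndarray]:
    """Ground-truth boxes of `structures`, rendered as masks in the
    letterboxed ROI frame (for attribution-localization checks)."""
    box = roi.source_box
    h, w = roi.patch.shape
    scale = min(out_size / h, out_size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    top, left = (out_size - nh) // 2, (out_size - nw) // 2
    masks = []
    for name in structures:
        gb = case.gt_boxes.get(roi.view, {}).get(name)
        if gb is None:
            continue
        x0 = max(gb.x_min, box.x_min) - box.x_min
        y0 = max(gb.y_min, box.y_min) - box.y_min
        x1 = min(gb.x_max, box.x_max) - box.x_min
        y1 = min(gb.y_max, box.y_max) - box.y_min
        if x1 <= x0 or y1 <= y0:
            continue
        m = np.zeros((out_size, out_size), dtype=bool)
        ry0 = top + int(np.floor(y0 * scale))
        ry1 = top + int(np.ceil(y1 * scale))
        rx0 = left + int(np.floor(x0 * scale))
        rx1 = left + int(np.ceil(x1 * scale))
        m[ry0:ry1, rx0:rx1] = True
        masks.append(m)
    return masks


def cases_to_arrays(cases, detectors=None, expansion: int | str = "auto",
                    input_size: int = 64, preprocessed: bool = False,
                    keep_rois: bool = False):
    """Preprocess, detect, crop and resize every case into an ArrayDataset."""
    detectors = detectors or default_detectors()
    x_sag, x_cor, labels, ids, rois = [], [], [], [], []
    prepped = []
    for case in cases:
        pc = case if preprocessed else preprocess_case(case)
        pair = extract_roi_pair(pc, detectors, expansion)
        x_sag.append(resize_letterbox(pair["sagittal"].patch, input_size))
        x_cor.append(resize_letterbox(pair["axial"].patch, input_size))
        labels.append(case.label)
        ids.append(case.case_id)
        if keep_rois:
            rois.append(pair)
            prepped.append(pc)
    data = ArrayDataset(np.stack(x_sag), np.stack(x_cor),
                        labels_to_indices(labels), ids)
    if keep_rois:
        return data, rois, prepped
    return data


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(run_config, out_dir: str | Path) -> dict:
    """simulate -> preprocess -> detect -> train -> TTA predict -> explain ->
    evaluate, writing report.json and a run log into out_dir."""
    from .interpretability import grad_cam_pp, band_fractions
    from .model import CCFocusModel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = {}
    cfg = run_config
    seed = cfg.seed

    def tick(name):
        stages[name] = round(time.time() - t0, 2)

    try:
        phantom_cfg = dataclasses.replace(cfg.phantom, prevalence=cfg.prevalence)
        cases, _ = ph.generate_dataset(phantom_cfg, cfg.n_cases, seed)
        tick("simulate")
        train_cases, test_cases = split_patient_level(
            cases, cfg.train.split_fraction, seed)
        detectors = default_detectors(phantom_cfg)
        input_size = cfg.network.resolved_input_size
        train_data, _, _ = cases_to_arrays(
            train_cases, detectors, cfg.expansion, input_size, keep_rois=True)
        test_data, test_rois, test_prepped = cases_to_arrays(
            test_cases, detectors, cfg.expansion, input_size, keep_rois=True)
        tick("preprocess_detect")

        model = CCFocusModel(train_data, network_config=cfg.network,
                             train_config=cfg.train)
        results = model.fit()
        tick("train")

        probs = results.predict_proba(test_data, tta=cfg.tta_k, seed=seed)
        tick("predict")

        # attribution on the first agenesis test case (if any)
        explain = None
        agen_idx = [i for i, c in enumerate(test_cases)
                    if c.label == ph.AGENESIS]
        if agen_idx:
            i = agen_idx[0]
            maps = grad_cam_pp(results.network, test_data.x_sag[i],
                               test_data.x_cor[i], target_class="agenesis")
            explain = {view: band_fractions(hm) for view, hm in maps.items()}
        tick("explain")

        report_metrics = evaluate_predictions(probs[:, 1], test_data.labels)
        tick("evaluate")
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        done = set(stages)
        order = ["simulate", "preprocess_detect", "train", "predict",
                 "explain", "evaluate"]
        current = next((s for s in order if s not in done), "unknown")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    report = {
        "config_hash": _config_hash(dataclasses.asdict(cfg)),
        "seed": seed,
        "n_train": len(train_data),
        "n_test": len(test_data),
        "metrics": report_metrics.as_dict(),
        "band_fractions_agenesis_example": explain,
        "stage_seconds": stages,
        "history": {k: v for k, v in results.history.items()
                    if k in ("train_loss", "val_loss", "stopped_early_at")},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "run_log.json").write_text(json.dumps({
        "seed": seed, "stages": stages,
        "train_case_ids": [c.case_id for c in train_cases],
        "test_case_ids": [c.case_id for c in test_cases],
        "config": dataclasses.asdict(cfg)}, indent=2, default=str))
    return report
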