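"""Patient-level splitting, the training loop, and TTA inference.

The training loop follows the reference hyperparameters: Adam at lr 1e-3
with betas (0.9, 0.999), batch size 32, class-weighted cross-entropy, early
stopping on a held-out 10% of the training split (patience 5 by default).
All randomness flows from TrainConfig.seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .adfnet import (ADFNet, ClassWeights, LABEL_TO_INDEX, INDEX_TO_LABEL,
                     Prediction, compute_class_weights)
from .preprocessing import AugmentationParams, apply_augmentation, draw_augmentation


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 32
    max_epochs: int = 10
    early_stop_patience: int = 5
    split_fraction: float = 0.7
    val_fraction: float = 0.1
    augment: bool = True  # rotation/brightness/elastic on training batches
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TTAResult:
    variant_probs: np.ndarray  # (k, 2)
    aggregate: Prediction


@dataclass
class ArrayDataset:
    """ROI patches resized to the classifier input, stacked as arrays."""

    x_sag: np.ndarray  # (N, H, W) float32, [0, 255]
    x_cor: np.ndarray
    labels: np.ndarray  # (N,) int, 0 = normal / 1 = agenesis
    case_ids: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.labels)

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return ArrayDataset(self.x_sag[idx], self.x_cor[idx],
                            self.labels[idx],
                            [self.case_ids[i] for i in idx] if self.case_ids else [])

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


def split_patient_level(cases: list, fraction: float = 0.7, seed: int = 0):
    """Stratified, disjoint train/test split over unique case ids.

    Train size is round(fraction * n) overall, realized per class so the
    minority class keeps at least one case on each side.
    """
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("case_ids must be unique for patient-level splitting")
    labels = np.array([c.label for c in cases])
    rng = np.random.default_rng(seed)
    classes = sorted(np.unique(labels))
    members = {}
    for cls in classes:
        m = np.nonzero(labels == cls)[0]
        if len(m) < 2:
            raise ValueError(
                f"class {cls!r} has {len(m)} case(s); need >= 2 to split")
        members[cls] = rng.permutation(m)
    # largest-remainder apportionment of round(fraction * n) train slots
    # across classes, each clamped to keep >= 1 case on both sides
    total_train = int(round(fraction * len(cases)))
    quotas = {cls: fraction * len(members[cls]) for cls in classes}
    n_train = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    leftover = total_train - sum(n_train.values())
    by_remainder = sorted(classes, key=lambda c: quotas[c] - n_train[c],
                          reverse=True)
    for cls in by_remainder[:max(0, leftover)]:
        n_train[cls] += 1
    train_idx, test_idx = [], []
    for cls in classes:
        k = min(max(n_train[cls], 1), len(members[cls]) - 1)
        train_idx.extend(members[cls][:k])
        test_idx.extend(members[cls][k:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    return ([cases[i] for i in train_idx], [cases[i] for i in test_idx])


def train(model: ADFNet, data: ArrayDataset, config: TrainConfig,
          weights: ClassWeights | None = None,
          augment_params: AugmentationParams | None = None):
    """Train in place; returns a history dict.

    A stratified `val_fraction` of the training data is held out for early
    stopping on validation loss; the best-validation parameters are restored
    at the end. When config.augment is set, every training example is
    perturbed per epoch by the standard augmentation (one geometric draw
    shared across the two views of a case); the validation holdout is never
    augmented.
    """
    if len(data) == 0:
        raise ValueError("empty training set")
    n_norm, n_agen = data.class_counts()
    if n_norm == 0 or n_agen == 0:
        raise ValueError("training set must contain both classes")
    if weights is None:
        weights = compute_class_weights(n_norm, n_agen)
    rng = np.random.default_rng(config.seed)

    # stratified early-stopping holdout
    val_idx = []
    for cls in (0, 1):
        members = rng.permutation(np.nonzero(data.labels == cls)[0])
        n_val = max(1, int(round(config.val_fraction * len(members))))
        n_val = min(n_val, len(members) - 1)
        val_idx.extend(members[:n_val])
    val_mask = np.zeros(len(data), dtype=bool)
    val_mask[val_idx] = True
    fit_set, val_set = data.subset(~val_mask), data.subset(val_mask)

    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  betas=config.adam_betas)
    w = weights.as_array()
    history = {"train_loss": [], "val_loss": [],
               "n_fit": len(fit_set), "n_val": len(val_set),
               "val_case_ids": list(val_set.case_ids)}
    best_val, best_state, patience_left = np.inf, None, config.early_stop_patience
    aug = augment_params or AugmentationParams()
    shape = fit_set.x_sag.shape[1:]
    model.train()
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(fit_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                xb_sag, xb_cor = [], []
                for i in idx:
                    draws = draw_augmentation(aug, rng, shape)
                    xb_sag.append(apply_augmentation(fit_set.x_sag[i], draws))
                    xb_cor.append(apply_augmentation(fit_set.x_cor[i], draws))
                xb_sag, xb_cor = np.stack(xb_sag), np.stack(xb_cor)
            else:
                xb_sag, xb_cor = fit_set.x_sag[idx], fit_set.x_cor[idx]
            logits = model.forward(xb_sag, xb_cor, rng=rng)
            loss = nn.weighted_softmax_ce(logits, fit_set.labels[idx], w)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss = evaluate_loss(model, val_set, weights)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history["stopped_early_at"] = epoch + 1
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate_loss(model: ADFNet, data: ArrayDataset,
                  weights: ClassWeights) -> float:
    was_training = model.training
    model.eval()
    try:
        logits = model.forward(data.x_sag, data.x_cor)
        loss = nn.weighted_softmax_ce(logits, data.labels, weights.as_array())
    finally:
        if was_training:
            model.train()
    return float(loss.data)


def predict_proba(model: ADFNet, data: ArrayDataset) -> np.ndarray:
    """(N, 2) softmax probabilities in eval mode."""
    was_training = model.training
    model.eval()
    try:
        # batch to bound the im2col memory footprint
        chunks = []
        for start in range(0, len(data), 64):
            logits = model.forward(data.x_sag[start:start + 64],
                                   data.x_cor[start:start + 64])
            chunks.append(nn.softmax(logits.data.astype(np.float64)))
    finally:
        if was_training:
            model.train()
    return np.vstack(chunks)


def predict_tta(model: ADFNet, x_sag: np.ndarray, x_cor: np.ndarray,
                k: int = 5, params: AugmentationParams | None = None,
                seed: int = 0) -> TTAResult:
    """TTA inference on one case pair.

    Each of the k variants shares one augmentation draw across the two views
    (the planes move together under probe/fetal motion); the aggregate is
    the arithmetic mean of the k softmax vectors. The input arrays are never
    modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or AugmentationParams()
    rng = np.random.default_rng(seed)
    x_sag = np.asarray(x_sag)
    x_cor = np.asarray(x_cor)
    variants_sag, variants_cor = [], []
    for _ in range(k):
        draws = draw_augmentation(params, rng, x_sag.shape[:2])
        variants_sag.append(apply_augmentation(x_sag, draws))
        variants_cor.append(apply_augmentation(x_cor, draws))
    batch = ArrayDataset(np.stack(variants_sag), np.stack(variants_cor),
                         np.zeros(k, dtype=np.int64))
    probs = predict_proba(model, batch)
    mean = probs.mean(axis=0)
    capture: dict = {}
    model.eval()
    model.forward(x_sag[None], x_cor[None], capture=capture)
    aggregate = Prediction(prob_normal=float(mean[0]),
                           prob_agenesis=float(mean[1]),
                           predicted_label=INDEX_TO_LABEL[int(mean.argmax())],
                           alpha_used=float(capture["alpha"][0]))
    return TTAResult(variant_probs=probs, aggregate=aggregate)


def labels_to_indices(labels) -> np.ndarray:
    return np.array([LABEL_TO_INDEX[l] for l in labels], dtype=np.int64)
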