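"""Confusion-matrix metrics, ROC/AUC, and clinician-AI score fusion.

Agenesis is the positive class throughout. Accuracy, recall, precision and
F1 follow the usual confusion-count definitions; sensitivity is the recall
of the agenesis class, specificity the true-negative rate of the normal
class, and balanced accuracy their arithmetic mean. AUC is computed by the
tie-aware Mann-Whitney formulation (equivalent to the trapezoidal ROC area
for distinct scores and well-defined under ties).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    sensitivity_agenesis: float
    specificity_normal: float
    balanced_accuracy: float
    auc: float | None = None
    undefined: tuple = ()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


@dataclass(frozen=True)
class ClinicianReading:
    diagnosis: str  # "normal" | "agenesis"
    confidence: float

    def __post_init__(self):
        if self.diagnosis not in ("normal", "agenesis"):
            raise ValueError("diagnosis must be 'normal' or 'agenesis'")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def prob_agenesis(self) -> float:
        """Signed mapping of confidence to a class probability."""
        return self.confidence if self.diagnosis == "agenesis" \
            else 1.0 - self.confidence


@dataclass(frozen=True)
class CollabMode:
    """AI-dominant mode for junior readers (0.7 AI / 0.3 clinician);
    balanced mode for senior readers (0.5 / 0.5)."""

    mode: str

    _WEIGHTS = {"junior": 0.7, "senior": 0.5}

    def __post_init__(self):
        if self.mode not in self._WEIGHTS:
            raise ValueError("mode must be 'junior' or 'senior'")

    @property
    def ai_weight(self) -> float:
        return self._WEIGHTS[self.mode]

    @property
    def clinician_weight(self) -> float:
        return 1.0 - self.ai_weight


def confusion(prob_agenesis, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Counts with agenesis positive; prob >= threshold predicts positive.

    `labels` are 1/0 ints or "agenesis"/"normal" strings.
    """
    scores = np.asarray(prob_agenesis, dtype=float)
    y = _as_binary(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("predictions and labels length mismatch")
    if scores.shape[0] == 0:
        raise ValueError("empty prediction list")
    pred = scores >= threshold
    return ConfusionCounts(tp=int(np.sum(pred & (y == 1))),
                           tn=int(np.sum(~pred & (y == 0))),
                           fp=int(np.sum(pred & (y == 0))),
                           fn=int(np.sum(~pred & (y == 1))))


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        return labels.astype(int)
    return np.array([1 if l == "agenesis" else 0 for l in labels], dtype=int)


def metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Derived metrics; a zero denominator yields 0 and flags the metric."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    undefined = []

    def safe(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    recall = safe(counts.tp, counts.tp + counts.fn, "recall")
    precision = safe(counts.tp, counts.tp + counts.fp, "precision")
    f1 = safe(2 * recall * precision, recall + precision, "f1")
    specificity = safe(counts.tn, counts.tn + counts.fp, "specificity_normal")
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        sensitivity_agenesis=recall, specificity_normal=specificity,
        balanced_accuracy=(recall + specificity) / 2.0,
        auc=auc, undefined=tuple(undefined))


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of class-wise sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # average ranks under ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(prob_agenesis, labels,
                         threshold: float = 0.5) -> MetricsReport:
    """Full report: confusion metrics plus AUC from the raw scores."""
    counts = confusion(prob_agenesis, labels, threshold)
    y = _as_binary(labels)
    auc = roc_auc(prob_agenesis, labels) if 0 < y.sum() < len(y) else None
    return metrics(counts, auc=auc)


def collab_score(ai_prob_agenesis: float, reading: ClinicianReading,
                 mode: CollabMode) -> tuple[float, str]:
    """Weighted fusion of the AI probability with the clinician reading.

    The clinician's confidence is mapped to an agenesis probability with the
    signed rule (confidence if they call agenesis, else 1 - confidence);
    the decision threshold 0.5 is inclusive toward agenesis, the safer
    screening direction.
    """
    if not 0.0 <= ai_prob_agenesis <= 1.0:
        raise ValueError("ai_prob_agenesis must lie in [0, 1]")
    fused = mode.ai_weight * ai_prob_agenesis \
        + mode.clinician_weight * reading.prob_agenesis
    return fused, ("agenesis" if fused >= 0.5 else "normal")


def simulate_collaboration(n_cases: int, ai_accuracy: float,
                           clinician_accuracy: float, mode: CollabMode,
                           seed: int = 0, prevalence: float = 0.5,
                           conf_correct: tuple[float, float] = (0.7, 1.0),
                           conf_wrong: tuple[float, float] = (0.6, 0.9)) -> dict:
    """Monte-Carlo stand-in for a reader study.

    Each case draws independent correct/incorrect outcomes for the AI and
    the clinician at their stated accuracies, with calibrated confidence:
    readings made in the correct direction carry confidence ~ U(0.7, 1.0),
    erroneous ones ~ U(0.6, 0.9) — confident but slightly less so when
    wrong. The AI probability of the favored class is drawn the same way.
    Reports the accuracy of AI alone, clinician alone, and the fusion.
    """
    if not (0.5 < ai_accuracy <= 1.0 and 0.5 < clinician_accuracy <= 1.0):
        raise ValueError("accuracies must lie in (0.5, 1]")
    rng = np.random.default_rng(seed)
    truth = (rng.random(n_cases) < prevalence).astype(int)

    def draw_confidence(correct: np.ndarray) -> np.ndarray:
        return np.where(correct, rng.uniform(*conf_correct, n_cases),
                        rng.uniform(*conf_wrong, n_cases))

    ai_correct = rng.random(n_cases) < ai_accuracy
    ai_conf = draw_confidence(ai_correct)
    ai_called_agenesis = np.where(ai_correct, truth == 1, truth == 0)
    ai_prob = np.where(ai_called_agenesis, ai_conf, 1.0 - ai_conf)

    cl_correct = rng.random(n_cases) < clinician_accuracy
    cl_conf = draw_confidence(cl_correct)
    cl_called_agenesis = np.where(cl_correct, truth == 1, truth == 0)
    cl_prob = np.where(cl_called_agenesis, cl_conf, 1.0 - cl_conf)

    fused = mode.ai_weight * ai_prob + mode.clinician_weight * cl_prob
    fused_call = (fused >= 0.5).astype(int)
    return {
        "mode": mode.mode,
        "ai_weight": mode.ai_weight,
        "clinician_weight": mode.clinician_weight,
        "n_cases": n_cases,
        "accuracy_ai": float(((ai_prob >= 0.5).astype(int) == truth).mean()),
        "accuracy_clinician": float((cl_called_agenesis.astype(int) == truth).mean()),
        "accuracy_fused": float((fused_call == truth).mean()),
    }
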