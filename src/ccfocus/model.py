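"""High-level modelling interface: a Model built from data whose fit()
returns a Results object with estimates, diagnostics and a summary table.

    >>> data = cases_to_arrays(train_cases)          # ROI arrays
    >>> model = CCFocusModel(data)
    >>> results = model.fit()
    >>> print(results.summary())
    >>> probs = results.predict_proba(test_data, tta=5)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .adfnet import (ADFNet, ClassWeights, NetworkConfig,
                     compute_class_weights)
from .evaluation import MetricsReport, evaluate_predictions
from .training import (ArrayDataset, TrainConfig, predict_proba, predict_tta,
                       train)


class CCFocusModel:
    """Dual-view CC classifier specified against a training ArrayDataset.

    Parameters
    ----------
    data : ArrayDataset
        ROI patches (both views) with 0/1 labels, already resized to the
        classifier input size.
    network_config, train_config : optional
        Architecture and optimization settings; class weights default to
        inverse class frequency of `data` (w_agenesis = N_normal/N_agenesis).
    """

    def __init__(self, data: ArrayDataset,
                 network_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None,
                 class_weights: ClassWeights | None = None):
        if len(data) == 0:
            raise ValueError("empty training data")
        self.data = data
        self.network_config = network_config or NetworkConfig()
        self.train_config = train_config or TrainConfig()
        n_norm, n_agen = data.class_counts()
        self.class_weights = class_weights or compute_class_weights(
            max(n_norm, 1), max(n_agen, 1))

    @classmethod
    def from_cases(cls, cases, network_config: NetworkConfig | None = None,
                   train_config: TrainConfig | None = None, **kwargs):
        """Build directly from CasePair objects (preprocess + ROI extraction)."""
        from .pipeline import cases_to_arrays

        network_config = network_config or NetworkConfig()
        data = cases_to_arrays(
            cases, input_size=network_config.resolved_input_size, **kwargs)
        return cls(data, network_config, train_config)

    def fit(self) -> "CCFocusResults":
        network = ADFNet(self.network_config)
        history = train(network, self.data, self.train_config,
                        self.class_weights)
        return CCFocusResults(self, network, history)


class CCFocusResults:
    """Fitted-model container: trained parameters, training history, and
    prediction/evaluation/attribution entry points."""

    def __init__(self, model: CCFocusModel, network: ADFNet, history: dict):
        self.model = model
        self.network = network
        self.history = history

    # -- inference ----------------------------------------------------------
    def predict_proba(self, data: ArrayDataset, tta: int = 0,
                      seed: int = 0) -> np.ndarray:
        """(N, 2) class probabilities; tta > 0 averages that many augmented
        variants per case (paired draws across views)."""
        if tta <= 0:
            return predict_proba(self.network, data)
        rows = []
        for i in range(len(data)):
            res = predict_tta(self.network, data.x_sag[i], data.x_cor[i],
                              k=tta, seed=seed + i)
            rows.append([res.aggregate.prob_normal,
                         res.aggregate.prob_agenesis])
        return np.asarray(rows)

    def predict(self, data: ArrayDataset, tta: int = 0, seed: int = 0):
        probs = self.predict_proba(data, tta=tta, seed=seed)
        return np.where(probs[:, 1] >= 0.5, "agenesis", "normal")

    def alphas(self, data: ArrayDataset) -> np.ndarray:
        """Per-case learned sagittal contribution coefficients."""
        capture: dict = {}
        self.network.eval()
        self.network.forward(data.x_sag, data.x_cor, capture=capture)
        return capture["alpha"]

    def evaluate(self, data: ArrayDataset, tta: int = 0,
                 seed: int = 0) -> MetricsReport:
        probs = self.predict_proba(data, tta=tta, seed=seed)
        return evaluate_predictions(probs[:, 1], data.labels)

    def grad_cam(self, x_sag, x_cor, target_class=None):
        from .interpretability import grad_cam_pp

        return grad_cam_pp(self.network, x_sag, x_cor, target_class)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path):
        """Parameters as .npz plus a JSON sidecar with the configuration."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.state_dict())
        sidecar = {
            "network_config": self.model.network_config.__dict__,
            "train_config": {k: list(v) if isinstance(v, tuple) else v
                             for k, v in self.model.train_config.__dict__.items()},
            "class_weights": [self.model.class_weights.w_normal,
                              self.model.class_weights.w_agenesis],
            "history": {k: v for k, v in self.history.items()
                        if k not in ("val_case_ids",)},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path, data: ArrayDataset | None = None):
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        ncfg = NetworkConfig(**sidecar["network_config"])
        network = ADFNet(ncfg)
        with np.load(path.with_suffix(".npz")) as archive:
            network.load_state_dict(dict(archive))
        network.eval()
        tc = sidecar["train_config"]
        tc["adam_betas"] = tuple(tc["adam_betas"])
        dummy = data or ArrayDataset(
            np.zeros((2, 4, 4), dtype=np.float32),
            np.zeros((2, 4, 4), dtype=np.float32),
            np.array([0, 1]))
        model = CCFocusModel(dummy, ncfg, TrainConfig(**tc),
                             ClassWeights(*sidecar["class_weights"]))
        return cls(model, network, sidecar.get("history", {}))

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.network_config
        tcfg = self.model.train_config
        n_params = sum(p.data.size for p in self.network.parameters())
        lines = [
            "CC-Focus dual-stream fusion classifier",
            "=" * 54,
            f"{'backbone':<28}{cfg.backbone}",
            f"{'input size':<28}{cfg.resolved_input_size} x {cfg.resolved_input_size}",
            f"{'cross-view stage':<28}{cfg.resolved_cvfim_stage}",
            f"{'parameters':<28}{n_params}",
            f"{'training cases':<28}{len(self.model.data)}",
            f"{'class weights (nrm/agen)':<28}"
            f"{self.model.class_weights.w_normal:.2f} / "
            f"{self.model.class_weights.w_agenesis:.2f}",
            f"{'optimizer':<28}Adam lr={tcfg.learning_rate} "
            f"betas={tcfg.adam_betas}",
            f"{'batch size':<28}{tcfg.batch_size}",
            f"{'epochs run':<28}{len(self.history.get('train_loss', []))}",
        ]
        tl = self.history.get("train_loss")
        vl = self.history.get("val_loss")
        if tl:
            lines.append(f"{'final train loss':<28}{tl[-1]:.4f}")
        if vl:
            lines.append(f"{'best val loss':<28}{min(vl):.4f}")
        if "stopped_early_at" in self.history:
            lines.append(f"{'early stop at epoch':<28}"
                         f"{self.history['stopped_early_at']}")
        lines.append("=" * 54)
        return "\n".join(lines)
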