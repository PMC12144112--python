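"""Hybrid iterative refinement: surrogate prediction, transport/quantum
re-simulation, dose-difference feedback, and model/parameter updates until
the discrepancy tolerance or the iteration cap is reached.

Each iteration: predict -> simulate -> compare -> update. An update that
increases the discrepancy is rejected: the model parameters are rolled
back and the learning-rate step is halved, so the accepted-iteration
discrepancy sequence is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .metrics import dice_isodose, hausdorff_isodose
from .surrogate import LossConfig, TrainedModel, TrainingConfig, train
from .transport import DoseGrid

__all__ = ["HybridConfig", "HybridTrace", "dose_difference_map", "run_hybrid_loop"]


@dataclass
class HybridConfig:
    """Loop settings.

    ``discrepancy_metric``: 'mae' (Gy), 'dice_complement' (1 - Dice at the
    isodose threshold) or 'hausdorff' (mm). ``refine_quantum_params``
    invokes the supplied parameter-refinement callback each iteration.
    """

    tolerance: float = 0.05
    max_iterations: int = 20
    discrepancy_metric: str = "mae"
    isodose_threshold: float = 1.0
    refine_quantum_params: bool = False
    learning_rate: float = 0.01
    epochs_per_iteration: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.discrepancy_metric not in ("mae", "dice_complement", "hausdorff"):
            raise ValueError(
                "discrepancy_metric must be one of mae, dice_complement, hausdorff"
            )


@dataclass
class HybridTrace:
    records: list = field(default_factory=list)  # dicts per accepted iteration
    stop_reason: str = ""

    @property
    def discrepancies(self) -> list[float]:
        return [r["discrepancy"] for r in self.records]

    def to_json_dict(self) -> dict:
        return {"records": self.records, "stop_reason": self.stop_reason}


def dose_difference_map(pred: DoseGrid, ref: DoseGrid) -> np.ndarray:
    """Voxelwise signed difference pred - ref (Gy)."""
    if pred.dose.shape != ref.dose.shape:
        raise ValueError(f"grid shape mismatch: {pred.dose.shape} vs {ref.dose.shape}")
    if not np.allclose(pred.spacing, ref.spacing):
        raise ValueError(f"grid spacing mismatch: {pred.spacing} vs {ref.spacing}")
    return pred.dose - ref.dose


def _discrepancy(pred: DoseGrid, sim: DoseGrid, config: HybridConfig) -> float:
    if config.discrepancy_metric == "mae":
        return float(np.mean(np.abs(dose_difference_map(pred, sim))))
    if config.discrepancy_metric == "dice_complement":
        return 1.0 - dice_isodose(pred, sim, config.isodose_threshold)
    a = pred.dose >= config.isodose_threshold
    b = sim.dose >= config.isodose_threshold
    if not a.any() or not b.any():
        if not a.any() and not b.any():
            return 0.0
        # one empty isodose volume: worst case, the grid diagonal (mm)
        return float(np.linalg.norm(np.asarray(pred.dose.shape) * np.asarray(pred.spacing)))
    return hausdorff_isodose(pred, sim, config.isodose_threshold)


def run_hybrid_loop(
    model,
    simulator: Callable[[DoseGrid], DoseGrid],
    features: np.ndarray,
    reference: DoseGrid,
    config: Optional[HybridConfig] = None,
    refine_params: Optional[Callable[[float], None]] = None,
) -> tuple[object, HybridTrace]:
    """Run the hybrid refinement loop.

    ``model`` is anything with ``predict(features) -> DoseGrid`` and
    ``fit(features, target_dose, learning_rate, epochs, seed)`` (the
    surrogate adapter below provides this for :class:`TrainedModel`);
    ``simulator`` maps the current prediction to a freshly simulated dose
    grid on the same grid (the transport/quantum evaluation). The loop
    stops when the discrepancy is at or below ``tolerance`` (stop_reason
    'tolerance') or after ``max_iterations`` ('max_iterations').
    Deterministic for a fixed seed.
    """
    config = config or HybridConfig()
    trace = HybridTrace()
    lr = config.learning_rate
    for it in range(config.max_iterations):
        pred = model.predict(features)
        sim = simulator(pred)
        if pred.dose.shape != reference.dose.shape:
            raise ValueError("model, simulator and reference must share one grid")
        disc = _discrepancy(pred, sim, config)
        if not np.isfinite(disc):
            raise RuntimeError(f"non-finite discrepancy at iteration {it}")
        if trace.records and disc > trace.records[-1]["discrepancy"]:
            # rejected step: roll back, halve the step, re-record the old state
            model.rollback()
            lr *= 0.5
            disc = trace.records[-1]["discrepancy"]
        trace.records.append(
            {
                "iteration": it,
                "discrepancy": float(disc),
                "learning_rate": float(lr),
            }
        )
        if disc <= config.tolerance:
            trace.stop_reason = "tolerance"
            return model, trace
        if config.refine_quantum_params and refine_params is not None:
            try:
                refine_params(disc)
            except Exception as exc:
                raise RuntimeError(f"simulator refinement failed at iteration {it}: {exc}") from exc
        model.checkpoint()
        model.fit(features, sim, learning_rate=lr, epochs=config.epochs_per_iteration,
                  seed=config.seed + it)
    trace.stop_reason = "max_iterations"
    return model, trace


class SurrogateAdapter:
    """Adapts a surrogate :class:`TrainedModel` to the hybrid-loop protocol."""

    def __init__(self, model: TrainedModel, spacing=(1.0, 1.0, 1.0), lam: float = 0.0):
        self.model = model
        self.spacing = tuple(spacing)
        self.lam = lam
        self._saved: Optional[list[np.ndarray]] = None

    def predict(self, features: np.ndarray) -> DoseGrid:
        from .surrogate import predict_dose

        return predict_dose(self.model, features, spacing=self.spacing)

    def checkpoint(self) -> None:
        self._saved = [p.copy() for p in self.model.theta]

    def rollback(self) -> None:
        if self._saved is not None:
            for p, s in zip(self.model.theta, self._saved):
                p[...] = s

    def fit(self, features: np.ndarray, target: DoseGrid, learning_rate: float,
            epochs: int, seed: int) -> None:
        cfg = TrainingConfig(
            learning_rate=learning_rate, batch_size=1, epochs=epochs,
            validation_split=0.5, optimizer="sgd", dropout_rate=0.0, seed=seed,
        )
        train(self.model, [(features, target.dose)], cfg, LossConfig(lam=self.lam))
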