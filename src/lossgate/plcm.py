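"""Per-class loss thresholds from correctly classified training examples.

During joint training, the per-example losses of *correctly* classified
examples are recorded batch by batch.  For each class t the batch-level mean
correct-prediction loss is averaged within each epoch and then across the last
``z`` epochs, giving a trailing average b_final_t that tracks how hard a
typical well-classified example of class t is near convergence.  The sampling
threshold is

    threshold_t = alpha_t * b_final_t

with a per-class multiplier alpha_t > 0 (the reference working point uses
1.0 for benign, 1.1 for dysplasia, 1.0 for malignant).  Pool candidates whose
predicted loss reaches the threshold of their predicted class are treated as
likely-noisy and excluded from acquisition.

A class that is never predicted correctly in the trailing window has no
defined average; its threshold is explicitly *undefined* and filtering for
that class is disabled (fail-open) rather than silently zeroed, which would
otherwise exclude the entire class.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lpm import TrainingTrace

__all__ = [
    "DEFAULT_ALPHAS",
    "ClassThreshold",
    "ThresholdSet",
    "batch_correct_avg",
    "aggregate_trailing_epochs",
    "make_thresholds",
    "thresholds_from_trace",
]

logger = logging.getLogger(__name__)

# reference per-class working point: benign 1.0, dysplasia 1.1, malignant 1.0
DEFAULT_ALPHAS = (1.0, 1.1, 1.0)

DEFAULT_Z = 5  # trailing epochs aggregated into the converged-loss average


@dataclass(frozen=True)
class ClassThreshold:
    """Threshold state for one class; ``b_final is None`` marks 'undefined'."""

    b_final: float | None
    alpha: float

    @property
    def defined(self) -> bool:
        return self.b_final is not None

    @property
    def threshold(self) -> float | None:
        return None if self.b_final is None else self.alpha * self.b_final

    @property
    def gate(self) -> float:
        """Effective filter bound: +inf (fail-open) when undefined."""
        return math.inf if self.b_final is None else self.alpha * self.b_final


@dataclass(frozen=True)
class ThresholdSet:
    """Per-class trailing-average correct losses and their scaled thresholds."""

    per_class: tuple[ClassThreshold, ...]
    z: int
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def n_classes(self) -> int:
        return len(self.per_class)

    def gates(self) -> np.ndarray:
        """Vector of effective bounds, +inf where undefined."""
        return np.array([c.gate for c in self.per_class])

    def to_json(self, path: str | Path, class_names: tuple[str, ...] | None = None) -> None:
        names = class_names or tuple(str(i) for i in range(self.n_classes))
        doc = {
            "iteration": self.provenance.get("iteration"),
            "z": self.z,
            "per_class": [
                {
                    "name": names[i],
                    "b_final": c.b_final if c.defined else "undefined",
                    "alpha": c.alpha,
                    "threshold": c.threshold if c.defined else "undefined",
                }
                for i, c in enumerate(self.per_class)
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def batch_correct_avg(
    losses: np.ndarray,
    correct_mask: np.ndarray,
    classes: np.ndarray,
    n_classes: int,
) -> np.ndarray:
    """Per-class mean loss over the batch's correctly classified examples.

    ``classes`` are the (true == predicted) labels of each example.  Classes
    with no correct example in the batch get NaN, the in-array 'undefined'
    marker.
    """
    losses = np.asarray(losses, dtype=float)
    correct_mask = np.asarray(correct_mask, dtype=bool)
    classes = np.asarray(classes)
    if not (len(losses) == len(correct_mask) == len(classes)):
        raise ValueError("losses, correct_mask and classes must align")
    out = np.full(n_classes, np.nan)
    for t in range(n_classes):
        sel = correct_mask & (classes == t)
        if sel.any():
            out[t] = losses[sel].mean()
    return out


def aggregate_trailing_epochs(
    trace: TrainingTrace, z: int = DEFAULT_Z, collect: str = "predicted"
) -> np.ndarray:
    """Two-level trailing average of per-class correct-prediction losses.

    For each of the last ``z`` epochs, average the per-batch correct means
    (batches without a correct example of a class are skipped for that class);
    then average the per-epoch values across the window, again skipping epochs
    in which the class never appeared correctly.  NaN marks a class undefined
    over the whole window.

    ``collect`` chooses which loss feeds the average: ``"predicted"`` (the LPM
    output l_hat, the default — the sampling gate compares l_hat against the
    threshold, so both must live on the same scale) or ``"true"`` (per-example
    cross-entropy).
    """
    if collect not in ("true", "predicted"):
        raise ValueError("collect must be 'true' or 'predicted'")
    if z < 1 or z > trace.n_epochs:
        raise ValueError(f"z={z} outside [1, {trace.n_epochs}]")
    c = trace.n_classes
    epoch_means = []
    for epoch in range(trace.n_epochs - z, trace.n_epochs):
        batch_vals = []
        for rec in trace.epoch_records(epoch):
            losses = rec.true_losses if collect == "true" else rec.predicted_losses
            batch_vals.append(batch_correct_avg(losses, rec.correct, rec.labels, c))
        if not batch_vals:
            raise ValueError(f"trace has no records for epoch {epoch}")
        stacked = np.stack(batch_vals)
        epoch_means.append(_nanmean_allow_empty(stacked))
    return _nanmean_allow_empty(np.stack(epoch_means))


def _nanmean_allow_empty(stacked: np.ndarray) -> np.ndarray:
    """Column-wise nanmean where an all-NaN column yields NaN, silently."""
    counts = (~np.isnan(stacked)).sum(axis=0)
    sums = np.nansum(stacked, axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def make_thresholds(
    b_final: np.ndarray,
    alphas: float | tuple[float, ...] | np.ndarray = DEFAULT_ALPHAS,
    z: int = DEFAULT_Z,
    provenance: dict | None = None,
) -> ThresholdSet:
    """Scale per-class trailing averages by alpha; NaN propagates to undefined."""
    b_final = np.asarray(b_final, dtype=float)
    alphas_arr = np.broadcast_to(np.asarray(alphas, dtype=float), b_final.shape).copy()
    if np.any(alphas_arr <= 0):
        raise ValueError("all alpha values must be positive")
    entries = []
    for b, a in zip(b_final, alphas_arr):
        if np.isnan(b):
            logger.warning("class threshold undefined (no correct predictions); fail-open")
            entries.append(ClassThreshold(None, float(a)))
        else:
            entries.append(ClassThreshold(float(b), float(a)))
    return ThresholdSet(tuple(entries), z=z, provenance=provenance or {})


def thresholds_from_trace(
    trace: TrainingTrace,
    alphas: float | tuple[float, ...] | np.ndarray = DEFAULT_ALPHAS,
    z: int = DEFAULT_Z,
    collect: str = "predicted",
    provenance: dict | None = None,
) -> ThresholdSet:
    """Convenience: trailing aggregation followed by alpha scaling."""
    b_final = aggregate_trailing_epochs(trace, z=z, collect=collect)
    return make_thresholds(b_final, alphas, z=z, provenance=provenance)
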