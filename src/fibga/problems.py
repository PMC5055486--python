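"""Benchmark problems: the XOR truth table and overlapping Gaussian classes.

Both problems feed the same 2 -> H -> 1 network.  XOR uses the four boolean
rows with targets {0, 1}; the overlapping-classification task draws two
isotropic Gaussian point clouds in the plane ("square" class near (0.25,
0.25), "circle" class near (0.75, 0.75)) with regression targets -0.5 / +0.5
and judges classification by the sign of the network output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "OverlapSpec",
    "xor_dataset",
    "mean_abs_error",
    "per_element_errors",
    "generate_overlap",
    "rcr",
]

SQUARE = "square"
CIRCLE = "circle"


@dataclass
class Dataset:
    """Aligned inputs (N, 2), targets (N,) and optional class labels (N,)."""

    inputs: np.ndarray
    targets: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.inputs.shape[1] != 2:
            raise ValueError("inputs must have shape (N, 2)")
        if self.targets.shape != (self.inputs.shape[0],):
            raise ValueError("targets must align with inputs")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != self.targets.shape:
                raise ValueError("labels must align with targets")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"a1": self.inputs[:, 0], "a2": self.inputs[:, 1], "target": self.targets}
        )
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else None
        return cls(
            inputs=df[["a1", "a2"]].to_numpy(dtype=float),
            targets=df["target"].to_numpy(dtype=float),
            labels=labels,
        )


def xor_dataset() -> Dataset:
    """The four XOR rows: inputs (1,1),(0,1),(1,0),(0,0), targets 0,1,1,0."""
    a1 = np.array([1.0, 0.0, 1.0, 0.0])
    a2 = np.array([1.0, 1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 1.0, 0.0])
    return Dataset(inputs=np.column_stack([a1, a2]), targets=y)


def mean_abs_error(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean absolute deviation (1/N) Σ |c_p − y_p| — the training/report error."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape or outputs.size == 0:
        raise ValueError("outputs and targets must be equal-length and non-empty")
    return float(np.mean(np.abs(outputs - targets)))


def per_element_errors(outputs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Signed element-wise errors c_i^calculated − c_i^actual (no absolute value)."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must be equal-length")
    return outputs - targets


@dataclass(frozen=True)
class OverlapSpec:
    """Generative spec of the two-class Gaussian task.

    Defaults are the canonical study conditions: class means (0.25, 0.25)
    and (0.75, 0.75), isotropic SD 0.2, 500 points per class, targets -0.5
    for the square class and +0.5 for the circle class.  Points are not
    clipped to the unit square.
    """

    mean_square: tuple = (0.25, 0.25)
    mean_circle: tuple = (0.75, 0.75)
    sd: float = 0.2
    n_per_class: int = 500
    target_square: float = -0.5
    target_circle: float = 0.5

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def generate_overlap(spec: OverlapSpec, rng: np.random.Generator) -> Dataset:
    """Draw both clouds, attach targets/labels, and shuffle the rows."""
    n = spec.n_per_class
    sq = rng.normal(loc=spec.mean_square, scale=spec.sd, size=(n, 2))
    ci = rng.normal(loc=spec.mean_circle, scale=spec.sd, size=(n, 2))
    inputs = np.vstack([sq, ci])
    targets = np.concatenate(
        [np.full(n, spec.target_square), np.full(n, spec.target_circle)]
    )
    labels = np.array([SQUARE] * n + [CIRCLE] * n, dtype=object)
    order = rng.permutation(2 * n)
    return Dataset(inputs=inputs[order], targets=targets[order], labels=labels[order])


def rcr(outputs: np.ndarray, labels: np.ndarray, which_class: str) -> float:
    """Relative correct rate of one class: N_correct / n_class − 0.5.

    A circle point is correct iff its output is strictly > 0; a square point
    iff strictly < 0.  An output of exactly 0 is incorrect for both classes.
    Ranges over [-0.5, 0.5].
    """
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if outputs.shape != labels.shape:
        raise ValueError("outputs and labels must align")
    if which_class not in (SQUARE, CIRCLE):
        raise ValueError(f"unknown class {which_class!r}")
    in_class = labels == which_class
    n_class = int(in_class.sum())
    if n_class == 0:
        raise ValueError(f"no points of class {which_class!r}")
    if which_class == CIRCLE:
        correct = outputs[in_class] > 0
    else:
        correct = outputs[in_class] < 0
    return float(correct.sum() / n_class - 0.5)
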