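"""Grad-CAM interpretation of the trained network on single spectra.

Gradient-weighted class activation mapping for 1-D signals: the gradient of
the target-class logit is taken with respect to a convolutional feature map
(by default the deepest residual-block output that still resolves the
spectrum at band scale, spatial length >= input_length / 4; the terminal
length-1 map would give a constant relevance profile and deep stride-2
stages delocalize it), channel-importance weights are the spatial means of
those gradients, and
the relevance profile is the ReLU of the weighted feature-map sum, linearly
upsampled to the 1024-channel input grid and min-max scaled to [0, 1].
With a single sigmoid head, the normal-class map is computed on the negated
logit.  Activated Raman-shift regions are annotated against a shipped
colorectal-tissue peak assignment table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_GRID
from .resnet import ResNet1D

__all__ = [
    "CamResult",
    "PeakAssignment",
    "PeakAssignmentTable",
    "grad_cam",
    "extract_regions",
    "assign_peaks",
]


@dataclass(frozen=True)
class PeakAssignment:
    raman_shift: float
    intensity: str  # Weak | Mid | Strong
    vibrational_mode: str
    component: str


@dataclass
class PeakAssignmentTable:
    rows: list[PeakAssignment]

    @staticmethod
    def default() -> "PeakAssignmentTable":
        """The packaged colorectal-tissue assignment table (15 bands,
        497-1447 cm^-1)."""
        with resources.files("ramanres.data").joinpath("peak_assignments.tsv").open() as f:
            df = pd.read_csv(f, sep="\t")
        return PeakAssignmentTable(
            [
                PeakAssignment(
                    float(r.raman_shift), str(r.intensity),
                    str(r.vibrational_mode), str(r.component),
                )
                for r in df.itertuples(index=False)
            ]
        )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass
class CamResult:
    """Per-channel relevance on the model grid, in [0, 1]."""

    relevance: np.ndarray
    grid: np.ndarray
    target_class: int
    activated_regions: list[tuple[float, float]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        pd.DataFrame({"shift": self.grid, "relevance": self.relevance}).to_csv(
            path, index=False
        )


def _target_block_index(model: ResNet1D, min_length: Optional[int] = None) -> int:
    """Deepest residual block whose feature map still resolves the input at
    band scale.

    Every stride-2 stage doubles the receptive field of a feature cell;
    a few stages in, one cell spans hundreds of channels — wider than any
    Raman band — and the class-activation map can no longer localize.
    The default keeps at least input_length / 4 cells (at least 8), the
    deepest level at which relevance maps remain band-resolved.
    """
    if min_length is None:
        min_length = max(8, model.config.input_length // 4)
    idx = None
    for i, spec in enumerate(model.block_specs):
        if spec.out_length >= min_length:
            idx = i
    if idx is None:
        idx = 0
    return idx


def grad_cam(
    model: ResNet1D,
    row: np.ndarray,
    target_class: int = 1,
    target_block: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
    cutoff: float = 0.5,
) -> CamResult:
    """Relevance profile of one spectrum for ``target_class`` (1 = tumor)."""
    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    row = np.asarray(row, dtype=float)
    n = model.config.input_length
    if row.shape != (n,):
        raise ValueError(f"row must have shape ({n},), got {row.shape}")
    if grid is None:
        start, end, _ = DEFAULT_GRID
        grid = start + np.arange(n) * (end - start) / (n - 1)
    idx = _target_block_index(model) if target_block is None else target_block
    model.forward_logits(row[None, None, :], training=False, capture=True)
    sign = 1.0 if target_class == 1 else -1.0
    model.backward(np.array([sign]), capture=True)
    feats = model.block_outputs[idx][0].astype(float)       # (C, L)
    grads = model.block_output_grads[idx][0].astype(float)  # (C, L)
    weights = grads.mean(axis=1)
    cam = np.maximum(weights @ feats, 0.0)
    length = cam.size
    positions = (np.arange(length) + 0.5) * (n / length) - 0.5
    upsampled = np.interp(np.arange(n), positions, cam)
    peak = upsampled.max()
    if peak <= 0:
        warnings.warn("Grad-CAM relevance is identically zero (untrained or zero head?)")
        relevance = np.zeros(n)
    else:
        lo = upsampled.min()
        relevance = (upsampled - lo) / (peak - lo) if peak > lo else np.zeros(n)
    result = CamResult(relevance=relevance, grid=np.asarray(grid, dtype=float),
                       target_class=target_class)
    result.activated_regions = extract_regions(result, cutoff)
    return result


def extract_regions(
    cam: CamResult, cutoff: float = 0.5, min_run: int = 3
) -> list[tuple[float, float]]:
    """Maximal channel runs with relevance >= cutoff, as (start, end) cm^-1
    intervals; runs shorter than ``min_run`` channels are discarded."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    above = cam.relevance >= cutoff
    regions: list[tuple[float, float]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                regions.append((float(cam.grid[i]), float(cam.grid[j])))
            i = j + 1
        else:
            i += 1
    return regions


def assign_peaks(
    regions: Sequence[tuple[float, float]],
    table: Optional[PeakAssignmentTable] = None,
    tolerance: float = 5.0,
) -> list[dict]:
    """Annotate each shift interval with every assignment-table band lying
    inside it (widened by ``tolerance`` cm^-1 on each side)."""
    table = table or PeakAssignmentTable.default()
    out = []
    for lo, hi in regions:
        matches = [
            {
                "raman_shift": r.raman_shift,
                "intensity": r.intensity,
                "vibrational_mode": r.vibrational_mode,
                "component": r.component,
            }
            for r in table
            if lo - tolerance <= r.raman_shift <= hi + tolerance
        ]
        out.append({"region": [lo, hi], "assignments": matches})
    return out


def write_annotations(annotations: list[dict], path) -> None:
    Path(path).write_text(json.dumps(annotations, indent=1))
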