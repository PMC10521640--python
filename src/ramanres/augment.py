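"""Dataset augmentation for preprocessed Raman spectra.

Three stochastic operators: Gaussian noise proportional to the local
channel magnitude, a small random left/right channel shift, and a random
multiplicative intensity factor drawn from [0.2, 2].  A separate
deterministic "intensify" transform multiplies the main (high-prominence)
peaks by a fixed factor, used as an ensemble strategy rather than for
dataset extension.

Augmentation operates on preprocessed [0,1] rows and renormalizes its
output, so the pure multiplicative scaling only has an effect when combined
with additive noise; the operator order (noise -> shift -> scale) reflects
that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .preprocess import PreprocessedMatrix, minmax

__all__ = [
    "AugmentConfig",
    "IntensifyConfig",
    "augment_noise",
    "augment_shift",
    "augment_scale",
    "intensify_peaks",
    "augment_dataset",
]


@dataclass
class AugmentConfig:
    """Stochastic augmentation settings; ``copies_per_spectrum`` augmented
    copies are appended per original row, originals retained."""

    noise_fraction: float = 0.03
    max_shift_channels: int = 3
    intensity_range: tuple[float, float] = (0.2, 2.0)
    enable_noise: bool = True
    enable_shift: bool = True
    enable_scale: bool = True
    copies_per_spectrum: int = 1
    seed: int = 0

    def validate(self, grid_len: int | None = None) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.max_shift_channels < 0:
            raise ValueError("max_shift_channels must be >= 0")
        lo, hi = self.intensity_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid intensity_range {self.intensity_range}")
        if self.copies_per_spectrum < 0:
            raise ValueError("copies_per_spectrum must be >= 0")
        if grid_len is not None and self.max_shift_channels >= grid_len:
            raise ValueError("max_shift_channels must be smaller than the grid")


@dataclass
class IntensifyConfig:
    """Main-peak intensification: multiply the spectrum by ``factor`` within
    ``peak_halfwidth_channels`` of every local maximum whose prominence (in
    normalized units) is at least ``peak_prominence``, blending linearly to
    1 at the window edges, then renormalize."""

    peak_prominence: float = 0.05
    peak_halfwidth_channels: int = 5
    factor: float = 1.5

    def validate(self) -> None:
        if not (0 < self.peak_prominence < 1):
            raise ValueError("peak_prominence must lie in (0, 1)")
        if self.peak_halfwidth_channels < 1:
            raise ValueError("peak_halfwidth_channels must be >= 1")
        if self.factor <= 0:
            raise ValueError("factor must be positive")


def augment_noise(row: np.ndarray, noise_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Add N(0, (noise_fraction * |row_i|)^2) noise per channel; channels at
    exactly zero magnitude stay unchanged."""
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    row = np.asarray(row, dtype=float)
    return row + rng.standard_normal(row.size) * (noise_fraction * np.abs(row))


def augment_shift(row: np.ndarray, max_shift_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Translate by k ~ Uniform{-max..+max} channels, edge-replicated."""
    if max_shift_channels < 0:
        raise ValueError("max_shift_channels must be >= 0")
    row = np.asarray(row, dtype=float)
    k = int(rng.integers(-max_shift_channels, max_shift_channels + 1))
    return shift_row(row, k)


def shift_row(row: np.ndarray, k: int) -> np.ndarray:
    """Deterministic translation by k channels (positive = rightward),
    vacated edge channels filled by edge replication."""
    row = np.asarray(row, dtype=float)
    if k == 0:
        return row.copy()
    out = np.empty_like(row)
    if k > 0:
        out[k:] = row[:-k]
        out[:k] = row[0]
    else:
        out[:k] = row[-k:]
        out[k:] = row[-1]
    return out


def augment_scale(
    row: np.ndarray, intensity_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Multiply by f ~ Uniform(low, high)."""
    lo, hi = intensity_range
    if lo <= 0:
        raise ValueError("intensity_range low bound must be positive")
    f = rng.uniform(lo, hi)
    return f * np.asarray(row, dtype=float)


def intensify_peaks(row: np.ndarray, cfg: IntensifyConfig | None = None) -> np.ndarray:
    """Multiply main peaks by cfg.factor (linearly blended windows) and
    min-max renormalize.  A row with no qualifying peak is returned
    renormalized but otherwise unchanged."""
    cfg = cfg or IntensifyConfig()
    cfg.validate()
    row = np.asarray(row, dtype=float)
    peaks, _ = find_peaks(row, prominence=cfg.peak_prominence)
    gain = np.ones_like(row)
    h = cfg.peak_halfwidth_channels
    for p in peaks:
        lo = max(0, p - h)
        hi = min(row.size - 1, p + h)
        offsets = np.abs(np.arange(lo, hi + 1) - p)
        # linear blend: full factor at the apex, 1 at the window edge
        blend = 1.0 + (cfg.factor - 1.0) * (1.0 - offsets / h)
        gain[lo : hi + 1] = np.maximum(gain[lo : hi + 1], blend) if cfg.factor >= 1 else np.minimum(gain[lo : hi + 1], blend)
    return minmax(row * gain)


def augment_dataset(matrix: PreprocessedMatrix, cfg: AugmentConfig | None = None) -> PreprocessedMatrix:
    """Append ``copies_per_spectrum`` augmented copies per row.

    Each copy passes through the enabled operators in order
    noise -> shift -> scale, then is min-max renormalized.  Labels and
    patient assignments are inherited; originals are retained first, in
    order.  Fully determined by ``cfg.seed``.
    """
    cfg = cfg or AugmentConfig()
    cfg.validate(grid_len=matrix.grid.size)
    if cfg.copies_per_spectrum == 0:
        return matrix
    rng = np.random.default_rng(cfg.seed)
    rows = [matrix.values]
    ids = list(matrix.sample_ids)
    labs = [] if matrix.labels is None else list(matrix.labels)
    pids = None if matrix.patient_ids is None else list(matrix.patient_ids)
    for c in range(cfg.copies_per_spectrum):
        out = np.empty_like(matrix.values)
        for i in range(matrix.n):
            row = matrix.values[i]
            if cfg.enable_noise:
                row = augment_noise(row, cfg.noise_fraction, rng)
            if cfg.enable_shift:
                row = augment_shift(row, cfg.max_shift_channels, rng)
            if cfg.enable_scale:
                row = augment_scale(row, cfg.intensity_range, rng)
            out[i] = minmax(row)
        rows.append(out)
        ids.extend(f"{sid}+aug{c}" for sid in matrix.sample_ids)
        if matrix.labels is not None:
            labs.extend(matrix.labels)
        if pids is not None:
            pids.extend(matrix.patient_ids)
    return PreprocessedMatrix(
        values=np.vstack(rows),
        grid=matrix.grid,
        sample_ids=ids,
        labels=np.asarray(labs) if matrix.labels is not None else None,
        patient_ids=pids,
    )
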