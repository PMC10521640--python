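"""Spectral cleaning chain: baseline correction, denoising, normalization.

The fluorescence baseline is estimated with asymmetric least squares in its
Whittaker-smoother form: find b minimizing

    sum_i w_i (y_i - b_i)^2  +  lambda * sum_i (D2 b)_i^2

with asymmetric weights w_i = p where y_i > b_i and 1 - p otherwise,
iterated to a fixed point.  Small p pulls the fit onto the lower envelope
of the spectrum so peaks are preserved when the baseline is subtracted.
Denoising is a Savitzky-Golay polynomial smoother; every spectrum is then
resampled onto the fixed 1024-point model grid and min-max scaled to [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .io import RamanSpectrum, SpectrumDataset, SpectrumValidationError

__all__ = [
    "PreprocessConfig",
    "PreprocessedMatrix",
    "estimate_baseline",
    "correct_baseline",
    "denoise",
    "normalize",
    "resample",
    "preprocess_pipeline",
]

DEFAULT_GRID = (385.0, 1545.0, 1024)


@dataclass
class PreprocessConfig:
    """Cleaning-chain parameters.

    als_lambda is the smoothness weight (larger -> stiffer baseline);
    als_p the asymmetry weight in (0, 1) (smaller -> tighter lower
    envelope).  Defaults are the community-standard ALS settings.
    Set denoise_window to 0 to disable smoothing.
    """

    als_lambda: float = 1e5
    als_p: float = 0.01
    als_max_iter: int = 10
    denoise_window: int = 11
    denoise_polyorder: int = 3
    grid: tuple[float, float, int] = DEFAULT_GRID

    def validate(self) -> None:
        if not (0.0 < self.als_p < 1.0):
            raise ValueError("als_p must lie in (0, 1)")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be positive")
        if self.als_max_iter < 1:
            raise ValueError("als_max_iter must be >= 1")
        if self.denoise_window:
            if self.denoise_window % 2 == 0 or self.denoise_window < 3:
                raise ValueError("denoise_window must be odd and >= 3 (or 0 to disable)")
            if self.denoise_polyorder >= self.denoise_window:
                raise ValueError("denoise_polyorder must be < denoise_window")

    def grid_axis(self) -> np.ndarray:
        start, end, n = self.grid
        return start + np.arange(n) * (end - start) / (n - 1)


@dataclass
class PreprocessedMatrix:
    """N spectra on the shared model grid, each row min-max scaled to [0,1]
    (all-zero in the degenerate constant case)."""

    values: np.ndarray
    grid: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: Optional[np.ndarray] = None
    patient_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.size:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid of {self.grid.size}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.values.shape[0]:
                raise ValueError("labels length must match row count")

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def subset(self, idx: np.ndarray) -> "PreprocessedMatrix":
        idx = np.asarray(idx)
        return PreprocessedMatrix(
            values=self.values[idx],
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx] if self.sample_ids else [],
            labels=None if self.labels is None else self.labels[idx],
            patient_ids=None
            if self.patient_ids is None
            else [self.patient_ids[i] for i in idx],
        )


def save_matrix(matrix: PreprocessedMatrix, path) -> None:
    """Serialize a matrix to the spectra CSV format (grid as header)."""
    from .io import RamanSpectrum, SpectrumDataset, write_spectra

    ids = matrix.sample_ids or [f"row{i:05d}" for i in range(matrix.n)]
    ds = SpectrumDataset(
        [RamanSpectrum(matrix.grid, row, sample_id=sid)
         for sid, row in zip(ids, matrix.values)]
    )
    if not ds.spectra:  # header-only file still needs the grid
        from .io import _fmt_axis

        header = "sample_id" + "".join("," + _fmt_axis(v) for v in matrix.grid)
        from pathlib import Path

        Path(path).write_text(header + "\n", encoding="utf-8")
        return
    write_spectra(ds, path)


def load_matrix(path, labels=None) -> PreprocessedMatrix:
    """Read a matrix written by :func:`save_matrix`; ``labels`` is an
    optional ``sample_id -> (patient_id, label)`` mapping."""
    from .io import read_spectra

    ds = read_spectra(path)
    grid = ds.spectra[0].shift_axis if ds.spectra else np.empty(0)
    values = np.vstack([s.intensity for s in ds]) if ds.spectra else np.empty((0, grid.size))
    sample_ids = [s.sample_id for s in ds]
    labs = None
    pids = None
    if labels is not None:
        pairs = [labels.get(sid) for sid in sample_ids]
        if all(p is not None for p in pairs):
            pids = [p[0] for p in pairs]
            labs = np.array([p[1] for p in pairs])
    return PreprocessedMatrix(values, grid, sample_ids, labs, pids)


_DTD_CACHE: dict[int, np.ndarray] = {}


def _second_difference_band(n: int) -> np.ndarray:
    """Upper banded form (bandwidth 2) of D2' D2 for the n-point grid."""
    band = _DTD_CACHE.get(n)
    if band is None:
        main = np.full(n, 6.0)
        main[[0, -1]] = 1.0
        main[[1, -2]] = 5.0
        off1 = np.full(n - 1, -4.0)
        off1[[0, -1]] = -2.0
        off2 = np.full(n - 2, 1.0)
        band = np.zeros((3, n))
        band[0, 2:] = off2
        band[1, 1:] = off1
        band[2, :] = main
        _DTD_CACHE[n] = band
    return band


def estimate_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, max_iter: int = 10
) -> np.ndarray:
    """Whittaker-smoother ALS baseline of a 1-D signal."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise SpectrumValidationError("need >= 4 channels for baseline estimation")
    band0 = lam * _second_difference_band(n)
    w = np.ones(n)
    b = y
    for _ in range(max_iter):
        band = band0.copy()
        band[2] += w
        b = solveh_banded(band, w * y, lower=False)
        w_new = np.where(y > b, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return b


def correct_baseline(spectrum: RamanSpectrum, cfg: PreprocessConfig) -> RamanSpectrum:
    """Subtract the ALS-estimated fluorescence baseline; axis unchanged."""
    cfg.validate()
    b = estimate_baseline(spectrum.intensity, cfg.als_lambda, cfg.als_p, cfg.als_max_iter)
    return spectrum.with_intensity(spectrum.intensity - b)


def denoise(spectrum: RamanSpectrum, cfg: PreprocessConfig) -> RamanSpectrum:
    """Savitzky-Golay smoothing; exact on polynomials of degree <= polyorder."""
    cfg.validate()
    if not cfg.denoise_window:
        return spectrum
    if cfg.denoise_window > len(spectrum):
        raise SpectrumValidationError(
            f"denoise window {cfg.denoise_window} exceeds spectrum length {len(spectrum)}"
        )
    y = savgol_filter(spectrum.intensity, cfg.denoise_window, cfg.denoise_polyorder)
    return spectrum.with_intensity(y)


def normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Min-max scale to [0, 1]; a constant spectrum maps to all zeros."""
    return spectrum.with_intensity(minmax(spectrum.intensity))


def minmax(y: np.ndarray) -> np.ndarray:
    """Row-wise min-max scaling of a vector or matrix to [0, 1]."""
    y = np.asarray(y, dtype=float)
    lo = y.min(axis=-1, keepdims=True)
    hi = y.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(y)
    np.divide(y - lo, span, out=out, where=span > 0)
    return out


def resample(spectrum: RamanSpectrum, grid: tuple[float, float, int] = DEFAULT_GRID) -> np.ndarray:
    """Linear interpolation onto the uniform model grid (values clamped at
    the measured range's edges); the spectrum must cover at least half of
    the target range."""
    start, end, n = grid
    target = start + np.arange(n) * (end - start) / (n - 1)
    if spectrum.shift_axis.size == n and np.allclose(
        spectrum.shift_axis, target, rtol=0, atol=1e-9
    ):
        return spectrum.intensity.copy()
    lo, hi = spectrum.shift_axis[0], spectrum.shift_axis[-1]
    overlap = max(0.0, min(hi, end) - max(lo, start))
    if overlap < 0.5 * (end - start):
        raise SpectrumValidationError(
            f"spectrum [{lo:g}, {hi:g}] covers less than 50% of target [{start:g}, {end:g}]"
        )
    return np.interp(target, spectrum.shift_axis, spectrum.intensity)


def preprocess_pipeline(
    dataset: SpectrumDataset,
    cfg: PreprocessConfig | None = None,
    labels: Optional[dict[str, tuple[str, int]]] = None,
) -> PreprocessedMatrix:
    """Apply baseline correction -> denoise -> resample -> normalize per
    spectrum, preserving dataset order.

    Labels/patients are taken from each spectrum's metadata, or looked up in
    the optional ``labels`` mapping (as produced by ``io.read_labels``).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    start, end, n = cfg.grid
    target = cfg.grid_axis()
    rows = np.empty((len(dataset), n))
    sample_ids: list[str] = []
    patient_ids: list[str] = []
    labs: list[int] = []
    have_labels = True
    for i, spec in enumerate(dataset):
        try:
            s = correct_baseline(spec, cfg)
            s = denoise(s, cfg)
            rows[i] = minmax(resample(s, cfg.grid))
        except Exception as exc:
            raise type(exc)(f"sample {spec.sample_id!r}: {exc}") from exc
        sample_ids.append(spec.sample_id)
        pid, lab = spec.patient_id, spec.label
        if labels is not None and spec.sample_id in labels:
            pid, lab = labels[spec.sample_id]
        patient_ids.append(pid)
        if lab is None:
            have_labels = False
        else:
            labs.append(int(lab))
    return PreprocessedMatrix(
        values=rows,
        grid=target,
        sample_ids=sample_ids,
        labels=np.asarray(labs) if (have_labels and labs) else None,
        patient_ids=patient_ids,
    )
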