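"""Two-class synthetic Raman dataset generator.

Emulates the acquisition set-up the classifier targets: spectra on a
385-1545 cm^-1 grid of 1024 channels, Gaussian peaks at standard
colorectal-tissue assignment positions riding on a smooth fluorescence
baseline, three noisy scans averaged per sample, and tumor-vs-normal
amplitude differences that are slight relative to the shared signal.
Samples are grouped into synthetic patients (each contributing both tissue
classes, as paired resections do) with a patient-level amplitude factor so
patient-wise data splits are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import RamanSpectrum, SpectrumDataset

__all__ = ["Peak", "SimConfig", "DEFAULT_PEAKS", "simulate_dataset", "ground_truth_channels"]


@dataclass(frozen=True)
class Peak:
    """One Gaussian band: center and width in cm^-1, base amplitude in
    arbitrary units, and the additive tumor-minus-normal amplitude delta."""

    center: float
    width: float
    base_amplitude: float
    class_delta: float = 0.0


# Band positions and relative strengths follow the standard colorectal-tissue
# peak assignment shipped with ramanres.interpret (Weak/Mid/Strong -> 1/2/3).
# The class signal is confined to four strong bands and is a REDUCTION in the
# tumor class (-0.3 on a base amplitude of 3): a slight difference next to
# the shared spectrum, and one that survives the per-spectrum min-max
# normalization step.  With reduced tumor bands the overlapping 1125/1130
# 1/cm complex acts as a class-independent normalization anchor, so the
# between-class difference stays localized at the discriminative bands
# instead of being redistributed onto every other channel by the rescaling.
_STRENGTH = {"Weak": 1.0, "Mid": 2.0, "Strong": 3.0}
_DISCRIMINATIVE = {936.0, 986.0, 1328.0, 1447.0}
_BANDS = [
    (497.0, "Weak"), (599.0, "Mid"), (725.0, "Mid"), (810.0, "Mid"),
    (876.0, "Weak"), (890.0, "Weak"), (936.0, "Strong"), (986.0, "Strong"),
    (1014.0, "Mid"), (1125.0, "Weak"), (1130.0, "Mid"), (1156.0, "Weak"),
    (1210.0, "Weak"), (1328.0, "Strong"), (1447.0, "Strong"),
]

DEFAULT_PEAKS: tuple[Peak, ...] = tuple(
    Peak(
        center=c,
        width=8.0,
        base_amplitude=_STRENGTH[s],
        class_delta=-0.3 if c in _DISCRIMINATIVE else 0.0,
    )
    for c, s in _BANDS
)

#: Fluorescence baseline: polynomial with positive coefficients in the
#: normalized coordinate u = (shift - start) / (end - start), magnitude
#: comparable to the strong peak amplitudes.
DEFAULT_BASELINE: tuple[float, ...] = (1.0, 1.5, 0.8, 0.5, 0.3)


@dataclass
class SimConfig:
    """Conditions of the simulated acquisition.

    ``noise_sd_fraction`` is the per-replicate Gaussian noise s.d. expressed
    as a fraction of the local (channel-wise) signal magnitude;
    ``replicate_count`` scans are averaged per sample, as the spectrometer
    protocol does.
    """

    n_per_class: int = 1000
    grid: tuple[float, float, int] = (385.0, 1545.0, 1024)
    peak_table: Sequence[Peak] = DEFAULT_PEAKS
    baseline: Sequence[float] = DEFAULT_BASELINE
    noise_sd_fraction: float = 0.02
    replicate_count: int = 3
    n_patients: int = 26
    patient_amplitude_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        start, end, n = self.grid
        if not (end > start and n >= 2):
            raise ValueError(f"invalid grid {self.grid}")
        for p in self.peak_table:
            if not (start <= p.center <= end):
                raise ValueError(f"peak center {p.center} outside grid [{start}, {end}]")
            if p.width <= 0 or p.base_amplitude <= 0:
                raise ValueError("peak widths and amplitudes must be positive")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def grid_axis(self) -> np.ndarray:
        """Channel i -> start + i * (end - start) / (n - 1), i = 0..n-1."""
        start, end, n = self.grid
        return start + np.arange(n) * (end - start) / (n - 1)


def _peak_signal(cfg: SimConfig, axis: np.ndarray, label: int) -> np.ndarray:
    y = np.zeros_like(axis)
    for p in cfg.peak_table:
        amp = p.base_amplitude + (p.class_delta if label == 1 else 0.0)
        y += amp * np.exp(-0.5 * ((axis - p.center) / p.width) ** 2)
    return y


def _baseline_signal(cfg: SimConfig, axis: np.ndarray) -> np.ndarray:
    start, end, _ = cfg.grid
    u = (axis - start) / (end - start)
    return sum(b * u**j for j, b in enumerate(cfg.baseline)) * np.ones_like(axis)


def class_mean_spectrum(cfg: SimConfig, label: int, include_baseline: bool = True) -> np.ndarray:
    """Noiseless expected spectrum of one class (patient factor at its mean 1)."""
    axis = cfg.grid_axis()
    y = _peak_signal(cfg, axis, label)
    if include_baseline:
        y = y + _baseline_signal(cfg, axis)
    return y


def simulate_dataset(cfg: SimConfig) -> tuple[SpectrumDataset, dict[str, tuple[str, int]]]:
    """Draw a balanced two-class dataset; fully determined by ``cfg.seed``.

    Each sample is the mean of ``replicate_count`` replicates of
    (patient_factor * peaks + baseline + noise), with noise drawn per
    replicate before averaging.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.grid_axis()
    baseline = _baseline_signal(cfg, axis)
    patient_factors = 1.0 + cfg.patient_amplitude_sd * rng.standard_normal(cfg.n_patients)
    patient_factors = np.clip(patient_factors, 0.2, None)

    spectra: list[RamanSpectrum] = []
    labels: dict[str, tuple[str, int]] = {}
    for label, tag in ((0, "n"), (1, "t")):
        peaks = _peak_signal(cfg, axis, label)
        for i in range(cfg.n_per_class):
            patient = i % cfg.n_patients
            clean = patient_factors[patient] * peaks + baseline
            acc = np.zeros_like(clean)
            for _ in range(cfg.replicate_count):
                noise = rng.standard_normal(axis.size) * (cfg.noise_sd_fraction * np.abs(clean))
                acc += clean + noise
            y = acc / cfg.replicate_count
            sid = f"{tag}{i:05d}"
            pid = f"P{patient:03d}"
            spectra.append(
                RamanSpectrum(axis, y, sample_id=sid, patient_id=pid, label=label)
            )
            labels[sid] = (pid, label)
    return SpectrumDataset(spectra), labels


def ground_truth_channels(cfg: SimConfig) -> set[int]:
    """0-based grid channels within one full width of any class-informative peak.

    A channel i belongs to the set iff |axis_i - center| <= width for some
    peak with class_delta != 0.
    """
    cfg.validate()
    axis = cfg.grid_axis()
    out: set[int] = set()
    for p in cfg.peak_table:
        if p.class_delta != 0.0:
            idx = np.flatnonzero(np.abs(axis - p.center) <= p.width)
            out.update(int(i) for i in idx)
    return out
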