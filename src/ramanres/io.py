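"""Reading and writing Raman spectra, labels and results.

The canonical on-disk format is a plain CSV with a header row of Raman-shift
values (cm^-1), a leading ``sample_id`` column, and one row per spectrum.
Labels live in a companion TSV with columns ``sample_id``, ``patient_id``,
``label``.  A minimal JCAMP-DX 4.24 reader (single spectrum, ``(X++(Y..Y))``
tables) is provided as a read-only convenience.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SpectrumDataset",
    "SpectrumValidationError",
    "read_spectra",
    "write_spectra",
    "read_labels",
    "write_labels",
]

#: Decimal places used when serializing the shift axis.
AXIS_DECIMALS = 4
#: Significant digits used when serializing intensities.
INTENSITY_SIGDIGITS = 8

LABEL_ALIASES = {
    "normal": 0,
    "tumor": 1,
    "tumour": 1,
    "0": 0,
    "1": 1,
}


class SpectrumValidationError(ValueError):
    """Raised when a spectrum, dataset or label table violates an invariant."""


@dataclass
class RamanSpectrum:
    """A single Raman spectrum: a strictly increasing shift axis (cm^-1)
    paired with finite intensities, plus sample metadata.

    ``label`` is the binary tissue class (0 = normal, 1 = tumor) when known.
    """

    shift_axis: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    patient_id: str = ""
    label: Optional[int] = None
    replicate_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.shift_axis = np.asarray(self.shift_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.shift_axis.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumValidationError("shift_axis and intensity must be 1-D")
        if self.shift_axis.size != self.intensity.size:
            raise SpectrumValidationError(
                f"axis length {self.shift_axis.size} != intensity length "
                f"{self.intensity.size} (sample {self.sample_id!r})"
            )
        if self.shift_axis.size < 2:
            raise SpectrumValidationError("spectrum needs at least 2 channels")
        if not np.all(np.diff(self.shift_axis) > 0):
            raise SpectrumValidationError(
                f"shift axis not strictly increasing (sample {self.sample_id!r})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumValidationError(
                f"non-finite intensity (sample {self.sample_id!r})"
            )
        if self.label is not None and self.label not in (0, 1):
            raise SpectrumValidationError(f"label must be 0/1, got {self.label!r}")

    def with_intensity(self, intensity: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with new intensities on the same axis."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def __len__(self) -> int:
        return int(self.shift_axis.size)


@dataclass
class SpectrumDataset:
    """An ordered collection of spectra, optionally on one shared grid."""

    spectra: list[RamanSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, Optional[int]]] = set()
        for s in self.spectra:
            key = (s.sample_id, s.replicate_index)
            if key in seen:
                raise SpectrumValidationError(
                    f"duplicate (sample_id, replicate_index) {key}"
                )
            seen.add(key)

    @property
    def uniform_grid(self) -> bool:
        if not self.spectra:
            return True
        first = self.spectra[0].shift_axis
        return all(
            s.shift_axis.size == first.size and np.array_equal(s.shift_axis, first)
            for s in self.spectra
        )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> RamanSpectrum:
        return self.spectra[i]


def _fmt_axis(v: float) -> str:
    return f"{v:.{AXIS_DECIMALS}f}"


def _fmt_intensity(v: float) -> str:
    return f"{v:.{INTENSITY_SIGDIGITS}g}"


def read_spectra(path: str | Path, format: str = "csv") -> SpectrumDataset:
    """Read a :class:`SpectrumDataset` from ``path``.

    ``format="csv"``: header of shift values with a leading id column, one
    row per spectrum.  A descending axis is reversed on read (intensities
    reordered with it).  ``format="jcamp"``: one spectrum per file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such spectra file: {path}")
    if format == "csv":
        return _read_csv(path)
    if format == "jcamp":
        return SpectrumDataset([_read_jcamp(path)])
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> SpectrumDataset:
    try:
        df = pd.read_csv(path, dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise SpectrumValidationError(f"empty spectra file: {path}") from exc
    if df.shape[1] < 3:
        raise SpectrumValidationError(
            f"{path}: need an id column plus >= 2 shift columns"
        )
    try:
        axis = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectrumValidationError(
            f"{path}: non-numeric shift in header: {exc}"
        ) from exc
    reverse = False
    if np.all(np.diff(axis) < 0):
        axis = axis[::-1]
        reverse = True
    if not np.all(np.diff(axis) > 0):
        raise SpectrumValidationError(f"{path}: shift axis is not monotone")
    spectra = []
    for row_i, (sid, *vals) in enumerate(df.itertuples(index=False)):
        try:
            y = np.asarray(vals, dtype=float)
        except (TypeError, ValueError) as exc:
            raise SpectrumValidationError(
                f"{path}: non-numeric intensity in row {row_i} ({sid})"
            ) from exc
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise SpectrumValidationError(
                f"{path}: non-finite intensity at row {row_i}, column {bad}"
            )
        if reverse:
            y = y[::-1]
        spectra.append(RamanSpectrum(axis, y, sample_id=str(sid)))
    return SpectrumDataset(spectra)


def write_spectra(dataset: SpectrumDataset, path: str | Path, format: str = "csv") -> None:
    """Write ``dataset`` so that :func:`read_spectra` round-trips it.

    Requires a uniform grid.  The axis is written to 4 decimal places and
    intensities to 8 significant digits; writing the same dataset twice
    yields identical bytes.
    """
    if format != "csv":
        raise ValueError("only CSV writing is supported")
    path = Path(path)
    if dataset.spectra and not dataset.uniform_grid:
        raise SpectrumValidationError("CSV writing requires a uniform grid")
    axis = dataset.spectra[0].shift_axis if dataset.spectra else np.empty(0)
    header = "sample_id" + "".join("," + _fmt_axis(v) for v in axis)
    lines = [header]
    for s in dataset:
        lines.append(s.sample_id + "".join("," + _fmt_intensity(v) for v in s.intensity))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_labels(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a labels TSV mapping sample_id -> (patient_id, label).

    Class strings are accepted case-insensitively ("Normal"/"Tumor"/"0"/"1").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such labels file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    required = {"sample_id", "patient_id", "label"}
    if not required.issubset(df.columns):
        raise SpectrumValidationError(
            f"{path}: labels table needs columns {sorted(required)}"
        )
    out: dict[str, tuple[str, int]] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid in out:
            raise SpectrumValidationError(f"{path}: duplicate sample_id {sid!r}")
        raw = str(row["label"]).strip().lower()
        if raw not in LABEL_ALIASES:
            raise SpectrumValidationError(
                f"{path}: unknown class {row['label']!r} for sample {sid!r}"
            )
        out[sid] = (str(row["patient_id"]), LABEL_ALIASES[raw])
    return out


def write_labels(labels: Mapping[str, tuple[str, int]], path: str | Path) -> None:
    """Write the labels mapping as a TSV readable by :func:`read_labels`."""
    path = Path(path)
    lines = ["sample_id\tpatient_id\tlabel"]
    for sid, (pid, lab) in labels.items():
        lines.append(f"{sid}\t{pid}\t{int(lab)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp(path: Path) -> RamanSpectrum:
    """Parse a single-spectrum JCAMP-DX file with an (X++(Y..Y)) XYDATA table."""
    text = path.read_text(encoding="utf-8", errors="replace")
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = val.strip()
            in_data = False
        elif in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise SpectrumValidationError(f"{path}: no XYDATA table found")
    xfactor = float(fields.get("XFACTOR", "1"))
    yfactor = float(fields.get("YFACTOR", "1"))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        nums = _JCAMP_NUM.findall(line)
        if len(nums) < 2:
            continue
        x0 = float(nums[0]) * xfactor
        yvals = [float(v) * yfactor for v in nums[1:]]
        if len(data_lines) > 1 and "DELTAX" in fields:
            dx = float(fields["DELTAX"]) * xfactor
        elif "LASTX" in fields and "FIRSTX" in fields and "NPOINTS" in fields:
            n = int(float(fields["NPOINTS"]))
            dx = (float(fields["LASTX"]) - float(fields["FIRSTX"])) / max(n - 1, 1) * xfactor
        else:
            dx = 1.0
        xs.extend(x0 + i * dx for i in range(len(yvals)))
        ys.extend(yvals)
    axis = np.asarray(xs)
    y = np.asarray(ys)
    order = np.argsort(axis)
    title = fields.get("TITLE", path.stem)
    return RamanSpectrum(axis[order], y[order], sample_id=title)
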