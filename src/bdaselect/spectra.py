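"""Spectra data model and delimited-text I/O.

A :class:`SpectraDataset` couples an absorbance matrix (samples x channels)
with its wavelength axis in nanometres and a per-sample target property
(e.g. octane number). A :class:`WavelengthMask` is a binary vector over
channels; a "1" means the corresponding wavelength enters the calibration
model. All selection machinery in this package operates on these two types.

The interchange format is plain CSV: an optional ``sample_id`` column,
one numeric column per wavelength (header = wavelength in nm), and a
target column (named ``target`` by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraDataset",
    "WavelengthMask",
    "make_wavelength_grid",
    "read_spectra",
    "write_spectra",
]


@dataclass
class SpectraDataset:
    """Absorbance matrix + wavelength axis + target vector.

    Parameters
    ----------
    absorbance : ndarray, shape (n_samples, n_channels)
        Absorbance values, arbitrary units.
    wavelengths_nm : ndarray, shape (n_channels,)
        Strictly increasing wavelength axis in nanometres.
    target : ndarray, shape (n_samples,)
        Property to be predicted, in its own units.
    sample_ids : list of str, optional
        Row labels; auto-generated ``s000, s001, ...`` when omitted.
    """

    absorbance: np.ndarray
    wavelengths_nm: np.ndarray
    target: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if self.wavelengths_nm.shape != (p,):
            raise ValueError(
                f"wavelength axis length {self.wavelengths_nm.size} does not "
                f"match {p} absorbance columns"
            )
        if self.target.shape != (n,):
            raise ValueError(
                f"target length {self.target.size} does not match {n} samples"
            )
        if p > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths not increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite values in absorbance")
        if not np.all(np.isfinite(self.target)):
            raise ValueError("non-finite values in target")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:03d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match n_samples")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, rows: Sequence[int]) -> "SpectraDataset":
        """New dataset restricted to the given sample rows (order preserved)."""
        rows = np.asarray(rows, dtype=int)
        return SpectraDataset(
            absorbance=self.absorbance[rows],
            wavelengths_nm=self.wavelengths_nm.copy(),
            target=self.target[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
        )


@dataclass
class WavelengthMask:
    """Binary selection vector over spectral channels (1 = selected)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.ndim != 1:
            raise ValueError("mask bits must be a 1-D vector")
        if not np.all(np.isin(bits, (0, 1))):
            raise ValueError("mask bits must be 0 or 1")
        self.bits = bits.astype(np.int8)

    @property
    def n_channels(self) -> int:
        return self.bits.size

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        """0-based channel indices of the selected wavelengths."""
        return np.flatnonzero(self.bits)

    def wavelengths(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Selected wavelengths in nm on the given axis."""
        return np.asarray(wavelengths_nm)[self.indices]

    def as_bool(self) -> np.ndarray:
        return self.bits.astype(bool)


def make_wavelength_grid(
    start_nm: float, stop_nm: float, step_nm: float
) -> np.ndarray:
    """Inclusive evenly spaced wavelength axis ``[start, start+step, ..., stop]``.

    ``stop_nm`` must be reachable from ``start_nm`` by an integer number of
    positive steps; the common NIR layout 900-1700 nm at 2 nm gives 401
    channels.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if stop_nm <= start_nm:
        raise ValueError("stop_nm must exceed start_nm")
    n_steps = (stop_nm - start_nm) / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"stop {stop_nm} not reachable from start {start_nm} "
            f"by whole steps of {step_nm}"
        )
    n = int(round(n_steps)) + 1
    return start_nm + step_nm * np.arange(n)


def read_spectra(
    path: str | Path,
    target_column: str = "target",
    id_column: str = "sample_id",
    sep: str = ",",
) -> SpectraDataset:
    """Read a spectra table from delimited text.

    Expects a header of numeric wavelength columns plus a target column;
    an ``id_column`` is used for sample labels when present.
    """
    df = pd.read_csv(path, sep=sep)
    if target_column not in df.columns:
        raise ValueError(f"missing target column {target_column!r}")
    sample_ids = None
    if id_column in df.columns:
        sample_ids = df[id_column].astype(str).tolist()
        df = df.drop(columns=[id_column])
    y = df.pop(target_column)
    try:
        wavelengths = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column in header: {exc}") from exc
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError("wavelengths not increasing")
    absorbance = df.to_numpy(dtype=float)
    return SpectraDataset(
        absorbance=absorbance,
        wavelengths_nm=wavelengths,
        target=y.to_numpy(dtype=float),
        sample_ids=sample_ids,
    )


def write_spectra(
    dataset: SpectraDataset,
    path: str | Path,
    target_column: str = "target",
    id_column: str = "sample_id",
) -> None:
    """Write a dataset in the CSV layout that :func:`read_spectra` accepts."""
    if dataset.n_samples == 0:
        raise ValueError("refusing to write a dataset with 0 samples")
    cols: dict[str, object] = {id_column: dataset.sample_ids}
    for j, wl in enumerate(dataset.wavelengths_nm):
        cols[repr(float(wl))] = dataset.absorbance[:, j]
    cols[target_column] = dataset.target
    pd.DataFrame(cols).to_csv(path, index=False)
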