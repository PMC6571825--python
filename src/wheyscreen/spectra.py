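"""In-memory containers and text I/O for Raman spectrum sets.

The central object is :class:`SpectrumSet`, the I x J intensity matrix of a
chemometric experiment: I spectra sharing one wavenumber axis of J channels,
with a per-spectrum metadata table (class label, adulterant mass fractions,
replicate copy, measurement position).

On-disk formats are plain text: the two-column per-spectrum dialect exported
by Renishaw instruments (wavenumber, intensity, whitespace separated), and a
wide CSV (first column the wavenumber axis, one column per spectrum) paired
with a metadata CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectra",
    "read_two_column",
    "write_two_column_dir",
]

#: metadata columns every generated set carries
META_COLUMNS = ("spectrum_id", "class_label", "creatine", "taurine", "glutamine",
                "copy", "position")


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("wavenumber axis must be a 1-D array with >= 2 points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


@dataclass
class Spectrum:
    """A single Raman spectrum: wavenumber axis, intensities, metadata."""

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _check_axis(self.axis)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise ValueError("axis and intensity must have equal length")

    def copy(self) -> "Spectrum":
        return Spectrum(self.axis.copy(), self.intensity.copy(), dict(self.meta))


class SpectrumSet:
    """I spectra on a shared wavenumber axis with a per-row metadata table.

    Parameters
    ----------
    axis
        Strictly increasing wavenumbers (cm^-1), shape (J,).
    intensities
        Intensity matrix, shape (I, J), arbitrary units.
    meta
        DataFrame with one row per spectrum; reset to a RangeIndex.
    """

    def __init__(self, axis: np.ndarray, intensities: np.ndarray,
                 meta: pd.DataFrame | None = None):
        self.axis = _check_axis(axis)
        X = np.asarray(intensities, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.axis.size:
            raise ValueError(
                f"intensity matrix has {X.shape[1]} channels, axis has {self.axis.size}")
        self.intensities = X
        if meta is None:
            meta = pd.DataFrame(index=range(X.shape[0]))
        if len(meta) != X.shape[0]:
            raise ValueError("metadata rows must match number of spectra")
        self.meta = meta.reset_index(drop=True)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i].copy(),
                        self.meta.iloc[i].to_dict())

    def subset(self, rows) -> "SpectrumSet":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return SpectrumSet(self.axis, self.intensities[rows],
                           self.meta.iloc[rows])

    def with_intensities(self, X: np.ndarray) -> "SpectrumSet":
        """Same axis and metadata, new intensity matrix (preprocessing output)."""
        return SpectrumSet(self.axis, X, self.meta)

    def labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    def fractions(self, adulterant: str) -> np.ndarray:
        """Mass fraction (%) of one adulterant for every spectrum."""
        return self.meta[adulterant].to_numpy(dtype=float)

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(self.axis.copy(), self.intensities.copy(),
                           self.meta.copy())

    # -- text I/O ----------------------------------------------------------
    def to_wide_csv(self, spectra_path, meta_path=None) -> None:
        """Write a wide CSV (wavenumber + one column per spectrum id).

        When ``meta_path`` is given the metadata table is written beside it.
        """
        ids = (self.meta["spectrum_id"].astype(str).tolist()
               if "spectrum_id" in self.meta else
               [f"s{i:04d}" for i in range(len(self))])
        wide = pd.DataFrame(self.intensities.T, columns=ids)
        wide.insert(0, "wavenumber", self.axis)
        Path(spectra_path).parent.mkdir(parents=True, exist_ok=True)
        wide.to_csv(spectra_path, index=False)
        if meta_path is not None:
            self.meta.to_csv(meta_path, index=False)

    @classmethod
    def from_wide_csv(cls, spectra_path, meta_path=None) -> "SpectrumSet":
        wide = pd.read_csv(spectra_path)
        axis = wide.iloc[:, 0].to_numpy(dtype=float)
        X = wide.iloc[:, 1:].to_numpy(dtype=float).T
        meta = pd.read_csv(meta_path) if meta_path is not None else None
        return cls(axis, X, meta)


def write_two_column_dir(sset: SpectrumSet, directory) -> list[Path]:
    """Write one two-column text file per spectrum (Renishaw export dialect)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(sset)):
        sid = (str(sset.meta["spectrum_id"].iloc[i])
               if "spectrum_id" in sset.meta else f"s{i:04d}")
        p = directory / f"{sid}.txt"
        np.savetxt(p, np.column_stack([sset.axis, sset.intensities[i]]),
                   fmt="%.6f\t%.8e")
        paths.append(p)
    return paths


def read_two_column(path) -> Spectrum:
    """Read one whitespace-separated (wavenumber, intensity) text file."""
    path = Path(path)
    try:
        arr = np.loadtxt(path)
    except ValueError as exc:  # re-raise naming the file
        raise ValueError(f"malformed spectrum file {path}: {exc}") from None
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"malformed spectrum file {path}: expected two columns")
    return Spectrum(arr[:, 0], arr[:, 1], {"spectrum_id": path.stem})


def read_spectra(paths, grid_tolerance: float = 0.5,
                 log: list[str] | None = None) -> SpectrumSet:
    """Assemble a SpectrumSet from per-spectrum text files.

    All files must share one wavenumber grid; grids shifted by at most
    ``grid_tolerance`` cm^-1 per point are linearly interpolated onto the
    first file's grid (and noted in ``log``), larger disagreement is an error.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no spectrum files given")
    first = read_two_column(paths[0])
    axis = first.axis
    rows, meta_rows = [first.intensity], [first.meta]
    for p in paths[1:]:
        s = read_two_column(p)
        if s.axis.shape == axis.shape and np.array_equal(s.axis, axis):
            rows.append(s.intensity)
        else:
            if (s.axis.shape != axis.shape
                    or np.max(np.abs(s.axis - axis)) > grid_tolerance):
                raise ValueError(
                    f"{p}: wavenumber grid differs from {paths[0]} by more than "
                    f"{grid_tolerance} cm^-1")
            rows.append(np.interp(axis, s.axis, s.intensity))
            if log is not None:
                log.append(f"interpolated {p.name} onto reference grid")
        meta_rows.append(s.meta)
    return SpectrumSet(axis, np.vstack(rows), pd.DataFrame(meta_rows))
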