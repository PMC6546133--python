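"""Reading, writing and validating spectra datasets.

Two on-disk representations are supported:

* ``delimited`` — a UTF-8 CSV whose first row carries the m/z axis, with
  optional leading metadata columns named ``id``, ``label`` and ``group``.
  Human-inspectable; used for small fixtures.
* ``container`` — an HDF5 file with datasets ``/intensities``, ``/mz`` and,
  when present, ``/labels``, ``/groups``, ``/spectrum_ids``.

Intensity matrices are dense and non-negative; spectra are rows.  Missing
values are not supported — any NaN is rejected at validation time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional

import h5py
import numpy as np

__all__ = [
    "SpectraDataset",
    "read_dataset",
    "write_dataset",
    "tic_normalize",
    "read_imzml",
]

_RESERVED = ("id", "label", "group")

Format = Literal["delimited", "container"]


class SpectraValidationError(ValueError):
    """Raised when a dataset violates the non-negativity / shape contract."""


@dataclass
class SpectraDataset:
    """A labeled, grouped collection of mass spectra on a common m/z axis.

    Parameters
    ----------
    intensities
        Non-negative matrix, one spectrum per row (n x m).
    mz_axis
        Strictly increasing vector of m/z values (length m, Thomson).
    labels
        Optional binary class labels in {0, 1}, one per spectrum.
    groups
        Optional group identifiers (e.g. the TMA a spectrum was measured
        on), one per spectrum; the unit of cross-validation.
    spectrum_ids
        Optional string identifiers, one per spectrum.
    """

    intensities: np.ndarray
    mz_axis: np.ndarray
    labels: Optional[np.ndarray] = None
    groups: Optional[np.ndarray] = None
    spectrum_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise SpectraValidationError(
                f"intensities must be 2-D, got shape {self.intensities.shape}"
            )
        n, m = self.intensities.shape
        if n == 0 or m == 0:
            raise SpectraValidationError("empty dataset (n=0 or m=0) rejected")
        if np.isnan(self.intensities).any():
            i, j = np.argwhere(np.isnan(self.intensities))[0]
            raise SpectraValidationError(
                f"NaN intensity at spectrum {i}, channel {j}; missing values unsupported"
            )
        if (self.intensities < 0).any():
            i, j = np.argwhere(self.intensities < 0)[0]
            raise SpectraValidationError(
                f"negative intensity {self.intensities[i, j]} at spectrum {i}, channel {j}"
            )
        if self.mz_axis.shape != (m,):
            raise SpectraValidationError(
                f"mz_axis length {self.mz_axis.shape} does not match {m} channels"
            )
        if not np.all(np.diff(self.mz_axis) > 0):
            k = int(np.argmax(np.diff(self.mz_axis) <= 0))
            raise SpectraValidationError(
                f"mz_axis not strictly increasing at index {k}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise SpectraValidationError(
                    f"labels length {self.labels.shape} does not match {n} spectra"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise SpectraValidationError("labels must be binary (0/1)")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != (n,):
                raise SpectraValidationError(
                    f"groups length {self.groups.shape} does not match {n} spectra"
                )
        if self.spectrum_ids is not None:
            self.spectrum_ids = np.asarray(self.spectrum_ids, dtype=object)
            if self.spectrum_ids.shape != (n,):
                raise SpectraValidationError("spectrum_ids length mismatch")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def subset(self, index: np.ndarray) -> "SpectraDataset":
        """Row-subset the dataset (used by cross-validation folds)."""
        index = np.asarray(index)
        return SpectraDataset(
            intensities=self.intensities[index],
            mz_axis=self.mz_axis,
            labels=None if self.labels is None else self.labels[index],
            groups=None if self.groups is None else self.groups[index],
            spectrum_ids=(
                None if self.spectrum_ids is None else self.spectrum_ids[index]
            ),
        )


def _read_delimited(path: Path) -> SpectraDataset:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectraValidationError(f"{path}: empty file") from None
        meta_cols = []
        for name in header:
            if name in _RESERVED:
                meta_cols.append(name)
            else:
                break
        k = len(meta_cols)
        try:
            mz = np.array([float(v) for v in header[k:]])
        except ValueError as exc:
            raise SpectraValidationError(
                f"{path}: non-numeric m/z value in header row: {exc}"
            ) from None
        ids, labels, groups, rows = [], [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != k + mz.size:
                raise SpectraValidationError(
                    f"{path}: row {lineno} has {len(row)} fields, expected {k + mz.size}"
                )
            for name, value in zip(meta_cols, row[:k]):
                if name == "id":
                    ids.append(value)
                elif name == "label":
                    labels.append(int(value))
                else:
                    groups.append(value)
            try:
                rows.append([float(v) for v in row[k:]])
            except ValueError as exc:
                raise SpectraValidationError(
                    f"{path}: non-numeric intensity in row {lineno}: {exc}"
                ) from None
    return SpectraDataset(
        intensities=np.array(rows, dtype=float, ndmin=2),
        mz_axis=mz,
        labels=np.array(labels) if labels else None,
        groups=np.array(groups) if groups else None,
        spectrum_ids=np.array(ids, dtype=object) if ids else None,
    )


def _write_delimited(ds: SpectraDataset, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header: list[str] = []
        if ds.spectrum_ids is not None:
            header.append("id")
        if ds.labels is not None:
            header.append("label")
        if ds.groups is not None:
            header.append("group")
        writer.writerow(header + [repr(float(v)) for v in ds.mz_axis])
        for i in range(ds.n_spectra):
            row: list[str] = []
            if ds.spectrum_ids is not None:
                row.append(str(ds.spectrum_ids[i]))
            if ds.labels is not None:
                row.append(str(int(ds.labels[i])))
            if ds.groups is not None:
                row.append(str(ds.groups[i]))
            writer.writerow(row + [repr(float(v)) for v in ds.intensities[i]])


def _read_container(path: Path) -> SpectraDataset:
    with h5py.File(path, "r") as f:
        intensities = f["intensities"][()]
        mz = f["mz"][()]
        labels = f["labels"][()] if "labels" in f else None
        groups = None
        if "groups" in f:
            groups = f["groups"].asstr()[()]
        ids = None
        if "spectrum_ids" in f:
            ids = f["spectrum_ids"].asstr()[()]
    return SpectraDataset(intensities, mz, labels=labels, groups=groups,
                          spectrum_ids=ids)


def _write_container(ds: SpectraDataset, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=ds.intensities)
        f.create_dataset("mz", data=ds.mz_axis)
        if ds.labels is not None:
            f.create_dataset("labels", data=ds.labels)
        if ds.groups is not None:
            f.create_dataset(
                "groups", data=np.asarray(ds.groups, dtype=str).astype("S")
            )
        if ds.spectrum_ids is not None:
            f.create_dataset(
                "spectrum_ids",
                data=np.asarray(ds.spectrum_ids, dtype=str).astype("S"),
            )


def read_dataset(path: str | Path, format: Format = "delimited") -> SpectraDataset:
    """Read a :class:`SpectraDataset` from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        ``"delimited"`` (CSV, m/z header row) or ``"container"`` (HDF5).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "container":
        return _read_container(path)
    raise ValueError(f"unknown format {format!r}")


def write_dataset(
    ds: SpectraDataset, path: str | Path, format: Format = "delimited"
) -> None:
    """Write ``ds`` to ``path``; ``read_dataset`` round-trips exactly."""
    path = Path(path)
    if format == "delimited":
        _write_delimited(ds, path)
    elif format == "container":
        _write_container(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def tic_normalize(ds: SpectraDataset) -> SpectraDataset:
    """Scale every spectrum to unit total ion count (row sum 1).

    Idempotent; preserves within-spectrum intensity ordering.  An all-zero
    spectrum has no defined TIC and is rejected.
    """
    sums = ds.intensities.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise SpectraValidationError(
            f"spectrum {zero[0]} has non-positive total ion count; cannot normalize"
        )
    return replace(ds, intensities=ds.intensities / sums[:, None])


def read_imzml(
    path: str | Path, mz_axis: Optional[np.ndarray] = None
) -> SpectraDataset:
    """Optional adapter: load an imzML imaging-MS file onto a common m/z axis.

    Continuous or processed spectra are binned onto ``mz_axis`` (defaults
    to the first spectrum's axis) by nearest-bin assignment, accumulating
    intensities that fall into the same bin.  Requires ``pyimzml``.
    """
    try:
        from pyimzml.ImzMLParser import ImzMLParser
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("read_imzml requires the pyimzml package") from exc

    parser = ImzMLParser(str(path))
    first_mz, _ = parser.getspectrum(0)
    axis = np.asarray(first_mz if mz_axis is None else mz_axis, dtype=float)
    n = len(parser.coordinates)
    Y = np.zeros((n, axis.size))
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        right = np.clip(np.searchsorted(axis, mzs), 1, axis.size - 1)
        idx = np.where(axis[right] - mzs <= mzs - axis[right - 1], right,
                       right - 1)
        np.add.at(Y[i], idx, ints)
    ids = np.array([f"{x}_{y}_{z}" for (x, y, z) in parser.coordinates],
                   dtype=object)
    return SpectraDataset(Y, axis, spectrum_ids=ids)
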