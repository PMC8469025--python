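"""Reading, writing and basic reshaping of GC-IMS sample matrices.

A GC-IMS measurement is a two-dimensional intensity grid: rows follow the
gas-chromatographic retention time (seconds), columns follow the ion-mobility
drift time (milliseconds).  Instruments export one such matrix per sample,
typically as a plain CSV dump of the intensity grid; axis vectors either ride
along as a header row/column or are reconstructed from the sampling periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SampleMatrix",
    "Dataset",
    "CsvDialect",
    "FormatError",
    "read_sample_csv",
    "write_sample_csv",
    "write_dataset_container",
    "read_dataset_container",
    "crop_and_decimate",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class SampleMatrix:
    """One GC-IMS measurement.

    Parameters
    ----------
    intensities
        2D array, shape ``(n_retention, n_drift)``; arbitrary intensity units.
    retention_axis
        Strictly increasing retention times in seconds, one per row.
    drift_axis
        Strictly increasing drift times in milliseconds, one per column.
    sample_id
        Free-text identifier.
    meta
        String key/value annotations (instrument settings, provenance, ...).
    """

    intensities: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D array")
        nr, nd = self.intensities.shape
        if self.retention_axis.shape != (nr,):
            raise ValueError(
                f"retention_axis length {self.retention_axis.size} != row count {nr}"
            )
        if self.drift_axis.shape != (nd,):
            raise ValueError(
                f"drift_axis length {self.drift_axis.size} != column count {nd}"
            )
        for name, ax in (("retention_axis", self.retention_axis),
                         ("drift_axis", self.drift_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def with_intensities(self, intensities: np.ndarray, **meta) -> "SampleMatrix":
        """Copy carrying new intensities on the same axes."""
        return SampleMatrix(
            intensities=np.asarray(intensities, dtype=float),
            retention_axis=self.retention_axis.copy(),
            drift_axis=self.drift_axis.copy(),
            sample_id=self.sample_id,
            meta={**self.meta, **{k: str(v) for k, v in meta.items()}},
        )


@dataclass
class Dataset:
    """Ordered collection of samples with per-sample class labels."""

    samples: list
    labels: np.ndarray
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.samples) == 0:
            raise ValueError("dataset is empty")
        if self.labels.shape != (len(self.samples),):
            raise ValueError("labels length != number of samples")
        if not 0 <= self.reference_index < len(self.samples):
            raise ValueError("reference_index out of range")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> SampleMatrix:
        return self.samples[i]

    @property
    def reference(self) -> SampleMatrix:
        return self.samples[self.reference_index]

    def assert_uniform_shape(self) -> None:
        shapes = {s.shape for s in self.samples}
        if len(shapes) != 1:
            raise ValueError(f"samples have inconsistent shapes: {sorted(shapes)}")

    def map(self, fn) -> "Dataset":
        """New dataset with ``fn`` applied to every sample."""
        return Dataset(
            samples=[fn(s) for s in self.samples],
            labels=self.labels.copy(),
            reference_index=self.reference_index,
        )


@dataclass
class CsvDialect:
    """How a per-sample CSV is laid out.

    The default matches the most common vendor export after conversion: no
    header, one row per retention point, comma separated; axes are rebuilt as
    uniform grids from the sampling periods.
    """

    delimiter: str = ","
    header_row_is_drift_axis: bool = False
    first_col_is_retention_axis: bool = False
    transpose: bool = False
    retention_period: float = 1.0   # seconds per row
    retention_origin: float = 0.0
    drift_period: float = 0.05      # ms per column
    drift_origin: float = 0.0


def read_sample_csv(path, dialect: CsvDialect | None = None,
                    sample_id: str | None = None) -> SampleMatrix:
    """Read one sample matrix from a CSV file.

    Raises :class:`FormatError` naming the offending line for ragged rows and
    the offending cell for non-numeric entries.
    """
    dialect = dialect or CsvDialect()
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if not lines:
        raise FormatError(f"{path}: empty file")

    rows = [ln.split(dialect.delimiter) for ln in lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"{path}: row {i + 1} has {len(r)} fields, expected {width}"
            )
    grid = np.empty((len(rows), width), dtype=float)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r):
            try:
                grid[i, j] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {i + 1}, "
                    f"column {j + 1}"
                ) from exc

    drift_axis = None
    retention_axis = None
    if dialect.header_row_is_drift_axis:
        header = grid[0]
        grid = grid[1:]
        drift_axis = header[1:] if dialect.first_col_is_retention_axis else header
    if dialect.first_col_is_retention_axis:
        retention_axis = grid[:, 0]
        grid = grid[:, 1:]
    if dialect.transpose:
        grid = grid.T

    nr, nd = grid.shape
    if retention_axis is None:
        retention_axis = dialect.retention_origin + \
            dialect.retention_period * np.arange(nr)
    if drift_axis is None:
        drift_axis = dialect.drift_origin + dialect.drift_period * np.arange(nd)

    if sample_id is None:
        sample_id = str(path)
    return SampleMatrix(grid, retention_axis, drift_axis, sample_id=sample_id)


def write_sample_csv(m: SampleMatrix, path, include_axes: bool = True) -> None:
    """Write a sample as CSV; with ``include_axes`` the first row carries the
    drift axis and the first column the retention axis (readable back with
    ``CsvDialect(header_row_is_drift_axis=True, first_col_is_retention_axis=True)``).
    """
    with open(path, "w", encoding="utf-8") as fh:
        if include_axes:
            fh.write("0," + ",".join(repr(float(v))
                                     for v in m.drift_axis) + "\n")
            for tr, row in zip(m.retention_axis, m.intensities):
                fh.write(repr(float(tr)) + "," +
                         ",".join(repr(float(v)) for v in row) + "\n")
        else:
            for row in m.intensities:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_dataset_container(ds: Dataset, path) -> None:
    """Persist a dataset to a single HDF5 container (lossless)."""
    ds.assert_uniform_shape()
    with h5py.File(path, "w") as f:
        f.attrs["reference_index"] = ds.reference_index
        f.create_dataset("labels", data=ds.labels)
        grp = f.create_group("samples")
        for i, s in enumerate(ds.samples):
            g = grp.create_group(f"{i:05d}")
            g.attrs["sample_id"] = s.sample_id
            for k, v in s.meta.items():
                g.attrs[f"meta_{k}"] = str(v)
            g.create_dataset("intensities", data=s.intensities)
            g.create_dataset("retention_axis", data=s.retention_axis)
            g.create_dataset("drift_axis", data=s.drift_axis)


def read_dataset_container(path) -> Dataset:
    """Read a dataset container written by :func:`write_dataset_container`."""
    with h5py.File(path, "r") as f:
        if "labels" not in f:
            raise FormatError(f"{path}: container has no labels block")
        labels = np.asarray(f["labels"])
        samples = []
        for key in sorted(f["samples"]):
            g = f["samples"][key]
            meta = {k[5:]: g.attrs[k] for k in g.attrs if k.startswith("meta_")}
            samples.append(SampleMatrix(
                intensities=np.asarray(g["intensities"]),
                retention_axis=np.asarray(g["retention_axis"]),
                drift_axis=np.asarray(g["drift_axis"]),
                sample_id=str(g.attrs.get("sample_id", key)),
                meta=meta,
            ))
        ref = int(f.attrs.get("reference_index", 0))
    return Dataset(samples=samples, labels=labels, reference_index=ref)


def crop_and_decimate(m: SampleMatrix, drift_window: tuple[float, float] | None = None,
                      retention_factor: int = 1,
                      block_average: bool = False) -> SampleMatrix:
    """Restrict the drift axis to a region of interest and decimate retention.

    ``drift_window`` is half-open ``[lo, hi)`` in milliseconds on the sampled
    grid.  ``retention_factor`` keeps every k-th retention row starting at
    row 0 (or averages blocks of k rows when ``block_average``).
    """
    if retention_factor < 1:
        raise ValueError("retention_factor must be >= 1")
    grid = m.intensities
    drift_axis = m.drift_axis
    if drift_window is not None:
        lo, hi = drift_window
        mask = (drift_axis >= lo) & (drift_axis < hi)
        if not mask.any():
            raise ValueError(f"drift window [{lo}, {hi}) selects no columns")
        grid = grid[:, mask]
        drift_axis = drift_axis[mask]
    k = retention_factor
    if k > 1:
        if block_average:
            nblocks = math.ceil(grid.shape[0] / k)
            out = np.empty((nblocks, grid.shape[1]))
            ax = np.empty(nblocks)
            for b in range(nblocks):
                out[b] = grid[b * k:(b + 1) * k].mean(axis=0)
                ax[b] = m.retention_axis[b * k:(b + 1) * k].mean()
            grid, retention_axis = out, ax
        else:
            grid = grid[::k]
            retention_axis = m.retention_axis[::k]
    else:
        retention_axis = m.retention_axis
    return SampleMatrix(grid.copy(), retention_axis.copy(), drift_axis.copy(),
                        sample_id=m.sample_id, meta=dict(m.meta))
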