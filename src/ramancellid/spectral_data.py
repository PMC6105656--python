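"""Domain types and plain-text I/O for Raman spectra, datasets, and maps.

The atomic record is a :class:`Spectrum`: one wavenumber axis (cm^-1) plus
one intensity vector (CCD counts) and acquisition metadata.  Collections of
spectra on a shared axis form a :class:`SpectralDataset` (the input to PCA
and PLS-DA); raster area scans form a :class:`HyperspectralMap`.

File dialect: comma-separated text, the axis as the first row, one intensity
row per spectrum, ``#``-prefixed comment lines ignored; per-spectrum metadata
lives in a second CSV keyed by row order.  Maps store their grid shape and
spatial step in a JSON sidecar next to the flattened cube.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataError",
    "ParseError",
    "StructuralError",
    "RangeError",
    "FINGERPRINT_WINDOW",
    "HIGH_WAVENUMBER_WINDOW",
    "WavenumberAxis",
    "SpectrumMeta",
    "Spectrum",
    "SpectralDataset",
    "HyperspectralMap",
    "read_dataset",
    "write_dataset",
    "read_map",
    "write_map",
    "crop_axis",
]


class SpectralDataError(ValueError):
    """Base class for domain validation failures."""


class ParseError(SpectralDataError):
    """A text field could not be parsed as a number."""


class StructuralError(SpectralDataError):
    """Row/axis bookkeeping is inconsistent (lengths, counts, shared axes)."""


class RangeError(SpectralDataError):
    """A requested wavenumber window does not overlap the axis."""


#: Fingerprint window used at 785 nm excitation (cm^-1).
FINGERPRINT_WINDOW = (600.0, 1800.0)
#: High-wavenumber (CH/OH stretch) window, reachable at 488 nm only.
HIGH_WAVENUMBER_WINDOW = (2700.0, 3600.0)

_META_COLUMNS = [
    "cell_line",
    "cell_id",
    "point_index",
    "scan_index",
    "excitation_nm",
    "exposure_s",
    "accumulations",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1.

    Spacing may be non-uniform but must be positive everywhere.  The grid
    is validated once at construction and treated as immutable thereafter.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise StructuralError(
                f"axis must be a non-empty 1-D sequence, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise StructuralError("axis contains non-finite values")
        if np.any(np.diff(v) <= 0):
            raise StructuralError("axis must be strictly increasing")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with eq override
        return hash((self.values.shape, self.values.tobytes()))

    @property
    def step(self) -> float:
        """Mean grid spacing (cm^-1)."""
        return float(np.mean(np.diff(self.values)))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points with lo <= nu <= hi."""
        return (self.values >= lo) & (self.values <= hi)

    @classmethod
    def regular(cls, lo: float, hi: float, step: float = 1.0) -> "WavenumberAxis":
        """Uniform grid from lo to hi inclusive (endpoint kept if on-grid)."""
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata for one spectrum.

    ``point_index`` is the position along a line scan, ``scan_index`` the
    repeat number (maps to elapsed time in longitudinal experiments).
    785 nm acquisitions cover the fingerprint window only; 488 nm also
    reaches the high-wavenumber CH/OH stretch region.
    """

    cell_line: str = ""
    cell_id: str = ""
    point_index: int = 0
    scan_index: int = 0
    excitation_nm: int = 785
    exposure_s: float = 1.0
    accumulations: int = 30

    def __post_init__(self) -> None:
        if self.excitation_nm not in (488, 785):
            raise SpectralDataError(
                f"excitation_nm must be 488 or 785, got {self.excitation_nm}"
            )
        if self.point_index < 0 or self.scan_index < 0:
            raise SpectralDataError("point_index and scan_index must be >= 0")
        if self.exposure_s <= 0 or self.accumulations <= 0:
            raise SpectralDataError("exposure_s and accumulations must be positive")


@dataclass(frozen=True)
class Spectrum:
    """One Raman spectrum: intensities (counts) on a wavenumber axis."""

    axis: WavenumberAxis
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1 or y.size != len(self.axis):
            raise StructuralError(
                f"intensities length {y.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise SpectralDataError("intensities contain NaN/Inf")
        y.setflags(write=False)
        object.__setattr__(self, "intensities", y)

    def replace_intensities(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.axis, y, self.meta)


class SpectralDataset:
    """Labeled spectrum collection on one shared wavenumber axis.

    Parameters
    ----------
    axis:
        Shared wavenumber grid.
    matrix:
        ``n_spectra x n_wavenumbers`` intensity matrix, one row per spectrum.
    meta:
        DataFrame with one row per spectrum; missing standard columns are
        filled with defaults.  ``cell_line`` doubles as the class label.
    """

    def __init__(self, axis: WavenumberAxis, matrix: np.ndarray, meta: pd.DataFrame):
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        if matrix.size == 0:
            matrix = matrix.reshape(0, len(axis))
        if matrix.shape[1] != len(axis):
            raise StructuralError(
                f"matrix has {matrix.shape[1]} columns but axis has {len(axis)} points"
            )
        if not np.all(np.isfinite(matrix)):
            raise SpectralDataError("matrix contains NaN/Inf")
        meta = meta.reset_index(drop=True).copy()
        if len(meta) != matrix.shape[0]:
            raise StructuralError(
                f"metadata has {len(meta)} rows but matrix has {matrix.shape[0]}"
            )
        defaults = dataclasses.asdict(SpectrumMeta())
        for col in _META_COLUMNS:
            if col not in meta.columns:
                meta[col] = defaults[col]
        self.axis = axis
        self.matrix = matrix
        self.meta = meta

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["cell_line"].to_numpy()

    @property
    def classes(self) -> list[str]:
        """Distinct class labels in first-appearance order."""
        return list(pd.unique(self.meta["cell_line"]))

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        m = SpectrumMeta(
            cell_line=str(row["cell_line"]),
            cell_id=str(row["cell_id"]),
            point_index=int(row["point_index"]),
            scan_index=int(row["scan_index"]),
            excitation_nm=int(row["excitation_nm"]),
            exposure_s=float(row["exposure_s"]),
            accumulations=int(row["accumulations"]),
        )
        return Spectrum(self.axis, self.matrix[i], m)

    def select(self, mask: np.ndarray) -> "SpectralDataset":
        mask = np.asarray(mask)
        return SpectralDataset(self.axis, self.matrix[mask], self.meta.loc[mask])

    def with_matrix(self, matrix: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.axis, matrix, self.meta)

    def cell_group_indices(self) -> list[np.ndarray]:
        """Row-index arrays per (cell_line, cell_id), first-appearance order.

        The explicit factorization guarantees a stable order shared by
        every consumer (cell averaging, pooled-CV aggregation), which
        pandas' ``groupby(...).groups`` does not under ``sort=False``.
        """
        key = (
            self.meta["cell_line"].astype(str)
            + "\x00"
            + self.meta["cell_id"].astype(str)
        )
        codes, uniques = pd.factorize(key)
        return [np.flatnonzero(codes == g) for g in range(len(uniques))]

    def average_by_cell(self) -> "SpectralDataset":
        """Pointwise mean spectrum per (cell_line, cell_id) group."""
        rows, metas = [], []
        for sel in self.cell_group_indices():
            rows.append(self.matrix[sel].mean(axis=0))
            first = self.meta.iloc[sel[0]].copy()
            first["point_index"] = 0
            metas.append(first)
        if not rows:
            return SpectralDataset(self.axis, np.empty((0, len(self.axis))), self.meta.iloc[:0])
        return SpectralDataset(self.axis, np.vstack(rows), pd.DataFrame(metas))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            self.axis == other.axis
            and np.array_equal(self.matrix, other.matrix)
            and self.meta[_META_COLUMNS].astype(str).equals(
                other.meta[_META_COLUMNS].astype(str)
            )
        )


@dataclass(frozen=True)
class HyperspectralMap:
    """Raster area scan: an (nx, ny) grid of spectra with spatial step in um.

    The cube is stored flattened row-major: pixel (ix, iy) is cube row
    ``ix * ny + iy``.
    """

    grid_shape: tuple[int, int]
    step_um: float
    axis: WavenumberAxis
    cube: np.ndarray

    def __post_init__(self) -> None:
        nx, ny = self.grid_shape
        cube = np.asarray(self.cube, dtype=float)
        if cube.shape != (nx * ny, len(self.axis)):
            raise StructuralError(
                f"cube shape {cube.shape} != ({nx * ny}, {len(self.axis)})"
            )
        if self.step_um <= 0:
            raise SpectralDataError("step_um must be positive")
        object.__setattr__(self, "cube", cube)
        object.__setattr__(self, "grid_shape", (int(nx), int(ny)))

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0]

    def image(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-pixel vector into the (nx, ny) grid."""
        return np.asarray(values).reshape(self.grid_shape)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_matrix_file(path: Path) -> np.ndarray:
    rows: list[np.ndarray] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",")
            try:
                row = np.array([float(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field ({exc})")
            if width is None:
                width = row.size
            elif row.size != width:
                raise StructuralError(
                    f"{path}:{lineno}: row has {row.size} values, expected {width}"
                )
            rows.append(row)
    if width is None:
        raise StructuralError(f"{path}: no data rows found")
    return np.vstack(rows)


def read_dataset(path: str | Path, meta_path: str | Path) -> SpectralDataset:
    """Read a CSV intensity matrix plus its metadata table.

    The first non-comment row of ``path`` is the wavenumber axis; each
    following row is one spectrum.  ``meta_path`` must have one row per
    spectrum, in the same order.
    """
    block = _parse_matrix_file(Path(path))
    axis = WavenumberAxis(block[0])
    matrix = block[1:]
    meta = pd.read_csv(meta_path, comment="#")
    if len(meta) != matrix.shape[0]:
        raise StructuralError(
            f"metadata rows ({len(meta)}) != spectrum rows ({matrix.shape[0]})"
        )
    return SpectralDataset(axis, matrix, meta)


def write_dataset(d: SpectralDataset, path: str | Path, meta_path: str | Path) -> None:
    """Write a dataset in the dialect understood by :func:`read_dataset`.

    Numbers are printed with 17 significant digits so the round trip is
    lossless for float64.
    """
    with open(path, "w") as fh:
        fh.write("# ramancellid spectral matrix: first row = wavenumber axis (cm-1)\n")
        fh.write(",".join(f"{v:.17g}" for v in d.axis.values) + "\n")
        for row in d.matrix:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    d.meta[_META_COLUMNS].to_csv(meta_path, index=False)


def write_map(m: HyperspectralMap, path: str | Path, meta_path: str | Path) -> None:
    """Write the flattened cube as CSV plus a JSON sidecar with the grid."""
    meta = pd.DataFrame(
        {
            "cell_line": "",
            "cell_id": "map",
            "point_index": np.arange(m.n_pixels),
            "scan_index": 0,
            "excitation_nm": 488,
            "exposure_s": 0.1,
            "accumulations": 1,
        }
    )
    d = SpectralDataset(m.axis, m.cube, meta)
    write_dataset(d, path, meta_path)
    sidecar = Path(str(path) + ".grid.json")
    sidecar.write_text(
        json.dumps({"grid_shape": list(m.grid_shape), "step_um": m.step_um})
    )


def read_map(path: str | Path, meta_path: str | Path) -> HyperspectralMap:
    d = read_dataset(path, meta_path)
    sidecar = Path(str(path) + ".grid.json")
    info = json.loads(sidecar.read_text())
    return HyperspectralMap(
        tuple(info["grid_shape"]), float(info["step_um"]), d.axis, d.matrix
    )


def crop_axis(d: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Restrict a dataset to wavenumbers lo <= nu <= hi (order preserved)."""
    if lo >= hi:
        raise RangeError(f"invalid window: lo={lo} >= hi={hi}")
    mask = d.axis.window_mask(lo, hi)
    if not mask.any():
        raise RangeError(
            f"window [{lo}, {hi}] does not overlap axis "
            f"[{d.axis.values[0]}, {d.axis.values[-1]}]"
        )
    return SpectralDataset(WavenumberAxis(d.axis.values[mask]), d.matrix[:, mask], d.meta)
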