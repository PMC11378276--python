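"""Spectrum I/O and alignment of centroided spectra into the X matrix.

A :class:`Spectrum` is a single sample's centroided peak list. A set of
spectra is aligned onto a fixed-width m/z grid with half-open bins
``[left, right)``; only bins occupied by at least one spectrum become
columns of the :class:`AlignedMatrix`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._mzml import read_mzml_peaklists
from .exceptions import EmptyMatrixError, FormatError, ManifestError

logger = logging.getLogger(__name__)

#: relative slack used when flooring (mz - mz_min)/resolution so that peaks
#: sitting a few ulp below a bin edge land in the bin they arithmetically
#: belong to (decimal-safe floor indexing).
_EDGE_EPS = 1e-9


@dataclass
class Spectrum:
    """One sample's centroided peak list.

    Invariants: m/z strictly increasing and positive, intensities >= 0.
    Duplicate m/z values are merged by summing on construction.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in spectrum {self.sample_id!r}")
        if self.mz.size and np.any(self.mz <= 0):
            raise ValueError(f"nonpositive m/z in spectrum {self.sample_id!r}")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        keep = self.intensity > 0
        mz, inten = self.mz[keep], self.intensity[keep]
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size > 1:
            uniq, inv = np.unique(mz, return_inverse=True)
            if uniq.size < mz.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inv, inten)
                mz, inten = uniq, summed
        self.mz, self.intensity = mz, inten

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class BinGrid:
    """Fixed-width m/z binning grid restricted to occupied bins."""

    mz_min: float
    mz_max: float
    resolution: float
    occupied_bins: np.ndarray  # sorted unique int indices

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        self.occupied_bins = np.asarray(self.occupied_bins, dtype=np.int64)
        if self.occupied_bins.size:
            if np.any(np.diff(self.occupied_bins) <= 0):
                raise ValueError("occupied_bins must be sorted and unique")
            if self.occupied_bins[0] < 0 or self.occupied_bins[-1] > self.max_index:
                raise ValueError("bin index out of range")

    @property
    def max_index(self) -> int:
        return bin_index(
            np.nextafter(self.mz_max, self.mz_min), self.mz_min, self.resolution
        )

    @property
    def bin_centers(self) -> np.ndarray:
        return self.mz_min + (self.occupied_bins + 0.5) * self.resolution


@dataclass
class AlignedMatrix:
    """Samples x occupied-bin intensity matrix (the calibration X)."""

    X: np.ndarray
    bin_centers: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != self.bin_centers.size:
            raise ValueError("X columns must match bin_centers")
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids must match X rows")
        if self.bin_centers.size > 1 and np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV with bin-center headers, one row per sample."""
        df = pd.DataFrame(
            self.X,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{c:.6f}" for c in self.bin_centers],
        )
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlignedMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            X=df.to_numpy(dtype=np.float64),
            bin_centers=np.asarray([float(c) for c in df.columns]),
            sample_ids=[str(i) for i in df.index],
        )


def bin_index(mz, mz_min: float, resolution: float):
    """Half-open floor bin index with a relative epsilon guard.

    Peaks within ~1e-9 (relative) below a bin edge are assigned to the
    upper bin, compensating binary-float representation error in
    ``(mz - mz_min) / resolution`` for decimal grids like 0.001.
    """
    scaled = (np.asarray(mz, dtype=np.float64) - mz_min) / resolution
    eps = _EDGE_EPS * np.maximum(1.0, np.abs(scaled))
    return np.floor(scaled + eps).astype(np.int64)


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    sample_id: str | None = None,
    dilution_factor: float = 1.0,
) -> Spectrum:
    """Read a centroided spectrum from a 2-column CSV or an mzML file.

    CSV: columns (m/z, intensity), optional header row. mzML: centroided
    scans only; multiple scans are merged peak-wise (summed at the native
    5-decimal precision, then divided by the scan count).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "mzml" if suffix == ".mzml" else "csv"
    sid = sample_id if sample_id is not None else path.stem
    if format == "csv":
        mz, inten = _read_csv_peaks(path)
    elif format == "mzml":
        mz, inten = _read_mzml_merged(path)
    else:
        raise FormatError(f"unknown spectrum format {format!r}")
    try:
        return Spectrum(sid, mz, inten, dilution_factor=dilution_factor)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def _read_csv_peaks(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"unparseable CSV file {path!r}: {exc}") from exc
    # tolerate a single header row of column names
    first = df.iloc[0] if len(df) else None
    if first is not None and pd.to_numeric(first, errors="coerce").isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2 or len(df) == 0:
        raise FormatError(f"CSV {path!r} must have two numeric columns (mz, intensity)")
    numeric = df.iloc[:, :2].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise FormatError(f"non-numeric peak values in CSV {path!r}")
    return numeric.iloc[:, 0].to_numpy(float), numeric.iloc[:, 1].to_numpy(float)


def _read_mzml_merged(path: Path) -> tuple[np.ndarray, np.ndarray]:
    scans = read_mzml_peaklists(str(path))
    n = len(scans)
    if n == 1:
        return scans[0]
    # merge scans: round m/z to the reader's native 1e-5 precision, sum, average
    merged: dict[float, float] = {}
    for mz, inten in scans:
        for m, i in zip(np.round(mz, 5), inten):
            merged[m] = merged.get(m, 0.0) + float(i)
    mzs = np.asarray(sorted(merged), dtype=np.float64)
    intens = np.asarray([merged[m] / n for m in mzs], dtype=np.float64)
    return mzs, intens


def bin_spectrum(
    spectrum: Spectrum, mz_min: float, mz_max: float, resolution: float
) -> dict[int, float]:
    """Sparse map bin_index -> summed intensity over [mz_min, mz_max)."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if not mz_min < mz_max:
        raise ValueError("mz_min must be < mz_max")
    mask = (spectrum.mz >= mz_min) & (spectrum.mz < mz_max)
    idx = bin_index(spectrum.mz[mask], mz_min, resolution)
    max_index = bin_index(np.nextafter(mz_max, mz_min), mz_min, resolution)
    np.clip(idx, 0, max_index, out=idx)
    out: dict[int, float] = {}
    for i, inten in zip(idx.tolist(), spectrum.intensity[mask].tolist()):
        out[i] = out.get(i, 0.0) + inten
    return out


def align_spectra(
    spectra: list[Spectrum], mz_min: float, mz_max: float, resolution: float
) -> tuple[AlignedMatrix, BinGrid]:
    """Align spectra onto the union of occupied bins.

    Columns are the occupied bins only (not the full grid); each row holds a
    sample's summed intensity per occupied bin, zero where absent.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    sparse = [bin_spectrum(s, mz_min, mz_max, resolution) for s in spectra]
    occupied = sorted(set().union(*[set(m) for m in sparse]))
    if not occupied:
        raise EmptyMatrixError(
            f"no peaks in [{mz_min}, {mz_max}) for any of {len(spectra)} spectra"
        )
    col = {b: j for j, b in enumerate(occupied)}
    X = np.zeros((len(spectra), len(occupied)))
    for i, m in enumerate(sparse):
        for b, inten in m.items():
            X[i, col[b]] = inten
    grid = BinGrid(mz_min, mz_max, resolution, np.asarray(occupied))
    matrix = AlignedMatrix(X, grid.bin_centers, [s.sample_id for s in spectra])
    logger.info(
        "aligned %d spectra onto %d occupied bins (%.0f possible)",
        len(spectra), len(occupied),
        math.floor((mz_max - mz_min) / resolution) + 1,
    )
    return matrix, grid


MANIFEST_COLUMNS = ["sample_id", "path", "role", "concentration_mg_per_L", "dilution_factor"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV.

    Required columns: sample_id, path. Optional: role (calibration /
    prediction / unknown), concentration_mg_per_L, dilution_factor.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "path" not in df.columns:
        raise ManifestError("manifest needs 'sample_id' and 'path' columns")
    if "role" not in df.columns:
        df["role"] = "unknown"
    bad = ~df["role"].isin(["calibration", "prediction", "unknown"])
    if bad.any():
        raise ManifestError(f"invalid roles: {df.loc[bad, 'role'].unique().tolist()}")
    if "concentration_mg_per_L" not in df.columns:
        df["concentration_mg_per_L"] = np.nan
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0
    return df[MANIFEST_COLUMNS]


def load_manifest_spectra(manifest: pd.DataFrame, base_dir: str | Path | None = None) -> list[Spectrum]:
    """Read every spectrum referenced by a manifest, relative to base_dir."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    spectra = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        spectra.append(
            read_spectrum(p, sample_id=str(row.sample_id), dilution_factor=float(row.dilution_factor))
        )
    return spectra
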