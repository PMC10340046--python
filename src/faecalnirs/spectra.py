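"""Spectral data model and I/O.

Near-infrared reflectance spectra are handled as absorbance, log(1/R),
sampled on a fixed wavelength grid.  The working instrument convention is
1100-2498 nm in 2 nm steps (700 points), the grid of a scanning
monochromator operated in reflectance mode.  Spectra are stored
row-per-observation (one row per sample x replicate scan) with wavelengths
as columns, matching the usual instrument CSV export.

The container here, :class:`SpectraSet`, couples the absorbance matrix with
per-sample metadata (batch, diet, pen, day, sample form).  Replicate scans
of the same sample are averaged with :meth:`SpectraSet.average_replicates`
before any chemometric treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectraSet",
    "DEFAULT_GRID",
    "META_COLUMNS",
    "read_spectra",
    "write_spectra",
    "read_jcampdx",
]

#: Metadata columns recognised in spectra CSV files, in canonical order.
META_COLUMNS = ("sample_id", "replicate_id", "batch", "diet", "pen", "day", "form")


class GridError(ValueError):
    """Wavelength header does not match the expected grid."""


class SpectraParseError(ValueError):
    """A spectra file contains a non-numeric or missing absorbance cell."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres.

    Parameters
    ----------
    start_nm, stop_nm : float
        First and last wavelength, inclusive.
    step_nm : float
        Increment between adjacent points; must be positive.

    Notes
    -----
    The default grid is 1100-2498 nm with a 2 nm step, i.e.
    (2498 - 1100)/2 + 1 = 700 points.
    """

    start_nm: float = 1100.0
    stop_nm: float = 2498.0
    step_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.stop_nm < self.start_nm:
            raise ValueError("stop_nm must be >= start_nm")
        span = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValueError(
                f"grid span {self.start_nm}-{self.stop_nm} is not an integer "
                f"multiple of step {self.step_nm}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelength vector in nm, strictly increasing."""
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_wavelengths(cls, values: Sequence[float]) -> "WavelengthGrid":
        """Build a grid from an explicit wavelength vector.

        The vector must be strictly increasing and uniformly spaced
        (within 1e-6 nm).
        """
        w = np.asarray(values, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise GridError("need at least two wavelengths to infer a grid")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if np.ptp(steps) > 1e-6:
            raise GridError("wavelengths are not uniformly spaced")
        return cls(start_nm=float(w[0]), stop_nm=float(w[-1]), step_nm=float(steps[0]))

    def truncate(self, n_left: int, n_right: int) -> "WavelengthGrid":
        """Grid with ``n_left``/``n_right`` points dropped at each edge."""
        if n_left < 0 or n_right < 0:
            raise ValueError("truncation counts must be non-negative")
        if n_left + n_right >= self.n_points:
            raise ValueError("truncation removes the whole grid")
        return WavelengthGrid(
            start_nm=self.start_nm + n_left * self.step_nm,
            stop_nm=self.stop_nm - n_right * self.step_nm,
            step_nm=self.step_nm,
        )


#: The instrument default: 1100-2498 nm, 2 nm steps, 700 points.
DEFAULT_GRID = WavelengthGrid()


class Spectrum(NamedTuple):
    """A single scan: identifiers plus the absorbance vector."""

    sample_id: str
    replicate_id: str
    absorbance: np.ndarray


class SpectraSet:
    """Absorbance matrix on a shared grid with per-sample metadata.

    Parameters
    ----------
    grid : WavelengthGrid
        The common wavelength grid.
    absorbance : ndarray, shape (n_obs, n_points)
        log(1/R) values; must be finite.
    meta : DataFrame
        One row per observation.  Must contain ``sample_id`` and
        ``replicate_id``; the remaining canonical columns (batch, diet,
        pen, day, form) are filled with empty strings when absent.
    """

    def __init__(self, grid: WavelengthGrid, absorbance: np.ndarray, meta: pd.DataFrame):
        A = np.asarray(absorbance, dtype=float)
        if A.ndim != 2:
            A = A.reshape(len(meta), -1) if len(meta) else A.reshape(0, grid.n_points)
        if A.shape[1] != grid.n_points:
            raise GridError(
                f"absorbance has {A.shape[1]} columns but grid has {grid.n_points} points"
            )
        if A.size and not np.all(np.isfinite(A)):
            bad = np.argwhere(~np.isfinite(A))[0]
            raise SpectraParseError(
                f"non-finite absorbance at row {bad[0]}, wavelength index {bad[1]}"
            )
        meta = meta.reset_index(drop=True).copy()
        for col in ("sample_id", "replicate_id"):
            if col not in meta.columns:
                raise ValueError(f"meta is missing required column '{col}'")
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = ""
        meta = meta.loc[:, list(META_COLUMNS)]
        meta["sample_id"] = meta["sample_id"].astype(str)
        meta["replicate_id"] = meta["replicate_id"].astype(str)
        if len(meta) != A.shape[0]:
            raise ValueError("meta and absorbance row counts differ")
        key = meta["sample_id"] + "\x00" + meta["replicate_id"]
        if key.duplicated().any():
            dup = meta.loc[key.duplicated(), ["sample_id", "replicate_id"]].iloc[0]
            raise ValueError(
                f"duplicate (sample_id, replicate_id): ({dup.sample_id}, {dup.replicate_id})"
            )
        self.grid = grid
        self.absorbance = A
        self.meta = meta

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield Spectrum(
                self.meta.at[i, "sample_id"],
                self.meta.at[i, "replicate_id"],
                self.absorbance[i],
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    def with_absorbance(self, absorbance: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectraSet":
        """Same metadata, new absorbance matrix (optionally a new grid)."""
        return SpectraSet(grid or self.grid, absorbance, self.meta)

    def select(self, mask_or_ids) -> "SpectraSet":
        """Subset by boolean mask (per row) or by an iterable of sample ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            mask = arr
        else:
            wanted = set(str(x) for x in mask_or_ids)
            mask = self.meta["sample_id"].isin(wanted).to_numpy()
        return SpectraSet(self.grid, self.absorbance[mask], self.meta.loc[mask])

    # -- operations --------------------------------------------------------

    def average_replicates(self) -> "SpectraSet":
        """Average replicate scans sample by sample.

        Returns one spectrum per ``sample_id`` (the pointwise arithmetic
        mean of its replicates, in first-appearance order) with the
        metadata of the first replicate and ``replicate_id`` set to
        ``"avg"``.  Idempotent.
        """
        if len(self) == 0:
            return self
        order = self.meta["sample_id"].drop_duplicates()
        groups = self.meta.groupby("sample_id", sort=False).indices
        rows = []
        meta_rows = []
        for sid in order:
            idx = groups[sid]
            rows.append(self.absorbance[idx].mean(axis=0))
            m = self.meta.iloc[idx[0]].copy()
            m["replicate_id"] = "avg"
            meta_rows.append(m)
        return SpectraSet(self.grid, np.vstack(rows), pd.DataFrame(meta_rows))

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then one column per wavelength."""
        cols = {c: self.meta[c] for c in META_COLUMNS}
        df = pd.DataFrame(cols)
        wl = self.wavelengths
        spec = pd.DataFrame(self.absorbance, columns=[_format_wavelength(v) for v in wl])
        return pd.concat([df, spec], axis=1)

    def plot(self, ax=None, max_spectra: int = 50, **kwargs):
        """Plot up to ``max_spectra`` absorbance traces against wavelength."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for row in self.absorbance[:max_spectra]:
            ax.plot(self.wavelengths, row, lw=0.6, **kwargs)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("log(1/R)")
        return ax


def _format_wavelength(v: float) -> str:
    return f"{v:g}"


def read_spectra(path, grid_policy: str = "strict") -> SpectraSet:
    """Read a wide spectra CSV.

    The file has one header row (metadata column names followed by
    wavelengths in nm) and one row per (sample, replicate) scan.

    Parameters
    ----------
    path : str or Path
        CSV file, UTF-8, comma-delimited, "." decimal.
    grid_policy : {"strict", "infer"}
        ``strict`` requires the wavelength header to match the default
        1100-2498 nm / 2 nm grid exactly; ``infer`` accepts any uniform,
        strictly increasing header.

    Raises
    ------
    GridError
        Header mismatch under ``strict``, or a non-uniform header.
    SpectraParseError
        Non-numeric or missing absorbance cell (the error names the
        offending row and column).
    """
    if grid_policy not in ("strict", "infer"):
        raise ValueError(f"unknown grid_policy {grid_policy!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta_cols = [c for c in df.columns if c in META_COLUMNS]
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise GridError(f"non-numeric wavelength column header: {exc}") from None
    if wavelengths.size == 0:
        raise GridError("file has no wavelength columns")
    grid = WavelengthGrid.from_wavelengths(wavelengths)
    if grid_policy == "strict" and grid != DEFAULT_GRID:
        raise GridError(
            f"header grid {grid.start_nm}-{grid.stop_nm}/{grid.step_nm} nm "
            f"({grid.n_points} points) does not match the default "
            f"{DEFAULT_GRID.start_nm}-{DEFAULT_GRID.stop_nm}/{DEFAULT_GRID.step_nm} nm "
            f"({DEFAULT_GRID.n_points} points)"
        )
    raw = df.loc[:, wl_cols]
    values = np.empty((len(df), len(wl_cols)), dtype=float)
    for j, col in enumerate(wl_cols):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SpectraParseError(
                f"non-numeric absorbance {raw[col].iloc[i]!r} at data row {i}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    meta = df.loc[:, meta_cols] if meta_cols else pd.DataFrame(index=df.index)
    if "sample_id" not in meta.columns:
        raise ValueError("spectra file must contain a sample_id column")
    if "replicate_id" not in meta.columns:
        meta = meta.copy()
        meta["replicate_id"] = "1"
    return SpectraSet(grid, values, meta)


def write_spectra(sset: SpectraSet, path) -> Path:
    """Write a :class:`SpectraSet` as a wide CSV (17 significant digits).

    ``read_spectra(write_spectra(s))`` reproduces the absorbance to well
    below 1e-9 and the metadata exactly.
    """
    path = Path(path)
    df = sset.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_jcampdx(path, grid: WavelengthGrid = DEFAULT_GRID, sample_id: str | None = None) -> SpectraSet:
    """Minimal JCAMP-DX import (single-block ``XYDATA=(X++(Y..Y))``).

    Reads one absorbance record and resamples it onto ``grid`` by linear
    interpolation.  Only the plain tabular AFFN form is supported; no
    compressed (SQZ/DIF) encodings.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("##"):
            if in_data:
                in_data = False
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            fields[key] = val.strip()
            if key == "XYDATA":
                in_data = True
            continue
        if in_data and line:
            data_lines.append(line)
    if "XYDATA" not in fields:
        raise SpectraParseError("no ##XYDATA block found")
    xfac = float(fields.get("XFACTOR", "1"))
    yfac = float(fields.get("YFACTOR", "1"))
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            continue
        x0 = float(parts[0]) * xfac
        yvals = [float(p) * yfac for p in parts[1:]]
        # x of successive y values advances by the (global) x increment
        xs.extend([x0 + i * _jcamp_dx(fields, len(parts) - 1) for i in range(len(yvals))])
        ys.extend(yvals)
    x = np.asarray(xs)
    y = np.asarray(ys)
    order = np.argsort(x)
    x, y = x[order], y[order]
    resampled = np.interp(grid.wavelengths, x, y)
    sid = sample_id or fields.get("TITLE", "jcamp")
    meta = pd.DataFrame({"sample_id": [sid], "replicate_id": ["1"]})
    return SpectraSet(grid, resampled[None, :], meta)


def _jcamp_dx(fields: dict, n_y_per_line: int) -> float:
    if "DELTAX" in fields:
        return float(fields["DELTAX"])
    first = float(fields.get("FIRSTX", "0"))
    last = float(fields.get("LASTX", "0"))
    npts = int(float(fields.get("NPOINTS", "0")))
    if npts > 1:
        return (last - first) / (npts - 1)
    return 1.0
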