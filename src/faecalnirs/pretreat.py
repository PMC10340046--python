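"""Scatter correction and derivative math treatments.

Two scatter corrections are provided: the standard normal variate (SNV),
which centres and scales each spectrum to unit standard deviation and so
removes multiplicative scatter and particle-size effects, and detrending
(DT), which removes baseline shift and curvilinearity by subtracting an
ordinary-least-squares polynomial (degree 2 by default) fitted over
wavelength.

Derivatives follow the four-digit "d,g,s1,s2" convention of scanning-NIR
calibration software: derivative order d, gap g (points) of the central
finite difference, first smoothing window s1 and second smoothing window
s2 (both centred boxcars).  The pipeline is smooth(s1) -> gap difference
-> smooth(s2); edges where any window is incomplete are truncated, never
padded, and the wavelength grid is shortened accordingly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "TreatmentCode",
    "parse_treatment_code",
    "STANDARD_TREATMENTS",
    "DEFAULT_TREATMENT",
    "snv",
    "detrend",
    "gap_segment_derivative",
    "apply_treatment",
]

_CODE_RE = re.compile(r"^\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*$")


class DegenerateSpectrumError(ValueError):
    """Input spectrum is constant (zero variance) where variance is required."""


@dataclass(frozen=True)
class TreatmentCode:
    """A four-digit math treatment plus the scatter-correction choice.

    Attributes
    ----------
    derivative : int
        Derivative order d in {0, 1, 2}.  d = 0 applies smoothing only.
    gap : int
        Half-window g (points) of the central gap difference.
    smooth1, smooth2 : int
        Boxcar widths (points) of the first and second smoothing; width 1
        means no smoothing.  Even widths are widened to the next odd value
        (with a warning) so the filters stay centred.
    scatter : {"snv_dt", "none"}
        Whether SNV + detrend scatter correction precedes the derivative.
    """

    derivative: int
    gap: int
    smooth1: int
    smooth2: int
    scatter: str = "snv_dt"

    def __post_init__(self):
        if self.derivative not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {self.derivative}")
        for name in ("gap", "smooth1", "smooth2"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.derivative > 0 and self.gap < 1:
            raise ValueError("gap must be >= 1 for a first or second derivative")
        if self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("smoothing windows must be >= 1 point")
        if self.scatter not in ("snv_dt", "none"):
            raise ValueError(f"scatter must be 'snv_dt' or 'none', got {self.scatter!r}")

    def __str__(self) -> str:
        return f"{self.derivative},{self.gap},{self.smooth1},{self.smooth2}"

    @property
    def code(self) -> str:
        return str(self)

    def with_scatter(self, scatter: str) -> "TreatmentCode":
        return replace(self, scatter=scatter)


def parse_treatment_code(code: str, scatter: str = "snv_dt") -> TreatmentCode:
    """Parse a "d,g,s1,s2" string into a :class:`TreatmentCode`.

    ``str(parse_treatment_code(x)) == x`` for any normalised code.
    """
    m = _CODE_RE.match(code)
    if not m:
        raise ValueError(f"malformed treatment code {code!r}; expected 'd,g,s1,s2'")
    d, g, s1, s2 = (int(x) for x in m.groups())
    return TreatmentCode(d, g, s1, s2, scatter=scatter)


#: The eight derivative treatments routinely screened for faeces calibrations.
STANDARD_TREATMENTS = tuple(
    parse_treatment_code(c)
    for c in ("1,4,4,1", "1,8,4,1", "1,5,5,1", "1,10,5,1",
              "2,4,4,1", "2,8,4,1", "2,5,5,1", "2,10,5,1")
)

#: First-derivative treatment used for population structuring / screening.
DEFAULT_TREATMENT = parse_treatment_code("1,5,5,1")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale to unit sample SD.

    Works on a single spectrum or row-wise on a matrix.  The output of
    every row has mean 0 and sample standard deviation (ddof=1) equal
    to 1.  SNV is invariant under positive affine transforms a*x + b.

    Raises
    ------
    DegenerateSpectrumError
        If any spectrum is constant (sample SD = 0).
    """
    x = np.asarray(spectrum, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        i = int(np.flatnonzero(sd.ravel() <= 0)[0])
        raise DegenerateSpectrumError(f"constant spectrum (zero variance) at row {i}")
    out = (X - mu) / sd
    return out[0] if one_d else out


def detrend(spectrum: np.ndarray, grid: WavelengthGrid | np.ndarray, degree: int = 2) -> np.ndarray:
    """Residuals of an OLS polynomial fit of absorbance on wavelength.

    Parameters
    ----------
    spectrum : ndarray
        One spectrum or a (n, p) matrix (row-wise).
    grid : WavelengthGrid or ndarray
        Wavelengths the spectrum is aligned to.
    degree : int
        Polynomial degree; 2 removes baseline shift and curvilinearity,
        0 simply mean-centres.

    The residuals are orthogonal to the polynomial basis (each power of
    wavelength up to ``degree``).
    """
    x = np.asarray(spectrum, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    wl = grid.wavelengths if isinstance(grid, WavelengthGrid) else np.asarray(grid, dtype=float)
    if X.shape[1] != wl.size:
        raise ValueError("spectrum length does not match the wavelength grid")
    if X.shape[1] <= degree:
        raise ValueError(f"need more than {degree} points to detrend at degree {degree}")
    # orthonormal polynomial basis via QR on a scaled Vandermonde keeps the
    # projection well conditioned across the 1100-2498 nm range
    span = np.ptp(wl)
    u = (wl - wl.mean()) / (span / 2 if span > 0 else 1.0)
    V = np.vander(u, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    out = X - (X @ Q) @ Q.T
    return out[0] if one_d else out


def _odd(width: int, name: str) -> int:
    if width % 2 == 0:
        warnings.warn(
            f"{name} width {width} is even; using {width + 1} to keep the filter centred",
            stacklevel=3,
        )
        return width + 1
    return width


def _boxcar(X: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average, valid region only (trims width//2 per edge)."""
    if width == 1:
        return X
    n = X.shape[1]
    if n < width:
        raise ValueError(f"spectrum of length {n} too short for smoothing width {width}")
    c = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X], axis=1), axis=1)
    return (c[:, width:] - c[:, :-width]) / width


def gap_segment_derivative(
    spectrum: np.ndarray,
    code: TreatmentCode,
    grid: WavelengthGrid | None = None,
):
    """Apply the smooth -> gap difference -> smooth pipeline of a code.

    The first boxcar (width s1) runs over the raw spectrum; the central
    gap difference follows (d=1: y[i+g] - y[i-g]; d=2: y[i+g] - 2 y[i] +
    y[i-g]); the second boxcar (width s2) smooths the result.  Every
    stage drops the edge points its window cannot cover, so the output is
    shorter than the input by s1//2 + g + s2//2 points per edge (g only
    when d > 0).

    Returns
    -------
    out : ndarray
        Derivative spectrum/spectra on the truncated grid.
    grid_out : WavelengthGrid or None
        The truncated grid when ``grid`` was given, else None.

    A first derivative annihilates constants; a second derivative
    annihilates straight lines.
    """
    x = np.asarray(spectrum, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    s1 = _odd(code.smooth1, "smooth1")
    s2 = _odd(code.smooth2, "smooth2")
    g = code.gap if code.derivative > 0 else 0
    trim = s1 // 2 + g + s2 // 2
    if X.shape[1] <= 2 * trim:
        raise ValueError(
            f"spectrum of length {X.shape[1]} too short for treatment {code}; "
            f"needs at least {2 * trim + 1} points"
        )
    Y = _boxcar(X, s1)
    if code.derivative == 1:
        Y = Y[:, 2 * g:] - Y[:, : Y.shape[1] - 2 * g]
    elif code.derivative == 2:
        Y = Y[:, 2 * g:] - 2 * Y[:, g : Y.shape[1] - g] + Y[:, : Y.shape[1] - 2 * g]
    Y = _boxcar(Y, s2)
    grid_out = grid.truncate(trim, trim) if grid is not None else None
    return (Y[0] if one_d else Y), grid_out


def apply_treatment(sset: SpectraSet, code: TreatmentCode, order: str = "scatter_first") -> SpectraSet:
    """Apply a full math treatment to every spectrum of a set.

    With ``code.scatter == "snv_dt"`` the default order is SNV, then
    degree-2 detrend, then the gap-segment derivative; ``order =
    "derivative_first"`` reproduces the alternative convention where the
    derivative precedes scatter correction (SNV/DT then run on the
    truncated grid).  With ``scatter == "none"`` only the derivative
    stage is applied; the identity code "0,0,1,1" then returns the input
    unchanged.

    Deterministic and order-stable: permuting sample order permutes the
    output rows identically.
    """
    if order not in ("scatter_first", "derivative_first"):
        raise ValueError(f"unknown pretreatment order {order!r}")
    X = sset.absorbance
    grid = sset.grid
    if code.scatter == "none":
        X, grid2 = gap_segment_derivative(X, code, grid)
        return sset.with_absorbance(X, grid2 or grid)
    if order == "scatter_first":
        X = snv(X)
        X = detrend(X, grid, degree=2)
        X, grid2 = gap_segment_derivative(X, code, grid)
        return sset.with_absorbance(X, grid2 or grid)
    X, grid2 = gap_segment_derivative(X, code, grid)
    grid = grid2 or grid
    X = snv(X)
    X = detrend(X, grid, degree=2)
    return sset.with_absorbance(X, grid)
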