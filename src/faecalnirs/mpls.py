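"""Modified partial least squares (PLS1) regression.

Single-response NIPALS partial least squares with an optional Shenk-
Westerhaus-style modification: after each factor is extracted and the
spectral matrix deflated, the residuals at each wavelength are divided by
their standard deviation before the next factor is calculated.  The
per-factor residual scales are recorded and replayed at prediction time,
so the fitted model remains an affine function of the pretreated
spectrum.  With standardisation off, the estimator is exactly classical
NIPALS PLS1, used throughout as the baseline and oracle route.

The public surface follows the statsmodels idiom: :class:`MPLS` is
constructed from data, ``fit`` returns an :class:`MPLSResults` carrying
coefficients, fitted values and calibration statistics, and ``fit_cv``
(in :mod:`faecalnirs.evaluate`) produces cross-validation statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pretreat import TreatmentCode, apply_treatment
from .spectra import SpectraSet

__all__ = ["MPLS", "MPLSResults", "fit", "predict"]

_MODEL_FORMAT_VERSION = 1


@dataclass
class _FitCore:
    """Raw NIPALS output: per-factor weights/loadings/scales and centring."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray          # (A, p)
    x_loadings: np.ndarray       # (A, p)
    y_loadings: np.ndarray       # (A,)
    residual_scales: np.ndarray  # (A, p); all ones when standardize is off
    standardized: bool

    @property
    def n_factors(self) -> int:
        return self.weights.shape[0]


def _nipals_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    standardize: bool,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> _FitCore:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    if n_factors < 0:
        raise ValueError("n_factors must be >= 0")
    if n_factors > 0 and n < n_factors + 2:
        raise ValueError(f"need at least n_factors + 2 = {n_factors + 2} samples, got {n}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (no missing values)")
    y_mean = float(y.mean())
    if n_factors > 0 and np.allclose(y, y_mean):
        raise ValueError("zero-variance response: nothing to calibrate")
    x_mean = X.mean(axis=0)
    E = X - x_mean
    f = y - y_mean
    initial_var = float((E**2).sum())
    W, P, Q, S = [], [], [], []
    for _ in range(n_factors):
        if initial_var > 0 and float((E**2).sum()) < 1e-12 * initial_var:
            warnings.warn(
                "residual X-variance exhausted; stopping factor extraction early",
                stacklevel=2,
            )
            break
        w = E.T @ f
        nw = float(np.linalg.norm(w))
        if nw < 1e-300:
            warnings.warn("zero covariance with residual y; stopping early", stacklevel=2)
            break
        w /= nw
        # single-response NIPALS: w = E'f/||E'f|| is the converged weight in
        # one pass (tol/max_iter kept in the signature for interface parity)
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-300:
            warnings.warn("degenerate score vector; stopping early", stacklevel=2)
            break
        p_load = (E.T @ t) / tt
        q = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - q * t
        if standardize:
            s = E.std(axis=0)  # population SD (divide by n)
            floor = 1e-12 * max(float(s.max()), 1.0)
            s = np.where(s > floor, s, 1.0)
            E = E / s
        else:
            s = np.ones(p)
        W.append(w)
        P.append(p_load)
        Q.append(q)
        S.append(s)
    A = len(W)
    return _FitCore(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.array(W).reshape(A, p),
        x_loadings=np.array(P).reshape(A, p),
        y_loadings=np.array(Q),
        residual_scales=np.array(S).reshape(A, p),
        standardized=bool(standardize),
    )


def _predict_path(core: _FitCore, X: np.ndarray) -> np.ndarray:
    """Cumulative predictions after 0..A factors; shape (n, A + 1).

    Column k holds the prediction using the first k factors (column 0 is
    the intercept-only prediction, the training mean of y).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != core.x_mean.size:
        raise ValueError(
            f"spectra have {X.shape[1]} points but the model was fitted on "
            f"{core.x_mean.size}; grid mismatch"
        )
    n = X.shape[0]
    out = np.empty((n, core.n_factors + 1))
    out[:, 0] = core.y_mean
    Xr = X - core.x_mean
    acc = np.full(n, core.y_mean)
    for a in range(core.n_factors):
        t = Xr @ core.weights[a]
        acc = acc + core.y_loadings[a] * t
        out[:, a + 1] = acc
        Xr = (Xr - np.outer(t, core.x_loadings[a])) / core.residual_scales[a]
    return out


class MPLS:
    """Modified PLS1 calibration model for one constituent.

    Parameters
    ----------
    endog : array_like
        Reference values y (one per sample), in their laboratory units
        (g/kg, MJ/kg, digestibility coefficients).  Centred only, never
        autoscaled: the units carry meaning.
    exog : array_like or SpectraSet
        Pretreated spectra (n x p).  A :class:`SpectraSet` is accepted
        directly; rows must align with ``endog``.
    n_factors : int
        Number of PLS factors to extract (cap 15 by convention for
        faeces calibrations).
    standardize : bool
        True (default) gives the modified algorithm; False gives
        classical NIPALS PLS1.
    constituent, treatment : optional metadata carried into results.
    """

    def __init__(
        self,
        endog,
        exog,
        n_factors: int = 15,
        standardize: bool = True,
        constituent: str | None = None,
        treatment: TreatmentCode | None = None,
    ):
        if isinstance(exog, SpectraSet):
            self.wavelengths = exog.wavelengths
            exog = exog.absorbance
        else:
            self.wavelengths = None
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be 2-D with one row per endog value")
        self.n_factors = int(n_factors)
        self.standardize = bool(standardize)
        self.constituent = constituent
        self.treatment = treatment

    @classmethod
    def from_spectra(
        cls,
        sset: SpectraSet,
        references: pd.Series | dict,
        treatment: TreatmentCode,
        n_factors: int = 15,
        standardize: bool = True,
        constituent: str | None = None,
        order: str = "scatter_first",
    ) -> "MPLS":
        """Build a model from raw spectra and a sample_id -> value mapping.

        Replicates are averaged, the math treatment applied, and the
        spectra aligned with the reference values by sample id; samples
        without a reference are dropped.
        """
        avg = sset.average_replicates()
        ref = pd.Series(references, dtype=float)
        ids = [sid for sid in avg.sample_ids if sid in ref.index]
        if len(ids) < 3:
            raise ValueError("fewer than 3 samples have both spectra and references")
        sub = avg.select(ids)
        treated = apply_treatment(sub, treatment, order=order)
        y = ref.loc[list(sub.sample_ids)].to_numpy()
        model = cls(
            y,
            treated.absorbance,
            n_factors=n_factors,
            standardize=standardize,
            constituent=constituent,
            treatment=treatment,
        )
        model.wavelengths = treated.wavelengths
        model.sample_ids = sub.sample_ids
        return model

    def fit(self, n_factors: int | None = None) -> "MPLSResults":
        """Extract the factors and return the fitted results object."""
        A = self.n_factors if n_factors is None else int(n_factors)
        core = _nipals_fit(self.exog, self.endog, A, self.standardize)
        return MPLSResults(self, core)

    def fit_cv(self, scheme=None, max_factors: int | None = None):
        """Cross-validate; see :func:`faecalnirs.evaluate.evaluate`."""
        from .evaluate import CvScheme, evaluate

        scheme = scheme or CvScheme()
        return evaluate(
            self.exog,
            self.endog,
            scheme=scheme,
            max_factors=max_factors or self.n_factors,
            standardize=self.standardize,
            constituent=self.constituent,
            treatment=self.treatment,
        )


class MPLSResults:
    """Fitted MPLS calibration: coefficients, diagnostics, persistence."""

    def __init__(self, model: MPLS, core: _FitCore):
        self.model = model
        self._core = core
        path = _predict_path(core, model.exog)
        self.fittedvalues = path[:, -1]
        self.resid = model.endog - self.fittedvalues
        self._sse_path = ((model.endog[:, None] - path) ** 2).sum(axis=0)

    # -- basic attributes --------------------------------------------------

    @property
    def n_factors(self) -> int:
        return self._core.n_factors

    @property
    def nobs(self) -> int:
        return self.model.endog.size

    @property
    def y_mean(self) -> float:
        return self._core.y_mean

    @property
    def residual_scales(self) -> np.ndarray:
        return self._core.residual_scales

    @property
    def sse(self) -> float:
        return float(self._sse_path[-1])

    @property
    def sse_by_factor(self) -> np.ndarray:
        """Training SSE after 0..n_factors factors (non-increasing)."""
        return self._sse_path

    @property
    def sec(self) -> float:
        """Standard error of calibration, sqrt(SSE / (n - k - 1))."""
        dof = self.nobs - self.n_factors - 1
        if dof <= 0:
            return float("nan")
        return float(np.sqrt(self.sse / dof))

    @property
    def r2c(self) -> float:
        sst = float(((self.model.endog - self.model.endog.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError("zero-variance response: R² undefined")
        return 1.0 - self.sse / sst

    @property
    def params(self) -> np.ndarray:
        """Affine prediction coefficients: [intercept, b_1 .. b_p].

        The modified algorithm replays the recorded residual scales at
        prediction, but the composition of centring, projection,
        deflation and rescaling is still affine in the input spectrum,
        so an exact coefficient vector exists; it is recovered by
        propagating the unit basis through the prediction recursion.
        """
        if not hasattr(self, "_params"):
            p = self._core.x_mean.size
            base = _predict_path(self._core, self._core.x_mean[None, :])[0, -1]
            probe = np.eye(p) + self._core.x_mean
            cols = _predict_path(self._core, probe)[:, -1] - base
            intercept = base - float(cols @ self._core.x_mean)
            self._params = np.concatenate([[intercept], cols])
        return self._params

    # -- prediction --------------------------------------------------------

    def predict(self, X, n_factors: int | None = None) -> np.ndarray:
        """Predict reference values for pretreated spectra.

        ``X`` may be an array on the model's (possibly truncated) grid or
        a :class:`SpectraSet`; a grid-length mismatch raises.
        """
        if isinstance(X, SpectraSet):
            X = X.absorbance
        path = _predict_path(self._core, X)
        k = self.n_factors if n_factors is None else int(n_factors)
        if not 0 <= k <= self.n_factors:
            raise ValueError(f"n_factors must be in [0, {self.n_factors}]")
        return path[:, k]

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Modified PLS calibration" if self._core.standardized else "PLS1 calibration",
            "=" * 44,
            f"constituent:      {self.model.constituent or '-'}",
            f"treatment:        {self.model.treatment or '-'}",
            f"n observations:   {self.nobs}",
            f"n factors:        {self.n_factors}",
            f"mean(y):          {self.y_mean:.4f}",
            f"SEC:              {self.sec:.4f}",
            f"R²c:              {self.r2c:.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MPLSResults: {self.model.constituent or 'constituent'} "
            f"k={self.n_factors} SEC={self.sec:.4g} R2c={self.r2c:.4g}>"
        )

    # -- persistence -------------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialise to a versioned JSON document (vectors inline)."""
        doc = {
            "format_version": _MODEL_FORMAT_VERSION,
            "constituent": self.model.constituent,
            "treatment": str(self.model.treatment) if self.model.treatment else None,
            "scatter": self.model.treatment.scatter if self.model.treatment else None,
            "standardized": self._core.standardized,
            "n_factors": self.n_factors,
            "x_mean": self._core.x_mean.tolist(),
            "y_mean": self._core.y_mean,
            "weights": self._core.weights.tolist(),
            "x_loadings": self._core.x_loadings.tolist(),
            "y_loadings": self._core.y_loadings.tolist(),
            "residual_scales": self._core.residual_scales.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MPLSResults":
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        if doc.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        from .pretreat import parse_treatment_code

        core = _FitCore(
            x_mean=np.array(doc["x_mean"]),
            y_mean=float(doc["y_mean"]),
            weights=np.array(doc["weights"]),
            x_loadings=np.array(doc["x_loadings"]),
            y_loadings=np.array(doc["y_loadings"]),
            residual_scales=np.array(doc["residual_scales"]),
            standardized=bool(doc["standardized"]),
        )
        treatment = (
            parse_treatment_code(doc["treatment"], scatter=doc.get("scatter") or "snv_dt")
            if doc.get("treatment")
            else None
        )
        # reconstruct a shell model so predict() and metadata work
        p = core.x_mean.size
        shell = MPLS(
            np.array([core.y_mean, core.y_mean, core.y_mean]),
            np.zeros((3, p)),
            n_factors=core.n_factors,
            standardize=core.standardized,
            constituent=doc.get("constituent"),
            treatment=treatment,
        )
        obj = cls.__new__(cls)
        obj.model = shell
        obj._core = core
        obj.fittedvalues = None
        obj.resid = None
        obj._sse_path = np.zeros(core.n_factors + 1)
        return obj


# -- functional aliases matching the operation-level interface --------------

def fit(X, y, n_factors: int, standardize: bool = True, **kwargs) -> MPLSResults:
    """Functional form: fit an (M)PLS1 calibration on a pretreated matrix."""
    return MPLS(y, X, n_factors=n_factors, standardize=standardize, **kwargs).fit()


def predict(results: MPLSResults, X) -> np.ndarray:
    """Functional form of :meth:`MPLSResults.predict`."""
    return results.predict(X)
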