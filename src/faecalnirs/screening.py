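"""Population structuring and spectral outlier screening.

Before calibration, the spectral population is examined with a principal
component analysis of the pretreated spectra and each sample's global
Mahalanobis distance (GH) from the population centroid in score space.
GH is the Mahalanobis D² divided by the number of retained components,
so that the calibration-set average is (n-1)/n, essentially 1.  Samples
with GH above a cutoff (3.0 by convention) are flagged as spectral
outliers and removed in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pretreat import DEFAULT_TREATMENT, TreatmentCode, apply_treatment
from .spectra import SpectraSet

__all__ = ["PcaModel", "ScreeningResult", "fit_pca", "gh_distance", "screen_outliers"]


@dataclass
class PcaModel:
    """Covariance PCA of a (pretreated) spectra matrix.

    Mean-centred, not autoscaled: all wavelengths share absorbance units.
    ``loadings`` rows are orthonormal; ``explained_variance`` (sample
    variance of each score, ddof=1) is non-increasing.  ``score_cov`` is
    the k x k sample covariance of the training scores, kept so the
    Mahalanobis form is exact even under rotations of the score basis.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray            # (k, p)
    explained_variance: np.ndarray  # (k,)
    total_variance: float
    n_samples: int
    score_cov: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_spectrum.size:
            raise ValueError("spectra are not on the model's grid")
        return (X - self.mean_spectrum) @ self.loadings.T


@dataclass
class ScreeningResult:
    """Per-sample GH values and the kept/flagged split at a cutoff."""

    gh: np.ndarray
    sample_ids: np.ndarray
    cutoff: float
    k: int
    explained_variance_ratio: np.ndarray

    @property
    def flagged_ids(self) -> list[str]:
        return [str(s) for s in self.sample_ids[self.gh > self.cutoff]]

    @property
    def kept_ids(self) -> list[str]:
        return [str(s) for s in self.sample_ids[self.gh <= self.cutoff]]

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "k": self.k,
            "explained_variance_ratio": [float(v) for v in self.explained_variance_ratio],
            "gh": {str(s): float(g) for s, g in zip(self.sample_ids, self.gh)},
            "flagged_ids": self.flagged_ids,
            "kept_ids": self.kept_ids,
        }


def fit_pca(data, variance_target: float = 0.99, max_k: int | None = None) -> PcaModel:
    """Fit a covariance PCA, retaining components up to a variance target.

    Parameters
    ----------
    data : SpectraSet or ndarray
        Pretreated spectra (n x p).
    variance_target : float
        Smallest k whose cumulative explained-variance fraction reaches
        this target is retained.
    max_k : int, optional
        Hard cap on k; k is additionally capped at n - 1.

    Raises
    ------
    ValueError
        Fewer than 3 samples, or a zero-variance matrix.
    """
    X = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"PCA needs at least 3 samples, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: covariance eigenvalues are s^2/(n-1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (n - 1)
    total = float(ev.sum())
    if total <= 0:
        raise ValueError("zero-variance matrix: PCA undefined")
    cum = np.cumsum(ev) / total
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    cap = n - 1
    if max_k is not None:
        cap = min(cap, int(max_k))
    k = min(k, cap)
    scores = U[:, :k] * s[:k]
    cov = np.cov(scores, rowvar=False, ddof=1).reshape(k, k)
    return PcaModel(
        mean_spectrum=mean,
        loadings=Vt[:k],
        explained_variance=ev[:k],
        total_variance=total,
        n_samples=n,
        score_cov=cov,
    )


def gh_distance(model: PcaModel, data) -> np.ndarray:
    """Global Mahalanobis statistic GH = D²/k for each sample.

    D² is the Mahalanobis distance of the sample's score vector from the
    training-score centroid (the origin), using the training score
    covariance.  The centroid itself has GH 0, and the average over the
    fitting set is exactly (n-1)/n.

    Raises
    ------
    ValueError
        If any retained component has (numerically) zero score variance.
    """
    X = data.absorbance if isinstance(data, SpectraSet) else np.asarray(data, dtype=float)
    T = model.scores(X)
    var = np.diag(model.score_cov)
    if np.any(var <= 1e-3 * np.finfo(float).eps * max(model.total_variance, 1.0)):
        raise ValueError("zero score variance in a retained component")
    sol = np.linalg.solve(model.score_cov, T.T)
    d2 = np.einsum("ij,ji->i", T, sol)
    return d2 / model.k


def screen_outliers(
    sset: SpectraSet,
    code: TreatmentCode = DEFAULT_TREATMENT,
    cutoff: float = 3.0,
    variance_target: float = 0.99,
    max_k: int | None = None,
    order: str = "scatter_first",
) -> ScreeningResult:
    """Single-pass GH screening of a spectra set.

    Applies the stated pretreatment (default "1,5,5,1" with SNV + DT),
    fits the PCA, and flags samples with GH above ``cutoff``.  The pass
    is not iterated: the kept set is not re-fitted.
    """
    if len(sset) < 3:
        raise ValueError("screening needs at least 3 samples")
    treated = apply_treatment(sset, code, order=order)
    model = fit_pca(treated, variance_target=variance_target, max_k=max_k)
    gh = gh_distance(model, treated)
    return ScreeningResult(
        gh=gh,
        sample_ids=treated.sample_ids,
        cutoff=float(cutoff),
        k=model.k,
        explained_variance_ratio=model.explained_variance_ratio,
    )
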