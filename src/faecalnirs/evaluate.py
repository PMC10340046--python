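"""Cross-validation and calibration statistics.

Calibrations are judged by the standard error of calibration (SEC), the
calibration coefficient of determination (R²c), the standard error of
cross-validation (SECV), the cross-validation coefficient of
determination (R²cv), and the residual predictive deviation (RPD), the
ratio of the reference-value standard deviation to the SECV.

Two cross-validation schemes are supported: a single random split into
four (near-)equal groups, and leave-one-out.  The factor count is chosen
as the global SECV minimum over k = 1..max_factors (cap 15 for faeces
calibrations), with an optional one-standard-error parsimony rule.

Conventions: SEC uses n - k - 1 degrees of freedom; SECV uses n; the
reference SD uses n - 1.  R²cv is reported as computed and may be
negative on pathological data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mpls import _nipals_fit, _predict_path
from .pretreat import TreatmentCode, apply_treatment
from .spectra import SpectraSet

__all__ = [
    "CvScheme",
    "CalibrationStats",
    "AccuracyBand",
    "make_cv_splits",
    "evaluate",
    "search_treatments",
    "classify_accuracy",
]


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation specification.

    ``random_groups`` partitions the samples into ``n_groups`` groups
    whose sizes differ by at most one (a single partition, not repeated);
    ``leave_one_out`` holds out each sample in turn.
    """

    method: str = "random_groups"
    n_groups: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("random_groups", "leave_one_out"):
            raise ValueError(f"unknown CV method {self.method!r}")
        if self.method == "random_groups" and self.n_groups < 2:
            raise ValueError("random_groups needs at least 2 groups")

    def label(self) -> str:
        return "loo" if self.method == "leave_one_out" else f"cv{self.n_groups}"


def make_cv_splits(n: int, scheme: CvScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """List of (train, held-out) index arrays; each sample held out once."""
    if scheme.method == "leave_one_out":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    if n < scheme.n_groups:
        raise ValueError(f"cannot split {n} samples into {scheme.n_groups} groups")
    rng = np.random.default_rng(scheme.seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, scheme.n_groups)
    all_idx = np.arange(n)
    return [(np.setdiff1d(all_idx, f), np.sort(f)) for f in folds]


@dataclass
class CalibrationStats:
    """Calibration and cross-validation statistics for one constituent."""

    constituent: str | None
    n: int
    mean: float
    sd: float
    sec: float
    r2c: float
    secv: float
    r2cv: float
    rpd: float
    n_factors: int
    treatment: TreatmentCode | None = None
    scheme: CvScheme | None = None
    secv_curve: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "constituent": self.constituent,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "sec": self.sec,
            "r2c": self.r2c,
            "secv": self.secv,
            "r2cv": self.r2cv,
            "rpd": self.rpd,
            "n_factors": self.n_factors,
            "treatment": str(self.treatment) if self.treatment else None,
            "cv": self.scheme.label() if self.scheme else None,
        }

    def summary(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        lines = ["Calibration statistics", "=" * 30]
        lines += [f"{k.ljust(width)}  {v}" for k, v in d.items()]
        return "\n".join(lines)

    def plot_secv(self, ax=None):
        """SECV as a function of the number of factors."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = np.arange(1, len(self.secv_curve) + 1)
        ax.plot(ks, self.secv_curve, marker="o")
        ax.axvline(self.n_factors, ls="--", color="grey")
        ax.set_xlabel("number of factors")
        ax.set_ylabel("SECV")
        return ax


def evaluate(
    X,
    y,
    scheme: CvScheme | None = None,
    max_factors: int = 15,
    standardize: bool = True,
    constituent: str | None = None,
    treatment: TreatmentCode | None = None,
    selection: str = "min",
) -> CalibrationStats:
    """Cross-validate an (M)PLS1 calibration and compute its statistics.

    For every factor count k = 1..max_factors the PRESS is accumulated by
    refitting on each fold's training samples and predicting its held-out
    samples (the factor count is fixed across folds within a pass).  The
    selected k* minimises SECV(k) = sqrt(PRESS_k / n); ``selection =
    "one_se"`` instead picks the smallest k whose SECV is within one
    standard error of the minimum.  SEC and R²c come from the full-data
    fit at k*.

    Raises
    ------
    ValueError
        If the response has zero variance (SST = 0), or inputs misalign.
    """
    if isinstance(X, SpectraSet):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y are not aligned")
    if max_factors >= n:
        raise ValueError("max_factors must be smaller than the sample count")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero-variance response (SST = 0)")
    if selection not in ("min", "one_se"):
        raise ValueError(f"unknown selection rule {selection!r}")
    scheme = scheme or CvScheme()
    splits = make_cv_splits(n, scheme)

    cv_pred = np.empty((n, max_factors + 1))
    a_min = max_factors
    for train, test in splits:
        core = _nipals_fit(X[train], y[train], max_factors, standardize)
        path = _predict_path(core, X[test])
        if core.n_factors < max_factors:  # early stop: extend with the last model
            pad = np.repeat(path[:, -1:], max_factors - core.n_factors, axis=1)
            path = np.concatenate([path, pad], axis=1)
            a_min = min(a_min, core.n_factors)
        cv_pred[test] = path
    if a_min < max_factors:
        warnings.warn(
            f"factor extraction stopped early at {a_min} in at least one fold",
            stacklevel=2,
        )

    press = ((y[:, None] - cv_pred) ** 2).sum(axis=0)  # index 0 = intercept only
    secv_curve = np.sqrt(press[1:] / n)
    k_min = int(np.argmin(secv_curve)) + 1
    if selection == "one_se":
        # SE of the mean squared CV error at the minimising k
        err2 = (y - cv_pred[:, k_min]) ** 2
        se = float(err2.std(ddof=1) / np.sqrt(n))
        msep = press[1:] / n
        threshold = msep[k_min - 1] + se
        k_star = int(np.flatnonzero(msep <= threshold)[0]) + 1
    else:
        k_star = k_min
    secv = float(secv_curve[k_star - 1])
    r2cv = 1.0 - float(press[k_star]) / sst

    full = _nipals_fit(X, y, k_star, standardize)
    fitted = _predict_path(full, X)[:, -1]
    sse = float(((y - fitted) ** 2).sum())
    dof = n - k_star - 1
    sec = float(np.sqrt(sse / dof)) if dof > 0 else float("nan")
    r2c = 1.0 - sse / sst
    sd = float(y.std(ddof=1))
    return CalibrationStats(
        constituent=constituent,
        n=n,
        mean=float(y.mean()),
        sd=sd,
        sec=sec,
        r2c=r2c,
        secv=secv,
        r2cv=r2cv,
        rpd=sd / secv if secv > 0 else float("inf"),
        n_factors=k_star,
        treatment=treatment,
        scheme=scheme,
        secv_curve=secv_curve,
    )


def search_treatments(
    sset: SpectraSet,
    references,
    codes,
    scheme: CvScheme | None = None,
    max_factors: int = 15,
    standardize: bool = True,
    constituent: str | None = None,
    order: str = "scatter_first",
) -> tuple[CalibrationStats, pd.DataFrame]:
    """Evaluate several math treatments and pick the lowest-SECV one.

    ``references`` maps sample_id to the reference value (Series/dict).
    Replicates are averaged before pretreatment.  Ties on SECV break
    towards fewer factors, then towards a first derivative, then towards
    the earlier code in the list.  Returns the winning statistics and
    the full results table.
    """
    codes = list(codes)
    if not codes:
        raise ValueError("need at least one treatment code")
    avg = sset.average_replicates()
    ref = pd.Series(references, dtype=float)
    ids = [sid for sid in avg.sample_ids if sid in ref.index]
    sub = avg.select(ids)
    y = ref.loc[list(sub.sample_ids)].to_numpy()
    scheme = scheme or CvScheme()

    results: list[CalibrationStats] = []
    for code in codes:
        treated = apply_treatment(sub, code, order=order)
        stats = evaluate(
            treated.absorbance,
            y,
            scheme=scheme,
            max_factors=max_factors,
            standardize=standardize,
            constituent=constituent,
            treatment=code,
        )
        results.append(stats)
    order_key = sorted(
        range(len(results)),
        key=lambda i: (
            results[i].secv,
            results[i].n_factors,
            0 if codes[i].derivative == 1 else 1,
            i,
        ),
    )
    best = results[order_key[0]]
    table = pd.DataFrame([r.to_dict() for r in results])
    return best, table


@dataclass(frozen=True)
class AccuracyBand:
    """Joint accuracy classification with a discordance marker."""

    band: str
    discordant: bool = False


_BAND_ORDER = {"poor": 0, "moderate": 1, "good": 2, "excellent": 3}


def _r2_band(r2cv: float) -> str:
    if r2cv >= 0.90:
        return "excellent"
    if r2cv >= 0.70:
        return "good"
    if r2cv >= 0.50:
        return "moderate"
    return "poor"


def _rpd_band(rpd: float) -> str:
    if rpd >= 3.0:
        return "excellent"
    if rpd >= 2.0:
        return "good"
    if rpd >= 1.5:
        return "moderate"
    return "poor"


def classify_accuracy(r2cv: float, rpd: float) -> AccuracyBand:
    """Joint R²cv / RPD accuracy band.

    Excellent: RPD >= 3 with R²cv >= 0.90; good: RPD 2-3 with R²cv
    0.70-0.89; moderate: RPD 1.5-2 with R²cv 0.50-0.69; poor below.
    When the two criteria land in different bands the weaker band is
    returned with ``discordant=True``.  Returns ``unclassified`` for a
    non-positive or non-finite RPD.
    """
    if not np.isfinite(rpd) or rpd <= 0 or not np.isfinite(r2cv):
        return AccuracyBand("unclassified", False)
    b1, b2 = _r2_band(r2cv), _rpd_band(rpd)
    if b1 == b2:
        return AccuracyBand(b1, False)
    weaker = b1 if _BAND_ORDER[b1] < _BAND_ORDER[b2] else b2
    return AccuracyBand(weaker, True)
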