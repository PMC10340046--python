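"""Fisher's variance-ratio test between two calibrations' SECVs.

To decide whether one sample-presentation form gives a genuinely better
calibration than another for the same constituent, the two models'
cross-validation errors are compared as variances: F = SECV²(larger) /
SECV²(smaller), referred to the upper (1 - P) quantile of the F
distribution whose numerator degrees of freedom follow the larger-SECV
model (n - 1 cross-validated samples each).  The difference is declared
significant when F exceeds that critical value; the one-sided form is
built in because the larger SECV is always placed on top.

No multiple-testing correction is applied across constituents; each
comparison stands alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "fisher_secv_test", "compare_models"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one SECV F-test between models a and b."""

    constituent: str | None
    secv_a: float
    secv_b: float
    n_a: int
    n_b: int
    f: float
    f_critical: float
    p_level: float
    significant: bool
    better_model: str  # "a", "b" or "tie"

    def to_dict(self) -> dict:
        return {
            "constituent": self.constituent,
            "secv_a": self.secv_a,
            "secv_b": self.secv_b,
            "f": self.f,
            "f_critical": self.f_critical,
            "significant": self.significant,
            "better_model": self.better_model,
        }


def fisher_secv_test(
    secv_a: float,
    secv_b: float,
    n_a: int,
    n_b: int,
    p_level: float = 0.05,
    constituent: str | None = None,
) -> ComparisonResult:
    """Variance-ratio test on two standard errors of cross-validation.

    F = max(SECV)² / min(SECV)² >= 1; F_critical is the upper (1 - P)
    F quantile with (n_larger - 1, n_smaller - 1) degrees of freedom,
    ordered with the larger-SECV model in the numerator.  The decision
    is computed before any rounding.  ``better_model`` names the
    smaller-SECV model when significant, otherwise "tie".
    """
    if secv_a <= 0 or secv_b <= 0:
        raise ValueError("SECVs must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each model needs at least 2 cross-validated samples")
    if not 0 < p_level < 1:
        raise ValueError("p_level must be in (0, 1)")
    if secv_a >= secv_b:
        hi, lo, n_hi, n_lo, better = secv_a, secv_b, n_a, n_b, "b"
    else:
        hi, lo, n_hi, n_lo, better = secv_b, secv_a, n_b, n_a, "a"
    f = (hi / lo) ** 2
    f_critical = float(sps.f.ppf(1.0 - p_level, n_hi - 1, n_lo - 1))
    significant = f > f_critical
    return ComparisonResult(
        constituent=constituent,
        secv_a=float(secv_a),
        secv_b=float(secv_b),
        n_a=int(n_a),
        n_b=int(n_b),
        f=float(f),
        f_critical=f_critical,
        p_level=float(p_level),
        significant=bool(significant),
        better_model=better if significant else "tie",
    )


def compare_models(stats_a, stats_b, p_level: float = 0.05) -> list[ComparisonResult]:
    """F-test every constituent shared by two lists of calibration stats.

    ``stats_a`` / ``stats_b`` are lists of
    :class:`~faecalnirs.evaluate.CalibrationStats`.  Constituents present
    in only one list are skipped with a warning.
    """
    by_b = {s.constituent: s for s in stats_b}
    seen = set()
    out: list[ComparisonResult] = []
    for sa in stats_a:
        sb = by_b.get(sa.constituent)
        if sb is None:
            warnings.warn(f"constituent {sa.constituent!r} missing from the second list",
                          stacklevel=2)
            continue
        seen.add(sa.constituent)
        out.append(
            fisher_secv_test(sa.secv, sb.secv, sa.n, sb.n, p_level=p_level,
                             constituent=sa.constituent)
        )
    for sb in stats_b:
        if sb.constituent not in seen:
            warnings.warn(f"constituent {sb.constituent!r} missing from the first list",
                          stacklevel=2)
    return out


def comparison_table(results: list[ComparisonResult], precision: int = 2) -> pd.DataFrame:
    """Render comparisons with F values at report precision (decisions
    are taken pre-rounding)."""
    rows = []
    for r in results:
        rows.append(
            {
                "constituent": r.constituent,
                "secv_a": r.secv_a,
                "secv_b": r.secv_b,
                "F": round(r.f, precision),
                "F_critical": round(r.f_critical, precision),
                "significant": r.significant,
                "better_model": r.better_model,
            }
        )
    return pd.DataFrame(rows)
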