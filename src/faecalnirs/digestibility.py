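"""Apparent total tract digestibility (ATTD) via the AIA marker.

Digestibility is estimated without total collection by using acid-
insoluble ash (AIA), a native indigestible marker.  For a nutrient with
concentration ``N_feed`` in the feed and ``N_faeces`` in the faeces, and
marker concentrations ``AIA_feed`` / ``AIA_faeces``:

    ATTD = 1 - (N_faeces / N_feed) * (AIA_feed / AIA_faeces)

Concentrations enter on a dry-matter basis (CP, OM, fat in g/kg DM, GE
in MJ/kg DM); the DM coefficient itself uses the g/kg DM contents as-is
with the same marker ratio.  ATTD values outside [0, 1] are returned
with a warning flag, not clipped: they signal data problems that should
surface rather than disappear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from numbers import Real
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CompositionRecord",
    "AttdRecord",
    "ATTD_CONSTITUENTS",
    "attd",
    "attd_table",
    "read_composition",
    "write_attd",
]

ATTD_CONSTITUENTS = ("dm", "cp", "om", "ge", "fat")

#: Loose validation bound: concentrations above this (g/kg) are rejected;
#: values between 1000 and the bound only warn (calculated OM can slightly
#: exceed 1000 g/kg DM in practice).
_CONC_HARD_BOUND = 1100.0


@dataclass(frozen=True)
class CompositionRecord:
    """Nutrient and marker concentrations for one feed or faeces sample.

    Units: dm, cp, om, fat, aia in g/kg (cp/om/fat on a DM basis);
    ge in MJ/kg DM.  Missing constituents may be None.
    """

    sample_id: str
    kind: str  # "feed" or "faeces"
    dm: float | None = None
    cp: float | None = None
    om: float | None = None
    ge: float | None = None
    fat: float | None = None
    aia: float | None = None

    def __post_init__(self):
        if self.kind not in ("feed", "faeces"):
            raise ValueError(f"kind must be 'feed' or 'faeces', got {self.kind!r}")
        for name in ("dm", "cp", "om", "fat", "aia"):
            v = getattr(self, name)
            if v is None:
                continue
            if not isinstance(v, Real) or not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")
            if v > _CONC_HARD_BOUND:
                raise ValueError(f"{name} = {v} g/kg exceeds the {_CONC_HARD_BOUND} g/kg bound")
            if v > 1000.0:
                warnings.warn(
                    f"{name} = {v} g/kg exceeds 1000 g/kg for sample {self.sample_id}",
                    stacklevel=3,
                )
        if self.ge is not None and (not np.isfinite(self.ge) or self.ge < 0):
            raise ValueError(f"ge must be finite and non-negative, got {self.ge!r}")


@dataclass(frozen=True)
class AttdRecord:
    """One digestibility coefficient; ``error`` set when not computable."""

    sample_id: str
    constituent: str
    attd: float
    flag: str | None = None   # "out_of_range" when outside [0, 1]
    error: str | None = None


def attd(nutrient_feed, nutrient_faeces, aia_feed, aia_faeces):
    """Marker-based digestibility coefficient (scalar or array).

    ``1 - (nutrient_faeces/nutrient_feed) * (aia_feed/aia_faeces)``.
    Strictly decreasing in the faecal nutrient and feed marker
    concentrations, increasing in the other two; invariant when both
    nutrient concentrations, or both marker concentrations, are scaled
    by a common factor.

    Raises
    ------
    ZeroDivisionError
        ``nutrient_feed`` or ``aia_faeces`` equal to zero.
    ValueError
        Any negative input.
    """
    nf, nfe = np.asarray(nutrient_feed, dtype=float), np.asarray(nutrient_faeces, dtype=float)
    af, afe = np.asarray(aia_feed, dtype=float), np.asarray(aia_faeces, dtype=float)
    if np.any(nf < 0) or np.any(nfe < 0) or np.any(af < 0) or np.any(afe < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(nf == 0) or np.any(afe == 0):
        raise ZeroDivisionError("nutrient_feed and aia_faeces must be positive")
    if np.any(af == 0):
        raise ValueError("aia_feed must be positive for a marker-based estimate")
    out = 1.0 - (nfe / nf) * (af / afe)
    return float(out) if out.ndim == 0 else out


def attd_table(
    feed: CompositionRecord,
    faeces: list[CompositionRecord],
    constituents=ATTD_CONSTITUENTS,
) -> list[AttdRecord]:
    """ATTD for every (faeces sample, constituent) pair.

    Per-record failures (missing nutrient or marker values) become error
    entries; the remaining records are still computed.
    """
    if feed.kind != "feed":
        raise ValueError("first record must be the feed composition")
    bad = [c for c in constituents if c not in ATTD_CONSTITUENTS]
    if bad:
        raise ValueError(f"unknown constituents: {bad}")
    out: list[AttdRecord] = []
    for rec in faeces:
        if rec.kind != "faeces":
            raise ValueError(f"record {rec.sample_id} is not a faeces record")
        for c in constituents:
            n_feed = getattr(feed, c)
            n_fae = getattr(rec, c)
            if n_feed is None or feed.aia is None:
                out.append(AttdRecord(rec.sample_id, c, float("nan"),
                                      error=f"feed {c} or AIA missing"))
                continue
            if n_fae is None or rec.aia is None:
                out.append(AttdRecord(rec.sample_id, c, float("nan"),
                                      error=f"faecal {c} or AIA missing"))
                continue
            try:
                value = attd(n_feed, n_fae, feed.aia, rec.aia)
            except (ZeroDivisionError, ValueError) as exc:
                out.append(AttdRecord(rec.sample_id, c, float("nan"), error=str(exc)))
                continue
            flag = None
            if not 0.0 <= value <= 1.0:
                flag = "out_of_range"
                warnings.warn(
                    f"ATTD {value:.4f} outside [0, 1] for sample {rec.sample_id}, "
                    f"constituent {c}",
                    stacklevel=2,
                )
            out.append(AttdRecord(rec.sample_id, c, value, flag=flag))
    return out


def read_composition(path) -> list[CompositionRecord]:
    """Read a composition CSV (sample_id, kind, dm, cp, om, ge, fat, aia)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in ("dm", "cp", "om", "ge", "fat", "aia"):
            v = row.get(c)
            kwargs[c] = None if pd.isna(v) else float(v)
        records.append(CompositionRecord(str(row["sample_id"]), str(row["kind"]), **kwargs))
    return records


def write_attd(records: list[AttdRecord], path) -> Path:
    """Write ATTD records (6-decimal coefficients) to CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "constituent": [r.constituent for r in records],
            "attd": [round(r.attd, 6) if np.isfinite(r.attd) else "" for r in records],
            "flag": [r.flag or "" for r in records],
            "error": [r.error or "" for r in records],
        }
    )
    df.to_csv(path, index=False)
    return path
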