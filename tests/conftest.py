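"""Shared fixtures: small random problems and the default simulated study.

The default study bundle (seed 42) and the calibrations derived from it
are expensive enough to share session-wide; everything else is built
per test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import faecalnirs as fn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(rng):
    """A 5-sample, default-grid spectra set with two replicates each."""
    n, p = 10, fn.DEFAULT_GRID.n_points
    meta = pd.DataFrame(
        {
            "sample_id": [f"S{i // 2}" for i in range(n)],
            "replicate_id": [str(i % 2 + 1) for i in range(n)],
            "batch": "B1",
            "diet": "Control",
            "pen": "1",
            "day": "1",
            "form": "FDG",
        }
    )
    absorbance = 0.5 + 0.1 * rng.standard_normal((n, p))
    return fn.SpectraSet(fn.DEFAULT_GRID, absorbance, meta)


@pytest.fixture(scope="session")
def bundle42():
    """The default simulated study (240 collected, 10 lost, 7 outliers)."""
    return fn.simulate_study(seed=42)


@pytest.fixture(scope="session")
def screened42(bundle42):
    """Replicate-averaged, GH-screened spectra per form."""
    out = {}
    for form, sset in (("FDG", bundle42.spectra_fdg), ("FDNG", bundle42.spectra_fdng)):
        avg = sset.average_replicates()
        result = fn.screen_outliers(avg)
        out[form] = (avg, result)
    return out


def _cp_loo(bundle, screened, form, scatter):
    avg, result = screened[form]
    kept = avg.select(result.kept_ids)
    code = fn.parse_treatment_code("1,5,5,1", scatter=scatter)
    treated = fn.apply_treatment(kept, code)
    y = bundle.chemistry.set_index("sample_id")["cp"].loc[list(kept.sample_ids)]
    return fn.evaluate(
        treated.absorbance,
        y.to_numpy(),
        scheme=fn.CvScheme("leave_one_out"),
        constituent="cp",
        treatment=code,
    )


@pytest.fixture(scope="session")
def cp_stats42(bundle42, screened42):
    """Leave-one-out CP calibrations: both forms plus FDNG without SNV/DT."""
    return {
        "FDG": _cp_loo(bundle42, screened42, "FDG", "snv_dt"),
        "FDNG": _cp_loo(bundle42, screened42, "FDNG", "snv_dt"),
        "FDNG_no_scatter": _cp_loo(bundle42, screened42, "FDNG", "none"),
    }
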