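"""Synthetic two-batch, five-diet faecal NIRS study generator.

Emulates the data layout of a grower-finisher pig digestibility study:
20 pens scanned daily for 6 days in two batches (240 faecal samples
before losses), five diets (control, low/high crude protein, low/high
net energy), duplicate NIR scans per sample in two presentation forms
(freeze-dried ground, FDG, and freeze-dried not ground, FDNG), per-diet
faecal chemistry, and marker-consistent apparent total tract
digestibility (ATTD).

Chemistry values are drawn from truncated normal distributions whose
parent parameters are calibrated so the *realised* truncated mean and SD
hit the per-diet targets.  ATTD is generated marker-consistently: one
anchor coefficient (dry-matter ATTD) is drawn per sample, the faecal
acid-insoluble-ash (AIA) concentration is back-solved from it, and the
remaining coefficients follow from the marker equation, so recomputing
any ATTD from the emitted feed/faeces/AIA records reproduces it exactly.

Spectra come from a Beer-Lambert band-mixing model: each constituent
contributes Gaussian absorption bands scaled by its concentration; a
per-scan multiplicative scatter factor (log-normal, larger for FDNG), a
linear baseline and i.i.d. instrument noise are added on top.  A small
number of samples are planted as spectral outliers (contamination band,
curved baseline, inflated scatter) so that outlier screening has true
positives.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .spectra import DEFAULT_GRID, SpectraSet, WavelengthGrid, write_spectra

__all__ = [
    "ConstituentDist",
    "ChemistryParams",
    "SpectraGenParams",
    "StudyDesign",
    "StudyBundle",
    "simulate_chemistry",
    "simulate_spectra",
    "simulate_study",
    "DIETS",
    "CONSTITUENTS",
]

DIETS = ("Control", "LCP", "HCP", "LNE", "HNE")
CONSTITUENTS = ("dm", "cp", "om", "ge", "fat")


@dataclass(frozen=True)
class ConstituentDist:
    """Target mean/SD and hard range for one constituent in one diet."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"mean {self.mean} outside [{self.min}, {self.max}]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def _dist_table(rows) -> dict:
    return {diet: {c: ConstituentDist(*v) for c, v in block.items()} for diet, block in rows.items()}


# Per-diet faecal chemistry targets (g/kg DM; GE in MJ/kg DM; DM in g/kg).
_CHEMISTRY_DEFAULTS = _dist_table({
    "Total":   {"dm": (930.0, 16.40, 901.0, 957.0), "cp": (266.0, 23.90, 218.0, 320.0),
                "om": (971.0, 14.50, 940.0, 1012.0), "ge": (20.3, 0.38, 19.1, 21.3),
                "fat": (47.0, 7.30, 32.0, 79.0)},
    "Control": {"dm": (929.0, 17.00, 903.0, 951.0), "cp": (258.0, 21.00, 221.0, 304.0),
                "om": (975.0, 16.00, 944.0, 1005.0), "ge": (20.3, 0.22, 19.9, 20.8),
                "fat": (45.0, 5.30, 36.0, 61.0)},
    "LCP":     {"dm": (931.0, 16.10, 911.0, 955.0), "cp": (246.0, 12.20, 218.0, 268.0),
                "om": (975.0, 15.10, 946.0, 1012.0), "ge": (20.3, 0.26, 19.7, 20.8),
                "fat": (46.0, 6.80, 32.0, 67.0)},
    "HCP":     {"dm": (928.0, 17.50, 901.0, 955.0), "cp": (298.0, 13.30, 262.0, 320.0),
                "om": (967.0, 11.60, 940.0, 992.0), "ge": (20.2, 0.37, 19.3, 21.1),
                "fat": (48.0, 6.70, 37.0, 69.0)},
    "LNE":     {"dm": (935.0, 15.50, 909.0, 957.0), "cp": (271.0, 14.20, 243.0, 310.0),
                "om": (965.0, 11.70, 945.0, 997.0), "ge": (20.0, 0.34, 19.1, 21.1),
                "fat": (41.0, 5.30, 32.0, 55.0)},
    "HNE":     {"dm": (929.0, 15.20, 904.0, 952.0), "cp": (263.0, 20.40, 225.0, 300.0),
                "om": (975.0, 13.70, 949.0, 1010.0), "ge": (20.7, 0.39, 19.7, 21.3),
                "fat": (53.0, 6.80, 41.0, 79.0)},
})

# Per-diet ATTD coefficient targets (fractions).
_ATTD_DEFAULTS = _dist_table({
    "Total":   {"dm": (0.83, 0.038, 0.71, 0.90), "cp": (0.71, 0.065, 0.52, 0.83),
                "om": (0.85, 0.035, 0.74, 0.91), "ge": (0.79, 0.045, 0.63, 0.88),
                "fat": (0.77, 0.061, 0.62, 0.90)},
    "Control": {"dm": (0.87, 0.016, 0.82, 0.90), "cp": (0.77, 0.029, 0.72, 0.82),
                "om": (0.88, 0.016, 0.84, 0.91), "ge": (0.83, 0.020, 0.77, 0.87),
                "fat": (0.81, 0.034, 0.74, 0.88)},
    "LCP":     {"dm": (0.82, 0.029, 0.73, 0.88), "cp": (0.66, 0.053, 0.52, 0.78),
                "om": (0.84, 0.027, 0.76, 0.90), "ge": (0.75, 0.038, 0.63, 0.84),
                "fat": (0.73, 0.051, 0.62, 0.82)},
    "HCP":     {"dm": (0.79, 0.042, 0.71, 0.88), "cp": (0.66, 0.062, 0.55, 0.80),
                "om": (0.81, 0.039, 0.74, 0.89), "ge": (0.76, 0.045, 0.68, 0.86),
                "fat": (0.77, 0.061, 0.62, 0.86)},
    "LNE":     {"dm": (0.84, 0.022, 0.80, 0.90), "cp": (0.73, 0.035, 0.67, 0.83),
                "om": (0.86, 0.020, 0.82, 0.91), "ge": (0.80, 0.026, 0.76, 0.88),
                "fat": (0.73, 0.054, 0.62, 0.87)},
    "HNE":     {"dm": (0.83, 0.032, 0.75, 0.90), "cp": (0.72, 0.051, 0.59, 0.83),
                "om": (0.85, 0.030, 0.77, 0.91), "ge": (0.80, 0.036, 0.71, 0.88),
                "fat": (0.81, 0.045, 0.67, 0.90)},
})

#: Analysed feed dry matter per diet, g/kg as fed.
_FEED_DM_DEFAULTS = {"Control": 880.0, "LCP": 877.0, "HCP": 883.0, "LNE": 879.0, "HNE": 879.0}


def _calibrate_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Parent (loc, scale) whose [lo, hi]-truncated normal has the target
    realised mean and SD.

    Truncating a normal at roughly +-2 SD shrinks the realised SD by
    about 10 %, which would push the generated descriptive statistics
    visibly off their targets; solving for the parent parameters removes
    that bias.  When the target SD approaches the uniform-distribution
    limit sd_max = (hi - lo)/sqrt(12) no normal parent can reach it; a
    near-flat parent is used and the small shortfall accepted.
    """
    span = hi - lo
    if sd < 0.05 * span:  # truncation negligible at +-10 SD or more
        return float(mean), float(sd)
    sd_uniform = span / np.sqrt(12.0)
    if sd >= 0.97 * sd_uniform:
        return float(mean), float(10.0 * span)

    def residual(p):
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd * 1.15)], method="hybr")
    if not sol.success:
        warnings.warn(
            f"truncated-normal calibration failed for target ({mean}, {sd}) on "
            f"[{lo}, {hi}]; using uncalibrated parameters",
            stacklevel=2,
        )
        return float(mean), float(sd)
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _draw_truncnorm(dist: ConstituentDist, size: int, rng: np.random.Generator,
                    mean_shift: float = 0.0) -> np.ndarray:
    if dist.max < dist.min:
        raise ValueError("infeasible truncation: max < min")
    mu, sigma = _calibrate_truncnorm(dist.mean, dist.sd, dist.min, dist.max)
    mu = mu + mean_shift
    a, b = (dist.min - mu) / sigma, (dist.max - mu) / sigma
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


@dataclass
class ChemistryParams:
    """Distribution targets for faecal chemistry and ATTD plus feed data.

    ``chemistry`` and ``attd`` map diet -> constituent ->
    :class:`ConstituentDist`; the defaults transcribe the study-design
    descriptive statistics (per-diet blocks plus a "Total" block used
    for direct total-set draws).  The feed composition is back-computed
    from these targets through the marker relation (see
    :meth:`feed_composition`), with the analysed feed DM and an assumed
    native feed AIA as the only external inputs.

    ``batch_shift_sd`` is the between-batch mean separation in SD units
    (batch 1 shifted down, batch 2 up by half each), applied to the
    chemistry draws and the anchor ATTD.
    """

    chemistry: dict = field(default_factory=lambda: dict(_CHEMISTRY_DEFAULTS))
    attd: dict = field(default_factory=lambda: dict(_ATTD_DEFAULTS))
    feed_dm: dict = field(default_factory=lambda: dict(_FEED_DM_DEFAULTS))
    feed_aia: float = 10.0           # g/kg DM, assumed native AIA of the diets
    anchor: str = "dm"               # ATTD coefficient drawn directly
    batch_shift_sd: float = 0.25

    def feed_composition(self) -> pd.DataFrame:
        """Per-diet feed concentrations consistent with the targets.

        For each diet the mean marker ratio r = AIA_feed/AIA_faeces
        implied by the anchor ATTD is computed, and each nutrient's feed
        concentration is the value that makes the mean marker equation
        hold: N_feed = mean(N_faeces) * r / (1 - mean(ATTD)).
        """
        rows = []
        for diet in DIETS:
            nf_dm = self.feed_dm[diet]
            r_mean = (1.0 - self.attd[diet]["dm"].mean) * nf_dm / self.chemistry[diet]["dm"].mean
            row = {"sample_id": f"feed_{diet}", "kind": "feed", "diet": diet, "dm": nf_dm}
            for c in ("cp", "om", "ge", "fat"):
                row[c] = self.chemistry[diet][c].mean * r_mean / (1.0 - self.attd[diet][c].mean)
            row["aia"] = self.feed_aia
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class StudyDesign:
    """Sampling design: pens x days x batches, with loss and outlier counts."""

    n_pens: int = 20
    pigs_per_pen: int = 11
    n_diets: int = 5
    days: int = 6
    batches: int = 2
    n_discard: int = 10   # freeze-dryer losses, removed entirely
    n_outliers: int = 7   # planted spectral outliers among the survivors

    @property
    def n_collected(self) -> int:
        return self.n_pens * self.days * self.batches

    def __post_init__(self):
        if self.n_pens % self.n_diets:
            raise ValueError("n_pens must be a multiple of n_diets")


@dataclass
class SpectraGenParams:
    """Band library and noise/scatter levels for the spectral model.

    ``bands`` maps constituent -> list of (centre nm, width nm, weight);
    the absorbance contribution of a constituent is its concentration
    times the sum of its Gaussian bands.  Standard NIR assignments are
    used: N-H combination/overtone bands near 2055/2180 nm for crude
    protein, C-H bands near 1725/2310 nm for fat, O-H bands at 1450/1940
    nm for residual moisture (1000 - DM), and broad fibre-like bands for
    organic matter; gross energy rides on C-H-like bands.

    ``scatter_sd`` is the log-normal sigma of the per-scan multiplicative
    factor, one value per form; the not-ground form must scatter at
    least as much as the ground form.  Baseline terms are per-scan
    normal draws; ``noise_sd`` is additive i.i.d. absorbance noise.
    """

    bands: dict = field(default_factory=lambda: {
        "moisture": [(1450.0, 45.0, 1.2e-3), (1940.0, 55.0, 1.5e-3)],
        "cp":       [(2055.0, 40.0, 0.9e-3), (2180.0, 35.0, 0.7e-3)],
        "om":       [(2100.0, 60.0, 2.5e-4), (2270.0, 50.0, 2.0e-4)],
        "ge":       [(1680.0, 50.0, 4.0e-3), (2330.0, 60.0, 5.0e-3)],
        "fat":      [(1725.0, 30.0, 1.5e-3), (2310.0, 35.0, 1.2e-3)],
    })
    scatter_sd: dict = field(default_factory=lambda: {"FDG": 0.06, "FDNG": 0.12})
    baseline_sd: dict = field(default_factory=lambda: {"FDG": 0.010, "FDNG": 0.020})
    baseline_mean: float = 0.30
    slope_mean: float = 0.25
    noise_sd: float = 3.0e-4
    n_replicates: int = 2
    outlier_band_amp: float = 0.15
    outlier_scatter_mult: float = 4.0

    def __post_init__(self):
        if self.scatter_sd["FDNG"] < self.scatter_sd["FDG"]:
            raise ValueError("FDNG scatter_sd must be >= FDG scatter_sd")
        for v in (self.noise_sd, *self.scatter_sd.values(), *self.baseline_sd.values()):
            if v < 0:
                raise ValueError("noise and scatter SDs must be non-negative")
        for bands in self.bands.values():
            for centre, width, _ in bands:
                if not (DEFAULT_GRID.start_nm <= centre <= DEFAULT_GRID.stop_nm):
                    raise ValueError(f"band centre {centre} nm outside the grid")
                if width <= 0:
                    raise ValueError("band width must be positive")


def draw_constituent(params: ChemistryParams, diet: str, constituent: str,
                     n: int, seed, kind: str = "chemistry") -> np.ndarray:
    """Draw ``n`` values for one (diet, constituent) target distribution.

    ``diet`` may be any per-diet key or ``"Total"``; ``kind`` selects
    the chemistry or the ATTD block.
    """
    table = params.chemistry if kind == "chemistry" else params.attd
    rng = np.random.default_rng(seed)
    return _draw_truncnorm(table[diet][constituent], n, rng)


def simulate_chemistry(params: ChemistryParams, design: StudyDesign, seed):
    """Generate marker-consistent faecal chemistry and ATTD records.

    Returns
    -------
    faeces : DataFrame
        One row per collected sample: identifiers (sample_id, batch,
        diet, pen, day) plus dm/cp/om/ge/fat concentrations and the
        back-solved faecal AIA (g/kg DM).
    feed : DataFrame
        One row per diet (see :meth:`ChemistryParams.feed_composition`).
    attd : DataFrame
        Long table (sample_id, constituent, attd).  Recomputing the
        marker equation from `faeces` and `feed` reproduces these values
        to machine precision.
    """
    rng = np.random.default_rng(seed)
    feed = params.feed_composition().set_index("diet", drop=False)
    pens_per_diet = design.n_pens // design.n_diets

    rows = []
    for b in range(1, design.batches + 1):
        # symmetric between-batch shift around the per-diet mean
        centre = (design.batches + 1) / 2.0
        shift_frac = params.batch_shift_sd * ((b - centre) / max(design.batches - 1, 1))
        for pen in range(1, design.n_pens + 1):
            diet = DIETS[(pen - 1) // pens_per_diet]
            for day in range(1, design.days + 1):
                rows.append({"sample_id": f"B{b}P{pen:02d}D{day}", "batch": f"B{b}",
                             "diet": diet, "pen": pen, "day": day,
                             "_shift": shift_frac})
    fae = pd.DataFrame(rows)

    for c in CONSTITUENTS:
        fae[c] = np.nan
    fae["aia"] = np.nan
    attd_cols = {c: np.full(len(fae), np.nan) for c in CONSTITUENTS}

    for (diet, shift), idx in fae.groupby(["diet", "_shift"], sort=True).groups.items():
        idx = np.asarray(idx)
        m = len(idx)
        for c in CONSTITUENTS:
            dist = params.chemistry[diet][c]
            fae.loc[idx, c] = _draw_truncnorm(dist, m, rng, mean_shift=shift * dist.sd)
        anchor_dist = params.attd[diet][params.anchor]
        a_anchor = _draw_truncnorm(anchor_dist, m, rng, mean_shift=shift * anchor_dist.sd)
        nf = feed.loc[diet]
        # back-solve the faecal marker level from the anchor coefficient
        ratio_anchor = fae.loc[idx, params.anchor].to_numpy() / nf[params.anchor]
        aia_faeces = params.feed_aia * ratio_anchor / (1.0 - a_anchor)
        fae.loc[idx, "aia"] = aia_faeces
        r = params.feed_aia / aia_faeces
        for c in CONSTITUENTS:
            attd_cols[c][idx] = 1.0 - (fae.loc[idx, c].to_numpy() / nf[c]) * r

    fae = fae.drop(columns="_shift")
    attd_long = pd.DataFrame(
        {
            "sample_id": np.repeat(fae["sample_id"].to_numpy(), len(CONSTITUENTS)),
            "constituent": np.tile(np.array(CONSTITUENTS), len(fae)),
            "attd": np.column_stack([attd_cols[c] for c in CONSTITUENTS]).ravel(),
        }
    )
    feed_out = feed.reset_index(drop=True)
    return fae, feed_out, attd_long


def _mixing_matrix(chem: pd.DataFrame, params: SpectraGenParams,
                   grid: WavelengthGrid) -> np.ndarray:
    """Deterministic Beer-Lambert mixture for each sample (no noise)."""
    wl = grid.wavelengths
    conc = {c: chem[c].to_numpy(dtype=float) for c in CONSTITUENTS}
    conc["moisture"] = 1000.0 - conc["dm"]
    mix = np.zeros((len(chem), wl.size))
    for constituent, bands in params.bands.items():
        shape = np.zeros_like(wl)
        for centre, width, weight in bands:
            shape = shape + weight * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        mix += np.outer(conc[constituent], shape)
    return mix


def simulate_spectra(
    chem: pd.DataFrame,
    params: SpectraGenParams,
    form: str,
    seed,
    grid: WavelengthGrid = DEFAULT_GRID,
    outlier_ids=(),
) -> SpectraSet:
    """Generate replicate NIR scans for one presentation form.

    Each scan is ``m * mixture + baseline + noise`` with a log-normal
    per-scan scatter factor m (sigma per form) and a per-scan linear
    baseline.  Samples listed in ``outlier_ids`` additionally receive a
    contamination band at a random centre, a curved baseline and an
    inflated scatter sigma, making them detectable anomalies.
    """
    if form not in ("FDG", "FDNG"):
        raise ValueError(f"form must be 'FDG' or 'FDNG', got {form!r}")
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    mix = _mixing_matrix(chem, params, grid)
    outliers = set(str(s) for s in outlier_ids)
    s_sd = params.scatter_sd[form]
    b_sd = params.baseline_sd[form]

    n_rep = params.n_replicates
    rows, meta = [], []
    for i, rec in enumerate(chem.itertuples(index=False)):
        sid = str(rec.sample_id)
        is_outlier = sid in outliers
        alien = np.zeros_like(wl)
        curvature = 0.0
        sigma = s_sd
        if is_outlier:
            centre = rng.uniform(1300.0, 2300.0)
            alien = params.outlier_band_amp * np.exp(-0.5 * ((wl - centre) / 30.0) ** 2)
            curvature = rng.choice([-1.0, 1.0]) * 0.5 * params.outlier_band_amp
            sigma = s_sd * params.outlier_scatter_mult
        for rep in range(1, n_rep + 1):
            m = float(np.exp(rng.normal(0.0, sigma)))
            b0 = rng.normal(params.baseline_mean, b_sd)
            b1 = rng.normal(params.slope_mean, 2.0 * b_sd)
            spectrum = (
                m * (mix[i] + alien)
                + b0 + b1 * u + curvature * u * u
                + rng.normal(0.0, params.noise_sd, wl.size)
            )
            rows.append(spectrum)
            meta.append({
                "sample_id": sid, "replicate_id": str(rep),
                "batch": getattr(rec, "batch", ""), "diet": getattr(rec, "diet", ""),
                "pen": getattr(rec, "pen", ""), "day": getattr(rec, "day", ""),
                "form": form,
            })
    return SpectraSet(grid, np.vstack(rows), pd.DataFrame(meta))


@dataclass
class StudyBundle:
    """Complete simulated study: spectra for both forms plus all tables."""

    spectra_fdg: SpectraSet
    spectra_fdng: SpectraSet
    chemistry: pd.DataFrame
    feed: pd.DataFrame
    attd: pd.DataFrame
    outlier_ids: tuple
    manifest: dict

    def attd_wide(self) -> pd.DataFrame:
        """ATTD pivoted to one column per constituent, indexed by sample."""
        return self.attd.pivot(index="sample_id", columns="constituent", values="attd")

    def write(self, outdir) -> Path:
        """Write the bundle as CSVs plus a manifest.json parameter dump."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spectra(self.spectra_fdg, outdir / "spectra_fdg.csv")
        write_spectra(self.spectra_fdng, outdir / "spectra_fdng.csv")
        self.chemistry.to_csv(outdir / "chemistry.csv", index=False, float_format="%.10g")
        self.feed.to_csv(outdir / "feed.csv", index=False, float_format="%.10g")
        self.attd.to_csv(outdir / "attd.csv", index=False, float_format="%.12g")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return outdir


def simulate_study(
    design: StudyDesign | None = None,
    chem_params: ChemistryParams | None = None,
    spec_params: SpectraGenParams | None = None,
    seed: int = 42,
) -> StudyBundle:
    """Generate the full study bundle, reproducibly from one seed.

    The collected samples are generated first; ``design.n_discard`` of
    them are removed entirely (emulating freeze-dryer losses), then
    ``design.n_outliers`` of the survivors are planted as spectral
    outliers in both presentation forms (the same samples in each, as a
    sample-level contamination would affect both scans).
    """
    design = design or StudyDesign()
    chem_params = chem_params or ChemistryParams()
    spec_params = spec_params or SpectraGenParams()
    ss = np.random.SeedSequence(seed)
    s_chem, s_select, s_fdg, s_fdng = ss.spawn(4)

    fae, feed, attd_long = simulate_chemistry(chem_params, design, s_chem)

    rng = np.random.default_rng(s_select)
    ids = fae["sample_id"].to_numpy()
    discard = rng.choice(ids, size=design.n_discard, replace=False) if design.n_discard else np.array([])
    keep_mask = ~fae["sample_id"].isin(discard)
    fae = fae.loc[keep_mask].reset_index(drop=True)
    attd_long = attd_long.loc[attd_long["sample_id"].isin(fae["sample_id"])].reset_index(drop=True)
    survivors = fae["sample_id"].to_numpy()
    outlier_ids = tuple(
        sorted(rng.choice(survivors, size=design.n_outliers, replace=False))
    ) if design.n_outliers else ()

    spectra_fdg = simulate_spectra(fae, spec_params, "FDG", s_fdg, outlier_ids=outlier_ids)
    spectra_fdng = simulate_spectra(fae, spec_params, "FDNG", s_fdng, outlier_ids=outlier_ids)

    manifest = {
        "seed": seed,
        "design": asdict(design),
        "chem_params": {
            "feed_aia": chem_params.feed_aia,
            "anchor": chem_params.anchor,
            "batch_shift_sd": chem_params.batch_shift_sd,
            "feed_dm": chem_params.feed_dm,
            "chemistry": {d: {c: asdict(v) for c, v in block.items()}
                          for d, block in chem_params.chemistry.items()},
            "attd": {d: {c: asdict(v) for c, v in block.items()}
                     for d, block in chem_params.attd.items()},
        },
        "spec_params": {
            "bands": spec_params.bands,
            "scatter_sd": spec_params.scatter_sd,
            "baseline_sd": spec_params.baseline_sd,
            "baseline_mean": spec_params.baseline_mean,
            "slope_mean": spec_params.slope_mean,
            "noise_sd": spec_params.noise_sd,
            "n_replicates": spec_params.n_replicates,
            "outlier_band_amp": spec_params.outlier_band_amp,
            "outlier_scatter_mult": spec_params.outlier_scatter_mult,
        },
        "n_collected": design.n_collected,
        "n_after_discard": int(len(fae)),
        "discarded_ids": sorted(str(s) for s in discard),
        "outlier_ids": [str(s) for s in outlier_ids],
    }
    return StudyBundle(spectra_fdg, spectra_fdng, fae, feed, attd_long, outlier_ids, manifest)
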