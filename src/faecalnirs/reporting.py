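"""Study-style report rendering and the end-to-end pipeline.

Produces the three canonical report tables of a faecal NIRS calibration
study: descriptive statistics of the calibration set per diet
(chemistry and ATTD), calibration/cross-validation statistics per
constituent and presentation form, and the Fisher SECV comparison
between forms.  Reports are a pure function of (input files, config):
rerunning the same configuration reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import compare_models, comparison_table
from .digestibility import ATTD_CONSTITUENTS
from .evaluate import CalibrationStats, CvScheme, classify_accuracy, search_treatments
from .pretreat import parse_treatment_code
from .screening import screen_outliers
from .spectra import read_spectra
from .simulate import CONSTITUENTS

logger = logging.getLogger("faecalnirs")

__all__ = ["RunConfig", "descriptive_stats", "descriptive_table",
           "calibration_table", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str, exit_code: int = 3):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


#: Report precision: decimals per quantity family.
PRECISION = {
    "chem_stat": 1,      # g/kg means, SDs, SECs, SECVs
    "energy_stat": 2,    # MJ/kg statistics
    "attd_stat": 3,      # digestibility coefficients and their errors
    "r2": 2,
    "rpd": 2,
    "cv": 3,
    "f": 2,
}


def descriptive_stats(values) -> dict:
    """Mean, sample SD, min, max and CV of a reference-value vector.

    CV = SD/mean (3 decimals in reports).  Raises when the mean is zero
    (CV undefined) or fewer than two values are supplied.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for descriptive statistics")
    mean = float(v.mean())
    if mean == 0:
        raise ValueError("mean is zero: CV undefined")
    sd = float(v.std(ddof=1))
    return {"n": int(v.size), "mean": mean, "sd": sd,
            "min": float(v.min()), "max": float(v.max()), "cv": sd / mean}


def descriptive_table(chemistry: pd.DataFrame, attd_wide: pd.DataFrame) -> pd.DataFrame:
    """Per-diet and total descriptive statistics of chemistry and ATTD."""
    rows = []
    diets = ["Total"] + sorted(chemistry["diet"].unique().tolist())
    for diet in diets:
        sub = chemistry if diet == "Total" else chemistry[chemistry["diet"] == diet]
        attd_sub = attd_wide.loc[attd_wide.index.isin(sub["sample_id"])]
        for c in CONSTITUENTS:
            stats_c = descriptive_stats(sub[c])
            stats_a = descriptive_stats(attd_sub[c]) if c in attd_sub else None
            prec = PRECISION["energy_stat"] if c == "ge" else PRECISION["chem_stat"]
            row = {"diet": diet, "constituent": c, "n": stats_c["n"]}
            for k in ("mean", "sd", "min", "max"):
                row[k] = round(stats_c[k], prec)
            row["cv"] = round(stats_c["cv"], PRECISION["cv"])
            if stats_a:
                for k in ("mean", "sd", "min", "max"):
                    row[f"attd_{k}"] = round(stats_a[k], PRECISION["attd_stat"])
                row["attd_cv"] = round(stats_a["cv"], PRECISION["cv"])
            rows.append(row)
    return pd.DataFrame(rows)


def calibration_table(stats: list[CalibrationStats], labels: dict | None = None) -> pd.DataFrame:
    """Render calibration statistics rows at report precision."""
    rows = []
    for s in stats:
        attd_like = s.constituent is not None and s.constituent.startswith("d")
        prec = (PRECISION["attd_stat"] if attd_like
                else PRECISION["energy_stat"] if s.constituent == "ge"
                else PRECISION["chem_stat"])
        band = classify_accuracy(s.r2cv, s.rpd)
        row = {
            "constituent": s.constituent,
            "form": (labels or {}).get(id(s), ""),
            "cv": s.scheme.label() if s.scheme else "",
            "treatment": str(s.treatment) if s.treatment else "",
            "n": s.n,
            "mean": round(s.mean, prec),
            "sd": round(s.sd, prec),
            "sec": round(s.sec, prec),
            "r2c": round(s.r2c, PRECISION["r2"]),
            "secv": round(s.secv, prec),
            "r2cv": round(s.r2cv, PRECISION["r2"]),
            "rpd": round(s.rpd, PRECISION["rpd"]),
            "n_factors": s.n_factors,
            "accuracy": band.band + ("*" if band.discordant else ""),
        }
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    spectra_fdg: str = ""
    spectra_fdng: str = ""
    chemistry: str = ""
    attd: str = ""
    outdir: str = "results"
    treatments: list = field(default_factory=lambda: [
        "1,4,4,1", "1,8,4,1", "1,5,5,1", "1,10,5,1",
        "2,4,4,1", "2,8,4,1", "2,5,5,1", "2,10,5,1",
    ])
    scatter: str = "snv_dt"
    pretreat_order: str = "scatter_first"
    screen_treatment: str = "1,5,5,1"
    gh_cutoff: float = 3.0
    variance_target: float = 0.99
    cv_method: str = "random_groups"
    cv_groups: int = 4
    cv_seed: int = 17
    max_factors: int = 15
    loo_final: bool = True
    alpha: float = 0.05
    constituents: list = field(default_factory=lambda: list(CONSTITUENTS) +
                               [f"d{c}" for c in ATTD_CONSTITUENTS])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}", 2)
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _references(config: RunConfig, chemistry: pd.DataFrame, attd_wide: pd.DataFrame,
                constituent: str) -> pd.Series:
    if constituent.startswith("d"):
        base = constituent[1:]
        if base not in attd_wide.columns:
            raise PipelineError("references", f"no ATTD values for {constituent}")
        return attd_wide[base]
    if constituent not in chemistry.columns:
        raise PipelineError("references", f"no chemistry column {constituent}")
    return chemistry.set_index("sample_id")[constituent]


def run_pipeline(config: RunConfig) -> dict:
    """Screen, calibrate, evaluate and compare both presentation forms.

    Stages: GH screening per form -> per-constituent math-treatment
    search under the configured cross-validation -> leave-one-out
    statistics of each winning treatment (when ``loo_final``) ->
    between-form Fisher comparison -> report tables written to
    ``config.outdir`` (descriptive.csv, calibration.csv, comparison.csv,
    screening_<form>.json, manifest.json).
    """
    for name in ("spectra_fdg", "spectra_fdng", "chemistry", "attd"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise PipelineError("config", f"missing input file for {name!r}: {path!r}", 2)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline(config, outdir, written)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_pipeline(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    try:
        sets = {"FDG": read_spectra(config.spectra_fdg, grid_policy="strict"),
                "FDNG": read_spectra(config.spectra_fdng, grid_policy="strict")}
        chemistry = pd.read_csv(config.chemistry)
        attd_long = pd.read_csv(config.attd)
    except (ValueError, OSError) as exc:
        raise PipelineError("load", str(exc)) from exc
    attd_wide = attd_long.pivot(index="sample_id", columns="constituent", values="attd")

    screen_code = parse_treatment_code(config.screen_treatment, scatter=config.scatter)
    kept = {}
    for form, sset in sets.items():
        avg = sset.average_replicates()
        result = screen_outliers(avg, screen_code, cutoff=config.gh_cutoff,
                                 variance_target=config.variance_target,
                                 order=config.pretreat_order)
        kept[form] = avg.select(result.kept_ids)
        logger.info("screen %s: %d -> %d samples (%d flagged, k=%d)",
                    form, len(avg), len(kept[form]), len(result.flagged_ids), result.k)
        p = outdir / f"screening_{form.lower()}.json"
        p.write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
        written.append(p)

    codes = [parse_treatment_code(c, scatter=config.scatter) for c in config.treatments]
    scheme = CvScheme(method=config.cv_method, n_groups=config.cv_groups, seed=config.cv_seed)
    loo = CvScheme(method="leave_one_out")

    all_stats: dict[str, list[CalibrationStats]] = {"FDG": [], "FDNG": []}
    final_stats: dict[str, list[CalibrationStats]] = {"FDG": [], "FDNG": []}
    search_tables = []
    for form in ("FDG", "FDNG"):
        for constituent in config.constituents:
            y = _references(config, chemistry, attd_wide, constituent)
            try:
                best, table = search_treatments(
                    kept[form], y, codes, scheme=scheme, max_factors=config.max_factors,
                    constituent=constituent, order=config.pretreat_order)
            except ValueError as exc:
                raise PipelineError("calibrate", f"{form}/{constituent}: {exc}", 4) from exc
            table.insert(0, "form", form)
            search_tables.append(table)
            all_stats[form].append(best)
            if config.loo_final:
                from .evaluate import evaluate
                from .pretreat import apply_treatment

                avg = kept[form]
                treated = apply_treatment(avg, best.treatment, order=config.pretreat_order)
                ids = [s for s in treated.sample_ids if s in y.index]
                sub = treated.select(ids)
                stats_loo = evaluate(sub.absorbance, y.loc[list(sub.sample_ids)].to_numpy(),
                                     scheme=loo, max_factors=config.max_factors,
                                     constituent=constituent, treatment=best.treatment)
                final_stats[form].append(stats_loo)
            else:
                final_stats[form].append(best)
            logger.info("calibrate %s/%s: treatment %s, SECV %.4g, R2cv %.3f",
                        form, constituent, best.treatment, best.secv, best.r2cv)

    comparisons = compare_models(final_stats["FDG"], final_stats["FDNG"], p_level=config.alpha)

    desc = descriptive_table(chemistry, attd_wide)
    calib_rows = []
    for form in ("FDG", "FDNG"):
        for s in all_stats[form] + (final_stats[form] if config.loo_final else []):
            t = calibration_table([s])
            t["form"] = form
            calib_rows.append(t)
    calib = pd.concat(calib_rows, ignore_index=True)
    comp = comparison_table(comparisons, precision=PRECISION["f"])

    for name, df in (("descriptive.csv", desc), ("calibration.csv", calib),
                     ("comparison.csv", comp),
                     ("treatment_search.csv", pd.concat(search_tables, ignore_index=True))):
        p = outdir / name
        df.to_csv(p, index=False)
        written.append(p)
    manifest = {"config": asdict(config), "config_hash": config.hash(),
                "n_kept": {f: int(len(kept[f])) for f in kept}}
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(p)
    return {"descriptive": desc, "calibration": calib, "comparison": comp,
            "stats": final_stats, "manifest": manifest}
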