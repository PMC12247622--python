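"""End-to-end orchestration and I/O.

Reads delimited signal tables (columns: subject, species, td_ms, b_ms_per_um2,
signal, optional signal_se), fits the cumulant representation per diffusion
time, assembles per-subject D(td)/K(td) series, runs the requested
time-dependence models, ranks functional forms by cAIC, and emits a single
JSON report that embeds the seed, a config hash and the package version so a
re-run reproduces every number.

The two-stage estimation mirrors the experimental analysis: stage one fits
S(b) per (subject, species, td); stage two fits td-dependence models to the
resulting cumulant series.  Fits run per subject and parameters are averaged
across subjects (mean and SEM); fitting the subject-averaged series instead
is available as an option.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import AnalysisError, SchemaError
from .fitting import (
    FitResult,
    fit_cumulant,
    fit_geometry,
    fit_karger,
    fit_log_singularity,
    fit_nexi,
    fit_powerlaw_fixed_theta,
    fit_powerlaw_free_theta,
)
from .models import CumulantSeries, DecayCurve

logger = logging.getLogger("dktime")

__all__ = ["AnalysisConfig", "read_signal_table", "write_signal_table",
           "run_analysis", "write_report", "DEFAULT_B_MAX", "WATER_MODELS",
           "METABOLITE_MODELS"]

REQUIRED_COLUMNS = ("subject", "species", "td_ms", "b_ms_per_um2", "signal")

#: per-species guard on the cumulant-expansion b range (ms/um^2): the
#: acquisition grids are designed around the convergence radius for water and
#: for the roughly four-times-slower metabolites.
DEFAULT_B_MAX = {"water": 2.5, "default": 8.0}

WATER_MODELS = ("powerlaw_theta05", "powerlaw_theta1", "powerlaw_free",
                "log_singularity", "karger_eq5", "karger_eq6")
METABOLITE_MODELS = ("geometry",)


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_path: str | None = None
    species: tuple[str, ...] | None = None   # None = all species in the table
    b_max: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_B_MAX))
    td_min_karger: float = 42.5
    models: tuple[str, ...] | None = None    # None = per-species defaults
    fit_averaged: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_signal_table(path) -> list[DecayCurve]:
    """Read a delimited signal table into DecayCurves grouped by (subject, species, td).

    Duplicated (subject, species, td, b) rows are averaged with a logged
    warning.  Missing columns raise SchemaError; non-numeric cells are
    reported with their row numbers.
    """
    import csv as _csv

    try:
        with open(path, newline="") as fh:
            sample = fh.read(65536)
    except OSError as exc:
        raise SchemaError(f"{path}: cannot read input ({exc})") from None
    if not sample.strip():
        raise SchemaError(f"{path}: empty input table")
    try:
        sep = _csv.Sniffer().sniff(sample.splitlines()[0], delimiters=",\t;").delimiter
    except _csv.Error:
        sep = ","
    try:
        # round_trip parsing keeps written values bit-identical on re-read
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input table") from None
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no data rows")
    for col in ("td_ms", "b_ms_per_um2", "signal"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 2  # 1-based incl. header
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col!r} in row(s) {list(bad)}")
        if vals.isna().any():
            raise SchemaError(
                f"{path}: missing {col!r} in row(s) {list(df.index[vals.isna()] + 2)}"
            )
        df[col] = vals
    has_se = "signal_se" in df.columns
    key = ["subject", "species", "td_ms", "b_ms_per_um2"]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        logger.warning("%s: %d duplicated (subject, species, td, b) rows averaged", path, n_dup)
        agg = {"signal": "mean", **({"signal_se": "mean"} if has_se else {})}
        df = df.groupby(key, as_index=False, sort=False).agg(agg)
    curves = []
    for (subj, spec, td), grp in df.groupby(["subject", "species", "td_ms"], sort=True):
        grp = grp.sort_values("b_ms_per_um2")
        curves.append(DecayCurve(
            subject=str(subj), species=str(spec), td=float(td),
            b=grp["b_ms_per_um2"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            signal_se=grp["signal_se"].to_numpy() if has_se else None,
        ))
    return curves


def write_signal_table(curves: list[DecayCurve], path) -> None:
    """Write DecayCurves to CSV; numeric values round-trip losslessly."""
    rows = []
    for c in curves:
        for i in range(c.b.size):
            row = {"subject": c.subject, "species": c.species, "td_ms": c.td,
                   "b_ms_per_um2": c.b[i], "signal": c.signal[i]}
            if c.signal_se is not None:
                row["signal_se"] = c.signal_se[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _fit_summary(fit: FitResult) -> dict:
    return {
        "params": fit.params,
        "se": fit.se,
        "rss": fit.rss,
        "caic": None if np.isnan(fit.caic) else fit.caic,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
        "converged": fit.converged,
        "flags": list(fit.flags),
        "derived": fit.derived,
    }


def _run_series_models(series: CumulantSeries, models, td_min_karger) -> dict:
    """Fit the requested td-dependence models to one cumulant series."""
    out = {}
    for name in models:
        try:
            if name == "powerlaw_theta05":
                fd, fk = fit_powerlaw_fixed_theta(series, 0.5)
                out[name] = {"D": _fit_summary(fd), "K": _fit_summary(fk)}
            elif name == "powerlaw_theta1":
                fd, fk = fit_powerlaw_fixed_theta(series, 1.0)
                out[name] = {"D": _fit_summary(fd), "K": _fit_summary(fk)}
            elif name == "powerlaw_free":
                out[name] = {"joint": _fit_summary(fit_powerlaw_free_theta(series))}
            elif name == "log_singularity":
                out[name] = {
                    "D": _fit_summary(fit_log_singularity(series, "D")),
                    "K": _fit_summary(fit_log_singularity(series, "K")),
                }
            elif name in ("karger_eq5", "karger_eq6"):
                variant = name.split("_")[1]
                out[name] = {"K": _fit_summary(
                    fit_karger(series, variant=variant, td_min=td_min_karger))}
            elif name == "geometry":
                out[name] = {"joint": _fit_summary(fit_geometry(series))}
            else:
                raise AnalysisError(f"unknown model {name!r}")
        except AnalysisError:
            raise
        except Exception as exc:  # fit failures are reported, never fatal
            logger.warning("model %s failed: %s", name, exc)
            out[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return out


def _caic_ranking(fits: dict) -> list[dict]:
    """Rank functional forms fitted to the same series by summed component cAIC."""
    rows = []
    for name, comp in fits.items():
        if "error" in comp:
            continue
        caics = [v["caic"] for v in comp.values() if v.get("caic") is not None]
        if caics and len(caics) == len(comp):
            rows.append({"model": name, "caic_total": float(sum(caics))})
    return sorted(rows, key=lambda r: r["caic_total"])


def _series_records(series: CumulantSeries) -> list[dict]:
    return [
        {"td_ms": p.td, "D": p.D, "K": p.K, "D_se": p.D_se, "K_se": p.K_se}
        for p in series.points
    ]


def _average_series(series_list: list[CumulantSeries], species: str) -> CumulantSeries | None:
    """Subject-mean series (SEM across subjects) on the common td grid."""
    tds = [tuple(s.td) for s in series_list]
    if len(set(tds)) != 1:
        return None
    td = series_list[0].td
    D = np.array([s.D for s in series_list])
    K = np.array([s.K for s in series_list])
    n = D.shape[0]
    sem = np.sqrt(n) if n > 1 else 1.0
    return CumulantSeries.from_arrays(
        td, D.mean(0), K.mean(0),
        D.std(0, ddof=1) / sem if n > 1 else [np.nan] * td.size,
        K.std(0, ddof=1) / sem if n > 1 else [np.nan] * td.size,
        species=species,
    )


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full two-stage analysis and return the report dictionary."""
    curves = read_signal_table(config.input_path)
    if config.species is not None:
        curves = [c for c in curves if c.species in config.species]
    if not curves:
        raise AnalysisError("no decay curves match the requested species selection")

    by_group: dict[tuple[str, str], list[DecayCurve]] = {}
    for c in curves:
        by_group.setdefault((c.subject, c.species), []).append(c)

    report: dict = {
        "meta": {
            "package": "dktime",
            "version": __version__,
            "seed": config.seed,
            "config": _jsonable(asdict(config)),
            "config_sha256": hashlib.sha256(
                json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()
            ).hexdigest(),
            "n_curves": len(curves),
        },
        "subjects": {},
        "group": {},
    }

    series_by_species: dict[str, list[CumulantSeries]] = {}
    fits_by_species: dict[str, dict[str, list[dict]]] = {}
    for (subject, species), group in sorted(by_group.items()):
        b_max = config.b_max.get(species, config.b_max.get("default", np.inf))
        points = []
        errors = []
        for curve in sorted(group, key=lambda c: c.td):
            keep = curve.b <= b_max + 1e-12
            sub = DecayCurve(curve.subject, curve.species, curve.td,
                             curve.b[keep], curve.signal[keep],
                             None if curve.signal_se is None else curve.signal_se[keep])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    points.append(fit_cumulant(sub))
            except Exception as exc:
                errors.append({"td_ms": curve.td, "error": f"{type(exc).__name__}: {exc}"})
        entry: dict = {"cumulants": [], "errors": errors}
        if points:
            series = CumulantSeries(points=points, species=species)
            entry["cumulants"] = _series_records(series)
            models = config.models
            if models is None:
                models = WATER_MODELS if species == "water" else METABOLITE_MODELS
            fits = _run_series_models(series, models, config.td_min_karger)
            entry["fits"] = fits
            entry["caic_ranking"] = _caic_ranking(fits)
            series_by_species.setdefault(species, []).append(series)
            for mname, comp in fits.items():
                fits_by_species.setdefault(species, {}).setdefault(mname, []).append(comp)
        report["subjects"].setdefault(subject, {})[species] = entry

    for species, series_list in series_by_species.items():
        gentry: dict = {"n_subjects": len(series_list)}
        gentry["param_summary"] = _group_param_summary(fits_by_species.get(species, {}))
        avg = _average_series(series_list, species)
        if avg is not None:
            gentry["cumulant_mean"] = _series_records(avg)
            if config.fit_averaged:
                models = config.models
                if models is None:
                    models = WATER_MODELS if species == "water" else METABOLITE_MODELS
                fits = _run_series_models(avg, models, config.td_min_karger)
                gentry["averaged_series_fits"] = fits
                gentry["caic_ranking"] = _caic_ranking(fits)
        report["group"][species] = gentry

    if config.output_path:
        write_report(report, config.output_path)
    return report


def _group_param_summary(model_fits: dict[str, list[dict]]) -> dict:
    """Across-subject mean and SEM of every fitted parameter, per model/component."""
    out: dict = {}
    for mname, entries in model_fits.items():
        comp_names = {k for e in entries for k in e if k != "error"}
        for comp in comp_names:
            params: dict[str, list[float]] = {}
            for e in entries:
                if comp not in e or "params" not in e[comp]:
                    continue
                for pname, val in e[comp]["params"].items():
                    params.setdefault(pname, []).append(val)
                for pname, val in e[comp].get("derived", {}).items():
                    if not pname.endswith("_se"):
                        params.setdefault(pname, []).append(val)
            summary = {}
            for pname, vals in params.items():
                arr = np.asarray(vals, dtype=float)
                summary[pname] = {
                    "mean": float(arr.mean()),
                    "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None,
                    "n": int(arr.size),
                }
            if summary:
                out.setdefault(mname, {})[comp] = summary
    return out


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(report: dict, path) -> None:
    """Write the analysis report as indented JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
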