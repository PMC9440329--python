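"""Orchestration of the five stages with file-passing between them.

Each stage's output is persisted as a delimited ASCII table so any stage can
be re-run from files; the in-memory entry point :func:`run_pipeline` drives
the same code without touching disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import goldpan, predictor, prospector, workhorse
from ..features import FeatureMatrix, build_feature_matrix
from .config import ControlFile
from . import tables

log = logging.getLogger("cropcast")


@dataclass
class YearArtifacts:
    screening: prospector.ScreeningResult
    eval_table: workhorse.EvalTable
    selection: goldpan.SelectionResult
    predictions: dict[str, float]


@dataclass
class PipelineResult:
    feature_matrix: FeatureMatrix
    years: dict[int, YearArtifacts]
    series: dict[str, pd.DataFrame]
    metrics: pd.DataFrame

    @property
    def national_series(self) -> pd.DataFrame:
        return self.series["ALL"]


def run_target_year(
    feature_matrix: FeatureMatrix,
    yields: pd.DataFrame,
    control: ControlFile,
    target_year: int,
    combos: np.ndarray | None = None,
) -> YearArtifacts | None:
    """Stages 1-4 for one target year; returns None if nothing was screened."""
    screening = prospector.screen_features(
        feature_matrix,
        yields,
        target_year,
        k=control.k_retain,
        d=control.d_max,
        confidence=control.confidence,
        min_years=control.min_years,
        enforce_nonoverlap=control.enforce_nonoverlap,
        fallback_top_m=control.fallback_top_m,
        combos=combos,
        n_jobs=control.n_jobs,
    )
    if not screening.selected:
        log.warning("target year %s: no features screened, year skipped", target_year)
        return None
    eval_table = workhorse.build_eval_table(
        feature_matrix,
        yields,
        target_year,
        screening.selected,
        d_max=control.d_max,
        strict=control.strict,
        min_pairs=control.min_pairs,
        min_years=control.min_years,
        enforce_nonoverlap=control.enforce_nonoverlap,
    )
    if control.selection_mode == "local":
        selection = goldpan.local_heroes_only(eval_table)
    else:
        pool = goldpan.build_pool(
            eval_table,
            n_global=control.global_top,
            fractions=tuple(control.fractions),
        )
        selection = goldpan.assign_district_combos(pool, eval_table)

    mode = "hindcast" if target_year in yields.columns else "forecast"
    predictions: dict[str, float] = {}
    for dist, name in selection.assignment.items():
        combo = eval_table.combos[name]
        rec = predictor.predict_district(
            dist,
            target_year,
            combo,
            yields.loc[dist] if dist in yields.index else pd.Series(dtype=float),
            feature_matrix.district_frame(dist),
            mode=mode,
            min_years=control.min_years,
        )
        if rec is not None:
            predictions[dist] = rec.predicted
    log.info(
        "year %s: q=%d screened, A=%d combos, c=%d applied, %d districts predicted",
        target_year, screening.q, eval_table.n_rows, selection.n_distinct,
        len(predictions),
    )
    return YearArtifacts(screening, eval_table, selection, predictions)


def run_pipeline(
    weather: pd.DataFrame,
    yields: pd.DataFrame,
    areas: pd.Series,
    region_map: pd.Series | None,
    control: ControlFile,
    target_years: list[int] | None = None,
) -> PipelineResult:
    """Run all stages over all target years, in memory."""
    variables = control.weather_variables()
    fm = build_feature_matrix(
        weather,
        variables,
        control.cutoff_month,
        window_bounds=(control.window_min, control.window_max),
        season_length=control.season_length,
    )
    names = fm.feature_names
    compat = (
        prospector.compatibility_matrix(names, fm.windows_by_name())
        if control.enforce_nonoverlap
        else None
    )
    combos = prospector.combos_array(names, control.d_max, compat)

    if target_years is None:
        target_years = control.target_years or sorted(int(y) for y in yields.columns)
    years: dict[int, YearArtifacts] = {}
    for yr in target_years:
        art = run_target_year(fm, yields, control, yr, combos=combos)
        if art is not None:
            years[yr] = art

    district_predictions = {yr: art.predictions for yr, art in years.items()}
    forecast_years = [yr for yr in years if yr not in yields.columns]
    series = predictor.build_aggregate_series(
        district_predictions, yields, areas, region_map, forecast_years=forecast_years
    )
    rows = []
    for region, df in series.items():
        paired = df.dropna(subset=["observed", "predicted"])
        if len(paired) >= 3:
            m = predictor.validation_metrics(paired["observed"], paired["predicted"])
            rows.append(
                {
                    "region": region,
                    "r2_val": m.r2_val,
                    "rmse": m.rmse,
                    "r2_pearson": m.r2_pearson,
                    "n_years": m.n_years,
                }
            )
    metrics = pd.DataFrame(rows).set_index("region") if rows else pd.DataFrame()
    return PipelineResult(feature_matrix=fm, years=years, series=series, metrics=metrics)


def _write_year(out: Path, yr: int, art: YearArtifacts, sep: str) -> None:
    scr = art.screening
    counts = scr.counts.rename("count").rename_axis("feature").reset_index()
    counts["selected"] = counts["feature"].isin(scr.selected)
    counts.to_csv(out / f"screening_{yr}.tsv", sep=sep, index=False)
    tables.write_matrix(art.eval_table.table.rename_axis("combo"), out / f"eval_{yr}.tsv", sep)
    pool = pd.DataFrame(
        [{"combo": e.name, "provenance": e.provenance, "score": e.score} for e in art.selection.pool]
    )
    pool.to_csv(out / f"pool_{yr}.tsv", sep=sep, index=False)
    assign = pd.DataFrame(
        [
            {"district": d, "combo": c, "r": art.selection.assigned_r.get(d, float("nan"))}
            for d, c in sorted(art.selection.assignment.items())
        ]
    )
    assign.to_csv(out / f"assignment_{yr}.tsv", sep=sep, index=False)
    preds = pd.DataFrame(
        [{"district": d, "predicted": v} for d, v in sorted(art.predictions.items())]
    )
    preds.to_csv(out / f"predictions_{yr}.tsv", sep=sep, index=False)


def run_all(control: ControlFile, base_dir: str | Path = ".") -> PipelineResult:
    """Read the control file's inputs, run everything, persist all artifacts."""
    base = Path(base_dir)
    sep = control.delimiter
    weather = tables.read_weather_table(base / control.weather_path, sep)
    yields = tables.read_yield_table(base / control.yields_path, sep)
    areas = tables.read_area_table(base / control.areas_path, sep)
    regions_path = base / control.regions_path
    region_map = tables.read_region_map(regions_path, sep) if regions_path.exists() else None

    enough = yields.notna().sum(axis=1) >= control.min_years
    if (~enough).any():
        log.info("excluding %d district(s) with < %d yield years", int((~enough).sum()),
                 control.min_years)

    result = run_pipeline(weather, yields, areas, region_map, control)

    out = base / control.out_dir
    out.mkdir(parents=True, exist_ok=True)
    for yr, art in result.years.items():
        _write_year(out, yr, art, sep)
    for region, df in result.series.items():
        df.reset_index().to_csv(
            out / f"series_{region}.tsv", sep=sep, index=False, na_rep=tables.NA_TOKEN,
            float_format=tables.FLOAT_FMT,
        )
    if not result.metrics.empty:
        result.metrics.reset_index().to_csv(
            out / "metrics.tsv", sep=sep, index=False, float_format=tables.FLOAT_FMT
        )
    return result
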