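"""End-to-end analysis: SST metrics -> reef indices -> driver model -> report.

The stages are plain functions over in-memory objects so they compose from
Python; :func:`run_pipeline` strings them together from a
:class:`~reefheat.io.PipelineConfig`, persisting every intermediate table.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices as idx
from .io import PipelineConfig, read_fc_table, read_sst, read_surveys, write_table
from .model import DriverModelResult, simplify_model
from .sst import ClimatologyProfile, DailySSTSeries, EXPOSURE_METRIC_NAMES, exposure_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "compute_exposure_table",
    "compute_index_table",
    "merge_metrics",
    "run_pipeline",
    "FIELD_METRIC_NAMES",
]

#: Field-based candidate predictors joining the 17 remote-sensing metrics.
FIELD_METRIC_NAMES = ["depth", "si_reef", "rfi", "richness", "diversity_n1", "dca1"]


def _obs_key(site_id, date) -> str:
    return f"{site_id}|{pd.Timestamp(date).date()}"


def compute_exposure_table(
    sst: dict[str, DailySSTSeries],
    samples: pd.DataFrame,
    baseline: tuple[int, int] = (1985, 2012),
    allow_partial: bool = False,
) -> pd.DataFrame:
    """All 17 remote-sensing metrics for each (site_id, sample_date) row."""
    profiles: dict[str, ClimatologyProfile] = {}
    rows = []
    for _, rec in samples.iterrows():
        site = str(rec["site_id"])
        if site not in sst:
            raise KeyError(f"no SST series for site {site!r}")
        if site not in profiles:
            profiles[site] = ClimatologyProfile.from_series(
                sst[site], baseline, allow_partial=allow_partial
            )
        em = exposure_metrics(sst[site], profiles[site], rec["sample_date"])
        rows.append(em.as_dict())
    out = pd.DataFrame(rows)
    logger.info("exposure metrics: %d rows x %d metrics", len(out), len(EXPOSURE_METRIC_NAMES))
    return out


def compute_index_table(
    surveys: list[idx.SurveyObservation],
    fc_table: idx.FunctionalCoefficientTable | None = None,
    si_table: idx.SpeciesSensitivityTable | None = None,
    min_colonies: int = 50,
    si_mode: str = "pooled",
) -> tuple[pd.DataFrame, idx.SpeciesSensitivityTable]:
    """Field-based metrics (BSI, SI_reef, RFI, richness, N1, DCA1) per survey.

    The species sensitivity table is taken from ``si_table`` when supplied
    (external mode); otherwise it is pooled from these very surveys
    (acknowledged circularity) or, with ``si_mode='leave-one-site-out'``,
    each observation is scored by a table pooled from all *other* sites.
    """
    if not surveys:
        raise ValueError("no surveys supplied")
    pooled = si_table or idx.species_bsi_table(surveys, min_colonies)

    # observation x species matrix for the ordination
    ab = {
        _obs_key(o.site_id, o.date): o.species_abundances() for o in surveys
    }
    matrix = pd.DataFrame(ab).T.fillna(0.0)
    matrix = matrix.div(matrix.sum(axis=1), axis=0)
    dca_scores = None
    try:
        dca_scores = idx.dca_axis1(matrix)
    except ValueError as err:
        logger.warning("DCA skipped: %s", err)

    rows = []
    for obs in surveys:
        table = pooled
        if si_table is None and si_mode == "leave-one-site-out":
            others = [o for o in surveys if o.site_id != obs.site_id]
            table = idx.species_bsi_table(others, min_colonies)
        try:
            rec = idx.reef_index_set(
                obs, table, fc_table, dca_scores, dca_key=_obs_key(obs.site_id, obs.date)
            )
        except ValueError as err:
            logger.warning("observation %s %s skipped: %s", obs.site_id, obs.date.date(), err)
            continue
        rows.append(rec.as_dict())
    out = pd.DataFrame(rows).rename(columns={"date": "sample_date"})
    logger.info("reef indices: %d observations", len(out))
    return out, pooled


def merge_metrics(exposure: pd.DataFrame, index_table: pd.DataFrame) -> pd.DataFrame:
    """One row per observation: 17 thermal + 6 field metrics + the BSI response."""
    merged = exposure.merge(index_table, on=["site_id", "sample_date"], how="inner")
    logger.info("merged table: %d rows", len(merged))
    return merged


def candidate_features(merged: pd.DataFrame) -> pd.DataFrame:
    """The 23 candidate predictor columns, dropping all-missing ones."""
    names = EXPOSURE_METRIC_NAMES + FIELD_METRIC_NAMES
    present = [n for n in names if n in merged.columns and merged[n].notna().any()]
    absent = sorted(set(names) - set(present))
    if absent:
        logger.warning("candidate metrics unavailable and skipped: %s", absent)
    return merged[present].astype(float)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and persist every stage under output_dir.

    Outputs: metrics.csv, indices.csv, species_bsi.csv, merged.csv,
    model_report.json, pd_curves.csv, residuals.csv. Deterministic given the
    config seeds. Raises on stage failure after persisting the stages that
    completed.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    surveys = read_surveys(config.surveys_path)
    logger.info("stage surveys: %d observations", len(surveys))
    sites = pd.DataFrame(
        [
            {"site_id": o.site_id, "lat": o.latitude, "lon": o.longitude}
            for o in surveys
        ]
    ).drop_duplicates("site_id")
    sst = read_sst(config.sst_path, sites=sites)
    logger.info("stage sst: %d sites", len(sst))

    fc_table = None
    if config.fc_path:
        fc_table = read_fc_table(config.fc_path)
    else:
        logger.warning("no functional-coefficient table: RFI will be skipped")

    samples = pd.DataFrame(
        [{"site_id": o.site_id, "sample_date": o.date} for o in surveys]
    )
    exposure = compute_exposure_table(sst, samples, baseline=config.baseline)
    write_table(exposure, out_dir / "metrics.csv")

    index_table, si_table = compute_index_table(
        surveys,
        fc_table=fc_table,
        min_colonies=config.min_colonies,
        si_mode=config.si_mode,
    )
    write_table(index_table, out_dir / "indices.csv")
    write_table(
        si_table.table.reset_index(names="species"), out_dir / "species_bsi.csv"
    )

    merged = merge_metrics(exposure, index_table)
    write_table(merged, out_dir / "merged.csv")

    X = candidate_features(merged)
    y = merged["bsi"].to_numpy(dtype=float)
    result = simplify_model(
        X,
        y,
        config.model,
        compute_h=config.compute_h,
        pd_n_boot=config.pd_n_boot,
    )
    report = result.report()
    report["n_observations"] = len(merged)
    report["candidate_predictors"] = list(X.columns)
    with open(out_dir / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    pd_frames = [c.to_frame() for c in result.pd_curves.values()]
    write_table(pd.concat(pd_frames, ignore_index=True), out_dir / "pd_curves.csv")
    resid = merged[["site_id", "sample_date"]].copy()
    resid["lat"] = merged["site_id"].map(sites.set_index("site_id")["lat"])
    resid["lon"] = merged["site_id"].map(sites.set_index("site_id")["lon"])
    resid["bsi"] = y
    resid["fitted"] = y - result.residuals
    resid["residual"] = result.residuals
    write_table(resid, out_dir / "residuals.csv")
    logger.info(
        "pipeline complete: cv_r2=%.3f, %d predictors selected",
        result.cv_r2,
        len(result.selected_predictors),
    )
    return {"result": result, "report": report, "merged": merged, "output_dir": out_dir}
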