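"""Readers, writers and configuration for the bleaching-vulnerability pipeline.

CSV is the interchange format throughout: long-format daily SST
(site_id, date, sst), colony surveys (site_id, date, lat, lon, depth_m,
species, category, count), functional coefficients (species, fc,
source_species), and tidy metric tables. Gridded SST can be read from
NetCDF (CoralTemp-like ``time x lat x lon`` layout) with nearest-cell
extraction per site. Every table written by the package carries a
schema-version comment in its first line.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .indices import CATEGORIES, FunctionalCoefficientTable, SurveyObservation
from .model import ModelConfig
from .sst import DailySSTSeries

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_SCHEMA_COMMENT = f"# reefheat-schema: {SCHEMA_VERSION}"

__all__ = [
    "read_sst_csv",
    "write_sst_csv",
    "read_sst_netcdf",
    "read_sst",
    "read_surveys",
    "write_surveys",
    "read_fc_table",
    "write_fc_table",
    "write_table",
    "read_table",
    "PipelineConfig",
]


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy CSV with the schema-version comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_SCHEMA_COMMENT + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# SST
# ---------------------------------------------------------------------------


def write_sst_csv(series_by_site: dict[str, DailySSTSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {"site_id": s.site_id, "date": s.dates.strftime("%Y-%m-%d"), "sst": s.sst}
        )
        for s in series_by_site.values()
    ]
    write_table(pd.concat(frames, ignore_index=True), path)


def read_sst_csv(path) -> dict[str, DailySSTSeries]:
    """Long-format CSV (site_id, date, sst) to per-site validated series."""
    df = read_table(path)
    required = {"site_id", "date", "sst"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SST CSV missing column(s) {sorted(missing)} in {path}")
    out = {}
    for site_id, grp in df.groupby("site_id", sort=True):
        dates = pd.DatetimeIndex(pd.to_datetime(grp["date"]))
        out[str(site_id)] = DailySSTSeries(
            str(site_id), dates, grp["sst"].to_numpy(dtype=float)
        )
    if not out:
        raise ValueError(f"no SST rows in {path}")
    return out


def read_sst_netcdf(
    path, sites: pd.DataFrame, var: str = "analysed_sst"
) -> dict[str, DailySSTSeries]:
    """Nearest-grid-cell extraction from a (time, lat, lon) NetCDF cube.

    ``sites`` needs columns site_id, lat, lon; the extraction distance to
    the chosen cell center is logged per site.
    """
    import xarray as xr
    from .robust import haversine_km

    ds = xr.open_dataset(path)
    if var not in ds:
        raise ValueError(f"variable {var!r} not in {path}; found {list(ds.data_vars)}")
    da = ds[var]
    out = {}
    for _, row in sites.iterrows():
        cell = da.sel(lat=row["lat"], lon=row["lon"], method="nearest")
        dist = float(
            haversine_km(row["lat"], row["lon"], float(cell.lat), float(cell.lon))
        )
        logger.info(
            "site %s: nearest grid cell at %.2f km", row["site_id"], dist
        )
        dates = pd.DatetimeIndex(pd.to_datetime(cell["time"].values)).normalize()
        out[str(row["site_id"])] = DailySSTSeries(
            str(row["site_id"]), dates, np.asarray(cell.values, dtype=float)
        )
    ds.close()
    return out


def read_sst(path, sites: pd.DataFrame | None = None, fmt: str | None = None):
    """Dispatch on format: 'csv' (long table) or 'netcdf' (gridded cube)."""
    path = Path(path)
    if fmt is None:
        fmt = "netcdf" if path.suffix.lower() in {".nc", ".nc4", ".cdf"} else "csv"
    if fmt == "csv":
        return read_sst_csv(path)
    if fmt == "netcdf":
        if sites is None:
            raise ValueError("NetCDF extraction needs a sites table (site_id, lat, lon)")
        return read_sst_netcdf(path, sites)
    raise ValueError(f"unknown SST format {fmt!r}")


# ---------------------------------------------------------------------------
# Surveys and functional coefficients
# ---------------------------------------------------------------------------

_SURVEY_COLUMNS = ["site_id", "date", "lat", "lon", "depth_m", "species", "category", "count"]


def _normalize_category(raw: str) -> str:
    cat = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
    if cat != raw:
        logger.warning("category %r normalized to %r", raw, cat)
    if cat not in CATEGORIES:
        raise ValueError(
            f"unknown bleaching category {raw!r}; expected one of {CATEGORIES}"
        )
    return cat


def read_surveys(path) -> list[SurveyObservation]:
    """Colony-survey CSV to validated observations (one per site x date)."""
    df = read_table(path)
    if df.empty:
        raise ValueError(f"empty survey file {path}")
    missing = set(_SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV missing column(s) {sorted(missing)} in {path}")
    df["category"] = df["category"].map(_normalize_category)
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for (site_id, date), grp in df.groupby(["site_id", "date"], sort=True):
        colonies = [
            (str(r["species"]), r["category"], int(r["count"]))
            for _, r in grp.iterrows()
        ]
        out.append(
            SurveyObservation(
                site_id=str(site_id),
                date=date,
                latitude=float(grp["lat"].iloc[0]),
                longitude=float(grp["lon"].iloc[0]),
                depth=float(grp["depth_m"].iloc[0]),
                colonies=colonies,
            )
        )
    return out


def write_surveys(surveys: list[SurveyObservation], path) -> None:
    rows = []
    for obs in surveys:
        for species, category, count in obs.colonies:
            rows.append(
                {
                    "site_id": obs.site_id,
                    "date": obs.date.strftime("%Y-%m-%d"),
                    "lat": obs.latitude,
                    "lon": obs.longitude,
                    "depth_m": obs.depth,
                    "species": species,
                    "category": category,
                    "count": count,
                }
            )
    write_table(pd.DataFrame(rows, columns=_SURVEY_COLUMNS), path)


def read_fc_table(path) -> FunctionalCoefficientTable:
    df = read_table(path)
    missing = {"species", "fc"} - set(df.columns)
    if missing:
        raise ValueError(f"functional-coefficient CSV missing {sorted(missing)}")
    if "source_species" not in df.columns:
        df["source_species"] = df["species"]
    return FunctionalCoefficientTable(table=df.set_index("species"))


def write_fc_table(table: FunctionalCoefficientTable, path) -> None:
    write_table(table.table.reset_index().rename(columns={"index": "species"}), path)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; round-trips losslessly through YAML."""

    sst_path: str = ""
    surveys_path: str = ""
    fc_path: str | None = None
    output_dir: str = "reefheat_out"
    baseline: tuple[int, int] = (1985, 2012)
    min_colonies: int = 50
    si_mode: str = "pooled"  # pooled | leave-one-site-out
    model: ModelConfig = field(default_factory=ModelConfig)
    pd_n_boot: int = 0
    compute_h: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.baseline = tuple(self.baseline)
        if len(self.baseline) != 2 or self.baseline[0] > self.baseline[1]:
            raise ValueError(f"invalid baseline year range {self.baseline}")
        if self.si_mode not in {"pooled", "leave-one-site-out"}:
            raise ValueError(
                f"si_mode must be 'pooled' or 'leave-one-site-out', got {self.si_mode!r}"
            )
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["baseline"] = list(self.baseline)
        d["model"]["learning_rates"] = list(self.model.learning_rates)
        d["model"]["tree_complexities"] = list(self.model.tree_complexities)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "model" in d and isinstance(d["model"], dict):
            m = d["model"]
            for key in ("learning_rates", "tree_complexities"):
                if key in m:
                    m[key] = tuple(m[key])
            d["model"] = ModelConfig(**m)
        return cls(**d)
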