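"""Readers and writers for the package's tabular and gridded formats.

Tabular data are plain CSV with declared headers.  Gridded data are
accepted in two equivalent dialects: a long CSV (one row per cell, with
the dimension columns spelled out) or a netCDF file with the same
dimensions; both load into identical :mod:`xarray` objects.

Charcoal input is a pair of tables:

* samples: ``site_id, lat, lon, zone, depth_top, depth_bottom, concentration``
* age controls: ``site_id, depth, age``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .core import (
    TAXA,
    AgeDepthModel,
    CharcoalRecord,
    FormatError,
    PollenAssemblage,
    SiteMeta,
    ValidationError,
)

CHARCOAL_COLUMNS = ["site_id", "lat", "lon", "zone", "depth_top", "depth_bottom", "concentration"]
AGE_CONTROL_COLUMNS = ["site_id", "depth", "age"]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_charcoal_csv(samples_path, age_controls_path) -> list[CharcoalRecord]:
    """Read charcoal records from a samples table and its companion
    age-control table; returns one record per site, samples sorted by depth.

    Malformed rows are reported with 1-based data line numbers.
    """
    samples_path, age_controls_path = Path(samples_path), Path(age_controls_path)
    df = pd.read_csv(samples_path)
    ctl = pd.read_csv(age_controls_path)
    _require_columns(df, CHARCOAL_COLUMNS, samples_path)
    _require_columns(ctl, AGE_CONTROL_COLUMNS, age_controls_path)

    bad = df[CHARCOAL_COLUMNS].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 1).tolist()
        raise FormatError(f"{samples_path}: malformed rows at data lines {lines}")

    records = []
    for site_id, g in df.groupby("site_id", sort=True):
        g = g.sort_values("depth_top")
        c = ctl[ctl["site_id"] == site_id].sort_values("depth")
        if c.empty:
            raise ValidationError(f"site {site_id}: no age-control points")
        try:
            model = AgeDepthModel(c["depth"].to_numpy(), c["age"].to_numpy())
        except ValidationError as exc:
            raise ValidationError(f"site {site_id}: {exc}") from exc
        meta = SiteMeta(
            site_id=str(site_id),
            lat=float(g["lat"].iloc[0]),
            lon=float(g["lon"].iloc[0]),
            zone=str(g["zone"].iloc[0]),
        )
        records.append(
            CharcoalRecord(
                meta=meta,
                depth_top=g["depth_top"].to_numpy(float),
                depth_bottom=g["depth_bottom"].to_numpy(float),
                concentration=g["concentration"].to_numpy(float),
                age_model=model,
            )
        )
    return records


def write_charcoal_csv(records, samples_path, age_controls_path) -> None:
    rows, ctl_rows = [], []
    for r in records:
        for i in range(r.n_samples):
            rows.append(
                {
                    "site_id": r.meta.site_id,
                    "lat": r.meta.lat,
                    "lon": r.meta.lon,
                    "zone": r.meta.zone,
                    "depth_top": r.depth_top[i],
                    "depth_bottom": r.depth_bottom[i],
                    "concentration": r.concentration[i],
                }
            )
        for d, a in zip(r.age_model.depths, r.age_model.ages):
            ctl_rows.append({"site_id": r.meta.site_id, "depth": d, "age": a})
    pd.DataFrame(rows, columns=CHARCOAL_COLUMNS).to_csv(samples_path, index=False)
    pd.DataFrame(ctl_rows, columns=AGE_CONTROL_COLUMNS).to_csv(age_controls_path, index=False)


def read_pollen_csv(path) -> list[PollenAssemblage]:
    """Read pollen assemblages: ``sample_id, lat, lon, age`` plus one
    count column per taxon; an empty ``age`` marks a modern sample."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "lat", "lon"] + list(TAXA), path)
    out = []
    for _, row in df.iterrows():
        age = None
        if "age" in df.columns and pd.notna(row.get("age")):
            age = float(row["age"])
        out.append(
            PollenAssemblage(
                sample_id=str(row["sample_id"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                age=age,
                counts={t: float(row[t]) for t in TAXA},
            )
        )
    return out


def write_pollen_csv(assemblages, path) -> None:
    rows = []
    for a in assemblages:
        row = {"sample_id": a.sample_id, "lat": a.lat, "lon": a.lon, "age": a.age}
        row.update({t: a.counts.get(t, 0.0) for t in TAXA})
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", "lat", "lon", "age"] + list(TAXA)).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Gridded data


def grid_to_long(ds: xr.Dataset) -> pd.DataFrame:
    """Flatten a Dataset to a long table (dimension columns + one column
    per data variable)."""
    return ds.to_dataframe().reset_index()


def long_to_grid(df: pd.DataFrame, dims) -> xr.Dataset:
    """Rebuild a Dataset from a long table with the given dimension columns."""
    missing = [d for d in dims if d not in df.columns]
    if missing:
        raise FormatError(f"long grid table missing dimension columns {missing}")
    return xr.Dataset.from_dataframe(df.set_index(list(dims)))


def write_grid(ds: xr.Dataset, path) -> None:
    """Write a Dataset as long CSV (``.csv``) or netCDF (``.nc``)."""
    path = Path(path)
    if path.suffix == ".csv":
        grid_to_long(ds).to_csv(path, index=False)
    elif path.suffix == ".nc":
        ds.to_netcdf(path, engine="scipy")
    else:
        raise FormatError(f"unsupported grid extension {path.suffix!r} (use .csv or .nc)")


def read_grid(path, dims) -> xr.Dataset:
    """Read a Dataset from either grid dialect; both load identically."""
    path = Path(path)
    if path.suffix == ".csv":
        return long_to_grid(pd.read_csv(path), dims)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            return ds.load()
    raise FormatError(f"unsupported grid extension {path.suffix!r} (use .csv or .nc)")


def read_biomass_grid(path) -> xr.Dataset:
    """Per-genus biomass rasters (t/ha), dims (lat, lon)."""
    ds = read_grid(path, ("lat", "lon"))
    if np.any(np.array([ds[v].values for v in ds.data_vars]) < 0):
        raise ValidationError(f"{path}: negative biomass")
    return ds


def read_population_grid(path) -> xr.Dataset:
    """Population counts per pixel, dims (time, lat, lon); time in years BP."""
    ds = read_grid(path, ("time", "lat", "lon"))
    if float(ds["population"].min()) < 0:
        raise ValidationError(f"{path}: negative population count")
    return ds


def read_climate_grid(path) -> xr.Dataset:
    """Climate anomaly cube, dims (variable, season, model, millennium, lat, lon)."""
    return read_grid(path, ("variable", "season", "model", "millennium", "lat", "lon"))


def validate_bundle(directory) -> list[str]:
    """Check the invariants of an input bundle directory; return a report
    (one line per check).  Raises nothing: problems are reported as lines
    starting with ``ERROR``."""
    directory = Path(directory)
    report: list[str] = []

    def check(name, fn):
        try:
            n = fn()
            report.append(f"OK    {name}: {n}")
        except Exception as exc:  # report, do not abort the sweep
            report.append(f"ERROR {name}: {exc}")

    charcoal = directory / "charcoal.csv"
    controls = directory / "age_controls.csv"
    if charcoal.exists() and controls.exists():
        check("charcoal records", lambda: f"{len(read_charcoal_csv(charcoal, controls))} records")
    pollen = directory / "pollen_modern.csv"
    if pollen.exists():
        check("modern pollen", lambda: f"{len(read_pollen_csv(pollen))} samples")
    fossil = directory / "pollen_fossil.csv"
    if fossil.exists():
        check("fossil pollen", lambda: f"{len(read_pollen_csv(fossil))} samples")
    biomass = directory / "biomass.csv"
    if biomass.exists():
        check("biomass grid", lambda: f"{len(read_biomass_grid(biomass).data_vars)} genera")
    pop = directory / "population.csv"
    if pop.exists():
        check("population grid", lambda: f"{read_population_grid(pop).sizes} dims")
    clim = directory / "climate.csv"
    if clim.exists():
        check("climate grid", lambda: f"{read_climate_grid(clim).sizes} dims")
    if not report:
        report.append("ERROR bundle: no recognised input files found")
    return report
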