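"""Explanatory driver series: seasonal climate anomalies around sites and
human population density in 100-km buffers.

Climate comes as millennial-mean rasters from coarse general-circulation
models; anomalies are expressed against the pre-industrial (c. AD 1750)
state — differences for temperature (degC) and percent change for
precipitation — optionally downscaled onto a finer observational
baseline by nearest-coarse-cell lookup.  Site-level values are means of
grid cells within a 100-km radius; zone-level values average over the
zone's sites.  Population density is the summed pixel count within the
100-km buffer divided by the exact buffer area pi * r^2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

from .core import SedfireError, ValidationError, haversine_within

SEASONS = {"MAM": (3, 4, 5), "JJA": (6, 7, 8)}


def seasonal_anomaly(monthly: xr.DataArray, season: str) -> xr.DataArray:
    """Cellwise mean of the three monthly rasters of a season.

    ``monthly`` must carry a ``month`` dimension with calendar month
    numbers; ``season`` is ``"MAM"`` (spring) or ``"JJA"`` (summer).
    """
    if season not in SEASONS:
        raise ValidationError(f"unknown season {season!r}; expected MAM or JJA")
    months = SEASONS[season]
    have = set(np.asarray(monthly["month"].values).tolist())
    missing = [m for m in months if m not in have]
    if missing:
        raise SedfireError(f"season {season}: missing months {missing}")
    return monthly.sel(month=list(months)).mean(dim="month")


def anomaly_vs_preindustrial(millennium: xr.DataArray, preindustrial: xr.DataArray, variable: str) -> xr.DataArray:
    """Anomaly of one millennium against the pre-industrial baseline.

    Temperature: difference in degC.  Precipitation: percent change,
    100 * (x - x0) / x0; baseline cells with x0 = 0 become missing (a
    percent change is undefined there) and are counted in a warning.
    """
    if millennium.shape != preindustrial.shape:
        raise SedfireError("millennium and pre-industrial grids are not aligned")
    if variable == "temperature":
        return millennium - preindustrial
    if variable == "precipitation":
        zero = preindustrial == 0
        n_zero = int(zero.sum())
        if n_zero:
            warnings.warn(f"{n_zero} zero-baseline cells set to missing in precipitation anomaly")
        return 100.0 * (millennium - preindustrial) / preindustrial.where(~zero)
    raise ValidationError(f"unknown variable {variable!r}")


def _nearest_tolerance(coord: np.ndarray) -> float:
    # a coarse cell covers +/- half the grid spacing around its centre
    d = np.diff(np.sort(np.asarray(coord, dtype=float)))
    return float(d.max()) / 2.0 * (1.0 + 1e-9) if d.size else np.inf


def apply_anomaly_downscale(anomaly: xr.DataArray, baseline: xr.DataArray, variable: str) -> xr.DataArray:
    """Apply a coarse anomaly field to a fine baseline grid.

    Each fine cell takes the anomaly of the coarse cell covering it
    (nearest centre); fine cells not covered by any coarse cell become
    missing.  Temperature: baseline + anomaly.  Precipitation:
    baseline * (1 + anomaly/100).
    """
    coarse = anomaly.reindex(
        lat=baseline["lat"].values, method="nearest", tolerance=_nearest_tolerance(anomaly["lat"].values)
    ).reindex(
        lon=baseline["lon"].values, method="nearest", tolerance=_nearest_tolerance(anomaly["lon"].values)
    )
    if variable == "temperature":
        return baseline + coarse
    if variable == "precipitation":
        return baseline * (1.0 + coarse / 100.0)
    raise ValidationError(f"unknown variable {variable!r}")


def _buffer_mask(field: xr.DataArray, lat: float, lon: float, radius_km: float):
    glat = np.asarray(field["lat"].values, dtype=float)
    glon = np.asarray(field["lon"].values, dtype=float)
    lat2, lon2 = np.meshgrid(glat, glon, indexing="ij")
    return haversine_within(lat, lon, lat2, lon2, radius_km)


def extract_site_climate(field: xr.DataArray, lat: float, lon: float, radius_km: float = 100.0):
    """Per-millennium mean of the fine cells within ``radius_km`` of a site.

    ``field`` has dims (millennium, lat, lon).  Returns a Series indexed
    by millennium, or None when no cell falls inside the radius.
    """
    mask = _buffer_mask(field, lat, lon, radius_km)
    if not mask.any():
        return None
    vals = field.values[:, mask]  # (millennium, cells)
    return pd.Series(np.nanmean(vals, axis=1), index=np.asarray(field["millennium"].values))


def extract_zone_climate(field: xr.DataArray, sites, radius_km: float = 100.0) -> pd.Series:
    """Zone-level climate series: mean over the zone's sites of the
    per-site 100-km buffer means.  Sites with no cell in the radius are
    skipped with a warning."""
    per_site = []
    for s in sites:
        series = extract_site_climate(field, s.lat, s.lon, radius_km)
        if series is None:
            warnings.warn(f"site {s.site_id}: no climate cells within {radius_km} km; skipped")
            continue
        per_site.append(series)
    if not per_site:
        raise SedfireError("no site in the zone has climate coverage")
    return pd.concat(per_site, axis=1).mean(axis=1)


def population_density(pop: xr.DataArray, sites, radius_km: float = 100.0) -> pd.Series:
    """Average population density (inhabitants/km^2) around a zone's sites.

    Per site and time slice, density = (sum of pixel counts within the
    radius) / (pi * r^2); the zone value is the mean over sites.  An
    empty buffer contributes density 0.
    """
    if radius_km <= 0:
        raise ValidationError("radius_km must be > 0")
    area_km2 = buffer_area_km2(radius_km)
    times = np.asarray(pop["time"].values)
    per_site = []
    for s in sites:
        mask = _buffer_mask(pop.isel(time=0), s.lat, s.lon, radius_km)
        if mask.any():
            counts = pop.values[:, mask].sum(axis=1)
        else:
            counts = np.zeros(times.size)
        per_site.append(pd.Series(counts / area_km2, index=times))
    return pd.concat(per_site, axis=1).mean(axis=1)


def buffer_area_km2(radius_km: float = 100.0) -> float:
    """Planar area of the extraction buffer, pi * r^2 (km^2)."""
    return float(np.pi * radius_km**2)


def zone_driver_table(climate_fields: dict, pop: xr.DataArray, sites_by_zone: dict, radius_km: float = 100.0) -> pd.DataFrame:
    """Assemble the long driver table.

    ``climate_fields`` maps ``(variable, season, model)`` to a DataArray
    with dims (millennium, lat, lon).  Returns columns
    (zone, variable, season, model, millennium, value); population rows
    carry season ``"annual"`` and model ``"hyde"``.
    """
    rows = []
    for zone, sites in sites_by_zone.items():
        for (variable, season, model), field in climate_fields.items():
            series = extract_zone_climate(field, sites, radius_km)
            for m, v in series.items():
                rows.append(
                    {"zone": zone, "variable": variable, "season": season, "model": model,
                     "millennium": float(m), "value": float(v)}
                )
        dens = population_density(pop, sites, radius_km)
        for t, v in dens.items():
            rows.append(
                {"zone": zone, "variable": "pop_density", "season": "annual", "model": "hyde",
                 "millennium": float(t), "value": float(v)}
            )
    return pd.DataFrame(rows)
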