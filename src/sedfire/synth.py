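"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
not the mechanics of fire or vegetation:

* charcoal: each zone has a smooth latent burning index b(t)
  (Gaussian-filtered noise) plus a linear response to the configured
  driver series on the log scale of fire intensity; per-site
  concentrations are overdispersed counts (gamma-Poisson) with a
  site-specific intensity scale, so the minmax/Box-Cox/Z-score chain has
  real work to do and zero counts occur;
* modern calibration: per-genus biomass surfaces are smooth random
  fields; pollen counts at a sample point are multinomial with expected
  proportions increasing in the biomass averaged within a genus-specific
  true source radius (the recoverable ground truth);
* fossil pollen: counts follow a prescribed per-genus biomass
  trajectory through the same pollen-production link;
* drivers: two "model" variants of one latent climate anomaly field
  plus independent noise, and a population grid growing toward present.

All randomness flows through :class:`numpy.random.Generator` (PCG64)
seeded as ``default_rng([seed, stream])`` with a fixed stream id per
generator, so a fixed seed gives bit-identical outputs and the
generators can be called independently yet see consistent latent
drivers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import (
    GENERA,
    TAXA,
    ZONES,
    AgeDepthModel,
    CharcoalRecord,
    PollenAssemblage,
    SiteMeta,
    ValidationError,
)

# fixed RNG stream ids, one per generator
_STREAM_DRIVERS = 0
_STREAM_CHARCOAL = 1
_STREAM_MODERN = 2
_STREAM_FOSSIL = 3
_STREAM_GRIDS = 4
_STREAM_PANEL = 5

#: latitude bands (deg N) of the four zones, south to north
ZONE_LAT_BANDS = {
    "temperate": (44.0, 47.0),
    "boreal_mixedwood": (47.0, 50.0),
    "boreal_conifer": (50.0, 53.0),
    "open_conifer_tundra": (53.0, 56.0),
}
ZONE_LON_BAND = (-78.0, -64.0)

CLIMATE_VARIABLES = ("T_spring", "T_summer", "P_spring", "P_summer")


@dataclass
class SynthConfig:
    """Ground-truth parameters of the synthetic study.

    ``driver_effects`` are signed effects on the log scale of fire
    intensity per standard deviation of the driver; the default injects
    a negative summer-precipitation effect and leaves every other
    driver null.
    """

    seed: int = 0
    n_sites_per_zone: int = 15
    time_span: tuple = (0.0, 8000.0)  # covers 8 full millennia, 0-7000 BP labels
    n_millennia: int = 8

    # charcoal generator
    driver_effects: dict = field(default_factory=lambda: {"P_summer": -1.0})
    gp_amplitude: float = 1.0  # sd of the smooth latent burning index
    gp_length_yr: float = 800.0  # correlation length of b(t)
    nb_dispersion: float = 0.5  # gamma shape; smaller = burstier counts
    mean_concentration: float = 20.0  # particles per cm^3 at b = 0
    site_scale_sd: float = 1.0  # lognormal sd of per-site intensity
    sed_rate_yr_per_cm: float = 20.0
    sed_rate_jitter: float = 0.3
    record_depth_cm: float = 352.0
    control_spacing_cm: float = 32.0

    # modern calibration generator
    n_modern: int = 60
    pollen_count_total: int = 300
    pollen_noise_sd: float = 0.15  # lognormal noise on expected proportions
    pollen_coeff: dict = field(default_factory=lambda: {g: 1.0 for g in GENERA})
    true_source_radius_km: dict = field(
        default_factory=lambda: {
            "Abies": 30.0, "Acer": 15.0, "Betula": 15.0,
            "Picea": 20.0, "Pinus": 120.0, "Populus": 15.0,
        }
    )
    genus_mean_biomass: dict = field(
        default_factory=lambda: {
            "Abies": 15.0, "Acer": 15.0, "Betula": 20.0,
            "Picea": 40.0, "Pinus": 30.0, "Populus": 10.0,
        }
    )
    grid_lat: tuple = (45.0, 50.0)
    grid_lon: tuple = (-75.0, -70.0)
    grid_res_deg: float = 0.05
    biomass_length_km: float = 12.0  # correlation length of biomass fields

    # fossil generator
    n_fossil_sites_per_zone: int = 3
    fossil_step_age: float = 4000.0  # conifer rise in the mixedwood zone
    fossil_sample_spacing_yr: float = 100.0

    # driver grids
    climate_res_deg: float = 0.25
    climate_spatial_sd: float = 0.2
    inter_model_sd: float = 0.1
    population_res_deg: float = 1.0 / 12.0  # 5-arcminute HYDE-like pixels
    population_growth: float = 3.0  # log growth over the whole span
    population_base_density: float = 0.02  # inhabitants/km^2 at 7000 BP

    # panel generator (attribution recovery at the study's own N)
    panel_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0 or self.gp_amplitude < 0:
            raise ValidationError("dispersion must be > 0 and amplitudes >= 0")
        if self.pollen_noise_sd < 0 or self.climate_spatial_sd < 0 or self.inter_model_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        unknown = set(self.driver_effects) - set(CLIMATE_VARIABLES) - {"pop_density", "conifer_broadleaf_ratio", "tree_biomass"}
        if unknown:
            raise ValidationError(f"unknown driver_effects keys {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        d = dict(d)
        for key in ("time_span", "grid_lat", "grid_lon"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# Latent drivers (shared across generators)


def latent_drivers(cfg: SynthConfig) -> dict:
    """Per-zone millennial driver series, standardised to zero mean and
    unit variance within each (zone, variable).

    Deterministic in ``cfg.seed``; every generator that needs the
    drivers derives them from this one stream, so charcoal records and
    climate grids embed the same truth.
    """
    rng = cfg.rng(_STREAM_DRIVERS)
    out = {}
    for zone in ZONES:
        data = {}
        for v in CLIMATE_VARIABLES:
            walk = np.cumsum(rng.normal(size=cfg.n_millennia))
            walk = gaussian_filter1d(walk, sigma=1.0, mode="nearest")
            data[v] = (walk - walk.mean()) / walk.std(ddof=0)
        data["pop_density"] = _population_trajectory(cfg, zone)
        out[zone] = pd.DataFrame(data, index=np.arange(cfg.n_millennia) * 1000.0)
    return out


def _population_trajectory(cfg: SynthConfig, zone: str) -> np.ndarray:
    # density grows monotonically toward the present; strongest in the
    # temperate zone, weakest in the tundra
    weight = {"temperate": 1.0, "boreal_mixedwood": 0.5, "boreal_conifer": 0.2, "open_conifer_tundra": 0.1}[zone]
    m = np.arange(cfg.n_millennia) * 1000.0  # years BP
    return cfg.population_base_density * weight * np.exp(cfg.population_growth * (7000.0 - m) / 7000.0)


def latent_burning_index(cfg: SynthConfig, zone: str, ages: np.ndarray, drivers: pd.DataFrame, rng) -> np.ndarray:
    """b(t): smooth stochastic curve plus the configured linear response
    to the (interpolated) driver series, on the log-intensity scale."""
    step = 10.0
    grid = np.arange(cfg.time_span[0], cfg.time_span[1] + step, step)
    noise = rng.normal(size=grid.size)
    smooth = gaussian_filter1d(noise, sigma=cfg.gp_length_yr / step, mode="nearest")
    sd = smooth.std(ddof=0)
    smooth = cfg.gp_amplitude * smooth / (sd if sd > 0 else 1.0)

    forced = np.zeros(grid.size)
    mill_centers = drivers.index.to_numpy() + 500.0
    for v, beta in cfg.driver_effects.items():
        if v not in drivers.columns or beta == 0:
            continue
        series = drivers[v].to_numpy()
        forced += beta * np.interp(grid, mill_centers, series)
    b = smooth + forced
    return np.interp(ages, grid, b)


# ---------------------------------------------------------------------------
# Charcoal records


def _site_locations(cfg: SynthConfig, rng) -> dict:
    sites = {}
    for zone in ZONES:
        lo, hi = ZONE_LAT_BANDS[zone]
        lats = rng.uniform(lo + 0.1, hi - 0.1, size=cfg.n_sites_per_zone)
        lons = rng.uniform(ZONE_LON_BAND[0] + 0.1, ZONE_LON_BAND[1] - 0.1, size=cfg.n_sites_per_zone)
        sites[zone] = list(zip(lats, lons))
    return sites


def gen_charcoal_records(cfg: SynthConfig):
    """Generate charcoal records for all zones.

    Returns ``(records, truth)``; ``truth`` holds the latent burning
    index per zone on a 10-yr grid, the driver series and the injected
    effects.
    """
    rng = cfg.rng(_STREAM_CHARCOAL)
    drivers = latent_drivers(cfg)
    locations = _site_locations(cfg, rng)
    step = 10.0
    grid_ages = np.arange(cfg.time_span[0], cfg.time_span[1] + step, step)

    records, truth_b = [], {}
    for zone in ZONES:
        b_grid = latent_burning_index(cfg, zone, grid_ages, drivers[zone], rng)
        truth_b[zone] = b_grid
        for i, (lat, lon) in enumerate(locations[zone]):
            meta = SiteMeta(site_id=f"{zone}_{i:02d}", lat=float(lat), lon=float(lon), zone=zone)
            model = _sedimentation(cfg, rng)
            top = np.arange(0.0, cfg.record_depth_cm, 1.0)
            bottom = top + 1.0
            mid_age = model.age_at_depth(0.5 * (top + bottom))
            b = np.interp(mid_age, grid_ages, b_grid)
            site_scale = float(np.exp(rng.normal(0.0, cfg.site_scale_sd)))
            mean = cfg.mean_concentration * site_scale * np.exp(b)
            lam = rng.gamma(shape=cfg.nb_dispersion, scale=mean / cfg.nb_dispersion)
            conc = rng.poisson(lam).astype(float)
            records.append(
                CharcoalRecord(meta=meta, depth_top=top, depth_bottom=bottom,
                               concentration=conc, age_model=model)
            )
    truth = {
        "ages": grid_ages,
        "burning_index": truth_b,
        "drivers": drivers,
        "driver_effects": dict(cfg.driver_effects),
    }
    return records, truth


def _sedimentation(cfg: SynthConfig, rng) -> AgeDepthModel:
    """A jittered sedimentation history spanning the configured period."""
    n_controls = int(round(cfg.record_depth_cm / cfg.control_spacing_cm)) + 1
    depths = np.linspace(0.0, cfg.record_depth_cm, n_controls)
    increments = rng.gamma(
        shape=1.0 / cfg.sed_rate_jitter**2,
        scale=cfg.sed_rate_yr_per_cm * cfg.control_spacing_cm * cfg.sed_rate_jitter**2,
        size=depths.size - 1,
    )
    ages = np.concatenate([[cfg.time_span[0] - 5.0], cfg.time_span[0] - 5.0 + np.cumsum(increments)])
    # rescale so the record spans the study period with a little overhang
    span = cfg.time_span[1] - cfg.time_span[0] + 10.0
    ages = ages[0] + (ages - ages[0]) * span / (ages[-1] - ages[0])
    return AgeDepthModel(depths=depths, ages=ages)


# ---------------------------------------------------------------------------
# Modern calibration


def _biomass_fields(cfg: SynthConfig, rng) -> xr.Dataset:
    lats = np.arange(cfg.grid_lat[0], cfg.grid_lat[1], cfg.grid_res_deg) + cfg.grid_res_deg / 2.0
    lons = np.arange(cfg.grid_lon[0], cfg.grid_lon[1], cfg.grid_res_deg) + cfg.grid_res_deg / 2.0
    km_per_cell = cfg.grid_res_deg * 111.2
    sigma_cells = cfg.biomass_length_km / km_per_cell
    data = {}
    for genus in GENERA:
        z = gaussian_filter(rng.normal(size=(lats.size, lons.size)), sigma=sigma_cells, mode="reflect")
        z = z / z.std(ddof=0)
        data[genus] = (("lat", "lon"), cfg.genus_mean_biomass[genus] * np.exp(0.6 * z - 0.18))
    return xr.Dataset(data, coords={"lat": lats, "lon": lons})


def _expected_proportions(cfg: SynthConfig, biomass_by_genus: dict, rng) -> np.ndarray:
    """Pollen-production link: expected proportions increase with the
    source-area biomass of each genus; 'other' takes a fixed weight."""
    weights = []
    for genus in GENERA:
        w = cfg.pollen_coeff.get(genus, 1.0) * biomass_by_genus[genus]
        if cfg.pollen_noise_sd > 0:
            w = w * np.exp(rng.normal(0.0, cfg.pollen_noise_sd))
        weights.append(max(w, 0.0))
    other = 0.5 * sum(cfg.genus_mean_biomass.values())
    weights.append(other)
    w = np.array(weights)
    return w / w.sum()


def gen_modern_calibration(cfg: SynthConfig):
    """Generate the modern surface-sample network and the biomass grid.

    Returns ``(assemblages, grid, truth)`` where truth records the true
    source radius per genus.
    """
    rng = cfg.rng(_STREAM_MODERN)
    grid = _biomass_fields(cfg, rng)
    from .mat import radius_average_biomass  # local import: mat depends on core only

    assemblages = []
    margin = 0.2
    for i in range(cfg.n_modern):
        lat = rng.uniform(cfg.grid_lat[0] + margin, cfg.grid_lat[1] - margin)
        lon = rng.uniform(cfg.grid_lon[0] + margin, cfg.grid_lon[1] - margin)
        biomass = {
            g: radius_average_biomass(grid, lat, lon, cfg.true_source_radius_km[g])[0][g]
            for g in GENERA
        }
        p = _expected_proportions(cfg, biomass, rng)
        counts = rng.multinomial(cfg.pollen_count_total, p)
        assemblages.append(
            PollenAssemblage(
                sample_id=f"modern_{i:03d}", lat=float(lat), lon=float(lon),
                counts={t: int(c) for t, c in zip(TAXA, counts)},
            )
        )
    truth = {"true_source_radius_km": dict(cfg.true_source_radius_km)}
    return assemblages, grid, truth


# ---------------------------------------------------------------------------
# Fossil pollen


def fossil_biomass_trajectory(cfg: SynthConfig, zone: str, ages: np.ndarray) -> pd.DataFrame:
    """Prescribed per-genus biomass (t/ha) through time for one zone.

    The boreal mixedwood zone carries the step of interest: conifer
    biomass rises (and broadleaf falls) at ``cfg.fossil_step_age``;
    other zones have stationary compositions.
    """
    base = {g: cfg.genus_mean_biomass[g] * 0.5 for g in GENERA}
    traj = {g: np.full(ages.size, base[g]) for g in GENERA}
    if zone == "boreal_mixedwood":
        before = ages >= cfg.fossil_step_age  # older than the step
        traj["Picea"] = np.where(before, 10.0, 30.0)
        traj["Abies"] = np.where(before, 5.0, 10.0)
        traj["Betula"] = np.where(before, 25.0, 12.0)
        traj["Acer"] = np.where(before, 15.0, 8.0)
    elif zone == "open_conifer_tundra":
        for g in ("Acer", "Populus"):
            traj[g] = np.full(ages.size, 0.5)
    return pd.DataFrame(traj, index=ages)


def gen_fossil_pollen(cfg: SynthConfig, charcoal_records=None):
    """Generate fossil pollen series near charcoal sites.

    Returns ``(assemblages, truth)``; truth holds the prescribed
    per-zone biomass trajectories.  When ``charcoal_records`` is given,
    fossil sites are placed next to existing charcoal sites (so the
    100-km proximity filter retains them); otherwise zone-band locations
    are drawn.
    """
    rng = cfg.rng(_STREAM_FOSSIL)
    ages = np.arange(cfg.time_span[0] + 50.0, cfg.time_span[1], cfg.fossil_sample_spacing_yr)
    by_zone = {}
    if charcoal_records is not None:
        for r in charcoal_records:
            by_zone.setdefault(r.meta.zone, []).append((r.meta.lat, r.meta.lon))

    assemblages, truth_traj = [], {}
    for zone in ZONES:
        traj = fossil_biomass_trajectory(cfg, zone, ages)
        truth_traj[zone] = traj
        for s in range(cfg.n_fossil_sites_per_zone):
            if by_zone.get(zone):
                anchor = by_zone[zone][int(rng.integers(len(by_zone[zone])))]
                lat = anchor[0] + rng.uniform(-0.3, 0.3)
                lon = anchor[1] + rng.uniform(-0.3, 0.3)
            else:
                lo, hi = ZONE_LAT_BANDS[zone]
                lat = rng.uniform(lo, hi)
                lon = rng.uniform(*ZONE_LON_BAND)
            for j, age in enumerate(ages):
                p = _expected_proportions(cfg, traj.loc[age].to_dict(), rng)
                counts = rng.multinomial(cfg.pollen_count_total, p)
                assemblages.append(
                    PollenAssemblage(
                        sample_id=f"fossil_{zone}_{s}_{j:03d}",
                        lat=float(lat), lon=float(lon), age=float(age),
                        counts={t: int(c) for t, c in zip(TAXA, counts)},
                    )
                )
    return assemblages, {"biomass_trajectory": truth_traj, "step_age": cfg.fossil_step_age}


# ---------------------------------------------------------------------------
# Driver grids


def gen_driver_grids(cfg: SynthConfig):
    """Climate anomaly cubes for two GCM-like "models" plus a population
    grid.

    Both models share one latent per-zone anomaly series (from
    :func:`latent_drivers`) and differ only by independent cellwise
    noise of sd ``inter_model_sd`` (zero noise makes them identical).
    Returns ``(climate_fields, population, truth)`` with
    ``climate_fields`` mapping (variable, season, model) to a DataArray
    of dims (millennium, lat, lon).
    """
    rng = cfg.rng(_STREAM_GRIDS)
    drivers = latent_drivers(cfg)
    lats = np.arange(44.0, 56.0, cfg.climate_res_deg) + cfg.climate_res_deg / 2.0
    lons = np.arange(ZONE_LON_BAND[0], ZONE_LON_BAND[1], cfg.climate_res_deg) + cfg.climate_res_deg / 2.0
    mill = np.arange(cfg.n_millennia) * 1000.0

    zone_of_lat = np.empty(lats.size, dtype=object)
    for zone, (lo, hi) in ZONE_LAT_BANDS.items():
        zone_of_lat[(lats >= lo) & (lats < hi)] = zone

    var_season = {
        "T_spring": ("temperature", "MAM"), "T_summer": ("temperature", "JJA"),
        "P_spring": ("precipitation", "MAM"), "P_summer": ("precipitation", "JJA"),
    }
    fields = {}
    for key, (variable, season) in var_season.items():
        latent = np.empty((mill.size, lats.size, lons.size))
        for i, zone in enumerate(zone_of_lat):
            series = drivers[zone][key].to_numpy()
            latent[:, i, :] = series[:, None]
        latent += cfg.climate_spatial_sd * rng.normal(size=latent.shape)
        for model in ("hadcm3like", "ccsm3like"):
            noisy = latent + cfg.inter_model_sd * rng.normal(size=latent.shape)
            fields[(variable, season, model)] = xr.DataArray(
                noisy, coords={"millennium": mill, "lat": lats, "lon": lons},
                dims=("millennium", "lat", "lon"), name=f"{variable}_{season}_{model}",
            )

    plats = np.arange(44.0, 56.0, cfg.population_res_deg) + cfg.population_res_deg / 2.0
    plons = np.arange(ZONE_LON_BAND[0], ZONE_LON_BAND[1], cfg.population_res_deg) + cfg.population_res_deg / 2.0
    cell_km2 = (cfg.population_res_deg * 111.2) ** 2  # nominal pixel area
    counts = np.empty((mill.size, plats.size, plons.size))
    for zone, (lo, hi) in ZONE_LAT_BANDS.items():
        band = (plats >= lo) & (plats < hi)
        dens = _population_trajectory(cfg, zone)  # inhabitants/km^2 per millennium
        counts[:, band, :] = dens[:, None, None] * cell_km2
    counts *= rng.uniform(0.5, 1.5, size=counts.shape)  # spatial heterogeneity
    population = xr.DataArray(
        counts, coords={"time": mill, "lat": plats, "lon": plons},
        dims=("time", "lat", "lon"), name="population",
    )
    return fields, population, {"drivers": drivers}


# ---------------------------------------------------------------------------
# Region x millennium panel (attribution recovery at the study's own N)


def gen_region_panel(cfg: SynthConfig):
    """Generate a complete region x millennium panel with the configured
    effects embedded.

    Biomass burning is built as the linear combination of the
    standardised driver series (coefficients ``cfg.driver_effects``)
    plus Gaussian noise of sd ``cfg.panel_noise_sd``; vegetation
    variables are independent smooth series unless given an effect.
    Returns ``(panel, truth)``.
    """
    rng = cfg.rng(_STREAM_PANEL)
    drivers = latent_drivers(cfg)
    rows = []
    for zone in ZONES:
        df = drivers[zone].copy()
        for extra in ("conifer_broadleaf_ratio", "tree_biomass"):
            walk = np.cumsum(rng.normal(size=cfg.n_millennia))
            walk = gaussian_filter1d(walk, sigma=1.0, mode="nearest")
            df[extra] = (walk - walk.mean()) / walk.std(ddof=0)
        y = cfg.panel_noise_sd * rng.normal(size=cfg.n_millennia)
        for v, beta in cfg.driver_effects.items():
            y = y + beta * df[v].to_numpy()
        df["biomass_burning"] = y
        df.insert(0, "millennium", df.index)
        df.insert(0, "region", zone)
        rows.append(df.reset_index(drop=True))
    panel = pd.concat(rows, ignore_index=True)
    return panel, {"driver_effects": dict(cfg.driver_effects), "noise_sd": cfg.panel_noise_sd}
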