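"""Core domain types, time/coordinate conventions and spherical geometry.

Conventions used throughout the package:

* Ages are calendar years BP, with "present" fixed at AD 1950; ages after
  1950 are negative.  Analyses span 0--7000 BP unless stated otherwise.
* Coordinates are decimal degrees (latitude N, longitude E).
* Distances are great-circle (haversine) distances on a sphere of radius
  6371 km; a radius test is boundary-inclusive.
* Grids are cell-centred: the distance from a site to a pixel is measured
  to the pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: The four vegetation zones of the study transect, north to south.
ZONES = (
    "open_conifer_tundra",
    "boreal_conifer",
    "boreal_mixedwood",
    "temperate",
)

#: Tree genera carried through the pollen/biomass analysis; all other
#: pollen types are lumped into ``other``.
GENERA = ("Abies", "Acer", "Betula", "Picea", "Pinus", "Populus")
TAXA = GENERA + ("other",)

CONIFERS = ("Abies", "Picea", "Pinus")
BROADLEAVES = ("Acer", "Betula", "Populus")


class SedfireError(Exception):
    """Base class for errors raised by this package."""


class FormatError(SedfireError):
    """An input file does not match the declared tabular/grid layout."""


class ValidationError(SedfireError):
    """Input data violate a domain invariant."""


class OutOfRangeError(SedfireError):
    """A query falls outside the supported domain (e.g. age-model depth)."""


class DegenerateSeriesError(SedfireError):
    """A series is constant or too short for the requested transform."""


@dataclass(frozen=True)
class SiteMeta:
    """Identity and location of one sedimentary site."""

    site_id: str
    lat: float
    lon: float
    zone: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"site {self.site_id}: lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"site {self.site_id}: lon {self.lon} outside [-180, 180]")
        if self.zone not in ZONES:
            raise ValidationError(
                f"site {self.site_id}: unknown zone {self.zone!r}; expected one of {ZONES}"
            )


@dataclass(frozen=True)
class AgeDepthModel:
    """Piecewise-linear age-depth model from dated control points.

    Depths are cm below the sediment surface and must be strictly
    increasing; ages (years BP) must strictly increase with depth.
    Extrapolation beyond the dated interval is refused.
    """

    depths: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        a = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "ages", a)
        if d.ndim != 1 or d.shape != a.shape or d.size < 2:
            raise ValidationError("age-depth model needs >=2 (depth, age) control points")
        if not np.all(np.diff(d) > 0):
            raise ValidationError("age-depth control depths must be strictly increasing")
        if not np.all(np.diff(a) > 0):
            raise ValidationError("age-depth control ages must strictly increase with depth")

    def age_at_depth(self, depth):
        """Interpolate age (years BP) at ``depth`` (cm); scalar or array."""
        depth = np.asarray(depth, dtype=float)
        if np.any(depth < self.depths[0]) or np.any(depth > self.depths[-1]):
            raise OutOfRangeError(
                f"depth outside dated interval [{self.depths[0]}, {self.depths[-1]}] cm"
            )
        out = np.interp(depth, self.depths, self.ages)
        return float(out) if out.ndim == 0 else out


@dataclass
class CharcoalRecord:
    """One site's charcoal series: contiguous depth slices with
    charcoal concentration (quantity per cm^3) and an age-depth model."""

    meta: SiteMeta
    depth_top: np.ndarray
    depth_bottom: np.ndarray
    concentration: np.ndarray
    age_model: AgeDepthModel

    def __post_init__(self) -> None:
        top = np.asarray(self.depth_top, dtype=float)
        bot = np.asarray(self.depth_bottom, dtype=float)
        conc = np.asarray(self.concentration, dtype=float)
        self.depth_top, self.depth_bottom, self.concentration = top, bot, conc
        if not (top.shape == bot.shape == conc.shape) or top.ndim != 1 or top.size == 0:
            raise ValidationError(f"site {self.meta.site_id}: malformed sample arrays")
        if np.any(conc < 0):
            raise ValidationError(f"site {self.meta.site_id}: negative charcoal concentration")
        if np.any(bot <= top):
            raise ValidationError(f"site {self.meta.site_id}: sample with depth_bottom <= depth_top")
        if np.any(top[1:] < bot[:-1]):
            raise ValidationError(f"site {self.meta.site_id}: overlapping depth intervals")

    @property
    def n_samples(self) -> int:
        return int(self.depth_top.size)


@dataclass
class PollenAssemblage:
    """A pollen count spectrum at one site/level.

    ``age`` is years BP for fossil samples and ``None`` for modern
    surface samples.  ``counts`` maps taxon -> non-negative count over
    the fixed taxon list :data:`TAXA`.
    """

    sample_id: str
    lat: float
    lon: float
    counts: dict = field(default_factory=dict)
    age: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(TAXA)
        if unknown:
            raise ValidationError(f"sample {self.sample_id}: unknown taxa {sorted(unknown)}")
        vals = np.array([float(self.counts.get(t, 0.0)) for t in TAXA])
        if np.any(vals < 0):
            raise ValidationError(f"sample {self.sample_id}: negative pollen count")
        if vals.sum() <= 0:
            raise ValidationError(f"sample {self.sample_id}: total pollen count must be > 0")

    def proportions(self) -> np.ndarray:
        """Counts normalised to proportions, in :data:`TAXA` order."""
        v = np.array([float(self.counts.get(t, 0.0)) for t in TAXA])
        return v / v.sum()


@dataclass
class CompositeSeries:
    """A regional binned/bootstrapped/smoothed curve with its CI band."""

    bin_age: np.ndarray  # bin centres, years BP
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_records: np.ndarray  # records contributing per bin
    bandwidth: float  # smoother half-width, years
    n_boot: int
    ci_level: float

    def __post_init__(self) -> None:
        ok = self.n_records > 0
        finite = ok & np.isfinite(self.mean)
        if np.any(self.ci_low[finite] > self.mean[finite] + 1e-9) or np.any(
            self.mean[finite] > self.ci_high[finite] + 1e-9
        ):
            raise ValidationError("composite CI band does not bracket the mean")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Fully vectorised; broadcasting rules apply.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_within(center_lat, center_lon, lats, lons, radius_km):
    """Boolean mask of the points within ``radius_km`` of the centre.

    The boundary is inclusive (distance == radius counts as inside).
    """
    if radius_km <= 0:
        raise ValidationError("radius_km must be > 0")
    d = haversine_km(center_lat, center_lon, lats, lons)
    return d <= radius_km
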