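"""Modern analogue technique (MAT) pollen-to-biomass transfer functions.

The calibration links modern pollen spectra to the tree biomass
surrounding each surface sample: per genus, biomass is averaged over
the grid cells within a source-area radius of the sample, and the
radius itself is chosen by maximising the leave-one-out predictive R^2
of the MAT over a candidate radius grid (pollen source areas differ
strongly between genera — wind-dispersed Pinus integrates over ~100 km
while Acer or Populus reflect quite local stands).

Prediction for a fossil assemblage is the mean biomass of its k most
similar modern spectra, similarity being measured on proportions with
the squared-chord dissimilarity (the palynological standard); k is
selected by bootstrap train/test resampling minimising the RMSEP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import (
    BROADLEAVES,
    CONIFERS,
    GENERA,
    SedfireError,
    ValidationError,
    haversine_km,
    haversine_within,
)

#: Candidate source-area radii (km) swept when calibrating a genus.
DEFAULT_RADII_KM = (1, 5, 15, 20, 30, 50, 75, 100, 120, 150)


def radius_average_biomass(grid, lat, lon, radius_km):
    """Unweighted mean biomass (t/ha) per genus over the grid cells whose
    centres lie within ``radius_km`` of the point.

    Returns ``(means, n_cells)`` where ``means`` maps genus -> mean.
    """
    if radius_km <= 0:
        raise ValidationError("radius_km must be > 0")
    glat = np.asarray(grid["lat"].values, dtype=float)
    glon = np.asarray(grid["lon"].values, dtype=float)
    lat2, lon2 = np.meshgrid(glat, glon, indexing="ij")
    mask = haversine_within(lat, lon, lat2.ravel(), lon2.ravel(), radius_km)
    n = int(mask.sum())
    if n == 0:
        raise SedfireError(f"no grid cells within {radius_km} km of ({lat}, {lon})")
    means = {}
    for genus in grid.data_vars:
        means[str(genus)] = float(grid[genus].values.ravel()[mask].mean())
    return means, n


def squared_chord_dissimilarity(p, q):
    """Squared-chord distance sum_t (sqrt(p_t) - sqrt(q_t))^2 between two
    proportion vectors on the same taxon list."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("proportion vectors must share one taxon list")
    return float(((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


def dissimilarity_matrix(P, Q, metric="squared_chord"):
    """Pairwise dissimilarities between the rows of two proportion matrices."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape[1] != Q.shape[1]:
        raise ValidationError("proportion matrices must share one taxon list")
    if metric == "squared_chord":
        return cdist(np.sqrt(P), np.sqrt(Q), metric="sqeuclidean")
    if metric == "euclidean_sqrt":
        return cdist(np.sqrt(P), np.sqrt(Q), metric="euclidean")
    if metric == "bray_curtis":
        return cdist(P, Q, metric="braycurtis")
    raise ValidationError(f"unknown dissimilarity metric {metric!r}")


@dataclass
class CalibrationSet:
    """Modern pollen proportions paired with radius-averaged biomass."""

    sample_ids: list
    proportions: np.ndarray  # n x taxa
    biomass: pd.DataFrame  # n x genus, t/ha
    radius_used_km: dict  # genus -> km

    def __post_init__(self) -> None:
        s = self.proportions.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValidationError("calibration proportions must sum to 1")
        if (self.biomass.to_numpy() < 0).any():
            raise ValidationError("calibration biomass must be >= 0")

    @property
    def n(self) -> int:
        return self.proportions.shape[0]


@dataclass
class TransferFunction:
    """A fitted per-genus MAT transfer function."""

    genus: str
    k: int
    metric: str
    train_proportions: np.ndarray
    train_biomass: np.ndarray
    rmsep: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        n = self.train_proportions.shape[0]
        if not 1 <= self.k <= n:
            raise ValidationError(f"k={self.k} outside [1, {n}]")


def _knn_mean(dist_row, y, k):
    # stable sort: ties at the k-th rank resolved by training sample order
    order = np.argsort(dist_row, kind="stable")[:k]
    return float(y[order].mean())


def mat_predict(tf: TransferFunction, proportions):
    """Predict biomass for one assemblage (proportion vector) or a matrix
    of assemblages: mean biomass of the k nearest training spectra."""
    P = np.atleast_2d(np.asarray(proportions, dtype=float))
    D = dissimilarity_matrix(P, tf.train_proportions, tf.metric)
    out = np.array([_knn_mean(row, tf.train_biomass, tf.k) for row in D])
    return float(out[0]) if np.asarray(proportions).ndim == 1 else out


def loo_predictions(P, y, k, metric="squared_chord"):
    """Leave-one-out MAT predictions over a calibration matrix."""
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 1 <= k <= P.shape[0] - 1:
        raise ValidationError(f"k={k} outside [1, n-1]")
    D = dissimilarity_matrix(P, P, metric)
    np.fill_diagonal(D, np.inf)
    return np.array([_knn_mean(row, y, k) for row in D])


def predictive_r2(obs, pred):
    """1 - SSE/SST of cross-validated predictions against observations."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = ((obs - obs.mean()) ** 2).sum()
    if sst == 0:
        raise SedfireError("predictive R^2 undefined: observed biomass is constant")
    return float(1.0 - ((obs - pred) ** 2).sum() / sst)


def optimize_radius(grid, modern, radii, genus, k=5, metric="squared_chord"):
    """Choose the source-area radius maximising leave-one-out predictive
    R^2 for one genus.

    Returns ``(best_radius_km, table)`` where ``table`` is a DataFrame
    with one row per candidate radius and its R^2.  Ties go to the
    smaller radius.  A radius that cannot be evaluated (no grid cell
    within it for some sample — possible when the grid is coarser than
    the smallest candidate) is kept in the table with R^2 = NaN and a
    warning.
    """
    import warnings

    radii = list(radii)
    if not radii:
        raise ValidationError("need at least one candidate radius")
    if len(modern) < 20:
        raise ValidationError("radius optimisation needs >= 20 modern samples")
    P = np.array([a.proportions() for a in modern])
    rows = []
    for r in sorted(radii):
        try:
            y = np.array([radius_average_biomass(grid, a.lat, a.lon, r)[0][genus] for a in modern])
            r2 = predictive_r2(y, loo_predictions(P, y, k, metric))
        except SedfireError as exc:
            warnings.warn(f"radius {r} km skipped for {genus}: {exc}")
            r2 = np.nan
        rows.append({"radius_km": r, "r2": r2})
    table = pd.DataFrame(rows)
    if table["r2"].isna().all():
        raise SedfireError(f"predictive R^2 undefined at every candidate radius for {genus}")
    best = float(table.loc[table["r2"].idxmax(), "radius_km"])
    return best, table


def build_calibration(grid, modern, radius_km_per_genus) -> CalibrationSet:
    """Assemble the calibration set given a chosen radius per genus."""
    P = np.array([a.proportions() for a in modern])
    biomass = {}
    for genus in GENERA:
        r = radius_km_per_genus[genus]
        biomass[genus] = [radius_average_biomass(grid, a.lat, a.lon, r)[0][genus] for a in modern]
    return CalibrationSet(
        sample_ids=[a.sample_id for a in modern],
        proportions=P,
        biomass=pd.DataFrame(biomass, index=[a.sample_id for a in modern]),
        radius_used_km=dict(radius_km_per_genus),
    )


def rmsep(pred, obs):
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    return float(np.sqrt(((pred - obs) ** 2).mean()))


def select_k(P, y, k_candidates, n_boot=100, metric="squared_chord", rng=None):
    """Select k by bootstrap train/test splitting.

    Each of ``n_boot`` replicates resamples the calibration with
    replacement as the training set and predicts the out-of-bag samples;
    RMSEP_k pools the squared errors over all replicates.  A replicate
    with an empty out-of-bag set is redrawn.  Returns
    ``(best_k, rmsep_table)``; ties go to the smaller k.
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    n = P.shape[0]
    ks = sorted(set(int(k) for k in k_candidates))
    if not all(1 <= k <= n - 1 for k in ks):
        raise ValidationError(f"k candidates must lie in [1, {n - 1}]")
    rng = np.random.default_rng() if rng is None else rng
    sq_errors = {k: [] for k in ks}
    b = 0
    while b < n_boot:
        pick = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), pick)
        if oob.size == 0:
            continue  # redrawn
        D = dissimilarity_matrix(P[oob], P[pick], metric)
        for k in ks:
            if k > pick.size:
                continue
            pred = np.array([_knn_mean(row, y[pick], k) for row in D])
            sq_errors[k].extend(((pred - y[oob]) ** 2).tolist())
        b += 1
    table = pd.DataFrame(
        {"k": ks, "rmsep": [float(np.sqrt(np.mean(sq_errors[k]))) for k in ks]}
    )
    best = int(table.loc[table["rmsep"].idxmin(), "k"])
    return best, table


def fit_transfer_functions(calibration: CalibrationSet, k_candidates=(1, 2, 3, 5, 8), n_boot=100, metric="squared_chord", rng=None):
    """Fit one MAT transfer function per genus, with bootstrap k selection
    and leave-one-out performance statistics."""
    rng = np.random.default_rng() if rng is None else rng
    tfs = {}
    for genus in calibration.biomass.columns:
        y = calibration.biomass[genus].to_numpy()
        k, _table = select_k(calibration.proportions, y, k_candidates, n_boot=n_boot, metric=metric, rng=rng)
        pred = loo_predictions(calibration.proportions, y, k, metric)
        tfs[genus] = TransferFunction(
            genus=genus,
            k=k,
            metric=metric,
            train_proportions=calibration.proportions,
            train_biomass=y,
            rmsep=rmsep(pred, y),
            r2=predictive_r2(y, pred),
        )
    return tfs


def filter_fossil_sites(fossil, charcoal_records, max_km=100.0):
    """Keep fossil assemblages within ``max_km`` of at least one charcoal
    site; each retained assemblage is tagged with the zone of its nearest
    charcoal site.  Returns a list of ``(assemblage, zone)`` pairs."""
    site_lat = np.array([r.meta.lat for r in charcoal_records])
    site_lon = np.array([r.meta.lon for r in charcoal_records])
    zones = [r.meta.zone for r in charcoal_records]
    out = []
    for a in fossil:
        d = haversine_km(a.lat, a.lon, site_lat, site_lon)
        j = int(np.argmin(d))
        if d[j] <= max_km:
            out.append((a, zones[j]))
    return out


def reconstruct_biomass(tfs, fossil, charcoal_records, max_km=100.0) -> pd.DataFrame:
    """Apply the transfer functions to fossil assemblages near charcoal
    sites.

    Returns a long DataFrame (sample_id, zone, lat, lon, age, one column
    per genus with predicted biomass in t/ha).  Zones with no qualifying
    fossil site are simply absent from the result.
    """
    kept = filter_fossil_sites(fossil, charcoal_records, max_km=max_km)
    rows = []
    for a, zone in kept:
        row = {"sample_id": a.sample_id, "zone": zone, "lat": a.lat, "lon": a.lon, "age": a.age}
        p = a.proportions()
        for genus, tf in tfs.items():
            row[genus] = mat_predict(tf, p)
        rows.append(row)
    return pd.DataFrame(rows)


def conifer_broadleaf_ratio(biomass: pd.DataFrame, denominator_floor=0.1, mean_span=(0.0, 7000.0)) -> pd.DataFrame:
    """Conifer vs broadleaf biomass ratio through time.

    ``biomass`` has an age index (years BP) and per-genus columns.  The
    ratio is the summed conifer biomass (Abies, Picea, Pinus) over the
    summed broadleaf biomass (Acer, Betula, Populus); denominators below
    ``denominator_floor`` t/ha are raised to the floor and the step
    flagged ``capped``.  ``above_mean`` flags steps where the ratio
    exceeds its long-term (0-7000 BP) average.  Steps where both sums
    are zero are missing.
    """
    con = biomass[[g for g in CONIFERS if g in biomass.columns]].sum(axis=1)
    brd = biomass[[g for g in BROADLEAVES if g in biomass.columns]].sum(axis=1)
    capped = brd < denominator_floor
    denom = brd.clip(lower=denominator_floor)
    ratio = con / denom
    ratio[(con == 0) & (brd == 0)] = np.nan
    in_span = (biomass.index >= mean_span[0]) & (biomass.index <= mean_span[1])
    long_term = ratio[in_span].mean()
    return pd.DataFrame(
        {
            "ratio": ratio,
            "above_mean": ratio > long_term,
            "capped": capped,
            "long_term_mean": long_term,
        }
    )
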