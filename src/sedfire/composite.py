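"""Charcoal standardization and regional bootstrap compositing.

A single charcoal record is turned into a comparable index in four
steps: concentrations are converted to charcoal accumulation rates
(CHAR, quantity cm^-2 yr^-1) using the record's age-depth model; CHAR is
minmax-rescaled to [0, 1]; a Box-Cox transform (with a small offset
``epsilon`` because minmax maps the minimum to exactly 0) homogenises
the within-record variance, with the exponent ``lambda`` fitted per
record by grid maximum likelihood; and a Z-score standardisation puts
records on a common dimensionless scale.  Regional curves are then
built by binning each transformed record into non-overlapping 10-yr
bins, bootstrap-resampling the *sites* 999 times, smoothing each pooled
draw with a fixed-bandwidth tricube local-linear smoother, and taking
the across-draw mean and percentile confidence band.

The same binning/bootstrap/smoothing machinery is reused for
reconstructed tree-biomass series (without the CHAR standardisation),
via :func:`composite_from_series`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CompositeSeries, DegenerateSeriesError, ValidationError


@dataclass(frozen=True)
class TransformParams:
    """Tunable parameters of the standardisation/compositing chain."""

    minmax_epsilon: float = 0.01
    boxcox_lambda_min: float = -2.0
    boxcox_lambda_max: float = 2.0
    boxcox_lambda_step: float = 0.01
    bin_width: float = 10.0  # yr
    n_boot: int = 999
    bandwidths: tuple = (500.0, 200.0)  # smoother half-widths, yr
    ci_level: float = 0.90

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.minmax_epsilon < 0:
            raise ValidationError("minmax_epsilon must be >= 0")


def compute_char(record):
    """Charcoal accumulation rate per sample.

    CHAR_i = concentration_i * thickness_i / (age(bottom_i) - age(top_i)),
    i.e. concentration times sediment accumulation rate.  Sample age is
    the midpoint age of the slice.

    Returns ``(ages, char)`` arrays.
    """
    age_top = record.age_model.age_at_depth(record.depth_top)
    age_bot = record.age_model.age_at_depth(record.depth_bottom)
    duration = age_bot - age_top
    if np.any(duration <= 0):
        i = int(np.argmax(duration <= 0))
        raise ValidationError(
            f"site {record.meta.site_id}: sample {i} "
            f"({record.depth_top[i]}-{record.depth_bottom[i]} cm) has zero duration"
        )
    thickness = record.depth_bottom - record.depth_top
    char = record.concentration * thickness / duration
    ages = 0.5 * (age_top + age_bot)
    return ages, char


def minmax_rescale(values):
    """Rescale to [0, 1] as (x - min) / (max - min)."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSeriesError("constant series cannot be minmax-rescaled")
    return (x - lo) / (hi - lo)


def boxcox_loglik(lam, x):
    """Box-Cox profile log-likelihood of exponent ``lam`` for data ``x > 0``."""
    return stats.boxcox_llf(lam, np.asarray(x, dtype=float))


def boxcox_transform(values, params: TransformParams = TransformParams(), lam=None):
    """Box-Cox transform of values in [0, 1] after adding ``epsilon``.

    y = ((x + eps)^lam - 1) / lam for lam != 0, log(x + eps) for lam = 0.
    When ``lam`` is None the exponent is chosen per series by maximising
    the Box-Cox log-likelihood over the configured grid.

    Returns ``(transformed, lam)``.
    """
    x = np.asarray(values, dtype=float) + params.minmax_epsilon
    if np.any(x <= 0):
        raise ValidationError("Box-Cox input must be positive after the epsilon offset")
    if lam is None:
        grid = np.arange(
            params.boxcox_lambda_min,
            params.boxcox_lambda_max + 0.5 * params.boxcox_lambda_step,
            params.boxcox_lambda_step,
        )
        # profile log-likelihood, vectorised over the lambda grid:
        # (lam - 1) sum(log x) - n/2 log(var(y_lam))
        logx = np.log(x)
        n = x.size
        with np.errstate(divide="ignore", invalid="ignore"):
            Y = np.where(
                np.abs(grid[:, None]) > 1e-12,
                (np.exp(np.outer(grid, logx)) - 1.0) / np.where(np.abs(grid) > 1e-12, grid, 1.0)[:, None],
                logx[None, :],
            )
        var = Y.var(axis=1)
        ll = (grid - 1.0) * logx.sum() - 0.5 * n * np.log(var)
        lam = float(grid[int(np.argmax(ll))])
    if lam == 0.0:
        return np.log(x), 0.0
    return (x**lam - 1.0) / lam, float(lam)


def zscore(values):
    """Standardise to zero mean, unit sample standard deviation (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateSeriesError("constant or too-short series cannot be Z-scored")
    return (x - x.mean()) / x.std(ddof=1)


def standardize_char(char_values, params: TransformParams = TransformParams()):
    """Full within-record chain: minmax -> Box-Cox (grid MLE) -> Z-score."""
    y, _lam = boxcox_transform(minmax_rescale(char_values), params)
    return zscore(y)


def bin_series(ages, values, bin_width):
    """Average values into non-overlapping age bins.

    Bin ``b`` covers ages in [b*w, (b+1)*w); bins are indexed by
    floor(age / w), so negative (post-1950) ages are allowed.  Empty
    bins carry no value.

    Returns ``(bin_index, bin_mean)`` with bin_index sorted ascending.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    idx = np.floor(ages / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    idx, values = idx[order], values[order]
    uniq, start = np.unique(idx, return_index=True)
    sums = np.add.reduceat(values, start)
    counts = np.add.reduceat(np.ones_like(values), start)
    return uniq, sums / counts


def bin_centers(bin_index, bin_width):
    """Centre age of each bin."""
    return (np.asarray(bin_index, dtype=float) + 0.5) * bin_width


def _tricube_weights(eval_x, x, half_width):
    u = np.abs(eval_x[:, None] - x[None, :]) / half_width
    return np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)


def lowess_smooth_many(x, Y, half_width, eval_x=None):
    """Fixed-bandwidth tricube local-linear smoothing of many series
    sharing one abscissa.

    ``Y`` is (n_series, n_points) and may hold NaN for missing points
    (missingness may differ between series).  For each evaluation point
    ``t`` a weighted linear fit is computed over the window [t-h, t+h];
    windows holding fewer than 3 points (or with degenerate spread)
    yield NaN, so gaps propagate instead of being invented.  The
    computation is cast as a handful of matrix products so bootstrap
    ensembles smooth in one call.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    eval_x = x if eval_x is None else np.asarray(eval_x, dtype=float)
    if half_width <= 0:
        raise ValidationError("half_width must be > 0")

    W = _tricube_weights(eval_x, x, half_width)  # (J, B)
    Wt = W.T
    M = np.isfinite(Y).astype(float)  # (n, B)
    Y0 = np.where(M > 0, Y, 0.0)

    t = eval_x[None, :]
    S0 = M @ Wt
    WX = (M * x) @ Wt
    WX2 = (M * x**2) @ Wt
    WY = Y0 @ Wt
    WXY = (Y0 * x) @ Wt
    n_in = M @ (Wt > 0)

    # local coordinates centred at each evaluation point
    s1 = WX - t * S0
    s2 = WX2 - 2.0 * t * WX + t**2 * S0
    t1 = WXY - t * WY
    denom = S0 * s2 - s1**2

    out = np.full(S0.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        fit = (s2 * WY - s1 * t1) / denom
        flat_fit = WY / S0
    ok = (n_in >= 3) & (np.abs(denom) > 1e-12 * np.maximum(S0 * s2, 1e-300))
    out[ok] = fit[ok]
    # degenerate spread (all window points at one x): weighted mean
    flat = (n_in >= 3) & ~ok & (S0 > 0)
    out[flat] = flat_fit[flat]
    return out


def lowess_smooth(x, y, half_width, eval_x=None):
    """Fixed-bandwidth locally weighted (tricube, local linear) smoother
    of one series; see :func:`lowess_smooth_many`."""
    return lowess_smooth_many(x, np.asarray(y, dtype=float)[None, :], half_width, eval_x)[0]


def _binned_matrix(series_list, params):
    """Bin each (ages, values) series onto a common bin grid.

    Returns (bin_index grid, sums R x B, counts R x B).
    """
    binned = [bin_series(a, v, params.bin_width) for a, v in series_list]
    lo = min(int(b[0][0]) for b in binned)
    hi = max(int(b[0][-1]) for b in binned)
    grid = np.arange(lo, hi + 1)
    n = len(binned)
    sums = np.zeros((n, grid.size))
    counts = np.zeros((n, grid.size))
    for r, (idx, mean) in enumerate(binned):
        pos = idx - lo
        sums[r, pos] = mean
        counts[r, pos] = 1.0
    return grid, sums, counts


def _pooled(sums, counts, multiplicity):
    """Pooled per-bin mean over a multiset of records."""
    m = np.asarray(multiplicity, dtype=float)
    num = m @ sums
    den = m @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = num / den
    pooled[den == 0] = np.nan
    return pooled


def composite_from_series(
    series_list,
    params: TransformParams = TransformParams(),
    bandwidth: float | None = None,
    rng: np.random.Generator | None = None,
) -> CompositeSeries:
    """Site-bootstrap composite of already-standardised (ages, values)
    series.

    For each of ``n_boot`` draws the sites are resampled with
    replacement, their binned values pooled (per-bin mean over the
    resampled multiset) and smoothed; the composite mean is the
    across-draw mean at each bin and the confidence band the percentile
    interval over draws.
    """
    if len(series_list) < 2:
        raise ValidationError("compositing needs >= 2 records")
    if bandwidth is None:
        bandwidth = params.bandwidths[0]
    rng = np.random.default_rng() if rng is None else rng

    grid, sums, counts = _binned_matrix(series_list, params)
    ages = bin_centers(grid, params.bin_width)
    n = len(series_list)

    # site multiplicities of each resample-with-replacement draw
    mult = rng.multinomial(n, np.full(n, 1.0 / n), size=params.n_boot)
    num = mult @ sums
    den = mult @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(den > 0, num / den, np.nan)
    draws = lowess_smooth_many(ages, pooled, bandwidth, eval_x=ages)

    alpha = (1.0 - params.ci_level) / 2.0
    with np.errstate(invalid="ignore"):
        any_finite = np.isfinite(draws).any(axis=0)
        mean = np.where(any_finite, np.nanmean(np.where(np.isfinite(draws), draws, np.nan), axis=0), np.nan)
        lo_q = np.full(grid.size, np.nan)
        hi_q = np.full(grid.size, np.nan)
        lo_q[any_finite] = np.nanpercentile(draws[:, any_finite], 100.0 * alpha, axis=0)
        hi_q[any_finite] = np.nanpercentile(draws[:, any_finite], 100.0 * (1.0 - alpha), axis=0)
    return CompositeSeries(
        bin_age=ages,
        mean=mean,
        ci_low=np.minimum(lo_q, mean),
        ci_high=np.maximum(hi_q, mean),
        n_records=counts.sum(axis=0).astype(int),
        bandwidth=float(bandwidth),
        n_boot=params.n_boot,
        ci_level=params.ci_level,
    )


def transform_record(record, params: TransformParams = TransformParams()):
    """CHAR -> minmax -> Box-Cox -> Z-score for one record; returns
    ``(ages, standardized)``."""
    ages, char = compute_char(record)
    return ages, standardize_char(char, params)


def composite_bootstrap(
    records,
    params: TransformParams = TransformParams(),
    bandwidth: float | None = None,
    rng: np.random.Generator | None = None,
) -> CompositeSeries:
    """Regional biomass-burning composite from raw charcoal records.

    Records whose CHAR series is constant (not standardisable) are
    excluded; at least two usable records are required.
    """
    series = []
    for r in records:
        try:
            series.append(transform_record(r, params))
        except DegenerateSeriesError:
            continue  # excluded, as a constant record carries no signal
    return composite_from_series(series, params, bandwidth=bandwidth, rng=rng)
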