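"""Millennial-scale driver attribution of biomass burning.

All series are downsampled to the millennial resolution of the climate
records and stacked into one region x millennium panel (4 regions x 8
millennia = 32 rows), centred to zero mean within each region.  The
unique contribution of each candidate driver is measured by the
semipartial Spearman rank correlation: the correlation between biomass
burning and the focal driver after the influence of the remaining
drivers has been removed from the focal driver only (not from the
response).  Significance uses the usual t approximation with
n - 2 - g degrees of freedom for g covariates.  The functional form of
a significant relationship is explored with a one-component partial
least squares (PLS) regression on the centred panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .core import SedfireError, ValidationError

#: Panel columns tested for their unique contribution (response is
#: ``biomass_burning``).
DRIVER_VARIABLES = (
    "conifer_broadleaf_ratio",
    "tree_biomass",
    "pop_density",
    "T_spring",
    "T_summer",
    "P_spring",
    "P_summer",
)


@dataclass(frozen=True)
class SemipartialResult:
    variable: str
    sr: float
    p_value: float
    n: int
    n_covariates: int
    model: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.sr <= 1.0 + 1e-12:
            raise ValidationError("semipartial correlation outside [-1, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def downsample_millennial(ages, values, n_millennia=8, millennium_width=1000.0):
    """Average a finer series onto millennial steps.

    Millennium m (m = 0, 1000, ...) holds the mean of the values whose
    age lies in [m, m + 1000); empty millennia are missing (NaN).
    Returns a Series indexed by millennium start (years BP).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    starts = np.arange(n_millennia) * millennium_width
    out = np.full(n_millennia, np.nan)
    for i, m in enumerate(starts):
        sel = (ages >= m) & (ages < m + millennium_width) & np.isfinite(values)
        if sel.any():
            out[i] = values[sel].mean()
    return pd.Series(out, index=starts)


def assemble_panel(series_by_region: dict) -> pd.DataFrame:
    """Stack per-region variable -> millennial Series mappings into the
    long panel (region, millennium, one column per variable)."""
    frames = []
    for region, mapping in series_by_region.items():
        df = pd.DataFrame(mapping)
        df.insert(0, "millennium", df.index)
        df.insert(0, "region", region)
        frames.append(df.reset_index(drop=True))
    panel = pd.concat(frames, ignore_index=True)
    return panel


def check_panel(panel: pd.DataFrame, columns=None) -> None:
    cols = [c for c in panel.columns if c not in ("region", "millennium")] if columns is None else columns
    bad = panel[cols].isna()
    if bad.to_numpy().any():
        cells = [
            f"({panel.loc[i, 'region']}, {panel.loc[i, 'millennium']}, {c})"
            for i in panel.index
            for c in cols
            if bad.loc[i, c]
        ]
        raise ValidationError(f"panel has missing cells: {', '.join(cells)}")


def center_by_region(panel: pd.DataFrame) -> pd.DataFrame:
    """Subtract the within-region mean from every variable column (the
    variance is deliberately left unscaled)."""
    out = panel.copy()
    cols = [c for c in panel.columns if c not in ("region", "millennium")]
    out[cols] = panel.groupby("region")[cols].transform(lambda s: s - s.mean())
    return out


def semipartial_spearman(y, x, Z=None, variable="", model="") -> SemipartialResult:
    """Semipartial Spearman rank correlation of y with x given covariates Z.

    All columns are rank-transformed (average ranks on ties); rank(x) is
    residualised on rank(Z) (with intercept) by least squares, and sr is
    the Pearson correlation of rank(y) with those residuals.  The
    covariates are removed from x only.  The p-value is the two-sided
    t-test of the unique contribution of x in the rank regression of y
    on (x, Z): t = sr * sqrt(n - 2 - g) / sqrt(1 - R2_full) with
    n - 2 - g degrees of freedom, where R2_full is the full-model R^2 on
    ranks.  (With no covariates this reduces to the usual Spearman
    t-test.)
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z = np.empty((y.size, 0)) if Z is None else np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != y.size:
        Z = Z.T
    n, g = y.size, Z.shape[1]
    if n <= g + 2:
        raise ValidationError(f"need n > n_covariates + 2 (n={n}, g={g})")
    if np.isnan(y).any() or np.isnan(x).any() or np.isnan(Z).any():
        raise ValidationError("missing values in correlation input")

    ry = stats.rankdata(y)
    rx = stats.rankdata(x)
    if np.ptp(ry) == 0:
        raise SedfireError("response is constant after ranking")
    if np.ptp(rx) == 0:
        raise SedfireError(f"variable {variable or 'x'} is constant after ranking")
    rZ = np.column_stack([stats.rankdata(Z[:, j]) for j in range(g)]) if g else np.empty((n, 0))

    design = np.column_stack([np.ones(n), rZ])
    beta, *_ = np.linalg.lstsq(design, rx, rcond=None)
    resid = rx - design @ beta
    if np.allclose(resid, 0):
        raise SedfireError(f"variable {variable or 'x'} is fully explained by the covariates")
    ry_c = ry - ry.mean()
    sr = float(ry_c @ resid / np.sqrt((ry_c @ ry_c) * (resid @ resid)))
    sr = float(np.clip(sr, -1.0, 1.0))

    df = n - 2 - g
    full = np.column_stack([np.ones(n), rx, rZ])
    coef, *_ = np.linalg.lstsq(full, ry, rcond=None)
    res_y = ry - full @ coef
    r2_full = 1.0 - (res_y @ res_y) / (ry_c @ ry_c)
    if abs(sr) >= 1.0 or r2_full >= 1.0:
        p = 0.0
    else:
        t = sr * np.sqrt(df) / np.sqrt(1.0 - r2_full)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return SemipartialResult(variable=variable, sr=sr, p_value=p, n=n, n_covariates=g, model=model)


def run_attribution(panel: pd.DataFrame, variables=DRIVER_VARIABLES, response="biomass_burning", model="") -> pd.DataFrame:
    """Test every driver for its unique contribution to biomass burning.

    Iterative substitution: each variable in turn is the focal driver,
    all remaining ones the covariates removed from it.  The panel must
    be complete (no missing cells) and is centred by region here.
    Returns one row per variable: (variable, model, sr, p_value, n,
    significant), significance at p < 0.05 without multiple-testing
    correction.
    """
    cols = [response] + list(variables)
    check_panel(panel, cols)
    centered = center_by_region(panel)
    rows = []
    for v in variables:
        others = [u for u in variables if u != v]
        res = semipartial_spearman(
            centered[response].to_numpy(),
            centered[v].to_numpy(),
            centered[others].to_numpy(),
            variable=v,
            model=model,
        )
        rows.append(
            {"variable": v, "model": model, "sr": res.sr, "p_value": res.p_value,
             "n": res.n, "significant": res.significant}
        )
    return pd.DataFrame(rows)


def holm_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Optional Holm step-down adjustment of an attribution table (off by
    default in :func:`run_attribution`, which reports raw p-values)."""
    out = table.copy()
    p = out["p_value"].to_numpy()
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    out["p_holm"] = adj
    out["significant"] = out["p_holm"] < 0.05
    return out


def pls_functional_form(y, x):
    """One-component PLS regression of biomass burning on one forcing.

    Predictor and response are centred (not scaled), matching the
    zero-mean panel normalisation.  Returns a dict with the fitted
    slope, per-point fitted values, scores and x-loading, for plotting
    the functional form.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    X = np.asarray(x, dtype=float)
    X = X.reshape(-1, 1) if X.ndim == 1 else X
    if np.any(np.ptp(X, axis=0) == 0):
        raise SedfireError("zero-variance predictor in PLS")
    pls = PLSRegression(n_components=1, scale=False)
    pls.fit(X, y)
    fitted = pls.predict(X).ravel()
    slope = float(pls.coef_.ravel()[0]) if X.shape[1] == 1 else None
    return {
        "slope": slope,
        "coef": pls.coef_.ravel(),
        "fitted": fitted,
        "scores": pls.x_scores_.ravel(),
        "x_loading": pls.x_loadings_.ravel(),
        "r2": float(pls.score(X, y)),
    }
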