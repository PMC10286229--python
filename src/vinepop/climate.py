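"""Viticultural bioclimatic indices and the environmental PCA.

All indices operate on monthly climate normals per site (tmean/tmin/
tmax in degC, precipitation and potential evapotranspiration in mm) and
follow the standard viticultural zoning definitions: growing-season
temperature and rainfall windows, the Branas hydrothermal product, the
frost/heat risk months, the Huglin heliothermal index with its
latitude-dependent day-length coefficient, the cool-night index, and
the Riou-type soil-water-balance dryness index.  Monthly values are
expanded to days by replication, matching the effective resolution of
gridded monthly climate products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: index columns, longer-window members listed first in each pair
INDEX_COLUMNS = ["GST", "GST49", "GSR", "GSR49", "RRSPR", "HYB",
                 "WFR", "SFR", "HST", "CI", "HI", "DI"]

#: when a pair is near-collinear, drop the full-season member and keep
#: the Apr-Sep ("49") variant
DROP_PREFERENCE = ["GST", "GSR"]


def _series(site_df: pd.DataFrame, col: str, months) -> np.ndarray:
    """Monthly values for 1-based ``months``, erroring on absent months."""
    s = site_df.set_index("month")[col]
    missing = [m for m in months if m not in s.index]
    if missing:
        raise ValueError(f"missing months {missing} in climate series")
    return s.loc[list(months)].to_numpy(dtype=float)


def gst(site_df: pd.DataFrame, months=range(4, 11)) -> float:
    """Day-weighted mean of monthly tmean over the window (GST Apr-Oct)."""
    months = list(months)
    t = _series(site_df, "tmean", months)
    w = MONTH_DAYS[np.array(months) - 1]
    return float(np.sum(t * w) / w.sum())


def gst49(site_df: pd.DataFrame) -> float:
    """GST over the vegetative window Apr-Sep."""
    return gst(site_df, months=range(4, 10))


def gsr(site_df: pd.DataFrame, months=range(4, 11)) -> float:
    """Cumulative rainfall (mm) over the window (GSR Apr-Oct)."""
    p = _series(site_df, "precip", list(months))
    if (p < 0).any():
        raise ValueError("negative precipitation")
    return float(p.sum())


def gsr49(site_df: pd.DataFrame) -> float:
    return gsr(site_df, months=range(4, 10))


def rrspr(site_df: pd.DataFrame) -> float:
    """Springtime rainfall, Apr-Jul."""
    return gsr(site_df, months=range(4, 8))


def hyb(site_df: pd.DataFrame, months=range(4, 9)) -> float:
    """Branas hydrothermal index: sum of tmean x precip over Apr-Aug."""
    months = list(months)
    t = _series(site_df, "tmean", months)
    p = _series(site_df, "precip", months)
    return float(np.sum(t * p))


@dataclass
class FrostHeat:
    """Monthly risk indices with their classification bands."""

    wfr: float   # mean minimum temperature, January
    sfr: float   # mean minimum temperature, April
    hst: float   # mean maximum temperature, July
    ci: float    # mean minimum temperature, September
    wfr_band: str = ""
    sfr_band: str = ""
    hst_band: str = ""
    ci_band: str = ""


def classify_wfr(x: float) -> str:
    return "low" if x > 4 else ("high" if x < -11 else "moderate")


def classify_sfr(x: float) -> str:
    return "low" if x > 12 else ("high" if x < 0 else "moderate")


def classify_hst(x: float) -> str:
    return "low" if x < 25 else ("high" if x > 30 else "moderate")


def classify_ci(x: float) -> str:
    if x > 18:
        return "warm nighttime (>18)"
    if x >= 14:
        return "temperate nights (14-18)"
    return "cool nights (<14)"


def frost_heat(site_df: pd.DataFrame) -> FrostHeat:
    wfr = float(_series(site_df, "tmin", [1])[0])
    sfr = float(_series(site_df, "tmin", [4])[0])
    hst = float(_series(site_df, "tmax", [7])[0])
    ci = float(_series(site_df, "tmin", [9])[0])
    return FrostHeat(
        wfr=wfr, sfr=sfr, hst=hst, ci=ci,
        wfr_band=classify_wfr(wfr), sfr_band=classify_sfr(sfr),
        hst_band=classify_hst(hst), ci_band=classify_ci(ci),
    )


def huglin_day_length_coefficient(latitude: float, extrapolate: bool = False) -> float:
    """Huglin's stepwise day-length coefficient d by absolute latitude."""
    alat = abs(latitude)
    if alat > 90:
        raise ValueError("latitude outside [-90, 90]")
    steps = [(40, 1.00), (42, 1.02), (44, 1.03), (46, 1.04), (48, 1.05), (50, 1.06)]
    for bound, d in steps:
        if alat <= bound:
            return d
    if extrapolate:
        return 1.06
    raise ValueError("Huglin coefficient undefined above 50 deg latitude")


def huglin(site_df: pd.DataFrame, latitude: float, extrapolate: bool = False) -> float:
    """Huglin heliothermal index, Apr 1 - Sep 30.

    Daily term ((tmean-10) + (tmax-10))/2 x d, monthly values replicated
    per calendar day; negative daily terms floored at zero.
    """
    d = huglin_day_length_coefficient(latitude, extrapolate)
    months = list(range(4, 10))
    t = _series(site_df, "tmean", months)
    tx = _series(site_df, "tmax", months)
    days = MONTH_DAYS[np.array(months) - 1]
    daily = np.maximum(((t - 10.0) + (tx - 10.0)) / 2.0, 0.0)
    return float(np.sum(daily * days) * d)


def classify_huglin(hi: float) -> str:
    return "very warm (>3000)" if hi > 3000 else ("warm" if hi > 2400 else "temperate or cooler")


# vine transpiration coefficient k per month of the Apr-Sep window
_DI_K = {4: 0.1, 5: 0.3, 6: 0.5, 7: 0.5, 8: 0.5, 9: 0.5}


def dryness_index(site_df: pd.DataFrame, w0: float = 200.0) -> float:
    """Riou-type end-of-season soil-water balance (dryness index).

    Starting from an initial reserve ``w0`` at the end of March, each
    month Apr-Sep updates W = min(w0, W + P - Tv - Es) with vine
    transpiration Tv = k * PET and direct soil evaporation
    Es = (PET/N) * (1-k) * min(P/5, N); W may go negative.  DI is the
    September balance.
    """
    months = list(range(4, 10))
    p = _series(site_df, "precip", months)
    pet = _series(site_df, "pet", months)
    if np.isnan(pet).any():
        raise ValueError("PET missing in the Apr-Sep window")
    w = w0
    for m, pm, petm in zip(months, p, pet):
        k = _DI_K[m]
        n_days = MONTH_DAYS[m - 1]
        tv = k * petm
        es = (petm / n_days) * (1.0 - k) * min(pm / 5.0, n_days)
        w = min(w0, w + pm - tv - es)
    return float(w)


def classify_dryness(di: float) -> str:
    if di > 150:
        return "humid"
    if di > 50:
        return "sub-humid"
    if di > -100:
        return "moderately dry"
    return "very dry"


def index_table(meta: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    """All ten indices (plus elevation) per site.

    ``climate`` holds 12 monthly rows per site; ``meta`` supplies the
    site elevation (first row per site).
    """
    elev = meta.drop_duplicates("site").set_index("site")["elevation"]
    rows = []
    for site, df in climate.groupby("site", sort=True):
        lat = float(df["latitude"].iloc[0])
        fh = frost_heat(df)
        rows.append(
            {
                "site": site,
                "GST": gst(df),
                "GST49": gst49(df),
                "GSR": gsr(df),
                "GSR49": gsr49(df),
                "RRSPR": rrspr(df),
                "HYB": hyb(df),
                "WFR": fh.wfr,
                "SFR": fh.sfr,
                "HST": fh.hst,
                "CI": fh.ci,
                "HI": huglin(df, lat),
                "DI": dryness_index(df),
                "elevation": float(elev.get(site, np.nan)),
            }
        )
    return pd.DataFrame(rows).set_index("site")


def screen_correlations(indices: pd.DataFrame, threshold: float = 0.99):
    """Drop one member of every near-collinear index pair.

    For |Pearson r| >= threshold the longer-window member (GST over
    GST49, GSR over GSR49; otherwise the second of the pair) is
    dropped.  Constant columns are kept with a warning-style note.  The
    screen never reduces the index set below three variables — the
    minimum the downstream PCA needs.
    Returns (kept frame, dropped column names).
    """
    cols = [c for c in INDEX_COLUMNS if c in indices.columns]
    dropped = []
    corr = indices[cols].corr()
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a in dropped or b in dropped:
                continue
            if len(cols) - len(dropped) <= 3:
                break
            r = corr.loc[a, b]
            if np.isnan(r):
                continue
            if abs(r) >= threshold:
                victim = a if a in DROP_PREFERENCE else (b if b in DROP_PREFERENCE else b)
                dropped.append(victim)
    kept = indices.drop(columns=dropped)
    return kept, dropped


@dataclass
class EnvPCA:
    """Environmental PCA: loadings, per-site scores, variance fractions."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained: np.ndarray


def env_pca(indices: pd.DataFrame, n_components: int = 2) -> EnvPCA:
    """PCA of standardized climate indices (elevation excluded).

    Elevation is analyzed separately in the association scan because it
    is a field measurement, not an interpolated climate product.
    """
    X = indices.drop(columns=[c for c in ("elevation",) if c in indices.columns])
    if X.shape[1] < 3:
        raise ValueError("need >=3 index variables for the environmental PCA")
    sd = X.std(ddof=0)
    keep = sd > 0
    X = X.loc[:, keep]
    Z = (X - X.mean()) / X.std(ddof=0)
    n_components = min(n_components, min(Z.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return EnvPCA(
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=X.index, columns=pcs),
        explained=pca.explained_variance_ratio_,
    )
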