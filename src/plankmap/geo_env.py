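"""Geographic cluster labeling and environmental derivations.

Covers: nitracline depth by linear interpolation of bottle nitrate, haversine
distance to a coastline polyline, weighted-centroid nearshore/offshore
labeling of the two community clusters, per-cruise regional nitracline slope
(OLS of nitracline depth on distance to coast), nearshore-proportion series,
upwelling-index arithmetic (regionally available nitrate = BEUTI / CUTI,
2-month moving averages) and primary-production day scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0


def nitracline_depth(depths: np.ndarray, no3: np.ndarray,
                     threshold: float = 1.0) -> tuple[float, str]:
    """Depth where nitrate first reaches ``threshold`` µM, by linear interpolation.

    Scans downward for the first bracketing pair (NO3 below the threshold
    above, at or above it below) and interpolates between those two bottles.
    If the shallowest measurement already meets the threshold the shallowest
    sampled depth is returned (no extrapolation above the data).  Returns
    ``(depth, "ok")``, or ``(nan, "deeper-than-profile")`` when the threshold
    is never reached, or ``(nan, "insufficient")`` with fewer than two valid
    nitrate points.
    """
    depths = np.asarray(depths, dtype=float)
    no3 = np.asarray(no3, dtype=float)
    valid = np.isfinite(depths) & np.isfinite(no3)
    depths, no3 = depths[valid], no3[valid]
    if len(depths) < 2:
        return float("nan"), "insufficient"
    order = np.argsort(depths)
    depths, no3 = depths[order], no3[order]
    if no3[0] >= threshold:
        return float(depths[0]), "ok"
    for i in range(len(depths) - 1):
        if no3[i] < threshold <= no3[i + 1]:
            frac = (threshold - no3[i]) / (no3[i + 1] - no3[i])
            return float(depths[i] + frac * (depths[i + 1] - depths[i])), "ok"
    return float("nan"), "deeper-than-profile"


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(a))


def distance_to_coast(station: pd.Series | dict,
                      coastline: np.ndarray | None = None,
                      n_subdivisions: int = 100) -> float:
    """Distance to coast in km for one station.

    A ``distance_to_coast_km`` metadata value takes precedence.  Otherwise
    the minimum haversine distance from the station to the coastline polyline
    (two columns, lon/lat) is computed over the vertices and points linearly
    interpolated along each segment.
    """
    meta = station.get("distance_to_coast_km")
    if meta is not None and np.isfinite(meta):
        return float(meta)
    if coastline is None:
        raise ValueError("no metadata distance and no coastline polyline provided")
    coastline = np.asarray(coastline, dtype=float)
    pts = [coastline]
    for i in range(len(coastline) - 1):
        t = np.linspace(0, 1, n_subdivisions + 1)[1:-1, None]
        pts.append(coastline[i] + t * (coastline[i + 1] - coastline[i]))
    pts = np.vstack(pts)
    d = haversine_km(station["lon"], station["lat"], pts[:, 0], pts[:, 1])
    return float(np.min(d))


def label_clusters(classifications: pd.DataFrame, samples: pd.DataFrame,
                   stations: pd.DataFrame,
                   coastline: np.ndarray | None = None) -> pd.DataFrame:
    """Name the two community clusters nearshore/offshore from station geography.

    For each cluster, station weights are the frequency of that cluster among
    the station's classified samples; the weighted centroid is the
    weight-normalized mean of station (lon, lat).  The cluster whose centroid
    lies closer to the coast is labeled nearshore.  Adds a ``label`` column to
    ``classifications`` in place and returns a per-cluster geography frame.

    Raises on an exact centroid-distance tie: the data carry no cross-shore
    signal and a manual label is required.
    """
    st = stations.set_index("station_id")
    merged = classifications.merge(samples[["sample_id", "station_id"]], on="sample_id")
    clusters = sorted(merged["cluster"].unique())
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {clusters}")

    per_station = (merged.groupby(["station_id", "cluster"]).size()
                   .unstack(fill_value=0))
    totals = per_station.sum(axis=1)
    rows = []
    for c in clusters:
        weights = (per_station[c] / totals).to_numpy(dtype=float)
        if weights.sum() == 0:
            raise ValueError(f"cluster {c} observed at no station")
        weights = weights / weights.sum()
        lons = st.loc[per_station.index, "lon"].to_numpy(dtype=float)
        lats = st.loc[per_station.index, "lat"].to_numpy(dtype=float)
        cen_lon = float(np.sum(weights * lons))
        cen_lat = float(np.sum(weights * lats))
        if coastline is not None:
            cen_dist = distance_to_coast({"lon": cen_lon, "lat": cen_lat,
                                          "distance_to_coast_km": None}, coastline)
        else:
            # no polyline: inverse-distance-weight the stations' own metadata
            # distances with the same occurrence weights
            dists = st.loc[per_station.index, "distance_to_coast_km"].to_numpy(dtype=float)
            cen_dist = float(np.sum(weights * dists))
        rows.append({"cluster": c, "centroid_lon": cen_lon, "centroid_lat": cen_lat,
                     "centroid_distance_km": cen_dist})
    geo = pd.DataFrame(rows)
    d = geo["centroid_distance_km"].to_numpy()
    if d[0] == d[1]:
        raise ValueError("centroid distance tie: assign nearshore/offshore manually")
    labels = {geo.loc[int(np.argmin(d)), "cluster"]: "nearshore",
              geo.loc[int(np.argmax(d)), "cluster"]: "offshore"}
    geo["label"] = geo["cluster"].map(labels)
    classifications["label"] = classifications["cluster"].map(labels)
    return geo


def nearshore_frequency(classifications: pd.DataFrame,
                        samples: pd.DataFrame) -> pd.DataFrame:
    """Per-station frequency of the nearshore community with trial counts."""
    merged = classifications.merge(samples[["sample_id", "station_id"]], on="sample_id")
    g = merged.groupby("station_id")
    out = pd.DataFrame({
        "successes": g["label"].apply(lambda s: int((s == "nearshore").sum())),
        "trials": g.size(),
    }).reset_index()
    out["frequency"] = out["successes"] / out["trials"]
    return out


@dataclass
class CruiseSlope:
    cruise_id: str
    slope: float
    intercept: float
    slope_se: float
    n_stations: int
    flag: str = "ok"


def regional_nitracline_slope(nitracline: pd.DataFrame, stations: pd.DataFrame,
                              cruise_id: str) -> CruiseSlope:
    """OLS of nitracline depth (m) on distance to coast (km) for one cruise.

    ``nitracline`` needs columns station_id, cruise_id, nitracline_m (missing
    allowed).  Requires >= 3 stations with a nitracline that cruise; returns a
    flagged missing slope otherwise.
    """
    sub = nitracline[(nitracline["cruise_id"] == cruise_id)
                     & np.isfinite(nitracline["nitracline_m"])]
    sub = sub.merge(stations[["station_id", "distance_to_coast_km"]], on="station_id")
    n = len(sub)
    if n < 3:
        return CruiseSlope(cruise_id, float("nan"), float("nan"), float("nan"),
                           n, flag="insufficient-stations")
    x = sub["distance_to_coast_km"].to_numpy(dtype=float)
    y = sub["nitracline_m"].to_numpy(dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    dof = n - 2
    sigma2 = float(np.sum(resid ** 2) / dof) if dof > 0 else 0.0
    se = float(np.sqrt(sigma2 / sxx))
    return CruiseSlope(cruise_id, slope, intercept, se, n)


def cruise_slope_table(profiles: pd.DataFrame, stations: pd.DataFrame,
                       cruises: pd.Series | list[str] | None = None,
                       threshold: float = 1.0) -> pd.DataFrame:
    """Nitracline depths and regional slopes for every cruise in the profiles."""
    ncd_rows = []
    for (st, cr), cast in profiles.groupby(["station_id", "cruise_id"]):
        depth, flag = nitracline_depth(cast["depth_m"].to_numpy(),
                                       cast["no3"].to_numpy(), threshold=threshold)
        ncd_rows.append({"station_id": st, "cruise_id": cr,
                         "nitracline_m": depth, "flag": flag})
    ncd = pd.DataFrame(ncd_rows)
    cruise_ids = (list(cruises) if cruises is not None
                  else sorted(ncd["cruise_id"].unique()))
    rows = []
    for cr in cruise_ids:
        cs = regional_nitracline_slope(ncd, stations, cr)
        rows.append({"cruise_id": cr, "slope_m_per_km": cs.slope,
                     "intercept_m": cs.intercept, "slope_se": cs.slope_se,
                     "n_stations": cs.n_stations, "flag": cs.flag})
    return pd.DataFrame(rows)


def proportion_nearshore(classifications: pd.DataFrame, samples: pd.DataFrame,
                         group: str | None = None) -> pd.DataFrame:
    """Per-cruise proportion of classified samples labeled nearshore."""
    df = classifications
    if group is not None:
        df = df[df["group"] == group]
    merged = df.merge(samples[["sample_id", "cruise_id"]], on="sample_id")
    g = merged.groupby("cruise_id")
    out = pd.DataFrame({
        "n_nearshore": g["label"].apply(lambda s: int((s == "nearshore").sum())),
        "n_samples": g.size(),
    }).reset_index()
    out["proportion_nearshore"] = out["n_nearshore"] / out["n_samples"]
    return out


def index_arithmetic(indices: pd.DataFrame, cuti_epsilon: float = 1e-6,
                     window_days: int = 61) -> pd.DataFrame:
    """Regionally available nitrate (BEUTI / CUTI) and 2-month moving averages.

    The ratio is set missing wherever |CUTI| falls below ``cuti_epsilon``
    (never infinite).  Moving averages use a centered ``window_days`` window
    on the date index; partial windows at the edges are allowed.
    """
    out = indices.sort_values("date").reset_index(drop=True).copy()
    cuti = out["cuti"].to_numpy(dtype=float)
    beuti = out["beuti"].to_numpy(dtype=float)
    small = np.abs(cuti) < cuti_epsilon
    ratio = np.where(small, np.nan, beuti / np.where(small, 1.0, cuti))
    out["regional_nitrate"] = ratio
    dated = out.set_index("date")
    for colname in ("cuti", "beuti", "regional_nitrate"):
        out[f"{colname}_smooth"] = (
            dated[colname].rolling(f"{window_days}D", min_periods=1, center=True)
            .mean().to_numpy())
    return out


def daily_primary_production(half_day_values: np.ndarray,
                             light_level_values: np.ndarray | None = None
                             ) -> dict[str, float | np.ndarray]:
    """Scale half-day 14C incubations to full light days and integrate light levels.

    Daily production = 2 x the half-day value; the euphotic-zone integrated
    value is the arithmetic mean over the six light-level measurements (a
    warning is emitted and the mean of what is available used if not six).
    """
    half = np.asarray(half_day_values, dtype=float)
    if np.any(half < 0):
        raise ValueError("negative primary production")
    result: dict = {"daily": 2.0 * half}
    if light_level_values is not None:
        levels = np.asarray(light_level_values, dtype=float)
        if levels.size != 6:
            warnings.warn(f"expected 6 light levels, got {levels.size}; "
                          "averaging available values", stacklevel=2)
        result["integrated"] = float(np.mean(levels))
    return result
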