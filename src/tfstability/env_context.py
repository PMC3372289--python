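"""Environmental context of metagenome samples.

This module turns a gridded monthly ocean climatology (one value per grid
node per month, World-Ocean-Atlas style) into per-site descriptors:

* inverse-distance-weighted (IDW) interpolation of a parameter at a sample's
  GPS position and depth, for each of the 12 climatological months;
* an *environment stability* measure per site and parameter — the sample
  standard deviation of the 12 monthly values (the lower the SD, the more
  stable the environment);
* z-scoring of stability measures across sites so parameters on different
  scales (degC, PSU, umol/l) become comparable;
* Spearman-based pruning of co-varying stability measures;
* OLS validation of interpolated values against in-situ shipboard
  measurements.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GriddedClimatology",
    "SampleSite",
    "MonthlySeries",
    "StabilityTable",
    "InterpolationError",
    "DEFAULT_PRUNE_PRIORITY",
    "idw_interpolate",
    "monthly_series",
    "stability",
    "stability_table",
    "zscore",
    "prune_collinear",
    "validate_interpolation",
    "ValidationReport",
    "read_climatology",
    "write_climatology",
    "read_sites",
    "write_sites",
    "average_composite_series",
]

EARTH_RADIUS_KM = 6371.0

#: Tie order used when dropping one member of a correlated stability pair.
DEFAULT_PRUNE_PRIORITY = (
    "temperature",
    "salinity",
    "phosphate",
    "silicate",
    "dissolved_oxygen",
    "nitrate",
    "aou",
    "oxygen_saturation",
)


class InterpolationError(ValueError):
    """No reliable interpolation is possible at a site (e.g. all-missing
    neighborhood, as for coastal/mangrove stations)."""


def _haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2).

    Accepts scalars or broadcastable arrays of degrees; handles longitude
    wraparound at +-180 by construction.
    """
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class GriddedClimatology:
    """Monthly climatology of one parameter on a lat x lon x depth grid.

    ``values`` has shape (n_lat, n_lon, n_depth, 12); NaN marks missing
    (land / unsampled) nodes. Axes must be strictly increasing.
    """

    parameter: str
    units: str
    latitudes: np.ndarray
    longitudes: np.ndarray
    depth_levels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.depth_levels = np.asarray(self.depth_levels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, ax in (
            ("latitudes", self.latitudes),
            ("longitudes", self.longitudes),
            ("depth_levels", self.depth_levels),
        ):
            if ax.ndim != 1 or ax.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D axis")
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        expected = (
            self.latitudes.size,
            self.longitudes.size,
            self.depth_levels.size,
            12,
        )
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (lat, lon, depth, 12) {expected}"
            )

    def nearest_depth_index(self, depth_m: float) -> int:
        return int(np.argmin(np.abs(self.depth_levels - depth_m)))

    def contains(self, latitude: float, longitude: float) -> bool:
        return (
            self.latitudes[0] <= latitude <= self.latitudes[-1]
            and self.longitudes[0] <= longitude <= self.longitudes[-1]
        )


def _normalize_longitude(lon: float) -> float:
    """Map longitude into (-180, 180]."""
    lon = (float(lon) + 180.0) % 360.0 - 180.0
    return 180.0 if lon == -180.0 else lon


@dataclass
class SampleSite:
    """One metagenome sample's location, depth, date and metadata."""

    sample_id: str
    latitude: float
    longitude: float
    depth: float
    date: str = ""
    habitat: str = ""
    filter_min_um: float = 0.1
    filter_max_um: float = 0.8
    insitu_temperature: float | None = None
    insitu_salinity: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        self.longitude = _normalize_longitude(self.longitude)
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 < self.filter_min_um <= self.filter_max_um):
            raise ValueError("filter bounds must be positive and ordered")


@dataclass
class MonthlySeries:
    """Twelve interpolated monthly values of one parameter at one site."""

    sample_id: str
    parameter: str
    values: np.ndarray
    available: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("a monthly series holds exactly 12 values")
        if self.available and not np.all(np.isfinite(self.values)):
            raise ValueError("available series must be entirely finite")


@dataclass
class StabilityTable:
    """Sites x parameters matrix of stability values (sigma or z-scores).

    ``column_stats`` retains the population mean/SD used for z-scoring so a
    scored table stays traceable to the raw sigmas.
    """

    data: pd.DataFrame
    scored: bool = False
    column_stats: pd.DataFrame | None = None

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.data.columns)


def idw_interpolate(
    grid: GriddedClimatology,
    site: SampleSite,
    month: int,
    power: float = 2.0,
    k_neighbors: int = 4,
) -> float:
    """Inverse-distance-weighted estimate of ``grid.parameter`` at a site.

    Uses the ``k_neighbors`` nearest non-missing horizontal nodes at the
    nearest standard depth level, with weights d**-power on great-circle
    node distances. A zero-distance node short-circuits to that node's
    value. Raises :class:`InterpolationError` when every node at that depth
    is missing, and ``ValueError`` when the site is outside the grid.
    """
    if not 1 <= int(month) <= 12:
        raise ValueError("month must be in 1..12")
    if power <= 0:
        raise ValueError("power must be positive")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if not grid.contains(site.latitude, site.longitude):
        raise ValueError(
            f"site {site.sample_id} ({site.latitude}, {site.longitude}) "
            f"outside {grid.parameter} grid"
        )
    iz = grid.nearest_depth_index(site.depth)
    plane = grid.values[:, :, iz, int(month) - 1]
    ok = np.isfinite(plane)
    if not ok.any():
        raise InterpolationError(
            f"no finite {grid.parameter} nodes at depth level "
            f"{grid.depth_levels[iz]} m for {site.sample_id}"
        )
    lat_g, lon_g = np.meshgrid(grid.latitudes, grid.longitudes, indexing="ij")
    d = _haversine_km(site.latitude, site.longitude, lat_g[ok], lon_g[ok])
    v = plane[ok]
    order = np.argsort(d, kind="stable")[: int(k_neighbors)]
    d, v = d[order], v[order]
    if d[0] < 1e-9:  # query coincides with a grid node
        return float(v[0])
    w = d ** (-float(power))
    return float(np.sum(w * v) / np.sum(w))


def monthly_series(
    grid: GriddedClimatology,
    site: SampleSite,
    power: float = 2.0,
    k_neighbors: int = 4,
) -> MonthlySeries:
    """Interpolate all 12 climatological months at a site.

    If any month cannot be interpolated the series is returned flagged
    unavailable (NaN values) rather than raising, mirroring how coastal
    stations without reliable interpolations are dropped downstream.
    """
    out = np.full(12, np.nan)
    for m in range(1, 13):
        try:
            out[m - 1] = idw_interpolate(grid, site, m, power, k_neighbors)
        except (InterpolationError, ValueError):
            return MonthlySeries(site.sample_id, grid.parameter, out, available=False)
    return MonthlySeries(site.sample_id, grid.parameter, out, available=True)


def average_composite_series(series: Sequence[MonthlySeries], sample_id: str) -> MonthlySeries:
    """Average monthly series of a composite sample's constituent stations
    (pooled-library samples combining material from two stations)."""
    if not series:
        raise ValueError("need at least one constituent series")
    params = {s.parameter for s in series}
    if len(params) != 1:
        raise ValueError("constituent series must share one parameter")
    if not all(s.available for s in series):
        return MonthlySeries(sample_id, series[0].parameter, np.full(12, np.nan), False)
    vals = np.mean([s.values for s in series], axis=0)
    return MonthlySeries(sample_id, series[0].parameter, vals, True)


def stability(series: MonthlySeries) -> float:
    """Environment stability: sample SD (ddof=1) of the 12 monthly values.

    sigma = sqrt(sum((X_i - mean)^2) / (N - 1)), N = 12. Lower sigma means a
    more stable environment.
    """
    if not series.available or not np.all(np.isfinite(series.values)):
        raise ValueError(f"series {series.sample_id}/{series.parameter} unavailable")
    return float(np.std(series.values, ddof=1))


def stability_table(
    grids: Mapping[str, GriddedClimatology],
    sites: Sequence[SampleSite],
    power: float = 2.0,
    k_neighbors: int = 4,
) -> StabilityTable:
    """Stability sigma for every site x parameter; NaN where unavailable."""
    rows = {}
    for site in sites:
        row = {}
        for name, grid in grids.items():
            series = monthly_series(grid, site, power, k_neighbors)
            row[name] = stability(series) if series.available else np.nan
        rows[site.sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(grids)]
    return StabilityTable(df, scored=False)


def zscore(table: StabilityTable) -> StabilityTable:
    """Z-score each stability column across all sites (the population).

    z = (x - mu) / sigma with mu, sigma (sample SD) per column; scored
    columns come out with mean 0 and sample SD 1. Zero-variance columns are
    an error: a constant stability measure cannot discriminate sites.
    """
    df = table.data
    if len(df) < 2:
        raise ValueError("z-scoring needs at least 2 sites")
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    bad = sd[(sd == 0) | ~np.isfinite(sd)]
    if len(bad):
        raise ValueError(f"zero-variance stability column(s): {list(bad.index)}")
    stats_df = pd.DataFrame({"mean": mu, "sd": sd})
    return StabilityTable((df - mu) / sd, scored=True, column_stats=stats_df)


def prune_collinear(
    table: StabilityTable,
    rho_threshold: float = 0.6,
    priority: Sequence[str] = DEFAULT_PRUNE_PRIORITY,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Drop co-varying stability measures by pairwise Spearman rank correlation.

    Parameters are visited in ``priority`` order (any column absent from the
    list is appended in table order); a parameter is dropped when its |rho|
    with an already-retained parameter exceeds ``rho_threshold`` and the
    two-sided test is significant at ``alpha``. Pairs over the threshold but
    not significant are retained with a warning. Returns the retained
    parameter names and a report of every pairwise rho and p.
    """
    cols = list(table.data.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 parameters to prune")
    order = [p for p in priority if p in cols] + [c for c in cols if c not in priority]

    records = []
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = table.data[[a, b]].dropna()
            r, p = stats.spearmanr(pair[a], pair[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
            records.append({"parameter_a": a, "parameter_b": b, "rho": r, "p_value": p})

    retained: list[str] = []
    for cand in order:
        clash = False
        for kept in retained:
            if abs(rho.loc[cand, kept]) > rho_threshold:
                if pval.loc[cand, kept] < alpha:
                    clash = True
                    break
                warnings.warn(
                    f"|rho|={abs(rho.loc[cand, kept]):.2f} between {cand} and "
                    f"{kept} exceeds {rho_threshold} but is not significant "
                    f"(p={pval.loc[cand, kept]:.3g}); retaining both"
                )
        if not clash:
            retained.append(cand)
    report = pd.DataFrame.from_records(records)
    return retained, report


@dataclass
class ValidationReport:
    parameter: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    worst_site: str | None
    residuals: pd.Series


def validate_interpolation(
    pairs: pd.DataFrame,
    parameter: str,
    measured_col: str = "measured",
    interpolated_col: str = "interpolated",
    exclude: Iterable[str] = (),
) -> ValidationReport:
    """OLS of interpolated (response) on in-situ measured (explanatory).

    ``pairs`` is indexed by sample id with one row per unique sampling site;
    rows listed in ``exclude`` (e.g. stations with no reliable
    interpolation) and rows with missing values are dropped first.
    """
    import statsmodels.api as sm

    df = pairs.drop(index=[s for s in exclude if s in pairs.index])
    df = df[[measured_col, interpolated_col]].dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(df)}")
    x = sm.add_constant(df[measured_col].to_numpy())
    fit = sm.OLS(df[interpolated_col].to_numpy(), x).fit()
    resid = pd.Series(fit.resid, index=df.index)
    worst = resid.abs().idxmax() if len(resid) else None
    return ValidationReport(
        parameter=parameter,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.f_pvalue),
        n=len(df),
        worst_site=worst,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_climatology(grid: GriddedClimatology, path) -> None:
    """Write a grid as the plain-text long format:
    a '# parameter=... units=...' header then latitude, longitude, depth_m,
    month, value columns (missing nodes omitted)."""
    la, lo, de = np.meshgrid(
        grid.latitudes, grid.longitudes, grid.depth_levels, indexing="ij"
    )
    rows = []
    for m in range(12):
        v = grid.values[:, :, :, m]
        ok = np.isfinite(v)
        rows.append(
            pd.DataFrame(
                {
                    "latitude": la[ok],
                    "longitude": lo[ok],
                    "depth_m": de[ok],
                    "month": m + 1,
                    "value": v[ok],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# parameter={grid.parameter} units={grid.units}\n")
        out.to_csv(fh, index=False)


def read_climatology(path) -> GriddedClimatology:
    with open(path) as fh:
        header = fh.readline().strip()
        body = fh.read()
    if not header.startswith("#"):
        raise ValueError("climatology file must start with a '# parameter=' header")
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok)
    df = pd.read_csv(io.StringIO(body))
    lats = np.unique(df["latitude"])
    lons = np.unique(df["longitude"])
    deps = np.unique(df["depth_m"])
    values = np.full((lats.size, lons.size, deps.size, 12), np.nan)
    ila = np.searchsorted(lats, df["latitude"])
    ilo = np.searchsorted(lons, df["longitude"])
    ide = np.searchsorted(deps, df["depth_m"])
    values[ila, ilo, ide, df["month"].to_numpy() - 1] = df["value"]
    return GriddedClimatology(
        meta.get("parameter", "unknown"), meta.get("units", ""), lats, lons, deps, values
    )


_SITE_COLUMNS = [
    "sample_id",
    "latitude",
    "longitude",
    "depth_m",
    "date",
    "habitat",
    "filter_min_um",
    "filter_max_um",
    "insitu_temperature",
    "insitu_salinity",
]


def write_sites(sites: Sequence[SampleSite], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "latitude": s.latitude,
                "longitude": s.longitude,
                "depth_m": s.depth,
                "date": s.date,
                "habitat": s.habitat,
                "filter_min_um": s.filter_min_um,
                "filter_max_um": s.filter_max_um,
                "insitu_temperature": s.insitu_temperature,
                "insitu_salinity": s.insitu_salinity,
            }
            for s in sites
        ],
        columns=_SITE_COLUMNS,
    ).to_csv(path, index=False)


def read_sites(path) -> list[SampleSite]:
    df = pd.read_csv(path)
    sites = []
    for _, r in df.iterrows():
        sites.append(
            SampleSite(
                sample_id=str(r["sample_id"]),
                latitude=float(r["latitude"]),
                longitude=float(r["longitude"]),
                depth=float(r["depth_m"]),
                date=str(r.get("date", "")),
                habitat=str(r.get("habitat", "")),
                filter_min_um=float(r.get("filter_min_um", 0.1)),
                filter_max_um=float(r.get("filter_max_um", 0.8)),
                insitu_temperature=(
                    None if pd.isna(r.get("insitu_temperature")) else float(r["insitu_temperature"])
                ),
                insitu_salinity=(
                    None if pd.isna(r.get("insitu_salinity")) else float(r["insitu_salinity"])
                ),
            )
        )
    return sites
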