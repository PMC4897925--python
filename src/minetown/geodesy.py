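"""Great-circle distances from residences to point sources and exposure variables.

Exposure to an industrial point source (here: an open-pit mine) is proxied by
residential proximity.  Each child's distance to every source is computed with
the haversine formula on a sphere; the "average" exposure is the arithmetic
mean of the per-source distances.  For the dichotomized analyses a child is
coded exposed when its distance lies in the closest quartile (distance at or
below the empirical 25th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: km per degree of latitude on the reference sphere
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2).

    Inputs are in decimal degrees and may be scalars or arrays (broadcast).
    Latitudes must lie in [-90, 90] and longitudes in [-180, 180].
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0) or not np.all(np.isfinite(lat)):
            raise ValueError("latitude outside [-90, 90] or non-finite")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0) or not np.all(np.isfinite(lon)):
            raise ValueError("longitude outside [-180, 180] or non-finite")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def to_planar_km(lat, lon, center: tuple[float, float]) -> np.ndarray:
    """Project lat/lon onto a local tangent plane (km east, km north) at *center*.

    Adequate for the few-km extents this package works at.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    c_lat, c_lon = center
    x = (lon - c_lon) * KM_PER_DEG * np.cos(np.radians(c_lat))
    y = (lat - c_lat) * KM_PER_DEG
    return np.column_stack([x, y])


def from_planar_km(xy: np.ndarray, center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_planar_km`: planar (east, north) km back to lat/lon."""
    xy = np.asarray(xy, dtype=float)
    c_lat, c_lon = center
    lat = c_lat + xy[:, 1] / KM_PER_DEG
    lon = c_lon + xy[:, 0] / (KM_PER_DEG * np.cos(np.radians(c_lat)))
    return lat, lon


@dataclass
class ExposureSet:
    """Per-child distances to each source with closest-quartile indicators.

    Attributes
    ----------
    table : DataFrame indexed by child_id with columns ``d_<source>`` (km),
        ``d_average`` and ``q1_<source>``/``q1_average`` in {0, 1}.
    cutoffs : first-quartile cut-off (km) per exposure name.
    excluded : child ids dropped for missing/invalid coordinates.
    """

    table: pd.DataFrame
    cutoffs: dict[str, float]
    excluded: list = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.cutoffs)


def build_exposures(table: pd.DataFrame, sources: pd.DataFrame) -> ExposureSet:
    """Distances to every source, their average, and first-quartile indicators.

    ``table`` needs ``child_id``, ``lat``, ``lon``; ``sources`` needs
    ``source_id``, ``lat``, ``lon``.  The dichotomization cut-off is the
    empirical 25th percentile (linear-interpolation quantile); ties at the
    cut-off are coded exposed.  Children with missing coordinates are excluded
    and listed in ``excluded``.
    """
    if len(sources) < 1:
        raise ValueError("at least one source required")
    coords_ok = np.isfinite(table["lat"].astype(float)) & np.isfinite(table["lon"].astype(float))
    excluded = table.loc[~coords_ok, "child_id"].tolist()
    tab = table.loc[coords_ok]
    if len(tab) < 4:
        raise ValueError("need at least 4 children with coordinates for quartiles")

    out = pd.DataFrame(index=pd.Index(tab["child_id"], name="child_id"))
    dist_cols = []
    for _, src in sources.iterrows():
        d = haversine_km(tab["lat"].to_numpy(float), tab["lon"].to_numpy(float),
                         float(src["lat"]), float(src["lon"]))
        col = f"d_{src['source_id']}"
        out[col] = d
        dist_cols.append(col)
    out["d_average"] = out[dist_cols].mean(axis=1)

    cutoffs = {}
    for col in dist_cols + ["d_average"]:
        name = col[2:]
        cut = float(np.quantile(out[col].to_numpy(), 0.25))
        cutoffs[name] = cut
        out[f"q1_{name}"] = (out[col] <= cut).astype(int)
    return ExposureSet(table=out, cutoffs=cutoffs, excluded=excluded)
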