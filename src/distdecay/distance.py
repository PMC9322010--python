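"""Site-pair distance matrices: great-circle spatial distance (km) and
standardized Euclidean environmental distance rescaled to [0, 1]."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0  # mean Earth radius


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray  # condensed (i < j), non-negative
    kind: str           # spatial_km | environmental_unit

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    def to_square(self) -> pd.DataFrame:
        return pd.DataFrame(squareform(self.values), index=self.labels, columns=self.labels)

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.triu_indices(self.n_sites, k=1)
        return pd.DataFrame(
            {
                "site_i": [self.labels[i] for i in ii],
                "site_j": [self.labels[j] for j in jj],
                "kind": self.kind,
                "distance": self.values,
            }
        )

    @property
    def max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between decimal-degree points."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def spatial_distance_matrix(coords: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) from a sites-by-(lat, lon) table."""
    lat = coords.iloc[:, 0].to_numpy(dtype=float)
    lon = coords.iloc[:, 1].to_numpy(dtype=float)
    bad = (lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)
    if bad.any():
        raise ValueError(f"coordinates out of range for sites {list(coords.index[bad])}")
    ii, jj = np.triu_indices(len(lat), k=1)
    vals = haversine_km(lat[ii], lon[ii], lat[jj], lon[jj])
    return DistanceMatrix(list(coords.index), np.asarray(vals, dtype=float), "spatial_km")


def environmental_distance_matrix(env: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance over z-scored environmental variables, divided by
    the maximum so the matrix spans [0, 1] within the dataset.

    Standardisation uses the sample (n-1) standard deviation.  Zero-variance
    variables carry no information and are dropped with a warning; if all
    site pairs are identical the rescaling is undefined and this is fatal.
    """
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(env.columns, keep) if not k]
        log.warning("dropping zero-variance environmental variables: %s", dropped)
    if not keep.any():
        raise ValueError("all environmental variables have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    vals = pdist(Z, metric="euclidean")
    mx = vals.max() if vals.size else 0.0
    if mx <= 0:
        raise ValueError("all site pairs environmentally identical; cannot rescale")
    return DistanceMatrix(list(env.index), vals / mx, "environmental_unit")
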