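"""Spatial predictors: geographic distances, PCoA embedding, polynomial terms.

Inter-sample distances are great-circle (haversine) kilometers on a sphere
of radius 6371 km (chord distance through the Earth is available as an
option). Principal coordinate analysis maps the distance matrix to a 2-D
plane; the two axes X1, X2 and their element-wise powers up to degree 3
(X1^2, X1^3, X2^2, X2^3) are the spatial explanatory variables used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .env_context import EARTH_RADIUS_KM, SampleSite, _haversine_km

__all__ = [
    "SpatialCoordinates",
    "distance_matrix",
    "pcoa",
    "spatial_terms",
    "haversine_km",
    "chord_km",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometers (sphere radius 6371 km)."""
    return _haversine_km(lat1, lon1, lat2, lon2)


def chord_km(lat1, lon1, lat2, lon2):
    """Straight-line (3-D Cartesian chord) distance in kilometers."""
    theta = _haversine_km(lat1, lon1, lat2, lon2) / EARTH_RADIUS_KM
    return 2.0 * EARTH_RADIUS_KM * np.sin(np.asarray(theta) / 2.0)


@dataclass
class SpatialCoordinates:
    """PCoA embedding of the inter-sample distances.

    ``coords`` holds the retained axes (columns X1, X2, ...), scaled by the
    square root of their eigenvalues and centered at 0; ``eigenvalues`` are
    all eigenvalues in decreasing order (negative ones reported, not used).
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coords.index)


def distance_matrix(
    sites: Sequence[SampleSite],
    mode: str = "great_circle",
    composites: Mapping[str, Sequence[tuple[float, float]]] | None = None,
) -> DistanceMatrix:
    """Pairwise geographic distances between samples, in kilometers.

    ``composites`` maps a sample id to the (lat, lon) pairs of its
    constituent stations (for pooled libraries combining material from two
    stations); the distance between a composite sample and any other sample
    is the average over its constituents.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    dist = {"great_circle": haversine_km, "chord": chord_km}.get(mode)
    if dist is None:
        raise ValueError(f"unknown distance mode {mode!r}")
    composites = composites or {}
    pts = [
        [(float(a), float(b)) for a, b in composites[s.sample_id]]
        if s.sample_id in composites
        else [(s.latitude, s.longitude)]
        for s in sites
    ]
    n = len(sites)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [dist(a1, o1, a2, o2) for a1, o1 in pts[i] for a2, o2 in pts[j]]
            d[i, j] = d[j, i] = float(np.mean(pairs))
    return DistanceMatrix(d, ids=[s.sample_id for s in sites])


def pcoa(dm: DistanceMatrix, k: int = 2) -> SpatialCoordinates:
    """Principal coordinate analysis (metric MDS) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns the ``k``
    eigenvectors with the largest positive eigenvalues, each scaled by
    sqrt(eigenvalue). Negative eigenvalues (non-Euclidean distances) are
    reported but their axes discarded. Signs are fixed so each axis's
    largest-magnitude coordinate is positive.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-10
    n_pos = int(np.sum(evals > tol))
    if k > n_pos:
        raise ValueError(f"requested {k} axes but only {n_pos} positive eigenvalues")
    axes = evecs[:, :k] * np.sqrt(evals[:k])
    for c in range(k):
        if axes[np.argmax(np.abs(axes[:, c])), c] < 0:
            axes[:, c] = -axes[:, c]
    coords = pd.DataFrame(
        axes, index=list(dm.ids), columns=[f"X{i + 1}" for i in range(k)]
    )
    return SpatialCoordinates(coords=coords, eigenvalues=evals)


def spatial_terms(coords: SpatialCoordinates | pd.DataFrame, degree: int = 3) -> pd.DataFrame:
    """Polynomial spatial predictors from the PCoA axes.

    Axes are centered before raising to powers (limits collinearity among
    the power terms). With the default degree 3 and two axes the output
    columns are X1, X2, X1^2, X1^3, X2^2, X2^3.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    df = coords.coords if isinstance(coords, SpatialCoordinates) else coords
    centered = df - df.mean(axis=0)
    out = {c: centered[c] for c in centered.columns}
    for c in centered.columns:
        for p in range(2, degree + 1):
            out[f"{c}^{p}"] = centered[c] ** p
    # linear axes first, then grouped powers per axis
    names = list(centered.columns) + [
        f"{c}^{p}" for c in centered.columns for p in range(2, degree + 1)
    ]
    return pd.DataFrame(out)[names]
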