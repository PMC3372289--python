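"""Shared fixtures: small synthetic datasets built once per session.

The reduced grid extent keeps interpolation cheap; the study conditions
that matter downstream (44 sites, 65 TF / 53 SCG models, planted variance
fractions 0.35 / 0.06) are the generator defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tfstability import domain_counts as dc
from tfstability import env_context as env
from tfstability import spatial as sp
from tfstability import synthetic as syn

#: Reduced grid for fast interpolation in tests (21 x 21 nodes, 5 depths).
FAST_GRID = dict(
    lat_range=(-20.0, 20.0), lon_range=(-60.0, -20.0), grid_step_deg=2.0
)


def fast_spec(seed: int, **overrides) -> syn.SyntheticSpec:
    kwargs = {**FAST_GRID, **overrides}
    return syn.SyntheticSpec(seed=seed, **kwargs)


def build_dataset(seed: int, **overrides) -> dict:
    """Run the synthetic generators through the real pipeline stages."""
    spec = fast_spec(seed, **overrides)
    sites = syn.make_sites(spec)
    grids = {p: syn.make_climatology(spec, p) for p in syn.PARAMETER_DEFAULTS}
    stab = env.stability_table(grids, sites)
    z = env.zscore(stab)
    dm = sp.distance_matrix(sites)
    coords = sp.pcoa(dm, k=2)
    terms = sp.spatial_terms(coords, degree=3)
    gen = syn.make_counts(spec, z, coords)
    y_std = dc.standardize_counts(gen.tf, gen.scg).data.T
    return {
        "spec": spec,
        "sites": sites,
        "grids": grids,
        "stab": stab,
        "z": z,
        "dm": dm,
        "coords": coords,
        "terms": terms,
        "gen": gen,
        "y_std": y_std,
    }


@pytest.fixture(scope="session")
def demo44() -> dict:
    """One seeded 44-site dataset shared by the read-only tests."""
    return build_dataset(seed=11)


@pytest.fixture(scope="session")
def candidates44(demo44) -> pd.DataFrame:
    """Regression candidates: the four retained stability z-scores plus the
    spatial axes and their polynomial terms."""
    four = demo44["z"].data[["temperature", "salinity", "phosphate", "silicate"]]
    return pd.concat([four, demo44["terms"]], axis=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
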