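"""Synthetic data with known statistical structure for every pipeline stage.

The generators emulate the study conditions of the marine-metagenome TF
analysis — 44 epipelagic sample sites, 65 TF and 53 SCG Pfam models, an
environment-stability effect of 0.35 and a spatial effect of 0.06 on the
variance of standardized TF abundances — so that interpolation, stability,
standardization, ordination and regression can all be tested against a
recorded ground truth without any external download.

Components:

* ``make_climatology`` — gridded monthly fields with a sinusoidal seasonal
  cycle (closed-form stability A*sqrt(6/11)), a linear latitudinal trend
  and Gaussian node noise;
* ``make_sites`` — sample sites inside the grid with marine habitat labels
  and prokaryote filter ranges;
* ``make_counts`` — TF/SCG count tables whose expected standardized
  abundances carry exactly the requested environment and space variance
  fractions (empirical Gram-Schmidt construction), thinned by Poisson
  sampling at the per-sample genome-equivalent depth;
* ``make_domtblout`` — HMMER3 per-domain text that round-trips through the
  parser and significance filter to the source counts, plus decoy records
  built to fail the filter;
* ``make_synthetic_validation_table`` / ``make_synthetic_tf_panel`` —
  synthetic stand-ins for the shipboard-validation pairs and the per-TF
  regression panel, with the published summary statistics planted as the
  generating truth (the original supplementary tables are not
  redistributable here, so recovery of the planted values is what the
  tests can verify).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .domain_counts import CountMatrix, load_scg_models, load_tf_models
from .env_context import GriddedClimatology, SampleSite, StabilityTable, zscore
from .spatial import SpatialCoordinates

__all__ = [
    "SyntheticSpec",
    "SyntheticCounts",
    "PARAMETER_DEFAULTS",
    "DEFAULT_TF_PANEL",
    "make_climatology",
    "make_sites",
    "make_counts",
    "make_domtblout",
    "make_synthetic_validation_table",
    "make_synthetic_tf_panel",
]

#: Per-parameter (units, base level, seasonal amplitude, latitudinal trend
#: per degree, node noise SD) for the eight climatology parameters.
PARAMETER_DEFAULTS: dict[str, tuple[str, float, float, float, float]] = {
    "temperature": ("degC", 18.0, 4.0, -0.25, 0.6),
    "salinity": ("PSU", 35.0, 0.4, 0.02, 0.15),
    "dissolved_oxygen": ("umol/kg", 230.0, 18.0, 0.8, 5.0),
    "aou": ("umol/kg", 20.0, 10.0, 0.5, 3.0),
    "oxygen_saturation": ("percent", 95.0, 4.0, -0.1, 1.5),
    "phosphate": ("umol/l", 0.6, 0.25, 0.01, 0.08),
    "nitrate": ("umol/l", 5.0, 2.5, 0.08, 0.8),
    "silicate": ("umol/l", 8.0, 3.0, 0.1, 1.0),
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_sites: int = 44
    lat_range: tuple[float, float] = (-35.0, 45.0)
    lon_range: tuple[float, float] = (-80.0, -10.0)
    depth_range: tuple[float, float] = (0.0, 30.0)
    grid_step_deg: float = 1.0
    depth_levels: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 50.0)
    seasonal_amplitude: dict[str, float] = field(default_factory=dict)
    spatial_trend: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    env_fraction: float = 0.35
    space_fraction: float = 0.06
    env_loadings: dict[str, float] = field(
        default_factory=lambda: {"temperature": 0.9, "phosphate": 0.436}
    )
    space_loadings: dict[str, float] = field(default_factory=lambda: {"X2": 1.0})
    n_tf: int = 65
    n_scg: int = 53
    mean_depth_of_coverage: float = 200.0
    tf_mean_abundance: float = 1.5
    tf_abundance_cv: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_tf < 1 or self.n_scg < 1:
            raise ValueError("model counts must be >= 1")
        if self.env_fraction < 0 or self.space_fraction < 0:
            raise ValueError("variance fractions must be >= 0")
        if self.env_fraction + self.space_fraction > 1:
            raise ValueError("env_fraction + space_fraction must be <= 1")
        for name, rng_ in (("lat_range", self.lat_range), ("lon_range", self.lon_range)):
            if not rng_[1] > rng_[0]:
                raise ValueError(f"{name} must span a positive extent")
        for d in (self.seasonal_amplitude, self.noise_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("amplitudes and noise must be >= 0")

    def amplitude(self, parameter: str) -> float:
        return self.seasonal_amplitude.get(parameter, PARAMETER_DEFAULTS[parameter][2])

    def trend(self, parameter: str) -> float:
        return self.spatial_trend.get(parameter, PARAMETER_DEFAULTS[parameter][3])

    def noise(self, parameter: str) -> float:
        return self.noise_sd.get(parameter, PARAMETER_DEFAULTS[parameter][4])


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), int(stream)]))


def make_climatology(spec: SyntheticSpec, parameter: str) -> GriddedClimatology:
    """Monthly climatology grid for one of the eight study parameters.

    Node values follow base + trend * (latitude - mid) +
    amplitude * sin(2 pi month / 12) + N(0, noise_sd); with zero noise the
    per-node stability is exactly amplitude * sqrt(6/11).
    """
    spec.validate()
    if parameter not in PARAMETER_DEFAULTS:
        raise ValueError(f"unknown parameter {parameter!r}")
    units, base, _, _, _ = PARAMETER_DEFAULTS[parameter]
    amp, trend, noise = spec.amplitude(parameter), spec.trend(parameter), spec.noise(parameter)
    lats = np.arange(spec.lat_range[0], spec.lat_range[1] + 1e-9, spec.grid_step_deg)
    lons = np.arange(spec.lon_range[0], spec.lon_range[1] + 1e-9, spec.grid_step_deg)
    deps = np.asarray(spec.depth_levels, dtype=float)
    rng = _rng(spec.seed, list(PARAMETER_DEFAULTS).index(parameter))
    mid = 0.5 * (spec.lat_range[0] + spec.lat_range[1])
    months = np.arange(1, 13)
    seasonal = amp * np.sin(2.0 * np.pi * months / 12.0)  # (12,)
    spatial = base + trend * (lats - mid)  # (nlat,)
    values = (
        spatial[:, None, None, None]
        + np.zeros((1, lons.size, deps.size, 1))
        + seasonal[None, None, None, :]
    )
    if noise > 0:
        values = values + rng.normal(0.0, noise, size=values.shape)
    return GriddedClimatology(parameter, units, lats, lons, deps, values)


_HABITATS = ("open ocean", "coastal water", "estuary", "coral reef", "upwelling zone")


def make_sites(spec: SyntheticSpec) -> list[SampleSite]:
    """Sample sites uniform inside the grid extent; seeded-reproducible."""
    spec.validate()
    rng = _rng(spec.seed, 101)
    pad_lat = 0.02 * (spec.lat_range[1] - spec.lat_range[0])
    pad_lon = 0.02 * (spec.lon_range[1] - spec.lon_range[0])
    sites = []
    for i in range(spec.n_sites):
        lo, hi = spec.depth_range
        f_min = float(rng.uniform(0.1, 0.22))
        f_max = float(rng.uniform(max(f_min, 0.45), 0.8))
        sites.append(
            SampleSite(
                sample_id=f"SYN{i + 1:03d}",
                latitude=float(rng.uniform(spec.lat_range[0] + pad_lat, spec.lat_range[1] - pad_lat)),
                longitude=float(rng.uniform(spec.lon_range[0] + pad_lon, spec.lon_range[1] - pad_lon)),
                depth=float(rng.uniform(lo, hi)),
                date=f"200{rng.integers(3, 7)}-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}",
                habitat=str(rng.choice(_HABITATS)),
                filter_min_um=f_min,
                filter_max_um=f_max,
            )
        )
    return sites


@dataclass
class SyntheticCounts:
    """Generated count tables plus the generating truth for recovery tests."""

    tf: CountMatrix
    scg: CountMatrix
    truth: dict


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    nrm = np.sqrt(np.mean(v**2))
    if nrm < 1e-12:
        raise ValueError("degenerate (constant) signal vector")
    return v / nrm


def make_counts(
    spec: SyntheticSpec,
    stability: StabilityTable,
    coords: SpatialCoordinates | pd.DataFrame,
) -> SyntheticCounts:
    """TF and SCG count tables with planted env/space variance fractions.

    Effects are planted in standardized (per-genome-equivalent) space: each
    TF's expected standardized abundance is mu_j (1 + cv * s_j) with
    s_j = sqrt(f_env) e_j + sqrt(f_space) p_j + sqrt(1-f_env-f_space) eps_j,
    where e_j is a linear combination of the z-scored stability columns
    (only parameters with a nonzero loading carry signal), p_j a
    combination of the spatial axes Gram-Schmidt-orthogonalized against
    e_j, and eps_j Gaussian noise orthogonalized against both; all three
    are scaled to unit population variance across sites, so the planted
    variance fractions are exact. Interpolated stability fields are
    spatially autocorrelated, so a seed-dependent part of the environment
    effect is genuinely shared with the spatial axes; the planted fractions
    are recovered as (env unique + shared) and (space unique), with the
    shared fraction small on average. Realized counts are Poisson(expected * g_s) with
    per-sample genome equivalents g_s drawn around mean_depth_of_coverage;
    SCG counts are Poisson(g_s) per model.
    """
    spec.validate()
    if stability.data.empty:
        raise ValueError("empty stability table")
    ztab = stability if stability.scored else zscore(stability)
    Z = ztab.data
    C = coords.coords if isinstance(coords, SpatialCoordinates) else pd.DataFrame(coords)
    if not Z.index.equals(C.index):
        C = C.reindex(Z.index)
        if C.isna().any().any():
            raise ValueError("stability and coords must cover the same sites")
    n = len(Z)
    rng = _rng(spec.seed, 202)

    env_u = np.array([spec.env_loadings.get(c, 0.0) for c in Z.columns])
    if not env_u.any():
        env_u = np.ones(len(Z.columns))
    spa_u = np.array([spec.space_loadings.get(c, 0.0) for c in C.columns])
    if not spa_u.any():
        spa_u = np.ones(len(C.columns))

    tf_names = list(load_tf_models()["model_name"])[: spec.n_tf]
    tf_names += [f"TF_{i + 1:03d}" for i in range(len(tf_names), spec.n_tf)]
    scg_names = list(load_scg_models()["model_name"])[: spec.n_scg]
    scg_names += [f"SCG_{i + 1:03d}" for i in range(len(scg_names), spec.n_scg)]
    cats = load_tf_models().set_index("model_name")["category"]

    fe, fs = spec.env_fraction, spec.space_fraction
    fr = 1.0 - fe - fs
    mu = rng.lognormal(
        mean=np.log(spec.tf_mean_abundance) - 0.5 * 0.6**2, sigma=0.6, size=spec.n_tf
    )
    g = spec.mean_depth_of_coverage * np.exp(rng.normal(-0.045, 0.3, size=n))

    # per-TF weight jitter, confined to the loaded columns so unloaded
    # parameters carry strictly no planted signal
    w_env = env_u[None, :] * (1.0 + 0.15 * rng.normal(size=(spec.n_tf, len(env_u))))
    w_spa = spa_u[None, :] * (1.0 + 0.15 * rng.normal(size=(spec.n_tf, len(spa_u))))
    Zc = Z.to_numpy() - Z.to_numpy().mean(axis=0)
    expected = np.empty((n, spec.n_tf))
    env_sig = np.empty((n, spec.n_tf))
    spa_sig = np.empty((n, spec.n_tf))
    for j in range(spec.n_tf):
        e = _unit(Zc @ w_env[j]) if fe > 0 else np.zeros(n)
        p_raw = C.to_numpy() @ w_spa[j]
        if fs > 0:
            p_raw = p_raw - p_raw.mean()
            if fe > 0:
                p_raw = p_raw - (p_raw @ e) / n * e  # e has unit pop variance
            p = _unit(p_raw)
        else:
            p = np.zeros(n)
        eps = rng.normal(size=n)
        eps = eps - eps.mean()
        for v in (e, p):
            if v.any():
                eps = eps - (eps @ v) / n * v
        eps = _unit(eps)
        s = np.sqrt(fe) * e + np.sqrt(fs) * p + np.sqrt(max(fr, 0.0)) * eps
        expected[:, j] = np.clip(mu[j] * (1.0 + spec.tf_abundance_cv * s), 0.02 * mu[j], None)
        env_sig[:, j], spa_sig[:, j] = e, p

    tf_counts = rng.poisson(expected * g[:, None]).T  # models x samples
    scg_counts = rng.poisson(np.broadcast_to(g, (spec.n_scg, n)))

    samples = list(Z.index)
    tf_cm = CountMatrix(
        pd.DataFrame(tf_counts, index=tf_names, columns=samples),
        kind="raw",
        categories=cats.reindex(tf_names).fillna("non-DBD"),
    )
    scg_cm = CountMatrix(pd.DataFrame(scg_counts, index=scg_names, columns=samples), kind="raw")
    truth = {
        "env_fraction": fe,
        "space_fraction": fs,
        "expected_standardized": pd.DataFrame(expected, index=samples, columns=tf_names),
        "genome_equivalents": pd.Series(g, index=samples),
        "env_signal": pd.DataFrame(env_sig, index=samples, columns=tf_names),
        "space_signal": pd.DataFrame(spa_sig, index=samples, columns=tf_names),
        "env_weights": pd.DataFrame(w_env, index=tf_names, columns=Z.columns),
        "space_weights": pd.DataFrame(w_spa, index=tf_names, columns=C.columns),
        "seed": spec.seed,
    }
    return SyntheticCounts(tf=tf_cm, scg=scg_cm, truth=truth)


# ---------------------------------------------------------------------------
# domtblout emission


def _domtbl_record(
    read_id: str,
    model: str,
    model_len: int,
    i_evalue: float,
    score: float,
    bias: float,
    hmm_from: int,
    hmm_to: int,
    note: str,
) -> str:
    tlen = model_len + 40
    ali_from, ali_to = 5, 5 + (hmm_to - hmm_from)
    return (
        f"{read_id:<20} - {tlen:5d} {model:<20} - {model_len:5d} "
        f"{i_evalue / 2:9.2g} {score + 0.5:6.1f} {bias:5.1f}   1   1 "
        f"{i_evalue / 2:9.2g} {i_evalue:9.2g} {score:6.1f} {bias:5.1f} "
        f"{hmm_from:5d} {hmm_to:5d} {ali_from:5d} {ali_to:5d} "
        f"{max(ali_from - 2, 1):5d} {ali_to + 2:5d} 0.90 {note}"
    )


def make_domtblout(
    counts: CountMatrix,
    model_lengths: Mapping[str, int],
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """HMMER3 per-domain text per sample reproducing ``counts`` after filtering.

    Every counted hit becomes one record satisfying all three significance
    criteria; decoys (``decoy_rate`` per significant record) are emitted on
    top, each failing exactly one criterion, cycling E-value / coverage /
    bias so the filter is exercised per criterion.
    """
    if decoy_rate < 0:
        raise ValueError("decoy_rate must be >= 0")
    arr = counts.data.to_numpy()
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    for m in counts.models:
        if m not in model_lengths or model_lengths[m] <= 0:
            raise ValueError(f"missing or non-positive length for model {m}")
    rng = np.random.default_rng(seed)
    header = (
        "# target name        accession   tlen query name           accession   qlen"
        "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
        "  from    to  from    to  acc description of target"
    )
    out: dict[str, str] = {}
    decoy_mode = 0
    for sample in counts.samples:
        lines = [header]
        n_good = 0
        for model in counts.models:
            length = int(model_lengths[model])
            min_span = int(np.ceil(0.2 * length))
            for _ in range(int(counts.data.loc[model, sample])):
                n_good += 1
                span = int(rng.integers(min_span, length))
                start = int(rng.integers(1, length - span + 1))
                score = float(rng.uniform(25.0, 150.0))
                lines.append(
                    _domtbl_record(
                        f"{sample}_r{n_good:06d}",
                        model,
                        length,
                        float(10.0 ** rng.uniform(-20.0, -3.5)),
                        score,
                        float(rng.uniform(0.0, max(score / 10.0 - 0.06, 0.0))),
                        start,
                        start + span,
                        "significant",
                    )
                )
        for d in range(int(round(decoy_rate * n_good))):
            model = counts.models[int(rng.integers(0, len(counts.models)))]
            length = int(model_lengths[model])
            min_span = int(np.ceil(0.2 * length))
            i_ev, span, score = 10.0 ** rng.uniform(-20.0, -3.5), min_span, float(rng.uniform(25.0, 150.0))
            bias = float(rng.uniform(0.0, max(score / 10.0 - 0.06, 0.0)))
            note = ("decoy evalue", "decoy coverage", "decoy bias")[decoy_mode]
            if decoy_mode == 0:
                i_ev = 1e-2
            elif decoy_mode == 1:
                span = max(1, min_span // 2)
                if span >= 0.2 * length:  # tiny models: shrink until it fails
                    span = max(1, int(0.2 * length) - 1)
            else:
                bias = score / 2.0
            decoy_mode = (decoy_mode + 1) % 3
            lines.append(
                _domtbl_record(
                    f"{sample}_d{d + 1:04d}", model, length, i_ev, score, bias, 1, 1 + span, note
                )
            )
        lines.append("#")
        out[sample] = "\n".join(lines) + "\n"
    return out


# ---------------------------------------------------------------------------
# synthetic stand-ins for the published summary statistics


def make_synthetic_validation_table(
    seed: int = 0,
    r2_temperature: float = 0.76,
    n_temperature: int = 55,
    r2_salinity: float = 0.60,
    n_salinity: int = 44,
    outlier_id: str = "GS033",
    salinity_gap: float = 29.0,
    temperature_gap: float = 12.0,
) -> pd.DataFrame:
    """SYNTHETIC stand-in for the shipboard-validation pair table.

    Builds measured/interpolated temperature and salinity pairs whose OLS
    goodness-of-fit is *exactly* the published values by construction: the
    planted truths are R^2 = ``r2_temperature`` over ``n_temperature``
    samples (the hypersaline outlier station included, its interpolation
    ``temperature_gap`` degC and ``salinity_gap`` PSU below the measured
    values) and R^2 = ``r2_salinity`` over ``n_salinity`` samples once the
    outlier is excluded. The real pair table is not redistributable, so
    recovering these planted statistics is what validation tests verify.
    """
    rng = np.random.default_rng(seed)
    ids = [f"GS{i:03d}" for i in range(1, n_temperature + 1)]
    if outlier_id not in ids:
        ids[-1] = outlier_id
    others = [i for i in ids if i != outlier_id]

    # temperature: outlier pair fixed at the planted gap; noise scale of the
    # remaining pairs solved so the 55-sample OLS R^2 hits the target.
    x_t = rng.uniform(3.0, 30.0, size=len(others))
    e_t = rng.normal(size=len(others))
    out_meas_t, out_interp_t = 29.5, 29.5 - temperature_gap

    def temp_r2(scale: float) -> float:
        x = np.append(x_t, out_meas_t)
        y = np.append(x_t + scale * e_t, out_interp_t)
        r = np.corrcoef(x, y)[0, 1]
        return r * r

    scale = optimize.brentq(lambda s: temp_r2(s) - r2_temperature, 1e-9, 100.0, xtol=1e-13)
    temp = pd.Series(np.append(x_t + scale * e_t, out_interp_t), index=others + [outlier_id])
    temp_meas = pd.Series(np.append(x_t, out_meas_t), index=others + [outlier_id])

    # salinity: exact construction — noise orthogonal to (1, x) scaled so
    # R^2 = var(x) / (var(x) + var(e)); outlier pair added on top.
    sal_ids = others[:n_salinity]
    x_s = rng.uniform(31.5, 38.5, size=n_salinity)
    e = rng.normal(size=n_salinity)
    xc = x_s - x_s.mean()
    e = e - e.mean()
    e = e - (e @ xc) / (xc @ xc) * xc
    e *= np.sqrt((xc @ xc) * (1.0 / r2_salinity - 1.0) / (e @ e))
    sal = pd.Series(x_s + e, index=sal_ids)
    sal_meas = pd.Series(x_s, index=sal_ids)
    out_meas_s = 47.3
    sal_meas[outlier_id] = out_meas_s
    sal[outlier_id] = out_meas_s - salinity_gap

    df = pd.DataFrame(index=ids)
    df["measured_temperature"] = temp_meas
    df["interpolated_temperature"] = temp
    df["measured_salinity"] = sal_meas
    df["interpolated_salinity"] = sal
    df.index.name = "sample_id"
    return df


#: Planted per-TF regression panel: (tf, category, terms, R^2). The 19 TFs
#: above the R^2 > 0.3 screen, with the published fit qualities as the
#: generating truth.
DEFAULT_TF_PANEL: tuple[tuple[str, str, tuple[str, ...], float], ...] = (
    ("Response_reg", "non-DBD", ("temperature", "phosphate", "X2^2"), 0.31),
    ("Peptidase_S24", "non-DBD", ("temperature",), 0.34),
    ("Pro_dh", "non-DBD", ("temperature", "X1"), 0.38),
    ("Aldedh", "non-DBD", ("temperature", "X2"), 0.46),
    ("Sugar_bind", "non-DBD", ("temperature", "salinity"), 0.47),
    ("UTRA", "non-DBD", ("temperature",), 0.49),
    ("TOBE", "non-DBD", ("temperature", "salinity", "silicate", "X2"), 0.56),
    ("LysR_substrate", "non-DBD", ("temperature", "X2"), 0.58),
    ("LacI", "DBD", ("temperature", "phosphate"), 0.31),
    ("ArsR", "DBD", ("temperature", "silicate"), 0.33),
    ("GntR", "DBD", ("temperature", "X2"), 0.38),
    ("Penicillinase_R", "DBD", ("temperature", "salinity", "phosphate", "X2"), 0.41),
    ("HTH_AraC", "DBD", ("temperature", "X2"), 0.41),
    ("HTH_6", "DBD", ("temperature", "phosphate"), 0.43),
    ("HTH_3", "DBD", ("temperature", "silicate", "X2"), 0.52),
    ("TetR_N", "DBD", ("temperature", "X2"), 0.54),
    ("Trp_repressor", "DBD", ("temperature", "phosphate"), 0.55),
    ("LytTR", "DBD", ("temperature", "silicate", "X2"), 0.57),
    ("HTH_1", "DBD", ("temperature", "salinity", "X2"), 0.60),
)


def make_synthetic_tf_panel(
    candidates: pd.DataFrame,
    seed: int = 0,
    panel: Sequence[tuple[str, str, tuple[str, ...], float]] = DEFAULT_TF_PANEL,
    n_tf: int = 65,
    base_abundance: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, tuple[tuple[str, ...], float]]]:
    """SYNTHETIC per-TF response panel with exactly planted term sets and R^2.

    For each planted TF the response is built as a combination of its named
    candidate terms — coefficients inversely proportional to each term's
    unique (partial) norm, so every term carries an equal, comfortably
    significant partial contribution — plus noise orthogonal to *all*
    candidate terms scaled so the OLS R^2 on the true term set is exact.
    Remaining TFs (up to ``n_tf``) are pure orthogonal noise and must fall
    out of any honest screen. Returns (responses, categories, truth).
    """
    rng = np.random.default_rng(seed)
    X = candidates.copy()
    n = len(X)
    Xc = X - X.mean(axis=0)
    full = np.hstack([np.ones((n, 1)), Xc.to_numpy()])
    q_full, _ = np.linalg.qr(full)

    def ortho_noise() -> np.ndarray:
        e = rng.normal(size=n)
        e = e - q_full @ (q_full.T @ e)
        return e / np.linalg.norm(e)

    names = [p[0] for p in panel]
    filler = [m for m in load_tf_models()["model_name"] if m not in names]
    filler += [f"TF_{i:03d}" for i in range(len(filler) + len(names), n_tf)]
    cats = dict(load_tf_models().set_index("model_name")["category"])

    Y = {}
    categories = {}
    truth: dict[str, tuple[tuple[str, ...], float]] = {}
    for tf, cat, terms, r2 in panel:
        M = Xc[list(terms)].to_numpy()
        beta = np.empty(len(terms))
        for k in range(len(terms)):
            others = np.delete(M, k, axis=1)
            if others.shape[1]:
                qo, _ = np.linalg.qr(others)
                resid = M[:, k] - qo @ (qo.T @ M[:, k])
            else:
                resid = M[:, k]
            beta[k] = rng.choice([-1.0, 1.0]) / np.linalg.norm(resid)
        base = M @ beta
        e = ortho_noise() * np.linalg.norm(base) * np.sqrt(1.0 / r2 - 1.0)
        Y[tf] = base_abundance + base + e
        categories[tf] = cat
        truth[tf] = (tuple(terms), r2)
    for tf in filler[: n_tf - len(panel)]:
        Y[tf] = base_abundance + 0.3 * ortho_noise()
        categories[tf] = cats.get(tf, "non-DBD")
        truth[tf] = ((), 0.0)
    responses = pd.DataFrame(Y, index=X.index)
    return responses, categories, truth
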