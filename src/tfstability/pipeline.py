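"""End-to-end orchestration: from inputs (or a synthetic simulation) to the
variation-partitioning summary and the per-TF regression table.

The full analysis sequence is: sample selection -> SCG standardization ->
monthly interpolation / stability / z-scoring / collinearity pruning ->
distances / PCoA / polynomial spatial terms -> RDA model selection and
environment-vs-space variation partitioning -> per-TF stepwise regression
screen. ``run_full`` executes whichever stages its inputs require (providing
a downstream table bypasses the upstream stages) and writes every
intermediate table plus a JSON summary; ``run_demo`` wires the synthetic
generators into the same path.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import domain_counts as dc
from . import env_context as env
from . import ordination as ord_
from . import spatial as sp
from . import synthetic as syn
from . import tf_regression as tfr

__all__ = ["RunConfig", "run_full", "run_demo", "run_validation"]

log = logging.getLogger("tfstability")


@dataclass
class RunConfig:
    """Configuration of a full run; every threshold is the study default."""

    outdir: str = "tfstability_out"
    seed: int = 0
    # inputs (any stage's table may be given directly; None = derive or simulate)
    sites_csv: str | None = None
    climatology_files: list[str] = field(default_factory=list)
    domtblout_dir: str | None = None
    tf_counts_csv: str | None = None
    scg_counts_csv: str | None = None
    stability_csv: str | None = None
    distances_csv: str | None = None
    simulate: bool = True
    # thresholds
    evalue_max: float = 0.001
    coverage_fraction: float = 0.20
    bias_ratio: float = 10.0
    rho_threshold: float = 0.6
    r2_min: float = 0.3
    alpha_enter: float = 0.05
    p_max: float = 0.1
    # numerics
    idw_power: float = 2.0
    idw_neighbors: int = 4
    distance_mode: str = "great_circle"
    n_perm: int = 999
    n_perm_select: int = 199
    divisor: str = "mean"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(name, exc) from exc
            log.info("stage %-18s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_demo(config: RunConfig, spec: syn.SyntheticSpec | None = None) -> dict:
    """Synthetic end-to-end demo: generate the study conditions, then run
    the full analysis on them. Returns the summary dict (also written to
    ``outdir``)."""
    spec = spec or syn.SyntheticSpec(seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sites = syn.make_sites(spec)
    grids = {p: syn.make_climatology(spec, p) for p in syn.PARAMETER_DEFAULTS}
    stab = env.stability_table(grids, sites, config.idw_power, config.idw_neighbors)
    stab_z = env.zscore(env.StabilityTable(stab.data.dropna()))
    dm = sp.distance_matrix(sites, mode=config.distance_mode)
    coords = sp.pcoa(dm, k=2)
    gen = syn.make_counts(spec, stab_z, coords)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            _jsonable(
                {
                    "env_fraction": gen.truth["env_fraction"],
                    "space_fraction": gen.truth["space_fraction"],
                    "seed": spec.seed,
                }
            ),
            fh,
            indent=2,
            sort_keys=True,
        )
    env.write_sites(sites, outdir / "sites.csv")
    return _analyse(config, sites, gen.tf, gen.scg, stab, dm)


def run_full(config: RunConfig) -> dict:
    """Run the analysis from configured inputs (simulating any missing
    upstream stage when ``simulate`` is set)."""
    if config.simulate and not (config.tf_counts_csv and config.scg_counts_csv):
        return run_demo(config)
    sites = env.read_sites(config.sites_csv) if config.sites_csv else None
    tf = dc.CountMatrix(pd.read_csv(config.tf_counts_csv, index_col=0))
    scg = dc.CountMatrix(pd.read_csv(config.scg_counts_csv, index_col=0))
    stab = None
    if config.stability_csv:
        stab = env.StabilityTable(pd.read_csv(config.stability_csv, index_col=0))
    elif config.climatology_files and sites:
        grids = {}
        for f in config.climatology_files:
            g = env.read_climatology(f)
            grids[g.parameter] = g
        stab = env.stability_table(grids, sites, config.idw_power, config.idw_neighbors)
    if stab is None:
        raise StageError("stability", ValueError("no stability table or climatologies given"))
    dm = None
    if config.distances_csv:
        df = pd.read_csv(config.distances_csv, index_col=0)
        from skbio import DistanceMatrix

        dm = DistanceMatrix(df.to_numpy(), ids=list(df.index))
    elif sites:
        dm = sp.distance_matrix(sites, mode=config.distance_mode)
    else:
        raise StageError("spatial", ValueError("no distances or site coordinates given"))
    return _analyse(config, sites, tf, scg, stab, dm)


def _analyse(config, sites, tf, scg, stab, dm) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}

    retained_samples = list(scg.samples)
    exclusions: list[tuple[str, str]] = []
    if sites is not None:
        retained_samples, exclusions = _stage("select_samples")(dc.select_samples)(
            sites, scg
        )
    tf = dc.CountMatrix(tf.data[retained_samples], categories=tf.categories)
    scg = dc.CountMatrix(scg.data[retained_samples])
    tf_std = _stage("standardize")(dc.standardize_counts)(tf, scg, divisor=config.divisor)

    stab_data = stab.data.loc[[s for s in retained_samples if s in stab.data.index]].dropna()
    samples = list(stab_data.index)
    stab_z = _stage("zscore")(env.zscore)(env.StabilityTable(stab_data))
    retained_params, corr_report = _stage("prune_collinear")(env.prune_collinear)(
        stab_z, rho_threshold=config.rho_threshold
    )

    dm = dm.filter(samples)
    coords = _stage("pcoa")(sp.pcoa)(dm, k=2)
    terms = sp.spatial_terms(coords, degree=3)

    Y = tf_std.data.T.loc[samples]
    Y = Y.loc[:, Y.var(axis=0) > 0]
    env_cand = stab_z.data.loc[samples, retained_params]
    candidates = pd.concat([env_cand, terms.loc[samples]], axis=1)

    selected, trace = _stage("select_model")(ord_.select_model)(
        Y, candidates, alpha_enter=config.alpha_enter,
        n_perm=config.n_perm_select, seed=config.seed,
    )
    sel_env = [t for t in selected if t in env_cand.columns]
    sel_space = [t for t in selected if t not in env_cand.columns]
    # partition needs both sets: fall back to the pruned stability set and
    # the two linear axes when selection leaves one side empty
    part_env = sel_env or retained_params
    part_space = sel_space or ["X1", "X2"]
    part = _stage("variation_partition")(ord_.variation_partition)(
        Y, candidates[part_env], terms.loc[samples, part_space],
        n_perm=config.n_perm, seed=config.seed, labels=("environment", "space"),
    )
    within = None
    if len(part_env) >= 2:
        within = ord_.variation_partition(
            Y, candidates[[part_env[0]]], candidates[[part_env[1]]],
            n_perm=0, seed=config.seed,
            condition=terms.loc[samples, part_space],
            labels=(part_env[0], part_env[1]),
        )

    records = _stage("tf_regression")(tfr.screen_all)(
        Y, candidates, r2_min=config.r2_min, p_max=config.p_max,
        categories=(tf.categories.to_dict() if tf.categories is not None else {}),
    )

    # outputs
    stab.data.to_csv(outdir / "stability.csv")
    stab_z.data.to_csv(outdir / "stability_z.csv")
    corr_report.to_csv(outdir / "stability_correlations.csv", index=False)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(outdir / "distances.csv")
    pd.concat([coords.coords, terms], axis=1).iloc[:, [0, 1]].to_csv(outdir / "coords.csv")
    terms.to_csv(outdir / "spatial_terms.csv")
    tf.data.to_csv(outdir / "tf_counts_raw.csv")
    scg.data.to_csv(outdir / "scg_counts_raw.csv")
    tf_std.data.to_csv(outdir / "tf_counts_standardized.csv")
    tfr.records_to_table(records).to_csv(outdir / "tf_regression.csv", index=False)
    with open(outdir / "exclusions.txt", "w") as fh:
        for sid, reason in exclusions:
            fh.write(f"{sid}\t{reason}\n")

    summary.update(
        {
            "n_samples": len(samples),
            "excluded": [list(e) for e in exclusions],
            "retained_parameters": list(retained_params),
            "selected_terms": list(selected),
            "partition": part.as_dict(),
            "partition_within_environment": within.as_dict() if within else None,
            "n_tf_reported": len(records),
            "tf_regression": [
                {"tf": r.tf, "category": r.category, "r_squared": round(r.r_squared, 4),
                 "model": r.formula()}
                for r in records
            ],
        }
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    return summary


def run_validation(
    config: RunConfig,
    pairs: pd.DataFrame | None = None,
    exclude_salinity: tuple[str, ...] = ("GS033",),
) -> dict:
    """Interpolation-vs-shipboard validation report for temperature and
    salinity, with and without the configured exclusions.

    ``pairs`` must hold measured_/interpolated_ temperature and salinity
    columns indexed by sample; when omitted, the synthetic stand-in table
    is generated at the configured seed.
    """
    if pairs is None:
        pairs = syn.make_synthetic_validation_table(seed=config.seed)
    for col in ("measured_temperature", "interpolated_temperature"):
        if col not in pairs.columns:
            raise StageError("validate", ValueError(f"missing in-situ column {col!r}"))
    out: dict = {}
    r6 = lambda x: round(float(x), 6)  # noqa: E731 - report-precision rounding
    t = env.validate_interpolation(
        pairs.rename(
            columns={"measured_temperature": "measured", "interpolated_temperature": "interpolated"}
        ),
        "temperature",
    )
    out["temperature"] = {"r_squared": r6(t.r_squared), "slope": r6(t.slope),
                          "p_value": t.p_value, "n": t.n}
    if "measured_salinity" in pairs.columns:
        ren = pairs.rename(
            columns={"measured_salinity": "measured", "interpolated_salinity": "interpolated"}
        )
        s_all = env.validate_interpolation(ren, "salinity")
        s_excl = env.validate_interpolation(ren, "salinity", exclude=exclude_salinity)
        out["salinity_all"] = {"r_squared": r6(s_all.r_squared), "n": s_all.n}
        out["salinity"] = {
            "r_squared": r6(s_excl.r_squared),
            "slope": r6(s_excl.slope),
            "p_value": s_excl.p_value,
            "n": s_excl.n,
            "excluded": list(exclude_salinity),
        }
        for sid in exclude_salinity:
            if sid in pairs.index:
                row = pairs.loc[sid]
                out[f"{sid}_gaps"] = {
                    "salinity_psu": float(row["measured_salinity"] - row["interpolated_salinity"]),
                    "temperature_degc": float(
                        row["measured_temperature"] - row["interpolated_temperature"]
                    ),
                }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "validation.json", "w") as fh:
        json.dump(_jsonable(out), fh, indent=2, sort_keys=True)
    return out
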