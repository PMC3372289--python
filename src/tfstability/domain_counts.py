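"""From HMMER3 per-domain tables to SCG-standardized TF count matrices.

The raw evidence is HMMER3 ``--domtblout`` output from searching Pfam
profile HMMs (transcription-factor families and universal single-copy
genes) against six-frame translations of metagenomic reads. A hit is kept
as *significant* when all three criteria hold:

1. domain independent E-value < 0.001,
2. the alignment covers at least 20% of the model length
   (hmm_to - hmm_from >= 0.20 * model_length), and
3. the bias is at least an order of magnitude smaller than the score
   (bias * 10 <= score; ties pass).

Counts of significant hits per model and sample are standardized by a
per-sample statistic of the single-copy-gene (SCG) counts — by default the
mean, which estimates the number of genome equivalents in the sample — so
TF abundances become per-genome copy numbers comparable across samples of
very different sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .env_context import SampleSite

__all__ = [
    "DomainHit",
    "CountMatrix",
    "SCGDiagnostics",
    "SelectionRules",
    "DomtbloutParseError",
    "parse_domtblout",
    "filter_significant",
    "build_count_matrix",
    "scg_diagnostics",
    "select_samples",
    "standardize_counts",
    "load_tf_models",
    "load_scg_models",
]


class DomtbloutParseError(ValueError):
    """A malformed domtblout record, reported with its line number."""


@dataclass
class DomainHit:
    """One per-domain HMMER3 record (the fields the significance filter needs)."""

    sample_id: str
    read_id: str
    model_name: str
    model_length: int
    hmm_from: int
    hmm_to: int
    independent_evalue: float
    score: float
    bias: float

    def __post_init__(self) -> None:
        if not 1 <= self.hmm_from <= self.hmm_to <= self.model_length:
            raise ValueError(
                f"invalid hmm coordinates {self.hmm_from}..{self.hmm_to} "
                f"for model {self.model_name} (length {self.model_length})"
            )
        if self.independent_evalue < 0:
            raise ValueError("E-value must be >= 0")


@dataclass
class CountMatrix:
    """Model x sample count matrix, raw (integers) or SCG-standardized (reals).

    A standardized matrix records the divisor statistic and the per-sample
    divisors it was produced with.
    """

    data: pd.DataFrame
    kind: str = "raw"
    divisor_type: str | None = None
    divisors: pd.Series | None = None
    categories: pd.Series | None = None  # model -> "DBD" / "non-DBD"

    def __post_init__(self) -> None:
        if self.kind == "raw":
            arr = self.data.to_numpy()
            if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
                raise ValueError("raw counts must be non-negative integers")

    @property
    def models(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


# domtblout columns (fixed order, whitespace-separated, description last):
# 0 target name, 1 target acc, 2 tlen, 3 query name, 4 query acc, 5 qlen,
# 6 full E-value, 7 full score, 8 full bias, 9 #, 10 of, 11 c-Evalue,
# 12 i-Evalue, 13 dom score, 14 dom bias, 15 hmm from, 16 hmm to,
# 17 ali from, 18 ali to, 19 env from, 20 env to, 21 acc, 22 description
_N_FIELDS = 23


def parse_domtblout(stream: Iterable[str] | str, sample_id: str) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output ('#' comment lines ignored).

    Assumes the hmmsearch orientation: the query is the profile HMM (query
    name = model, qlen = model length) and the target is the translated
    read. Raises :class:`DomtbloutParseError` naming the offending line on
    malformed records.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    hits: list[DomainHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(None, _N_FIELDS - 1)
        if len(fields) < _N_FIELDS - 1:  # description column may be empty
            raise DomtbloutParseError(
                f"line {lineno}: expected >= {_N_FIELDS - 1} fields, got {len(fields)}"
            )
        try:
            hit = DomainHit(
                sample_id=sample_id,
                read_id=fields[0],
                model_name=fields[3],
                model_length=int(fields[5]),
                independent_evalue=float(fields[12]),
                score=float(fields[13]),
                bias=float(fields[14]),
                hmm_from=int(fields[15]),
                hmm_to=int(fields[16]),
            )
        except ValueError as exc:
            raise DomtbloutParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def filter_significant(
    hits: Iterable[DomainHit],
    coverage_fraction: float = 0.20,
    evalue_max: float = 0.001,
    bias_ratio: float = 10.0,
) -> list[DomainHit]:
    """Keep hits satisfying all three significance criteria (module docstring).

    Coverage uses hmm_to - hmm_from (without +1), with >= at the boundary;
    the bias criterion is bias * bias_ratio <= score, ties passing.
    """
    kept = []
    for h in hits:
        if h.model_length is None:
            raise ValueError(f"hit to {h.model_name} has no model length")
        if (
            h.independent_evalue < evalue_max
            and (h.hmm_to - h.hmm_from) >= coverage_fraction * h.model_length
            and h.bias * bias_ratio <= h.score
        ):
            kept.append(h)
    return kept


def build_count_matrix(
    hits: Iterable[DomainHit],
    model_list: Sequence[str],
    sample_list: Sequence[str],
    categories: Mapping[str, str] | None = None,
) -> tuple[CountMatrix, int]:
    """Count significant hits per (model, sample); each domain record counts once.

    Hits to models not in ``model_list`` are ignored; their number is
    returned alongside the matrix. Samples with no hits get all-zero
    columns.
    """
    if len(set(model_list)) != len(model_list):
        raise ValueError("duplicate model names in model_list")
    data = pd.DataFrame(0, index=list(model_list), columns=list(sample_list), dtype=int)
    ignored = 0
    for h in hits:
        if h.model_name not in data.index:
            ignored += 1
            continue
        if h.sample_id not in data.columns:
            raise ValueError(f"hit sample {h.sample_id!r} not in sample_list")
        data.loc[h.model_name, h.sample_id] += 1
    cats = pd.Series(categories).reindex(data.index) if categories else None
    return CountMatrix(data, kind="raw", categories=cats), ignored


@dataclass
class SCGDiagnostics:
    """Per-model over/under-representation flags and per-sample spread stats.

    Within each sample an SCG count is an outlier if it lies outside
    median +- 1.5 * IQR of that sample's SCG counts; a model is flagged
    over-/under-represented when it is a high/low outlier in more than half
    of the samples.
    """

    model_flags: pd.DataFrame  # index model: high_fraction, low_fraction, status
    sample_stats: pd.DataFrame  # index sample: mean, median, iqr, cv

    @property
    def overrepresented(self) -> list[str]:
        return list(self.model_flags.index[self.model_flags["status"] == "overrepresented"])

    @property
    def underrepresented(self) -> list[str]:
        return list(self.model_flags.index[self.model_flags["status"] == "underrepresented"])


def scg_diagnostics(scg: CountMatrix, flag_fraction: float = 0.5) -> SCGDiagnostics:
    df = scg.data
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need >= 2 SCG models and >= 2 samples")
    med = df.median(axis=0)
    q1, q3 = df.quantile(0.25, axis=0), df.quantile(0.75, axis=0)
    iqr = q3 - q1
    high = df.gt(med + 1.5 * iqr, axis=1)
    low = df.lt(med - 1.5 * iqr, axis=1)
    high_frac = high.mean(axis=1)
    low_frac = low.mean(axis=1)
    status = pd.Series("typical", index=df.index)
    status[high_frac > flag_fraction] = "overrepresented"
    status[low_frac > flag_fraction] = "underrepresented"
    mean = df.mean(axis=0)
    cv = df.std(axis=0, ddof=1) / mean.where(mean != 0, np.nan)
    model_flags = pd.DataFrame(
        {"high_fraction": high_frac, "low_fraction": low_frac, "status": status}
    )
    sample_stats = pd.DataFrame(
        {"mean": mean, "median": med, "iqr": iqr, "cv": cv.fillna(0.0)}
    )
    return SCGDiagnostics(model_flags, sample_stats)


@dataclass
class SelectionRules:
    """Sample inclusion rules for the prokaryote-targeted marine subset."""

    filter_min_um: float = 0.1
    filter_max_um: float = 0.8
    freshwater_keywords: tuple[str, ...] = ("fresh",)
    contaminated: tuple[str, ...] = ("GS000a",)
    max_mean_scg: float = 1.0  # exclude when mean SCG count <= this


def select_samples(
    sites: Sequence[SampleSite],
    scg: CountMatrix,
    rules: SelectionRules | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Apply the sample-exclusion rules; returns (retained ids, exclusion log).

    Excludes samples whose filter-size range falls outside the
    prokaryote-targeting window, freshwater habitats, samples on the named
    contamination list, and samples with a mean SCG count at or below
    ``max_mean_scg`` (too few sequences to standardize). One reason is
    logged per excluded sample, checked in that order.
    """
    rules = rules or SelectionRules()
    meta = {s.sample_id: s for s in sites}
    missing = [s for s in scg.samples if s not in meta]
    if missing:
        raise ValueError(f"samples in counts without metadata: {missing}")
    retained, log = [], []
    for sid in scg.samples:
        site = meta[sid]
        if site.filter_min_um < rules.filter_min_um or site.filter_max_um > rules.filter_max_um:
            log.append((sid, "filter size outside prokaryote range"))
            continue
        if any(k in site.habitat.lower() for k in rules.freshwater_keywords):
            log.append((sid, "freshwater habitat"))
            continue
        if sid in rules.contaminated:
            log.append((sid, "suspected contamination"))
            continue
        if float(scg.data[sid].mean()) <= rules.max_mean_scg:
            log.append((sid, "extremely low SCG counts"))
            continue
        retained.append(sid)
    return retained, log


def standardize_counts(
    tf: CountMatrix,
    scg: CountMatrix,
    divisor: str = "mean",
    k: float = 2.0,
) -> CountMatrix:
    """Divide each sample's TF counts by a statistic of its SCG counts.

    ``divisor`` is ``mean`` (genome equivalents; the default), or the
    sensitivity variants ``mean_plus_ksd`` / ``mean_minus_ksd`` at ``k``
    sample standard deviations. Raises when any divisor is <= 0 (an
    unusable sample).
    """
    samples = [s for s in tf.samples if s in scg.data.columns]
    if len(samples) != len(tf.samples):
        raise ValueError("every TF sample needs SCG counts")
    mean = scg.data[samples].mean(axis=0)
    sd = scg.data[samples].std(axis=0, ddof=1)
    if divisor == "mean":
        div = mean
    elif divisor == "mean_plus_ksd":
        div = mean + k * sd
    elif divisor == "mean_minus_ksd":
        div = mean - k * sd
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    bad = div[div <= 0]
    if len(bad):
        raise ValueError(f"non-positive divisor for sample(s): {list(bad.index)}")
    return CountMatrix(
        tf.data[samples] / div,
        kind="standardized",
        divisor_type=divisor if divisor == "mean" else f"{divisor}(k={k})",
        divisors=div,
        categories=tf.categories,
    )


def _read_model_table(name: str) -> pd.DataFrame:
    with resources.files("tfstability.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_tf_models() -> pd.DataFrame:
    """Packaged default TF model list: model_name, category (DBD / non-DBD),
    model_length. A curated, editable set of 65 prokaryotic regulator Pfam
    families (40 DNA-binding-domain models minus one with no usable hits,
    plus 26 associated effector/receiver domains)."""
    return _read_model_table("tf_models.tsv")


def load_scg_models() -> pd.DataFrame:
    """Packaged default single-copy-gene model list (53 universal,
    translation-dominated prokaryotic families): model_name, model_length."""
    return _read_model_table("scg_models.tsv")
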