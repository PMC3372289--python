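"""Per-TF multiple linear regression on stability and spatial predictors.

Each TF's SCG-standardized abundance across sites is regressed on the same
candidate terms as the ordination (z-scored stability measures, the PCoA
axes X1/X2 and their polynomial terms) with both-direction stepwise
selection minimizing the least-squares AIC

    AIC = n log(RSS / n) + 2 k,   k = number of terms + 1 (intercept),

starting from the intercept-only model. Models explaining enough variation
are then manually pruned: the least significant term is dropped while its
two-sided t-test p-value exceeds a cutoff (default 0.1), refitting each
time. The screen reports TFs whose final R^2 clears a threshold (default
0.3), grouped by DBD / non-DBD category.

Term p-values come from the final fit only (no selection-adjusted
inference); they are exploratory descriptors, not confirmatory tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StepwiseModel",
    "TFRegressionRecord",
    "stepwise_fit",
    "prune_terms",
    "screen_all",
    "records_to_table",
]

P_BINS = ((0.001, "p < 0.001"), (0.01, "p < 0.01"), (0.05, "p < 0.05"), (0.1, "p < 0.1"))


@dataclass
class StepwiseModel:
    """A stepwise-selected OLS model for one response."""

    terms: list[str]
    candidates: pd.DataFrame
    response: pd.Series
    coefficients: pd.Series
    term_pvalues: pd.Series
    r_squared: float
    model_pvalue: float
    aic: float
    n_steps: int = 0

    @property
    def n(self) -> int:
        return len(self.response)


def _ls_aic(rss: float, n: int, n_terms: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * (n_terms + 1)


def _ols(y: np.ndarray, X: pd.DataFrame, terms: Sequence[str]):
    design = sm.add_constant(X[list(terms)].to_numpy()) if terms else np.ones((len(y), 1))
    return sm.OLS(y, design).fit()


def _make_model(y: pd.Series, X: pd.DataFrame, terms: list[str], n_steps: int) -> StepwiseModel:
    fit = _ols(y.to_numpy(), X, terms)
    if terms:
        coefs = pd.Series(fit.params[1:], index=terms)
        pvals = pd.Series(fit.pvalues[1:], index=terms)
        r2 = float(fit.rsquared)
        mp = float(fit.f_pvalue)
    else:
        coefs = pd.Series(dtype=float)
        pvals = pd.Series(dtype=float)
        r2, mp = 0.0, 1.0
    return StepwiseModel(
        terms=list(terms),
        candidates=X,
        response=y,
        coefficients=coefs,
        term_pvalues=pvals,
        r_squared=r2,
        model_pvalue=mp,
        aic=_ls_aic(float(fit.ssr), len(y), len(terms)),
        n_steps=n_steps,
    )


def stepwise_fit(y: pd.Series, candidates: pd.DataFrame, max_steps: int = 1000) -> StepwiseModel:
    """Both-direction stepwise least squares minimizing AIC.

    Starts from the intercept-only model; at each step the single addition
    or removal with the lowest AIC is taken if it improves on the current
    model, for at most ``max_steps`` steps. Deterministic given the
    candidate column order (ties break on order: removals before additions,
    then first column).
    """
    y = pd.Series(y)
    X = candidates.reindex(y.index)
    if float(np.var(y.to_numpy())) == 0.0:
        # a constant response carries no signal: intercept-only, R^2 = 0
        return _make_model(y, X, [], 0)
    if X.isna().any().any():
        raise ValueError("candidates must cover every observation of y")
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    terms: list[str] = []
    rss = float(np.sum((yv - yv.mean()) ** 2))
    current_aic = _ls_aic(rss, n, 0)
    steps = 0
    while steps < max_steps:
        moves: list[tuple[float, int, str, list[str]]] = []
        for i, t in enumerate(terms):  # removals first in tie order
            cand = [u for u in terms if u != t]
            fit = _ols(yv, X, cand)
            moves.append((_ls_aic(float(fit.ssr), n, len(cand)), i, "drop", cand))
        offset = len(terms)
        for i, t in enumerate(c for c in X.columns if c not in terms):
            cand = terms + [t]
            if n <= len(cand) + 1:
                continue
            fit = _ols(yv, X, cand)
            moves.append((_ls_aic(float(fit.ssr), n, len(cand)), offset + i, "add", cand))
        if not moves:
            break
        best = min(moves, key=lambda m: (m[0], m[1]))
        if best[0] < current_aic - 1e-10:
            current_aic, terms = best[0], best[3]
            steps += 1
        else:
            break
    return _make_model(y, X, terms, steps)


def prune_terms(model: StepwiseModel, p_max: float = 0.1) -> StepwiseModel:
    """Iteratively drop the least significant term while its p exceeds ``p_max``.

    Refits after each removal; stops when every remaining term has
    p <= p_max or the model is intercept-only. Idempotent.
    """
    terms = list(model.terms)
    y, X = model.response, model.candidates
    current = model
    while terms:
        worst = current.term_pvalues.idxmax()
        if current.term_pvalues[worst] <= p_max:
            break
        terms.remove(worst)
        current = _make_model(y, X, terms, current.n_steps)
    if not terms and current.terms:
        current = _make_model(y, X, [], current.n_steps)
    return current


@dataclass
class TFRegressionRecord:
    """One row of the per-TF regression screen."""

    tf: str
    category: str
    terms: list[str]
    term_pvalues: dict[str, float]
    r_squared: float
    model_pvalue: float

    def formula(self) -> str:
        if not self.terms:
            return "(intercept only)"
        return " + ".join(f"{t} ({_bin_p(self.term_pvalues[t])})" for t in self.terms)


def _bin_p(p: float) -> str:
    for cut, label in P_BINS:
        if p < cut:
            return label
    return "n.s."


def screen_all(
    Y: pd.DataFrame,
    candidates: pd.DataFrame,
    r2_min: float = 0.3,
    p_max: float = 0.1,
    categories: Mapping[str, str] | None = None,
    max_steps: int = 1000,
) -> list[TFRegressionRecord]:
    """Stepwise-fit + prune every TF; report those with final R^2 > ``r2_min``.

    ``Y`` is sites x TFs (standardized abundances); ``categories`` maps TF
    name to "DBD"/"non-DBD". Records are sorted by R^2 ascending within
    category, non-DBD first.
    """
    categories = dict(categories or {})
    records = []
    for tf in Y.columns:
        y = Y[tf]
        if float(np.var(y.to_numpy())) == 0.0:
            continue
        model = prune_terms(stepwise_fit(y, candidates, max_steps=max_steps), p_max=p_max)
        if model.r_squared > r2_min and model.terms:
            records.append(
                TFRegressionRecord(
                    tf=tf,
                    category=categories.get(tf, "unknown"),
                    terms=list(model.terms),
                    term_pvalues=model.term_pvalues.to_dict(),
                    r_squared=model.r_squared,
                    model_pvalue=model.model_pvalue,
                )
            )
    cat_order = {"non-DBD": 0, "DBD": 1}
    records.sort(key=lambda r: (cat_order.get(r.category, 2), r.r_squared))
    return records


def records_to_table(records: Sequence[TFRegressionRecord]) -> pd.DataFrame:
    """Tabular report: tf, category, model formula with p-value bins, R^2,
    model p-value."""
    return pd.DataFrame(
        [
            {
                "tf": r.tf,
                "category": r.category,
                "model": r.formula(),
                "r_squared": round(r.r_squared, 2),
                "model_p_value": r.model_pvalue,
            }
            for r in records
        ]
    )
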