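"""Redundancy analysis (RDA), permutation tests and variation partitioning.

RDA is the multivariate extension of linear regression used here to
quantify how much of the between-sample variation in standardized TF
abundances is explained by environment-stability measures and by spatial
predictors. The response matrix Y (sites x TFs) is column-centered and
projected onto the predictor column space by least squares; the canonical
axes are the principal components of the fitted matrix and

    R^2 = SS(fitted) / SS(total),
    adjusted R^2 = 1 - (1 - R^2) (n - 1) / (n - m - 1),

with n sites and m predictor terms. Significance is assessed with the
pseudo-F statistic

    F = (SS(fitted) / m) / (SS(residual) / (n - m - 1))

under permutation of the response rows (residual permutation under the
reduced model for partial tests). Variation partitioning decomposes the
adjusted R^2 of the combined model into fractions unique to predictor set
A ([a]), unique to set B ([c]), shared ([b]) and residual ([d]):

    [a] = adjR2(A+B) - adjR2(B),  [c] = adjR2(A+B) - adjR2(A),
    [b] = adjR2(A) + adjR2(B) - adjR2(A+B),  [d] = 1 - adjR2(A+B).

Everything in this module is implemented from first principles on numpy
linear algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "RDAModel",
    "PartitionResult",
    "rda_fit",
    "permutation_test",
    "partial_permutation_test",
    "select_model",
    "variation_partition",
]


def _centered(df: pd.DataFrame) -> pd.DataFrame:
    return df - df.mean(axis=0)


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, pd.Series):
        return x.to_frame()
    return pd.DataFrame(x)


@dataclass
class RDAModel:
    """A fitted redundancy analysis."""

    response: pd.DataFrame  # centered Y
    predictors: pd.DataFrame  # centered X
    coefficients: pd.DataFrame
    fitted: pd.DataFrame
    residuals: pd.DataFrame
    eigenvalues: np.ndarray  # canonical eigenvalues, decreasing
    r_squared: float
    adj_r_squared: float
    pseudo_f: float
    n: int
    m: int
    permutation_p: float | None = None

    def scores(self, scaling: int = 2, k: int | None = None):
        """Site and TF (species) scores from the SVD of the fitted matrix.

        Scaling 1 preserves inter-site distances (site scores U*S, TF
        scores V); scaling 2 — used for TF-focused biplots — scales the TF
        scores instead (site scores U, TF scores V*S).
        """
        u, s, vt = np.linalg.svd(self.fitted.to_numpy(), full_matrices=False)
        k = min(k or self.m, int(np.sum(s > s[0] * 1e-12)) if s.size else 0)
        u, s, v = u[:, :k], s[:k], vt[:k].T
        if scaling == 1:
            site, species = u * s, v
        elif scaling == 2:
            site, species = u, v * s
        else:
            raise ValueError("scaling must be 1 or 2")
        axes = [f"RDA{i + 1}" for i in range(k)]
        return (
            pd.DataFrame(site, index=self.response.index, columns=axes),
            pd.DataFrame(species, index=self.response.columns, columns=axes),
        )


def _fit_core(Yc: np.ndarray, Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of centered response on centered predictors.

    Returns (coefficients, fitted). Raises on rank-deficient predictors.
    """
    if Xc.shape[1] == 0:
        return np.zeros((0, Yc.shape[1])), np.zeros_like(Yc)
    norms = np.linalg.norm(Xc, axis=0)
    if np.any(norms == 0):
        raise ValueError("constant predictor column (zero variance after centering)")
    Xs = Xc / norms  # unit columns: rank check independent of term units
    q, r = np.linalg.qr(Xs)
    if np.min(np.abs(np.diag(r))) < 1e-8:
        raise ValueError("rank-deficient predictor matrix (collinear terms)")
    coef = np.linalg.solve(r, q.T @ Yc) / norms[:, None]
    return coef, Xc @ coef


def rda_fit(Y: pd.DataFrame, X: pd.DataFrame) -> RDAModel:
    """Fit an RDA of response matrix ``Y`` on predictor table ``X``.

    Rows of both tables are sites (must align); Y columns are TFs, X
    columns are terms. Y is column-centered; X is centered so the intercept
    is implicit.
    """
    Y, X = _as_frame(Y), _as_frame(X)
    if not Y.index.equals(X.index):
        X = X.reindex(Y.index)
        if X.isna().any().any():
            raise ValueError("X and Y must cover the same sites")
    n, m = len(Y), X.shape[1]
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m} terms)")
    if Y.isna().any().any() or X.isna().any().any():
        raise ValueError("missing cells are not allowed")
    Yc, Xc = _centered(Y), _centered(X)
    coef, fitted = _fit_core(Yc.to_numpy(), Xc.to_numpy())
    resid = Yc.to_numpy() - fitted
    ss_total = float(np.sum(Yc.to_numpy() ** 2))
    if ss_total <= 0:
        raise ValueError("response has zero total variance")
    ss_fit = float(np.sum(fitted**2))
    r2 = ss_fit / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    ss_res = ss_total - ss_fit
    f = (ss_fit / m) / (ss_res / (n - m - 1)) if m > 0 and ss_res > 0 else np.inf
    s = np.linalg.svd(fitted, compute_uv=False)
    eig = (s**2) / (n - 1)
    return RDAModel(
        response=Yc,
        predictors=Xc,
        coefficients=pd.DataFrame(coef, index=X.columns, columns=Y.columns),
        fitted=pd.DataFrame(fitted, index=Y.index, columns=Y.columns),
        residuals=pd.DataFrame(resid, index=Y.index, columns=Y.columns),
        eigenvalues=eig[: max(m, 0)],
        r_squared=r2,
        adj_r_squared=adj,
        pseudo_f=f,
        n=n,
        m=m,
    )


def _hat(Xc: np.ndarray) -> np.ndarray:
    if Xc.shape[1] == 0:
        return np.zeros((Xc.shape[0], Xc.shape[0]))
    norms = np.linalg.norm(Xc, axis=0)
    q, _ = np.linalg.qr(Xc / np.where(norms == 0, 1.0, norms))
    return q @ q.T


def permutation_test(
    model: RDAModel, n_perm: int = 1000, seed: int | np.random.Generator | None = None
) -> float:
    """Permutation p-value for a fitted RDA.

    Permutes the rows of the (centered) response, recomputes pseudo-F each
    time, and returns p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Yc = model.response.to_numpy()
    h = _hat(model.predictors.to_numpy())
    n, m = model.n, model.m
    ss_total = float(np.sum(Yc**2))
    f_obs = model.pseudo_f
    count = 0
    for _ in range(int(n_perm)):
        yp = Yc[rng.permutation(n)]
        ss_fit = float(np.sum((h @ yp) ** 2))
        ss_res = ss_total - ss_fit
        f = (ss_fit / m) / (ss_res / (n - m - 1)) if ss_res > 0 else np.inf
        if f >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + int(n_perm))
    model.permutation_p = p
    return p


def partial_permutation_test(
    Y: pd.DataFrame,
    X_test: pd.DataFrame,
    Z: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test of the marginal (partial) effect of ``X_test`` given
    covariables ``Z``.

    The statistic is the partial pseudo-F for the terms of X_test in the
    full model [Z, X_test]. Permutations follow the reduced-model residual
    scheme: residuals of Y on Z are permuted and added back to the fitted
    part, so the covariable structure is preserved under the null. Returns
    (F_observed, p).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y, X_test = _as_frame(Y), _as_frame(X_test)
    Yc = _centered(Y).to_numpy()
    Xt = _centered(X_test.reindex(Y.index)).to_numpy()
    if Z is not None and _as_frame(Z).shape[1] > 0:
        Zc = _centered(_as_frame(Z).reindex(Y.index)).to_numpy()
    else:
        Zc = np.zeros((len(Y), 0))
    n = len(Y)
    m_t, m_z = Xt.shape[1], Zc.shape[1]
    m_full = m_t + m_z
    if n <= m_full + 1:
        raise ValueError("too few sites for the full model")
    h_z = _hat(Zc)
    h_full = _hat(np.hstack([Zc, Xt]))
    fit_z = h_z @ Yc
    resid_z = Yc - fit_z
    ss_total = float(np.sum(Yc**2))

    def partial_f(y: np.ndarray) -> float:
        ss_z = float(np.sum((h_z @ y) ** 2))
        ss_full = float(np.sum((h_full @ y) ** 2))
        ss_res = float(np.sum(y**2)) - ss_full
        if ss_res <= 0:
            return np.inf
        return ((ss_full - ss_z) / m_t) / (ss_res / (n - m_full - 1))

    f_obs = partial_f(Yc)
    count = 0
    for _ in range(int(n_perm)):
        ystar = fit_z + resid_z[rng.permutation(n)]
        if partial_f(ystar) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (1 + int(n_perm))


def _adj_r2(Y: pd.DataFrame, X: pd.DataFrame | None) -> tuple[float, float]:
    """(raw R2, adjusted R2) of Y on X; (0, 0) for an empty predictor set."""
    if X is None or _as_frame(X).shape[1] == 0:
        return 0.0, 0.0
    model = rda_fit(Y, X)
    return model.r_squared, model.adj_r_squared


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)


def select_model(
    Y: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    n_perm: int = 199,
    seed: int | None = 0,
    max_iter: int = 100,
) -> tuple[list[str], SelectionTrace]:
    """Forward/backward selection of RDA terms by partial permutation tests.

    Forward steps add the candidate with the smallest marginal permutation
    p-value, provided p <= ``alpha_enter`` and the adjusted R^2 of the
    growing model does not exceed that of the full-candidate (scope) model;
    backward steps drop the term with the largest partial p when it rises
    above ``alpha_enter``. Iterates to a fixed point. Deterministic given
    the seed and the candidate column order (ties break on column order).
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate term")
    rng = np.random.default_rng(seed)
    scope_adj = _adj_r2(Y, candidates)[1]
    selected: list[str] = []
    trace = SelectionTrace()
    for _ in range(max_iter):
        changed = False
        # forward
        remaining = [c for c in candidates.columns if c not in selected]
        best: tuple[float, int, str] | None = None
        for idx, c in enumerate(remaining):
            z = candidates[selected] if selected else None
            _, p = partial_permutation_test(
                Y, candidates[[c]], z, n_perm=n_perm, seed=rng
            )
            if best is None or (p, idx) < (best[0], best[1]):
                best = (p, idx, c)
        if best is not None and best[0] <= alpha_enter:
            cand_set = selected + [best[2]]
            if _adj_r2(Y, candidates[cand_set])[1] <= scope_adj + 1e-12:
                selected.append(best[2])
                trace.steps.append({"action": "add", "term": best[2], "p": best[0]})
                changed = True
        # backward
        while len(selected) > 1:
            worst: tuple[float, str] | None = None
            for c in selected:
                others = [t for t in selected if t != c]
                _, p = partial_permutation_test(
                    Y, candidates[[c]], candidates[others], n_perm=n_perm, seed=rng
                )
                if worst is None or p > worst[0]:
                    worst = (p, c)
            if worst is not None and worst[0] > alpha_enter:
                selected.remove(worst[1])
                trace.steps.append({"action": "drop", "term": worst[1], "p": worst[0]})
                changed = True
            else:
                break
        if not changed:
            break
    return selected, trace


@dataclass
class PartitionResult:
    """Adjusted-R^2 variation partitioning between two predictor sets.

    Fractions: ``env_only`` [a] unique to set A, ``shared`` [b],
    ``space_only`` [c] unique to set B, ``residual`` [d]. When a
    ``condition`` table was supplied its own share is in ``conditioned``
    and the identity a+b+c+d+conditioned = 1 holds.
    """

    env_only: float
    shared: float
    space_only: float
    residual: float
    conditioned: float = 0.0
    raw: dict = field(default_factory=dict)
    p_full: float | None = None
    p_env: float | None = None
    p_space: float | None = None
    n: int = 0
    labels: tuple[str, str] = ("A", "B")

    def as_dict(self) -> dict:
        return {
            "env_only": self.env_only,
            "shared": self.shared,
            "space_only": self.space_only,
            "residual": self.residual,
            "conditioned": self.conditioned,
            "raw": dict(self.raw),
            "p_full": self.p_full,
            "p_env": self.p_env,
            "p_space": self.p_space,
            "n": self.n,
        }


def variation_partition(
    Y: pd.DataFrame,
    set_A: pd.DataFrame,
    set_B: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
    condition: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> PartitionResult:
    """Partition the variation of Y between predictor sets A and B.

    Fractions are adjusted R^2 (raw-R^2 analogues are reported alongside in
    ``raw``). Testable fractions — the combined model, A given B, and B
    given A — receive reduced-model permutation p-values when
    ``n_perm`` > 0. An optional ``condition`` table is partialled into
    every model (its own adjusted share is reported separately).
    """
    set_A, set_B = _as_frame(set_A), _as_frame(set_B)
    overlap = set(set_A.columns) & set(set_B.columns)
    if overlap:
        raise ValueError(f"sets A and B share terms: {sorted(overlap)}")
    cond = _as_frame(condition) if condition is not None else None

    def with_cond(X: pd.DataFrame | None) -> pd.DataFrame | None:
        parts = [p for p in (cond, X) if p is not None and p.shape[1] > 0]
        if not parts:
            return None
        return pd.concat(parts, axis=1)

    base_raw, base_adj = _adj_r2(Y, cond) if cond is not None else (0.0, 0.0)
    ab = pd.concat([set_A, set_B], axis=1) if set_B.shape[1] else set_A
    r_ab, g_ab = _adj_r2(Y, with_cond(ab))
    r_a, g_a = _adj_r2(Y, with_cond(set_A))
    r_b, g_b = (_adj_r2(Y, with_cond(set_B)) if set_B.shape[1] else (base_raw, base_adj))

    a = g_ab - g_b
    c = g_ab - g_a
    b = g_a + g_b - g_ab - base_adj
    d = 1.0 - g_ab
    raw = {
        "env_only": r_ab - r_b,
        "space_only": r_ab - r_a,
        "shared": r_a + r_b - r_ab - base_raw,
        "residual": 1.0 - r_ab,
        "combined_r2": r_ab,
        "combined_adj_r2": g_ab,
    }
    res = PartitionResult(
        env_only=a,
        shared=b,
        space_only=c,
        residual=d,
        conditioned=base_adj,
        raw=raw,
        n=len(Y),
        labels=labels,
    )
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        _, res.p_full = partial_permutation_test(Y, ab, cond, n_perm=n_perm, seed=rng)
        _, res.p_env = partial_permutation_test(
            Y, set_A, with_cond(set_B), n_perm=n_perm, seed=rng
        )
        if set_B.shape[1]:
            _, res.p_space = partial_permutation_test(
                Y, set_B, with_cond(set_A), n_perm=n_perm, seed=rng
            )
    return res
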