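"""Regression, permutation and multiple-testing machinery.

This module carries the confirmatory half of the pipeline:

* ordinary least squares with backward model selection by nested F-tests
  (marginality respected: a main effect is never dropped while its
  interaction stays);
* interaction prediction profiles — the family of fitted lines obtained by
  holding a moderator at a grid of values between 0 and its observed
  maximum;
* PERMANOVA with sequential sums of squares on a Gower-centered distance
  matrix, pseudo-F tested by free permutation of sample labels;
* partial distance-based redundancy analysis (db-RDA / CAP): the variance of
  a "Condition" covariate is projected out of the centered inner-product
  matrix first, the remainder is decomposed into a constrained part (the
  span of the constraint covariates) and a residual, and constraint
  significance is assessed by permuting the conditioned matrix;
* an OTU screen correlating every taxon with every latent factor, with
  Benjamini–Yekutieli false-discovery-rate control (valid under arbitrary
  dependence between taxa).

Permutation p-values use the (1 + exceedances) / (1 + n_perm) convention so
they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import (
    CollinearityError,
    DegenerateInputError,
    InvalidArgumentError,
)
from .metrics import DistanceMatrix

__all__ = [
    "LinearFit", "ols_fit", "fit_terms", "backward_select",
    "prediction_profile", "permanova", "partial_dbrda",
    "correlation_screen", "by_adjust", "OrdinationResult",
]


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """An OLS fit with enough bookkeeping to refit and predict."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    df_resid: int
    rsquared: float
    fvalue: float
    f_pvalue: float
    nobs: int
    ssr: float                      # residual sum of squares
    terms: list[str]                # model terms (column groups)
    term_columns: dict[str, list[str]]
    levels: dict[str, list]         # categorical level sets seen in training
    description: str = ""
    path: list[dict] = field(default_factory=list)

    def predict(self, data: pd.DataFrame) -> pd.Series:
        X = _build_design(data, self.terms, self.levels)
        X.insert(0, "Intercept", 1.0)
        X = X.reindex(columns=self.params.index, fill_value=0.0)
        return pd.Series(X.to_numpy() @ self.params.to_numpy(), index=data.index)


def _is_categorical(col: pd.Series) -> bool:
    return (col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == bool)


def _factor_block(data: pd.DataFrame, name: str,
                  levels: dict[str, list]) -> pd.DataFrame:
    col = data[name]
    if _is_categorical(col):
        if name in levels:
            cats = levels[name]
        else:
            cats = sorted(pd.unique(col.dropna()))
            levels[name] = list(cats)
        codes = pd.Categorical(col, categories=cats)
        dummies = pd.get_dummies(codes, prefix=name, drop_first=True)
        dummies.index = data.index
        return dummies.astype(float)
    return pd.DataFrame({name: col.astype(float)}, index=data.index)


def _term_block(data: pd.DataFrame, term: str,
                levels: dict[str, list]) -> pd.DataFrame:
    parts = term.split(":")
    block = _factor_block(data, parts[0], levels)
    for part in parts[1:]:
        nxt = _factor_block(data, part, levels)
        cols = {}
        for c1 in block.columns:
            for c2 in nxt.columns:
                cols[f"{c1}:{c2}"] = block[c1] * nxt[c2]
        block = pd.DataFrame(cols, index=data.index)
    return block


def _build_design(data: pd.DataFrame, terms: list[str],
                  levels: dict[str, list]) -> pd.DataFrame:
    blocks = [_term_block(data, t, levels) for t in terms]
    if not blocks:
        return pd.DataFrame(index=data.index)
    return pd.concat(blocks, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        _, _, piv = linalg.qr(Xv, mode="economic", pivoting=True)
        aliased = [X.columns[i] for i in piv[rank:]]
        raise CollinearityError(aliased)


def ols_fit(y, design: pd.DataFrame, terms: list[str] | None = None,
            term_columns: dict[str, list[str]] | None = None,
            levels: dict[str, list] | None = None) -> LinearFit:
    """Least squares of ``y`` on a labelled design matrix (intercept added).

    Raises :class:`CollinearityError` naming the aliased columns when the
    design (with intercept) is rank deficient.
    """
    yv = pd.Series(np.asarray(y, dtype=float),
                   index=design.index if len(design.index) else None)
    X = design.astype(float).copy()
    X.insert(0, "Intercept", 1.0)
    if len(yv) <= X.shape[1] - 1:
        raise InvalidArgumentError("need n > number of predictors")
    _check_rank(X)
    res = sm.OLS(yv.to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    return LinearFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        fvalue=float(res.fvalue) if X.shape[1] > 1 else float("nan"),
        f_pvalue=float(res.f_pvalue) if X.shape[1] > 1 else float("nan"),
        nobs=int(res.nobs),
        ssr=float(res.ssr),
        terms=list(terms) if terms is not None else list(design.columns),
        term_columns=dict(term_columns or
                          {c: [c] for c in design.columns}),
        levels=dict(levels or {}),
        description=" + ".join(terms or list(design.columns)) or "1",
    )


def fit_terms(y, data: pd.DataFrame, terms: list[str]) -> LinearFit:
    """Fit ``y ~ term1 + term2 + ...`` where terms name columns of ``data``
    and ``a:b`` denotes an interaction; categoricals are dummy-coded."""
    levels: dict[str, list] = {}
    blocks = {t: _term_block(data, t, levels) for t in terms}
    design = (pd.concat(blocks.values(), axis=1) if blocks
              else pd.DataFrame(index=data.index))
    return ols_fit(y, design, terms=terms,
                   term_columns={t: list(b.columns) for t, b in blocks.items()},
                   levels=levels)


def _nested_f(full: LinearFit, reduced: LinearFit) -> tuple[float, float]:
    df_num = reduced.df_resid - full.df_resid
    if df_num <= 0:
        return float("nan"), float("nan")
    fstat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    return fstat, float(f_dist.sf(fstat, df_num, full.df_resid))


def _contains(term: str, other: str) -> bool:
    """True when ``other`` is a higher-order term involving ``term``."""
    a, b = set(term.split(":")), set(other.split(":"))
    return a < b


def backward_select(y, data: pd.DataFrame, terms: list[str],
                    alpha_drop: float = 0.05) -> LinearFit:
    """Backward elimination by nested F-tests.

    At each step, every droppable term (one not contained in a remaining
    interaction) is tested by comparing the model with and without it; the
    least significant term is removed while its p-value exceeds
    ``alpha_drop``. The elimination path is kept on the returned fit.
    """
    current = list(terms)
    path: list[dict] = []
    fit = fit_terms(y, data, current)
    while current:
        droppable = [t for t in current
                     if not any(_contains(t, o) for o in current if o != t)]
        tested = []
        for t in droppable:
            reduced = fit_terms(y, data, [u for u in current if u != t])
            _, p = _nested_f(fit, reduced)
            tested.append((t, p, reduced))
        t_max, p_max, reduced = max(tested, key=lambda x: (x[1], x[0]))
        if not np.isnan(p_max) and p_max > alpha_drop:
            path.append({"dropped": t_max, "p_drop": p_max,
                         "remaining": [u for u in current if u != t_max]})
            current.remove(t_max)
            fit = reduced
        else:
            break
    fit.path = path
    return fit


def prediction_profile(fit: LinearFit, data: pd.DataFrame, focal: str,
                       moderator: str, steps: int = 100,
                       focal_steps: int = 25) -> pd.DataFrame:
    """Predicted response over the focal range at a grid of moderator values.

    The moderator runs from 0 to its observed maximum in ``steps`` values
    (one fitted line each); every other covariate is held at its reference
    (mean for numeric, most frequent level for categorical). Requires the
    focal-by-moderator interaction in the fitted model.
    """
    inter = {focal, moderator}
    if not any(set(t.split(":")) == inter for t in fit.terms):
        raise InvalidArgumentError(
            f"model lacks the {focal}:{moderator} interaction")
    mod_grid = np.linspace(0.0, float(data[moderator].max()), steps)
    foc_grid = np.linspace(float(data[focal].min()),
                           float(data[focal].max()), focal_steps)

    ref = {}
    for name in {p for t in fit.terms for p in t.split(":")}:
        col = data[name]
        ref[name] = (col.mode().iloc[0] if _is_categorical(col)
                     else float(col.mean()))

    frames = []
    for mv in mod_grid:
        newdata = pd.DataFrame([ref] * focal_steps)
        newdata[focal] = foc_grid
        newdata[moderator] = mv
        pred = fit.predict(newdata)
        frames.append(pd.DataFrame({
            "moderator_value": mv,
            "focal_value": foc_grid,
            "predicted": pred.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# distance-matrix tests
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, abs(R[0, 0]))))
    Q = Q[:, :rank]
    return Q @ Q.T


def permanova(dist: DistanceMatrix, data: pd.DataFrame, terms: list[str],
              n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Permutational multivariate ANOVA with sequential sums of squares.

    The squared distance matrix is Gower-centered; each term's SS is the
    trace of the centered matrix against the increment in projection (hat)
    matrices as terms enter in the given order. Pseudo-F compares each
    term's mean square to the residual mean square of the full model, and
    p-values come from freely permuting sample labels (rows and columns of
    the centered matrix together).
    """
    ids = dist.sample_ids
    data = data.reindex(ids)
    if data.isna().any().any():
        raise InvalidArgumentError("covariates missing for some samples")
    D = dist.values.to_numpy()
    n = D.shape[0]
    G = _gower_center(D)

    levels: dict[str, list] = {}
    X = np.ones((n, 1))
    H_prev = _hat(X)
    increments, dfs = [], []
    rank_prev = 1
    for term in terms:
        block = _term_block(data, term, levels).to_numpy(dtype=float)
        X = np.hstack([X, block])
        rank_new = np.linalg.matrix_rank(X)
        if rank_new == rank_prev:
            raise CollinearityError([term])
        H_new = _hat(X)
        increments.append(H_new - H_prev)
        dfs.append(rank_new - rank_prev)
        H_prev, rank_prev = H_new, rank_new
    M_res = np.eye(n) - H_prev
    df_res = n - rank_prev
    if df_res < 1:
        raise InvalidArgumentError("no residual degrees of freedom")

    ss_terms = np.array([float(np.sum(Hi * G)) for Hi in increments])
    ss_res = float(np.sum(M_res * G))
    ss_total = float(np.trace(G))
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ssp = np.array([float(np.sum(Hi * Gp)) for Hi in increments])
        ssr = float(np.sum(M_res * Gp))
        fp = (ssp / np.array(dfs)) / (ssr / df_res)
        exceed += fp >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append({"term": term, "df": dfs[i], "ss": ss_terms[i],
                     "pseudo_f": f_obs[i], "r2": ss_terms[i] / ss_total,
                     "p_value": pvals[i]})
    rows.append({"term": "Residual", "df": df_res, "ss": ss_res,
                 "pseudo_f": np.nan, "r2": ss_res / ss_total,
                 "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total,
                 "pseudo_f": np.nan, "r2": 1.0, "p_value": np.nan})
    out = pd.DataFrame(rows)
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out


@dataclass
class OrdinationResult:
    """A (possibly partial) distance-based RDA decomposition."""

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    biplot: pd.DataFrame
    conditioned_inertia: float
    constrained_inertia: float
    residual_inertia: float
    pseudo_f: float
    p_value: float
    n_perm: int
    seed: int


def partial_dbrda(dist: DistanceMatrix, constraints: pd.DataFrame,
                  condition: pd.DataFrame | None = None,
                  n_perm: int = 999, seed: int = 0) -> OrdinationResult:
    """Constrained ordination of a distance matrix, optionally after
    partialling out a Condition covariate block.

    The Gower-centered matrix is first residualized on the condition block
    (its variance is removed before anything else is considered); the
    remaining matrix is projected onto the span of the (condition-adjusted,
    centered) constraints, and the projection is eigen-decomposed to give
    the constrained axes. Significance of the constraints comes from
    permuting the conditioned matrix, i.e. permutation of residuals under
    the reduced (condition-only) model.
    """
    ids = dist.sample_ids
    n = len(ids)
    G = _gower_center(dist.values.to_numpy())
    levels: dict[str, list] = {}

    def _numeric_block(df: pd.DataFrame) -> np.ndarray:
        blocks = [_factor_block(df.reindex(ids), c, levels) for c in df.columns]
        M = pd.concat(blocks, axis=1).to_numpy(dtype=float)
        return M - M.mean(axis=0)

    if condition is not None and condition.shape[1] > 0:
        C = _numeric_block(condition)
        rank_c = np.linalg.matrix_rank(C)
        if rank_c < C.shape[1]:
            raise CollinearityError(list(condition.columns),
                                    "condition block is rank deficient")
        Hc = _hat(C)
        P = np.eye(n) - Hc
        Gr = P @ G @ P
        conditioned = float(np.trace(G) - np.trace(Gr))
    else:
        C, rank_c = None, 0
        P = np.eye(n)
        Gr = G
        conditioned = 0.0

    Xr = P @ _numeric_block(constraints)
    q = np.linalg.matrix_rank(Xr)
    if q < Xr.shape[1]:
        raise CollinearityError(list(constraints.columns))
    Hx = _hat(Xr)

    constrained = float(np.sum(Hx * Gr))
    residual = float(np.trace(Gr) - constrained)
    df_res = n - q - rank_c - 1
    if df_res < 1:
        raise InvalidArgumentError("no residual degrees of freedom")
    if abs(residual) < 1e-12:       # degenerate: nothing left to test against
        f_obs, p_value = float("nan"), float("nan")
    else:
        f_obs = (constrained / q) / (residual / df_res)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = Gr[np.ix_(perm, perm)]
            cp = float(np.sum(Hx * Gp))
            rp = float(np.trace(Gp) - cp)
            if rp != 0 and (cp / q) / (rp / df_res) >= f_obs:
                exceed += 1
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    M = Hx @ Gr @ Hx
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-10, 1e-10 * abs(vals[0])) if vals.size else vals > 0
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(vals)[None, :]
    axes = [f"CAP{i + 1}" for i in range(coords.shape[1])]
    site = pd.DataFrame(coords, index=ids, columns=axes)

    Xb = _numeric_block(constraints)
    bip = np.zeros((Xb.shape[1], coords.shape[1]))
    for j in range(Xb.shape[1]):
        for a in range(coords.shape[1]):
            sx, sa = Xb[:, j].std(), coords[:, a].std()
            bip[j, a] = (np.corrcoef(Xb[:, j], coords[:, a])[0, 1]
                         if sx > 0 and sa > 0 else 0.0)
    biplot = pd.DataFrame(bip, index=list(constraints.columns)
                          if Xb.shape[1] == len(constraints.columns)
                          else [f"x{j}" for j in range(Xb.shape[1])],
                          columns=axes)

    return OrdinationResult(
        eigenvalues=vals, site_scores=site, biplot=biplot,
        conditioned_inertia=conditioned, constrained_inertia=constrained,
        residual_inertia=residual, pseudo_f=f_obs, p_value=p_value,
        n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# taxon screen and FDR
# ---------------------------------------------------------------------------

def by_adjust(p) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR adjustment.

    Sorted p-values are scaled by ``m * c(m) / i`` with
    ``c(m) = sum_{j<=m} 1/j`` (the harmonic correction that buys validity
    under arbitrary dependence), capped at 1, and made monotone from the
    largest rank downward.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InvalidArgumentError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    q = ranked * m * c_m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def correlation_screen(abund: pd.DataFrame, scores: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Correlate every OTU's (normalized) abundance with every factor score.

    Pearson r is tested with ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 df;
    the BY adjustment is applied jointly across all OTU-by-factor tests.
    Zero-variance OTUs yield missing results rather than zeros. The output
    is one tidy row per (OTU, factor) with the correlation sign preserved.
    """
    common = abund.index.intersection(scores.index)
    if len(common) < 3:
        raise InvalidArgumentError("need at least 3 aligned samples")
    A = abund.loc[common].to_numpy(dtype=float)
    S = scores.loc[common].to_numpy(dtype=float)
    n = len(common)

    sd_a = A.std(axis=0, ddof=1)
    sd_s = S.std(axis=0, ddof=1)
    usable = sd_a > 0
    if np.any(sd_s <= 0):
        raise DegenerateInputError("constant factor score column")

    Az = (A[:, usable] - A[:, usable].mean(axis=0)) / sd_a[usable]
    Sz = (S - S.mean(axis=0)) / sd_s
    r = (Az.T @ Sz) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * t_dist.sf(np.abs(t), n - 2)
    q = by_adjust(p.ravel()).reshape(p.shape)

    otus = np.asarray(abund.columns)
    factors = list(scores.columns)
    rows = []
    ui = 0
    for j, otu in enumerate(otus):
        if not usable[j]:
            for fac in factors:
                rows.append({"otu": otu, "factor": fac, "r": np.nan,
                             "t": np.nan, "p_value": np.nan,
                             "p_adjusted": np.nan, "n": n,
                             "significant": False})
            continue
        for fi, fac in enumerate(factors):
            rows.append({"otu": otu, "factor": fac, "r": r[ui, fi],
                         "t": t[ui, fi], "p_value": p[ui, fi],
                         "p_adjusted": q[ui, fi], "n": n,
                         "significant": bool(q[ui, fi] < alpha)})
        ui += 1
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["m_tests"] = int(usable.sum() * len(factors))
    return out
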