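"""Maximum-likelihood exploratory factor analysis of lifestyle indicators.

Household market integration is measured by seven style-of-life indicators:
five ordered house-construction codes (wall, floor, bathroom, water,
electricity — treated as numeric after z-scoring) and two ownership
proportions (traditional-item and market-item lists). The latent structure
behind them is extracted by ML factor analysis of the sample correlation
matrix:

    R ~ Lambda Lambda' + Psi

with ``Lambda`` the (7 x k) loadings and ``Psi`` diagonal uniquenesses. The
likelihood is profiled: for fixed Psi the optimal loadings come from the top
eigenpairs of ``Psi^{-1/2} R Psi^{-1/2}``, leaving a k-free criterion

    F(Psi) = sum_{j>k} (lambda_j - log lambda_j) - (p - k)

minimized over ``Psi in [0.005, 1]^p`` (the lower bound wards off Heywood
cases). Model fit is judged by the Bartlett-corrected likelihood-ratio test

    X^2 = (n - 1 - (2p + 5)/6 - 2k/3) * F_min,
    df  = ((p - k)^2 - (p + k)) / 2,

and the number of factors is chosen by fitting k = 1, 2, ... until the model
is no longer rejected or ``max_factors(p)`` (the largest k with df >= 0) is
reached; for seven indicators that ceiling is three. Loadings are varimax
rotated with Kaiser row normalization, columns ordered by explained
variance, signed so each column's largest loading is positive. Per-sample
scores use the regression (Thomson) estimator ``f = Z R^{-1} Lambda``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import eigh, svd
from scipy.stats import chi2

from .errors import DegenerateInputError, FitFailureError, InvalidArgumentError
from .sim import INDICATOR_COLUMNS

log = logging.getLogger(__name__)

__all__ = ["FactorSolution", "standardize_indicators", "max_factors",
           "fit_factor_model", "select_num_factors", "factor_scores"]

PSI_MIN, PSI_MAX = 0.005, 1.0


@dataclass
class FactorSolution:
    """A fitted k-factor model of an indicator correlation matrix."""

    k: int
    loadings: pd.DataFrame        # p x k
    uniquenesses: pd.Series       # length p
    rotation: str
    scores: pd.DataFrame          # n x k regression scores
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    n_obs: int
    selection_log: list[tuple[int, float]] = field(default_factory=list)

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)


def standardize_indicators(meta: pd.DataFrame,
                           columns: list[str] | None = None) -> pd.DataFrame:
    """Z-score the indicator columns; rows with any missing value are
    dropped (and logged). A zero-variance column is unusable and raises."""
    columns = list(columns or INDICATOR_COLUMNS)
    missing_cols = [c for c in columns if c not in meta.columns]
    if missing_cols:
        raise InvalidArgumentError(f"metadata lacks indicators: {missing_cols}")
    X = meta[columns].astype(float)
    incomplete = X.isna().any(axis=1)
    if incomplete.any():
        log.info("standardize_indicators: dropped %d incomplete rows: %s",
                 int(incomplete.sum()), list(X.index[incomplete]))
        X = X.loc[~incomplete]
    sd = X.std(ddof=1)
    dead = list(sd.index[(sd == 0) | sd.isna()])
    if dead:
        raise DegenerateInputError(f"zero-variance indicator(s): {dead}")
    return (X - X.mean()) / sd


def max_factors(p: int) -> int:
    """Largest k for which the ML factor model of p indicators has a
    non-negative test df, i.e. ((p - k)^2 - (p + k)) / 2 >= 0."""
    if p < 1:
        raise InvalidArgumentError("p must be >= 1")
    k = 0
    while k + 1 < p and ((p - (k + 1)) ** 2 - (p + k + 1)) >= 0:
        k += 1
    return k


def _profile_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    inv_sqrt = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(inv_sqrt, inv_sqrt)
    vals = np.linalg.eigvalsh(Rs)[::-1]
    tail = np.clip(vals[k:], 1e-12, None)
    return float(np.sum(tail - np.log(tail)) - (len(psi) - k))


def _loadings_given_psi(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    inv_sqrt = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(inv_sqrt, inv_sqrt)
    vals, vecs = eigh(Rs)
    order = np.argsort(vals)[::-1][:k]
    lam = np.sqrt(np.clip(vals[order] - 1.0, 0.0, None))
    return (vecs[:, order] * lam[None, :]) * np.sqrt(psi)[:, None]


def _varimax(L: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """Varimax rotation with Kaiser row normalization (SVD iteration)."""
    p, k = L.shape
    if k < 2:
        return L.copy()
    h = np.sqrt((L ** 2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    A = L / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ T
        grad = A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p)
        u, s, vt = svd(grad)
        T = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return (A @ T) * h[:, None]


def _canonicalize(L: np.ndarray, scores: np.ndarray | None):
    """Order columns by explained variance, sign each so its largest-
    magnitude loading is positive."""
    ssq = (L ** 2).sum(axis=0)
    order = np.argsort(ssq)[::-1]
    L = L[:, order]
    if scores is not None:
        scores = scores[:, order]
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
            if scores is not None:
                scores[:, j] = -scores[:, j]
    return L, scores


def fit_factor_model(X: pd.DataFrame, k: int,
                     rotation: str = "varimax",
                     n_starts: int = 4) -> FactorSolution:
    """Fit the k-factor ML model to a standardized indicator matrix.

    Several starting points for the uniquenesses are tried (the classic
    ``(1 - k/(2p)) / diag(R^-1)`` start plus flat and randomized starts);
    the best converged optimum wins. Raises on k above the df ceiling or if
    every start fails.
    """
    Xv = np.asarray(X, dtype=float)
    n, p = Xv.shape
    if not 1 <= k <= max_factors(p):
        raise InvalidArgumentError(
            f"k={k} outside 1..{max_factors(p)} for p={p}")
    if n <= p:
        raise InvalidArgumentError("need more samples than indicators")
    R = np.corrcoef(Xv, rowvar=False)

    starts = []
    try:
        starts.append((1.0 - 0.5 * k / p) / np.diag(np.linalg.inv(R)))
    except np.linalg.LinAlgError:
        pass
    starts.append(np.full(p, 0.5))
    rng = np.random.default_rng(0)
    while len(starts) < n_starts:
        starts.append(rng.uniform(0.2, 0.9, size=p))

    best = None
    for psi0 in starts:
        psi0 = np.clip(psi0, PSI_MIN, PSI_MAX)
        res = optimize.minimize(
            _profile_objective, psi0, args=(R, k), method="L-BFGS-B",
            bounds=[(PSI_MIN, PSI_MAX)] * p,
            options={"maxiter": 1000, "ftol": 1e-12})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(f"factor model (k={k}) failed to converge")

    psi = np.clip(best.x, PSI_MIN, PSI_MAX)
    f_min = float(best.fun)
    L = _loadings_given_psi(psi, R, k)
    if rotation == "varimax":
        L = _varimax(L)
    elif rotation not in ("none", None):
        raise InvalidArgumentError(f"unknown rotation {rotation!r}")

    stat = (n - 1 - (2 * p + 5) / 6 - 2 * k / 3) * f_min
    df = ((p - k) ** 2 - (p + k)) // 2
    pval = float(chi2.sf(stat, df)) if df > 0 else float("nan")

    scores = Xv @ np.linalg.solve(R, L)
    L, scores = _canonicalize(L, scores)

    cols = [f"factor{j + 1}" for j in range(k)]
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(p))
    return FactorSolution(
        k=k,
        loadings=pd.DataFrame(L, index=names, columns=cols),
        uniquenesses=pd.Series(psi, index=names, name="uniqueness"),
        rotation=rotation if k > 1 else "none",
        scores=pd.DataFrame(scores, index=index, columns=cols),
        lrt_statistic=float(stat),
        lrt_df=int(df),
        lrt_p=pval,
        n_obs=n,
    )


def select_num_factors(X: pd.DataFrame, alpha: float = 0.05,
                       stopping: str = "fit_adequate",
                       rotation: str = "varimax") -> FactorSolution:
    """Grow the model one factor at a time and stop by the likelihood-ratio
    fit test.

    ``stopping="fit_adequate"`` (default) adds factors while the model is
    rejected and stops once the fit p-value reaches ``alpha`` — the reading
    under which seven indicators with three latent drivers end at k = 3.
    ``stopping="as_printed"`` stops as soon as the p-value drops below
    ``alpha`` instead. Either way k never exceeds ``max_factors(p)``, and
    the (k, p-value) path is kept in ``selection_log``.
    """
    if stopping not in ("fit_adequate", "as_printed"):
        raise InvalidArgumentError(f"unknown stopping rule {stopping!r}")
    kmax = max_factors(X.shape[1])
    if kmax < 1:
        raise InvalidArgumentError("too few indicators for any factor")
    path: list[tuple[int, float]] = []
    sol = None
    for k in range(1, kmax + 1):
        sol = fit_factor_model(X, k, rotation=rotation)
        path.append((k, sol.lrt_p))
        if stopping == "fit_adequate" and sol.lrt_p >= alpha:
            break
        if stopping == "as_printed" and sol.lrt_p < alpha:
            break
    sol.selection_log = path
    return sol


def factor_scores(solution: FactorSolution, X: pd.DataFrame) -> pd.DataFrame:
    """Regression (Thomson) factor scores ``f = Z R^{-1} Lambda`` for data
    standardized the same way the solution was fitted."""
    Xv = np.asarray(X, dtype=float)
    R = np.corrcoef(Xv, rowvar=False)
    try:
        f = Xv @ np.linalg.solve(R, solution.loadings.to_numpy())
    except np.linalg.LinAlgError as exc:
        raise FitFailureError("singular correlation matrix") from exc
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(f))
    return pd.DataFrame(f, index=index, columns=list(solution.loadings.columns))
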