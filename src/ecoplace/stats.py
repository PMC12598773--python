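"""Cross-sample statistics: Pearson matrix, OLS, and redundancy analysis.

The Pearson and ordinary-least-squares routines are written out from the
product-moment / normal-equation formulas (scipy supplies only the t and
F distribution functions for p-values).  Redundancy analysis (RDA) — the
constrained ordination used to ask how much ecotype variation the
environment explains — is implemented from first principles: project the
centered community matrix onto the column space of the standardized
predictors and take the PCA (SVD) of the fitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Simple OLS of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("x has zero variance")
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(yc @ yc)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if ss_res == 0 or n == 3 and ss_tot == 0:
        p = 0.0 if ss_tot > 0 else 1.0
    else:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se if se > 0 else np.inf
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return RegressionResult(slope=slope, intercept=intercept, r_squared=r2,
                            p_value=p, n=n)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        return float("nan"), float("nan"), n
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt(float(xc @ xc) * float(yc @ yc))
    if den == 0:
        return float("nan"), float("nan"), n
    r = float(np.clip((xc @ yc) / den, -1.0, 1.0))
    if n < 3:
        return r, float("nan"), n
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * sps.t.sf(abs(t), n - 2)), n


def pearson_matrix(table: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """All-pairs Pearson correlations with two-sided p-values.

    Pairwise-complete deletion of missing values; pairs with fewer than
    ``min_n`` complete observations, and zero-variance variables, yield
    NaN.  Returns a long-format frame (var1, var2, r, p, n, q) including
    the diagonal; q is a Benjamini-Hochberg adjusted p over the
    off-diagonal upper triangle, reported for convenience (the r/p values
    themselves are uncorrected).
    """
    cols = list(table.columns)
    data = table.to_numpy(dtype=float)
    rows = []
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j < i:
                continue
            r, p, n = _pearson(data[:, i], data[:, j])
            if n < min_n:
                r, p = float("nan"), float("nan")
            rows.append((a, b, r, p, n))
    out = pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "n"])
    off = out["var1"] != out["var2"]
    out["q"] = np.nan
    pvals = out.loc[off, "p"]
    valid = pvals.dropna()
    if len(valid):
        order = valid.sort_values().index
        m = len(valid)
        ranked = valid[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked.to_numpy()[::-1])[::-1]
        out.loc[order, "q"] = np.clip(q, 0, 1)
    return out


@dataclass
class RdaResult:
    """Constrained ordination of a community matrix on predictors."""

    constrained_proportion: float         # SS(fitted) / SS(total), in [0, 1]
    eigenvalues: np.ndarray               # non-increasing, >= 0
    site_scores: pd.DataFrame             # samples x axes (U * S)
    response_scores: pd.DataFrame         # response variables x axes (V)
    predictor_loadings: pd.DataFrame      # predictors x axes (correlations)
    dropped_predictors: list[str] = field(default_factory=list)


def rda(Y: pd.DataFrame, X: pd.DataFrame, n_axes: int | None = None) -> RdaResult:
    """Redundancy analysis of responses Y constrained by predictors X.

    Y columns are centered; X columns are z-scored.  Collinear predictors
    are dropped (with a warning) until X has full column rank.  Predictor
    loadings are correlation-style (correlation of each predictor with
    each constrained axis).
    """
    Y = Y.astype(float)
    X = X.astype(float)
    if len(Y) != len(X):
        raise ValueError("Y and X must have the same samples")
    complete = np.isfinite(Y.to_numpy()).all(axis=1) & \
        np.isfinite(X.to_numpy()).all(axis=1)
    Y, X = Y.loc[complete], X.loc[complete]
    n = len(Y)
    if n < X.shape[1] + 2:
        raise ValueError("need at least (number of predictors + 2) samples")

    Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
    Xz = X.to_numpy() - X.to_numpy().mean(axis=0)
    sd = Xz.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    Xz = Xz[:, keep] / sd[keep]
    xcols = [c for c, k in zip(X.columns, keep) if k]
    # drop collinear columns until full rank (greedy, left to right)
    while Xz.shape[1] and np.linalg.matrix_rank(Xz) < Xz.shape[1]:
        for j in range(Xz.shape[1]):
            trial = np.delete(Xz, j, axis=1)
            if np.linalg.matrix_rank(trial) == np.linalg.matrix_rank(Xz):
                dropped.append(xcols.pop(j))
                Xz = trial
                break
    if dropped:
        warnings.warn(f"dropped collinear/constant predictors: {dropped}")
    if Xz.shape[1] == 0:
        raise ValueError("no usable predictors")

    coef, *_ = np.linalg.lstsq(Xz, Yc, rcond=None)
    Yhat = Xz @ coef
    ss_tot = float((Yc ** 2).sum())
    ss_fit = float((Yhat ** 2).sum())
    proportion = 0.0 if ss_tot == 0 else ss_fit / ss_tot

    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if n_axes is not None:
        rank = min(rank, n_axes)
    U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    axes = [f"RDA{k + 1}" for k in range(rank)]
    eig = S ** 2 / max(n - 1, 1)
    sites = U * S
    with np.errstate(invalid="ignore"):
        loadings = np.array([
            [np.corrcoef(Xz[:, i], sites[:, k])[0, 1] if np.std(sites[:, k]) > 0
             else np.nan for k in range(rank)]
            for i in range(Xz.shape[1])])

    return RdaResult(
        constrained_proportion=proportion,
        eigenvalues=eig,
        site_scores=pd.DataFrame(sites, index=Y.index, columns=axes),
        response_scores=pd.DataFrame(Vt.T, index=Y.columns, columns=axes),
        predictor_loadings=pd.DataFrame(loadings, index=xcols, columns=axes),
        dropped_predictors=dropped)
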