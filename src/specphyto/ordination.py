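"""PCA of explanatory variables, EM imputation, and redundancy analysis
with adjusted-R2 / permutation forward selection.

RDA regresses the (centred, scaled) multivariate response on explanatory
variables; the variance of the fitted values is the constrained variance and
R2 its share of the total.  Adjusted R2 uses the Ezekiel correction
1 - (1 - R2)(n - 1)/(n - m - 1).  Forward selection adds, at each step, the
candidate with the highest gain in adjusted R2 and keeps it only if (i) its
permutation p-value (free permutation of the residualised response rows,
199 permutations by default) is below alpha and (ii) the cumulative adjusted
R2 does not exceed that of the all-candidates model.  Selection only starts
when the global (all-candidates) permutation test is itself significant;
together the three rules keep the selection-wide type-I error near alpha.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


# ---------------------------------------------------------------------------
# Missing-value imputation
# ---------------------------------------------------------------------------

def impute_missing(matrix: pd.DataFrame, seed: int = 0,
                   max_iter: int = 200, tol: float = 1e-10) -> pd.DataFrame:
    """Single imputation under a multivariate-normal EM model.

    Missing cells are initialised at column means, then iteratively replaced
    by their conditional means given the observed cells and the current
    mean/covariance estimates, until convergence.  The procedure is
    deterministic for given data; ``seed`` is accepted for interface
    symmetry with the stochastic stages.
    """
    df = matrix.astype(float)
    x = df.to_numpy().copy()
    miss = np.isnan(x)
    if not miss.any():
        return df.copy()
    if np.any(miss.all(axis=0)):
        raise ValidationError("a column is entirely missing; cannot impute")
    frac = miss.mean(axis=0)
    if np.any(frac >= 0.2):
        raise ValidationError("more than 20% missing in a column")

    col_means = np.nanmean(x, axis=0)
    x[miss] = np.take(col_means, np.nonzero(miss)[1])
    for _ in range(max_iter):
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1)
        cov = cov + 1e-10 * np.eye(cov.shape[0]) * max(np.trace(cov), 1.0)
        x_new = x.copy()
        for i in np.nonzero(miss.any(axis=1))[0]:
            m = miss[i]
            o = ~m
            coef = np.linalg.solve(cov[np.ix_(o, o)], (x[i, o] - mu[o]))
            x_new[i, m] = mu[m] + cov[np.ix_(m, o)] @ coef
        delta = np.max(np.abs(x_new[miss] - x[miss]))
        x = x_new
        if delta < tol:
            break
    out = df.copy()
    out.values[miss] = x[miss]
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    loadings: pd.DataFrame          # variables x axes
    scores: pd.DataFrame            # rows x axes
    contributions: pd.DataFrame     # per-variable contribution (%) per axis


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """PCA by eigendecomposition of the correlation (or covariance) matrix.

    Axes are signed so the largest-magnitude loading on each is positive.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValidationError("PCA needs >= 3 rows and >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("PCA input contains missing values; impute first")
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = matrix.columns[sd == 0].tolist()
            raise ValidationError(f"zero-variance column(s) under scaling: {zero}")
        x = x / sd
    n = x.shape[0]
    cmat = x.T @ x / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cmat)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i_max = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    axes = [f"axis{j + 1}" for j in range(eigvals.size)]
    loadings = pd.DataFrame(eigvecs * np.sqrt(eigvals)[None, :],
                            index=matrix.columns, columns=axes)
    scores = pd.DataFrame(x @ eigvecs, index=matrix.index, columns=axes)
    contrib = pd.DataFrame(100.0 * eigvecs**2, index=matrix.columns,
                           columns=axes)
    pct = 100.0 * eigvals / eigvals.sum()
    return PCAResult(eigenvalues=eigvals, pct_variance=pct,
                     loadings=loadings, scores=scores, contributions=contrib)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def _standardise(m: np.ndarray, scale: bool = True) -> np.ndarray:
    m = m - m.mean(axis=0)
    if scale:
        sd = m.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("zero-variance column in RDA input")
        m = m / sd
    return m


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel correction: 1 - (1 - R2)(n - 1)/(n - m - 1)."""
    if n <= m + 1:
        raise ValidationError("adjusted R2 undefined: need n > m + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class RDAFit:
    r2: float
    adj_r2: float
    constrained_variance: float
    residual_variance: float
    total_variance: float
    axes_eigenvalues: np.ndarray
    axes_pct: np.ndarray
    n: int
    m: int


def rda(y: pd.DataFrame | np.ndarray, x: pd.DataFrame | np.ndarray,
        scale: bool = True) -> RDAFit:
    """Redundancy analysis of response Y on explanatory X.

    Both matrices are centred (and scaled by default).  Variances are
    expressed with the 1/(n-1) convention, so constrained + residual equals
    the total variance of Y.
    """
    ya = np.asarray(y, dtype=float)
    xa = np.asarray(x, dtype=float)
    if xa.ndim == 1:
        xa = xa[:, None]
    if ya.shape[0] != xa.shape[0]:
        raise ValidationError("Y and X must have aligned rows")
    n, m = xa.shape
    ya = _standardise(ya, scale)
    xa = _standardise(xa, scale)
    if np.linalg.matrix_rank(xa) < m:
        raise ValidationError("columns of X are linearly dependent")
    beta, *_ = np.linalg.lstsq(xa, ya, rcond=None)
    fitted = xa @ beta
    total = float(np.sum(ya**2) / (n - 1))
    constrained = float(np.sum(fitted**2) / (n - 1))
    r2 = constrained / total
    eigvals = np.linalg.svd(fitted, compute_uv=False) ** 2 / (n - 1)
    eigvals = eigvals[eigvals > 1e-12 * max(eigvals[0], 1.0)] if eigvals.size else eigvals
    pct = (100.0 * eigvals / eigvals.sum()) if eigvals.size else eigvals
    return RDAFit(r2=r2, adj_r2=adjusted_r2(r2, n, m),
                  constrained_variance=constrained,
                  residual_variance=total - constrained,
                  total_variance=total, axes_eigenvalues=eigvals,
                  axes_pct=pct, n=n, m=m)


# ---------------------------------------------------------------------------
# Permutation tests and forward selection
# ---------------------------------------------------------------------------

def _residualise(m: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    if z is None or z.shape[1] == 0:
        return m - m.mean(axis=0)
    zc = z - z.mean(axis=0)
    mc = m - m.mean(axis=0)
    beta, *_ = np.linalg.lstsq(zc, mc, rcond=None)
    return mc - zc @ beta


def _perm_r2(yr: np.ndarray, xr: np.ndarray, rng: np.random.Generator,
             nperm: int) -> float:
    """Permutation p for adding predictors xr given residualised response yr.

    The statistic is the R2 of the residualised regression; rows of the
    response are permuted freely.  p = (1 + #{perm >= obs}) / (1 + nperm).
    """
    qx, _ = np.linalg.qr(xr)
    tss = np.sum(yr**2)
    if tss <= 1e-12 * yr.size:
        # Nothing left to explain: no evidence for adding further terms.
        return 1.0
    obs = np.sum((qx.T @ yr) ** 2) / tss
    count = 0
    n = yr.shape[0]
    for _ in range(nperm):
        perm = rng.permutation(n)
        stat = np.sum((qx.T @ yr[perm]) ** 2) / tss
        if stat >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + nperm)


def _full_rank_subset(xall: np.ndarray, names: list, n: int) -> list:
    """Candidates kept in order while X stays full rank and m <= n - 2."""
    kept_idx: list[int] = []
    for j in range(len(names)):
        if len(kept_idx) >= n - 2:
            break
        trial = kept_idx + [j]
        if np.linalg.matrix_rank(xall[:, trial]) == len(trial):
            kept_idx.append(j)
    if not kept_idx:
        raise ValidationError("no usable candidate (all collinear or n too small)")
    return [names[j] for j in kept_idx]


@dataclass
class RDAResult:
    response_id: str
    selected: list
    steps: list                       # per-step dicts (variable, adj_r2, p)
    final: RDAFit | None
    global_adj_r2: float
    global_p: float
    candidates: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "response_id": self.response_id,
            "selected": self.selected,
            "steps": self.steps,
            "global_adj_r2": self.global_adj_r2,
            "global_p": self.global_p,
            "candidates": self.candidates,
        }
        if self.final is not None:
            d["final"] = {
                "r2": self.final.r2, "adj_r2": self.final.adj_r2,
                "constrained_variance": self.final.constrained_variance,
                "residual_variance": self.final.residual_variance,
                "total_variance": self.final.total_variance,
            }
        return d


def forward_select(
    y: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    nperm: int = 199,
    seed: int = 0,
    response_id: str = "",
) -> RDAResult:
    """Forward selection of RDA explanatory variables.

    At each step the candidate with the highest gain in adjusted R2 enters;
    it is retained only if its permutation p-value is below ``alpha`` and
    the cumulative adjusted R2 stays at or below the all-candidates model's
    adjusted R2.  Ties in gain are broken by column order.
    """
    if candidates.shape[1] < 1:
        raise ValidationError("need >= 1 candidate variable")
    rng = np.random.default_rng(seed)
    ya = _standardise(np.asarray(y, dtype=float))
    names = list(candidates.columns)
    xall = _standardise(np.asarray(candidates, dtype=float))
    n = ya.shape[0]

    # Global (all-candidates) model for the adjusted-R2 ceiling.  If the
    # full pool is rank deficient or exhausts the degrees of freedom, a
    # greedy full-rank subset capped at n - 2 predictors stands in.
    global_cols = _full_rank_subset(xall, names, n)
    global_fit = rda(y, candidates[global_cols])
    ceiling = global_fit.adj_r2
    xg = _standardise(np.asarray(candidates[global_cols], dtype=float))
    global_p = _perm_r2(ya - ya.mean(axis=0), xg - xg.mean(axis=0),
                        np.random.default_rng(seed + 1), nperm)

    selected: list[str] = []
    steps: list[dict] = []
    remaining = list(range(len(names)))
    # Global pre-test: selection proceeds only when the all-candidates model
    # is itself significant, which keeps the selection-wide type-I error
    # near alpha.
    if global_p >= alpha:
        remaining = []
    while remaining:
        z = xall[:, [names.index(s) for s in selected]] if selected else None
        best_gain, best_j, best_adj = -np.inf, None, None
        base_adj = (rda(y, candidates[selected]).adj_r2 if selected else 0.0)
        for j in remaining:
            cols = selected + [names[j]]
            if len(cols) >= n - 1:
                continue
            try:
                adj = rda(y, candidates[cols]).adj_r2
            except ValidationError:
                continue
            gain = adj - base_adj
            if gain > best_gain + 1e-12:
                best_gain, best_j, best_adj = gain, j, adj
        if best_j is None:
            break
        # Ceiling rule: stop once cumulative adjusted R2 would pass the
        # all-candidates model.
        if best_adj > ceiling + 1e-12:
            break
        yr = _residualise(ya, z)
        xr = _residualise(xall[:, [best_j]], z)
        p = _perm_r2(yr, xr, rng, nperm)
        if p >= alpha:
            break
        selected.append(names[best_j])
        remaining.remove(best_j)
        steps.append({"variable": names[best_j], "adj_r2": best_adj, "p": p})

    final = rda(y, candidates[selected]) if selected else None
    return RDAResult(response_id=response_id, selected=selected, steps=steps,
                     final=final, global_adj_r2=ceiling, global_p=global_p,
                     candidates=names)
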