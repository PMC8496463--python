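"""Partial triadic analysis (STATIS family) of wavelength K-tables.

The detrended parameter tables (one per wavelength, stations in rows, the
eight-parameter roster in columns) are analysed in three steps:

* interstructure - RV coefficients between tables, eigendecomposition of the
  RV matrix, table weights (first eigenvector, oriented positive) and cos2;
* compromise - weighted consensus table (convex combination of the tables),
  eigendecomposition of its cross-product, axis inertias and variable/row
  coordinates;
* intrastructure - every table's rows and columns projected onto the
  compromise axes; the weighted average of the per-table projections
  reproduces the compromise coordinates exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PTA_PARAMETERS
from .errors import ValidationError


@dataclass
class KTableStack:
    """K aligned tables sharing rows (stations) and columns (parameters).

    ``values`` has shape (K, n_rows, n_cols) after global standardisation;
    ``scaling`` records the per-column mean and scale computed over the
    stacked rows of all tables.
    """

    wavelengths: list
    stations: list
    parameters: list
    values: np.ndarray
    scaling: pd.DataFrame
    dropped_stations: list = field(default_factory=list)

    def table(self, wavelength) -> pd.DataFrame:
        k = self.wavelengths.index(wavelength)
        return pd.DataFrame(self.values[k], index=self.stations,
                            columns=self.parameters)

    def unscale(self) -> np.ndarray:
        mean = self.scaling["mean"].to_numpy()
        scale = self.scaling["scale"].to_numpy()
        return self.values * scale[None, None, :] + mean[None, None, :]


@dataclass
class PTAResult:
    rv: np.ndarray
    inter_eigenvalues: np.ndarray
    inter_pct_inertia: np.ndarray
    weights: np.ndarray                 # unit norm, all positive
    cos2: np.ndarray
    compromise: pd.DataFrame
    comp_eigenvalues: np.ndarray
    comp_pct_inertia: np.ndarray
    variable_coords: pd.DataFrame       # parameters x axes
    row_coords: pd.DataFrame            # stations x axes
    table_variable_coords: dict         # wavelength -> DataFrame
    table_row_coords: dict              # wavelength -> DataFrame

    def polygon_vertices(self, axes=(0, 1)) -> dict:
        """Per-station polygon: its row coordinate at each wavelength."""
        out = {}
        stations = self.row_coords.index
        for st in stations:
            pts = np.array([
                self.table_row_coords[wl].loc[st].to_numpy()[list(axes)]
                for wl in self.table_row_coords])
            out[st] = pts
        return out

    def polygon_areas(self, axes=(0, 1)) -> pd.Series:
        """Shoelace area of each station's wavelength polygon."""
        areas = {}
        for st, pts in self.polygon_vertices(axes).items():
            x, y = pts[:, 0], pts[:, 1]
            areas[st] = 0.5 * abs(np.dot(x, np.roll(y, -1))
                                  - np.dot(y, np.roll(x, -1)))
        return pd.Series(areas, name="polygon_area")

    def to_dict(self) -> dict:
        return {
            "wavelengths": [str(w) for w in self.table_row_coords],
            "rv": self.rv.tolist(),
            "inter_eigenvalues": self.inter_eigenvalues.tolist(),
            "inter_pct_inertia": self.inter_pct_inertia.tolist(),
            "weights": self.weights.tolist(),
            "cos2": self.cos2.tolist(),
            "comp_eigenvalues": self.comp_eigenvalues.tolist(),
            "comp_pct_inertia": self.comp_pct_inertia.tolist(),
            "variable_coords": self.variable_coords.to_dict(),
            "row_coords": self.row_coords.to_dict(),
            "table_variable_coords": {
                str(k): v.to_dict() for k, v in self.table_variable_coords.items()},
            "table_row_coords": {
                str(k): v.to_dict() for k, v in self.table_row_coords.items()},
        }


# ---------------------------------------------------------------------------
# Stack construction
# ---------------------------------------------------------------------------

def build_stack(
    detrended: pd.DataFrame,
    parameters=PTA_PARAMETERS,
    value_col: str = "detrended",
    drop_incomplete: bool = True,
    scale: str = "sd",
) -> KTableStack:
    """Pivot a detrended long table into a standardised K-table stack.

    Columns are standardised globally: each parameter's mean and scale are
    computed over the stacked rows of all tables.  ``scale`` selects the
    reduction: "sd" (default) or "range" (max - min).  Stations missing any
    wavelength x parameter cell are dropped when ``drop_incomplete``.
    """
    required = {"station", "wavelength", "parameter", value_col}
    missing = required - set(detrended.columns)
    if missing:
        raise ValidationError(f"detrended table missing columns {sorted(missing)}")
    df = detrended[detrended["parameter"].isin(parameters)]
    wavelengths = sorted(df["wavelength"].unique())
    if len(wavelengths) < 2:
        raise ValidationError("need >= 2 wavelengths for a K-table stack")

    wide = df.pivot_table(index="station", columns=["wavelength", "parameter"],
                          values=value_col, aggfunc="mean")
    full_cols = pd.MultiIndex.from_product([wavelengths, list(parameters)])
    wide = wide.reindex(columns=full_cols)
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if drop_incomplete:
        wide = wide.drop(index=incomplete)
    elif incomplete:
        raise ValidationError(
            f"stations with missing cells: {incomplete} (set drop_incomplete)")
    if wide.shape[0] < 2:
        raise ValidationError("need >= 2 complete stations")

    stations = wide.index.tolist()
    k, n, p = len(wavelengths), len(stations), len(parameters)
    values = np.empty((k, n, p))
    for i, wl in enumerate(wavelengths):
        values[i] = wide[wl][list(parameters)].to_numpy()

    stacked = values.reshape(k * n, p)
    mean = stacked.mean(axis=0)
    if scale == "sd":
        scl = stacked.std(axis=0, ddof=0)
    elif scale == "range":
        scl = stacked.max(axis=0) - stacked.min(axis=0)
    else:
        raise ValidationError("scale must be 'sd' or 'range'")
    if np.any(scl == 0):
        zero = [parameters[j] for j in np.nonzero(scl == 0)[0]]
        raise ValidationError(f"zero-variance parameter column(s): {zero}")
    values = (values - mean[None, None, :]) / scl[None, None, :]

    scaling = pd.DataFrame({"mean": mean, "scale": scl}, index=list(parameters))
    return KTableStack(wavelengths=wavelengths, stations=stations,
                       parameters=list(parameters), values=values,
                       scaling=scaling, dropped_stations=incomplete)


# ---------------------------------------------------------------------------
# The three PTA steps
# ---------------------------------------------------------------------------

def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """RV coefficient between two configurations sharing rows."""
    wx = x @ x.T
    wy = y @ y.T
    num = np.trace(wx @ wy)
    den = np.sqrt(np.trace(wx @ wx) * np.trace(wy @ wy))
    if den == 0:
        raise ValidationError("degenerate (all-zero) table in RV computation")
    return float(num / den)


def interstructure(stack: KTableStack):
    """RV matrix, its eigendecomposition, table weights and cos2."""
    k = len(stack.wavelengths)
    rv = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rv[i, j] = rv[j, i] = rv_coefficient(stack.values[i], stack.values[j])
    eigvals, eigvecs = np.linalg.eigh(rv)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    weights = eigvecs[:, 0]
    if weights.sum() < 0:
        weights = -weights
    # Table coordinates on the interstructure axes.
    coords = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))[None, :]
    cos2 = coords[:, 0] ** 2 / np.sum(coords**2, axis=1)
    pct = 100.0 * eigvals / eigvals.sum()
    return rv, eigvals, pct, weights, cos2


def compromise(stack: KTableStack, weights: np.ndarray):
    """Weighted consensus table and its principal axes.

    The compromise is the convex combination sum_k (w_k / sum w) X_k; axis
    inertias are invariant to rescaling all weights by a positive constant.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(stack.wavelengths):
        raise ValidationError("weight count does not match table count")
    if np.any(weights <= 0):
        raise ValidationError("weights must all be positive")
    alphas = weights / weights.sum()
    comp = np.tensordot(alphas, stack.values, axes=(0, 0))

    u, s, vt = np.linalg.svd(comp, full_matrices=False)
    eigvals = s**2
    # Sign convention: largest-|loading| variable positive on each axis.
    for j in range(vt.shape[0]):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    pct = 100.0 * eigvals / eigvals.sum()
    axes_names = [f"axis{j + 1}" for j in range(len(s))]
    var_coords = pd.DataFrame((vt.T * s[None, :]), index=stack.parameters,
                              columns=axes_names)
    row_coords = pd.DataFrame(u * s[None, :], index=stack.stations,
                              columns=axes_names)
    comp_df = pd.DataFrame(comp, index=stack.stations, columns=stack.parameters)
    return comp_df, eigvals, pct, var_coords, row_coords, u, vt.T


def intrastructure(stack: KTableStack, u: np.ndarray, v: np.ndarray):
    """Project each table's rows and columns onto the compromise axes.

    Row projections use the right singular vectors (X_k V), variable
    projections the left ones (X_k' U); their alpha-weighted averages equal
    the compromise coordinates.
    """
    if u.shape[1] > min(stack.values.shape[1:]):
        raise ValidationError("axis count exceeds compromise rank")
    axes_names = [f"axis{j + 1}" for j in range(v.shape[1])]
    table_rows, table_vars = {}, {}
    for i, wl in enumerate(stack.wavelengths):
        xk = stack.values[i]
        table_rows[wl] = pd.DataFrame(xk @ v, index=stack.stations,
                                      columns=axes_names)
        table_vars[wl] = pd.DataFrame(xk.T @ u, index=stack.parameters,
                                      columns=axes_names)
    return table_rows, table_vars


def pta(stack: KTableStack) -> PTAResult:
    """Run all three PTA steps on a standardised stack."""
    rv, inter_eig, inter_pct, weights, cos2 = interstructure(stack)
    comp_df, comp_eig, comp_pct, var_coords, row_coords, u, v = compromise(
        stack, weights)
    table_rows, table_vars = intrastructure(stack, u, v)
    return PTAResult(
        rv=rv, inter_eigenvalues=inter_eig, inter_pct_inertia=inter_pct,
        weights=weights, cos2=cos2, compromise=comp_df,
        comp_eigenvalues=comp_eig, comp_pct_inertia=comp_pct,
        variable_coords=var_coords, row_coords=row_coords,
        table_variable_coords=table_vars, table_row_coords=table_rows)
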