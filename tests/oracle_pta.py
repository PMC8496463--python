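"""Independent brute-force partial triadic analysis.

Follows the step definitions literally with explicit loops and elementwise
sums, independent of the package implementation, to serve as a tiny-problem
oracle.
"""
import numpy as np


def rv_brute(x, y):
    wx = np.zeros((x.shape[0], x.shape[0]))
    wy = np.zeros_like(wx)
    for i in range(x.shape[0]):
        for j in range(x.shape[0]):
            wx[i, j] = sum(x[i, a] * x[j, a] for a in range(x.shape[1]))
            wy[i, j] = sum(y[i, a] * y[j, a] for a in range(y.shape[1]))
    num = sum(wx[i, j] * wy[i, j] for i in range(wx.shape[0])
              for j in range(wx.shape[0]))
    den_x = sum(wx[i, j] ** 2 for i in range(wx.shape[0])
                for j in range(wx.shape[0]))
    den_y = sum(wy[i, j] ** 2 for i in range(wy.shape[0])
                for j in range(wy.shape[0]))
    return num / np.sqrt(den_x * den_y)


def pta_brute(tables):
    """All PTA outputs for a list of (n x p) arrays sharing rows/columns."""
    k = len(tables)
    rv = np.eye(k)
    for i in range(k):
        for j in range(k):
            rv[i, j] = rv_brute(tables[i], tables[j])
    eigvals, eigvecs = np.linalg.eigh(rv)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    weights = eigvecs[:, 0]
    if weights.sum() < 0:
        weights = -weights
    coords = eigvecs * np.sqrt(np.maximum(eigvals, 0))[None, :]
    cos2 = coords[:, 0] ** 2 / (coords**2).sum(axis=1)

    alphas = weights / weights.sum()
    comp = sum(a * t for a, t in zip(alphas, tables))
    cross = comp.T @ comp
    c_eigvals, c_eigvecs = np.linalg.eigh(cross)
    order = np.argsort(c_eigvals)[::-1]
    c_eigvals = np.maximum(c_eigvals[order], 0)
    c_eigvecs = c_eigvecs[:, order]
    for j in range(c_eigvecs.shape[1]):
        i_max = np.argmax(np.abs(c_eigvecs[:, j]))
        if c_eigvecs[i_max, j] < 0:
            c_eigvecs[:, j] = -c_eigvecs[:, j]
    sing = np.sqrt(c_eigvals)
    var_coords = c_eigvecs * sing[None, :]
    row_coords = comp @ c_eigvecs
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sing[None, :] > 0, row_coords / sing[None, :], 0.0)

    table_rows = [t @ c_eigvecs for t in tables]
    table_vars = [t.T @ u for t in tables]
    return {
        "rv": rv, "inter_eigenvalues": eigvals,
        "inter_pct": 100 * eigvals / eigvals.sum(),
        "weights": weights, "cos2": cos2,
        "compromise": comp, "comp_eigenvalues": c_eigvals,
        "comp_pct": 100 * c_eigvals / c_eigvals.sum(),
        "variable_coords": var_coords, "row_coords": row_coords,
        "table_rows": table_rows, "table_vars": table_vars,
    }
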