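"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities with the most literal possible
code (double loops, closed forms) and must stay independent of the
package's implementation paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np

#: (drow, dcol) unit offsets per direction, matching the engine's
#: convention: 0 deg along image rows, counter-clockwise.
OFFSETS = {"D1": (0, 1), "D2": (-1, 1), "D3": (-1, 0), "D4": (-1, -1)}


def brute_force_glcm(
    window: np.ndarray,
    direction: str,
    displacement: int = 1,
    symmetric: bool = True,
    levels: int | None = None,
) -> np.ndarray:
    """Literal pair-counting co-occurrence matrix (normalized)."""
    w = np.asarray(window)
    if levels is None:
        levels = int(w.max()) + 1
    dr, dc = OFFSETS[direction]
    dr *= displacement
    dc *= displacement
    mat = np.zeros((levels, levels), dtype=float)
    rows, cols = w.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                mat[w[r, c], w[r2, c2]] += 1
                if symmetric:
                    mat[w[r2, c2], w[r, c]] += 1
    total = mat.sum()
    if total == 0:
        raise ValueError("no valid pairs")
    return mat / total


def literal_haralick(p: np.ndarray) -> dict[str, float]:
    """Literal double-loop evaluation of the eight texture statistics."""
    n = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * p[i, j] for i in range(n) for j in range(n))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    mean = mu_i
    hom = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    con = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    dis = sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n))
    ent = -sum(
        p[i, j] * math.log(p[i, j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0
    )
    sm = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    denom = math.sqrt(var_i) * math.sqrt(var_j)
    if denom > 1e-12:
        cor = (
            sum(i * j * p[i, j] for i in range(n) for j in range(n))
            - mu_i * mu_j
        ) / denom
    else:
        cor = 0.0
    return {
        "Mean": mean,
        "Var": var_i,
        "Hom": hom,
        "Con": con,
        "Dis": dis,
        "Ent": ent,
        "SM": sm,
        "Cor": cor,
    }


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple linear regression: slope, intercept, slope SE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    dof = max(n - 2, 1)
    se = math.sqrt((resid**2).sum() / dof / sxx)
    return slope, intercept, se
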