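"""Numba kernels for the sliding-window GLCM texture engine.

The per-pixel kernel recomputes the window co-occurrence histogram from
scratch for every output pixel.  Touched histogram bins are tracked and
zeroed after use, so the cost per pixel scales with the number of pixel
pairs in the window rather than with the full Ng x Ng histogram.  The
pair total T is identical for every interior window of a given
(window, displacement) cell, which turns the entropy sum into
``ln T - (1/T) sum cnt*ln(cnt)`` with a precomputed ``c*ln c`` table,
and lets all other sums accumulate in integers until a single final
division.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Output plane order of :func:`glcm_feature_maps`.
FEATURE_ORDER = ("Mean", "Var", "Hom", "Con", "Dis", "Ent", "SM", "Cor")


@njit(cache=True, fastmath=False)
def glcm_feature_maps(
    padded: np.ndarray,
    dr: int,
    dc: int,
    win: int,
    levels: int,
    symmetric: bool,
) -> np.ndarray:  # pragma: no cover - exercised via texture_image
    """Compute the eight Haralick feature rasters for one (window, offset).

    ``padded`` is the quantized image already reflect-padded by ``win // 2``
    on every side.  Returns an array of shape ``(8, rows, cols)`` in
    ``FEATURE_ORDER`` aligned with the unpadded grid.
    """
    half = win // 2
    n_rows = padded.shape[0] - 2 * half
    n_cols = padded.shape[1] - 2 * half
    out = np.empty((8, n_rows, n_cols), dtype=np.float64)

    hist = np.zeros(levels * levels, dtype=np.int64)
    touched = np.empty(2 * win * win, dtype=np.int64)

    # Anchor offsets inside the window whose displaced partner also falls
    # inside the window.
    r_lo = -dr if dr < 0 else 0
    r_hi = win - (dr if dr > 0 else 0)
    c_lo = -dc if dc < 0 else 0
    c_hi = win - (dc if dc > 0 else 0)

    n_pairs = (r_hi - r_lo) * (c_hi - c_lo)
    total = 2 * n_pairs if symmetric else n_pairs
    inv_total = 1.0 / total
    log_total = np.log(float(total))

    # Lookup tables: c*ln(c) for histogram counts, 1/(1+d^2) per |i-j|.
    ln_tab = np.zeros(total + 1, dtype=np.float64)
    for c in range(2, total + 1):
        ln_tab[c] = c * np.log(float(c))
    inv_tab = np.empty(levels, dtype=np.float64)
    for d in range(levels):
        inv_tab[d] = 1.0 / (1.0 + d * d)

    for y in range(n_rows):
        for x in range(n_cols):
            n_touch = 0
            for wr in range(r_lo, r_hi):
                rr = y + wr
                for wc in range(c_lo, c_hi):
                    cc = x + wc
                    a = padded[rr, cc]
                    b = padded[rr + dr, cc + dc]
                    code = a * levels + b
                    if hist[code] == 0:
                        touched[n_touch] = code
                        n_touch += 1
                    hist[code] += 1
                    if symmetric:
                        code2 = b * levels + a
                        if hist[code2] == 0:
                            touched[n_touch] = code2
                            n_touch += 1
                        hist[code2] += 1

            s_i = 0
            s_j = 0
            s_ii = 0
            s_jj = 0
            s_ij = 0
            s_con = 0
            s_dis = 0
            s_sq = 0
            s_hom = 0.0
            s_ln = 0.0
            for t in range(n_touch):
                code = touched[t]
                cnt = hist[code]
                i = code // levels
                j = code % levels
                d = i - j
                if d < 0:
                    d = -d
                s_i += cnt * i
                s_j += cnt * j
                s_ii += cnt * i * i
                s_jj += cnt * j * j
                s_ij += cnt * i * j
                s_con += cnt * d * d
                s_dis += cnt * d
                s_sq += cnt * cnt
                s_hom += cnt * inv_tab[d]
                s_ln += ln_tab[cnt]
                hist[code] = 0

            mean_i = s_i * inv_total
            mean_j = s_j * inv_total
            var_i = s_ii * inv_total - mean_i * mean_i
            var_j = s_jj * inv_total - mean_j * mean_j
            if var_i < 0.0:
                var_i = 0.0
            if var_j < 0.0:
                var_j = 0.0
            denom = np.sqrt(var_i) * np.sqrt(var_j)
            if denom > 1e-12:
                cor = (s_ij * inv_total - mean_i * mean_j) / denom
            else:
                cor = 0.0  # constant window: no linear-dependency signal

            out[0, y, x] = mean_i
            out[1, y, x] = var_i
            out[2, y, x] = s_hom * inv_total
            out[3, y, x] = s_con * inv_total
            out[4, y, x] = s_dis * inv_total
            out[5, y, x] = log_total - s_ln * inv_total
            out[6, y, x] = s_sq * inv_total * inv_total
            out[7, y, x] = cor
    return out
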