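"""Partial correlation and information theory (PCIT) edge significance.

For every unordered gene pair (x, y) and every third gene z, the first-order
partial correlations of the trio are combined into a trio tolerance

    eps_xyz = 1/3 (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz)

and the pair is flagged non-significant if some z explains it away:
|r_xy| < |eps * r_xz| and |r_xy| < |eps * r_yz|. Pairs never eliminated by
any trio are significant — regardless of correlation strength, which is what
lets weak but independent associations survive.

``pcit_mask`` is the vectorized O(n^3) implementation (one pass per
conditioning gene); ``pcit_mask_bruteforce`` is an independent plain-Python
exhaustive-trio reference kept for cross-checking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

_EPS_DENOM = 1e-12


def pearson_matrix(values: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Pairwise Pearson correlations across samples (genes x genes).

    Constant rows are flagged with a warning and correlate 0 with everything
    (diagonal stays 1).
    """
    if values.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    mat = values.to_numpy(float)
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    return list(values.index), np.clip(r, -1.0, 1.0)


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).

    Undefined (NaN, with a warning) when a conditioning correlation is +-1.
    """
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        warnings.warn("partial correlation undefined for |r| = 1", stacklevel=2)
        return float("nan")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


def pcit_mask(r: np.ndarray) -> np.ndarray:
    """Significance mask (symmetric boolean, False diagonal) for ``r``.

    Trios containing a near-zero raw correlation (|r| < 1e-12, ratio
    undefined) or a unit correlation (partial undefined) never eliminate a
    pair. With fewer than 3 genes every off-diagonal pair is significant.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if r.shape != (n, n) or n < 2:
        raise ValueError("need a square correlation matrix with n >= 2")
    eliminated = np.zeros((n, n), dtype=bool)
    absr = np.abs(r)
    off_diag = ~np.eye(n, dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        for z in range(n):
            rz = r[:, z]  # r_xz for every x
            one_minus_rz2 = 1.0 - rz**2
            one_minus_r2 = 1.0 - r**2
            sq_z = np.sqrt(one_minus_rz2)
            # partials of the trio (x, y, z), all as x-by-y matrices
            p_xy_z = (r - np.outer(rz, rz)) / np.outer(sq_z, sq_z)
            p_xz_y = (rz[:, None] - r * rz[None, :]) / (np.sqrt(one_minus_r2) * sq_z[None, :])
            p_yz_x = p_xz_y.T

            ratio_valid = (absr > _EPS_DENOM) \
                & (absr[:, [z]] > _EPS_DENOM) & (absr[[z], :] > _EPS_DENOM)
            partial_valid = np.isfinite(p_xy_z) & np.isfinite(p_xz_y) & np.isfinite(p_yz_x)
            valid = ratio_valid & partial_valid

            eps = (p_xy_z / r + p_xz_y / rz[:, None] + p_yz_x / rz[None, :]) / 3.0
            cond = (absr < np.abs(eps * rz[:, None])) & (absr < np.abs(eps * rz[None, :]))
            cond &= valid & off_diag
            cond[z, :] = False
            cond[:, z] = False
            eliminated |= cond

    significant = ~eliminated & off_diag
    return significant


def pcit_mask_bruteforce(r: np.ndarray) -> np.ndarray:
    """Exhaustive-trio reference implementation (plain loops, tiny n only)."""
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    significant = np.ones((n, n), dtype=bool)
    np.fill_diagonal(significant, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for x in range(n):
            for y in range(x + 1, n):
                for z in range(n):
                    if z in (x, y):
                        continue
                    r_xy, r_xz, r_yz = r[x, y], r[x, z], r[y, z]
                    if min(abs(r_xy), abs(r_xz), abs(r_yz)) <= _EPS_DENOM:
                        continue
                    p1 = first_order_partial(r_xy, r_xz, r_yz)
                    p2 = first_order_partial(r_xz, r_xy, r_yz)
                    p3 = first_order_partial(r_yz, r_xy, r_xz)
                    if not (np.isfinite(p1) and np.isfinite(p2) and np.isfinite(p3)):
                        continue
                    eps = (p1 / r_xy + p2 / r_xz + p3 / r_yz) / 3.0
                    if abs(r_xy) < abs(eps * r_xz) and abs(r_xy) < abs(eps * r_yz):
                        significant[x, y] = significant[y, x] = False
                        break
    return significant
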