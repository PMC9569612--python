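"""Shared statistical primitives: Spearman correlation, BH adjustment, t-tests.

The scalar routines follow the conventions used throughout the pipeline:

* Spearman rho uses average ranks for ties and the t-approximation for the
  p-value; strictly monotone pairs give rho of exactly +/-1.
* The two-group t-test is pooled-variance Student by default (Welch
  optional).  Degenerate zero-variance features use the conventions
  p=1 when the means agree and p=0 (flagged) when they differ.
* BH adjustment is the step-up procedure: q_i = min_{j >= i} m * p_(j) / j,
  capped at 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "spearman",
    "spearman_rows",
    "ttest_two_groups",
    "ttest_rows",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return q
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # running minimum from the largest p down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[mask] = out
    return q


def _rho_pvalue(rho: float, n: int) -> float:
    """Two-sided p for Spearman rho via the t-approximation on n-2 df."""
    if n < 3:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def spearman(x, y, min_pairs: int = 8) -> tuple[float, float, int]:
    """Spearman correlation with pairwise-complete deletion.

    Returns ``(rho, p, n_used)``.  If fewer than ``min_pairs`` complete
    pairs remain, or either vector is constant after deletion, returns
    ``(nan, nan, n_used)`` — such records are excluded from any BH family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have identical length")
    mask = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[mask], y[mask]
    n = int(xs.size)
    if n < max(min_pairs, 3):
        return float("nan"), float("nan"), n
    rx = sps.rankdata(xs)  # average ranks for ties
    ry = sps.rankdata(ys)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan"), float("nan"), n
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    return rho, _rho_pvalue(rho, n), n


def spearman_rows(
    X: np.ndarray, Y: np.ndarray, min_pairs: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Spearman between aligned matrices (one pair per row).

    Rows without missing values are ranked and correlated in one vectorised
    pass; rows containing NaN fall back to the pairwise-complete scalar path.
    Returns ``(rho, p, n_used)`` arrays of length ``X.shape[0]``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("matrices must be aligned")
    nrow, n = X.shape
    rho = np.full(nrow, np.nan)
    nused = np.full(nrow, n, dtype=int)
    complete = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    if np.any(complete):
        rx = sps.rankdata(X[complete], axis=1)
        ry = sps.rankdata(Y[complete], axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        sx = np.sqrt((rx * rx).sum(axis=1))
        sy = np.sqrt((ry * ry).sum(axis=1))
        ok = (sx > 0) & (sy > 0)
        r = np.full(int(complete.sum()), np.nan)
        r[ok] = (rx * ry).sum(axis=1)[ok] / (sx * sy)[ok]
        rho[complete] = np.clip(r, -1.0, 1.0)
    for i in np.nonzero(~complete)[0]:
        rho[i], _, nused[i] = spearman(X[i], Y[i], min_pairs=min_pairs)
    if n < max(min_pairs, 3):
        rho[complete] = np.nan
    p = np.array([_rho_pvalue(r, k) if not np.isnan(r) else np.nan
                  for r, k in zip(rho, nused)])
    return rho, p, nused


def ttest_two_groups(
    values_a, values_b, welch: bool = False
) -> tuple[float, float, float, float, float]:
    """Two-sided two-sample t-test; returns (t, p, mean_a, mean_b, delta).

    ``delta = mean_a - mean_b``.  Missing values are dropped per group.
    Pooled-variance Student by default; Welch when ``welch`` is True.
    Zero-variance conventions: equal means -> (t=0, p=1); unequal means with
    zero pooled variance -> (t=+/-inf, p=0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 non-missing values per group")
    t, p, d = _ttest_core(
        a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1), a.size, b.size, welch
    )
    return t, p, float(a.mean()), float(b.mean()), d


def _ttest_core(ma, mb, va, vb, na, nb, welch):
    delta = float(ma - mb)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate(delta)
        t = delta / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            return _degenerate(delta)
        t = delta / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), p, delta


def _degenerate(delta):
    if delta == 0:
        return 0.0, 1.0, 0.0
    return float(np.sign(delta) * np.inf), 0.0, float(delta)


def ttest_rows(
    A: np.ndarray, B: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-group t-test with per-row NaN omission.

    ``A`` and ``B`` are feature x sample matrices for the two groups.
    Returns (t, p, mean_a, mean_b, delta); rows with fewer than 2
    non-missing values in either group get NaN throughout.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = (~np.isnan(A)).sum(axis=1)
    nb = (~np.isnan(B)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)
    nrow = A.shape[0]
    t = np.full(nrow, np.nan)
    p = np.full(nrow, np.nan)
    delta = ma - mb
    valid = (na >= 2) & (nb >= 2)
    if welch:
        se2 = va / na + vb / nb
        pos = valid & (se2 > 0)
        t[pos] = delta[pos] / np.sqrt(se2[pos])
        df = np.full(nrow, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            df[pos] = se2[pos] ** 2 / (
                (va[pos] / na[pos]) ** 2 / (na[pos] - 1)
                + (vb[pos] / nb[pos]) ** 2 / (nb[pos] - 1)
            )
        p[pos] = 2.0 * sps.t.sf(np.abs(t[pos]), df[pos])
    else:
        sp2 = np.where(
            valid, ((na - 1) * va + (nb - 1) * vb) / np.maximum(na + nb - 2, 1), np.nan
        )
        pos = valid & (sp2 > 0)
        t[pos] = delta[pos] / np.sqrt(sp2[pos] * (1.0 / na[pos] + 1.0 / nb[pos]))
        p[pos] = 2.0 * sps.t.sf(np.abs(t[pos]), na[pos] + nb[pos] - 2)
    # zero-variance conventions
    zv = valid & ~pos
    t[zv & (delta == 0)] = 0.0
    p[zv & (delta == 0)] = 1.0
    nz = zv & (delta != 0)
    t[nz] = np.sign(delta[nz]) * np.inf
    p[nz] = 0.0
    delta = np.where(valid, delta, np.nan)
    return t, p, ma, mb, delta
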