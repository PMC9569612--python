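"""Reference-based cell-type deconvolution by constrained least squares.

For each bulk sample b over shared marker CpGs, solve

    minimize ||A w - b||^2   subject to   w >= 0,  sum(w) = 1

where A is the reference atlas (marker CpG x cell type).  The equality
constraint is imposed through a heavily weighted sum-to-one row appended
to the non-negative least-squares system, followed by exact
renormalization; on noiseless mixtures this recovers the weights to
machine precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .stats import bh_adjust

__all__ = ["estimate_proportions", "compare_groups"]

_SUM_WEIGHT = 1000.0


def _check_atlas(A: np.ndarray, names) -> None:
    if A.shape[1] < 2:
        raise ValueError("atlas needs >= 2 cell types")
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the dependent ones
        from scipy.linalg import qr

        _, _, piv = qr(A, pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient atlas: collinear cell types {bad}")


def estimate_proportions(
    beta: pd.DataFrame | pd.Series,
    atlas: pd.DataFrame,
) -> pd.DataFrame:
    """Estimated cell-type fractions per sample plus the residual norm.

    ``beta`` is a marker-CpG x sample matrix (or a single sample Series);
    only marker CpGs shared with the atlas are used, and missing marker
    betas are dropped per sample.  Requires at least as many usable
    markers as cell types.
    """
    if isinstance(beta, pd.Series):
        beta = beta.to_frame()
    shared = atlas.index.intersection(beta.index)
    k = atlas.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared marker CpGs for {k} cell types"
        )
    A_full = atlas.loc[shared].to_numpy(dtype=float)
    _check_atlas(A_full, list(atlas.columns))
    B = beta.loc[shared].to_numpy(dtype=float)
    rows = []
    for j, sample in enumerate(beta.columns):
        b = B[:, j]
        ok = ~np.isnan(b)
        if ok.sum() < k:
            rows.append([np.nan] * k + [np.nan])
            continue
        A = A_full[ok]
        aug_A = np.vstack([A, _SUM_WEIGHT * np.ones(k)])
        aug_b = np.concatenate([b[ok], [_SUM_WEIGHT]])
        w, _ = optimize.nnls(aug_A, aug_b)
        total = w.sum()
        w = w / total if total > 0 else np.full(k, 1.0 / k)
        resid = float(np.linalg.norm(A @ w - b[ok]))
        rows.append(list(w) + [resid])
    return pd.DataFrame(
        rows, index=list(beta.columns), columns=list(atlas.columns) + ["residual"]
    )


def compare_groups(
    estimates: pd.DataFrame,
    mutation_flag: np.ndarray,
) -> pd.DataFrame:
    """Per-cell-type Mann-Whitney comparison of fractions between groups.

    Returns a frame with the group medians, two-sided rank-test p and BH q
    across cell types.
    """
    mut = np.asarray(mutation_flag, dtype=bool)
    if len(mut) != len(estimates):
        raise ValueError("mutation_flag length must match samples")
    if mut.sum() < 2 or (~mut).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    types = [c for c in estimates.columns if c != "residual"]
    rows = []
    for t in types:
        a = estimates.loc[mut, t].dropna()
        b = estimates.loc[~mut, t].dropna()
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "cell_type": t,
                "median_mut": float(a.median()),
                "median_wt": float(b.median()),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out.p_value.to_numpy())
    return out
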