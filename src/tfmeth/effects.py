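"""Headline stratifications: delta-meth near TFBS vs the rest,
hypermethylation proportions, coverage metaprofiles and stage profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CoverageTrack

__all__ = [
    "StratifiedSummary",
    "stratify_delta",
    "proportion_test",
    "metaprofile",
    "stage_profile",
]


@dataclass
class StratifiedSummary:
    group_label: str            # 'near_tfbs' or 'rest'
    n: int
    mean_delta: float
    proportion_hypermethylated: float
    test_p: float               # shared between the pair (rank test)


def stratify_delta(
    dm_results: pd.DataFrame,
    proximity: dict[str, bool] | pd.Series,
    restrict: str = "dm",
    tl_flags: pd.Series | None = None,
) -> tuple[StratifiedSummary, StratifiedSummary]:
    """Mean delta-meth in the motif-proximal stratum vs the rest.

    ``restrict`` selects the CpG population: ``dm`` (differentially
    methylated CpGs, the figure population), ``all`` (every tested CpG) or
    ``tl`` (restricted to traffic lights, requires ``tl_flags`` indexed by
    CpG).  Stratum difference is tested with a two-sided Mann-Whitney rank
    test; the hypermethylated proportion within each stratum is the
    fraction of DHM CpGs.
    """
    prox = pd.Series(proximity) if isinstance(proximity, dict) else proximity
    df = dm_results
    if restrict == "dm":
        df = df[df.is_dm]
    elif restrict == "tl":
        if tl_flags is None:
            raise ValueError("restrict='tl' needs tl_flags")
        df = df[df.feature_id.map(tl_flags).fillna(False).astype(bool)]
    elif restrict != "all":
        raise ValueError(f"unknown restrict {restrict!r}")
    near_mask = df.feature_id.map(prox).fillna(False).astype(bool)
    near_delta = df.delta[near_mask].dropna()
    rest_delta = df.delta[~near_mask].dropna()
    if len(near_delta) and len(rest_delta):
        p = float(sps.mannwhitneyu(near_delta, rest_delta, alternative="two-sided").pvalue)
    else:
        p = float("nan")  # empty stratum: comparison skipped

    def _summ(label, sub, sub_df):
        hyper = float(sub_df.is_dhm.mean()) if "is_dhm" in sub_df and len(sub_df) else float("nan")
        return StratifiedSummary(
            group_label=label,
            n=int(len(sub)),
            mean_delta=float(sub.mean()) if len(sub) else float("nan"),
            proportion_hypermethylated=hyper,
            test_p=p,
        )

    return (
        _summ("near_tfbs", near_delta, df[near_mask]),
        _summ("rest", rest_delta, df[~near_mask]),
    )


def proportion_test(
    dhm_flags_near, dhm_flags_rest
) -> tuple[float, float, float]:
    """Fisher exact test on hypermethylated-CpG proportions near TFBS vs rest.

    Returns ``(prop_near, prop_rest, p)``; p is NaN when a margin is empty.
    """
    near = np.asarray(dhm_flags_near, dtype=bool)
    rest = np.asarray(dhm_flags_rest, dtype=bool)
    if near.size == 0 or rest.size == 0:
        return float("nan"), float("nan"), float("nan")
    a, b = int(near.sum()), int(near.size - near.sum())
    c, d = int(rest.sum()), int(rest.size - rest.sum())
    table = [[a, b], [c, d]]
    if (a + c == 0) or (b + d == 0):
        p = float("nan")  # empty margin: odds ratio undefined
    else:
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return near.mean(), rest.mean(), p


def metaprofile(
    track: CoverageTrack,
    anchors: dict[str, list[tuple[str, int]]],
    flank_bp: int = 2000,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Mean coverage in fixed bins around anchor positions, per class.

    ``anchors`` maps class label -> list of (chrom, position).  Bins cover
    ``[-flank_bp, +flank_bp)`` symmetrically about each anchor; bins that
    fall off the start of a contig are dropped from that anchor's average
    (marked missing).  Returns a tidy frame with columns ``class_label``,
    ``bin_start``, ``bin_end`` (relative bp), ``mean_coverage``,
    ``n_regions``.
    """
    if n_bins < 1 or n_bins % 2:
        raise ValueError("n_bins must be a positive even number (symmetric about 0)")
    edges = np.linspace(-flank_bp, flank_bp, n_bins + 1)
    rows = []
    for label, points in anchors.items():
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for chrom, pos in points:
            starts = pos + edges[:-1]
            ends = pos + edges[1:]
            valid = starts >= 0
            if not np.any(valid):
                continue
            means = track.means(chrom, starts[valid], ends[valid])
            sums[valid] += means
            counts[valid] += 1
        with np.errstate(invalid="ignore"):
            mean_cov = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for b in range(n_bins):
            rows.append(
                {
                    "class_label": label,
                    "bin_start": float(edges[b]),
                    "bin_end": float(edges[b + 1]),
                    "mean_coverage": float(mean_cov[b]),
                    "n_regions": int(len(points)),
                }
            )
    return pd.DataFrame(rows)


def stage_profile(
    strong_cpgs: list[str],
    stage_matrix: pd.DataFrame,
    cohort_beta: pd.DataFrame,
    mut_flags: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean methylation over strong-TL CpGs per maturation stage and per
    patient group, with bootstrap CIs over CpGs (percentile, 2.5/97.5).

    ``stage_matrix`` is CpG x stage; ``cohort_beta`` CpG x sample.
    """
    rng = np.random.default_rng(seed)
    cpgs = [c for c in strong_cpgs if c in stage_matrix.index and c in cohort_beta.index]
    if not cpgs:
        raise ValueError("no strong CpGs present in the stage matrix")
    stage_vals = stage_matrix.loc[cpgs]
    mut_flags = np.asarray(mut_flags, dtype=bool)
    groups = {
        "mutated": cohort_beta.loc[cpgs, cohort_beta.columns[mut_flags]].mean(axis=1),
        "wild_type": cohort_beta.loc[cpgs, cohort_beta.columns[~mut_flags]].mean(axis=1),
    }
    columns = {**{s: stage_vals[s] for s in stage_vals.columns}, **groups}
    n = len(cpgs)
    idx = rng.integers(0, n, size=(n_boot, n))
    rows = []
    for label, series in columns.items():
        vals = series.to_numpy(dtype=float)
        boots = vals[idx].mean(axis=1)
        rows.append(
            {
                "profile": label,
                "mean_beta": float(vals.mean()),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
                "n_cpgs": n,
            }
        )
    return pd.DataFrame(rows)
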