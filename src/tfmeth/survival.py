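"""Kaplan-Meier estimation and two-group log-rank testing, with a landmark
variant that conditions on survival past a cutoff.

The landmark analysis at time L keeps only subjects still at risk after L
and re-origins their clocks at L (conditional survival), the construction
that makes a late-divergence comparison ("beyond day 500") a valid test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "dichotomize_by_methylation",
    "kaplan_meier",
    "logrank",
    "apply_landmark",
]


def dichotomize_by_methylation(
    beta_row: pd.Series,
    rule: str = "median",
    threshold: float | None = None,
) -> pd.Series:
    """Label samples 'hyper'/'hypo' from one CpG's beta values.

    ``median`` splits at the cohort median with ties going to 'hypo'
    (so an all-constant row yields a single 'hypo' group and downstream
    tests are skipped); ``threshold`` uses a fixed beta cutoff.
    """
    vals = beta_row.astype(float)
    if rule == "median":
        cut = float(np.nanmedian(vals))
        hyper = vals > cut
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule needs a threshold")
        hyper = vals > threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(np.where(hyper, "hyper", "hypo"), index=beta_row.index)


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with one row per distinct event time: ``time``,
    ``n_at_risk``, ``n_events``, ``survival``.  Censored times reduce the
    risk set but never drop the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t < 0):
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n = len(t)
    i = 0
    while i < n:
        ti = t[i]
        j = i
        d = 0
        while j < n and t[j] == ti:
            d += int(e[j])
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append({"time": ti, "n_at_risk": at_risk, "n_events": d, "survival": s})
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def apply_landmark(df: pd.DataFrame, landmark_days: float) -> pd.DataFrame:
    """Retain subjects with time > landmark and reset their clocks to 0."""
    out = df[df.time > landmark_days].copy()
    out["time"] = out.time - landmark_days
    return out


def logrank(
    df: pd.DataFrame,
    landmark_days: float | None = None,
) -> tuple[float, float]:
    """Two-group log-rank chi-square and two-sided p.

    ``df`` needs columns ``time``, ``event`` (bool) and ``group`` (two
    labels).  With a landmark L, only subjects with time > L enter and
    their clocks restart at L; a landmark of 0 equals the overall test.
    Raises if a group is empty (e.g. emptied by the landmark).
    """
    if landmark_days:
        df = apply_landmark(df, landmark_days)
    labels = sorted(df.group.unique())
    if len(labels) != 2:
        raise ValueError(
            f"log-rank needs exactly 2 non-empty groups, got {labels!r}"
        )
    g = (df.group == labels[1]).to_numpy()
    t = df.time.to_numpy(dtype=float)
    e = df.event.to_numpy(dtype=bool)
    event_times = np.unique(t[e])
    observed = 0.0
    expected = 0.0
    variance = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d_tot = int((e & (t == ti)).sum())
        d1 = int((e & (t == ti) & g).sum())
        observed += d1
        expected += d_tot * n1 / n_tot
        if n_tot > 1:
            variance += (
                d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
            )
    if variance == 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p
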