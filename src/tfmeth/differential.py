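"""Differential methylation/expression between mutation groups.

* DM CpG: pooled-variance Student t between mutated and wild-type beta
  values, BH FDR < ``dm_fdr`` (default 0.05).
* DHM CpG: a DM CpG whose group mean difference (mutated - wild-type,
  i.e. delta-meth) exceeds ``dhm_delta`` (default 0.15, strict).
* DEG: the same machinery on expression rows, with a linear-scale fold
  change attached.
* Strong CpG TL: a traffic light whose CpG is differentially methylated
  and whose gene is differentially expressed; the prioritized gene table
  applies the fold-change, FDR and absolute-expression gates on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .stats import bh_adjust, ttest_rows, ttest_two_groups
from .types import CohortMatrices

__all__ = [
    "ttest_two_groups",
    "call_dm_dhm",
    "call_deg",
    "select_strong_tl_genes",
]


def _differential_frame(
    mat: pd.DataFrame, mut: np.ndarray, fdr: float, welch: bool
) -> pd.DataFrame:
    A = mat.loc[:, mut].to_numpy(dtype=float)
    B = mat.loc[:, ~mut].to_numpy(dtype=float)
    t, p, ma, mb, delta = ttest_rows(A, B, welch=welch)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "feature_id": list(mat.index),
            "mean_mut": ma,
            "mean_wt": mb,
            "delta": delta,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "is_dm": ~np.isnan(q) & (q < fdr),
        }
    )
    out.index = pd.Index(out.feature_id.to_numpy(), name=None)
    return out


def call_dm_dhm(
    cohort: CohortMatrices,
    mutation: str = "runx1",
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-CpG differential methylation; DHM = DM and delta > dhm_delta."""
    config = config or PipelineConfig()
    if cohort.beta is None:
        raise ValueError("no beta matrix in cohort")
    mut = cohort.mutation_flags(mutation)
    if mut.sum() < 2 or (~mut).sum() < 2:
        raise ValueError("need >= 2 samples per mutation group")
    out = _differential_frame(cohort.beta, mut, config.dm_fdr, config.welch)
    out["is_dhm"] = out.is_dm & (out.delta > config.dhm_delta)
    return out


def call_deg(
    cohort: CohortMatrices,
    mutation: str = "runx1",
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression with linear-scale fold change.

    ``fc = mean_mut / mean_wt`` on the linear scale; a small stabilizer
    replaces a zero wild-type mean so the ratio stays defined for silent
    genes.
    """
    config = config or PipelineConfig()
    if cohort.expression is None:
        raise ValueError("no expression matrix in cohort")
    mut = cohort.mutation_flags(mutation)
    if mut.sum() < 2 or (~mut).sum() < 2:
        raise ValueError("need >= 2 samples per mutation group")
    out = _differential_frame(cohort.expression, mut, config.dm_fdr, config.welch)
    denom = out.mean_wt.where(out.mean_wt > 0, config.fc_stabilizer)
    out["fc"] = out.mean_mut / denom
    return out


def select_strong_tl_genes(
    tls: pd.DataFrame,
    dm: pd.DataFrame,
    deg: pd.DataFrame,
    proximity: dict[str, bool] | pd.Series,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strong traffic lights and the prioritized gene table.

    A strong CpG TL is a TL whose CpG shows a significant methylation
    change (DM by default, DHM when ``strong_tl_requires_dhm``) and whose
    gene is differentially expressed.  A gene is retained iff it has at
    least one strong TL (optionally restricted to motif-proximal CpGs),
    |log2 fc| > log2(gene_fc), expression q < dm_fdr, and
    max(group means) > gene_min_expr.

    Returns ``(strong_tls, gene_table)``.
    """
    config = config or PipelineConfig()
    prox = pd.Series(proximity) if isinstance(proximity, dict) else proximity
    meth_col = "is_dhm" if config.strong_tl_requires_dhm else "is_dm"
    rows = []
    for rec in tls.itertuples(index=False):
        if not rec.is_tl or rec.cpg_id not in dm.index or rec.gene not in deg.index:
            continue
        m = dm.loc[rec.cpg_id]
        e = deg.loc[rec.gene]
        if bool(m[meth_col]) and bool(e.is_dm):
            rows.append(
                {
                    "cpg_id": rec.cpg_id,
                    "gene": rec.gene,
                    "near_tfbs": bool(prox.get(rec.cpg_id, False)),
                    "rho": rec.rho,
                    "tl_q": rec.q_value,
                    "delta_meth": m.delta,
                    "meth_q": m.q_value,
                    "fc": e.fc,
                    "expr_q": e.q_value,
                    "mean_expr_mut": e.mean_mut,
                    "mean_expr_wt": e.mean_wt,
                }
            )
    strong = pd.DataFrame(
        rows,
        columns=[
            "cpg_id", "gene", "near_tfbs", "rho", "tl_q", "delta_meth",
            "meth_q", "fc", "expr_q", "mean_expr_mut", "mean_expr_wt",
        ],
    )
    candidates = strong
    if config.restrict_genes_to_near_tfbs and not strong.empty:
        candidates = strong[strong.near_tfbs]
    gene_rows = []
    for gene, grp in candidates.groupby("gene", sort=True):
        e = deg.loc[gene]
        fc = float(e.fc)
        passes = (
            abs(np.log2(fc)) > np.log2(config.gene_fc)
            if fc > 0
            else True  # fc == 0: infinite downregulation passes the gate
        )
        if (
            passes
            and e.q_value < config.dm_fdr
            and max(e.mean_mut, e.mean_wt) > config.gene_min_expr
        ):
            gene_rows.append(
                {
                    "gene": gene,
                    "n_strong_tl": len(grp),
                    "n_near_tfbs": int(grp.near_tfbs.sum()),
                    "fc": fc,
                    "expr_q": float(e.q_value),
                    "mean_expr_mut": float(e.mean_mut),
                    "mean_expr_wt": float(e.mean_wt),
                    "best_delta_meth": float(grp.delta_meth.max()),
                }
            )
    gene_table = pd.DataFrame(
        gene_rows,
        columns=[
            "gene", "n_strong_tl", "n_near_tfbs", "fc", "expr_q",
            "mean_expr_mut", "mean_expr_wt", "best_delta_meth",
        ],
    )
    return strong, gene_table
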