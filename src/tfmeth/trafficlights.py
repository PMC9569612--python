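"""CpG traffic lights: methylation-expression correlation across samples.

A CpG traffic light (CpG TL) is a CpG whose methylation level correlates
significantly with the expression of its associated gene across the
cohort (Spearman, BH FDR below ``tl_fdr``, default 0.005).  Both signs of
correlation qualify; the sign is retained for downstream filtering (a
negative rho means higher methylation goes with lower expression).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .stats import bh_adjust, spearman, spearman_rows
from .types import CohortMatrices, CpGRecord

__all__ = ["call_traffic_lights", "spearman", "bh_adjust"]

log = logging.getLogger(__name__)


def call_traffic_lights(
    cohort: CohortMatrices,
    manifest: list[CpGRecord],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One record per testable CpG-gene pair with rho, p, BH q and the TL call.

    Pairs whose gene is absent from the expression matrix are skipped (a
    count is logged).  Pairs with too few complete observations or a
    constant vector get NaN statistics and are excluded from the BH family.
    The BH family is all testable pairs of this run.
    """
    config = config or PipelineConfig()
    if cohort.beta is None or cohort.expression is None:
        raise ValueError("traffic lights need both beta and expression matrices")
    beta, expr = cohort.beta, cohort.expression
    pairs = [
        (r.cpg_id, r.gene)
        for r in manifest
        if r.gene and r.cpg_id in beta.index and r.gene in expr.index
    ]
    n_skipped = sum(1 for r in manifest if not r.gene or r.gene not in expr.index)
    if n_skipped:
        log.info("skipping %d manifest CpGs without a testable gene", n_skipped)
    if not pairs:
        raise ValueError("no testable CpG-gene pairs")
    cpg_ids = [c for c, _ in pairs]
    genes = [g for _, g in pairs]
    X = beta.loc[cpg_ids].to_numpy(dtype=float)
    Y = expr.loc[genes].to_numpy(dtype=float)
    rho, p, n_used = spearman_rows(X, Y, min_pairs=config.min_pairs)
    q = bh_adjust(p)
    is_tl = ~np.isnan(q) & (q < config.tl_fdr)
    return pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene": genes,
            "rho": rho,
            "n_used": n_used,
            "p_value": p,
            "q_value": q,
            "is_tl": is_tl,
        }
    )
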