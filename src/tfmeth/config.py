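"""Pipeline configuration: every statistical threshold in one auditable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All thresholds used by the pipeline stages.

    Attributes
    ----------
    pwm_pvalue:
        Exact tail probability for the motif score threshold (default 0.001).
    tl_fdr:
        BH FDR cutoff for calling a CpG traffic light (default 0.005).
    dm_fdr:
        BH FDR cutoff for differential methylation / expression (default 0.05).
    dhm_delta:
        Minimum group mean beta difference (strict) for a differentially
        hypermethylated CpG (default 0.15).
    window_halfwidth:
        Half-width in bp of the CpG-centered scan window (default 100,
        i.e. 200 bp windows).
    gene_fc:
        Fold-change gate for prioritized genes (default 2).
    gene_min_expr:
        Minimum group-mean expression gate, linear scale (default 0.5).
    landmark_days:
        Landmark time for the conditional survival comparison (default 500).
    rng_seed:
        Seed for every stochastic stage.
    """

    pwm_pvalue: float = 0.001
    tl_fdr: float = 0.005
    dm_fdr: float = 0.05
    dhm_delta: float = 0.15
    window_halfwidth: int = 100
    gene_fc: float = 2.0
    gene_min_expr: float = 0.5
    landmark_days: float = 500.0
    rng_seed: int = 0

    # secondary knobs (defaults chosen once; see docs/methods.md)
    pwm_pseudocount: float = 0.01
    pwm_background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    min_pairs: int = 8              # pairwise-complete floor for Spearman
    welch: bool = False             # pooled-variance t by default
    strong_tl_requires_dhm: bool = False
    restrict_genes_to_near_tfbs: bool = True
    fc_stabilizer: float = 0.01     # added to denominator of fold change
    survival_rule: str = "median"   # beta dichotomization rule

    def __post_init__(self) -> None:
        for name in ("pwm_pvalue", "tl_fdr", "dm_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.dhm_delta < 1:
            raise ValueError(f"dhm_delta must be in (0,1), got {self.dhm_delta}")
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be > 0")
        if self.gene_fc <= 0 or self.gene_min_expr < 0:
            raise ValueError("invalid gene gates")
        if self.landmark_days < 0:
            raise ValueError("landmark_days must be >= 0")
        bg = tuple(float(b) for b in self.pwm_background)
        if len(bg) != 4 or abs(sum(bg) - 1.0) > 1e-9 or min(bg) < 0:
            raise ValueError("pwm_background must be 4 non-negative values summing to 1")
        self.pwm_background = bg
        if self.survival_rule not in ("median", "threshold"):
            raise ValueError(f"unknown survival_rule {self.survival_rule!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["pwm_background"] = list(d["pwm_background"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pwm_background"] = list(d["pwm_background"])
        return d
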