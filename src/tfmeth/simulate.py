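"""Synthetic study generator with planted, known effects.

Generates every input the pipeline consumes — genome with planted motif
instances, CpG manifest, beta/expression matrices, coverage track,
reference atlas and mixtures, stage profiles, survival times — so each
downstream stage can be validated against ground truth.

The default scenario mirrors the study conditions the pipeline targets:
a 186-patient cohort with 17 mutated samples (RUNX1 preset; 13 for the
CEBPA preset), a +0.18 beta shift at motif-proximal CpGs and +0.06 at a
fraction of the remaining CpGs in mutated samples (0.13 / 0.09 for the
CEBPA preset), methylation-expression coupling for a designated traffic
light subset, elevated ChIP coverage around motif-proximal CpGs, known
cell-type mixing proportions, and group-dependent late-divergence survival.

Motif-proximal CpGs draw their baseline methylation from the
hypomethylated mode of the array-like bimodal base distribution: binding
sites kept demethylated in normal cells are exactly the positions that
can gain methylation when the factor is lost.  Shifts that would leave
[0, 1] are clipped (never wrapped) and the realized group difference is
recomputed and stored as truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motifs import MotifModel, _encode, _score_all_offsets
from .types import CohortMatrices, CoverageTrack, CpGRecord, SampleMeta

__all__ = [
    "SimulationScenario",
    "DEMO_MOTIF_COUNTS",
    "make_truth_table",
    "simulate_study",
    "simulate_genome_with_motifs",
    "simulate_cohort",
    "simulate_coverage",
    "make_reference_atlas",
    "simulate_mixtures",
    "simulate_stage_profiles",
    "simulate_survival",
    "simulate_late_divergence_survival",
]

CHROM = "chrSim"
STAGES = ("HSC", "CMP", "GMP", "promyelocyte", "neutrophil")
CELL_TYPES = ("granulocyte", "monocyte", "macrophage", "lymphocyte", "blast")

WT_FRACTIONS = {
    "granulocyte": 0.30,
    "monocyte": 0.25,
    "macrophage": 0.20,
    "lymphocyte": 0.15,
    "blast": 0.10,
}
# mutated patients: fewer mature macrophages, expanded blast compartment
MUT_FRACTIONS = {
    "granulocyte": 0.25,
    "monocyte": 0.25,
    "macrophage": 0.07,
    "lymphocyte": 0.13,
    "blast": 0.30,
}


# Demo count matrix with a RUNX1-like TGTGGTTT core, used by the CLI
# simulate command when no PWM file is supplied.
DEMO_MOTIF_COUNTS = np.array(
    [
        [5, 5, 5, 85],
        [5, 5, 85, 5],
        [5, 25, 5, 65],
        [2, 2, 94, 2],
        [2, 2, 94, 2],
        [5, 2, 2, 91],
        [10, 5, 5, 80],
        [10, 25, 5, 60],
    ],
    dtype=float,
)


@dataclass
class SimulationScenario:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_samples: int = 186
    n_mutated: int = 17
    n_cpgs: int = 5000
    frac_near_tfbs: float = 0.1
    delta_near: float = 0.18
    delta_far: float = 0.06
    frac_responsive_far: float = 0.3
    frac_tl: float = 0.1
    tl_coupling: float = 0.7       # target |Spearman| for ordinary TL CpGs
    strong_coupling: float = 0.9   # target |Spearman| for planted strong TLs
    coupling_sign: int = -1        # methylation up -> expression down
    n_strong_genes: int = 12
    expression_scale: float = 5.0  # baseline RPKM-like level of strong genes
    expr_log2_slope: float = 1.25  # log2-expression change per latent unit
    beta_precision: float = 100.0  # concentration of per-sample beta noise
    coverage_enrichment: float = 5.0
    cell_fractions_wt: dict = field(default_factory=lambda: dict(WT_FRACTIONS))
    cell_fractions_mut: dict = field(default_factory=lambda: dict(MUT_FRACTIONS))
    survival_hazard_ratio: float = 3.0
    landmark_days: float = 500.0
    survival_hazard_pre: float = 1 / 1000
    survival_hazard_post: float = 1 / 2500
    followup_days: float = 2000.0
    mutation: str = "runx1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_mutated < self.n_samples:
            raise ValueError("need 0 < n_mutated < n_samples")
        for name in ("delta_near", "delta_far"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("frac_near_tfbs", "frac_responsive_far", "frac_tl",
                     "tl_coupling", "strong_coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coupling_sign not in (-1, 1):
            raise ValueError("coupling_sign must be -1 or +1")
        for fr in (self.cell_fractions_wt, self.cell_fractions_mut):
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError("cell fractions must sum to 1")

    @classmethod
    def runx1(cls, **overrides) -> "SimulationScenario":
        return cls(**{**dict(mutation="runx1", n_mutated=17, delta_near=0.18,
                             delta_far=0.06, n_strong_genes=12), **overrides})

    @classmethod
    def cebpa(cls, **overrides) -> "SimulationScenario":
        return cls(**{**dict(mutation="cebpa", n_mutated=13, delta_near=0.13,
                             delta_far=0.09, n_strong_genes=11), **overrides})


# ---------------------------------------------------------------- genome


def make_truth_table(
    n_cpgs: int,
    frac_near_tfbs: float,
    seed: int,
    locus_spacing: int = 5000,
) -> pd.DataFrame:
    """Positions, genes and motif-proximity labels without any sequence.

    Each CpG owns one locus of ``locus_spacing`` bp on a single synthetic
    chromosome, with the CpG at the locus center.  Used directly by
    cohort-level simulations that do not need sequence.
    """
    rng = np.random.default_rng(seed)
    n_near = int(round(frac_near_tfbs * n_cpgs))
    near = np.zeros(n_cpgs, dtype=bool)
    near[rng.choice(n_cpgs, size=n_near, replace=False)] = True
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i:06d}" for i in range(n_cpgs)],
            "chrom": CHROM,
            "pos": np.arange(n_cpgs) * locus_spacing + locus_spacing // 2,
            "gene": [f"G{i:05d}" for i in range(n_cpgs)],
            "near_tfbs": near,
        }
    )


def _sample_site(motif: MotifModel, rng, max_tries: int = 2000) -> str:
    """A motif instance drawn from the PWM, conditioned on passing threshold."""
    probs = np.power(2.0, motif.log_odds) * motif.background  # back to pfm
    probs = probs / probs.sum(axis=1, keepdims=True)
    L = len(motif)
    for _ in range(max_tries):
        idx = np.array([rng.choice(4, p=probs[j]) for j in range(L)])
        seq = "".join("ACGT"[b] for b in idx)
        if motif.score(seq) >= motif.threshold_score:
            return seq
    consensus = "".join("ACGT"[b] for b in probs.argmax(axis=1))
    if motif.score(consensus) >= motif.threshold_score:
        return consensus
    raise RuntimeError("motif too uninformative: no instance reaches threshold")


def _window_hits(window: str, motif: MotifModel) -> int:
    codes = _encode(window)
    thr = motif.threshold_score
    n = 0
    for mat in (motif.log_odds, motif.reverse_complement_matrix()):
        scores = _score_all_offsets(codes, mat)
        n += int(np.sum(scores >= thr))
    return n


def simulate_genome_with_motifs(
    motif: MotifModel,
    n_cpgs: int,
    frac_near_tfbs: float,
    seed: int,
    window_halfwidth: int = 100,
    locus_spacing: int = 5000,
) -> tuple[dict[str, str], list[CpGRecord], pd.DataFrame]:
    """Synthetic chromosome with CpG loci and planted motif instances.

    Each CpG sits at the center of a window of ``2 * window_halfwidth`` bp.
    Background windows are rejection-sampled until they contain no match at
    the motif's threshold (either strand); for the motif-proximal subset a
    PWM-sampled instance above threshold is then embedded at a random
    offset that avoids the central CpG dinucleotide.  Returns the genome,
    the manifest and the truth table of planted windows.
    """
    L = len(motif)
    hw = window_halfwidth
    if L >= 2 * hw:
        raise ValueError("motif longer than the scan window")
    if locus_spacing < 2 * hw + 2:
        raise ValueError("locus_spacing too small for the window")
    truth = make_truth_table(n_cpgs, frac_near_tfbs, seed, locus_spacing)
    rng = np.random.default_rng(seed + 1)
    chrom_len = n_cpgs * locus_spacing
    genome_arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=chrom_len)
    site_start = np.full(n_cpgs, -1, dtype=np.int64)
    site_strand = np.array(["."] * n_cpgs)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_cpgs):
        pos = int(truth.pos.iloc[i])
        wstart = pos - hw
        # background window free of motif matches (rejection sampling)
        for attempt in range(500):
            win = rng.choice(bases, size=2 * hw)
            win[hw] = ord("C")
            win[hw + 1] = ord("G")
            if _window_hits(win.tobytes().decode(), motif) == 0:
                break
        else:
            raise RuntimeError("could not sample a motif-free window")
        if truth.near_tfbs.iloc[i]:
            site = _sample_site(motif, rng)
            # offset keeping the planted site clear of the central CpG
            choices = [o for o in range(0, 2 * hw - L + 1) if o + L <= hw or o >= hw + 2]
            off = int(rng.choice(choices))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else _revcomp(site)
            win[off : off + L] = np.frombuffer(planted.encode(), dtype=np.uint8)
            site_start[i] = wstart + off
            site_strand[i] = strand
        genome_arr[wstart : wstart + 2 * hw] = win
    genome = {CHROM: genome_arr.tobytes().decode()}
    truth = truth.assign(site_start=site_start, site_strand=site_strand)
    manifest = [
        CpGRecord(r.cpg_id, r.chrom, int(r.pos), r.gene)
        for r in truth.itertuples(index=False)
    ]
    return genome, manifest, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------- cohort


def _latent_rho(target_spearman: float) -> float:
    """Gaussian-copula latent correlation giving a target Spearman rho."""
    return 2.0 * math.sin(math.pi * target_spearman / 6.0)


def simulate_cohort(
    scenario: SimulationScenario,
    truth: pd.DataFrame,
) -> tuple[CohortMatrices, pd.DataFrame, dict]:
    """Generate beta/expression matrices, metadata and all truth labels.

    ``truth`` is a table from :func:`make_truth_table` or
    :func:`simulate_genome_with_motifs` (columns cpg_id, gene, near_tfbs).
    Returns ``(cohort, cpg_truth, extras)`` where ``cpg_truth`` carries the
    per-CpG planted labels (responsive, TL, strong, realized delta) and
    ``extras`` holds the atlas, per-sample cell fractions, marker-CpG beta
    matrix, stage profiles and the designated survival CpG.
    """
    sc = scenario
    rng = np.random.default_rng(sc.rng_seed)
    n_cpgs = len(truth)
    n = sc.n_samples
    near = truth.near_tfbs.to_numpy(dtype=bool)

    # --- groups
    mut_idx = np.sort(rng.choice(n, size=sc.n_mutated, replace=False))
    mut = np.zeros(n, dtype=bool)
    mut[mut_idx] = True
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # --- baselines: bimodal array-like marginal; near-TFBS CpGs start low
    base = np.where(
        rng.random(n_cpgs) < 0.5, rng.beta(2, 10, n_cpgs), rng.beta(10, 2, n_cpgs)
    )
    base[near] = rng.beta(2, 10, int(near.sum()))
    base = np.clip(base, 0.02, 0.98)

    # --- responsive CpGs and planted shifts
    far_idx = np.nonzero(~near)[0]
    n_resp_far = int(round(sc.frac_responsive_far * len(far_idx)))
    resp_far = np.zeros(n_cpgs, dtype=bool)
    if n_resp_far:
        resp_far[rng.choice(far_idx, size=n_resp_far, replace=False)] = True
    shift = np.where(near, sc.delta_near, np.where(resp_far, sc.delta_far, 0.0))

    # --- traffic-light structure
    near_idx = np.nonzero(near)[0]
    if sc.n_strong_genes > len(near_idx):
        raise ValueError("n_strong_genes exceeds the number of motif-proximal CpGs")
    strong_idx = rng.choice(near_idx, size=sc.n_strong_genes, replace=False)
    is_strong = np.zeros(n_cpgs, dtype=bool)
    is_strong[strong_idx] = True
    n_tl = int(round(sc.frac_tl * n_cpgs))
    is_tl = is_strong.copy()
    pool = np.nonzero(~near & ~resp_far)[0]  # ordinary TLs carry no group shift
    extra = max(0, n_tl - sc.n_strong_genes)
    if extra > len(pool):
        extra = len(pool)
    if extra:
        is_tl[rng.choice(pool, size=extra, replace=False)] = True

    # --- beta matrix
    kappa = sc.beta_precision
    beta = rng.beta(base[:, None] * kappa, (1 - base[:, None]) * kappa, (n_cpgs, n))
    beta[:, mut] = np.clip(beta[:, mut] + shift[:, None], 0.0, 1.0)
    realized_delta = beta[:, mut].mean(axis=1) - beta[:, ~mut].mean(axis=1)

    # --- expression, Gaussian copula on beta ranks for coupled rows
    genes = truth.gene.to_numpy()
    level = rng.lognormal(mean=math.log(2.0), sigma=1.2, size=n_cpgs)
    level[is_tl] = rng.lognormal(mean=math.log(3.0), sigma=0.7, size=int(is_tl.sum()))
    level[is_strong] = sc.expression_scale
    coupling = np.zeros(n_cpgs)
    coupling[is_tl] = sc.tl_coupling
    coupling[is_strong] = sc.strong_coupling
    expr = np.empty((n_cpgs, n))
    eps = rng.standard_normal((n_cpgs, n))
    ranks = sps.rankdata(beta, axis=1)
    z = sps.norm.ppf(ranks / (n + 1))
    for i in range(n_cpgs):
        if coupling[i] > 0:
            rho_l = _latent_rho(coupling[i])
            y = rho_l * z[i] + math.sqrt(max(0.0, 1 - rho_l**2)) * eps[i]
            # orient y to rise with methylation for the silencing sign (-1)
            y_up = -sc.coupling_sign * y
            if is_strong[i]:
                # switch-like silenced target: active plateau in unshifted
                # samples, expression floor once methylation rises
                expr[i] = level[i] / (1.0 + np.power(2.0, 3.0 * (y_up - 0.8)))
            else:
                expr[i] = level[i] * np.power(2.0, -sc.expr_log2_slope * y_up)
        else:
            expr[i] = level[i] * np.power(2.0, sc.expr_log2_slope * eps[i])

    # --- cell mixtures at dedicated marker CpGs
    atlas = make_reference_atlas(seed=sc.rng_seed + 7)
    frac_truth = _sample_fractions(sc, mut, rng)
    marker_beta = simulate_mixtures(atlas, frac_truth, noise_sd=0.02,
                                    rng=rng, sample_ids=sample_ids)

    # --- survival anchored on the first planted strong CpG (BIK-like);
    # without planted strong genes fall back to any motif-proximal CpG
    if len(strong_idx):
        surv_cpg = int(strong_idx[0])
    else:
        surv_cpg = int(near_idx[0]) if len(near_idx) else 0
    surv_beta = beta[surv_cpg]
    hyper = surv_beta > np.median(surv_beta)
    times, events = simulate_survival(
        hyper,
        hazard_pre=sc.survival_hazard_pre,
        hazard_post=sc.survival_hazard_post,
        hr_post=sc.survival_hazard_ratio,
        changepoint=sc.landmark_days,
        followup=sc.followup_days,
        rng=rng,
    )

    samples = [
        SampleMeta(
            sample_id=sample_ids[j],
            runx1_mutated=bool(mut[j]) and sc.mutation == "runx1",
            cebpa_mutated=bool(mut[j]) and sc.mutation == "cebpa",
            survival_days=float(times[j]),
            death_observed=bool(events[j]),
        )
        for j in range(n)
    ]
    beta_df = pd.DataFrame(beta, index=pd.Index(truth.cpg_id, name="cpg_id"),
                           columns=sample_ids)
    # one gene per CpG row; duplicate genes collapse to their first CpG row
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                           columns=sample_ids)
    expr_df = expr_df[~expr_df.index.duplicated(keep="first")]
    cohort = CohortMatrices(beta=beta_df, expression=expr_df, samples=samples)

    cpg_truth = truth.copy()
    cpg_truth["base_beta"] = base
    cpg_truth["planted_shift"] = shift
    cpg_truth["true_delta"] = realized_delta
    cpg_truth["is_responsive"] = shift > 0
    cpg_truth["is_tl"] = is_tl
    cpg_truth["is_strong"] = is_strong
    cpg_truth["coupling"] = coupling

    extras = {
        "atlas": atlas,
        "cell_fractions": frac_truth,
        "marker_beta": marker_beta,
        "survival_cpg": truth.cpg_id.iloc[surv_cpg],
        "hyper_truth": pd.Series(hyper, index=sample_ids),
        "stage_profiles": simulate_stage_profiles(cpg_truth, seed=sc.rng_seed + 11),
    }
    return cohort, cpg_truth, extras


def _sample_fractions(sc: SimulationScenario, mut: np.ndarray, rng) -> pd.DataFrame:
    types = list(sc.cell_fractions_wt)
    conc = 200.0
    rows = []
    for is_mut in mut:
        mean = sc.cell_fractions_mut if is_mut else sc.cell_fractions_wt
        alpha = np.array([mean[t] for t in types]) * conc
        rows.append(rng.dirichlet(alpha))
    return pd.DataFrame(rows, columns=types,
                        index=[f"S{i + 1:04d}" for i in range(len(mut))])


# ---------------------------------------------------------------- atlas / mixtures


def make_reference_atlas(
    n_markers_per_type: int = 50,
    cell_types: tuple[str, ...] = CELL_TYPES,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference beta profiles: each cell type hypomethylated at its markers.

    Marker block k is near 0.1 in cell type k and near 0.85 elsewhere,
    the classic differentially-methylated-marker design of reference-based
    deconvolution.
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    values = rng.uniform(0.75, 0.95, size=(n_markers_per_type * k, k))
    for j in range(k):
        block = slice(j * n_markers_per_type, (j + 1) * n_markers_per_type)
        values[block, j] = rng.uniform(0.05, 0.15, size=n_markers_per_type)
    ids = [f"mk{i:05d}" for i in range(n_markers_per_type * k)]
    return pd.DataFrame(values, index=pd.Index(ids, name="cpg_id"),
                        columns=list(cell_types))


def simulate_mixtures(
    atlas: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.02,
    rng=None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Bulk marker-CpG betas: atlas @ fractions + Gaussian noise, clipped."""
    rng = np.random.default_rng() if rng is None else rng
    W = fractions[atlas.columns].to_numpy()  # samples x types
    mixed = atlas.to_numpy() @ W.T
    mixed = np.clip(mixed + rng.normal(0, noise_sd, mixed.shape), 0.0, 1.0)
    cols = sample_ids if sample_ids is not None else list(fractions.index)
    return pd.DataFrame(mixed, index=atlas.index.copy(), columns=cols)


# ---------------------------------------------------------------- coverage


def simulate_coverage(
    truth: pd.DataFrame,
    coverage_enrichment: float,
    seed: int,
    baseline: float = 50.0,
    bin_size: int = 25,
    kernel_sigma: float = 150.0,
    poisson_noise: bool = True,
) -> CoverageTrack:
    """Binned coverage: flat Poisson baseline plus Gaussian bumps at
    motif-proximal CpGs with the requested fold enrichment at the peak."""
    if coverage_enrichment < 1:
        raise ValueError("coverage_enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    pos = truth.pos.to_numpy()
    spacing = int(pos[1] - pos[0]) if len(pos) > 1 else 5000
    chrom_len = int(pos[-1] + spacing // 2 + 1) if len(pos) else spacing
    edges = np.arange(0, chrom_len + bin_size, bin_size)
    centers = (edges[:-1] + edges[1:]) / 2.0
    lam = np.full(len(centers), baseline)
    amp = baseline * (coverage_enrichment - 1.0)
    for p in pos[truth.near_tfbs.to_numpy(dtype=bool)]:
        lo = np.searchsorted(centers, p - 5 * kernel_sigma)
        hi = np.searchsorted(centers, p + 5 * kernel_sigma)
        d = centers[lo:hi] - p
        lam[lo:hi] += amp * np.exp(-0.5 * (d / kernel_sigma) ** 2)
    values = rng.poisson(lam).astype(float) if poisson_noise else lam
    return CoverageTrack(
        {CHROM: (edges[:-1].astype(np.int64), edges[1:].astype(np.int64), values)}
    )


# ---------------------------------------------------------------- stages


def simulate_stage_profiles(
    cpg_truth: pd.DataFrame,
    seed: int,
    stages: tuple[str, ...] = STAGES,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Per-stage mean beta across normal maturation (CpG x stage).

    Strong-TL CpGs follow a monotone demethylation gradient from immature
    (high beta) to mature (low beta) stages — the maturation program the
    mutated cohort is expected to resemble at its immature end.  Other CpGs
    stay flat at their baseline.
    """
    rng = np.random.default_rng(seed)
    n = len(cpg_truth)
    k = len(stages)
    base = cpg_truth["base_beta"].to_numpy() if "base_beta" in cpg_truth else np.full(n, 0.5)
    values = np.tile(base[:, None], (1, k))
    strong = cpg_truth["is_strong"].to_numpy(dtype=bool) if "is_strong" in cpg_truth \
        else np.zeros(n, dtype=bool)
    gradient = np.linspace(0.85, 0.15, k)
    values[strong] = gradient[None, :]
    values = np.clip(values + rng.normal(0, noise_sd, values.shape), 0.0, 1.0)
    return pd.DataFrame(values, index=pd.Index(cpg_truth.cpg_id, name="cpg_id"),
                        columns=list(stages))


# ---------------------------------------------------------------- survival


def simulate_survival(
    hyper: np.ndarray,
    hazard_pre: float,
    hazard_post: float,
    hr_post: float,
    changepoint: float,
    followup: float,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-exponential survival with group divergence after a changepoint.

    Both groups share ``hazard_pre`` before ``changepoint``; afterwards the
    hyper group's hazard is ``hazard_post * hr_post`` against ``hazard_post``.
    Administrative censoring at ``followup`` days.
    """
    hyper = np.asarray(hyper, dtype=bool)
    n = len(hyper)
    t_pre = rng.exponential(1.0 / hazard_pre, n)
    h2 = np.where(hyper, hazard_post * hr_post, hazard_post)
    t_post = changepoint + rng.exponential(1.0 / h2)
    times = np.where(t_pre < changepoint, t_pre, t_post)
    events = times < followup
    times = np.minimum(times, followup)
    return times, events


def simulate_study(
    scenario: SimulationScenario,
    outdir,
    motif_counts: np.ndarray | None = None,
    window_halfwidth: int = 100,
    locus_spacing: int = 5000,
    peak_halfwidth: int = 50,
    peak_coverage: float = 1.0,
    target_pvalue: float = 0.001,
):
    """Write a complete synthetic study to ``outdir``.

    Emits every downstream input format — genome FASTA, CpG manifest,
    PWM, beta/expression matrices, sample sheet, ChIP peak BED, coverage
    bedGraph, reference atlas + marker betas, stage profiles — plus truth
    tables.  Peaks cover a ``peak_coverage`` fraction of planted sites
    (plus decoys in motif-free loci), so peak filtering can be exercised.
    Returns ``(paths_dict, cpg_truth, extras)``.
    """
    from pathlib import Path

    from . import io as tio
    from .motifs import build_motif

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = DEMO_MOTIF_COUNTS if motif_counts is None else motif_counts
    motif = build_motif(counts, target_pvalue=target_pvalue,
                        name=f"{scenario.mutation.upper()}_demo")
    genome, manifest, truth = simulate_genome_with_motifs(
        motif, scenario.n_cpgs, scenario.frac_near_tfbs, scenario.rng_seed,
        window_halfwidth=window_halfwidth, locus_spacing=locus_spacing,
    )
    cohort, cpg_truth, extras = simulate_cohort(scenario, truth)
    track = simulate_coverage(cpg_truth, scenario.coverage_enrichment,
                              seed=scenario.rng_seed + 3)

    rng = np.random.default_rng(scenario.rng_seed + 5)
    L = len(motif)
    from .types import GenomicInterval

    peaks = []
    planted = cpg_truth[cpg_truth.site_start >= 0]
    for r in planted.itertuples(index=False):
        if rng.random() < peak_coverage:
            peaks.append(GenomicInterval(
                r.chrom, max(0, int(r.site_start) - peak_halfwidth),
                int(r.site_start) + L + peak_halfwidth,
            ))
    far = cpg_truth[~cpg_truth.near_tfbs]
    for r in far.sample(n=min(len(far), max(1, len(planted) // 2)),
                        random_state=int(rng.integers(2**31))).itertuples(index=False):
        # decoy peaks outside any scan window
        start = int(r.pos) + window_halfwidth + 100
        peaks.append(GenomicInterval(r.chrom, start, start + 2 * peak_halfwidth))
    peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    paths = {
        "genome": str(outdir / "genome.fa"),
        "manifest": str(outdir / "manifest.tsv"),
        "pwm": str(outdir / "pwm.txt"),
        "beta": str(outdir / "beta.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "peaks": str(outdir / "peaks.bed"),
        "coverage": str(outdir / "coverage.bedgraph"),
        "atlas": str(outdir / "atlas.tsv"),
        "marker_beta": str(outdir / "marker_beta.tsv"),
        "stage_profiles": str(outdir / "stage_profiles.tsv"),
        "survival_cpg": extras["survival_cpg"],
    }
    tio.write_fasta(genome, paths["genome"])
    tio.write_manifest(manifest, paths["manifest"])
    tio.write_pwm(motif.name, counts, paths["pwm"])
    tio.write_beta_matrix(cohort.beta, paths["beta"])
    tio.write_expression_matrix(cohort.expression, paths["expression"])
    tio.write_sample_sheet(cohort.samples, paths["samples"])
    tio.write_bed(peaks, paths["peaks"])
    tio.write_bedgraph(track, paths["coverage"])
    tio.write_atlas(extras["atlas"], paths["atlas"])
    tio.write_beta_matrix(extras["marker_beta"], paths["marker_beta"])
    tio.write_beta_matrix(extras["stage_profiles"], paths["stage_profiles"])
    cpg_truth.to_csv(outdir / "truth_cpgs.tsv", sep="\t", index=False)
    extras["cell_fractions"].rename_axis("sample_id").to_csv(
        outdir / "truth_cell_fractions.tsv", sep="\t"
    )
    return paths, cpg_truth, extras


def simulate_late_divergence_survival(
    seed: int,
    n: int = 4000,
    hr_post: float = 3.0,
    changepoint: float = 500.0,
    hazard_pre: float = -math.log(0.15) / 500.0,  # 85% of events before changepoint
    hazard_post: float = 0.9e-4,
    followup: float = 1000.0,
) -> pd.DataFrame:
    """Demonstration cohort for the landmark-vs-overall contrast.

    Group hazards are identical before the changepoint and differ by
    ``hr_post`` afterwards, so the overall log-rank comparison is diluted by
    the shared early phase while the landmark test at the changepoint is
    well powered; the cohort size comes from that power calculation (see
    docs/methods.md).
    """
    rng = np.random.default_rng(seed)
    hyper = np.zeros(n, dtype=bool)
    hyper[rng.choice(n, size=n // 2, replace=False)] = True
    times, events = simulate_survival(
        hyper, hazard_pre, hazard_post, hr_post, changepoint, followup, rng
    )
    return pd.DataFrame(
        {"time": times, "event": events, "group": np.where(hyper, "hyper", "hypo")},
        index=[f"S{i + 1:05d}" for i in range(n)],
    )
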