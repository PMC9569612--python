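"""End-to-end orchestration: scan -> traffic lights -> differential ->
TFBS effects -> deconvolution -> survival, with a run manifest.

Every threshold comes from the :class:`~tfmeth.config.PipelineConfig`
snapshot recorded in the run manifest; stages fail loudly with the stage
name.  Re-running with identical config and inputs reproduces identical
output checksums for all deterministic stages (the bootstrap CIs of the
stage profile are seeded from the config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .deconvolve import compare_groups, estimate_proportions
from .differential import call_dm_dhm, call_deg, select_strong_tl_genes
from .effects import metaprofile, proportion_test, stage_profile, stratify_delta
from .io import (
    load_cohort,
    read_atlas,
    read_bed,
    read_bedgraph,
    read_beta_matrix,
    read_fasta,
    read_manifest,
    read_pwm,
    write_bed,
)
from .motifs import annotate_cpg_proximity, build_motif, filter_by_peaks, scan_windows
from .survival import dichotomize_by_methylation, kaplan_meier, logrank
from .trafficlights import call_traffic_lights
from .types import SampleMeta

__all__ = ["StudyPaths", "run_all", "cohort_summary"]


@dataclass
class StudyPaths:
    """Locations of every input file a full run consumes.

    ``peaks``, ``coverage``, ``atlas``/``marker_beta``, ``stage_profiles``
    and ``survival_cpg`` are optional; the corresponding stages are skipped
    when absent.
    """

    manifest: str
    genome: str
    pwm: str
    beta: str
    expression: str
    samples: str
    peaks: str | None = None
    coverage: str | None = None
    atlas: str | None = None
    marker_beta: str | None = None
    stage_profiles: str | None = None
    survival_cpg: str | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:
                raise StageError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def cohort_summary(samples: list[SampleMeta]) -> dict:
    """Counts and display percentages of mutated patients.

    The display percentage is 100 * count / total rounded to the nearest
    integer; the exact fraction is retained alongside.
    """
    total = len(samples)
    n_runx1 = sum(s.runx1_mutated for s in samples)
    n_cebpa = sum(s.cebpa_mutated for s in samples)

    def pct(k):
        return 0 if total == 0 else int(round(100.0 * k / total))

    return {
        "n_samples": total,
        "n_runx1_mutated": n_runx1,
        "pct_runx1_mutated": pct(n_runx1),
        "frac_runx1_mutated": 0.0 if total == 0 else n_runx1 / total,
        "n_cebpa_mutated": n_cebpa,
        "pct_cebpa_mutated": pct(n_cebpa),
        "frac_cebpa_mutated": 0.0 if total == 0 else n_cebpa / total,
    }


def run_all(
    config: PipelineConfig,
    paths: StudyPaths,
    outdir: str | Path,
    mutation: str = "runx1",
) -> dict:
    """Run every stage in dependency order; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # ---- input stage
    @_stage("read_inputs")
    def _read():
        manifest = read_manifest(paths.manifest)
        genome = read_fasta(paths.genome)
        pwm_name, pwm_counts = read_pwm(paths.pwm)
        cohort = load_cohort(paths.beta, paths.expression, paths.samples, manifest)
        peaks = read_bed(paths.peaks) if paths.peaks else None
        return manifest, genome, pwm_name, pwm_counts, cohort, peaks

    manifest, genome, pwm_name, pwm_counts, cohort, peaks = _read()
    counts["manifest_cpgs"] = len(manifest)
    counts["samples"] = len(cohort.samples)

    # ---- motif scan
    @_stage("motif_scan")
    def _scan():
        motif = build_motif(
            pwm_counts,
            background=config.pwm_background,
            pseudocount=config.pwm_pseudocount,
            target_pvalue=config.pwm_pvalue,
            name=pwm_name,
        )
        sites = scan_windows(genome, manifest, motif, config.window_halfwidth)
        if peaks is not None:
            sites = filter_by_peaks(sites, peaks)
        prox = annotate_cpg_proximity(manifest, sites)
        return motif, sites, prox

    motif, sites, proximity = _scan()
    counts["predicted_sites"] = len(sites)
    counts["cpgs_near_tfbs"] = int(sum(proximity.values()))
    write_bed([s.interval for s in sites], outdir / "sites.bed",
              scores=[s.score for s in sites])
    pd.Series(proximity, name="near_tfbs").rename_axis("cpg_id").astype(int).to_csv(
        outdir / "proximity.tsv", sep="\t"
    )

    # ---- traffic lights
    tls = _stage("traffic_lights")(call_traffic_lights)(cohort, manifest, config)
    counts["traffic_lights"] = int(tls.is_tl.sum())
    tls.to_csv(outdir / "trafficlights.tsv", sep="\t", index=False)

    # ---- differential
    @_stage("differential")
    def _diff():
        dm = call_dm_dhm(cohort, mutation, config)
        deg = call_deg(cohort, mutation, config)
        strong, genes = select_strong_tl_genes(tls, dm, deg, proximity, config)
        return dm, deg, strong, genes

    dm, deg, strong, gene_table = _diff()
    counts["dm_cpgs"] = int(dm.is_dm.sum())
    counts["dhm_cpgs"] = int(dm.is_dhm.sum())
    counts["deg_genes"] = int(deg.is_dm.sum())
    counts["strong_tls"] = len(strong)
    counts["prioritized_genes"] = len(gene_table)
    dm.to_csv(outdir / "dm.tsv", sep="\t", index=False)
    deg.to_csv(outdir / "deg.tsv", sep="\t", index=False)
    strong.to_csv(outdir / "strong_tls.tsv", sep="\t", index=False)
    gene_table.to_csv(outdir / "gene_table.tsv", sep="\t", index=False)

    # ---- TFBS effects
    @_stage("tfbs_effects")
    def _effects():
        near_s, rest_s = stratify_delta(dm, proximity, restrict="dm")
        dhm_near = dm.loc[[c for c, v in proximity.items() if v and c in dm.index], "is_dhm"]
        dhm_rest = dm.loc[[c for c, v in proximity.items() if not v and c in dm.index], "is_dhm"]
        pn, pr, fisher_p = proportion_test(dhm_near.to_numpy(), dhm_rest.to_numpy())
        pd.DataFrame(
            [
                {"stratum": s.group_label, "n": s.n, "mean_delta": s.mean_delta,
                 "prop_hypermethylated": s.proportion_hypermethylated,
                 "rank_test_p": s.test_p, "fisher_p": fisher_p}
                for s in (near_s, rest_s)
            ]
        ).to_csv(outdir / "strata.tsv", sep="\t", index=False)
        if paths.coverage:
            track = read_bedgraph(paths.coverage)
            dhm_ids = set(dm.feature_id[dm.is_dhm])
            pos = {r.cpg_id: (r.chrom, r.pos) for r in manifest}
            anchors = {
                "near_tfbs": [pos[c] for c in dhm_ids if proximity.get(c)],
                "rest": [pos[c] for c, v in proximity.items() if not v and c in pos],
            }
            prof = metaprofile(track, anchors)
            prof.to_csv(outdir / "metaprofile.tsv", sep="\t", index=False)
        if paths.stage_profiles and len(strong):
            stages = read_beta_matrix(paths.stage_profiles)
            sp = stage_profile(
                list(strong.cpg_id.unique()), stages, cohort.beta,
                cohort.mutation_flags(mutation), seed=config.rng_seed,
            )
            sp.to_csv(outdir / "stage_profile.tsv", sep="\t", index=False)

    _effects()

    # ---- deconvolution
    if paths.atlas and paths.marker_beta:
        @_stage("deconvolution")
        def _deconv():
            atlas = read_atlas(paths.atlas)
            marker = read_beta_matrix(paths.marker_beta)
            marker = marker[[s.sample_id for s in cohort.samples]]
            props = estimate_proportions(marker, atlas)
            comp = compare_groups(props, cohort.mutation_flags(mutation))
            props.rename_axis("sample_id").to_csv(outdir / "deconvolution.tsv", sep="\t")
            comp.to_csv(outdir / "deconv_groups.tsv", sep="\t", index=False)

        _deconv()

    # ---- survival
    surv_cpg = paths.survival_cpg
    if surv_cpg is None and len(strong):
        surv_cpg = strong.sort_values("delta_meth", ascending=False).cpg_id.iloc[0]
    if surv_cpg is not None:
        @_stage("survival")
        def _surv():
            sf = cohort.survival_frame().dropna()
            if sf.empty:
                return
            groups = dichotomize_by_methylation(
                cohort.beta.loc[surv_cpg], rule=config.survival_rule
            )
            df = sf.join(groups.rename("group"))
            df["event"] = df.event.astype(bool)
            results = {"cpg_id": surv_cpg}
            if df.group.nunique() == 2:
                chi2, p = logrank(df)
                results["overall_chi2"], results["overall_p"] = chi2, p
                try:
                    chi2l, pl = logrank(df, landmark_days=config.landmark_days)
                    results["landmark_chi2"], results["landmark_p"] = chi2l, pl
                    results["landmark_days"] = config.landmark_days
                except ValueError as e:
                    results["landmark_error"] = str(e)
            km_rows = []
            for label, grp in df.groupby("group"):
                km = kaplan_meier(grp.time, grp.event)
                km["group"] = label
                km_rows.append(km)
            pd.concat(km_rows).to_csv(outdir / "kaplan_meier.tsv", sep="\t", index=False)
            with open(outdir / "logrank.json", "w") as fh:
                json.dump(results, fh, indent=2)

        _surv()

    # ---- run manifest
    checksums = {
        name: _sha256(p)
        for name, p in vars(paths).items()
        if p and name != "survival_cpg" and Path(p).exists()
    }
    run_manifest = {
        "version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "mutation": mutation,
        "input_checksums": checksums,
        "record_counts": counts,
        "cohort_summary": cohort_summary(cohort.samples),
        "output_checksums": {
            f.name: _sha256(f) for f in sorted(outdir.glob("*.tsv"))
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=float)
    return run_manifest
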