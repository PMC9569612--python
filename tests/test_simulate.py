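"""Generator properties: determinism, bounds, planted-effect fidelity."""

import numpy as np
import pandas as pd
import pytest

from tfmeth.motifs import build_motif, scan_windows, annotate_cpg_proximity
from tfmeth.simulate import (
    DEMO_MOTIF_COUNTS,
    SimulationScenario,
    make_reference_atlas,
    make_truth_table,
    simulate_cohort,
    simulate_coverage,
    simulate_genome_with_motifs,
    simulate_mixtures,
    simulate_stage_profiles,
)
from tfmeth.stats import spearman


@pytest.fixture(scope="module")
def motif():
    return build_motif(DEMO_MOTIF_COUNTS, target_pvalue=0.001, name="demo")


def _small(**kw):
    base = dict(n_cpgs=300, n_samples=60, n_mutated=8, n_strong_genes=4,
                frac_near_tfbs=0.2, rng_seed=0)
    base.update(kw)
    return SimulationScenario.runx1(**base)


class TestDeterminism:
    def test_identical_seeds_are_bit_identical(self):
        sc = _small()
        truth = make_truth_table(sc.n_cpgs, sc.frac_near_tfbs, sc.rng_seed)
        c1, t1, e1 = simulate_cohort(sc, truth)
        c2, t2, e2 = simulate_cohort(sc, truth)
        pd.testing.assert_frame_equal(c1.beta, c2.beta)
        pd.testing.assert_frame_equal(c1.expression, c2.expression)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_same_schema(self):
        sc1, sc2 = _small(), _small(rng_seed=9)
        t1 = make_truth_table(sc1.n_cpgs, sc1.frac_near_tfbs, sc1.rng_seed)
        t2 = make_truth_table(sc2.n_cpgs, sc2.frac_near_tfbs, sc2.rng_seed)
        _, ct1, _ = simulate_cohort(sc1, t1)
        _, ct2, _ = simulate_cohort(sc2, t2)
        assert list(ct1.columns) == list(ct2.columns)
        assert not ct1.equals(ct2)


class TestBounds:
    def test_beta_in_unit_interval_expression_nonnegative(self):
        sc = _small(delta_near=0.6)  # large shift exercises clipping
        truth = make_truth_table(sc.n_cpgs, sc.frac_near_tfbs, sc.rng_seed)
        cohort, ct, _ = simulate_cohort(sc, truth)
        b = cohort.beta.to_numpy()
        assert b.min() >= 0.0 and b.max() <= 1.0
        assert cohort.expression.to_numpy().min() >= 0.0
        # clipping is reflected in the realized (not the planted) delta
        near = ct[ct.near_tfbs]
        assert (near.true_delta <= near.planted_shift + 0.05).all()


class TestPlantedEffects:
    def test_null_scenario_deltas_within_monte_carlo_error(self, null_cohort):
        _, cohort, ct, _, _ = null_cohort
        mut = cohort.mutation_flags("runx1")
        b = cohort.beta.to_numpy()
        delta = b[:, mut].mean(axis=1) - b[:, ~mut].mean(axis=1)
        se = delta.std() / np.sqrt(len(delta))
        assert abs(delta.mean()) < 3 * se

    def test_perfect_coupling_gives_exact_minus_one_spearman(self):
        sc = _small(tl_coupling=1.0, strong_coupling=1.0)
        truth = make_truth_table(sc.n_cpgs, sc.frac_near_tfbs, sc.rng_seed)
        cohort, ct, _ = simulate_cohort(sc, truth)
        for _, row in ct[ct.is_tl].head(10).iterrows():
            rho, _, _ = spearman(
                cohort.beta.loc[row.cpg_id], cohort.expression.loc[row.gene]
            )
            assert rho == -1.0

    def test_realized_near_delta_matches_planted_level(self):
        sc = SimulationScenario.runx1(n_cpgs=1000, rng_seed=0)
        truth = make_truth_table(sc.n_cpgs, sc.frac_near_tfbs, sc.rng_seed)
        _, ct, _ = simulate_cohort(sc, truth)
        assert ct[ct.near_tfbs].true_delta.mean() == pytest.approx(0.18, abs=0.02)
        resp_far = ct[ct.is_responsive & ~ct.near_tfbs]
        assert resp_far.true_delta.mean() == pytest.approx(0.06, abs=0.02)


class TestGenome:
    def test_no_proximal_fraction_yields_zero_hits(self, motif):
        genome, manifest, truth = simulate_genome_with_motifs(
            motif, 40, 0.0, seed=0, locus_spacing=600
        )
        assert scan_windows(genome, manifest, motif, 100) == []

    def test_full_proximal_fraction_hits_every_window(self, motif):
        genome, manifest, truth = simulate_genome_with_motifs(
            motif, 40, 1.0, seed=0, locus_spacing=600
        )
        near = annotate_cpg_proximity(manifest, scan_windows(genome, manifest, motif, 100))
        assert all(near.values())

    def test_scan_recovers_truth_table_exactly(self, motif):
        genome, manifest, truth = simulate_genome_with_motifs(
            motif, 150, 0.3, seed=2, locus_spacing=600
        )
        near = annotate_cpg_proximity(manifest, scan_windows(genome, manifest, motif, 100))
        got = pd.Series(near).loc[truth.cpg_id].to_numpy()
        np.testing.assert_array_equal(got, truth.near_tfbs.to_numpy())

    def test_motif_longer_than_window_rejected(self, motif):
        with pytest.raises(ValueError, match="longer than the scan window"):
            simulate_genome_with_motifs(motif, 5, 0.5, seed=0, window_halfwidth=3)


class TestCoverage:
    def test_unit_enrichment_is_flat_within_noise(self):
        truth = make_truth_table(100, 0.3, seed=0, locus_spacing=2000)
        track = simulate_coverage(truth, 1.0, seed=1, baseline=100.0)
        _, _, v = track.intervals("chrSim")
        # Poisson(100) bins: relative sd 10%, mean within a few SE of baseline
        assert v.mean() == pytest.approx(100.0, rel=0.05)
        assert v.std() == pytest.approx(10.0, rel=0.5)

    def test_noise_free_profile_peaks_at_cpg(self):
        truth = make_truth_table(20, 1.0, seed=0, locus_spacing=4000)
        track = simulate_coverage(truth, 5.0, seed=1, poisson_noise=False)
        s, e, v = track.intervals("chrSim")
        pos = int(truth.pos.iloc[3])
        centers = (s + e) / 2
        window = np.abs(centers - pos) < 1500
        assert centers[window][np.argmax(v[window])] == pytest.approx(pos, abs=25)

    def test_proximal_class_center_exceeds_distal(self):
        truth = make_truth_table(200, 0.3, seed=3, locus_spacing=4000)
        track = simulate_coverage(truth, 5.0, seed=4)
        near_pos = truth.pos[truth.near_tfbs].to_numpy()
        far_pos = truth.pos[~truth.near_tfbs].to_numpy()
        near_mean = np.mean([track.mean("chrSim", p - 40, p + 40) for p in near_pos])
        far_mean = np.mean([track.mean("chrSim", p - 40, p + 40) for p in far_pos])
        assert near_mean > far_mean


class TestMixturesAndStages:
    def test_mixture_construction_recovers_fractions_linearly(self):
        atlas = make_reference_atlas(seed=0)
        rng = np.random.default_rng(1)
        W = rng.dirichlet(np.ones(5), size=10)
        fr = pd.DataFrame(W, columns=atlas.columns, index=[f"X{i}" for i in range(10)])
        mix = simulate_mixtures(atlas, fr, noise_sd=0.0, rng=rng)
        np.testing.assert_allclose(
            mix.to_numpy(), atlas.to_numpy() @ W.T, atol=1e-12
        )

    def test_stage_gradient_is_monotone_for_strong_cpgs(self):
        ct = pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(50)],
                "base_beta": np.full(50, 0.5),
                "is_strong": [True] * 10 + [False] * 40,
            }
        )
        prof = simulate_stage_profiles(ct, seed=0, noise_sd=0.0)
        strong = prof.iloc[:10]
        diffs = np.diff(strong.to_numpy(), axis=1)
        assert (diffs < 0).all()  # immature high -> mature low
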