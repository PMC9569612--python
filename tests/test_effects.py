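"""Stratified delta-meth, proportion tests, metaprofiles and stage profiles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import hypergeom

from tfmeth.effects import metaprofile, proportion_test, stage_profile, stratify_delta
from tfmeth.types import CoverageTrack


def _dm_frame(deltas, is_dm=None, is_dhm=None):
    n = len(deltas)
    ids = [f"cg{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "feature_id": ids,
            "delta": deltas,
            "is_dm": np.ones(n, bool) if is_dm is None else is_dm,
            "is_dhm": np.zeros(n, bool) if is_dhm is None else is_dhm,
        },
        index=ids,
    )


class TestStratifyDelta:
    def test_equal_deltas_give_equal_means_and_large_p(self):
        dm = _dm_frame([0.1] * 8)
        prox = {f"cg{i}": i < 4 for i in range(8)}
        near, rest = stratify_delta(dm, prox, restrict="all")
        assert near.mean_delta == rest.mean_delta == pytest.approx(0.1)
        assert near.test_p > 0.5

    def test_overall_mean_is_weighted_stratum_mean(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(0.1, 0.05, 50)
        dm = _dm_frame(deltas)
        prox = {f"cg{i}": bool(rng.random() < 0.3) for i in range(50)}
        near, rest = stratify_delta(dm, prox, restrict="all")
        weighted = (near.mean_delta * near.n + rest.mean_delta * rest.n) / 50
        assert weighted == pytest.approx(deltas.mean(), abs=1e-12)

    def test_empty_stratum_skips_test(self):
        dm = _dm_frame([0.1, 0.2, 0.3])
        near, rest = stratify_delta(dm, {f"cg{i}": False for i in range(3)},
                                    restrict="all")
        assert near.n == 0 and np.isnan(near.test_p)

    def test_rank_test_matches_exhaustive_permutation(self):
        """Strata of sizes 3 and 4: exact MWU p equals full enumeration."""
        deltas = [0.31, 0.12, 0.55, 0.07, 0.21, 0.44, 0.18]
        dm = _dm_frame(deltas)
        prox = {f"cg{i}": i < 3 for i in range(7)}
        near, _ = stratify_delta(dm, prox, restrict="all")
        x = np.array(deltas)
        obs_u = sps.mannwhitneyu(x[:3], x[3:], alternative="two-sided").statistic
        # enumerate all C(7,3) group assignments of the pooled values
        count = total = 0
        for idx in combinations(range(7), 3):
            a = x[list(idx)]
            b = x[[i for i in range(7) if i not in idx]]
            u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
            d_obs = abs(obs_u - 3 * 4 / 2)
            if abs(u - 3 * 4 / 2) >= d_obs - 1e-12:
                count += 1
            total += 1
        assert near.test_p == pytest.approx(count / total, abs=1e-12)

    def test_dm_restriction_drops_nonsignificant(self):
        dm = _dm_frame([0.1, 0.5, 0.2], is_dm=np.array([True, False, True]))
        prox = {"cg0": True, "cg1": True, "cg2": False}
        near, rest = stratify_delta(dm, prox, restrict="dm")
        assert near.n == 1 and rest.n == 1


class TestProportionTest:
    def test_matches_hypergeometric_enumeration(self):
        near = np.array([True] * 8 + [False] * 2)
        rest = np.array([True] * 1 + [False] * 9)
        pn, pr, p = proportion_test(near, rest)
        # exhaustive tail sum: P of tables at least as extreme by pmf
        M, n, N = 20, 9, 10  # total, total hyper, near-stratum size
        obs = hypergeom.pmf(8, M, n, N)
        exact = sum(
            hypergeom.pmf(k, M, n, N)
            for k in range(max(0, N + n - M), min(n, N) + 1)
            if hypergeom.pmf(k, M, n, N) <= obs + 1e-12
        )
        assert p == pytest.approx(exact, abs=1e-12)
        assert (pn, pr) == (0.8, 0.1)

    def test_transpose_invariance(self):
        near = np.array([True] * 5 + [False] * 15)
        rest = np.array([True] * 9 + [False] * 11)
        _, _, p1 = proportion_test(near, rest)
        # transposing the 2x2 swaps strata with hyper/non-hyper margins
        near_t = np.array([True] * 5 + [False] * 9)
        rest_t = np.array([True] * 15 + [False] * 11)
        _, _, p2 = proportion_test(near_t, rest_t)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_identical_proportions_large_n(self):
        near = np.array([True] * 50 + [False] * 50)
        rest = np.array([True] * 200 + [False] * 200)
        _, _, p = proportion_test(near, rest)
        assert p > 0.9

    def test_empty_margin_flagged(self):
        _, _, p = proportion_test(np.zeros(5, bool), np.zeros(9, bool))
        assert np.isnan(p)


class TestMetaprofile:
    def test_constant_track_gives_constant_bins(self):
        track = CoverageTrack({"c": (np.array([0]), np.array([10000]), np.array([3.5]))})
        prof = metaprofile(track, {"x": [("c", 5000)]}, flank_bp=1000, n_bins=10)
        np.testing.assert_allclose(prof.mean_coverage, 3.5)

    def test_single_interval_hand_computation(self):
        # track: value 2 on [100, 120); anchor at 100, bins of 20bp over +/-40
        track = CoverageTrack({"c": (np.array([100]), np.array([120]), np.array([2.0]))})
        prof = metaprofile(track, {"x": [("c", 100)]}, flank_bp=40, n_bins=4)
        np.testing.assert_allclose(prof.mean_coverage, [0.0, 0.0, 2.0, 0.0])

    def test_class_profile_is_mean_of_single_anchor_profiles(self):
        rng = np.random.default_rng(0)
        starts = np.arange(0, 4000, 100)
        track = CoverageTrack(
            {"c": (starts, starts + 100, rng.random(len(starts)) * 10)}
        )
        a = metaprofile(track, {"x": [("c", 1500)]}, flank_bp=500, n_bins=10)
        b = metaprofile(track, {"x": [("c", 2500)]}, flank_bp=500, n_bins=10)
        both = metaprofile(track, {"x": [("c", 1500), ("c", 2500)]},
                           flank_bp=500, n_bins=10)
        np.testing.assert_allclose(
            both.mean_coverage, (a.mean_coverage + b.mean_coverage) / 2, atol=1e-12
        )

    def test_off_contig_bins_marked_missing(self):
        track = CoverageTrack({"c": (np.array([0]), np.array([500]), np.array([1.0]))})
        prof = metaprofile(track, {"x": [("c", 100)]}, flank_bp=200, n_bins=4)
        assert np.isnan(prof.mean_coverage.iloc[0])  # bin [-200,-100) off contig
        np.testing.assert_allclose(prof.mean_coverage.iloc[1:], 1.0)

    def test_odd_bin_count_rejected(self):
        track = CoverageTrack({"c": (np.array([0]), np.array([10]), np.array([1.0]))})
        with pytest.raises(ValueError, match="even"):
            metaprofile(track, {"x": [("c", 5)]}, flank_bp=10, n_bins=5)


class TestStageProfile:
    def _inputs(self):
        stages = pd.DataFrame(
            {"HSC": [0.8, 0.9], "GMP": [0.5, 0.6], "neutrophil": [0.1, 0.2]},
            index=["cg1", "cg2"],
        )
        beta = pd.DataFrame(
            {"M0": [0.9, 0.8], "W0": [0.3, 0.2], "W1": [0.4, 0.3]},
            index=["cg1", "cg2"],
        )
        return stages, beta, np.array([True, False, False])

    def test_single_cpg_stage_mean_is_its_beta(self):
        stages, beta, mut = self._inputs()
        out = stage_profile(["cg1"], stages, beta, mut, n_boot=50).set_index("profile")
        assert out.loc["HSC"].mean_beta == pytest.approx(0.8)
        assert out.loc["neutrophil"].mean_beta == pytest.approx(0.1)

    def test_planted_maturation_ordering_recovered(self):
        stages, beta, mut = self._inputs()
        out = stage_profile(["cg1", "cg2"], stages, beta, mut, n_boot=50)
        means = out.set_index("profile").mean_beta
        assert means["HSC"] > means["GMP"] > means["neutrophil"]

    def test_mutated_group_more_methylated(self, runx1_cohort):
        _, cohort, ct, extras, _ = runx1_cohort
        strong = list(ct[ct.is_strong].cpg_id)
        out = stage_profile(
            strong, extras["stage_profiles"], cohort.beta,
            cohort.mutation_flags("runx1"), n_boot=100,
        ).set_index("profile")
        assert out.loc["mutated"].mean_beta > out.loc["wild_type"].mean_beta
        assert (out.ci_lo <= out.mean_beta).all() and (out.mean_beta <= out.ci_hi).all()
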