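"""Motif model and scanner against exhaustive-enumeration oracles."""

from itertools import product

import numpy as np
import pytest

from tfmeth.motifs import (
    MotifModel,
    build_motif,
    filter_by_peaks,
    annotate_cpg_proximity,
    scan_windows,
    PredictedSite,
)
from tfmeth.types import CpGRecord, GenomicInterval

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def enumeration_threshold(motif: MotifModel, target: float):
    """Exact threshold by scoring all 4^L background sequences."""
    L = len(motif)
    scores = np.array([motif.score("".join(k)) for k in product("ACGT", repeat=L)])
    p1 = 0.25**L
    uniq = np.sort(np.unique(scores))
    cands = [s for s in uniq if (scores >= s - 1e-9).sum() * p1 <= target + 1e-12]
    return min(cands) if cands else float(uniq[-1] + 1.0)


def brute_force_scan(seq: str, motif: MotifModel):
    """Score every offset on both strands with the scalar scorer."""
    L = len(motif)
    hits = []
    for off in range(len(seq) - L + 1):
        sub = seq[off : off + L]
        for strand, s in (("+", sub), ("-", revcomp(sub))):
            score = motif.score(s)
            if score >= motif.threshold_score:
                hits.append((off, strand, round(score, 9)))
    return sorted(hits)


class TestThreshold:
    def test_uniform_motif_identity_case(self):
        # counts proportional to background at every position -> log-odds 0
        m = build_motif(np.full((3, 4), 25.0), target_pvalue=1.0, pseudocount=0.0)
        np.testing.assert_allclose(m.log_odds, 0.0)
        assert m.threshold_score == 0.0
        assert m.threshold_pvalue == 1.0
        assert m.score("ACG") == 0.0

    def test_length3_threshold_matches_enumeration(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 60, size=(3, 4)).astype(float)
        m = build_motif(counts, target_pvalue=0.05)
        assert m.threshold_score == pytest.approx(enumeration_threshold(m, 0.05), abs=1e-6)

    @pytest.mark.parametrize("seed", range(12))
    def test_dp_equals_enumeration_random_pwms(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 9))
        target = float(rng.choice([0.05, 0.01, 0.001]))
        counts = rng.integers(0, 80, size=(L, 4)).astype(float)
        m = build_motif(counts, target_pvalue=target)
        enum_thr = enumeration_threshold(m, target)
        assert m.threshold_score == pytest.approx(enum_thr, abs=1e-6)
        # self-consistency: tail at threshold <= target
        scores = np.array([m.score("".join(k)) for k in product("ACGT", repeat=L)])
        assert (scores >= m.threshold_score - 1e-9).mean() <= target + 1e-12

    @pytest.mark.parametrize("seed", range(6))
    def test_binned_dp_is_conservative_and_close(self, seed):
        rng = np.random.default_rng(seed + 100)
        L = int(rng.integers(3, 9))
        counts = rng.integers(0, 80, size=(L, 4)).astype(float)
        m = build_motif(counts, target_pvalue=0.01)
        mb = m.with_threshold(0.01, method="binned")
        scores = np.array([m.score("".join(k)) for k in product("ACGT", repeat=L)])
        # conservative: exact tail at the binned threshold never exceeds target
        assert (scores >= mb.threshold_score - 1e-9).mean() <= 0.01 + 1e-12
        assert mb.threshold_score >= m.threshold_score - 1e-6

    def test_threshold_monotone_in_target_pvalue(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 60, size=(6, 4)).astype(float)
        thresholds = [
            build_motif(counts, target_pvalue=p).threshold_score
            for p in (0.05, 0.01, 0.001)
        ]
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_zero_background_with_counts_rejected(self):
        with pytest.raises(ValueError, match="background"):
            build_motif(np.ones((2, 4)), background=(0.5, 0.5, 0.0, 0.0))


@pytest.fixture(scope="module")
def motif():
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 80, size=(6, 4)).astype(float)
    return build_motif(counts, target_pvalue=0.01)


class TestScan:
    def test_all_n_window_yields_no_sites(self, motif):
        genome = {"c": "N" * 200}
        sites = scan_windows(genome, [CpGRecord("cg1", "c", 100)], motif, 50)
        assert sites == []

    @pytest.mark.parametrize("seed", range(10))
    def test_scan_equals_brute_force_on_toy_contigs(self, motif, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = {"c": seq}
        hw = 150
        sites = scan_windows(genome, [CpGRecord("cg1", "c", hw)], motif, hw)
        got = sorted(
            (s.interval.start, s.interval.strand, round(s.score, 9)) for s in sites
        )
        assert got == brute_force_scan(seq, motif)

    def test_strand_symmetry(self, motif):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=240))
        hw = 120
        fwd = scan_windows({"c": seq}, [CpGRecord("cg1", "c", hw)], motif, hw)
        rev = scan_windows({"c": revcomp(seq)}, [CpGRecord("cg1", "c", hw)], motif, hw)
        n = len(seq)
        mirrored = sorted(
            (n - s.interval.end, "-" if s.interval.strand == "+" else "+",
             round(s.score, 9))
            for s in fwd
        )
        got = sorted(
            (s.interval.start, s.interval.strand, round(s.score, 9)) for s in rev
        )
        assert got == mirrored

    def test_raising_pvalue_never_removes_sites(self, motif):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        manifest = [CpGRecord("cg1", "c", 150)]
        loose = motif.with_threshold(0.05)
        strict_sites = {
            (s.interval.start, s.interval.strand)
            for s in scan_windows({"c": seq}, manifest, motif, 150)
        }
        loose_sites = {
            (s.interval.start, s.interval.strand)
            for s in scan_windows({"c": seq}, manifest, loose, 150)
        }
        assert strict_sites <= loose_sites

    def test_position_beyond_contig_rejected(self, motif):
        with pytest.raises(ValueError, match="exceeds contig"):
            scan_windows({"c": "ACGT"}, [CpGRecord("cg1", "c", 10)], motif, 2)


class TestPeakFilter:
    def _site(self, start, end):
        return PredictedSite(GenomicInterval("c", start, end, "+"), 1.0, "cg1")

    def test_one_bp_overlap_supported(self):
        out = filter_by_peaks([self._site(10, 20)], [GenomicInterval("c", 19, 25)])
        assert out[0].peak_supported is True

    def test_touching_halfopen_unsupported(self):
        out = filter_by_peaks([self._site(10, 20)], [GenomicInterval("c", 20, 30)])
        assert out[0].peak_supported is False

    def test_empty_peak_set_all_unsupported_and_require_drops(self):
        sites = [self._site(0, 5), self._site(10, 15)]
        assert all(s.peak_supported is False for s in filter_by_peaks(sites, []))
        assert filter_by_peaks(sites, [], require_peak=True) == []

    def test_random_flags_match_quadratic_oracle(self):
        rng = np.random.default_rng(21)
        sites = [
            self._site(int(a), int(a) + int(rng.integers(1, 20)))
            for a in rng.integers(0, 500, size=60)
        ]
        peaks = []
        for a in rng.integers(0, 500, size=40):
            peaks.append(GenomicInterval("c", int(a), int(a) + int(rng.integers(1, 30))))
        peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        flagged = filter_by_peaks(sites, peaks)
        for site in flagged:
            expect = any(site.interval.overlaps(pk) for pk in peaks)
            assert site.peak_supported == expect


class TestProximity:
    def test_owning_cpg_flagged(self):
        manifest = [CpGRecord("cg1", "c", 100), CpGRecord("cg2", "c", 400)]
        site = PredictedSite(GenomicInterval("c", 90, 96, "+"), 2.0, "cg1")
        near = annotate_cpg_proximity(manifest, [site])
        assert near == {"cg1": True, "cg2": False}

    def test_no_sites_all_false(self):
        manifest = [CpGRecord("cg1", "c", 100)]
        assert annotate_cpg_proximity(manifest, []) == {"cg1": False}

    def test_peak_rejected_sites_do_not_count(self):
        manifest = [CpGRecord("cg1", "c", 100)]
        site = PredictedSite(GenomicInterval("c", 90, 96, "+"), 2.0, "cg1", False)
        assert annotate_cpg_proximity(manifest, [site]) == {"cg1": False}
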