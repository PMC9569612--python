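"""PWM motif scanning with exact score-distribution p-value thresholds.

A motif is held as a log2-odds matrix against a background base
distribution.  The score threshold for a target p-value is derived from
the exact distribution of the score of a random background sequence,
computed by dynamic programming: the per-position score distributions are
convolved across positions.  Two DP backends are provided:

* ``exact`` — convolution over the exact achievable score sums (floating
  scores keyed on a fine rounding grid).  The state space is bounded by
  4^L, so this is the default for motifs up to length 10 and is what the
  exhaustive-enumeration tests compare against.
* ``binned`` — per-position scores are rounded **up** onto a fixed grid
  (1000 bins spanning the achievable score range) before convolution.
  Rounding up makes the reported threshold conservative: the true tail
  probability at the threshold never exceeds the target.

Scanning covers both strands of every CpG-centered window; ambiguous
bases (N) contribute a score of minus infinity at their position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import CpGRecord, GenomicInterval

__all__ = [
    "MotifModel",
    "PredictedSite",
    "build_motif",
    "scan_windows",
    "filter_by_peaks",
    "annotate_cpg_proximity",
    "score_distribution",
]

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)  # 4 = ambiguous
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

EXACT_DP_MAX_LEN = 10
_KEY_DECIMALS = 9  # rounding grid aligning float sums in the exact DP


@dataclass(frozen=True)
class MotifModel:
    """A PWM in log2-odds form with its exact-tail score threshold."""

    name: str
    log_odds: np.ndarray          # L x 4, log2(p_base / background)
    background: np.ndarray        # 4 probabilities summing to 1
    threshold_score: float
    threshold_pvalue: float       # exact tail probability at threshold_score

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or bg.min() < 0:
            raise ValueError("background must be 4 non-negative values summing to 1")

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    def score(self, seq: str) -> float:
        """Log-odds score of a sequence of exactly motif length; N -> -inf."""
        if len(seq) != len(self):
            raise ValueError("sequence length must equal motif length")
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if np.any(codes == 4):
            return float("-inf")
        return float(self.log_odds[np.arange(len(self)), codes].sum())

    def reverse_complement_matrix(self) -> np.ndarray:
        """Log-odds matrix scoring the minus-strand site on forward sequence."""
        return self.log_odds[::-1, ::-1].copy()

    def with_threshold(self, target_pvalue: float, method: str = "auto") -> "MotifModel":
        thr, pv = _threshold_from_distribution(
            self.log_odds, self.background, target_pvalue, method
        )
        return replace(self, threshold_score=thr, threshold_pvalue=pv)


@dataclass
class PredictedSite:
    """A PWM match inside a CpG-centered window."""

    interval: GenomicInterval
    score: float
    cpg_id: str
    peak_supported: bool | None = None


def build_motif(
    counts: np.ndarray,
    background=(0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
    target_pvalue: float = 0.001,
    name: str = "motif",
    method: str = "auto",
) -> MotifModel:
    """Build a log-odds motif and its exact-tail score threshold.

    ``counts`` is an L x 4 non-negative count (or weight) matrix in
    A, C, G, T order.  Each row is normalized after adding ``pseudocount``
    to every entry; the threshold is the smallest score s with
    P(score of a random background L-mer >= s) <= ``target_pvalue``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
        raise ValueError("counts must be an L x 4 matrix with L >= 1")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    bg = np.asarray(background, dtype=float)
    if np.any((bg == 0) & (counts.sum(axis=0) > 0)):
        raise ValueError("background has a zero entry at a base with nonzero counts")
    if not 0 < target_pvalue <= 1:
        raise ValueError("target_pvalue must be in (0, 1]")
    probs = counts + pseudocount
    probs = probs / probs.sum(axis=1, keepdims=True)
    log_odds = np.log2(probs / bg)
    thr, pv = _threshold_from_distribution(log_odds, bg, target_pvalue, method)
    return MotifModel(
        name=name,
        log_odds=log_odds,
        background=bg,
        threshold_score=thr,
        threshold_pvalue=pv,
    )


def score_distribution(
    log_odds: np.ndarray, background: np.ndarray, method: str = "exact", n_bins: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the background score: (sorted scores, probabilities).

    ``exact`` convolves the achievable sums directly; ``binned`` rounds
    per-position scores up onto an ``n_bins`` grid first (conservative).
    """
    log_odds = np.asarray(log_odds, dtype=float)
    bg = np.asarray(background, dtype=float)
    if method == "exact":
        dist: dict[float, float] = {0.0: 1.0}
        for row in log_odds:
            nxt: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    if bg[b] == 0:
                        continue
                    key = round(s + row[b], _KEY_DECIMALS)
                    nxt[key] = nxt.get(key, 0.0) + p * bg[b]
            dist = nxt
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        return scores, probs
    if method == "binned":
        lo = log_odds.min(axis=1).sum()
        hi = log_odds.max(axis=1).sum()
        width = (hi - lo) / n_bins if hi > lo else 1.0
        # integer grid per position, rounded UP -> threshold is conservative
        grid = np.ceil(log_odds / width).astype(np.int64)
        gmin = grid.min(axis=1).sum()
        gmax = grid.max(axis=1).sum()
        pmf = np.zeros(gmax - gmin + 1)
        pmf[0] = 1.0
        offset = 0
        for row in grid:
            new = np.zeros_like(pmf)
            rmin = row.min()
            for b in range(4):
                if bg[b] == 0:
                    continue
                shift = row[b] - rmin
                new[shift:] += bg[b] * pmf[: len(pmf) - shift if shift else None]
            pmf = new
            offset += rmin
        # grid index i corresponds to score (gmin + i) * width, where the
        # accumulated offset equals gmin by construction
        scores = (np.arange(len(pmf)) + gmin) * width
        keep = pmf > 0
        return scores[keep], pmf[keep]
    raise ValueError(f"unknown method {method!r}")


def _threshold_from_distribution(log_odds, background, target_pvalue, method="auto"):
    if method == "auto":
        method = "exact" if log_odds.shape[0] <= EXACT_DP_MAX_LEN else "binned"
    scores, probs = score_distribution(log_odds, background, method=method)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= scores[i])
    ok = tail <= target_pvalue + 1e-12
    if not np.any(ok):
        # no achievable score is rare enough: threshold just above the max
        return float(scores[-1] + 1.0), 0.0
    i = int(np.argmax(ok))
    return float(scores[i]), float(tail[i])


# ---------------------------------------------------------------- scanning


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)


def _score_all_offsets(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every offset of ``codes`` against an L x 4 matrix (N -> -inf)."""
    L = matrix.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    padded = np.hstack([matrix, np.full((L, 1), -np.inf)])  # column 4 = N
    acc = np.zeros(n)
    for j in range(L):
        acc = acc + padded[j, codes[j : j + n]]
    return acc


def scan_windows(
    genome: dict[str, str],
    manifest: list[CpGRecord],
    motif: MotifModel,
    window_halfwidth: int = 100,
) -> list[PredictedSite]:
    """Scan both strands of every CpG-centered window for motif matches.

    The window for a CpG at position p is ``[p - hw, p + hw)``, truncated
    at contig edges.  Every offset whose score reaches the motif threshold
    is reported as a site owned by that CpG.
    """
    fwd = motif.log_odds
    rev = motif.reverse_complement_matrix()
    L = len(motif)
    sites: list[PredictedSite] = []
    seen_windows = set()
    for rec in manifest:
        if rec.chrom not in genome:
            raise KeyError(f"CpG {rec.cpg_id}: chromosome {rec.chrom!r} not in genome")
        contig = genome[rec.chrom]
        if rec.pos >= len(contig):
            raise ValueError(
                f"CpG {rec.cpg_id}: position {rec.pos} exceeds contig length "
                f"{len(contig)}"
            )
        key = (rec.cpg_id, rec.chrom, rec.pos)
        if key in seen_windows:  # multi-gene CpGs scan once
            continue
        seen_windows.add(key)
        start = max(0, rec.pos - window_halfwidth)
        end = min(len(contig), rec.pos + window_halfwidth)
        codes = _encode(contig[start:end])
        for matrix, strand in ((fwd, "+"), (rev, "-")):
            scores = _score_all_offsets(codes, matrix)
            for off in np.nonzero(scores >= motif.threshold_score)[0]:
                sites.append(
                    PredictedSite(
                        interval=GenomicInterval(
                            rec.chrom, start + int(off), start + int(off) + L, strand
                        ),
                        score=float(scores[off]),
                        cpg_id=rec.cpg_id,
                    )
                )
    return sites


def filter_by_peaks(
    sites: list[PredictedSite],
    peaks: list[GenomicInterval],
    require_peak: bool = False,
) -> list[PredictedSite]:
    """Set ``peak_supported`` = site overlaps >= 1 bp with any peak.

    With ``require_peak`` unsupported sites are dropped.  An empty peak
    set marks every site unsupported.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for pk in peaks:
        tmp.setdefault(pk.chrom, []).append((pk.start, pk.end))
    for chrom, ivs in tmp.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        # running max of ends handles contained intervals
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        by_chrom[chrom] = (starts, ends)
    out = []
    for site in sites:
        supported = False
        if site.interval.chrom in by_chrom:
            starts, ends = by_chrom[site.interval.chrom]
            # candidate: last peak starting before site end
            i = int(np.searchsorted(starts, site.interval.end, side="left")) - 1
            supported = bool(i >= 0 and ends[i] > site.interval.start)
        site = PredictedSite(site.interval, site.score, site.cpg_id, supported)
        if supported or not require_peak:
            out.append(site)
    return out


def annotate_cpg_proximity(
    manifest: list[CpGRecord],
    sites: list[PredictedSite],
    retained_only: bool = True,
) -> dict[str, bool]:
    """Per-CpG flag: does >= 1 (retained) site lie in the CpG's own window?

    Sites carry their owning CpG from the scan, so proximity is membership
    of the owner's site list.  With ``retained_only`` sites filtered to
    ``peak_supported is False`` do not count (unfiltered sites, where
    ``peak_supported`` is None, always count).
    """
    near = {rec.cpg_id: False for rec in manifest}
    for site in sites:
        if retained_only and site.peak_supported is False:
            continue
        if site.cpg_id in near:
            near[site.cpg_id] = True
    return near
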