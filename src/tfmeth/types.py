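"""Core domain types shared by every pipeline stage.

Coordinate convention: all genomic coordinates are 0-based, half-open
``[start, end)``.  Beta-values live in ``[0, 1]``; expression values are
non-negative, RPKM-like.  Missing values are carried explicitly as NaN and
are never imputed here — each statistic states its own missing-data policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGRecord",
    "SampleMeta",
    "GenomicInterval",
    "CoverageTrack",
    "CohortMatrices",
]


@dataclass(frozen=True)
class CpGRecord:
    """One array CpG: identifier, genomic position and associated gene.

    ``pos`` is the 0-based position of the C of the CpG on the forward
    strand.  ``gene`` may be empty when the manifest associates no gene.
    """

    cpg_id: str
    chrom: str
    pos: int
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"CpG {self.cpg_id}: pos must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: mutation flags and optional survival fields."""

    sample_id: str
    runx1_mutated: bool = False
    cebpa_mutated: bool = False
    survival_days: float | None = None
    death_observed: bool | None = None

    def __post_init__(self) -> None:
        if self.survival_days is None and self.death_observed is not None:
            raise ValueError(
                f"sample {self.sample_id}: death_observed set without survival_days"
            )
        if self.survival_days is not None and self.survival_days < 0:
            raise ValueError(f"sample {self.sample_id}: negative survival_days")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-chromosome step function: sorted, non-overlapping valued intervals.

    Gaps between intervals have value 0.  Supports length-weighted mean
    queries over arbitrary half-open windows, the primitive the coverage
    metaprofile is built on.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # intervals: chrom -> (starts, ends, values), each already validated
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged interval arrays")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: interval with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping intervals")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite coverage value")
            # cum[i] = integral of the track over [0, starts[i])
            seg = values * (ends - starts)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            self._data[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_lists(
        cls, chroms: list[str], starts: list[int], ends: list[int], values: list[float]
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for c, s, e, v in zip(chroms, starts, ends, values):
            by_chrom.setdefault(c, []).append((s, e, v))
        packed = {}
        for c, rows in by_chrom.items():
            rows.sort()
            s, e, v = zip(*rows)
            packed[c] = (np.array(s), np.array(e), np.array(v))
        return cls(packed)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s, e, v, _ = self._data[chrom]
        return s, e, v

    def _integral_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the step function over [0, x) for each x."""
        starts, ends, values, cum = self._data[chrom]
        x = np.asarray(x, dtype=np.float64)
        idx = np.searchsorted(starts, x, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        inside = idx >= 0
        if np.any(inside):
            i = np.maximum(idx, 0)
            overlap = np.clip(x - starts[i], 0, ends[i] - starts[i])
            out = out + np.where(inside, values[i] * overlap, 0.0)
        return out

    def mean(self, chrom: str, start: float, end: float) -> float:
        """Length-weighted mean coverage over [start, end); gaps count as 0."""
        if end <= start:
            raise ValueError("mean() needs start < end")
        if chrom not in self._data:
            return 0.0
        lo, hi = self._integral_at(chrom, np.array([start, end]))
        return float((hi - lo) / (end - start))

    def means(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`mean` for aligned start/end arrays."""
        starts = np.asarray(starts, dtype=np.float64)
        ends = np.asarray(ends, dtype=np.float64)
        if np.any(ends <= starts):
            raise ValueError("means() needs start < end elementwise")
        if chrom not in self._data:
            return np.zeros(len(starts))
        lo = self._integral_at(chrom, starts)
        hi = self._integral_at(chrom, ends)
        return (hi - lo) / (ends - starts)


@dataclass
class CohortMatrices:
    """Aligned beta-value and expression matrices plus sample metadata.

    ``beta`` is CpG x sample, ``expression`` gene x sample; columns of both
    follow ``samples`` order exactly.  Either matrix may be absent (None)
    for partially loaded cohorts.
    """

    beta: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for mat, name in ((self.beta, "beta"), (self.expression, "expression")):
            if mat is None:
                continue
            if list(mat.columns) != ids:
                raise ValueError(f"{name} columns do not match sample order")
        if self.beta is not None:
            vals = self.beta.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                raise ValueError("beta values outside [0, 1]")
        if self.expression is not None:
            vals = self.expression.to_numpy(dtype=float)
            if np.any((vals < 0) & ~np.isnan(vals)):
                raise ValueError("negative expression values")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def mutation_flags(self, which: str) -> np.ndarray:
        """Boolean array over samples for mutation ``which`` (runx1|cebpa)."""
        if which == "runx1":
            return np.array([s.runx1_mutated for s in self.samples], dtype=bool)
        if which == "cebpa":
            return np.array([s.cebpa_mutated for s in self.samples], dtype=bool)
        raise ValueError(f"unknown mutation flag {which!r}")

    def survival_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "time": np.nan if s.survival_days is None else s.survival_days,
                    "event": np.nan if s.death_observed is None else bool(s.death_observed),
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))
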