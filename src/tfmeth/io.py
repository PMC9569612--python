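"""Readers and writers for every flat-file format the pipeline touches.

All formats are plain text: TSV matrices (CpG x sample, gene x sample),
a TSV CpG manifest and sample sheet, BED (3 or 6 column), bedGraph,
FASTA, and HOCOMOCO-style plain-text PWM/PCM files.  Coordinates in BED
and bedGraph are 0-based half-open, which is also the internal convention,
so no conversion happens at these boundaries.  No statistics live here.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CohortMatrices, CoverageTrack, CpGRecord, GenomicInterval, SampleMeta

__all__ = [
    "FormatError",
    "read_manifest",
    "write_manifest",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_pwm",
    "write_pwm",
    "read_fasta",
    "write_fasta",
    "read_atlas",
    "write_atlas",
]

NA_STRINGS = {"", "NA", "NaN", "nan", "na", "NULL", "."}


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- manifest


def read_manifest(path: str | Path) -> list[CpGRecord]:
    """Read a CpG manifest TSV with columns cpg_id, chrom, pos, gene.

    Duplicate (cpg_id, gene) rows are rejected; duplicate cpg_id rows with
    different genes are allowed (multi-gene CpGs appear once per gene).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cpg_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest missing columns {sorted(required - set(df.columns))}")
    if "gene" not in df.columns:
        df["gene"] = ""
    seen = set()
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        key = (row.cpg_id, row.gene)
        if key in seen:
            raise FormatError(f"duplicate manifest row for CpG {row.cpg_id!r}")
        seen.add(key)
        try:
            pos = int(row.pos)
        except ValueError as e:
            raise FormatError(f"manifest line {i + 2}: bad pos {row.pos!r}") from e
        records.append(CpGRecord(row.cpg_id, row.chrom, pos, row.gene))
    return records


def write_manifest(records: list[CpGRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.cpg_id, r.chrom, r.pos, r.gene) for r in records],
        columns=["cpg_id", "chrom", "pos", "gene"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- matrices


def _read_matrix(path, value_name, lo, hi) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: matrix needs an id column plus >=1 sample column")
    id_col = df.columns[0]
    sample_ids = list(df.columns[1:])
    if any(s.strip() == "" or s.startswith("Unnamed:") for s in sample_ids):
        raise FormatError(f"{path}: empty sample id in header")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ids in header")
    ids = df[id_col].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate row id {dup.iloc[0]!r}")
    values = np.full((len(ids), len(sample_ids)), np.nan)
    for j, col in enumerate(sample_ids):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell in NA_STRINGS:
                continue
            try:
                v = float(cell)
            except ValueError:
                continue  # unparseable cells become missing
            if math.isnan(v):
                continue
            if not (lo <= v <= (hi if hi is not None else math.inf)):
                raise FormatError(
                    f"{path}: {value_name} value {v} out of range for row "
                    f"{ids[i]!r}, column {col!r}"
                )
            values[i, j] = v
    return pd.DataFrame(values, index=pd.Index(ids, name=id_col), columns=sample_ids)


def read_beta_matrix(
    path: str | Path, manifest: list[CpGRecord] | None = None
) -> pd.DataFrame:
    """Read a CpG x sample beta matrix; values outside [0,1] are rejected.

    When a manifest is given, rows are restricted to manifest CpGs and
    reordered to manifest order; manifest CpGs absent from the file become
    all-missing rows.
    """
    mat = _read_matrix(path, "beta", 0.0, 1.0)
    if manifest is not None:
        order = list(dict.fromkeys(r.cpg_id for r in manifest))
        mat = mat.reindex(order)
    return mat


def write_beta_matrix(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label=beta.index.name or "cpg_id", na_rep="NA")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression matrix; negative values are rejected."""
    return _read_matrix(path, "expression", 0.0, None)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "gene", na_rep="NA")


# ---------------------------------------------------------------- sample sheet

_BOOL = {"true": True, "1": True, "t": True, "false": False, "0": False, "f": False}


def _parse_bool(cell: str, where: str) -> bool:
    v = _BOOL.get(cell.strip().lower())
    if v is None:
        raise FormatError(f"{where}: bad boolean {cell!r}")
    return v


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet TSV (sample_id, mutation flags, survival fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "runx1_mutated", "cebpa_mutated"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet missing columns {sorted(required - set(df.columns))}")
    samples = []
    for i, row in df.iterrows():
        where = f"sample sheet line {i + 2}"
        surv = row.get("survival_days", "")
        surv_val = None if surv.strip() in NA_STRINGS else float(surv)
        dead = row.get("death_observed", "")
        dead_val = None if dead.strip() in NA_STRINGS else _parse_bool(dead, where)
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                runx1_mutated=_parse_bool(row["runx1_mutated"], where),
                cebpa_mutated=_parse_bool(row["cebpa_mutated"], where),
                survival_days=surv_val,
                death_observed=dead_val,
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample ids in sample sheet")
    return samples


def write_sample_sheet(samples: list[SampleMeta], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "runx1_mutated": int(s.runx1_mutated),
                "cebpa_mutated": int(s.cebpa_mutated),
                "survival_days": "NA" if s.survival_days is None else s.survival_days,
                "death_observed": "NA" if s.death_observed is None else int(s.death_observed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- BED / bedGraph


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read 3+ column BED; output sorted by (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {ln}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: non-integer coordinates") from e
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: {e}") from e
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if scores is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0.0 if scores is None else scores[i]
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tsite{i}\t{score:g}\t{iv.strand}\n"
                )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a coverage track (gaps read as 0)."""
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path} line {ln}: fewer than 4 bedGraph columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as err:
                raise FormatError(f"{path} line {ln}: bad numeric field") from err
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            values.append(v)
    try:
        return CoverageTrack.from_lists(chroms, starts, ends, values)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.intervals(chrom)
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")


# ---------------------------------------------------------------- PWM


def read_pwm(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a plain-text count/weight matrix, one row per motif position.

    Columns are A, C, G, T.  An optional leading ``>`` line carries the
    motif name; otherwise the file stem is used.  Returns (name, L x 4 array).
    """
    path = Path(path)
    name = path.stem
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].strip() or name
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{path} row {len(rows) + 1} (line {ln}): expected 4 numbers, "
                    f"got {len(parts)}"
                )
            try:
                vals = [float(x) for x in parts]
            except ValueError as e:
                raise FormatError(f"{path} line {ln}: non-numeric entry") from e
            if any(v < 0 for v in vals):
                raise FormatError(f"{path} line {ln}: negative count")
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty PWM")
    return name, np.asarray(rows, dtype=float)


def write_pwm(name: str, counts: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for row in np.asarray(counts, dtype=float):
            fh.write("\t".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) genome FASTA into a dict of upper-case sequences."""
    seqs: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise FormatError(f"duplicate FASTA record {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise FormatError("FASTA sequence before first header")
                seqs[current].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- atlas


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Read a reference atlas TSV (marker CpG x cell type, beta in [0,1])."""
    atlas = _read_matrix(path, "atlas beta", 0.0, 1.0)
    if atlas.shape[1] < 2:
        raise FormatError("atlas needs >= 2 cell types")
    return atlas


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(path, sep="\t", index_label=atlas.index.name or "cpg_id", na_rep="NA")


# ---------------------------------------------------------------- cohort assembly


def load_cohort(
    beta_path: str | Path | None,
    expr_path: str | Path | None,
    sheet_path: str | Path,
    manifest: list[CpGRecord] | None = None,
) -> CohortMatrices:
    """Assemble a cohort from matrix files + sample sheet, aligning columns.

    Samples are restricted to those present in every supplied matrix;
    raises if the intersection is empty.
    """
    samples = read_sample_sheet(sheet_path)
    ids = [s.sample_id for s in samples]
    beta = read_beta_matrix(beta_path, manifest) if beta_path else None
    expr = read_expression_matrix(expr_path) if expr_path else None
    keep = [
        sid
        for sid in ids
        if (beta is None or sid in beta.columns) and (expr is None or sid in expr.columns)
    ]
    if not keep:
        raise FormatError("no samples shared between sample sheet and matrices")
    samples = [s for s in samples if s.sample_id in set(keep)]
    if beta is not None:
        beta = beta[keep]
    if expr is not None:
        expr = expr[keep]
    return CohortMatrices(beta=beta, expression=expr, samples=samples)
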