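"""Readers and writers for the plain-text formats used across the pipeline.

BED records are tab-separated with no header; 3, 4 (name) or 6 (name, score,
strand) columns. FASTA goes through Biopython. Expression-style tables are
headered TSVs read with pandas. All readers validate coordinates and report
the offending line number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionRecord, Gene, GenomicInterval


@dataclass(frozen=True, slots=True)
class BedRecord:
    """One BED line. ``name`` alone -> BED4; name+score+strand -> BED6."""

    interval: GenomicInterval
    name: str | None = None
    score: int | None = None


def _parse_bed_line(line: str, lineno: int) -> BedRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) not in (3, 4, 6):
        raise ValueError(f"line {lineno}: expected 3, 4 or 6 BED columns, got {len(fields)}")
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinate") from exc
    strand = fields[5] if len(fields) == 6 else "."
    try:
        iv = GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc
    name = fields[3] if len(fields) >= 4 else None
    score = int(fields[4]) if len(fields) == 6 else None
    return BedRecord(iv, name, score)


def read_bed(path: str | Path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            records.append(_parse_bed_line(line, lineno))
    return records


def format_bed_record(rec: BedRecord) -> str:
    iv = rec.interval
    fields = [iv.chrom, str(iv.start), str(iv.end)]
    if rec.name is not None:
        fields.append(rec.name)
        if rec.score is not None:
            fields += [str(rec.score), iv.strand]
    return "\t".join(fields)


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_bed_record(rec) + "\n")


def read_gene_bed(path: str | Path) -> list[Gene]:
    """Genes from a BED6 file: name column is the gene id, strand required."""
    genes = []
    for rec in read_bed(path):
        if rec.name is None:
            raise ValueError("gene BED requires a name column")
        genes.append(Gene(rec.name, rec.interval))
    return genes


def write_gene_bed(genes: Iterable[Gene], path: str | Path) -> None:
    write_bed([BedRecord(g.body, g.gene_id, 0) for g in genes], path)


# -- coverage points: two columns, chrom <TAB> 0-based position, one read per line


def read_points(path: str | Path) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer position") from exc
            if pos < 0:
                raise ValueError(f"line {lineno}: negative position {pos}")
            by_chrom.setdefault(fields[0], []).append(pos)
    return {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}


def write_points(points: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in points:
            for pos in points[chrom]:
                fh.write(f"{chrom}\t{int(pos)}\n")


def write_bedgraph(
    values: Sequence[tuple[str, int, int, float]], path: str | Path
) -> None:
    """(chrom, start, end, value) rows to a bedGraph file."""
    with open(path, "w") as fh:
        for chrom, start, end, value in values:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# -- FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- headered TSV tables


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """TSV with columns gene_id, log2fc, fdr and optional mean_expr."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    mean = df["mean_expr"] if "mean_expr" in df.columns else pd.Series(0.0, index=df.index)
    return [
        ExpressionRecord(str(g), float(l), float(f), float(m))
        for g, l, f, m in zip(df["gene_id"], df["log2fc"], df["fdr"], mean)
    ]


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.log2fc, r.fdr, r.mean_expr) for r in records],
        columns=["gene_id", "log2fc", "fdr", "mean_expr"],
    )
    # %.17g guarantees float round-trip to the bit
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_two_column_table(path: str | Path, value_col: str = "log2fc") -> dict[str, float]:
    """gene_id -> value mapping from a headered two-column TSV (Nutlin tables)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "gene_id" not in df.columns or value_col not in df.columns:
        raise ValueError(f"table must have columns gene_id, {value_col}")
    return {str(g): float(v) for g, v in zip(df["gene_id"], df[value_col])}


def write_two_column_table(
    mapping: dict[str, float], path: str | Path, value_col: str = "log2fc"
) -> None:
    with open(path, "w") as fh:
        fh.write(f"gene_id\t{value_col}\n")
        for gene_id, value in mapping.items():
            fh.write(f"{gene_id}\t{value:.17g}\n")
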