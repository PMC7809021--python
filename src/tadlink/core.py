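"""Genomic coordinate types, interval algebra and differential-expression calls.

All coordinates are 0-based half-open (BED convention) throughout the
package; readers converting from 1-based dialects must do so at the parsing
boundary. Chromosome names are matched by exact string equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other``; 0 if disjoint or on another chromosome."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) >= 1


@dataclass(frozen=True, slots=True)
class Gene:
    """A gene body (longest transcript) with a strand-aware TSS."""

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} requires a +/- strand")

    @property
    def tss(self) -> int:
        """Transcription start site: body.start on +, body.end - 1 on -."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    gene_id: str
    log2fc: float
    fdr: float
    mean_expr: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.gene_id}: fdr {self.fdr} outside [0, 1]")


@dataclass(frozen=True, slots=True)
class DEThresholds:
    """Differential-expression cutoffs: FDR < fdr_max and |log2FC| > abs_lfc_min.

    Both inequalities are strict, so a gene sitting exactly on a threshold is
    called stable.
    """

    fdr_max: float = 0.05
    abs_lfc_min: float = 0.5

    def __post_init__(self) -> None:
        if self.fdr_max <= 0 or self.abs_lfc_min <= 0:
            raise ValueError("thresholds must be positive")


def classify_de(
    records: Iterable[ExpressionRecord], thr: DEThresholds = DEThresholds()
) -> dict[str, str]:
    """Partition genes into ``up`` / ``down`` / ``stable``.

    up: fdr < fdr_max and log2fc > abs_lfc_min; down: fdr < fdr_max and
    log2fc < -abs_lfc_min; everything else stable. Duplicate gene ids are
    rejected.
    """
    out: dict[str, str] = {}
    for rec in records:
        if rec.gene_id in out:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        if rec.fdr < thr.fdr_max and rec.log2fc > thr.abs_lfc_min:
            out[rec.gene_id] = "up"
        elif rec.fdr < thr.fdr_max and rec.log2fc < -thr.abs_lfc_min:
            out[rec.gene_id] = "down"
        else:
            out[rec.gene_id] = "stable"
    return out


def _interval_of(obj) -> GenomicInterval:
    """Accept either a bare interval or any object with an ``interval`` field."""
    if isinstance(obj, GenomicInterval):
        return obj
    iv = getattr(obj, "interval", None)
    if isinstance(iv, GenomicInterval):
        return iv
    body = getattr(obj, "body", None)
    if isinstance(body, GenomicInterval):
        return body
    raise TypeError(f"cannot extract a GenomicInterval from {obj!r}")


def build_trees(items: Iterable) -> dict[str, IntervalTree]:
    """Index items carrying intervals into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    for item in items:
        iv = _interval_of(item)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, item)
    return trees


def intersect_sets(a: Iterable, b: Iterable) -> list[tuple[object, object, int]]:
    """All pairs (a_member, b_member, overlap_bp) with >= 1 bp overlap.

    Equivalent to ``intersectBed`` with the 1-bp rule: half-open abutment is
    not an overlap. Input order of ``a`` is preserved; within one ``a``
    member, partners are ordered by (start, end).
    """
    trees = build_trees(b)
    pairs: list[tuple[object, object, int]] = []
    for item in a:
        iv = _interval_of(item)
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.end))
        for h in hits:
            ov = min(iv.end, h.end) - max(iv.start, h.begin)
            if ov >= 1:
                pairs.append((item, h.data, ov))
    return pairs


def overlaps_any(query: GenomicInterval, trees: Mapping[str, IntervalTree]) -> bool:
    tree = trees.get(query.chrom)
    return bool(tree is not None and tree.overlap(query.start, query.end))


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals (per-chromosome sweep)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total
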