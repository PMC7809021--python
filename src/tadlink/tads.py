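"""TAD-framework gene assignment and direction analysis.

TAD calls from several cell lines are merged into one (possibly nested)
set, each gene is assigned to the smallest TAD overlapping its body, TADs
are declared "up"/"down"/"mixed" from the DE direction of their genes, and
the genomic-footprint overlap between up- and down-TADs is tested with a
label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Gene, GenomicInterval, build_trees, union_length
from .stats import empirical_p, mann_whitney


@dataclass(frozen=True, slots=True)
class TAD:
    interval: GenomicInterval
    source: str = ""

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class TadAssignment:
    gene_to_tad: dict[str, TAD]
    tad_genes: dict[TAD, list[str]]

    @property
    def unassigned(self) -> set[str]:
        return {g for g, t in self.gene_to_tad.items() if t is None}


@dataclass
class TadDirection:
    """TAD -> up / down / mixed / none from the DE calls of its genes."""

    direction: dict[TAD, str]

    def tads(self, label: str) -> list[TAD]:
        return [t for t, d in self.direction.items() if d == label]


@dataclass
class PermutationResult:
    observed_mb: float
    null_mb: list[float]
    n_perm: int
    p_lower: float
    seed: int


def merge_tad_sets(tad_sets: Iterable[Sequence[TAD]]) -> list[TAD]:
    """Concatenate per-cell-line TAD lists, dropping exact coordinate duplicates.

    The first occurrence's source label is kept; nesting across sources is
    preserved on purpose (it is what the smallest-TAD rule exploits).
    """
    seen: set[tuple[str, int, int]] = set()
    merged: list[TAD] = []
    for tads in tad_sets:
        for tad in tads:
            key = (tad.interval.chrom, tad.interval.start, tad.interval.end)
            if key not in seen:
                seen.add(key)
                merged.append(tad)
    return merged


def assign_smallest_tad(genes: Sequence[Gene], tads: Sequence[TAD]) -> TadAssignment:
    """Assign each gene the smallest TAD overlapping its body by >= 1 bp.

    Ties on length break by leftmost start, then source label. Genes with no
    overlapping TAD stay unassigned (absent from gene_to_tad).
    """
    trees = build_trees(tads)
    gene_to_tad: dict[str, TAD] = {}
    tad_genes: dict[TAD, list[str]] = {}
    for gene in genes:
        tree = trees.get(gene.body.chrom)
        if tree is None:
            continue
        hits = tree.overlap(gene.body.start, gene.body.end)
        if not hits:
            continue
        best = min(
            (h.data for h in hits),
            key=lambda t: (len(t.interval), t.interval.start, t.source),
        )
        gene_to_tad[gene.gene_id] = best
        tad_genes.setdefault(best, []).append(gene.gene_id)
    return TadAssignment(gene_to_tad, tad_genes)


def declare_direction(assignment: TadAssignment, de_map: Mapping[str, str]) -> TadDirection:
    """up iff >= 1 up gene and no down gene; down symmetric; both -> mixed."""
    direction: dict[TAD, str] = {}
    for tad, gene_ids in assignment.tad_genes.items():
        has_up = any(de_map.get(g) == "up" for g in gene_ids)
        has_down = any(de_map.get(g) == "down" for g in gene_ids)
        if has_up and has_down:
            direction[tad] = "mixed"
        elif has_up:
            direction[tad] = "up"
        elif has_down:
            direction[tad] = "down"
        else:
            direction[tad] = "none"
    return TadDirection(direction)


def tad_overlap_mb(tads_up: Iterable[TAD], tads_down: Iterable[TAD]) -> float:
    """Intersection, in Mb, of the two sets' genomic footprints.

    Footprint = union of member intervals; |A ∩ B| = |A| + |B| - |A ∪ B|.
    """
    a = [t.interval for t in tads_up]
    b = [t.interval for t in tads_down]
    if not a or not b:
        return 0.0
    la = union_length(a)
    lb = union_length(b)
    lab = union_length(a + b)
    return (la + lb - lab) / 1e6


def _directional_footprints(
    assignment: TadAssignment, de_map: Mapping[str, str]
) -> tuple[list[TAD], list[TAD]]:
    """Up and down TAD sets for the overlap statistic; mixed TADs join both."""
    direction = declare_direction(assignment, de_map)
    up = [t for t, d in direction.direction.items() if d in ("up", "mixed")]
    down = [t for t, d in direction.direction.items() if d in ("down", "mixed")]
    return up, down


def segregation_permutation(
    de_map: Mapping[str, str],
    assignment: TadAssignment,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for direction segregation of DE genes across TADs.

    The statistic is the Mb overlap between up-TAD and down-TAD footprints
    (mixed TADs count in both). The null shuffles up/down labels over the DE
    genes, preserving counts and gene positions. p_lower asks whether the
    real overlap is smaller than expected at random.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    de_genes = sorted(g for g, d in de_map.items() if d in ("up", "down"))
    if not de_genes:
        raise ValueError("no differentially expressed genes")
    # a single-direction DE set is degenerate: overlap is 0 observed and in
    # every permutation, so the test runs through and reports p = 1
    labels = np.array([de_map[g] for g in de_genes])
    observed = tad_overlap_mb(*_directional_footprints(assignment, de_map))
    rng = np.random.default_rng(seed)
    null: list[float] = []
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        perm_map = dict(zip(de_genes, perm))
        null.append(tad_overlap_mb(*_directional_footprints(assignment, perm_map)))
    p = empirical_p(observed, null, tail="lower")
    return PermutationResult(observed, null, n_perm, p, seed)


@dataclass
class DensityResult:
    up_density: list[float]
    down_density: list[float]
    u_statistic: float | None
    p: float | None
    flagged: bool


def peak_density_by_tad(
    peaks: Sequence, direction: TadDirection
) -> DensityResult:
    """Peaks per Mb in up- vs down-TADs, compared by two-sided Mann-Whitney.

    A peak counts toward every TAD it overlaps by >= 1 bp. Mixed TADs are
    excluded from both strata. Missing strata flag the result; no test runs.
    """
    peak_trees = build_trees(peaks)
    def densities(tads: list) -> list[float]:
        out = []
        for tad in tads:
            tree = peak_trees.get(tad.interval.chrom)
            n = len(tree.overlap(tad.interval.start, tad.interval.end)) if tree else 0
            out.append(n / (len(tad.interval) / 1e6))
        return out

    up = densities(direction.tads("up"))
    down = densities(direction.tads("down"))
    if not up or not down:
        return DensityResult(up, down, None, None, True)
    u, p = mann_whitney(up, down)
    return DensityResult(up, down, u, p, False)


def link_dars_to_tads(dars, direction: TadDirection) -> dict[int, str]:
    """Stratify DARs by TAD direction.

    Returns index -> label over the concatenation gained + lost, with labels
    'gained_up', 'gained_down', 'lost_up', 'lost_down' or 'outside'. A DAR
    overlapping several directional TADs takes the smallest one.
    """
    directional = [
        (t, d) for t, d in direction.direction.items() if d in ("up", "down")
    ]
    trees = build_trees([_DirTad(t.interval, d) for t, d in directional])
    labels: dict[int, str] = {}
    idx = 0
    for cls, peaks in (("gained", dars.gained), ("lost", dars.lost)):
        for peak in peaks:
            tree = trees.get(peak.interval.chrom)
            hits = tree.overlap(peak.interval.start, peak.interval.end) if tree else set()
            if hits:
                best = min(
                    (h.data for h in hits),
                    key=lambda w: (len(w.interval), w.interval.start),
                )
                labels[idx] = f"{cls}_{best.tad_direction}"
            else:
                labels[idx] = "outside"
            idx += 1
    return labels


class _DirTad:
    __slots__ = ("interval", "tad_direction")

    def __init__(self, interval: GenomicInterval, tad_direction: str):
        self.interval = interval
        self.tad_direction = tad_direction
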