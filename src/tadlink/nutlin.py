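"""Stratification of genes by regulatory context and p53-activation response.

Genes are grouped into: all expressed; up after transformation; down after
transformation; and down genes whose TAD harbours a lost DAR with a p53
motif in its summit. The response statistic is |log2FC| after a short
Nutlin-3a treatment, compared between groups with Mann-Whitney tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import GenomicInterval, build_trees
from .motifs import PWM, has_hit, window_sequence
from .stats import mann_whitney
from .tads import TadAssignment


@dataclass
class ResponseGroups:
    all_expressed: set[str]
    hras_up: set[str]
    hras_down: set[str]
    hras_down_p53: set[str]

    def __post_init__(self) -> None:
        assert self.hras_down_p53 <= self.hras_down


def build_groups(
    de_map: Mapping[str, str],
    assignment: TadAssignment,
    dars,
    genome: Mapping[str, str],
    p53_pwm: PWM,
    threshold: float,
) -> ResponseGroups:
    """Derive the response groups from upstream pipeline stages.

    hras_down_p53 = down-regulated genes whose assigned TAD overlaps
    (>= 1 bp) a lost DAR whose 150-bp summit window carries a p53 motif hit.
    """
    if assignment is None or dars is None:
        raise ValueError("TAD assignment and DAR calling must run first")
    motif_lost = [
        d for d in dars.lost
        if has_hit(window_sequence(genome, d.summit), p53_pwm, threshold)
    ]
    trees = build_trees(motif_lost)
    all_expressed = set(de_map)
    up = {g for g, d in de_map.items() if d == "up"}
    down = {g for g, d in de_map.items() if d == "down"}
    down_p53 = set()
    for gene_id in down:
        tad = assignment.gene_to_tad.get(gene_id)
        if tad is None:
            continue
        tree = trees.get(tad.interval.chrom)
        if tree is not None and tree.overlap(tad.interval.start, tad.interval.end):
            down_p53.add(gene_id)
    return ResponseGroups(all_expressed, up, down, down_p53)


@dataclass
class ResponseComparison:
    group_sizes: dict[str, int]
    group_abs_lfc: dict[str, list[float]]
    pvalues: dict[str, float | None]
    excluded: list[str]


def compare_response(
    groups: ResponseGroups, nutlin_lfc: Mapping[str, float]
) -> ResponseComparison:
    """|log2FC| distributions per group and pairwise Mann-Whitney p-values.

    Comparisons: each group against all expressed genes, plus
    hras_down_p53 vs hras_down. Groups with fewer than 2 covered genes are
    excluded and listed.
    """
    member_sets = {
        "all_expressed": groups.all_expressed,
        "hras_up": groups.hras_up,
        "hras_down": groups.hras_down,
        "hras_down_p53": groups.hras_down_p53,
    }
    values = {
        name: [abs(nutlin_lfc[g]) for g in sorted(members) if g in nutlin_lfc]
        for name, members in member_sets.items()
    }
    excluded = [name for name, v in values.items() if len(v) < 2]
    pvalues: dict[str, float | None] = {}
    ref = values["all_expressed"]
    for name in ("hras_up", "hras_down", "hras_down_p53"):
        if name in excluded or "all_expressed" in excluded:
            pvalues[f"{name}_vs_all"] = None
        else:
            pvalues[f"{name}_vs_all"] = mann_whitney(values[name], ref)[1]
    if "hras_down_p53" in excluded or "hras_down" in excluded:
        pvalues["hras_down_p53_vs_hras_down"] = None
    else:
        pvalues["hras_down_p53_vs_hras_down"] = mann_whitney(
            values["hras_down_p53"], values["hras_down"]
        )[1]
    return ResponseComparison(
        {name: len(v) for name, v in values.items()}, values, pvalues, excluded
    )
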