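"""End-to-end orchestration: simulate (or load) a dataset, run every stage
in dependency order, and emit a consolidated, deterministic report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import io as tio
from .accessibility import (
    AnnotationParams, DARSet, Peak, PeakCallParams, annotate_location, call_dars,
    call_peaks, promoter_direction_table,
)
from .chip import dar_chip_overlap, partition_peaks
from .core import DEThresholds, GenomicInterval, classify_de
from .motifs import calibrate_threshold, motif_enrichment, read_jaspar
from .nutlin import build_groups, compare_response
from .simulate import (
    PARENTAL, TRANSFORMED, SimBundle, SimParams, SimTruth, simulate,
)
from .tads import (
    TadAssignment, assign_smallest_tad, declare_direction, link_dars_to_tads,
    merge_tad_sets, peak_density_by_tad, segregation_permutation,
)

logger = logging.getLogger("tadlink")


@dataclass(frozen=True, slots=True)
class PipelineConfig:
    sim: SimParams = SimParams()
    de: DEThresholds = DEThresholds()
    peaks: PeakCallParams = PeakCallParams()
    annotation: AnnotationParams = AnnotationParams()
    n_perm: int = 1000
    motif_target_rate: float = 1e-4
    kmeans_k: int = 2
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        # one user-facing seed; per-stage streams stay independent
        return (zlib.crc32(stage.encode()) ^ (self.seed * 2654435761)) % (2**31)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Report tables plus the in-memory stage objects for further analysis."""

    report: dict
    bundle: SimBundle
    de_map: dict[str, str]
    peaks: dict[str, list[Peak]]
    dars: DARSet
    assignment: TadAssignment
    strata: dict[int, str]

    def to_json(self) -> str:
        return json.dumps(self.report, indent=1, sort_keys=True)


def dar_recovery_jaccard(dars: DARSet, truth: SimTruth) -> float:
    """Region-level Jaccard between called and true DARs, direction-matched.

    A called DAR matches a true DAR of the same direction on >= 1 bp
    overlap; J = matched / (called + true - matched) counting true regions
    once.
    """
    called = {"gained": dars.gained, "lost": dars.lost}
    n_called = len(dars.gained) + len(dars.lost)
    n_true = len(truth.dars_of("gained")) + len(truth.dars_of("lost"))
    matched_true = 0
    matched_called_idx: set[tuple[str, int]] = set()
    for direction in ("gained", "lost"):
        for t in truth.dars_of(direction):
            hit = False
            for i, peak in enumerate(called[direction]):
                if peak.interval.overlap_bp(t.interval) >= 1:
                    hit = True
                    matched_called_idx.add((direction, i))
            if hit:
                matched_true += 1
    # unmatched called + unmatched true + matched (counted once)
    n_matched_called = len(matched_called_idx)
    union = (n_called - n_matched_called) + n_true
    return matched_true / union if union else 1.0


def run(config: PipelineConfig, bundle: SimBundle | None = None) -> PipelineResult:
    """Execute all stages; any stage failure raises with the stage name."""
    stage = "simulate"
    try:
        if bundle is None:
            bundle = simulate(dataclasses.replace(config.sim, seed=config.stage_seed("simulate")))
        logger.info("stage %s done", stage)

        stage = "differential_expression"
        de_map = classify_de(bundle.expression, config.de)
        de_counts = {
            d: sum(1 for v in de_map.values() if v == d) for d in ("up", "down", "stable")
        }

        stage = "peak_calling"
        track_pa = bundle.combined_track(PARENTAL)
        track_tr = bundle.combined_track(TRANSFORMED)
        peaks_pa = call_peaks(track_pa, bundle.genome_sizes, config.peaks, PARENTAL)
        peaks_tr = call_peaks(track_tr, bundle.genome_sizes, config.peaks, TRANSFORMED)

        stage = "dar_calling"
        dars = call_dars(
            peaks_pa, peaks_tr, track_pa, track_tr, bundle.genome_sizes, config.peaks
        )

        stage = "annotation"
        all_dars = dars.gained + dars.lost
        _, location_props = annotate_location(all_dars, bundle.genes, config.annotation)
        prom_dir = promoter_direction_table(dars, bundle.genes, de_map, config.annotation)

        stage = "tad_assignment"
        merged = merge_tad_sets(bundle.tad_sets.values())
        assignment = assign_smallest_tad(bundle.genes, merged)
        direction = declare_direction(assignment, de_map)
        dir_counts = {
            d: len(direction.tads(d)) for d in ("up", "down", "mixed", "none")
        }

        stage = "segregation_permutation"
        perm = segregation_permutation(
            de_map, assignment, config.n_perm, seed=config.stage_seed("segregation")
        )

        stage = "peak_density"
        density_pa = peak_density_by_tad(peaks_pa, direction)
        density_tr = peak_density_by_tad(peaks_tr, direction)

        stage = "dar_tad_linking"
        strata = link_dars_to_tads(dars, direction)

        stage = "motif_enrichment"
        motif_rows = {}
        gained_summits = [p.summit for p in dars.gained]
        lost_summits = [p.summit for p in dars.lost]
        for motif_id, pwm in bundle.pwms.items():
            thr = calibrate_threshold(pwm, config.motif_target_rate)
            fg, bg = (
                (gained_summits, lost_summits)
                if "MG" in motif_id
                else (lost_summits, gained_summits)
            )
            if fg and bg:
                res = motif_enrichment(fg, bg, bundle.genome, pwm, thr)
                motif_rows[motif_id] = {
                    "k_fg": res.k_fg, "n_fg": res.n_fg,
                    "k_bg": res.k_bg, "n_bg": res.n_bg,
                    "fg_pct": 100.0 * res.fg_fraction,
                    "bg_pct": 100.0 * res.bg_fraction,
                    "p": res.p_one_sided,
                }

        stage = "chip_overlap"
        chip_report = {}
        partition = None
        if bundle.chip_peaks:
            partition = partition_peaks(
                bundle.chip_peaks.get(PARENTAL, []), bundle.chip_peaks.get(TRANSFORMED, [])
            )
            from .core import build_trees, overlaps_any
            from .stats import proportion_test

            for condition, peaks in bundle.chip_peaks.items():
                ov = dar_chip_overlap(dars, peaks, strata)
                trees = build_trees(peaks)
                kg = sum(1 for p in dars.gained if overlaps_any(p.interval, trees))
                kl = sum(1 for p in dars.lost if overlaps_any(p.interval, trees))
                ng, nl = len(dars.gained), len(dars.lost)
                overall_p = (
                    proportion_test(kg, ng, kl, nl).p if ng and nl else None
                )
                chip_report[condition] = {
                    "percent": ov.percent,
                    "counts": {k: list(v) for k, v in ov.counts.items()},
                    "tests": {
                        k: (t.p if t is not None else None) for k, t in ov.tests.items()
                    },
                    "overall": {
                        "gained": [kg, ng], "lost": [kl, nl], "p": overall_p,
                    },
                }

        stage = "nutlin_response"
        nutlin_report = None
        if bundle.nutlin:
            p53_id = next((m for m in bundle.pwms if "ML" in m), None)
            p53_pwm = bundle.pwms[p53_id] if p53_id else next(iter(bundle.pwms.values()))
            thr = calibrate_threshold(p53_pwm, config.motif_target_rate)
            groups = build_groups(de_map, assignment, dars, bundle.genome, p53_pwm, thr)
            comparison = compare_response(groups, bundle.nutlin)
            nutlin_report = {
                "group_sizes": comparison.group_sizes,
                "pvalues": comparison.pvalues,
                "excluded": comparison.excluded,
            }

        stage = "report"
        report = {
            "provenance": {
                "config_hash": config_hash(config),
                "seed": config.seed,
                "version": __version__,
            },
            "de_counts": de_counts,
            "peak_counts": {PARENTAL: len(peaks_pa), TRANSFORMED: len(peaks_tr)},
            "dar_counts": {
                "gained": len(dars.gained), "lost": len(dars.lost), "shared": len(dars.shared),
            },
            "location_proportions": location_props,
            "promoter_direction": {
                "gained_up": prom_dir.gained_up, "gained_down": prom_dir.gained_down,
                "lost_up": prom_dir.lost_up, "lost_down": prom_dir.lost_down,
                "p": prom_dir.test.p if prom_dir.test else None,
                "flagged": prom_dir.flagged,
            },
            "tad_direction_counts": dir_counts,
            "segregation": {
                "observed_mb": perm.observed_mb,
                "null_mean_mb": float(np.mean(perm.null_mb)),
                "n_perm": perm.n_perm,
                "p_lower": perm.p_lower,
            },
            "peak_density": {
                PARENTAL: {"p": density_pa.p, "flagged": density_pa.flagged},
                TRANSFORMED: {"p": density_tr.p, "flagged": density_tr.flagged},
            },
            "dar_strata_counts": {
                s: sum(1 for v in strata.values() if v == s)
                for s in sorted(set(strata.values()))
            },
            "motif_enrichment": motif_rows,
            "chip_overlap": chip_report,
            "chip_partition": (
                {
                    "shared": len(partition.shared),
                    "parental_specific": len(partition.a_specific),
                    "transformed_specific": len(partition.b_specific),
                }
                if partition
                else None
            ),
            "nutlin": nutlin_report,
        }
        if bundle.truth is not None:
            report["recovery"] = {
                "dar_jaccard": dar_recovery_jaccard(dars, bundle.truth),
            }
        return PipelineResult(
            report, bundle, de_map,
            {PARENTAL: peaks_pa, TRANSFORMED: peaks_tr},
            dars, assignment, strata,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def load_bundle(indir: str | Path) -> SimBundle:
    """Reassemble a bundle from the files write_bundle produced."""
    indir = Path(indir)
    genome = tio.read_fasta(indir / "genome.fa")
    genes = tio.read_gene_bed(indir / "genes.bed")
    from .tads import TAD

    tad_sets = {}
    for path in sorted(indir.glob("tads_*.bed")):
        source = path.stem.removeprefix("tads_")
        tad_sets[source] = [TAD(r.interval, r.name or source) for r in tio.read_bed(path)]
    expression = tio.read_expression_table(indir / "expression.tsv")
    from .accessibility import CoverageTrack

    tracks = {}
    for path in sorted(indir.glob("reads_*_r*.tsv")):
        stem = path.stem.removeprefix("reads_")
        condition, rep = stem.rsplit("_r", 1)
        tracks[(condition, int(rep))] = CoverageTrack(
            tio.read_points(path), label=stem
        )
    chip_peaks = {}
    for path in sorted(indir.glob("chip_*.bed")):
        condition = path.stem.removeprefix("chip_")
        chip_peaks[condition] = [r.interval for r in tio.read_bed(path)]
    pwms = {}
    motif_path = indir / "motifs.jaspar"
    if motif_path.exists():
        pwms = {p.motif_id: p for p in read_jaspar(motif_path)}
    nutlin = {}
    nutlin_path = indir / "nutlin.tsv"
    if nutlin_path.exists():
        nutlin = tio.read_two_column_table(nutlin_path)
    genome_sizes = {c: len(s) for c, s in genome.items()}
    return SimBundle(
        genome, genome_sizes, genes, tad_sets, expression, tracks,
        chip_peaks, pwms, nutlin, truth=None,
    )
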