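"""ATAC-seq style accessibility analysis.

Read starts are shifted to the transposase insertion centre, peaks are
called with a transparent fixed-window local-Poisson scan (a simplified
stand-in for MACS using its published parameter values), differential
accessibility is decided by a comparative scan that uses the other
condition as background, and peaks are annotated against gene features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import Gene, GenomicInterval, build_trees, overlaps_any
from .stats import ProportionTestResult, proportion_test


@dataclass
class CoverageTrack:
    """Per-chromosome sorted adjusted read-start positions."""

    positions: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = {
            c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in self.positions.items()
        }

    @property
    def total(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def count(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass(frozen=True, slots=True)
class PeakCallParams:
    window: int = 150
    local_lambda_span: int = 25_000
    p_threshold: float = 1e-4
    shift: int = 75
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if min(self.window, self.local_lambda_span, self.shift, self.merge_gap) <= 0:
            raise ValueError("all span parameters must be positive")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass(frozen=True, slots=True)
class Peak:
    interval: GenomicInterval
    summit: GenomicInterval
    read_count: int
    p_value: float
    condition: str = ""
    comparative_p: float | None = None

    def __post_init__(self) -> None:
        if self.summit.chrom != self.interval.chrom or not (
            self.interval.start <= self.summit.start and self.summit.end <= self.interval.end
        ):
            raise ValueError("summit must lie inside the peak interval")


@dataclass
class DARSet:
    """Differentially accessible regions: gained (transformed-specific),
    lost (parental-specific) and shared peaks, disjoint by interval."""

    gained: list[Peak] = field(default_factory=list)
    lost: list[Peak] = field(default_factory=list)
    shared: list[Peak] = field(default_factory=list)


@dataclass(frozen=True, slots=True)
class AnnotationParams:
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    midrange: int = 100_000

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.midrange) <= 0:
            raise ValueError("annotation spans must be positive")


def adjust_reads(
    reads: Iterable[GenomicInterval],
    label: str = "",
    plus_offset: int = 4,
    minus_offset: int = 5,
) -> CoverageTrack:
    """Shift read starts to the Tn5 insertion centre (+4 on +, end-5 on -).

    Unstranded reads are left at their start. Adjusted positions below 0 are
    clamped to 0.
    """
    by_chrom: dict[str, list[int]] = {}
    for read in reads:
        if read.strand == "+":
            pos = read.start + plus_offset
        elif read.strand == "-":
            pos = read.end - 1 - minus_offset
        else:
            pos = read.start
        by_chrom.setdefault(read.chrom, []).append(max(0, pos))
    return CoverageTrack({c: np.asarray(v) for c, v in by_chrom.items()}, label=label)


def poisson_tail(k, lam):
    """Upper tail P(X >= k) for X ~ Poisson(lam); stable for tiny p.

    Vectorised over both arguments.
    """
    k = np.asarray(k)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    p = sps.poisson.sf(k - 1, lam)
    if p.ndim == 0:
        return float(p)
    return p


def _window_counts(pos: np.ndarray, starts: np.ndarray, span: int, offset: int) -> np.ndarray:
    lo = np.searchsorted(pos, starts - offset)
    hi = np.searchsorted(pos, starts - offset + span)
    return hi - lo


def _scan_chrom(
    treat_pos: np.ndarray,
    ctrl_pos: np.ndarray,
    chrom_len: int,
    params: PeakCallParams,
    treat_total: int,
    ctrl_total: int,
    genome_len: int,
    comparative: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window starts, counts and p-values for one chromosome."""
    step = max(1, params.window // 2)
    starts = np.arange(0, chrom_len, step, dtype=np.int64)
    span = params.window + 2 * params.shift
    k = _window_counts(treat_pos, starts, span, params.shift)
    depth = treat_total / ctrl_total if ctrl_total > 0 else 1.0
    lam_bg = ctrl_total * depth / genome_len * span
    centers = starts + params.window // 2
    half_local = params.local_lambda_span // 2
    local = (
        np.searchsorted(ctrl_pos, centers + half_local)
        - np.searchsorted(ctrl_pos, centers - half_local)
    ) / params.local_lambda_span * span * depth
    lam = np.maximum(lam_bg, local)
    if comparative:
        # the control's own small-scale rates guard against calling regions
        # that are equally enriched in both conditions
        ctrl_window = _window_counts(ctrl_pos, starts, span, params.shift) * depth
        half5 = 2500
        ctrl_5k = (
            np.searchsorted(ctrl_pos, centers + half5)
            - np.searchsorted(ctrl_pos, centers - half5)
        ) / 5000.0 * span * depth
        lam = np.maximum.reduce([lam, ctrl_window, ctrl_5k])
    lam = np.maximum(lam, 1e-12)
    p = sps.poisson.sf(k - 1, lam)
    return starts, k, p


def _merge_windows(
    starts: np.ndarray, sig: np.ndarray, pvals: np.ndarray, window: int, merge_gap: int, chrom_len: int
) -> list[tuple[int, int, float]]:
    """Merge significant windows closer than merge_gap into (start, end, min_p)."""
    regions: list[tuple[int, int, float]] = []
    cur = None
    for w, p in zip(starts[sig], pvals[sig]):
        w_end = min(int(w) + window, chrom_len)
        if cur is None:
            cur = [int(w), w_end, float(p)]
        elif int(w) - cur[1] <= merge_gap:
            cur[1] = max(cur[1], w_end)
            cur[2] = min(cur[2], float(p))
        else:
            regions.append(tuple(cur))
            cur = [int(w), w_end, float(p)]
    if cur is not None:
        regions.append(tuple(cur))
    return regions


def significant_regions(
    treat: CoverageTrack,
    ctrl: CoverageTrack,
    genome_sizes: Mapping[str, int],
    params: PeakCallParams,
    comparative: bool,
) -> dict[str, list[tuple[int, int, float]]]:
    genome_len = sum(genome_sizes.values())
    out: dict[str, list[tuple[int, int, float]]] = {}
    empty = np.empty(0, dtype=np.int64)
    for chrom, chrom_len in genome_sizes.items():
        treat_pos = treat.positions.get(chrom, empty)
        ctrl_pos = ctrl.positions.get(chrom, empty)
        if len(treat_pos) == 0:
            out[chrom] = []
            continue
        starts, k, p = _scan_chrom(
            treat_pos, ctrl_pos, chrom_len, params,
            treat.total, ctrl.total, genome_len, comparative,
        )
        sig = (p < params.p_threshold) & (k >= 1)
        out[chrom] = _merge_windows(starts, sig, p, params.window, params.merge_gap, chrom_len)
    return out


def _extract_summit(pos: np.ndarray, start: int, end: int, width: int) -> tuple[int, int]:
    """Leftmost max-count window of ``width`` bp within [start, end)."""
    if end - start <= width:
        return start, start + width
    offsets = np.arange(start, end - width + 1, dtype=np.int64)
    counts = np.searchsorted(pos, offsets + width) - np.searchsorted(pos, offsets)
    best = int(offsets[int(np.argmax(counts))])
    return best, best + width


def call_peaks(
    track: CoverageTrack,
    genome_sizes: Mapping[str, int],
    params: PeakCallParams = PeakCallParams(),
    condition: str | None = None,
) -> list[Peak]:
    """Local-Poisson sliding-window peak calling with summit extraction.

    Windows of ``params.window`` bp slide in half-window steps; reads are
    counted over the +/-shift extended window; lambda is the larger of the
    genome-wide and the 25-kb local rate over the same span. Significant
    windows (Poisson tail < p_threshold) closer than merge_gap are merged,
    and the summit is the leftmost max-count 150-bp window inside each peak.
    """
    condition = condition if condition is not None else track.label
    regions = significant_regions(track, track, genome_sizes, params, comparative=False)
    peaks: list[Peak] = []
    empty = np.empty(0, dtype=np.int64)
    for chrom in genome_sizes:
        pos = track.positions.get(chrom, empty)
        for start, end, p in regions.get(chrom, []):
            s0, s1 = _extract_summit(pos, start, end, params.window)
            count = int(
                np.searchsorted(pos, end + params.shift)
                - np.searchsorted(pos, start - params.shift)
            )
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end),
                    GenomicInterval(chrom, s0, s1),
                    max(count, 1),
                    p,
                    condition=condition,
                )
            )
    return peaks


def _overlapping_region_p(
    peak: Peak, regions: dict[str, list[tuple[int, int, float]]]
) -> float | None:
    best: float | None = None
    for start, end, p in regions.get(peak.interval.chrom, []):
        if min(end, peak.interval.end) - max(start, peak.interval.start) >= 1:
            best = p if best is None else min(best, p)
    return best


def call_dars(
    peaks_parental: Sequence[Peak],
    peaks_transformed: Sequence[Peak],
    track_parental: CoverageTrack,
    track_transformed: CoverageTrack,
    genome_sizes: Mapping[str, int],
    params: PeakCallParams = PeakCallParams(),
) -> DARSet:
    """Comparative DAR calling: each condition scanned against the other.

    A transformed-condition peak overlapping (>= 1 bp) a significant
    transformed-over-parental comparative region is gained; the symmetric
    case is lost; every remaining peak from either solo call is shared.
    """
    comp_gain = significant_regions(
        track_transformed, track_parental, genome_sizes, params, comparative=True
    )
    comp_loss = significant_regions(
        track_parental, track_transformed, genome_sizes, params, comparative=True
    )
    dars = DARSet()
    claimed: set[tuple[str, int, int]] = set()
    for peak in peaks_transformed:
        p = _overlapping_region_p(peak, comp_gain)
        if p is not None:
            dars.gained.append(replace(peak, comparative_p=p))
            claimed.add((peak.interval.chrom, peak.interval.start, peak.interval.end))
    for peak in peaks_parental:
        p = _overlapping_region_p(peak, comp_loss)
        if p is not None:
            dars.lost.append(replace(peak, comparative_p=p))
            claimed.add((peak.interval.chrom, peak.interval.start, peak.interval.end))
    seen = set(claimed)
    for peak in list(peaks_parental) + list(peaks_transformed):
        key = (peak.interval.chrom, peak.interval.start, peak.interval.end)
        if key not in seen:
            seen.add(key)
            dars.shared.append(peak)
    return dars


def promoter_window(gene: Gene, params: AnnotationParams = AnnotationParams()) -> GenomicInterval:
    """Strand-aware promoter: [TSS-1000, TSS+500) on +, mirrored on -."""
    t = gene.tss
    if gene.body.strand == "+":
        lo, hi = t - params.promoter_upstream, t + params.promoter_downstream
    else:
        lo, hi = t - params.promoter_downstream + 1, t + params.promoter_upstream + 1
    return GenomicInterval(gene.body.chrom, max(0, lo), hi)


def midrange_window(gene: Gene, params: AnnotationParams = AnnotationParams()) -> GenomicInterval:
    t = gene.tss
    return GenomicInterval(gene.body.chrom, max(0, t - params.midrange), t + params.midrange)


def annotate_location(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    params: AnnotationParams = AnnotationParams(),
) -> tuple[dict[int, str], dict[str, float]]:
    """Label each peak promoter / midrange / far (priority in that order).

    Promoter: >= 1 bp overlap with any gene's strand-aware promoter window;
    midrange: overlap with any +/-100 kb TSS window; otherwise far. Each peak
    receives exactly one label; returns (index -> label, class proportions).
    """
    prom_trees = build_trees([promoter_window(g, params) for g in genes])
    mid_trees = build_trees([midrange_window(g, params) for g in genes])
    labels: dict[int, str] = {}
    for i, peak in enumerate(peaks):
        if overlaps_any(peak.interval, prom_trees):
            labels[i] = "promoter"
        elif overlaps_any(peak.interval, mid_trees):
            labels[i] = "midrange"
        else:
            labels[i] = "far"
    n = max(len(peaks), 1)
    props = {
        cls: sum(1 for v in labels.values() if v == cls) / n
        for cls in ("promoter", "midrange", "far")
    }
    return labels, props


@dataclass
class PromoterDirectionResult:
    """Counts of promoter DARs split by DAR class and promoter-gene direction."""

    gained_up: int
    gained_down: int
    lost_up: int
    lost_down: int
    gained_up_fraction: float | None
    lost_up_fraction: float | None
    test: ProportionTestResult | None
    flagged: bool


def promoter_direction_table(
    dars: DARSet,
    genes: Sequence[Gene],
    de_map: Mapping[str, str],
    params: AnnotationParams = AnnotationParams(),
) -> PromoterDirectionResult:
    """Cross gained/lost promoter DARs with up/down promoter genes.

    Each DAR is counted once, at the DE gene with the nearest TSS among the
    promoters it overlaps. The two-proportion test compares the up-gene
    fraction between gained and lost promoter DARs; with an empty class the
    result is flagged and no test is run.
    """
    de_genes = [g for g in genes if de_map.get(g.gene_id) in ("up", "down")]
    prom_trees = build_trees(
        [_PromoterOfGene(promoter_window(g, params), g) for g in de_genes]
    )
    counts = {("gained", "up"): 0, ("gained", "down"): 0, ("lost", "up"): 0, ("lost", "down"): 0}
    for cls, peaks in (("gained", dars.gained), ("lost", dars.lost)):
        for peak in peaks:
            tree = prom_trees.get(peak.interval.chrom)
            if tree is None:
                continue
            hits = tree.overlap(peak.interval.start, peak.interval.end)
            if not hits:
                continue
            mid = (peak.interval.start + peak.interval.end) / 2
            gene = min(
                hits, key=lambda h: (abs(h.data.gene.tss - mid), h.data.gene.gene_id)
            ).data.gene
            counts[(cls, de_map[gene.gene_id])] += 1
    n_gained = counts[("gained", "up")] + counts[("gained", "down")]
    n_lost = counts[("lost", "up")] + counts[("lost", "down")]
    flagged = n_gained == 0 or n_lost == 0
    test = None
    if not flagged:
        test = proportion_test(counts[("gained", "up")], n_gained, counts[("lost", "up")], n_lost)
    return PromoterDirectionResult(
        counts[("gained", "up")],
        counts[("gained", "down")],
        counts[("lost", "up")],
        counts[("lost", "down")],
        counts[("gained", "up")] / n_gained if n_gained else None,
        counts[("lost", "up")] / n_lost if n_lost else None,
        test,
        flagged,
    )


class _PromoterOfGene:
    """A promoter window that remembers its gene, for tree indexing."""

    __slots__ = ("interval", "gene")

    def __init__(self, interval: GenomicInterval, gene: Gene):
        self.interval = interval
        self.gene = gene


def subsample_track(track: CoverageTrack, n: int, rng: np.random.Generator) -> CoverageTrack:
    """Draw n positions without replacement, preserving chromosome structure."""
    chroms = list(track.positions)
    sizes = np.array([len(track.positions[c]) for c in chroms])
    total = int(sizes.sum())
    if n > total:
        raise ValueError(f"cannot subsample {n} from {total} reads")
    keep = rng.permutation(total)[:n]
    keep.sort()
    out: dict[str, np.ndarray] = {}
    offset = 0
    for chrom, size in zip(chroms, sizes):
        idx = keep[(keep >= offset) & (keep < offset + size)] - offset
        out[chrom] = track.positions[chrom][idx]
        offset += size
    return CoverageTrack(out, label=track.label)


def replicate_correlation(
    rep1: CoverageTrack,
    rep2: CoverageTrack,
    genome_sizes: Mapping[str, int],
    n_subsample: int | None = None,
    params: PeakCallParams = PeakCallParams(),
    seed: int = 0,
) -> float | None:
    """Reproducibility QC: Pearson r of read counts over merged peaks.

    Each replicate is subsampled (without replacement) to ``n_subsample``
    reads, peaks are called per replicate, their intervals are merged by
    union, and the per-replicate read counts over the merged peaks are
    correlated. Returns None (flagged) when fewer than 2 merged peaks exist.
    """
    rng = np.random.default_rng(seed)
    if n_subsample is not None:
        rep1 = subsample_track(rep1, n_subsample, rng)
        rep2 = subsample_track(rep2, n_subsample, rng)
    peaks1 = call_peaks(rep1, genome_sizes, params)
    peaks2 = call_peaks(rep2, genome_sizes, params)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks1 + peaks2:
        by_chrom.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    merged: list[tuple[str, int, int]] = []
    for chrom, spans in sorted(by_chrom.items()):
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        merged.append((chrom, cur_s, cur_e))
    if len(merged) < 2:
        return None
    v1 = np.array([rep1.count(c, s, e) for c, s, e in merged], dtype=float)
    v2 = np.array([rep2.count(c, s, e) for c, s, e in merged], dtype=float)
    if v1.std() == 0 or v2.std() == 0:
        return None
    return float(np.corrcoef(v1, v2)[0, 1])
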