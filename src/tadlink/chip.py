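"""ChIP-seq peak partitioning, DAR co-occupancy statistics, signal heatmap
matrices with deterministic k-means ordering, and 4C sliding-window profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval, build_trees, overlaps_any
from .stats import ProportionTestResult, proportion_test


@dataclass
class ChipPartition:
    """Shared vs cell-type-specific binding sites (presence/absence overlap)."""

    shared: list
    a_specific: list
    b_specific: list


def _interval(p) -> GenomicInterval:
    return p if isinstance(p, GenomicInterval) else p.interval


def partition_peaks(peaks_a: Sequence, peaks_b: Sequence) -> ChipPartition:
    """Split two peak sets into shared and condition-specific groups.

    A peak overlapping (>= 1 bp) any peak of the other set is shared; each
    overlapping cluster contributes its members once. Peaks without a
    partner are specific to their condition.
    """
    trees_b = build_trees(peaks_b)
    trees_a = build_trees(peaks_a)
    shared: list = []
    a_specific: list = []
    b_specific: list = []
    for p in peaks_a:
        iv = _interval(p)
        (shared if overlaps_any(iv, trees_b) else a_specific).append(p)
    for p in peaks_b:
        iv = _interval(p)
        (shared if overlaps_any(iv, trees_a) else b_specific).append(p)
    return ChipPartition(shared, a_specific, b_specific)


@dataclass
class DarChipOverlap:
    """Per-stratum DAR/ChIP co-occupancy with gained-vs-lost tests."""

    percent: dict[str, float | None]
    counts: dict[str, tuple[int, int]]  # stratum -> (overlapping, total)
    tests: dict[str, ProportionTestResult | None]  # per TAD-direction class


def dar_chip_overlap(dars, chip_peaks: Sequence, strata: Mapping[int, str]) -> DarChipOverlap:
    """% of DARs overlapping a ChIP peak, per (DAR class x TAD direction).

    ``strata`` labels the concatenation gained + lost (see
    tads.link_dars_to_tads). Within each TAD direction, gained vs lost rates
    are compared with the two-proportion test; empty strata report None.
    """
    trees = build_trees(chip_peaks)
    all_dars = list(dars.gained) + list(dars.lost)
    counts: dict[str, list[int]] = {}
    for idx, dar in enumerate(all_dars):
        stratum = strata.get(idx, "outside")
        if stratum == "outside":
            continue
        hit = overlaps_any(_interval(dar), trees)
        entry = counts.setdefault(stratum, [0, 0])
        entry[0] += int(hit)
        entry[1] += 1
    percent = {
        s: (100.0 * k / n if n else None) for s, (k, n) in counts.items()
    }
    tests: dict[str, ProportionTestResult | None] = {}
    for tad_dir in ("up", "down"):
        g = counts.get(f"gained_{tad_dir}")
        l = counts.get(f"lost_{tad_dir}")
        if g and l and g[1] > 0 and l[1] > 0:
            tests[tad_dir] = proportion_test(g[0], g[1], l[0], l[1])
        else:
            tests[tad_dir] = None
    return DarChipOverlap(percent, {s: tuple(v) for s, v in counts.items()}, tests)


def chip_dar_fraction(loci: Sequence, dars) -> float:
    """Fraction of ChIP binding loci overlapping (>= 1 bp) a lost DAR."""
    if not loci:
        raise ValueError("empty locus set")
    trees = build_trees(dars.lost)
    return sum(1 for p in loci if overlaps_any(_interval(p), trees)) / len(loci)


@dataclass
class SignalMatrix:
    matrix: np.ndarray  # rows = peaks, cols = bins
    row_ids: list[str]
    flank: int
    bin_width: int


def signal_matrix(
    peaks: Sequence, track, flank: int = 2000, bin_width: int = 50
) -> SignalMatrix:
    """Binned read counts around each peak summit centre (+/- flank)."""
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    rows = []
    row_ids = []
    empty = np.empty(0, dtype=np.int64)
    for i, peak in enumerate(peaks):
        summit = getattr(peak, "summit", None)
        iv = summit if summit is not None else _interval(peak)
        center = (iv.start + iv.end) // 2
        edges = center - flank + np.arange(n_bins + 1) * bin_width
        pos = track.positions.get(iv.chrom, empty)
        counts = np.diff(np.searchsorted(pos, edges))
        rows.append(counts)
        row_ids.append(f"{iv.chrom}:{iv.start}-{iv.end}#{i}")
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, n_bins))
    return SignalMatrix(matrix, row_ids, flank, bin_width)


def _farthest_point_init(rows: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centroids = [rows[int(rng.integers(len(rows)))]]
    for _ in range(1, k):
        d = np.min(
            [((rows - c) ** 2).sum(axis=1) for c in centroids], axis=0
        )
        centroids.append(rows[int(np.argmax(d))])
    return np.array(centroids)


def kmeans_order(
    sm: SignalMatrix, k: int = 2, seed: int = 0, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic k-means on unit-total-scaled rows; heatmap row order.

    Farthest-point initialisation from a seeded first pick, L2 metric,
    clusters renumbered by decreasing mean raw row signal. Returns
    (labels, row_order) where row_order lists rows cluster-major, within a
    cluster by decreasing total signal then index.
    """
    n = sm.matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in [1, #rows={n}]")
    totals = sm.matrix.sum(axis=1)
    scaled = sm.matrix / np.where(totals > 0, totals, 1.0)[:, None]
    rng = np.random.default_rng(seed)
    centroids = _farthest_point_init(scaled, k, rng)
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = ((scaled[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            members = scaled[labels == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
    # stable cluster numbering: 0 = highest mean raw signal
    means = np.array(
        [totals[labels == j].mean() if (labels == j).any() else -np.inf for j in range(k)]
    )
    rank = np.argsort(-means, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[rank] = np.arange(k)
    labels = remap[labels]
    order = np.lexsort((np.arange(n), -totals, labels))
    return labels, order


def fourc_profile(
    sites: Sequence[tuple[int, float]], window: int = 50_000, step: int = 25_000
) -> list[tuple[int, float]]:
    """Sliding-window sum of per-restriction-site read counts.

    Windows start at multiples of ``step`` from 0 through the last site;
    each value is the count sum over [w, w + window). The final windows may
    extend past the last site (partial coverage).
    """
    if not sites:
        return []
    pos = np.array([s[0] for s in sites], dtype=np.int64)
    cnt = np.array([s[1] for s in sites], dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, cnt = pos[order], cnt[order]
    csum = np.concatenate([[0.0], np.cumsum(cnt)])
    last = int(pos[-1])
    starts = np.arange(0, last + 1, step, dtype=np.int64)
    lo = np.searchsorted(pos, starts)
    hi = np.searchsorted(pos, starts + window)
    values = csum[hi] - csum[lo]
    return [(int(w), float(v)) for w, v in zip(starts, values)]
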