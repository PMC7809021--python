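"""PWM motif models, exact threshold calibration and summit-window scanning.

A PWM is built from a JASPAR-style count matrix as a log2-odds model over a
background base composition. The score threshold is calibrated exactly by
dynamic programming on the discretised score distribution of a random
background k-mer, scans cover both strands of 150-bp summit windows, and
enrichment contrasts a foreground window set against a background set
(gained vs lost DARs and vice versa) with a one-sided hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval
from .stats import EnrichmentResult, bh_adjust, hypergeom_enrichment

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass
class PWM:
    """Log-odds position weight matrix (bits) over A/C/G/T."""

    motif_id: str
    counts: np.ndarray  # 4 x L
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (A/C/G/T rows)")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.pseudocount < 0 or np.any(self.background <= 0):
            raise ValueError("pseudocount must be >= 0 and background positive")
        adj = self.counts + self.pseudocount
        freqs = adj / adj.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(freqs / self.background[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.counts[_COMP][:, ::-1].copy(),
            self.pseudocount,
            self.background[_COMP].copy(),
        )

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))


@dataclass(frozen=True, slots=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float


def build_logodds(
    motif_id: str,
    counts: np.ndarray,
    pseudocount: float = 0.25,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    return PWM(motif_id, np.asarray(counts, dtype=float), pseudocount, np.asarray(background))


def read_jaspar(path) -> list[PWM]:
    """JASPAR-format PFM file: '>ID name' then four 'A [ ... ]' rows."""
    pwms: list[PWM] = []
    motif_id = None
    rows: dict[str, list[float]] = {}
    def flush():
        if motif_id is not None:
            counts = np.array([rows[b] for b in BASES])
            pwms.append(PWM(motif_id, counts))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[base] = [float(x) for x in body.split()]
    flush()
    return pwms


def write_jaspar(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in pwm.counts[i])
                fh.write(f"{base} [ {vals} ]\n")


def score_distribution(pwm: PWM, resolution: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the score of a random background k-mer, on a discrete grid.

    Per-column scores are rounded to ``resolution`` bits and convolved; the
    returned (scores, probabilities) enumerate the full support.
    """
    grid = np.rint(pwm.log_odds / resolution).astype(np.int64)
    lo = int(grid.min(axis=0).sum())
    hi = int(grid.max(axis=0).sum())
    pmf = np.zeros(hi - lo + 1)
    # start with the first column, then convolve column by column
    offset = lo
    cur = np.zeros(int(grid[:, 0].max() - grid[:, 0].min()) + 1)
    base_off = int(grid[:, 0].min())
    for b in range(4):
        cur[grid[b, 0] - base_off] += pwm.background[b]
    for j in range(1, pwm.length):
        col_lo = int(grid[:, j].min())
        col = np.zeros(int(grid[:, j].max()) - col_lo + 1)
        for b in range(4):
            col[grid[b, j] - col_lo] += pwm.background[b]
        cur = np.convolve(cur, col)
        base_off += col_lo
    pmf[base_off - lo : base_off - lo + len(cur)] = cur
    scores = (np.arange(lo, hi + 1)) * resolution
    return scores, pmf


def calibrate_threshold(
    pwm: PWM, target_rate: float = 1e-4, resolution: float = 0.01
) -> float:
    """Smallest threshold t with P(background k-mer score >= t) <= target_rate.

    If even the maximal score is more probable than the target, the
    threshold is placed just above the maximum (no hits possible) — callers
    should treat that as a flag that the motif cannot reach the rate.
    """
    if not (0.0 < target_rate <= 1.0):
        raise ValueError("target_rate must be in (0, 1]")
    scores, pmf = score_distribution(pwm, resolution)
    tail = np.cumsum(pmf[::-1])[::-1]
    ok = np.nonzero(tail <= target_rate + 1e-15)[0]
    if len(ok) == 0:
        return float(scores[-1] + resolution)
    return float(scores[ok[0]])


def encode(sequence: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, code in _CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _strand_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every offset; windows containing N score -inf."""
    L = log_odds.shape[1]
    n_off = len(codes) - L + 1
    if n_off <= 0:
        return np.empty(0)
    lo5 = np.vstack([log_odds, np.full(L, -np.inf)])
    scores = np.zeros(n_off)
    for j in range(L):
        scores += lo5[codes[j : j + n_off], j]
    return scores


def scan(
    sequence: str, pwm: PWM, threshold: float, sequence_id: str = ""
) -> list[MotifHit]:
    """All positions on both strands scoring >= threshold.

    Hits are ordered by offset, + before - at equal offset. Windows with an
    N are skipped. Sequences shorter than the motif give no hits.
    """
    codes = encode(sequence)
    fwd = _strand_scores(codes, pwm.log_odds)
    rev = _strand_scores(codes, pwm.reverse_complement().log_odds)
    hits: list[MotifHit] = []
    for off in range(len(fwd)):
        if fwd[off] >= threshold:
            hits.append(MotifHit(sequence_id, off, "+", float(fwd[off])))
        if rev[off] >= threshold:
            hits.append(MotifHit(sequence_id, off, "-", float(rev[off])))
    return hits


def has_hit(sequence: str, pwm: PWM, threshold: float) -> bool:
    codes = encode(sequence)
    fwd = _strand_scores(codes, pwm.log_odds)
    if len(fwd) and fwd.max() >= threshold:
        return True
    rev = _strand_scores(codes, pwm.reverse_complement().log_odds)
    return bool(len(rev) and rev.max() >= threshold)


def window_sequence(genome: Mapping[str, str], window: GenomicInterval) -> str:
    seq = genome.get(window.chrom)
    if seq is None or window.end > len(seq):
        raise ValueError(
            f"window {window.chrom}:{window.start}-{window.end} outside genome"
        )
    return seq[window.start : window.end]


def motif_fraction(
    windows: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float,
) -> float:
    """Fraction of windows containing >= 1 hit (each window counted once)."""
    if not windows:
        return 0.0
    n_hit = sum(1 for w in windows if has_hit(window_sequence(genome, w), pwm, threshold))
    return n_hit / len(windows)


def motif_enrichment(
    fg_windows: Sequence[GenomicInterval],
    bg_windows: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: PWM,
    threshold: float,
) -> EnrichmentResult:
    """Foreground-vs-background window-level motif enrichment.

    Presence/absence per window feeds the one-sided hypergeometric test;
    the background set is the opposing DAR class, mirroring the
    swapped-background design of the study this emulates.
    """
    if not fg_windows:
        raise ValueError("empty foreground window set")
    k_fg = sum(1 for w in fg_windows if has_hit(window_sequence(genome, w), pwm, threshold))
    k_bg = sum(1 for w in bg_windows if has_hit(window_sequence(genome, w), pwm, threshold))
    return hypergeom_enrichment(k_fg, len(fg_windows), k_bg, max(len(bg_windows), 1))


def enrichment_table(
    pwms: Sequence[PWM],
    fg_windows: Sequence[GenomicInterval],
    bg_windows: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    target_rate: float = 1e-4,
) -> list[dict]:
    """Per-motif enrichment with BH-adjusted p-values, for reports."""
    rows = []
    for pwm in pwms:
        thr = calibrate_threshold(pwm, target_rate)
        res = motif_enrichment(fg_windows, bg_windows, genome, pwm, thr)
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "k_fg": res.k_fg,
                "n_fg": res.n_fg,
                "k_bg": res.k_bg,
                "n_bg": res.n_bg,
                "fg_pct": 100.0 * res.fg_fraction,
                "bg_pct": 100.0 * res.bg_fraction,
                "p": res.p_one_sided,
            }
        )
    padj = bh_adjust([r["p"] for r in rows]) if rows else []
    for row, adj in zip(rows, padj):
        row["p_adj"] = float(adj)
    return rows
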