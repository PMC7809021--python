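"""Synthetic regulatory-genome generator with machine-readable ground truth.

Emulates the statistical structure the pipeline assumes: chromosomes
partitioned into TADs (with cell-line variants that split TADs, exercising
the smallest-TAD rule), genes whose differential-expression directions
segregate TAD-wise, condition-specific accessible regions with planted
gained/lost DARs, motif consensi planted in DAR summit sequences, ChIP
peaks co-located with DARs, and a Nutlin response table with a planted
group effect. Everything derives from one seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .accessibility import CoverageTrack
from .core import ExpressionRecord, Gene, GenomicInterval
from .motifs import BASES, PWM
from .tads import TAD

PARENTAL = "parental"
TRANSFORMED = "transformed"


@dataclass(frozen=True, slots=True)
class SimParams:
    """Generator settings. Defaults are the package's reference conditions."""

    n_chrom: int = 2
    chrom_len: int = 10_000_000
    tad_len_range: tuple[int, int] = (300_000, 1_500_000)
    n_celllines: int = 3
    genes_per_tad_range: tuple[int, int] = (3, 8)
    frac_de: float = 0.2
    de_tad_fraction: float = 0.35
    segregation_pi: float = 0.95
    read_rate: float = 0.02  # reads per bp per condition (replicas combined)
    n_dars_per_direction: int = 200
    n_shared_accessible: int = 100
    dar_len: int = 2000
    dar_fold: float = 8.0
    dar_fold_sd: float = 0.5  # lognormal sd of per-region fold, in log units
    rho_fg: float = 0.4
    rho_bg: float = 0.05
    chip_concordant_p: float = 0.7
    chip_discordant_p: float = 0.1
    n_chip_background: int = 50
    nutlin_effect: float = 0.5
    nutlin_noise: float = 0.3
    dar_placement_bias: float = 0.8
    promoter_bias: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.segregation_pi <= 1.0):
            raise ValueError("segregation_pi must be in [0.5, 1]")
        for name in ("frac_de", "de_tad_fraction", "rho_fg", "rho_bg",
                     "chip_concordant_p", "chip_discordant_p",
                     "dar_placement_bias", "promoter_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tad_len_range[1] > self.chrom_len:
            raise ValueError("TADs exceed chromosome length")


@dataclass
class TrueDar:
    interval: GenomicInterval
    direction: str  # gained / lost / shared
    fold: float = 8.0
    motif_gained: bool = False  # consensus of the gained-enriched motif planted
    motif_lost: bool = False
    chip_parental: bool = False
    chip_transformed: bool = False

    @property
    def summit_window(self) -> GenomicInterval:
        c = (self.interval.start + self.interval.end) // 2
        return GenomicInterval(self.interval.chrom, c - 75, c + 75)


@dataclass
class SimTruth:
    dars: list[TrueDar]
    tad_direction: dict[str, str]  # "chrom:start-end" -> up/down/mixed/none
    hras_down_p53: set[str]
    params: SimParams

    def dars_of(self, direction: str) -> list[TrueDar]:
        return [d for d in self.dars if d.direction == direction]

    def to_json(self) -> str:
        return json.dumps(
            {
                "dars": [
                    {
                        "chrom": d.interval.chrom,
                        "start": d.interval.start,
                        "end": d.interval.end,
                        "direction": d.direction,
                        "fold": d.fold,
                        "motif_gained": d.motif_gained,
                        "motif_lost": d.motif_lost,
                        "chip_parental": d.chip_parental,
                        "chip_transformed": d.chip_transformed,
                    }
                    for d in self.dars
                ],
                "tad_direction": self.tad_direction,
                "hras_down_p53": sorted(self.hras_down_p53),
                "params": dataclasses.asdict(self.params),
            },
            indent=1,
        )


@dataclass
class SimBundle:
    genome: dict[str, str]
    genome_sizes: dict[str, int]
    genes: list[Gene]
    tad_sets: dict[str, list[TAD]]
    expression: list[ExpressionRecord]
    tracks: dict[tuple[str, int], CoverageTrack]  # (condition, replicate)
    chip_peaks: dict[str, list[GenomicInterval]]
    pwms: dict[str, PWM]
    nutlin: dict[str, float]
    truth: SimTruth | None

    def combined_track(self, condition: str) -> CoverageTrack:
        """Replicas pooled, as the study's analysis pools them."""
        merged: dict[str, np.ndarray] = {}
        for (cond, _rep), track in self.tracks.items():
            if cond != condition:
                continue
            for chrom, pos in track.positions.items():
                merged[chrom] = (
                    np.concatenate([merged[chrom], pos]) if chrom in merged else pos
                )
        return CoverageTrack(merged, label=condition)


def _make_pwm(motif_id: str, consensus: str, strength: float = 85.0) -> PWM:
    counts = np.full((4, len(consensus)), (100.0 - strength) / 3)
    for j, base in enumerate(consensus):
        counts[BASES.index(base), j] = strength
    return PWM(motif_id, counts)


GAINED_MOTIF_CONSENSUS = "TGGCCACCAG"  # CTCF-like core, planted in gained DARs
LOST_MOTIF_CONSENSUS = "GGACATGTCC"  # p53 half-site-like, planted in lost DARs


def _partition_tads(rng: np.random.Generator, chrom: str, params: SimParams) -> list[TAD]:
    lo, hi = params.tad_len_range
    tads: list[TAD] = []
    pos = 0
    while pos < params.chrom_len:
        length = int(rng.integers(lo, hi + 1))
        end = min(pos + length, params.chrom_len)
        if params.chrom_len - end < lo:
            end = params.chrom_len
        tads.append(TAD(GenomicInterval(chrom, pos, end), source="CL1"))
        pos = end
    return tads


def _variant_tads(
    rng: np.random.Generator, base: list[TAD], source: str
) -> list[TAD]:
    """A cell-line variant: a random subset of TADs split in two."""
    out: list[TAD] = []
    for tad in base:
        iv = tad.interval
        if len(iv) >= 400_000 and rng.random() < 0.3:
            cut = int(rng.integers(iv.start + 150_000, iv.end - 150_000))
            out.append(TAD(GenomicInterval(iv.chrom, iv.start, cut), source))
            out.append(TAD(GenomicInterval(iv.chrom, cut, iv.end), source))
        else:
            out.append(TAD(iv, source))
    return out


def _place_genes(
    rng: np.random.Generator, base_tads: list[TAD], params: SimParams
) -> tuple[list[Gene], dict[int, list[int]]]:
    genes: list[Gene] = []
    tad_gene_idx: dict[int, list[int]] = {}
    g_lo, g_hi = params.genes_per_tad_range
    for t_idx, tad in enumerate(base_tads):
        n = int(rng.integers(g_lo, g_hi + 1))
        tad_gene_idx[t_idx] = []
        for _ in range(n):
            length = int(rng.integers(5_000, 50_001))
            iv = tad.interval
            if len(iv) <= length + 2_000:
                length = max(1_000, len(iv) // 4)
            start = int(rng.integers(iv.start + 1_000, iv.end - length - 1_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{len(genes):05d}"
            genes.append(Gene(gene_id, GenomicInterval(iv.chrom, start, start + length, strand)))
            tad_gene_idx[t_idx].append(len(genes) - 1)
    return genes, tad_gene_idx


def simulate(params: SimParams) -> SimBundle:
    """Generate the full dataset bundle with planted ground truth."""
    rng = np.random.default_rng(params.seed)
    chroms = [f"chr{i + 1}" for i in range(params.n_chrom)]
    genome_sizes = {c: params.chrom_len for c in chroms}

    # --- TADs and cell-line variants
    base_tads: list[TAD] = []
    for chrom in chroms:
        base_tads.extend(_partition_tads(rng, chrom, params))
    tad_sets = {"CL1": base_tads}
    for i in range(2, params.n_celllines + 1):
        tad_sets[f"CL{i}"] = _variant_tads(rng, base_tads, f"CL{i}")

    # --- genes, DE-active TADs, TAD-wise segregated DE directions
    genes, tad_gene_idx = _place_genes(rng, base_tads, params)
    p_de_in_active = min(1.0, params.frac_de / max(params.de_tad_fraction, 1e-9))
    # homogeneity interpolation: at pi = 0.5 directions are iid per gene,
    # which is exactly the exchangeable null of the permutation test
    p_homogeneous = max(0.0, 2.0 * params.segregation_pi - 1.0)

    de_dir: dict[str, str] = {g.gene_id: "stable" for g in genes}
    all_tads = sorted(tad_gene_idx)
    n_active = max(2, round(params.de_tad_fraction * len(all_tads)))
    while True:
        active = sorted(rng.choice(all_tads, size=min(n_active, len(all_tads)), replace=False))
        # balanced latent directions over the active TADs
        shuffled = rng.permutation(len(active))
        latent = {active[j]: ("up" if r % 2 == 0 else "down") for r, j in enumerate(shuffled)}
        for g in genes:
            de_dir[g.gene_id] = "stable"
        for t_idx in active:
            de_idxs = [g for g in tad_gene_idx[t_idx] if rng.random() < p_de_in_active]
            if not de_idxs:
                continue
            if rng.random() < p_homogeneous:
                for g_idx in de_idxs:
                    de_dir[genes[g_idx].gene_id] = latent[t_idx]
            else:
                for g_idx in de_idxs:
                    de_dir[genes[g_idx].gene_id] = "up" if rng.random() < 0.5 else "down"
        dirs = set(de_dir.values())
        if "up" in dirs and "down" in dirs:
            break

    expression: list[ExpressionRecord] = []
    for gene in genes:
        direction = de_dir[gene.gene_id]
        if direction == "stable":
            lfc = float(rng.normal(0.0, 0.2))
            fdr = float(rng.uniform(0.05, 1.0))
        else:
            mag = 0.6 + float(rng.exponential(0.8))
            lfc = mag if direction == "up" else -mag
            fdr = float(10 ** rng.uniform(-8.0, -2.0))
        expression.append(
            ExpressionRecord(gene.gene_id, lfc, fdr, float(rng.lognormal(3.0, 1.0)))
        )

    # true TAD directions (on the base partition)
    tad_key = lambda t: f"{t.interval.chrom}:{t.interval.start}-{t.interval.end}"
    tad_direction: dict[str, str] = {}
    for t_idx, tad in enumerate(base_tads):
        dirs = {de_dir[genes[g].gene_id] for g in tad_gene_idx[t_idx]}
        if "up" in dirs and "down" in dirs:
            tad_direction[tad_key(tad)] = "mixed"
        elif "up" in dirs:
            tad_direction[tad_key(tad)] = "up"
        elif "down" in dirs:
            tad_direction[tad_key(tad)] = "down"
        else:
            tad_direction[tad_key(tad)] = "none"

    # --- planted accessible regions (gained / lost / shared)
    up_tads = [t for t in base_tads if tad_direction[tad_key(t)] == "up"]
    down_tads = [t for t in base_tads if tad_direction[tad_key(t)] == "down"]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place_region(
        pref_tads: list[TAD], pref_tss: list[tuple[str, int]] | None = None
    ) -> GenomicInterval:
        margin = 5_000  # keep planted regions from merging into one called peak
        for _attempt in range(1000):
            if pref_tss and rng.random() < params.promoter_bias:
                chrom, tss = pref_tss[int(rng.integers(len(pref_tss)))]
                start = max(1_000, tss - params.dar_len // 2)
                if (
                    start + params.dar_len < params.chrom_len - 1_000
                    and all(
                        start + params.dar_len + margin <= s or start >= e + margin
                        for s, e in occupied[chrom]
                    )
                ):
                    occupied[chrom].append((start, start + params.dar_len))
                    return GenomicInterval(chrom, start, start + params.dar_len)
                continue
            if pref_tads and rng.random() < params.dar_placement_bias:
                tad = pref_tads[int(rng.integers(len(pref_tads)))]
                chrom = tad.interval.chrom
                lo_b = max(tad.interval.start, 1_000)
                hi_b = min(
                    tad.interval.end - params.dar_len,
                    params.chrom_len - params.dar_len - 1_000,
                )
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                lo_b, hi_b = 1_000, params.chrom_len - params.dar_len - 1_000
            if hi_b <= lo_b:
                continue
            start = int(rng.integers(lo_b, hi_b))
            if all(
                start + params.dar_len + margin <= s or start >= e + margin
                for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, start + params.dar_len))
                return GenomicInterval(chrom, start, start + params.dar_len)
        raise RuntimeError("could not place region; genome too crowded")

    gene_by_id = {g.gene_id: g for g in genes}
    up_tss = [
        (gene_by_id[g].body.chrom, gene_by_id[g].tss)
        for g, d in de_dir.items() if d == "up"
    ]
    down_tss = [
        (gene_by_id[g].body.chrom, gene_by_id[g].tss)
        for g, d in de_dir.items() if d == "down"
    ]
    def draw_fold() -> float:
        # peaks vary in strength around dar_fold, never below callability
        return float(np.clip(params.dar_fold * rng.lognormal(0.0, params.dar_fold_sd),
                             3.0, 6.0 * params.dar_fold))

    dars: list[TrueDar] = []
    for _ in range(params.n_dars_per_direction):
        dars.append(TrueDar(place_region(up_tads, up_tss), "gained", draw_fold()))
    for _ in range(params.n_dars_per_direction):
        dars.append(TrueDar(place_region(down_tads, down_tss), "lost", draw_fold()))
    for _ in range(params.n_shared_accessible):
        dars.append(TrueDar(place_region([]), "shared", draw_fold()))

    # --- read tracks: Poisson background + centre-peaked enrichment in regions
    def region_active(d: TrueDar, condition: str) -> bool:
        if d.direction == "shared":
            return True
        return d.direction == ("gained" if condition == TRANSFORMED else "lost")

    tracks: dict[tuple[str, int], CoverageTrack] = {}
    rep_rate = params.read_rate / 2.0
    for condition in (PARENTAL, TRANSFORMED):
        for rep in (1, 2):
            positions: dict[str, np.ndarray] = {}
            for chrom in chroms:
                n_bg = rng.poisson(rep_rate * params.chrom_len)
                bg = rng.integers(0, params.chrom_len, size=n_bg)
                parts = [bg]
                for d in dars:
                    if d.interval.chrom != chrom or not region_active(d, condition):
                        continue
                    extra = (d.fold - 1.0) * rep_rate * len(d.interval)
                    n_extra = rng.poisson(extra)
                    center = (d.interval.start + d.interval.end) / 2
                    # sharp central enrichment: summits localise like real
                    # nucleosome-free regions, so motif planting at the
                    # centre stays inside the called 150-bp summit window
                    pts = rng.normal(center, 75.0, size=n_extra)
                    pts = np.clip(pts, d.interval.start, d.interval.end - 1)
                    parts.append(pts.astype(np.int64))
                positions[chrom] = np.concatenate(parts)
            tracks[(condition, rep)] = CoverageTrack(positions, label=f"{condition}_r{rep}")

    # --- genome sequence with planted motif consensi at DAR centres
    pwm_gained = _make_pwm("MG_CTCF_LIKE", GAINED_MOTIF_CONSENSUS)
    pwm_lost = _make_pwm("ML_P53_LIKE", LOST_MOTIF_CONSENSUS)
    genome: dict[str, str] = {}
    seq_arrays = {
        c: rng.integers(0, 4, size=params.chrom_len).astype(np.int8) for c in chroms
    }
    base_codes = {b: i for i, b in enumerate(BASES)}

    def plant(seq: np.ndarray, at: int, consensus: str) -> None:
        seq[at : at + len(consensus)] = [base_codes[b] for b in consensus]

    for d in dars:
        center = (d.interval.start + d.interval.end) // 2
        seq = seq_arrays[d.interval.chrom]
        rho_g = params.rho_fg if d.direction == "gained" else params.rho_bg
        rho_l = params.rho_fg if d.direction == "lost" else params.rho_bg
        if rng.random() < rho_g:
            d.motif_gained = True
            plant(seq, center - len(GAINED_MOTIF_CONSENSUS) - 2, GAINED_MOTIF_CONSENSUS)
        if rng.random() < rho_l:
            d.motif_lost = True
            plant(seq, center + 2, LOST_MOTIF_CONSENSUS)
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for chrom in chroms:
        genome[chrom] = lut[seq_arrays[chrom]].tobytes().decode("ascii")

    # --- ChIP peaks co-located with DARs plus unrelated background peaks
    chip_peaks: dict[str, list[GenomicInterval]] = {PARENTAL: [], TRANSFORMED: []}
    half_chip = 150
    for d in dars:
        if d.direction == "shared":
            continue
        center = (d.interval.start + d.interval.end) // 2
        peak = GenomicInterval(d.interval.chrom, center - half_chip, center + half_chip)
        p_tr = (
            params.chip_concordant_p if d.direction == "gained" else params.chip_discordant_p
        )
        p_pa = (
            params.chip_concordant_p if d.direction == "lost" else params.chip_discordant_p
        )
        if rng.random() < p_tr:
            d.chip_transformed = True
            chip_peaks[TRANSFORMED].append(peak)
        if rng.random() < p_pa:
            d.chip_parental = True
            chip_peaks[PARENTAL].append(peak)
    for condition in (PARENTAL, TRANSFORMED):
        for _ in range(params.n_chip_background):
            iv = place_region([])
            center = (iv.start + iv.end) // 2
            chip_peaks[condition].append(
                GenomicInterval(iv.chrom, center - half_chip, center + half_chip)
            )

    # --- Nutlin response with a planted shift for the p53-linked down group
    gene_base_tad = {
        genes[g].gene_id: t_idx
        for t_idx, gene_idxs in tad_gene_idx.items()
        for g in gene_idxs
    }
    tads_with_motif_lost_dar = set()
    for d in dars:
        if d.direction == "lost" and d.motif_lost:
            for t_idx, tad in enumerate(base_tads):
                if tad.interval.overlap_bp(d.interval) >= 1:
                    tads_with_motif_lost_dar.add(t_idx)
    hras_down_p53 = {
        g for g, direction in de_dir.items()
        if direction == "down" and gene_base_tad[g] in tads_with_motif_lost_dar
    }
    nutlin: dict[str, float] = {}
    for gene in genes:
        base = float(rng.normal(0.0, params.nutlin_noise))
        if gene.gene_id in hras_down_p53:
            base = float(np.sign(base) or 1.0) * (abs(base) + params.nutlin_effect)
        nutlin[gene.gene_id] = base

    truth = SimTruth(dars, tad_direction, hras_down_p53, params)
    return SimBundle(
        genome, genome_sizes, genes, tad_sets, expression,
        tracks, chip_peaks, {p.motif_id: p for p in (pwm_gained, pwm_lost)},
        nutlin, truth,
    )


def null_variant(params: SimParams) -> SimBundle:
    """Same generator with every planted association removed.

    Segregation pi drops to 0.5, motif planting rates equalise at rho_bg,
    DAR placement ignores TAD direction, ChIP co-location probabilities
    equalise at their mean, and the Nutlin group effect is zero.
    """
    null = dataclasses.replace(
        params,
        segregation_pi=0.5,
        rho_fg=params.rho_bg,
        dar_placement_bias=0.0,
        promoter_bias=0.0,
        chip_concordant_p=(params.chip_concordant_p + params.chip_discordant_p) / 2,
        chip_discordant_p=(params.chip_concordant_p + params.chip_discordant_p) / 2,
        nutlin_effect=0.0,
    )
    return simulate(null)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Serialise the bundle to plain-text files plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(bundle.genome, outdir / "genome.fa")
    tio.write_gene_bed(bundle.genes, outdir / "genes.bed")
    for source, tads in bundle.tad_sets.items():
        tio.write_bed(
            [tio.BedRecord(t.interval, t.source) for t in tads],
            outdir / f"tads_{source}.bed",
        )
    tio.write_expression_table(bundle.expression, outdir / "expression.tsv")
    for (condition, rep), track in bundle.tracks.items():
        tio.write_points(track.positions, outdir / f"reads_{condition}_r{rep}.tsv")
    for condition, peaks in bundle.chip_peaks.items():
        tio.write_bed([tio.BedRecord(iv) for iv in peaks], outdir / f"chip_{condition}.bed")
    from .motifs import write_jaspar

    write_jaspar(list(bundle.pwms.values()), outdir / "motifs.jaspar")
    tio.write_two_column_table(bundle.nutlin, outdir / "nutlin.tsv")
    (outdir / "truth.json").write_text(bundle.truth.to_json())
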