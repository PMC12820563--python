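"""Seeded synthetic-data generators with planted ground truth.

Two families of generators produce every input the pipeline consumes:

* :func:`gen_pdseq_reads` / :func:`sample_site1_counts` emulate the
  pull-down reaction on the degenerate oligo libraries.  An input pool is
  drawn uniformly over the variable positions; the pull-down sample is
  drawn from that pool with replacement, with per-read weight
  ``noise_floor + sum of matched-motif weights`` — a single selection
  round by a binder of configurable specificity.

* :func:`gen_genome` builds a genome of i.i.d. background bases with
  planted paired motifs (chosen orientation and gap), planted TnG arrays
  (optionally anchored at a signed offset to an H-H site), peak intervals,
  peak-shaped coverage, and a differential-expression table whose
  feature-proximity structure is configurable.  All planted features are
  recorded as ground-truth tables so recovery can be asserted exactly.

Same seed + config give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import write_bed, write_bedgraph, write_fasta, write_fastq
from .pairs import (
    DEFAULT_OFFSETS,
    PairMatcher,
    PairPattern,
    build_pair_patterns,
    encode_seq,
    pack_windows,
)
from .pdseq import DegenerateTemplate
from .seqcore import IUPAC_SETS, iter_kmers, matches, pattern_to_regex, reverse_complement
from .tng import detect_tng_repeats

logger = logging.getLogger(__name__)

BASES = "ACGT"
Q30 = chr(33 + 30)


# ---------------------------------------------------------------------------
# binder models and PD-seq read generation


@dataclass(frozen=True)
class BinderModel:
    """Abstract selectivity of the pulled-down protein.

    ``dimeric_pair`` weights reads whose variable region completes an
    oriented motif pair (FoxP3-like head-to-head preference);
    ``monomeric_site2`` weights reads solely on the site-2 half-site
    (FoxP1-like, engaging only the rcFKHM); ``uniform`` reduces to equal
    sampling.  ``weights`` maps 7-nt motif patterns to relative enrichment
    weights; ``orientation_weights`` modulate pair orientations for the
    random-random design.
    """

    mode: str = "dimeric_pair"
    weights: Mapping[str, float] = field(default_factory=dict)
    orientation_weights: Mapping[str, float] = field(
        default_factory=lambda: {"HH": 1.0, "HT": 1.0, "TH": 1.0, "TT": 1.0}
    )
    noise_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in {"dimeric_pair", "monomeric_site2", "uniform"}:
            raise ValueError(f"unknown binder mode {self.mode!r}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("motif weights must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be >= 0")


def site1_weight_array(template: DegenerateTemplate, model: BinderModel) -> np.ndarray:
    """Selection weight of every site-1 7-mer on a fixed-site-2 template."""
    kmers = list(iter_kmers(template.site1_len))
    w = np.full(len(kmers), model.noise_floor, dtype=float)
    if model.mode == "uniform":
        return w
    if model.mode == "monomeric_site2":
        # binding reads only the fixed site 2: a constant boost when some
        # motif matches its forward (reverse-complemented) reading
        site2_fwd = reverse_complement(template.site2)
        boost = sum(
            wt for pat, wt in model.weights.items() if matches(pat, site2_fwd)
        )
        return w + boost
    for pat, wt in model.weights.items():
        w += wt * np.fromiter(
            (matches(pat, k) for k in kmers), dtype=bool, count=len(kmers)
        )
    return w


def sample_site1_counts(
    template: DegenerateTemplate,
    model: BinderModel,
    n_reads: int,
    seed: int,
) -> tuple[pd.Series, pd.Series]:
    """(input, pull-down) per-site-1-sequence counts over all 4**7 rows.

    The input pool is multinomial-uniform; the pull-down redraws from that
    pool with weight-proportional probability.
    """
    rng = np.random.default_rng(seed)
    kmers = pd.Index(list(iter_kmers(template.site1_len)), name="sequence")
    input_counts = rng.multinomial(n_reads, np.full(len(kmers), 1.0 / len(kmers)))
    pool_w = input_counts * site1_weight_array(template, model)
    total = pool_w.sum()
    if total == 0:
        pd_counts = np.zeros(len(kmers), dtype=int)
    else:
        pd_counts = rng.multinomial(n_reads, pool_w / total)
    return (
        pd.Series(input_counts, index=kmers, name="count"),
        pd.Series(pd_counts, index=kmers, name="count"),
    )


def rr_pair_patterns(
    model: BinderModel, gap: str = "TCGA"
) -> tuple[list[PairPattern], np.ndarray]:
    """Oriented pair patterns and weights implied by a binder model.

    Pattern weight = orientation weight x geometric mean of the two motif
    weights.
    """
    motifs = sorted(model.weights)
    patterns = build_pair_patterns(motifs, gap)
    w = np.array(
        [
            model.orientation_weights.get(p.orientation, 0.0)
            * float(np.sqrt(model.weights[p.motif_a] * model.weights[p.motif_b]))
            for p in patterns
        ]
    )
    return patterns, w


def _decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def rr_read_weights(
    var_arr: np.ndarray,
    template: DegenerateTemplate,
    model: BinderModel,
    matcher: PairMatcher | None = None,
    pattern_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Selection weights for (n, 14) arrays of site1+site2 base indices.

    Dimeric weights use any-shift pair matching (distinct matched patterns
    summed exactly); monomeric weights read only the site-2 columns at the
    fixed register.
    """
    n = len(var_arr)
    w = np.full(n, model.noise_floor, dtype=float)
    if model.mode == "uniform" or not model.weights:
        return w
    s1 = template.site1_len
    if model.mode == "monomeric_site2":
        for pat, wt in model.weights.items():
            rc = reverse_complement(pat)
            ok = np.ones(n, dtype=bool)
            for j, ch in enumerate(rc):
                allowed = np.array([BASES.index(b) for b in IUPAC_SETS[ch]])
                ok &= np.isin(var_arr[:, s1 + j], allowed)
            w += wt * ok
        return w
    if matcher is None or pattern_weights is None:
        patterns, pattern_weights = rr_pair_patterns(model, template.gap)
        matcher = PairMatcher(patterns, template)
    keys, _ = matcher.encoded_lookup()
    # reconstructed context: nbs1 tail | site1 | gap | site2 | nbs2 head
    pad = max(-min(matcher.offsets), 0), max(max(matcher.offsets), 0)
    left = encode_seq(template.nbs1[len(template.nbs1) - pad[0] :])
    gap = encode_seq(template.gap)
    right = encode_seq(template.nbs2[: pad[1]])
    ctx = np.empty((n, pad[0] + 14 + len(gap) + pad[1]), dtype=np.uint8)
    ctx[:, : pad[0]] = left
    ctx[:, pad[0] : pad[0] + s1] = var_arr[:, :s1]
    ctx[:, pad[0] + s1 : pad[0] + s1 + len(gap)] = gap
    ctx[:, pad[0] + s1 + len(gap) : pad[0] + s1 + len(gap) + 7] = var_arr[:, s1:]
    ctx[:, pad[0] + s1 + len(gap) + 7 :] = right
    wlen = template.insert_len
    hit_any = np.zeros(n, dtype=bool)
    for d in matcher.offsets:
        col = pad[0] + d
        packed = pack_windows(ctx[:, col : col + wlen])
        pos = np.searchsorted(keys, packed)
        pos[pos >= len(keys)] = 0
        hit_any |= keys[pos] == packed if len(keys) else False
    # exact distinct-pattern weights for the (rare) matching reads
    for i in np.flatnonzero(hit_any):
        insert = _decode(ctx[i, pad[0] : pad[0] + wlen])
        w[i] += sum(pattern_weights[j] for j in matcher.match(insert))
    return w


def sample_random_random_inserts(
    template: DegenerateTemplate,
    model: BinderModel,
    n_reads: int,
    seed: int,
    pool_factor: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """(input, pull-down) arrays of (n, 14) site1+site2 base indices.

    The input pool holds ``pool_factor * n_reads`` uniform molecules; the
    pull-down draws ``n_reads`` of them with weight-proportional
    replacement.
    """
    rng = np.random.default_rng(seed)
    n_pool = n_reads * pool_factor
    pool = rng.integers(0, 4, size=(n_pool, 14), dtype=np.uint8)
    w = rr_read_weights(pool, template, model)
    pd_idx = rng.choice(n_pool, size=n_reads, replace=True, p=w / w.sum())
    input_idx = rng.choice(n_pool, size=n_reads, replace=True)
    return pool[input_idx], pool[pd_idx]


def _reads_from_site1(
    kmers: Sequence[str], counts: np.ndarray, template: DegenerateTemplate, tag: str
) -> list[tuple[str, str, str]]:
    reads = []
    i = 0
    for kmer, c in zip(kmers, counts):
        for _ in range(int(c)):
            seq = template.assemble(kmer)
            reads.append((f"{tag}_{i}", seq, Q30 * len(seq)))
            i += 1
    return reads


def gen_pdseq_reads(
    template: DegenerateTemplate,
    model: BinderModel,
    n_reads: int,
    seed: int,
    out_input: str | Path | None = None,
    out_pd: str | Path | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Full synthetic (input, pull-down) read sets with constant Q30 quality.

    Works for both library designs; optionally writes FASTQ files.
    """
    if template.site2 is not None:
        inp, pdc = sample_site1_counts(template, model, n_reads, seed)
        input_reads = _reads_from_site1(inp.index, inp.to_numpy(), template, "input")
        pd_reads = _reads_from_site1(pdc.index, pdc.to_numpy(), template, "pd")
    else:
        inp_arr, pd_arr = sample_random_random_inserts(template, model, n_reads, seed)
        def _assemble(arr, tag):
            out = []
            for i, row in enumerate(arr):
                seq = template.assemble(_decode(row[:7]), _decode(row[7:]))
                out.append((f"{tag}_{i}", seq, Q30 * len(seq)))
            return out
        input_reads = _assemble(inp_arr, "input")
        pd_reads = _assemble(pd_arr, "pd")
    if out_input:
        write_fastq(input_reads, out_input)
    if out_pd:
        write_fastq(pd_reads, out_pd)
    return input_reads, pd_reads


# ---------------------------------------------------------------------------
# genome generation


@dataclass(frozen=True)
class PairPlant:
    """Planted oriented motif pairs (N positions instantiated at random)."""

    motif_a: str = "TGTTTNN"
    motif_b: str = "TGTTTNN"
    orientation: str = "HH"
    gap_len: int = 4
    count: int = 30
    in_peaks: bool = True


@dataclass(frozen=True)
class TnGPlant:
    """Planted TnG arrays, optionally anchored to an adjacent H-H site.

    ``hh_offset`` is the signed border distance from the anchored H-H site
    to the repeat (0 = abutting); ``None`` plants a standalone repeat kept
    at least ``GenomeConfig.far_guard`` bp from every H-H site.  Anchored
    geometry follows the aligned convention: a "+" repeat goes upstream of
    the H-H site, a "-" repeat downstream, unless the offset sign forces
    the divergent side.
    """

    unit: str = "TTTG"
    n_units: int = 5
    count: int = 30
    strand: str = "+"
    in_peaks: bool = True
    hh_offset: int | None = None
    hh_motif: str = "TGTTTAC"


@dataclass(frozen=True)
class GenePlant:
    """Differential-expression table structure on a dedicated chromosome.

    Genes are laid out on a grid (``spacing`` apart) so feature proximity
    never leaks between neighbours.  ``bin_fractions`` apportion genes to
    the adjusted-p bins; ``feature_prob`` is the chance a gene in each bin
    gets a feature planted within ``radius`` of its body.
    """

    n_genes: int = 200
    gene_length: int = 2_000
    spacing: int = 12_000
    radius: int = 2_000
    p_bins: tuple[float, ...] = (0.0, 1e-10, 1e-5, 0.05, 1.0)
    bin_fractions: tuple[float, ...] = (0.05, 0.10, 0.15, 0.70)
    feature_prob: tuple[float, ...] = (0.9, 0.6, 0.3, 0.05)
    suppressed_frac: float = 0.8
    feature_seq: str = "TGTTTACTCGAGTAAACA"  # concrete IR-FKHM, 4-nt gap
    chrom: str = "chrG"


@dataclass(frozen=True)
class CoverageSpec:
    """Piecewise-triangular coverage: peak-wide bumps plus local boosts at
    zero-gap-anchored repeats."""

    peak_height: float = 5.0
    zero_gap_boost: float = 20.0
    boost_halfwidth: int = 150


@dataclass(frozen=True)
class GenomeConfig:
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 200_000}
    )
    gc: float = 0.5
    n_chip_peaks: int = 40
    chip_peak_len: int = 600
    n_atac_peaks: int = 60
    atac_peak_len: int = 400
    pairs: tuple[PairPlant, ...] = ()
    tngs: tuple[TnGPlant, ...] = ()
    genes: GenePlant | None = None
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    far_guard: int = 1_500
    feature_margin: int = 200
    scrub: bool = True
    max_attempts: int = 2_000


@dataclass
class GenomeBundle:
    """A generated genome with its ground truth."""

    sequences: dict[str, str]
    chip_peaks: pd.DataFrame
    atac_peaks: pd.DataFrame
    planted_hh: pd.DataFrame
    planted_tng: pd.DataFrame
    gene_features: pd.DataFrame
    coverage: dict[str, np.ndarray]
    de_table: pd.DataFrame
    config: GenomeConfig
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fa")
        write_bed(self.chip_peaks, outdir / "chip_peaks.bed")
        write_bed(self.atac_peaks, outdir / "atac_peaks.bed")
        self.planted_hh.to_csv(outdir / "planted_hh.tsv", sep="\t", index=False)
        self.planted_tng.to_csv(outdir / "planted_tng.tsv", sep="\t", index=False)
        self.gene_features.to_csv(
            outdir / "gene_features.tsv", sep="\t", index=False
        )
        write_bedgraph(self.coverage, outdir / "coverage.bedgraph")
        self.de_table.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Replace degenerate positions with uniform draws from their sets."""
    return "".join(
        ch if ch in BASES else rng.choice(sorted(IUPAC_SETS[ch]))
        for ch in pattern
    )


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


class _Placer:
    """Rejection-samples non-overlapping placements on one chromosome."""

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 20):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def _collides(self, start: int, end: int) -> bool:
        m = self.margin
        return any(start - m < e and s < end + m for s, e in self.occupied)

    def place(
        self,
        size: int,
        bounds: tuple[int, int] | None = None,
        max_attempts: int = 2_000,
    ) -> int:
        lo, hi = bounds if bounds else (0, self.length)
        hi = min(hi, self.length) - size
        if hi <= lo:
            raise ValueError("no room to place feature")
        for _ in range(max_attempts):
            start = int(self.rng.integers(lo, hi + 1))
            if not self._collides(start, start + size):
                self.occupied.append((start, start + size))
                return start
        raise RuntimeError(f"could not place a {size} bp feature after {max_attempts} tries")


def _scrub(
    seqs: dict[str, np.ndarray],
    regexes: list,
    gc: float,
    rng: np.random.Generator,
    max_rounds: int = 20,
) -> None:
    """Re-randomize background spans matching any regex or the TnG grammar,
    so recovery tests see only planted features."""
    for chrom, arr in seqs.items():
        for _ in range(max_rounds):
            s = _decode(arr)
            dirty = []
            for rx in regexes:
                dirty += [(m.start(), m.end()) for m in rx.finditer(s)]
            reps = detect_tng_repeats(s, min_length=10, min_units=2, chrom=chrom)
            dirty += list(zip(reps["Start"], reps["End"]))
            if not dirty:
                break
            for a, b in dirty:
                arr[a:b] = _random_seq(b - a, gc, rng)
        else:
            logger.warning("scrubbing %s did not converge", chrom)


def gen_genome(config: GenomeConfig, seed: int) -> GenomeBundle:
    """Generate a genome bundle with planted ground truth (deterministic)."""
    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {
        c: _random_seq(n, config.gc, rng) for c, n in config.chrom_lengths.items()
    }
    gene_cfg = config.genes
    if gene_cfg is not None:
        glen = gene_cfg.n_genes * gene_cfg.spacing + 2 * gene_cfg.spacing
        seqs[gene_cfg.chrom] = _random_seq(glen, config.gc, rng)

    if config.scrub:
        regexes = [
            pattern_to_regex(
                PairPattern(p.motif_a, p.motif_b, p.orientation, "N" * g).rendered
            )
            for p in config.pairs
            for g in range(1, 11)
        ]
        if gene_cfg is not None:
            regexes.append(pattern_to_regex(gene_cfg.feature_seq))
        _scrub(seqs, regexes, config.gc, rng)

    placers = {c: _Placer(len(a), rng) for c, a in seqs.items()}
    main_chroms = list(config.chrom_lengths)

    def pick_chrom() -> str:
        lens = np.array([config.chrom_lengths[c] for c in main_chroms], dtype=float)
        return main_chroms[rng.choice(len(main_chroms), p=lens / lens.sum())]

    # peaks first, then features inside (or outside) them
    def make_peaks(n: int, size: int) -> pd.DataFrame:
        rows = []
        for i in range(n):
            chrom = pick_chrom()
            start = placers[chrom].place(size, max_attempts=config.max_attempts)
            rows.append((chrom, start, start + size))
        return (
            pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
            .sort_values(["Chromosome", "Start"], kind="stable")
            .reset_index(drop=True)
        )

    chip = make_peaks(config.n_chip_peaks, config.chip_peak_len)
    atac = make_peaks(config.n_atac_peaks, config.atac_peak_len)
    # features go inside peaks: track their own collisions separately
    feature_placers = {
        c: _Placer(len(a), rng, margin=config.feature_margin) for c, a in seqs.items()
    }

    def splice(chrom: str, start: int, s: str) -> None:
        seqs[chrom][start : start + len(s)] = encode_seq(s)

    def place_feature(size: int, in_peaks: bool, peak_pool: pd.DataFrame) -> tuple[str, int]:
        for _ in range(config.max_attempts):
            if in_peaks and len(peak_pool):
                peak = peak_pool.iloc[int(rng.integers(len(peak_pool)))]
                chrom = peak.Chromosome
                bounds = (int(peak.Start) + 5, int(peak.End) - 5)
            else:
                chrom = pick_chrom()
                bounds = None
            try:
                start = feature_placers[chrom].place(size, bounds, max_attempts=50)
                return chrom, start
            except (ValueError, RuntimeError):
                continue
        raise RuntimeError("feature placement failed")

    hh_rows = []
    tng_rows = []

    def guard_repeat(chrom: str, r_start: int, r_end: int, hh_span=None) -> None:
        # pin the bases flanking a planted array so random neighbours can
        # never extend the detected repeat ('C' cannot end a unit, 'G'
        # cannot start one, on either strand reading)
        arr = seqs[chrom]
        for pos, base in ((r_start - 1, "C"), (r_end, "G")):
            if 0 <= pos < len(arr) and (
                hh_span is None or not (hh_span[0] <= pos < hh_span[1])
            ):
                arr[pos] = encode_seq(base)[0]

    def record_hh(chrom, start, seq, spec_name, orientation, gap_len, linked):
        hh_rows.append(
            (chrom, start, start + len(seq), spec_name, orientation, gap_len, linked)
        )

    # 1. anchored TnG/H-H blocks
    for t in config.tngs:
        if t.hh_offset is None:
            continue
        unit = t.unit.upper()
        repeat = unit * t.n_units
        if t.strand == "-":
            repeat = reverse_complement(repeat)
        for _ in range(t.count):
            hh_seq = (
                _instantiate(t.hh_motif, rng)
                + "TCGA"
                + reverse_complement(_instantiate(t.hh_motif, rng))
            )
            filler = _decode(_random_seq(abs(t.hh_offset), config.gc, rng))
            # offset sign fixes the side; at 0 the aligned side is chosen
            # ("+" repeat upstream of the H-H, "-" repeat downstream)
            repeat_first = t.hh_offset < 0 or (t.hh_offset == 0 and t.strand == "+")
            block = (
                repeat + filler + hh_seq if repeat_first else hh_seq + filler + repeat
            )
            chrom, start = place_feature(len(block), t.in_peaks, chip)
            splice(chrom, start, block)
            if repeat_first:
                r0, h0 = start, start + len(repeat) + len(filler)
            else:
                h0, r0 = start, start + len(hh_seq) + len(filler)
            guard_repeat(chrom, r0, r0 + len(repeat), (h0, h0 + len(hh_seq)))
            tng_rows.append(
                (chrom, r0, r0 + len(repeat), t.strand, len(repeat), t.n_units, t.hh_offset)
            )
            record_hh(chrom, h0, hh_seq, f"{t.hh_motif}x2", "HH", 4, True)

    # 2. standalone pairs
    for p in config.pairs:
        for _ in range(p.count):
            a = _instantiate(p.motif_a, rng)
            b = _instantiate(p.motif_b, rng)
            gap = _decode(_random_seq(p.gap_len, config.gc, rng))
            seq = PairPattern(a, b, p.orientation, gap).rendered
            chrom, start = place_feature(len(seq), p.in_peaks, chip)
            splice(chrom, start, seq)
            record_hh(
                chrom, start, seq,
                f"{p.motif_a}_{p.motif_b}", p.orientation, p.gap_len, False,
            )

    # 3. standalone TnGs, kept far from every planted H-H site
    hh_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in hh_rows:
        hh_by_chrom.setdefault(chrom, []).append((start, end))
    for t in config.tngs:
        if t.hh_offset is not None:
            continue
        unit = t.unit.upper()
        repeat = unit * t.n_units
        if t.strand == "-":
            repeat = reverse_complement(repeat)
        for _ in range(t.count):
            for _ in range(config.max_attempts):
                chrom, start = place_feature(len(repeat), t.in_peaks, chip)
                near_hh = any(
                    start - config.far_guard < e and s < start + len(repeat) + config.far_guard
                    for s, e in hh_by_chrom.get(chrom, [])
                )
                if not near_hh:
                    break
            else:
                raise RuntimeError("could not place standalone repeat away from H-H sites")
            splice(chrom, start, repeat)
            guard_repeat(chrom, start, start + len(repeat))
            tng_rows.append(
                (chrom, start, start + len(repeat), t.strand, len(repeat), t.n_units, None)
            )

    planted_hh = pd.DataFrame(
        hh_rows,
        columns=["Chromosome", "Start", "End", "Name", "orientation", "gap_len", "linked"],
    ).sort_values(["Chromosome", "Start"], kind="stable").reset_index(drop=True)
    planted_tng = pd.DataFrame(
        tng_rows,
        columns=["Chromosome", "Start", "End", "Strand", "length", "n_units", "hh_offset"],
    ).sort_values(["Chromosome", "Start"], kind="stable").reset_index(drop=True)

    # 4. differential-expression table + gene-proximal features
    gene_rows = []
    gene_feature_rows = []
    if gene_cfg is not None:
        n_bins = len(gene_cfg.bin_fractions)
        bin_of = rng.choice(
            n_bins,
            size=gene_cfg.n_genes,
            p=np.array(gene_cfg.bin_fractions) / sum(gene_cfg.bin_fractions),
        )
        for i in range(gene_cfg.n_genes):
            gstart = gene_cfg.spacing + i * gene_cfg.spacing
            gend = gstart + gene_cfg.gene_length
            k = int(bin_of[i])
            lo = max(gene_cfg.p_bins[k], 1e-30)
            hi = gene_cfg.p_bins[k + 1]
            padj = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            up = rng.random() < gene_cfg.suppressed_frac
            sig = hi <= 0.05
            mag = abs(rng.normal(1.5, 0.5)) if sig else abs(rng.normal(0.1, 0.1))
            log2fc = mag if up else -mag
            gene_rows.append(
                (f"gene_{i:04d}", gene_cfg.chrom, gstart, gend, log2fc, padj)
            )
            if rng.random() < gene_cfg.feature_prob[k]:
                fseq = gene_cfg.feature_seq
                off = int(rng.integers(100, gene_cfg.radius - len(fseq) - 100))
                fstart = gend + off
                splice(gene_cfg.chrom, fstart, fseq)
                gene_feature_rows.append(
                    (gene_cfg.chrom, fstart, fstart + len(fseq), f"gene_{i:04d}")
                )
    de_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "Chromosome", "Start", "End", "log2fc", "padj"]
    )
    gene_features = pd.DataFrame(
        gene_feature_rows, columns=["Chromosome", "Start", "End", "Name"]
    )

    # 5. coverage: triangular bumps over ChIP peaks, plus boosts on
    # zero-gap-anchored repeats
    cov = {c: np.zeros(len(a), dtype=float) for c, a in seqs.items()}

    def add_triangle(chrom: str, center: int, halfwidth: int, height: float) -> None:
        track = cov[chrom]
        lo = max(center - halfwidth, 0)
        hi = min(center + halfwidth, len(track))
        x = np.arange(lo, hi)
        track[lo:hi] += height * np.maximum(
            0.0, 1.0 - np.abs(x - center) / halfwidth
        )

    cs = config.coverage
    for pk in chip.itertuples(index=False):
        add_triangle(
            pk.Chromosome, (pk.Start + pk.End) // 2, (pk.End - pk.Start) // 2,
            cs.peak_height,
        )
    for r in planted_tng.itertuples(index=False):
        if r.hh_offset is not None and r.hh_offset == 0:
            add_triangle(
                r.Chromosome, (r.Start + r.End) // 2, cs.boost_halfwidth,
                cs.zero_gap_boost,
            )

    return GenomeBundle(
        sequences={c: _decode(a) for c, a in seqs.items()},
        chip_peaks=chip,
        atac_peaks=atac,
        planted_hh=planted_hh,
        planted_tng=planted_tng,
        gene_features=gene_features,
        coverage=cov,
        de_table=de_table,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML config for the CLI


def config_from_yaml(path: str | Path) -> GenomeConfig:
    """Build a GenomeConfig from a YAML mapping mirroring the dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "pairs" in kwargs:
        kwargs["pairs"] = tuple(PairPlant(**p) for p in kwargs["pairs"])
    if "tngs" in kwargs:
        kwargs["tngs"] = tuple(TnGPlant(**t) for t in kwargs["tngs"])
    if "genes" in kwargs and kwargs["genes"] is not None:
        g = dict(kwargs["genes"])
        for key in ("p_bins", "bin_fractions", "feature_prob"):
            if key in g:
                g[key] = tuple(g[key])
        kwargs["genes"] = GenePlant(**g)
    if "coverage" in kwargs:
        kwargs["coverage"] = CoverageSpec(**kwargs["coverage"])
    return GenomeConfig(**kwargs)
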