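"""TnG-microsatellite detection and H-H/TnG topology analysis.

TnG repeats are tandem arrays of T{2-5}G units (forward reading, strand "+")
or of their reverse complement CA{2-5} (a CAn array on the positive strand,
recorded as strand "-").  Detection is grammar-based: maximal runs of units,
with a minimum array length and unit count, followed by exclusion of
low-complexity dinucleotide/homopolymer runs ((TG)x6-type and 12-mer
homopolymers) that the binder does not recognize.  Users with an external
PWM scan can import its hits from BED instead.

Each merged H-H site is then related to its nearest repeat by signed
border-to-border distance (positive = repeat downstream, 0 = overlap or
abutment) and a configuration call: the pairing is "aligned" when the
repeat's reading direction continues the proximal half-site — a "+" (TnG)
repeat upstream of the H-H, or a "-" (CAn) repeat downstream — and
"divergent" otherwise.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLUS_UNIT = re.compile(r"(?:T{2,5}G)+")
MINUS_UNIT = re.compile(r"(?:CA{2,5})+")

#: Low-complexity runs removed from candidate repeats: six tandem copies of
#: each dinucleotide and 12-mer homopolymers.
EXCLUDED_RUNS = [d * 6 for d in ("TG", "AC", "TA", "TC", "AG", "CG")] + [
    b * 12 for b in "TGCA"
]

REPEAT_COLUMNS = ["Chromosome", "Start", "End", "Name", "Score", "Strand", "n_units"]


def _excluded(seq: str) -> bool:
    return any(run in seq for run in EXCLUDED_RUNS)


def detect_tng_repeats(
    sequence: str,
    min_length: int = 12,
    min_units: int = 3,
    chrom: str = ".",
    offset: int = 0,
) -> pd.DataFrame:
    """Maximal TnG/CAn arrays in a concrete sequence, as BED6+ rows.

    ``offset`` shifts coordinates (for scanning interval sequences in
    genome coordinates).  Mixed-unit arrays (e.g. TTGTTTG) count as one
    repeat.  Arrays shorter than ``min_length`` bp or with fewer than
    ``min_units`` units are discarded, then the exclusion runs are applied.
    """
    seq = sequence.upper()
    rows = []
    for strand, rx, unit_end in (("+", PLUS_UNIT, "G"), ("-", MINUS_UNIT, "C")):
        for m in rx.finditer(seq):
            s = m.group()
            n_units = s.count(unit_end)
            if len(s) < min_length or n_units < min_units or _excluded(s):
                continue
            rows.append(
                (
                    chrom,
                    offset + m.start(),
                    offset + m.end(),
                    f"TnG:{s[:12]}{'...' if len(s) > 12 else ''}",
                    len(s),
                    strand,
                    n_units,
                )
            )
    return (
        pd.DataFrame(rows, columns=REPEAT_COLUMNS)
        .sort_values(["Chromosome", "Start"], kind="stable")
        .reset_index(drop=True)
    )


def apply_exclusion_filters(
    regions: pd.DataFrame, genome: Mapping[str, str]
) -> pd.DataFrame:
    """Drop imported repeat regions (e.g. an external PWM scan's BED) whose
    sequence contains any of the low-complexity exclusion runs."""
    keep = []
    for r in regions.itertuples(index=False):
        seq = str(genome[r.Chromosome][r.Start : r.End]).upper()
        keep.append(not _excluded(seq))
    return regions[np.array(keep, dtype=bool)].reset_index(drop=True)


def detect_tng_in_intervals(
    genome: Mapping[str, str],
    intervals: pd.DataFrame,
    min_length: int = 12,
    min_units: int = 3,
) -> pd.DataFrame:
    """Run :func:`detect_tng_repeats` over each interval's sequence."""
    frames = []
    for iv in intervals.itertuples(index=False):
        contig = genome.get(iv.Chromosome)
        if contig is None or iv.End > len(contig):
            logger.warning(
                "interval %s:%d-%d outside contig; skipped",
                iv.Chromosome, iv.Start, iv.End,
            )
            continue
        frames.append(
            detect_tng_repeats(
                str(contig[iv.Start : iv.End]),
                min_length, min_units, iv.Chromosome, iv.Start,
            )
        )
    if not frames:
        return pd.DataFrame(columns=REPEAT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def detect_tng_genome(
    genome: Mapping[str, str], min_length: int = 12, min_units: int = 3
) -> pd.DataFrame:
    frames = [
        detect_tng_repeats(str(genome[c]), min_length, min_units, c)
        for c in genome
    ]
    if not frames:
        return pd.DataFrame(columns=REPEAT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# signed distances and aligned/divergent topology


def _signed_distance_arrays(
    hh_start: int, hh_end: int, r_start: np.ndarray, r_end: np.ndarray
) -> np.ndarray:
    """Vectorized signed border distance from one H-H site to repeats."""
    down = r_start >= hh_end
    up = r_end <= hh_start
    d = np.zeros(len(r_start), dtype=int)
    d[down] = r_start[down] - hh_end
    d[up] = -(hh_start - r_end[up])
    return d


def _configuration(
    hh_start: int, hh_end: int, r_start: int, r_end: int, strand: str
) -> str:
    """Aligned iff a "+" repeat sits upstream or a "-" repeat downstream.

    For overlapping pairs the side is taken from the interval centers
    (repeat center left of the H-H center counts as upstream).
    """
    if r_end <= hh_start:
        upstream = True
    elif r_start >= hh_end:
        upstream = False
    else:
        upstream = (r_start + r_end) <= (hh_start + hh_end)
    aligned = (strand == "+" and upstream) or (strand == "-" and not upstream)
    return "aligned" if aligned else "divergent"


def _adjacency(distance: int, far_min: int) -> str:
    if distance == 0:
        return "zero_gap"
    if abs(distance) > far_min:
        return "far"
    return "intermediate"


def classify_topology(
    hh_sites: pd.DataFrame,
    repeats: pd.DataFrame,
    far_min: int = 1000,
) -> pd.DataFrame:
    """Nearest repeat and aligned/divergent call for each merged H-H site.

    Nearest is by absolute signed border distance; equidistant ties go to
    the repeat with the smaller start (flagged in the ``tie`` column).
    H-H sites on chromosomes without any repeat get a null record.
    """
    rows = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in repeats.groupby("Chromosome")}
    for hh in hh_sites.itertuples(index=False):
        reps = by_chrom.get(hh.Chromosome)
        if reps is None or len(reps) == 0:
            rows.append(
                (hh.Chromosome, hh.Start, hh.End,
                 np.nan, np.nan, None, np.nan, None, None, False)
            )
            continue
        d = _signed_distance_arrays(
            hh.Start, hh.End, reps["Start"].to_numpy(), reps["End"].to_numpy()
        )
        absd = np.abs(d)
        best = int(np.lexsort((reps["Start"].to_numpy(), absd))[0])
        tie = int((absd == absd[best]).sum()) > 1
        r = reps.iloc[best]
        rows.append(
            (
                hh.Chromosome, hh.Start, hh.End,
                int(r.Start), int(r.End), r.Strand, int(d[best]),
                _configuration(hh.Start, hh.End, int(r.Start), int(r.End), r.Strand),
                _adjacency(int(d[best]), far_min),
                tie,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Chromosome", "Start", "End",
            "repeat_start", "repeat_end", "repeat_strand",
            "signed_distance", "configuration", "adjacency", "tie",
        ],
    )


# ---------------------------------------------------------------------------
# coverage AUC and repeat stratification


def coverage_auc(
    coverage: Mapping[str, np.ndarray],
    chrom: str,
    center: int,
    halfwidth: int = 100,
) -> float:
    """Sum of per-base coverage over [center - halfwidth, center + halfwidth).

    Windows running off the contig are truncated with a warning.
    """
    track = coverage[chrom]
    lo, hi = center - halfwidth, center + halfwidth
    if lo < 0 or hi > len(track):
        logger.warning(
            "AUC window [%d, %d) truncated to contig %s bounds", lo, hi, chrom
        )
        lo, hi = max(lo, 0), min(hi, len(track))
    return float(np.sum(track[lo:hi]))


def repeat_hh_adjacency(
    repeats: pd.DataFrame,
    hh_sites: pd.DataFrame,
    far_min: int = 1000,
    require_aligned: bool = True,
) -> pd.DataFrame:
    """Per-repeat adjacency class relative to the H-H site set.

    ``zero_gap``: some H-H site overlaps/abuts the repeat (distance 0), in
    the aligned configuration when ``require_aligned``; ``far``: every H-H
    site is more than ``far_min`` bp away; ``intermediate`` otherwise
    (excluded from the two-class comparison downstream).
    """
    out = repeats.copy().reset_index(drop=True)
    classes = []
    by_chrom = {c: g for c, g in hh_sites.groupby("Chromosome")}
    for r in out.itertuples(index=False):
        sites = by_chrom.get(r.Chromosome)
        if sites is None or len(sites) == 0:
            classes.append("far")
            continue
        d = _signed_distance_arrays(
            r.Start, r.End, sites["Start"].to_numpy(), sites["End"].to_numpy()
        )
        # distances above are repeat->site; the site->repeat sign convention
        # just flips, leaving |d| and the zero class unchanged
        zero_idx = np.flatnonzero(d == 0)
        zero_ok = False
        for i in zero_idx:
            hh = sites.iloc[i]
            cfg = _configuration(hh.Start, hh.End, r.Start, r.End, r.Strand)
            if not require_aligned or cfg == "aligned":
                zero_ok = True
                break
        if zero_ok:
            classes.append("zero_gap")
        elif np.abs(d).min() > far_min:
            classes.append("far")
        else:
            classes.append("intermediate")
    out["adjacency"] = classes
    return out


def stratify_repeats(
    repeats: pd.DataFrame,
    hh_sites: pd.DataFrame,
    coverage: Mapping[str, np.ndarray],
    short_max: int = 20,
    long_min: int = 40,
    far_min: int = 1000,
    halfwidth: int = 100,
    log_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-repeat log2 coverage AUC stratified by length and H-H adjacency.

    Four strata: (short <= ``short_max`` bp, long >= ``long_min`` bp) x
    (zero_gap, far).  Repeats of intermediate length or intermediate H-H
    distance are excluded.  AUC is measured in a 2 x ``halfwidth`` window
    around the repeat center.
    """
    ann = repeat_hh_adjacency(repeats, hh_sites, far_min)
    ann["length"] = ann["End"] - ann["Start"]
    ann["length_class"] = np.where(
        ann["length"] <= short_max, "short",
        np.where(ann["length"] >= long_min, "long", "mid"),
    )
    ann = ann[
        ann["length_class"].isin(["short", "long"])
        & ann["adjacency"].isin(["zero_gap", "far"])
    ].copy()
    ann["auc"] = [
        coverage_auc(coverage, r.Chromosome, (r.Start + r.End) // 2, halfwidth)
        for r in ann.itertuples(index=False)
    ]
    ann["log2_auc"] = np.log2(ann["auc"] + log_pseudocount)
    return ann.reset_index(drop=True)


def foxp3_free_ocrs(
    atac_peaks: pd.DataFrame,
    chip_peaks: pd.DataFrame,
    coverage: Mapping[str, np.ndarray],
    min_dist: int = 10_000,
    halfwidth: int = 100,
) -> pd.DataFrame:
    """Open chromatin regions with no sign of focal protein occupancy.

    Keeps ATAC peaks at least ``min_dist`` bp from every ChIP peak whose
    center-window coverage AUC is below the minimum AUC observed across
    ChIP peaks.
    """
    if len(chip_peaks) == 0:
        return atac_peaks.copy()
    chip_auc = np.array(
        [
            coverage_auc(coverage, p.Chromosome, (p.Start + p.End) // 2, halfwidth)
            for p in chip_peaks.itertuples(index=False)
        ]
    )
    threshold = float(chip_auc.min())
    keep = []
    by_chrom = {c: g for c, g in chip_peaks.groupby("Chromosome")}
    for p in atac_peaks.itertuples(index=False):
        chip = by_chrom.get(p.Chromosome)
        if chip is not None and len(chip):
            d = np.abs(
                _signed_distance_arrays(
                    p.Start, p.End, chip["Start"].to_numpy(), chip["End"].to_numpy()
                )
            )
            if d.min() < min_dist:
                keep.append(False)
                continue
        auc = coverage_auc(coverage, p.Chromosome, (p.Start + p.End) // 2, halfwidth)
        keep.append(auc < threshold)
    return atac_peaks[np.array(keep, dtype=bool)].reset_index(drop=True)
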