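"""Genome-interval scanning for oriented motif pairs and enrichment tests.

Peak sequences are scanned on the positive strand only.  Within a single
pattern, matches are non-overlapping (the scan advances past each match);
overlaps between different patterns are allowed.  Foreground (ChIP/CNR
peaks) versus background (open chromatin regions) enrichment uses a
one-sided exact binomial test on occurrence counts with a
length-proportional success probability, and rates are reported per million
base pairs of total interval length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import ORIENTATIONS, PairPattern, build_pair_patterns
from .seqcore import pattern_to_regex

logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "Chromosome", "Start", "End", "Name", "Score", "Strand",
    "motif_a", "motif_b", "orientation", "gap_size", "matched",
]


def _interval_seq(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str | None:
    if chrom not in genome:
        return None
    contig = genome[chrom]
    if start < 0 or end > len(contig):
        return None
    return str(contig[start:end]).upper()


def scan_intervals(
    genome: Mapping[str, str],
    intervals: pd.DataFrame,
    patterns: Sequence[PairPattern],
) -> pd.DataFrame:
    """Scan interval sequences for each pattern; genome-absolute BED6+ rows.

    ``genome`` is any mapping of chromosome name to sequence (a dict or a
    ``pyfaidx.Fasta``).  Matches straddling an interval edge are not found;
    the scan sees only the per-interval sequence.  Strand is always "+".
    """
    regexes = [(p, pattern_to_regex(p.rendered)) for p in patterns]
    rows = []
    for iv in intervals.itertuples(index=False):
        seq = _interval_seq(genome, iv.Chromosome, iv.Start, iv.End)
        if seq is None:
            logger.warning(
                "interval %s:%d-%d outside contig; skipped",
                iv.Chromosome, iv.Start, iv.End,
            )
            continue
        for pat, rx in regexes:
            for m in rx.finditer(seq):
                rows.append(
                    (
                        iv.Chromosome,
                        iv.Start + m.start(),
                        iv.Start + m.end(),
                        pat.name,
                        0,
                        "+",
                        pat.motif_a,
                        pat.motif_b,
                        pat.orientation,
                        len(pat.gap),
                        m.group(),
                    )
                )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def total_length(intervals: pd.DataFrame) -> int:
    return int((intervals["End"] - intervals["Start"]).sum())


@dataclass(frozen=True)
class EnrichmentResult:
    """Foreground-vs-background occurrence enrichment for one pattern."""

    count_fg: int
    len_fg: int
    count_bg: int
    len_bg: int

    def __post_init__(self) -> None:
        if self.len_fg <= 0 or self.len_bg <= 0:
            raise ValueError("interval set lengths must be positive")

    @property
    def rate_fg(self) -> float:
        return self.count_fg * 1e6 / self.len_fg

    @property
    def rate_bg(self) -> float:
        return self.count_bg * 1e6 / self.len_bg

    @property
    def fold_change(self) -> float:
        """rate_fg / rate_bg, with a 0.5-count continuity correction on the
        background only when its count is zero."""
        bg = self.count_bg if self.count_bg > 0 else 0.5
        return (self.count_fg / self.len_fg) / (bg / self.len_bg)

    @property
    def p_value(self) -> float:
        """One-sided exact binomial P(X >= count_fg) with
        n = count_fg + count_bg and p0 = len_fg / (len_fg + len_bg)."""
        n = self.count_fg + self.count_bg
        if self.count_fg == 0:
            return 1.0
        p0 = self.len_fg / (self.len_fg + self.len_bg)
        return float(stats.binom.sf(self.count_fg - 1, n, p0))


def binomial_enrichment(
    count_fg: int, len_fg: int, count_bg: int, len_bg: int
) -> EnrichmentResult:
    return EnrichmentResult(count_fg, len_fg, count_bg, len_bg)


def enrichment_table(
    sites_fg: pd.DataFrame,
    sites_bg: pd.DataFrame,
    patterns: Sequence[PairPattern],
    len_fg: int,
    len_bg: int,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-pattern enrichment of foreground over background sites.

    Significance is a raw p < ``alpha`` threshold by default; optional
    Benjamini-Hochberg correction replaces p-values by FDR-adjusted ones
    before thresholding.
    """
    cf = sites_fg.groupby("Name").size() if len(sites_fg) else pd.Series(dtype=int)
    cb = sites_bg.groupby("Name").size() if len(sites_bg) else pd.Series(dtype=int)
    rows = []
    for p in patterns:
        r = EnrichmentResult(
            int(cf.get(p.name, 0)), len_fg, int(cb.get(p.name, 0)), len_bg
        )
        rows.append(
            (
                p.name, p.motif_a, p.motif_b, p.orientation,
                r.count_fg, r.count_bg, r.rate_fg, r.rate_bg,
                r.fold_change, r.p_value,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "pattern", "motif_a", "motif_b", "orientation",
            "count_fg", "count_bg", "rate_fg", "rate_bg",
            "fold_change", "p_value",
        ],
    )
    if bh_correct:
        out["p_adjusted"] = _bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def gap_size_sweep(
    genome: Mapping[str, str],
    intervals_fg: pd.DataFrame,
    intervals_bg: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
    gaps: Sequence[int] = range(1, 11),
) -> pd.DataFrame:
    """Per-Mb rates of (motif_a, motif_b, orientation) pairs at each gap size.

    The gap is rendered as a run of N wildcards, so any genomic spacer of
    that length counts.  Returns one row per pair x gap with foreground and
    background counts and per-Mb rates.
    """
    lf, lb = total_length(intervals_fg), total_length(intervals_bg)
    rows = []
    for a, b, orientation in pairs:
        for g in gaps:
            pat = PairPattern(a, b, orientation, "N" * g)
            fg = scan_intervals(genome, intervals_fg, [pat])
            bg = scan_intervals(genome, intervals_bg, [pat])
            rows.append(
                (
                    a, b, orientation, g,
                    len(fg), len(bg),
                    len(fg) * 1e6 / lf if lf else np.nan,
                    len(bg) * 1e6 / lb if lb else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_a", "motif_b", "orientation", "gap",
            "count_fg", "count_bg", "rate_fg", "rate_bg",
        ],
    )


def merge_hh_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting H-H motif sites into maximal intervals.

    Different patterns share similar structure and often match overlapping
    coordinates; merging avoids double-counting one physical site.  The
    constituent pattern names are retained comma-joined.
    """
    hh = sites[sites["orientation"] == "HH"] if "orientation" in sites else sites
    if len(hh) == 0:
        return pd.DataFrame(
            columns=["Chromosome", "Start", "End", "Name", "n_constituents"]
        )
    hh = hh.sort_values(["Chromosome", "Start", "End"], kind="stable")
    merged: list[list] = []
    for row in hh.itertuples(index=False):
        if (
            merged
            and merged[-1][0] == row.Chromosome
            and row.Start <= merged[-1][2]  # overlap or abut
        ):
            merged[-1][2] = max(merged[-1][2], row.End)
            merged[-1][3].append(row.Name)
        else:
            merged.append([row.Chromosome, row.Start, row.End, [row.Name]])
    return pd.DataFrame(
        [
            (c, s, e, ",".join(sorted(set(names))), len(names))
            for c, s, e, names in merged
        ],
        columns=["Chromosome", "Start", "End", "Name", "n_constituents"],
    )


def hh_count_matrix(sites: pd.DataFrame, motifs: Sequence[str]) -> pd.DataFrame:
    """10x10 matrix of raw H-H site counts by (motif_a, motif_b)."""
    hh = sites[sites["orientation"] == "HH"]
    mat = pd.DataFrame(0, index=list(motifs), columns=list(motifs))
    for (a, b), n in hh.groupby(["motif_a", "motif_b"]).size().items():
        mat.loc[a, b] = n
    return mat


def orientation_totals(sites: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {o: int((sites["orientation"] == o).sum()) for o in ORIENTATIONS}
    )


def scan_pair_library(
    genome: Mapping[str, str],
    intervals: pd.DataFrame,
    motifs: Sequence[str],
    gap_size: int = 4,
) -> pd.DataFrame:
    """Convenience: scan intervals for the full 400-pattern library with an
    N-wildcard gap of the given size."""
    patterns = build_pair_patterns(motifs, "N" * gap_size)
    return scan_intervals(genome, intervals, patterns)
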