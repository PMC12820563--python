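"""Degenerate "2N motif" discovery from site-1 count tables.

Each concrete 7-mer spawns C(7,2) = 21 degenerate patterns by replacing every
2-subset of positions with the wildcard N.  A 2N motif's count is the sum of
the counts of its 16 concrete instantiations, so total motif mass is exactly
21x total sequence mass.  Motifs are ranked by pull-down/input count ratio
and classified into:

* group 1 (G1): the concrete positions contain TGTTT or TGTTG — relaxed
  forkhead motifs (FKHM, TGTTTAC);
* group 2 (G2): the concrete positions contain a GCAT core whose flanking
  positions, where concrete, are T or C;
* other: everything else (e.g. GCGTG-core patterns, which look similar but
  are not bona fide forkhead-family sites).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .seqcore import matches

SITE_LEN = 7
N_PAIRS = list(combinations(range(SITE_LEN), 2))  # 21 position pairs


def enumerate_2n(seq7: str) -> list[str]:
    """The 21 2N motifs of a concrete 7-mer (two positions replaced by N)."""
    if len(seq7) != SITE_LEN:
        raise ValueError(f"need a 7-mer, got {seq7!r}")
    out = []
    for i, j in N_PAIRS:
        chars = list(seq7)
        chars[i] = chars[j] = "N"
        out.append("".join(chars))
    return out


def aggregate_2n_counts(counts: pd.Series) -> pd.Series:
    """Aggregate per-sequence counts into per-2N-motif counts.

    ``counts`` is indexed by concrete 7-mers.  For every distinct pattern
    (the N positions are part of the pattern's identity) the count is the
    sum over its 16 concrete instantiations present in the table.  Missing
    sequences contribute zero.
    """
    if counts.index.has_duplicates:
        raise ValueError("count table index has duplicate sequences")
    seq_arr = counts.index.to_numpy(dtype=object)
    chars = np.array([list(s) for s in seq_arr], dtype="U1")
    if chars.shape[1] != SITE_LEN:
        raise ValueError("count table must be indexed by 7-mers")
    pieces = []
    for i, j in N_PAIRS:
        masked = chars.copy()
        masked[:, i] = "N"
        masked[:, j] = "N"
        patterns = np.array(["".join(row) for row in masked], dtype=object)
        pieces.append(
            pd.Series(counts.to_numpy(), index=patterns).groupby(level=0).sum()
        )
    agg = pd.concat(pieces)
    agg.index.name = "motif"
    return agg.sort_index()


def classify_motif_group(pattern: str) -> str:
    """Classify a 2N motif as G1, G2 or other (concrete positions only).

    An N inside a would-be core breaks it; an N (or the 7-mer edge) at a
    GCAT flank position does not disqualify G2, but a concrete flank must be
    T or C.
    """
    if "TGTTT" in pattern or "TGTTG" in pattern:
        return "G1"
    for i in range(len(pattern) - 3):
        if pattern[i : i + 4] != "GCAT":
            continue
        left_ok = i == 0 or pattern[i - 1] in "TCN"
        right_ok = i + 4 == len(pattern) or pattern[i + 4] in "TCN"
        if left_ok and right_ok:
            return "G2"
    return "other"


def rank_2n_enrichment(
    pd_counts: pd.Series,
    input_counts: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank 2N motifs by pull-down/input aggregate-count ratio.

    Both inputs are per-sequence count tables; aggregation to the motif
    level happens here.  The pseudocount (raw counts) is added to the input
    aggregate.  Ties are broken lexicographically by pattern for
    determinism.  Output columns: group, count_pd, count_input, ratio, rank.
    """
    agg_pd = aggregate_2n_counts(pd_counts)
    agg_in = aggregate_2n_counts(input_counts)
    universe = agg_pd.index.union(agg_in.index)
    agg_pd = agg_pd.reindex(universe, fill_value=0)
    agg_in = agg_in.reindex(universe, fill_value=0)
    ratio = agg_pd / (agg_in + pseudocount)
    out = pd.DataFrame(
        {
            "group": [classify_motif_group(m) for m in universe],
            "count_pd": agg_pd,
            "count_input": agg_in,
            "ratio": ratio,
        },
        index=universe,
    )
    out.index.name = "motif"
    out = out.sort_index(kind="stable")
    out = out.sort_values("ratio", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_decile_coverage(
    enrichment: pd.Series, motifs: list[str], decile: float = 0.10
) -> float:
    """Fraction of the top-decile sequences matched by >= 1 of ``motifs``.

    ``enrichment`` is a per-sequence fold-enrichment series; the top
    ``decile`` of sequences by value is taken and each is tested against
    the given degenerate motifs.
    """
    n_top = max(1, int(round(len(enrichment) * decile)))
    top = enrichment.sort_values(ascending=False).index[:n_top]
    hit = sum(1 for s in top if any(matches(m, s) for m in motifs))
    return hit / n_top
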