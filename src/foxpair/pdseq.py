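"""Pull-down sequencing (PD-seq) read extraction and count tables.

The pull-down libraries are 80-bp degenerate oligos::

    NBS1 (27 nt) - site1 (7 nt, random) - gap (TCGA) - site2 (7 nt) - NBS2 (35 nt)

In the random-rcFKHM design site 2 is fixed to the reverse-complement
forkhead motif GTAAACA; in the random-random design both sites vary.  Reads
are anchored to the constant flanks, the variable region is extracted, and
per-unique-sequence count tables (raw and reads-per-million) are built for
the pull-down and input samples.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .io import iter_fastq, phred_scores
from .seqcore import iter_kmers, normalize

logger = logging.getLogger(__name__)

#: Synthetic stand-in non-binding flanks; real flank sequences can be supplied
#: through DegenerateTemplate.  Screened to contain no G1/G2 motif cores, no
#: rcFKHM, no TCGA and no TnG/CAn unit runs, so they contribute no spurious
#: motif matches in shifted windows.
DEFAULT_NBS1 = "AAGCCCAATAAACCACTCTGACTGGCC"
DEFAULT_NBS2 = "GAATAGGGATATAGGCAACGACATGTGCGGCGACC"

#: Canonical forkhead motif and its reverse complement.
FKHM = "TGTTTAC"
RC_FKHM = "GTAAACA"

ANCHOR_LEN = 10


@dataclass(frozen=True)
class DegenerateTemplate:
    """The fixed oligo scaffold locating the variable sites inside a read.

    ``site2 = None`` selects the random-random design (variable 7-mer in
    site 2); a concrete string fixes site 2 (random-rcFKHM design).
    """

    nbs1: str = DEFAULT_NBS1
    site1_len: int = 7
    gap: str = "TCGA"
    site2: str | None = RC_FKHM
    site2_len: int = 7
    nbs2: str = DEFAULT_NBS2

    def __post_init__(self) -> None:
        object.__setattr__(self, "nbs1", normalize(self.nbs1))
        object.__setattr__(self, "nbs2", normalize(self.nbs2))
        object.__setattr__(self, "gap", normalize(self.gap))
        if self.site2 is not None:
            object.__setattr__(self, "site2", normalize(self.site2))
            if len(self.site2) != self.site2_len:
                raise ValueError("site2 length disagrees with site2_len")
        if len(self.gap) != 4:
            raise ValueError("gap must be exactly 4 nt")

    @property
    def insert_len(self) -> int:
        """Length of site1 + gap + site2 (18 for the default design)."""
        return self.site1_len + len(self.gap) + self.site2_len

    @property
    def total_length(self) -> int:
        return len(self.nbs1) + self.insert_len + len(self.nbs2)

    @property
    def variable_len(self) -> int:
        """Length of the extracted variable sequence: 7 when site 2 is
        fixed, the full 18-nt insert when both sites vary."""
        return self.site1_len if self.site2 is not None else self.insert_len

    def assemble(self, site1: str, site2: str | None = None) -> str:
        """Render the full oligo for given variable site(s)."""
        s2 = self.site2 if self.site2 is not None else site2
        if s2 is None:
            raise ValueError("random-random template needs an explicit site2")
        return self.nbs1 + site1 + self.gap + s2 + self.nbs2

    def variable_of(self, site1: str, site2: str | None = None) -> str:
        if self.site2 is not None:
            return site1
        if site2 is None:
            raise ValueError("random-random template needs an explicit site2")
        return site1 + self.gap + site2


#: Template of the random-random library: both sites degenerate.
def random_random_template(**kw) -> DegenerateTemplate:
    kw.setdefault("site2", None)
    return DegenerateTemplate(**kw)


@dataclass
class ExtractionStats:
    total: int = 0
    kept: int = 0
    rejected: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejected[reason] += 1


def extract_variable_region(
    seq: str,
    qual: str | None,
    template: DegenerateTemplate,
    min_phred: int = 20,
) -> str | None:
    """Extract the variable sequence of one read, or ``None`` on rejection.

    The template is located by exact match to 10-nt anchors (the tail of
    NBS1 and the head of NBS2) at the expected spacing, so leading adapter
    remnants are tolerated.  A read is rejected when the anchors or the
    fixed gap/site-2 bases do not match exactly, when any variable position
    is 'N', or when any variable-position Phred score falls below
    ``min_phred``.  Reads without a quality string skip the Phred filter.
    """
    seq = seq.upper()
    anchor1 = template.nbs1[-ANCHOR_LEN:]
    anchor2 = template.nbs2[:ANCHOR_LEN]
    i = seq.find(anchor1)
    if i < 0:
        return None
    var_start = i + ANCHOR_LEN
    var_end = var_start + template.insert_len
    if seq[var_end : var_end + ANCHOR_LEN] != anchor2:
        return None
    insert = seq[var_start:var_end]
    site1 = insert[: template.site1_len]
    gap = insert[template.site1_len : template.site1_len + len(template.gap)]
    site2 = insert[template.site1_len + len(template.gap) :]
    if gap != template.gap:
        return None
    if template.site2 is not None and site2 != template.site2:
        return None
    variable = site1 if template.site2 is not None else insert
    if "N" in variable:
        return None
    if qual is not None:
        scores = phred_scores(qual)
        if template.site2 is not None:
            var_positions = range(var_start, var_start + template.site1_len)
        else:
            var_positions = range(var_start, var_end)
        if any(scores[p] < min_phred for p in var_positions):
            return None
    if any(c not in "ACGT" for c in variable):
        return None
    return variable


def extract_reads(
    reads: Iterable[tuple[str, str, str | None]],
    template: DegenerateTemplate,
    min_phred: int = 20,
) -> tuple[Counter, ExtractionStats]:
    """Run :func:`extract_variable_region` over reads, counting rejections."""
    counts: Counter = Counter()
    stats = ExtractionStats()
    warned_noqual = False
    for _, seq, qual in reads:
        stats.total += 1
        if qual is None and not warned_noqual:
            logger.warning("reads lack quality strings; Phred filter skipped")
            warned_noqual = True
        var = extract_variable_region(seq, qual, template, min_phred)
        if var is None:
            stats.reject("structure_or_quality")
        else:
            counts[var] += 1
            stats.kept += 1
    return counts, stats


def extract_fastq(
    path, template: DegenerateTemplate, min_phred: int = 20
) -> tuple[Counter, ExtractionStats]:
    return extract_reads(iter_fastq(path), template, min_phred)


def build_count_table(
    counts: Mapping[str, int] | Iterable[str],
    template: DegenerateTemplate,
    pad: bool | None = None,
) -> pd.DataFrame:
    """Build a per-unique-variable-sequence count/RPM table.

    For the random-rcFKHM design (``pad`` defaults to True there) the row
    space is the full set of 4**7 = 16,384 site-1 sequences, zero-filled.
    RPM = count * 1e6 / total kept reads of the sample.
    """
    if not isinstance(counts, Mapping):
        counts = Counter(counts)
    if pad is None:
        pad = template.site2 is not None
    if len(counts) == 0:
        logger.warning("building count table from zero accepted reads")
    if pad:
        index = pd.Index(list(iter_kmers(template.site1_len)), name="sequence")
        table = pd.DataFrame({"count": 0}, index=index)
        for seq, c in counts.items():
            table.loc[seq, "count"] = c
    else:
        index = pd.Index(sorted(counts), name="sequence")
        table = pd.DataFrame(
            {"count": [counts[s] for s in index]}, index=index
        )
    total = int(table["count"].sum())
    table["rpm"] = table["count"] * 1e6 / total if total else 0.0
    return table


def combine_replicates(*tables: pd.DataFrame) -> pd.DataFrame:
    """Sum raw counts across replicate tables, then recompute RPM."""
    combined = tables[0][["count"]].copy()
    for t in tables[1:]:
        combined = combined.add(t[["count"]], fill_value=0)
    combined["count"] = combined["count"].astype(int)
    total = int(combined["count"].sum())
    combined["rpm"] = combined["count"] * 1e6 / total if total else 0.0
    combined.index.name = "sequence"
    return combined


def fold_enrichment(
    pd_table: pd.DataFrame,
    input_table: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-sequence fold enrichment RPM(PD) / (RPM(input) + pseudocount).

    Rows are sorted by descending enrichment, ties broken lexicographically
    by sequence.  The pseudocount (RPM units) keeps input-dropout rows
    finite; 0 is allowed and yields +inf there.
    """
    idx = pd_table.index.union(input_table.index)
    rpm_pd = pd_table["rpm"].reindex(idx, fill_value=0.0)
    rpm_in = input_table["rpm"].reindex(idx, fill_value=0.0)
    with np.errstate(divide="ignore"):
        fe = rpm_pd / (rpm_in + pseudocount)
    out = pd.DataFrame(
        {
            "count_pd": pd_table["count"].reindex(idx, fill_value=0),
            "rpm_pd": rpm_pd,
            "count_input": input_table["count"].reindex(idx, fill_value=0),
            "rpm_input": rpm_in,
            "fold_enrichment": fe,
        }
    )
    out.index.name = "sequence"
    # stable two-key sort: lexicographic ascending, then enrichment descending
    out = out.sort_index(kind="stable")
    return out.sort_values("fold_enrichment", ascending=False, kind="stable")
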