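"""Oriented motif-pair analysis of the random-random pull-down library.

Ten 7-nt motifs give 100 ordered combinations; each is rendered in the four
relative orientations of two half-sites (head = forward reading, tail =
reverse complement), yielding 400 scan patterns of length 18 with the fixed
TCGA spacer:

* H-H:  A + gap + revcomp(B)   (heads pointing at each other)
* H-T:  A + gap + B
* T-H:  revcomp(A) + gap + revcomp(B)
* T-T:  revcomp(A) + gap + B

Because the protein's register on the random-random oligo is not fixed,
every read is expanded into five windows shifted by 0, +/-1 and +/-2 bp over
the reconstructed oligo; a read supports a pattern when any window matches.
Raw pattern counts are then normalized by each pattern's baseline likelihood
under random variable bases at those five offsets, which corrects for the
bias the fixed spacer and flanks introduce during shifting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pdseq import DegenerateTemplate
from .seqcore import IUPAC_SETS, normalize, reverse_complement

logger = logging.getLogger(__name__)

ORIENTATIONS = ("HH", "HT", "TH", "TT")
DEFAULT_OFFSETS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class PairPattern:
    """An oriented pair of 7-nt motifs with a fixed spacer."""

    motif_a: str
    motif_b: str
    orientation: str
    gap: str = "TCGA"

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if len(self.motif_a) != 7 or len(self.motif_b) != 7:
            raise ValueError("pair motifs must be 7-mers")

    @property
    def rendered(self) -> str:
        """The concatenated scan pattern of length 14 + len(gap)."""
        a, b, gap = self.motif_a, self.motif_b, self.gap
        if self.orientation == "HH":
            return a + gap + reverse_complement(b)
        if self.orientation == "HT":
            return a + gap + b
        if self.orientation == "TH":
            return reverse_complement(a) + gap + reverse_complement(b)
        return reverse_complement(a) + gap + b

    @property
    def name(self) -> str:
        g = self.gap if set(self.gap) != {"N"} else f"n{len(self.gap)}"
        return f"{self.motif_a}_{self.motif_b}_{self.orientation}_{g}"


def build_pair_patterns(
    motifs: Sequence[str], gap: str = "TCGA"
) -> list[PairPattern]:
    """All ordered pairs x 4 orientations (10 motifs -> 400 patterns).

    Patterns whose rendered scan strings coincide (possible for palindromic
    or mutually reverse-complementary motifs) are kept — they are distinct
    pattern identities — but flagged via :func:`duplicate_renders`.
    """
    motifs = [normalize(m) for m in motifs]
    return [
        PairPattern(a, b, o, gap)
        for a in motifs
        for b in motifs
        for o in ORIENTATIONS
    ]


def duplicate_renders(patterns: Iterable[PairPattern]) -> dict[str, list[PairPattern]]:
    """Rendered strings shared by more than one pattern identity."""
    by_render: dict[str, list[PairPattern]] = {}
    for p in patterns:
        by_render.setdefault(p.rendered, []).append(p)
    return {r: ps for r, ps in by_render.items() if len(ps) > 1}


def shifted_windows(
    variable: str,
    template: DegenerateTemplate,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> list[str]:
    """The shifted variants of a read's variable insert.

    The full oligo is reconstructed from the template flanks and windows of
    insert length are cut at each offset; offset 0 reproduces the input.
    """
    if len(variable) != template.insert_len:
        raise ValueError(
            f"variable region must be {template.insert_len} nt, got {len(variable)}"
        )
    full = template.nbs1 + variable + template.nbs2
    left = len(template.nbs1)
    return [full[left + d : left + d + len(variable)] for d in offsets]


# ---------------------------------------------------------------------------
# fast matching: degenerate patterns expanded to a concrete-window dictionary

_BASE_INDEX = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


def encode_seq(s: str) -> np.ndarray:
    """Encode a concrete DNA string as uint8 base indices (A=0..T=3)."""
    arr = _BASE_INDEX[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-ACGT character in {s!r}")
    return arr


def pack_windows(arr: np.ndarray) -> np.ndarray:
    """Pack an (n, k) uint8 base-index array into base-4 int64 keys."""
    k = arr.shape[-1]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return arr.astype(np.int64) @ powers


class PairMatcher:
    """Any-shift matcher for a fixed pattern list over one template.

    Every degenerate pattern is expanded to its concrete window strings
    (product over per-position IUPAC sets), keyed in one dictionary, so
    matching a read costs five lookups regardless of pattern count.
    """

    def __init__(
        self,
        patterns: Sequence[PairPattern],
        template: DegenerateTemplate,
        offsets: Sequence[int] = DEFAULT_OFFSETS,
        max_expansion: int = 4**8,
    ) -> None:
        self.patterns = list(patterns)
        self.template = template
        self.offsets = tuple(offsets)
        self._lookup: dict[str, list[int]] = {}
        for idx, pat in enumerate(self.patterns):
            rendered = pat.rendered
            sets = [sorted(IUPAC_SETS[c]) for c in rendered]
            n_concrete = int(np.prod([len(s) for s in sets]))
            if n_concrete > max_expansion:
                raise ValueError(
                    f"pattern {rendered} expands to {n_concrete} concrete "
                    f"windows (> {max_expansion})"
                )
            for combo in product(*sets):
                self._lookup.setdefault("".join(combo), []).append(idx)

    def match(self, variable: str) -> set[int]:
        """Indices of patterns matched by any shifted window of a read."""
        hit: set[int] = set()
        for w in shifted_windows(variable, self.template, self.offsets):
            ids = self._lookup.get(w)
            if ids:
                hit.update(ids)
        return hit

    def encoded_lookup(self) -> tuple[np.ndarray, list[list[int]]]:
        """(sorted int64 window keys, aligned pattern-index lists) for
        vectorized membership tests via ``np.searchsorted``."""
        keys = sorted(self._lookup)
        packed = pack_windows(
            np.stack([encode_seq(k) for k in keys]) if keys else
            np.empty((0, 0), dtype=np.uint8)
        )
        order = np.argsort(packed)
        return packed[order], [self._lookup[keys[i]] for i in order]


def count_pair_matches(
    seq_counts: Mapping[str, int] | Iterable[str],
    matcher: PairMatcher,
    unique_sequences: bool = False,
) -> np.ndarray:
    """Per-pattern supporting-read counts under any-shift semantics.

    A read contributes at most once to each pattern it supports but may
    support several distinct patterns.  ``seq_counts`` maps unique variable
    sequences to read multiplicities; with ``unique_sequences=True`` each
    unique sequence counts once instead.
    """
    if not isinstance(seq_counts, Mapping):
        counter: dict[str, int] = {}
        for s in seq_counts:
            counter[s] = counter.get(s, 0) + 1
        seq_counts = counter
    counts = np.zeros(len(matcher.patterns), dtype=np.int64)
    for seq, mult in seq_counts.items():
        w = 1 if unique_sequences else mult
        for idx in matcher.match(seq):
            counts[idx] += w
    return counts


# ---------------------------------------------------------------------------
# baseline correction

def _template_symbols(template: DegenerateTemplate) -> list[str | None]:
    """Per-position fixed base (or None where the oligo is random)."""
    sym: list[str | None] = list(template.nbs1)
    sym += [None] * template.site1_len
    sym += list(template.gap)
    if template.site2 is not None:
        sym += list(template.site2)
    else:
        sym += [None] * template.site2_len
    sym += list(template.nbs2)
    return sym


def baseline_probability(
    pattern: PairPattern | str,
    template: DegenerateTemplate,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> tuple[float, list[float]]:
    """Expected number of matching offsets for a pattern under random bases.

    Per offset, P(match) is the product over window positions of 1 (fixed
    template base inside the pattern's set), 0 (fixed base outside it) or
    |set|/4 (random position).  The baseline is the sum over offsets — the
    expected number of matching windows, which for these patterns is an
    excellent proxy for P(any window matches) because co-matching offsets
    are vanishingly rare.  A baseline of 0 means the pattern is
    incompatible with the fixed spacer/flanks at every offset and cannot be
    normalized.
    """
    rendered = pattern.rendered if isinstance(pattern, PairPattern) else normalize(pattern)
    sym = _template_symbols(template)
    left = len(template.nbs1)
    per_offset = []
    for d in offsets:
        p = 1.0
        for j, ch in enumerate(rendered):
            allowed = IUPAC_SETS[ch]
            fixed = sym[left + d + j]
            if fixed is None:
                p *= len(allowed) / 4.0
            elif fixed not in allowed:
                p = 0.0
                break
        per_offset.append(p)
    return float(sum(per_offset)), per_offset


def pair_count_table(
    patterns: Sequence[PairPattern],
    counts: np.ndarray,
    template: DegenerateTemplate,
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Per-pattern table of raw counts, baselines and normalized values."""
    baselines = np.array(
        [baseline_probability(p, template, offsets)[0] for p in patterns]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(baselines > 0, counts / baselines, np.nan)
    n_bad = int((baselines == 0).sum())
    if n_bad:
        logger.warning("%d patterns are non-normalizable (baseline 0)", n_bad)
    return pd.DataFrame(
        {
            "motif_a": [p.motif_a for p in patterns],
            "motif_b": [p.motif_b for p in patterns],
            "orientation": [p.orientation for p in patterns],
            "raw": counts,
            "baseline": baselines,
            "normalized": normalized,
        }
    )


def orientation_matrix(
    table: pd.DataFrame, scale_to: float = 100.0
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.Series]:
    """Pivot the per-pattern table into per-orientation 10x10 matrices.

    Returns ``(normalized, scaled, totals)``: the baseline-normalized
    matrices, the same matrices jointly rescaled so the global maximum is
    ``scale_to`` (a single scale across all four orientations, for
    comparable display), and per-orientation totals of normalized values
    (NaN entries from non-normalizable patterns are excluded).
    """
    normalized: dict[str, pd.DataFrame] = {}
    for o in ORIENTATIONS:
        sub = table[table["orientation"] == o]
        normalized[o] = sub.pivot(
            index="motif_a", columns="motif_b", values="normalized"
        )
    global_max = max(
        (np.nanmax(m.to_numpy()) for m in normalized.values() if m.size),
        default=0.0,
    )
    factor = scale_to / global_max if global_max > 0 else 0.0
    scaled = {o: m * factor for o, m in normalized.items()}
    totals = pd.Series(
        {o: float(np.nansum(normalized[o].to_numpy())) for o in ORIENTATIONS},
        name="normalized_total",
    )
    return normalized, scaled, totals
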