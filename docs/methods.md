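# Methods

This note documents the models, conventions and numerical choices behind
`foxpair`, and what the synthetic-data generators do and do not emulate.

## Coordinates, alphabets, scanning

All intervals are 0-based half-open (BED convention); all external
interval files are BED, so no conversion ever happens internally.  DNA
strings use the full IUPAC alphabet; lowercase (soft-masked FASTA) is
uppercased on ingestion and unknown characters are rejected.
Reverse-complementation maps degenerate codes correctly (K↔M, Y↔R, N↔N)
and is an involution.

Scanning a degenerate pattern over a sequence is greedy and
non-overlapping *within* a pattern: after a match at `i` the scan resumes
at `i + len(pattern)`.  This prevents inflated counts from sliding matches
of the same pattern over repetitive sequence, while matches of *different*
patterns may overlap freely (the per-pattern scans are independent).  An
`N` in the scanned sequence matches nothing; `N` in a pattern matches any
base.

Signed border-to-border distance between two intervals is positive when
the second interval lies downstream (`b.start − a.end`), negative when
upstream, and 0 when they overlap **or abut** — abutting half-open
intervals share no base but represent a 0-nt gap, which is the relevant
category for H-H/TnG adjacency.  The relation is antisymmetric for
disjoint intervals.

## Pull-down library extraction

The degenerate oligo is `NBS1 (27 nt) – site1 (7 nt) – TCGA – site2 (7 nt)
– NBS2 (35 nt)`, 80 bp in total; site 2 is either fixed to the
reverse-complement forkhead motif `GTAAACA` (random-rcFKHM design) or
variable (random-random design).  The flank sequences shipped as defaults
are *synthetic stand-ins*, screened so they contain no group-1/group-2
motif cores, no rcFKHM, no `TCGA` and no TnG/CAn unit runs; any real flank
sequences can be supplied through `DegenerateTemplate`.

Reads are located by exact match to 10-nt anchors (the tail of NBS1 and
the head of NBS2) at the expected spacing, so adapter remnants before the
template are harmless and extraction is position-independent.  No
mismatches are allowed in the anchors or in the fixed gap/site-2 bases.  A
read is rejected when any **variable** position is `N` or has Phred < 20;
the filter is applied per base (the stricter reading of a quality cutoff
"in the variable regions"), and FASTA input skips it with a logged
warning.  Replicates are combined by summing raw counts before RPM
renormalization.  For the random-rcFKHM design the count table is padded
to all 4⁷ = 16,384 site-1 sequences.  Per-sequence fold enrichment is
RPM(PD)/(RPM(input) + pseudocount) with a default pseudocount of 0.5 RPM
(configurable; 0 gives +inf for input dropouts), ties broken
lexicographically for determinism.

## 2N motif discovery

Every concrete 7-mer yields C(7,2) = 21 patterns with two positions
replaced by `N`; a pattern's N positions are part of its identity, so the
full motif universe is 21 × 4⁵ = 21,504 distinct patterns.  A motif's
count is the sum over its 16 instantiations, giving the exact conservation
law Σ motif counts = 21 × Σ sequence counts, which the tests assert
exactly.  Ranking uses the PD/input aggregate-count ratio with a default
pseudocount of 1 raw count on the input aggregate; ties break
lexicographically.

Group classification uses only the concrete positions: group 1 requires a
visible `TGTTT` or `TGTTG` substring; group 2 requires a visible `GCAT`
core whose flanking positions, *where concrete*, are T or C (an `N` flank
or the 7-mer edge does not disqualify).  A pattern whose potential core
spans an `N` is "other".  Group 1 takes precedence when both rules could
apply.

## Pair orientation and the shift baseline

Ten reference motifs give 100 ordered combinations, each rendered in four
orientations with the fixed `TCGA` spacer (head = forward reading, tail =
reverse complement): HH = `A·gap·rc(B)`, HT = `A·gap·B`, TH =
`rc(A)·gap·rc(B)`, TT = `rc(A)·gap·B` — 400 patterns of length 18.
Because the binder's register on the random-random oligo is not fixed,
each read is expanded into five windows at offsets 0, ±1, ±2 over the
oligo reconstructed from the template flanks; a read supports a pattern
when *any* window matches (it contributes once per pattern, but may
support several patterns).  Matching expands every pattern to its concrete
windows in one dictionary, so cost is five lookups per read independent of
pattern count.

The fixed spacer and flanks bias which patterns can match at shifted
offsets.  The baseline for each pattern is the **expected number of
matching offsets** under uniform random variable bases: per offset the
product over window positions of 1 (fixed base in the pattern's set), 0
(fixed base outside it) or |set|/4 (random position), summed over the five
offsets.  This equals P(≥1 matching offset) up to co-match terms that are
O(p²) for these patterns and is exactly computable without 4¹⁴
enumeration; the Monte-Carlo agreement is asserted at 3σ with 10⁶ draws.
A baseline of 0 (pattern incompatible with the spacer at every offset) is
reported as non-normalizable and excluded with a warning.  Normalized
values are count/baseline; for display the four orientation matrices are
rescaled **jointly** so the global maximum is 100, keeping orientations
comparable.  Reads are tabulated as unique sequences with multiplicities;
counting uses multiplicities by default, with a unique-sequence mode
available since published figures do not always state which was used.

## Genomic scanning and enrichment

Peak sequences are extracted per interval and scanned on the positive
strand only; matches straddling a peak edge are not found.  Analyzing the
negative strand would map HT↔TH and transpose the HH/TT matrices — an
exact identity the tests verify by scanning reverse-complemented contigs.

Foreground (ChIP/CNR peaks) vs background (open chromatin) enrichment
conditions on the total occurrence count: with `n = count_fg + count_bg`
and length-proportional success probability `p0 = len_fg/(len_fg+len_bg)`,
the one-sided exact binomial p-value is P(X ≥ count_fg).  An alternative
parameterization (foreground count against an independently fixed trial
count) exists; the conditional form was chosen because it needs no rate
assumption and is oracle-tested against direct pmf summation for all
n ≤ 20.  Rates are occurrences × 10⁶ / total interval length.  Fold change
is rate_fg/rate_bg with a 0.5-count continuity correction applied to the
background only when its count is 0.  Significance is raw p < 0.05 by
default — no multiple-testing correction, matching common practice for
this screen — with an optional Benjamini–Hochberg flag.  Gap sweeps render
the spacer as `N^g` for g = 1..10 so any genomic spacer of that length
counts.  Overlapping or abutting H-H sites (different patterns share
structure) are merged into maximal intervals before topology analysis,
retaining constituent pattern names.

## TnG repeats and topology

Detection is grammar-based: maximal tandem runs of `T{2,5}G` units
(strand "+") or `CA{2,5}` units (the reverse-complement reading on the
positive strand, recorded as strand "−"), with mixed unit sizes allowed
within one array.  Arrays shorter than 12 bp or with fewer than 3 units
are discarded (both configurable; a detectable array needs a few units,
and 12 bp = 3 × minimal unit).  Candidate regions containing six tandem
copies of any dinucleotide (`TGTGTGTGTGTG`, `ACAC…`, `TATA…`, `TCTC…`,
`AGAG…`, `CGCG…`) or a 12-mer homopolymer are excluded as low-complexity
sequence the binder does not recognize; the same filters are available for
repeat regions imported from an external PWM scan via BED.  Detection on a
reverse-complemented sequence yields exactly mirrored intervals with
flipped strands.

Each merged H-H site is assigned its nearest repeat by absolute signed
border distance (ties go to the smaller start and are flagged).  The
configuration is **aligned** when the repeat's reading direction continues
the proximal half-site — a "+" (TnG) repeat upstream of the H-H or a "−"
(CAn) repeat downstream — and **divergent** otherwise; for overlapping
pairs the side is taken from interval centers.  Adjacency classes are
0-nt gap, far (>1 kb) and intermediate; the two-class coverage comparison
uses only 0-gap (aligned) and far repeats, excluding intermediates, in the
two length classes ≤20 bp and ≥40 bp.  Coverage occupancy is the summed
per-base signal in a 200-bp window around the repeat center (log2 with a
pseudocount of 1), truncated with a warning at contig edges.  Binder-free
open chromatin is defined as ATAC peaks ≥10 kb from every ChIP peak whose
center-window AUC is below the minimum observed across ChIP peaks.

## Gene association

Distance is measured from the gene body (the annotation interval), not the
TSS, and windows expand the body symmetrically, clipped at zero.  Density
is overlapping feature **bp** per Mb of window (features merged first, so
density is invariant under splitting a feature into adjacent pieces),
averaged within the significant (adjusted p < 0.05) and non-significant
groups.  The fraction-with-feature statistic uses half-open overlap of the
2-kb expansion and default adjusted-p bins [0, 1e-10), [1e-10, 1e-5),
[1e-5, 0.05), [0.05, 1] — the published bin edges are not stated, so the
bins are configurable — split by log2-fold-change sign.

## Synthetic data: what it emulates, and what it does not

The pull-down generator draws an input pool uniformly over the variable
positions and then redraws the pull-down sample from that pool with
replacement, with per-molecule weight `noise_floor + Σ matched-motif
weights` — a single selection round.  Binder modes: `dimeric_pair`
(weights on oriented pairs, pattern weight = orientation weight ×
geometric mean of the two motif weights, any-shift matching),
`monomeric_site2` (weight from the site-2 half-site only, emulating a
paralog that engages the rcFKHM but gains nothing from site 1), and
`uniform`.  Qualities are constant Q30.  Not emulated: sequencing errors,
PCR duplicates, paired-end merging artifacts, multi-round selection, and
binding cooperativity beyond the additive weight model — so passing
recovery tests demonstrate the *analysis* is correct and well-powered at
these effect sizes, not that real libraries are this clean.

The genome generator produces i.i.d. background bases (uniform by default,
GC configurable down to mammalian ~0.42), places non-overlapping peaks,
and splices planted features inside them: oriented pairs with chosen gap
(degenerate positions instantiated at random), TnG arrays of chosen unit
and length, optionally anchored at a signed offset to a concrete H-H site
(the aligned side is used, unless the offset sign forces the divergent
side).  Standalone repeats are kept ≥1.5 kb from every H-H site so the
far stratum is unambiguous, and the bases immediately flanking every
planted array are pinned to non-extending values so random neighbours
cannot lengthen the detected repeat.  The background is scrubbed of
incidental TnG arrays and of the configured pair patterns (gaps 1–10)
before planting, so recovery is exact; scrubbing can be disabled for null
experiments.  Coverage is piecewise-triangular over ChIP peaks with an
extra boost at zero-gap-anchored repeats.  DE genes sit on a dedicated
chromosome on a 12-kb grid (so 2-kb proximity never leaks between
neighbours), with adjusted p drawn log-uniformly inside each configured
bin and a per-bin probability of planting a feature within 2 kb.  Not
emulated: chromatin context, mappability, peak-width variation, real
coverage noise, and correlated gene structure.

Simulation sizes throughout the tests and the acceptance script (10⁵–10⁶
reads, 0.1–0.3-Mb genomes, tens of planted features) were chosen as the
smallest scales at which the planted effects are unambiguous under the
configured effect sizes; all generators are deterministic given seed and
config, byte-identically on disk.

## Known limitations

* TnG detection is unit-grammar based; a position-weight-matrix scan (as
  used with external tools) would admit partially degraded arrays that the
  grammar rejects.  A BED import path accepts such external hits.
* The baseline correction reports the expected number of matching offsets
  rather than the probability of at least one; the difference is bounded
  by the pairwise co-match probability, negligible for 18-nt patterns with
  ≥8 concrete positions.
* The exact binomial parameterization conditions on total occurrences;
  alternative designs (e.g. Poisson rate tests) would differ in small-count
  regimes.
* Merged H-H sites keep no sub-site structure; topology distances are
  border-to-border of the merged interval.
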