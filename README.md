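# foxpair

Paired-motif discovery and head-to-head (H-H) / TnG-microsatellite topology
analysis for forkhead-family transcription factors.

FoxP3, the lineage-defining factor of regulatory T cells, reads DNA in two
modes: as a head-to-head dimer on inverted-repeat forkhead motifs
(IR-FKHM: `TGTTTAC ... GTAAACA`, optimally spaced by 4 nt), and as a
multimer on TnG microsatellites (tandem T<sub>n</sub>G units, n = 2–5).
`foxpair` reimplements, as a tested and reusable pipeline, the
computational side of characterizing these modes:

1. **PD-seq extraction** (`foxpair.pdseq`) — turn pull-down/input
   sequencing reads of degenerate 80-bp oligos
   (`NBS1–site1(7 nt)–TCGA–site2–NBS2`) into per-unique-sequence count
   tables with RPM normalization and fold enrichment (PD/input).
2. **2N motif discovery** (`foxpair.twon`) — enumerate the C(7,2) = 21
   degenerate "2N motifs" of every site-1 7-mer (two positions replaced by
   N), aggregate counts over each motif's 16 instantiations, rank by
   PD/input ratio, and classify motifs into group 1 (contains `TGTTT` or
   `TGTTG`, FKHM-like) and group 2 (a `GCAT` core with T/C flanks).
3. **Pair orientation** (`foxpair.pairs`) — build the 10 × 10 × 4 = 400
   oriented pair patterns (H-H, H-T, T-H, T-T with a fixed `TCGA` spacer),
   count supporting reads under 0/±1/±2-bp shifts, and normalize by each
   pattern's analytic baseline likelihood under random offsets.
4. **Genome scanning** (`foxpair.genscan`) — scan peak interval sets
   (positive strand, per-pattern non-overlapping matches), compute per-Mb
   rates, one-sided exact binomial enrichment of ChIP peaks against open
   chromatin regions, gap-size sweeps (1–10 nt), and merged H-H sites.
5. **TnG topology** (`foxpair.tng`) — grammar-based detection of
   T<sub>2-5</sub>G / CA<sub>2-5</sub> tandem arrays with low-complexity
   exclusion filters, signed border distances to merged H-H sites,
   aligned/divergent configuration calls, and coverage-AUC stratification
   of repeats by length (≤20 / ≥40 bp) and H-H adjacency (0-nt gap vs
   >1 kb).
6. **Gene association** (`foxpair.genes`) — feature density (bp/Mb) in
   windows expanding 1 kb–1 Mb around genes of a differential-expression
   table, and the fraction of genes with a feature within 2 kb, binned by
   adjusted p-value and fold-change direction.
7. **Synthetic data** (`foxpair.simulate`) — seeded generators for every
   input: pull-down reads under configurable binder models
   (dimeric-pair / monomeric-site-2 / uniform), and genomes with planted
   motif pairs, TnG arrays at chosen offsets from H-H sites, peaks,
   peak-shaped coverage, and DE tables with planted proximity structure.

## Worked example

Simulate a pull-down experiment whose binder prefers `TGTTTNN` (9× weight)
and `NNGCATN` (6×) in site 1, then recover the motifs:

```python
from foxpair import pdseq, simulate, twon

template = pdseq.DegenerateTemplate()          # 80-bp random-rcFKHM oligo
model = simulate.BinderModel(weights={"TGTTTNN": 9.0, "NNGCATN": 6.0})
inp, pd_counts = simulate.sample_site1_counts(template, model, 200_000, seed=42)
ranked = twon.rank_2n_enrichment(pd_counts, inp)
print(ranked.head(8))
```

```
         group  count_pd  count_input     ratio  rank
motif
TGTTTNN     G1      1792          185  9.634409     1
NAGCATN  other      1343          198  6.748744     2
NNGCATC     G2      1306          193  6.731959     3
NNGCATG  other      1467          218  6.698630     4
NTGCATN     G2      1278          190  6.691099     5
NNGCATT     G2      1224          182  6.688525     6
GNGCATN     G2      1289          192  6.678756     7
TNGCATN     G2      1295          193  6.675258     8
```

The planted FKHM-like motif ranks first at close to its planted 9–10×
enrichment; the GCAT-core family follows at ~6.7×. (Patterns such as
`NAGCATN` overlap the planted `NNGCATN` instantiations, so they rise with
it; the group label reflects the concrete letters only.)

The same workflow is available from the shell:

```bash
foxpair simulate-genome --seed 3 --out sim/
foxpair genscan --fasta sim/genome.fa --fg sim/chip_peaks.bed \
    --bg sim/atac_peaks.bed --motifs TGTTTNN,NNGCATN --sweep 1:10 \
    --out-prefix sim/scan
foxpair topology --fasta sim/genome.fa --hh sim/hh.bed \
    --cov sim/coverage.bedgraph --out-prefix sim/topo
```

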