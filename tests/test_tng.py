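"""TnG repeat detection, H-H topology, coverage AUC and stratification."""

import numpy as np
import pandas as pd
import pytest

from foxpair import simulate, tng
from foxpair.seqcore import reverse_complement


def hh_df(*triples):
    return pd.DataFrame(triples, columns=["Chromosome", "Start", "End"])


class TestDetection:
    def test_ttttg5_is_one_short_plus_repeat(self):
        reps = tng.detect_tng_repeats("CCACC" + "TTTG" * 5 + "CCACC")
        assert len(reps) == 1
        r = reps.iloc[0]
        assert (r.Start, r.End, r.Strand, r.n_units) == (5, 25, "+", 5)
        assert r.End - r.Start == 20  # the "short" (<= 20 bp) stratum

    def test_can_array_detected_on_minus_strand(self):
        reps = tng.detect_tng_repeats("CC" + "CAAA" * 5 + "GG")
        assert len(reps) == 1
        assert reps.iloc[0].Strand == "-"

    def test_mixed_unit_array_is_one_repeat(self):
        reps = tng.detect_tng_repeats("AA" + "TTG" + "TTTTG" + "TTG" + "TTTG" + "AA")
        assert len(reps) == 1
        assert reps.iloc[0].n_units == 4

    @pytest.mark.parametrize(
        "seq",
        ["TG" * 6, "T" * 12, "G" * 12, "A" * 12, "AC" * 6],
    )
    def test_low_complexity_runs_rejected(self, seq):
        assert len(tng.detect_tng_repeats(seq)) == 0

    def test_min_length_and_units_floors(self):
        assert len(tng.detect_tng_repeats("TTTGTTTG")) == 0  # 8 bp < 12
        assert len(tng.detect_tng_repeats("TTTTTGTTTTTG")) == 0  # 2 units < 3
        assert len(tng.detect_tng_repeats("TTTTTGTTTTTG", min_units=2)) == 1

    def test_exclusion_filter_for_imported_regions(self):
        genome = {"chr1": "AAAA" + "TG" * 6 + "TTTG" * 4 + "AAAA"}
        imported = pd.DataFrame(
            {"Chromosome": ["chr1", "chr1"], "Start": [4, 16], "End": [16, 32]}
        )
        kept = tng.apply_exclusion_filters(imported, genome)
        assert len(kept) == 1 and kept.iloc[0].Start == 16

    def test_reverse_complement_mirror(self, rng):
        """Detection on the reverse complement yields mirrored intervals
        with flipped strands."""
        parts = []
        for _ in range(6):
            parts.append("".join(rng.choice(list("ACGT"), size=60)))
            parts.append("TTTG" * int(rng.integers(3, 8)))
        seq = "".join(parts)
        fwd = tng.detect_tng_repeats(seq)
        rev = tng.detect_tng_repeats(reverse_complement(seq))
        assert len(fwd) == len(rev)
        n = len(seq)
        mirrored = sorted(
            (n - r.End, n - r.Start, {"+": "-", "-": "+"}[r.Strand])
            for r in fwd.itertuples(index=False)
        )
        observed = sorted(
            (r.Start, r.End, r.Strand) for r in rev.itertuples(index=False)
        )
        assert mirrored == observed


class TestTopology:
    def setup_method(self):
        # one "+" repeat abutting an H-H site from upstream
        self.reps_plus_up = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [80], "End": [100],
             "Strand": ["+"]}
        )

    def test_plus_repeat_abutting_upstream_is_aligned(self):
        topo = tng.classify_topology(hh_df(("chr1", 100, 118)), self.reps_plus_up)
        rec = topo.iloc[0]
        assert rec.signed_distance == 0
        assert rec.configuration == "aligned"
        assert rec.adjacency == "zero_gap"

    def test_minus_repeat_abutting_downstream_is_aligned(self):
        reps = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [118], "End": [140], "Strand": ["-"]}
        )
        rec = tng.classify_topology(hh_df(("chr1", 100, 118)), reps).iloc[0]
        assert rec.signed_distance == 0
        assert rec.configuration == "aligned"

    def test_plus_repeat_downstream_is_divergent(self):
        reps = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [150], "End": [170], "Strand": ["+"]}
        )
        rec = tng.classify_topology(hh_df(("chr1", 100, 118)), reps).iloc[0]
        assert rec.signed_distance == 32
        assert rec.configuration == "divergent"

    def test_case_enumeration_of_the_orientation_rule(self):
        """All four side x strand combinations."""
        cases = [
            ("+", (40, 60), "aligned"),     # TnG upstream
            ("+", (150, 170), "divergent"),
            ("-", (40, 60), "divergent"),
            ("-", (150, 170), "aligned"),   # CAn downstream
        ]
        for strand, (s, e), expected in cases:
            reps = pd.DataFrame(
                {"Chromosome": ["chr1"], "Start": [s], "End": [e], "Strand": [strand]}
            )
            rec = tng.classify_topology(hh_df(("chr1", 100, 118)), reps).iloc[0]
            assert rec.configuration == expected, (strand, s, e)

    def test_equidistant_tie_goes_to_smaller_start_and_is_flagged(self):
        reps = pd.DataFrame(
            {"Chromosome": ["chr1", "chr1"], "Start": [50, 150], "End": [70, 170],
             "Strand": ["+", "+"]}
        )
        rec = tng.classify_topology(hh_df(("chr1", 100, 120)), reps).iloc[0]
        assert rec.repeat_start == 50
        assert rec.tie

    def test_no_repeat_on_chromosome_gives_null_record(self):
        topo = tng.classify_topology(
            hh_df(("chr2", 100, 118)), self.reps_plus_up
        )
        assert topo.iloc[0].configuration is None

    def test_planted_offsets_recovered_exactly(self):
        """Signed distances of planted H-H/repeat blocks come back as the
        exact planted offsets."""
        cfg = simulate.GenomeConfig(
            chrom_lengths={"chr1": 200_000},
            n_chip_peaks=36, chip_peak_len=700, n_atac_peaks=0,
            tngs=(
                simulate.TnGPlant("TTTG", 5, count=8, strand="+", hh_offset=-50),
                simulate.TnGPlant("TTTG", 5, count=8, strand="+", hh_offset=0),
                simulate.TnGPlant("TTTG", 5, count=8, strand="+", hh_offset=50),
            ),
        )
        g = simulate.gen_genome(cfg, seed=23)
        reps = tng.detect_tng_genome(g.sequences)
        topo = tng.classify_topology(
            g.planted_hh[["Chromosome", "Start", "End"]], reps
        )
        observed = sorted(topo["signed_distance"].value_counts().items())
        assert observed == [(-50, 8), (0, 8), (50, 8)]


class TestCoverageAuc:
    def test_constant_coverage(self):
        cov = {"chr1": np.full(1000, 2.0)}
        assert tng.coverage_auc(cov, "chr1", 500) == pytest.approx(400.0)

    def test_zero_coverage(self):
        cov = {"chr1": np.zeros(1000)}
        assert tng.coverage_auc(cov, "chr1", 500) == 0.0

    def test_window_truncated_at_contig_edge(self, caplog):
        cov = {"chr1": np.ones(150)}
        with caplog.at_level("WARNING"):
            auc = tng.coverage_auc(cov, "chr1", 30)
        assert auc == pytest.approx(130.0)  # [-70, 130) -> [0, 130)
        assert "truncated" in caplog.text

    def test_centered_window_discriminates_peak_location(self):
        """A triangular peak centered on the feature scores higher than the
        same total mass spread flat across the contig."""
        n, h = 2000, 4.0
        x = np.arange(n)
        tri = np.maximum(0, 1 - np.abs(x - 1000) / 300) * h
        flat = np.full(n, tri.sum() / n)
        assert tng.coverage_auc({"c": tri}, "c", 1000) > tng.coverage_auc(
            {"c": flat}, "c", 1000
        )


class TestStratification:
    def test_zero_gap_strata_exceed_far_in_both_length_classes(self, topology_bundle):
        g = topology_bundle
        reps = tng.detect_tng_genome(g.sequences)
        hh = g.planted_hh[["Chromosome", "Start", "End"]]
        strata = tng.stratify_repeats(reps, hh, g.coverage)
        med = strata.groupby(["length_class", "adjacency"])["log2_auc"].median()
        for cls in ("short", "long"):
            assert med[cls]["zero_gap"] > med[cls]["far"]
            assert len(strata[(strata.length_class == cls)]) > 0

    def test_uniform_coverage_gives_equal_strata(self, topology_bundle):
        g = topology_bundle
        reps = tng.detect_tng_genome(g.sequences)
        hh = g.planted_hh[["Chromosome", "Start", "End"]]
        flat = {c: np.ones(len(s)) for c, s in g.sequences.items()}
        strata = tng.stratify_repeats(reps, hh, flat)
        med = strata.groupby("adjacency")["log2_auc"].median()
        assert med["zero_gap"] == pytest.approx(med["far"])

    def test_intermediate_distances_excluded(self):
        reps = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [500], "End": [520], "Strand": ["+"]}
        )
        hh = hh_df(("chr1", 600, 618))  # 80 bp away: neither 0 nor > 1 kb
        cov = {"chr1": np.ones(2000)}
        strata = tng.stratify_repeats(reps, hh, cov)
        assert len(strata) == 0

    def test_planted_cooccurrence_fraction_matches_design(self, topology_bundle):
        """Fraction of H-H-linked repeats among all planted repeats equals
        the planted design exactly."""
        g = topology_bundle
        reps = tng.detect_tng_genome(g.sequences)
        ann = tng.repeat_hh_adjacency(
            reps, g.planted_hh[["Chromosome", "Start", "End"]]
        )
        frac = (ann["adjacency"] == "zero_gap").mean()
        planted_frac = g.planted_tng["hh_offset"].notna().mean()
        assert frac == pytest.approx(planted_frac)


class TestFoxp3FreeOcrs:
    def _setup(self):
        chip = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [10_000], "End": [10_600]}
        )
        cov = {"chr1": np.zeros(100_000)}
        cov["chr1"][10_000:10_600] = 5.0  # ChIP min window AUC = 1000
        return chip, cov

    def test_distance_rule(self):
        chip, cov = self._setup()
        atac = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [15_000], "End": [15_400]}
        )  # 4.4 kb away
        assert len(tng.foxp3_free_ocrs(atac, chip, cov)) == 0

    def test_far_and_silent_peak_included(self):
        chip, cov = self._setup()
        atac = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [30_000], "End": [30_400]}
        )
        kept = tng.foxp3_free_ocrs(atac, chip, cov)
        assert len(kept) == 1

    def test_far_but_covered_peak_excluded(self):
        chip, cov = self._setup()
        cov["chr1"][30_000:30_400] = 50.0  # above the ChIP minimum
        atac = pd.DataFrame(
            {"Chromosome": ["chr1"], "Start": [30_000], "End": [30_400]}
        )
        assert len(tng.foxp3_free_ocrs(atac, chip, cov)) == 0
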