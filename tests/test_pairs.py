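"""Pair pattern construction, shifted windows, baselines, normalization."""

import numpy as np
import pytest

from foxpair import pairs, simulate
from foxpair.pairs import PairPattern, baseline_probability, build_pair_patterns
from foxpair.seqcore import IUPAC_SETS, matches, reverse_complement


class TestPairPatterns:
    def test_render_formulas(self):
        assert PairPattern("TGTTTNN", "TGTTTNN", "HH").rendered == "TGTTTNNTCGANNAAACA"
        assert PairPattern("TGTTTNN", "NNGCATN", "HT").rendered == "TGTTTNNTCGANNGCATN"
        assert (
            PairPattern("TGTTTNN", "NNGCATN", "TH").rendered
            == reverse_complement("TGTTTNN") + "TCGA" + reverse_complement("NNGCATN")
        )
        assert (
            PairPattern("TGTTTNN", "NNGCATN", "TT").rendered
            == reverse_complement("TGTTTNN") + "TCGA" + "NNGCATN"
        )

    def test_400_patterns_from_10_motifs(self, motifs10):
        patterns = build_pair_patterns(motifs10)
        assert len(patterns) == 400
        assert all(len(p.rendered) == 18 for p in patterns)
        per_orient = {o: 0 for o in pairs.ORIENTATIONS}
        for p in patterns:
            per_orient[p.orientation] += 1
        assert all(v == 100 for v in per_orient.values())

    def test_hh_swap_is_reverse_complement_for_palindromic_gap(self, motifs10):
        """HH(A,B) and HH(B,A) render as reverse complements (TCGA gap)."""
        for a in motifs10:
            for b in motifs10:
                assert PairPattern(a, b, "HH").rendered == reverse_complement(
                    PairPattern(b, a, "HH").rendered
                )

    def test_non_7mer_rejected(self):
        with pytest.raises(ValueError):
            PairPattern("TGTTT", "TGTTTNN", "HH")

    def test_duplicate_renders_flagged(self):
        dups = pairs.duplicate_renders(build_pair_patterns(["TGTTTNN", "NNAAACA"]))
        # rc-paired motifs make e.g. HH(a,a) and HT(a,b) render identically
        assert len(dups) > 0


class TestShiftedWindows:
    def test_offset_zero_is_identity(self, rr_template):
        var = "TGTTTACTCGAGTAAACA"
        w = pairs.shifted_windows(var, rr_template)
        assert len(w) == 5
        assert w[2] == var

    def test_offsets_against_slicing_oracle(self, rr_template):
        var = "TGTTTACTCGAGTAAACA"
        full = rr_template.nbs1 + var + rr_template.nbs2
        left = len(rr_template.nbs1)
        w = pairs.shifted_windows(var, rr_template)
        for i, d in enumerate(pairs.DEFAULT_OFFSETS):
            assert w[i] == full[left + d : left + d + 18]
        # +1 drops site 1's first base and appends NBS2's first base
        assert w[3] == var[1:] + rr_template.nbs2[0]

    def test_wrong_length_rejected(self, rr_template):
        with pytest.raises(ValueError):
            pairs.shifted_windows("TGTTTAC", rr_template)


def brute_force_match(variable, patterns, template):
    """Independent any-shift matcher: per-position set membership on every
    window of every pattern."""
    hit = set()
    for w in pairs.shifted_windows(variable, template):
        for i, p in enumerate(patterns):
            if all(c in IUPAC_SETS[q] for q, c in zip(p.rendered, w)):
                hit.add(i)
    return hit


class TestCounting:
    def test_matcher_agrees_with_brute_force(self, motifs10, rr_template, rng):
        patterns = build_pair_patterns(motifs10)
        matcher = pairs.PairMatcher(patterns, rr_template)
        # reads guaranteed to contain a planted pair, plus random ones
        planted = ["TGTTTACTCGAGTAAACA", "TTGCATCTCGATTGCATC"]
        reads = planted + [
            "".join(rng.choice(list("ACGT"), size=18)) for _ in range(60)
        ]
        for read in reads:
            assert matcher.match(read) == brute_force_match(
                read, patterns, rr_template
            )

    @staticmethod
    def _periodic_matcher():
        """A dinucleotide-periodic pattern over flanks chosen so the same
        read matches it at two different shifts."""
        from foxpair.pdseq import DegenerateTemplate

        template = DegenerateTemplate(
            nbs1="G" * 25 + "AC", site2=None, nbs2="AC" + "G" * 33
        )
        pat = PairPattern("ACACACA", "CACACAC", "HT", "CACA")
        matcher = pairs.PairMatcher([pat], template)
        read = "AC" * 9  # matches at offsets -2, 0 and +2
        assert len(matcher.match(read)) == 1
        per_shift = sum(
            w == pat.rendered for w in pairs.shifted_windows(read, template)
        )
        assert per_shift >= 2
        return matcher, read

    def test_any_shift_counts_once(self):
        """A pattern matching at several shifts still gets one count."""
        matcher, read = self._periodic_matcher()
        counts = pairs.count_pair_matches({read: 3}, matcher)
        assert counts[0] == 3  # multiplicity, not 2 shifts x 3

    def test_unique_sequence_mode(self):
        matcher, read = self._periodic_matcher()
        counts = pairs.count_pair_matches({read: 3}, matcher, unique_sequences=True)
        assert counts[0] == 1

    def test_no_match_contributes_zero(self, motifs10, rr_template):
        patterns = build_pair_patterns(motifs10)
        matcher = pairs.PairMatcher(patterns, rr_template)
        assert pairs.count_pair_matches({"A" * 18: 5}, matcher).sum() == 0

    def test_any_shift_never_exceeds_per_shift_sum(self, motifs10, rr_template, rng):
        patterns = build_pair_patterns(motifs10)
        matcher = pairs.PairMatcher(patterns, rr_template)
        for _ in range(30):
            read = "".join(rng.choice(list("ACGT"), size=18))
            any_shift = len(matcher.match(read))
            per_shift = sum(
                1
                for w in pairs.shifted_windows(read, rr_template)
                for i, p in enumerate(patterns)
                if all(c in IUPAC_SETS[q] for q, c in zip(p.rendered, w))
            )
            assert any_shift <= per_shift


class TestStrandFlip:
    def test_reverse_complement_read_maps_orientations(self, motifs10, rr_template):
        """On reverse-complemented reads HH(a,b)->HH(b,a), TT(a,b)->TT(b,a)
        and HT<->TH, exactly."""
        patterns = build_pair_patterns(motifs10)
        matcher = pairs.PairMatcher(patterns, rr_template)
        rc_template = type(rr_template)(
            nbs1=reverse_complement(rr_template.nbs2),
            site2=None,
            nbs2=reverse_complement(rr_template.nbs1),
        )
        rc_matcher = pairs.PairMatcher(patterns, rc_template)
        index = {(p.motif_a, p.motif_b, p.orientation): i for i, p in enumerate(patterns)}
        flip = {"HH": "HH", "TT": "TT", "HT": "TH", "TH": "HT"}
        rng = np.random.default_rng(5)
        reads = ["TGTTTACTCGAGTAAACA", "TTGCATCTCGATGTTTAC"] + [
            "".join(rng.choice(list("ACGT"), size=18)) for _ in range(200)
        ]
        fwd = pairs.count_pair_matches({r: 1 for r in reads}, matcher)
        rev = pairs.count_pair_matches(
            {reverse_complement(r): 1 for r in reads}, rc_matcher
        )
        for (a, b, o), i in index.items():
            j = index[(b, a, flip[o])]
            assert rev[j] == fwd[i]


class TestBaseline:
    def test_fully_wildcard_pattern(self, rr_template):
        full_n = PairPattern("NNNNNNN", "NNNNNNN", "HH", "NNNN")
        total, per_offset = baseline_probability(full_n, rr_template)
        assert per_offset == [1.0] * 5
        assert total == 5.0

    def test_fixed_gap_contributes_unit_factor_at_offset_zero(self, rr_template):
        """At offset 0 the template spacer TCGA sits exactly under the
        pattern's gap, so only the 14 motif positions carry probability."""
        pat = PairPattern("TGTTTNN", "TGTTTNN", "HH")
        _, per_offset = baseline_probability(pat, rr_template)
        # 10 concrete positions among the 14 variable ones, 4 N's
        assert per_offset[2] == pytest.approx((1 / 4) ** 10)

    def test_incompatible_pattern_reports_zero(self, rr_template):
        pat = PairPattern("TGTTTNN", "TGTTTNN", "HH", "AAAA")  # gap never AAAA
        total, _ = baseline_probability(pat, rr_template)
        assert total == 0.0

    def test_monte_carlo_agreement(self, rr_template, rng):
        """Analytic baseline vs Monte-Carlo match expectation, within 3 sigma."""
        pat = PairPattern("TGTTTNN", "NNGCATN", "HH")
        analytic, _ = baseline_probability(pat, rr_template)
        matcher = pairs.PairMatcher([pat], rr_template)
        keys, _ = matcher.encoded_lookup()
        n = 300_000
        draws = rng.integers(0, 4, size=(n, 14), dtype=np.uint8)
        hits = 0
        # count matching offsets directly via window packing
        ctx = np.empty((n, 22), dtype=np.uint8)
        ctx[:, :2] = pairs.encode_seq(rr_template.nbs1[-2:])
        ctx[:, 2:9] = draws[:, :7]
        ctx[:, 9:13] = pairs.encode_seq(rr_template.gap)
        ctx[:, 13:20] = draws[:, 7:]
        ctx[:, 20:] = pairs.encode_seq(rr_template.nbs2[:2])
        for d in pairs.DEFAULT_OFFSETS:
            packed = pairs.pack_windows(ctx[:, 2 + d : 20 + d])
            pos = np.searchsorted(keys, packed)
            pos[pos >= len(keys)] = 0
            hits += int((keys[pos] == packed).sum())
        mc = hits / n
        sigma = np.sqrt(analytic / n)  # Poisson-scale error on the mean
        assert abs(mc - analytic) <= 3 * sigma


class TestOrientationMatrix:
    def test_all_zero_counts_give_all_zero_matrices(self, motifs10, rr_template):
        patterns = build_pair_patterns(motifs10)
        table = pairs.pair_count_table(
            patterns, np.zeros(400, dtype=int), rr_template
        )
        normalized, scaled, totals = pairs.orientation_matrix(table)
        for o in pairs.ORIENTATIONS:
            assert np.nansum(normalized[o].to_numpy()) == 0
            assert np.nansum(scaled[o].to_numpy()) == 0
        assert (totals == 0).all()

    def test_joint_scaling_max_is_100(self, motifs10, rr_template, rng):
        patterns = build_pair_patterns(motifs10)
        counts = rng.integers(0, 50, size=400)
        table = pairs.pair_count_table(patterns, counts, rr_template)
        _, scaled, _ = pairs.orientation_matrix(table)
        global_max = max(np.nanmax(m.to_numpy()) for m in scaled.values())
        assert global_max == pytest.approx(100.0)

    def test_planted_hh_preference_dominates(self, motifs10, rr_template):
        """Reads sampled with extra weight on H-H renders push the H-H
        normalized total above every other orientation."""
        model = simulate.BinderModel(
            weights={m: 8.0 for m in motifs10},
            orientation_weights={"HH": 5.0, "HT": 1.0, "TH": 1.0, "TT": 1.0},
        )
        _, pd_arr = simulate.sample_random_random_inserts(
            rr_template, model, 60_000, seed=13
        )
        patterns = build_pair_patterns(motifs10)
        matcher = pairs.PairMatcher(patterns, rr_template)
        seq_counts: dict[str, int] = {}
        for row in pd_arr:
            s = simulate._decode(row[:7]) + rr_template.gap + simulate._decode(row[7:])
            seq_counts[s] = seq_counts.get(s, 0) + 1
        counts = pairs.count_pair_matches(seq_counts, matcher)
        table = pairs.pair_count_table(patterns, counts, rr_template)
        _, _, totals = pairs.orientation_matrix(table)
        assert totals["HH"] > max(totals["HT"], totals["TH"], totals["TT"])
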