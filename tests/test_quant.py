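"""Quantifier: alignment, window statistic, by-products, replicate stats."""

import numpy as np
import pytest
from scipy import stats

from bhsgrna.alphabet import reverse_complement
from bhsgrna.quant import (
    AmpliconLocus,
    align_read,
    byproduct_table,
    fold_reduction,
    replicate_stats,
    specificity_metrics,
    tally,
    two_sample_ttest,
)
from bhsgrna.simulate import SimulationConfig, simulate_amplicon_reads


def _subst(ref: str, pos0: int, base: str) -> str:
    return ref[:pos0] + base + ref[pos0 + 1 :]


class TestLocus:
    def test_coordinate_round_trip_both_strands(self, cbe_locus):
        for strand in "+-":
            locus = AmpliconLocus(
                "x", cbe_locus.reference, 11, 30, strand, "CBE"
            )
            for p in range(1, 21):
                assert locus.proto_position(locus.ref_position(p)) == p

    def test_minus_strand_orientation(self):
        # protospacer GGGGG...; on - strand the reference shows its revcomp
        ref = "AACCTT" + reverse_complement("GTCCGCTACCGGTCAGATCA") + "AACCTT"
        locus = AmpliconLocus("m", ref, 7, 26, "-", "CBE")
        assert locus.protospacer_sequence() == "GTCCGCTACCGGTCAGATCA"
        assert locus.pam_side == "left"

    def test_window_defaults(self):
        ref = "A" * 50
        assert AmpliconLocus("c", ref, 11, 30, "+", "CBE").window == (4, 8)
        assert AmpliconLocus("a", ref, 11, 30, "+", "ABE").window == (4, 7)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            AmpliconLocus("x", "ACGT", 1, 10, "+", "CBE")


class TestAlignRead:
    def test_identity_read(self, cbe_locus):
        aln = align_read(cbe_locus.reference, None, cbe_locus)
        assert aln.substitutions == [] and aln.indels == []
        assert aln.covers_protospacer

    def test_single_substitution(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)  # a C of the protospacer
        read = _subst(cbe_locus.reference, ref_pos - 1, "T")
        aln = align_read(read, None, cbe_locus)
        assert [(s[0], s[1], s[2]) for s in aln.substitutions] == [(ref_pos, "C", "T")]
        assert aln.indels == []

    def test_deletion_leftmost_placement(self):
        #          123456789...
        ref = "ACGTAAAGTCCGGTTACGTAGCATCGATTACG"
        locus = AmpliconLocus("d", ref, 3, 22, "+", "CBE")
        # delete one A of the AAA run (ref positions 5-7): must left-align to 5
        read = ref[:5] + ref[6:]
        aln = align_read(read, None, locus)
        assert aln.indels == [(5, "del", 1, "A")]

    def test_two_nt_deletion_inside_protospacer(self, cbe_locus):
        s, e = cbe_locus.ref_position(12) - 1, cbe_locus.ref_position(14) - 1
        read = cbe_locus.reference[:s] + cbe_locus.reference[s + 2 :]
        aln = align_read(read, None, cbe_locus)
        assert len(aln.indels) == 1
        pos, kind, length, _ = aln.indels[0]
        assert kind == "del" and length == 2
        assert cbe_locus.proto_start <= pos <= cbe_locus.proto_end

    def test_insertion_detected(self, cbe_locus):
        cut = cbe_locus.ref_position(10)
        read = cbe_locus.reference[:cut] + "TT" + cbe_locus.reference[cut:]
        aln = align_read(read, None, cbe_locus)
        kinds = [(k, l) for _, k, l, _ in aln.indels]
        assert kinds == [("ins", 2)]

    def test_short_read_flagged_not_raised(self, cbe_locus):
        aln = align_read(cbe_locus.reference[:15], None, cbe_locus)
        assert not aln.covers_protospacer
        assert not aln.passes()


class TestTally:
    def _aln(self, locus, read, quals=None):
        return align_read(read, quals, locus)

    def test_no_edits_zero_frequency(self, cbe_locus):
        alns = [self._aln(cbe_locus, cbe_locus.reference) for _ in range(10)]
        prof = tally(alns, cbe_locus)
        assert prof.window_frequency == 0.0 and prof.n_reads_pass == 10

    def test_window_statistic_hand_count(self, cbe_locus):
        """3 of 10 reads carry C6->T inside the 4-8 window: 30%."""
        ref_pos = cbe_locus.ref_position(6)
        edited = _subst(cbe_locus.reference, ref_pos - 1, "T")
        alns = [self._aln(cbe_locus, edited) for _ in range(3)]
        alns += [self._aln(cbe_locus, cbe_locus.reference) for _ in range(7)]
        prof = tally(alns, cbe_locus)
        assert prof.window_frequency == pytest.approx(0.30)
        assert prof.substitution_frequency(6, "T") == pytest.approx(0.30)

    def test_edit_outside_window_not_counted(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(3)  # C3, outside window 4-8
        edited = _subst(cbe_locus.reference, ref_pos - 1, "T")
        alns = [self._aln(cbe_locus, edited)]
        alns += [self._aln(cbe_locus, cbe_locus.reference) for _ in range(9)]
        prof = tally(alns, cbe_locus)
        assert prof.window_frequency == 0.0
        assert prof.substitution_frequency(3, "T") == pytest.approx(0.10)

    def test_noncanonical_requires_flag(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)
        edited = _subst(cbe_locus.reference, ref_pos - 1, "G")  # C->G by-product
        alns = [self._aln(cbe_locus, edited)]
        assert tally(alns, cbe_locus).window_frequency == 0.0
        assert tally(alns, cbe_locus, any_substitution=True).window_frequency == 1.0

    def test_order_and_duplication_invariance(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)
        edited = _subst(cbe_locus.reference, ref_pos - 1, "T")
        alns = [self._aln(cbe_locus, edited)] + [
            self._aln(cbe_locus, cbe_locus.reference) for _ in range(4)
        ]
        f1 = tally(alns, cbe_locus).window_frequency
        f2 = tally(alns[::-1], cbe_locus).window_frequency
        f3 = tally(alns * 3, cbe_locus).window_frequency
        assert f1 == f2 == f3 == pytest.approx(0.2)

    def test_quality_masking(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)
        edited = _subst(cbe_locus.reference, ref_pos - 1, "T")
        quals = [30] * len(edited)
        quals[ref_pos - 1] = 5  # below Q20: masked
        aln = self._aln(cbe_locus, edited, quals)
        assert tally([aln], cbe_locus).window_frequency == 0.0
        # threshold 0 reproduces unmasked counts
        assert tally([aln], cbe_locus, min_qual=0).window_frequency == 1.0

    def test_minus_strand_metamorphic(self, rng):
        """A locus on the - strand gives the same profile as the mirrored
        + strand locus quantified on reverse-complemented reads."""
        proto = "ATCCCCCTACGGTCAGATCA"
        plus_ref = "GATTACAGGA" + proto + "AGGTTCACGATCGATTACGA"
        plus = AmpliconLocus("p", plus_ref, 11, 30, "+", "CBE")
        minus = AmpliconLocus("m", reverse_complement(plus_ref), 21, 40, "-", "CBE")
        cfg = SimulationConfig(seed=5, n_reads=300, edit_rates={6: 0.4, 7: 0.1})
        reads, _ = simulate_amplicon_reads(plus, cfg)
        prof_p = tally([align_read(s, q, plus) for _, s, q in reads], plus)
        prof_m = tally(
            [align_read(reverse_complement(s), q[::-1], minus) for _, s, q in reads],
            minus,
        )
        assert prof_p.window_frequency == prof_m.window_frequency
        for p in range(1, 21):
            assert prof_p.substitution_frequency(p, "T") == prof_m.substitution_frequency(p, "T")

    def test_indel_overlap_rule(self, cbe_locus):
        inside = cbe_locus.reference[: cbe_locus.proto_start + 2]
        inside += cbe_locus.reference[cbe_locus.proto_start + 4 :]  # 2-nt del inside
        outside = cbe_locus.reference[:2] + cbe_locus.reference[4:]  # del near 5' end
        prof = tally(
            [align_read(inside, None, cbe_locus), align_read(outside, None, cbe_locus)],
            cbe_locus,
        )
        assert prof.n_reads_indel == 1


class TestByproducts:
    def test_all_canonical_zero_undesired(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)
        edited = _subst(cbe_locus.reference, ref_pos - 1, "T")
        prof = tally([align_read(edited, None, cbe_locus)], cbe_locus)
        bp = byproduct_table(prof).set_index("position")
        assert bp.loc[6, "undesired_fraction"] == 0.0
        assert bp.loc[6, "canonical_fraction"] == 1.0

    def test_mixture_counts(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)
        to_t = _subst(cbe_locus.reference, ref_pos - 1, "T")
        to_g = _subst(cbe_locus.reference, ref_pos - 1, "G")
        alns = [align_read(to_t, None, cbe_locus) for _ in range(50)]
        alns += [align_read(to_g, None, cbe_locus) for _ in range(5)]
        alns += [align_read(cbe_locus.reference, None, cbe_locus) for _ in range(45)]
        bp = byproduct_table(tally(alns, cbe_locus)).set_index("position")
        assert bp.loc[6, "canonical_fraction"] == pytest.approx(0.50)
        assert bp.loc[6, "undesired_fraction"] == pytest.approx(0.05)

    def test_no_coverage_reported_missing(self, cbe_locus):
        bp = byproduct_table(tally([], cbe_locus)).set_index("position")
        assert np.isnan(bp.loc[6, "canonical_fraction"])


class TestSpecificity:
    def test_fold_reduction_arithmetic(self):
        value, qual = fold_reduction(0.57, 0.114)
        assert value == pytest.approx(5.0) and qual == ""

    def test_identical_profiles_unity(self):
        value, qual = fold_reduction(0.25, 0.25)
        assert value == pytest.approx(1.0) and qual == ""

    def test_below_floor_reported_as_bound(self):
        value, qual = fold_reduction(0.57, 0.0)
        assert qual == ">=" and value == pytest.approx(0.57 / 0.001)

    def test_metrics_frame(self, cbe_locus):
        ref_pos = cbe_locus.ref_position(6)
        edited = _subst(cbe_locus.reference, ref_pos - 1, "T")

        def prof(n_edit, n_total):
            alns = [align_read(edited, None, cbe_locus) for _ in range(n_edit)]
            alns += [
                align_read(cbe_locus.reference, None, cbe_locus)
                for _ in range(n_total - n_edit)
            ]
            return tally(alns, cbe_locus)

        df = specificity_metrics(
            on=prof(9, 10), offs=[prof(1, 10)], comparator_on=prof(9, 10),
            comparator_offs=[prof(5, 10)],
        )
        row = df.iloc[0]
        assert row["fold_reduction"] == pytest.approx(5.0)
        assert row["on_off_ratio"] == pytest.approx(9.0)


class TestReplicateStats:
    def test_constant_values(self):
        mean, sem = replicate_stats([1.0, 1.0, 1.0])
        assert mean == 1.0 and sem == 0.0

    def test_closed_form(self):
        mean, sem = replicate_stats([2.0, 4.0, 6.0])
        assert mean == pytest.approx(4.0)
        assert sem == pytest.approx(2.0 / np.sqrt(3))

    def test_identical_groups_p_one(self):
        t, p = two_sample_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_student(self, rng):
        a = rng.normal(0, 1, size=8).tolist()
        b = rng.normal(0.5, 1, size=6).tolist()
        t, p = two_sample_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            replicate_stats([1.0])
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])
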