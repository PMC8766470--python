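"""Substitution tables, editing windows, indels, alleles, clones."""

import numpy as np
import pandas as pd
import pytest

from zfdkit import (
    Interval,
    InvalidArgumentError,
    align_read,
    align_records,
    allele_table,
    build_pileup,
    classify_clone,
    edit_frequency,
    indel_frequency,
    make_editing_model,
    simulate_reads,
    substitution_table,
    window_c2t,
)
from zfdkit.quant import GeneFrame, STANDARD_CODE, VERTEBRATE_MITO_CODE


def _table(reads, ref, min_depth=1):
    alns = [align_read(r, ref, read_id=f"r{i}") for i, r in enumerate(reads)]
    return alns, substitution_table(build_pileup(alns, ref), ref, min_depth=min_depth)


class TestSubstitutionTable:
    def test_hand_counted_frequency(self):
        ref = "AACAA"
        _, tab = _table(["AACAA"] * 7 + ["AATAA"] * 3, ref)
        assert tab.loc[2, "freq_T"] == pytest.approx(0.30)
        assert tab.loc[2, "freq_C"] == pytest.approx(0.70)

    def test_all_reference_reads_give_zero_frequencies(self):
        ref = "ACGTTGCA"
        _, tab = _table([ref] * 5, ref)
        # each position carries exactly its reference base at frequency 1
        assert tab[[c for c in tab.columns if c.startswith("freq_")]].sum().sum() == pytest.approx(
            float(len(ref))
        )
        assert (tab["freq_del"] == 0).all()

    def test_low_depth_position_flagged_missing_not_zero(self):
        ref = "AACAA"
        _, tab = _table(["AACAA"] * 3, ref, min_depth=10)
        assert tab["missing"].all()
        assert tab["freq_T"].isna().all()

    def test_positions_are_one_based_in_report(self):
        ref = "CAAAA"
        _, tab = _table([ref] * 2, ref)
        assert list(tab["pos"]) == [1, 2, 3, 4, 5]


class TestWindowProfile:
    def test_labels_contexts_and_strands(self):
        #         0123456789
        ref = "AAATCAGCAAAA"  # spacer [3,9): C4(0-based) ctx TC; G6 minus ctx GC?; C7 ctx GC
        _, tab = _table([ref] * 12, ref)
        prof = window_c2t(tab, Interval(3, 9), strand_of_edit="both")
        by_label = {r["label"]: r for _, r in prof.iterrows()}
        assert by_label["C_2"]["context"] == "TC" and by_label["C_2"]["strand"] == "+"
        assert by_label["C_4"]["strand"] == "-"  # reference G
        assert by_label["C_5"]["context"] == "GC"

    def test_spacer_without_c_gives_empty_profile(self):
        ref = "TTTATATATTTT"
        _, tab = _table([ref] * 12, ref)
        assert window_c2t(tab, Interval(3, 9), "+").empty

    def test_spacer_outside_reference_rejected(self):
        ref = "AACAA"
        _, tab = _table([ref] * 2, ref)
        with pytest.raises(InvalidArgumentError):
            window_c2t(tab, Interval(2, 99))


class TestIndelFrequency:
    def test_hand_counted_window_indels(self):
        ref = "AAAACGTACGTAAAA"
        win = Interval(4, 11)
        clean = [ref] * 8
        deleted = [ref[:6] + ref[7:]] * 2  # 1-bp deletion inside the window
        alns = [align_read(r, ref, read_id=f"r{i}") for i, r in enumerate(clean + deleted)]
        assert indel_frequency(alns, win) == pytest.approx(0.2)

    def test_no_indels_zero(self):
        ref = "AAAACGTACGTAAAA"
        alns = [align_read(ref, ref)] * 5
        assert indel_frequency(alns, Interval(4, 11)) == 0.0

    def test_indel_outside_window_not_counted(self):
        ref = "ACGTACGTAAAATTTTCCCCGGGG"
        win = Interval(16, 20)
        with_del = align_read(ref[:5] + ref[6:], ref)  # deletion near the start
        assert any(op == "D" for op, _ in with_del.cigar)
        assert indel_frequency([with_del] + [align_read(ref, ref)] * 4, win) == 0.0


class TestRoundTrip:
    def test_planted_rates_recovered_through_full_quantification(self, amplicon):
        ref, spacer = amplicon
        m = make_editing_model(
            ref, spacer,
            context_defaults={"TC": 0.3, "CC": 0.1, "GC": 0.05},
            seq_error_rate=0.001,
        )
        recs, truth = simulate_reads(ref, m, 4000, seed=13)
        alns = align_records(recs, ref)
        tab = substitution_table(build_pileup(alns, ref), ref)
        for e in truth.planted_edits:
            col = "freq_T" if e.strand == "+" else "freq_A"
            obs = tab.loc[e.pos, col]
            sd = np.sqrt(e.true_rate * (1 - e.true_rate) / 4000)
            assert abs(obs - e.true_rate) <= 3 * sd + 0.002

    def test_estimated_frequency_monotone_in_planted_rate(self):
        ref = "A" * 40 + "TC" + "A" * 40
        lo_mean, hi_mean = [], []
        for rep in range(60):
            for rate, sink in ((0.2, lo_mean), (0.5, hi_mean)):
                m = make_editing_model(ref, Interval(40, 42),
                                       explicit_rates={(41, "+"): rate})
                recs, _ = simulate_reads(ref, m, 100, seed=1000 + rep)
                sink.append(sum(r.seq[41] == "T" for r in recs) / 100)
        assert np.mean(hi_mean) > np.mean(lo_mean)


class TestAlleleTable:
    def _alns(self, reads, ref):
        return [align_read(r, ref, read_id=f"r{i}") for i, r in enumerate(reads)]

    def test_stop_gain_flagged_with_star(self):
        ref = "ATGCAAGCATTAGGCTAA"
        window = Interval(3, 15)
        reads = [ref] * 7 + [ref.replace("CAA", "TAA", 1)] * 3
        tab = allele_table(self._alns(reads, ref), ref, window,
                          gene_frame=GeneFrame(0, "+"), genetic_code=VERTEBRATE_MITO_CODE)
        mut = tab[~tab["is_reference"]].iloc[0]
        assert mut["aa_changes"] == "Q2*"
        assert mut["stop_gained"]
        assert mut["fraction"] == pytest.approx(0.3)

    def test_aga_is_stop_under_mito_code_and_arg_under_standard(self):
        ref = "ATGGGAGCATTAGGCTAA"
        window = Interval(3, 15)
        reads = [ref] * 5 + [ref[:3] + "AGA" + ref[6:]] * 5  # GGA -> AGA
        for code, expected in ((VERTEBRATE_MITO_CODE, "G2*"), (STANDARD_CODE, "G2R")):
            tab = allele_table(self._alns(reads, ref), ref, window,
                              gene_frame=GeneFrame(0, "+"), genetic_code=code)
            mut = tab[~tab["is_reference"]].iloc[0]
            assert mut["aa_changes"] == expected

    def test_reference_only_reads_single_allele(self):
        ref = "ATGCAAGCATTAGGCTAA"
        tab = allele_table(self._alns([ref] * 10, ref), ref, Interval(3, 15),
                          gene_frame=GeneFrame(0, "+"))
        assert len(tab) == 1
        assert tab.iloc[0]["fraction"] == 1.0
        assert tab.iloc[0]["is_reference"]
        assert tab.iloc[0]["aa_changes"] == ""

    def test_minus_strand_gene_translation(self):
        # coding strand is the minus strand; plus carries the complement
        ref = "TTATTAGCCTAATGCTTT"
        window = Interval(3, 15)
        # minus-strand CDS over the window: revcomp(ref[3:15]) = GCATTAGGCTAA
        frame = GeneFrame(codon_start=14, strand="-")
        reads = [ref] * 6 + [ref[:8] + "T" + ref[9:]] * 4
        tab = allele_table(self._alns(reads, ref), ref, window, gene_frame=frame,
                          genetic_code=VERTEBRATE_MITO_CODE)
        mut = tab[~tab["is_reference"]].iloc[0]
        assert mut["aa_changes"] != ""

    def test_frame_mismatch_rejected(self):
        ref = "ATGCAAGCATTAGGCTAA"
        with pytest.raises(InvalidArgumentError):
            allele_table(self._alns([ref] * 3, ref), ref, Interval(3, 14),
                        gene_frame=GeneFrame(0, "+"))

    def test_fractions_sum_to_one_over_spanning_reads(self):
        ref = "ATGCAAGCATTAGGCTAA"
        reads = [ref] * 4 + [ref.replace("CAA", "TAA", 1)] * 3 + [ref.replace("GCA", "GTA", 1)] * 3
        tab = allele_table(self._alns(reads, ref), ref, Interval(3, 15))
        assert tab["fraction"].sum() == pytest.approx(1.0)


class TestCloneClassification:
    @pytest.mark.parametrize(
        "freq,label",
        [(0.76, "edited"), (0.26, "edited"), (0.005, "background"),
         (0.0, "background"), (0.035, "indeterminate")],
    )
    def test_threshold_labels(self, freq, label):
        assert classify_clone(freq).label == label

    def test_boundaries_are_inclusive(self):
        assert classify_clone(0.02, 0.02, 0.05).label == "background"
        assert classify_clone(0.05, 0.02, 0.05).label == "edited"

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_clone(0.5, background_max=0.5, edited_min=0.1)

    def test_edit_frequency_averages_planted_positions(self):
        ref = "AACAAGAA"
        alns = [align_read("AATAAAAA", ref), align_read("AACAAGAA", ref)]
        tab = substitution_table(build_pileup(alns, ref), ref, min_depth=1)
        # the mutant read carries both the C->T at 2 and the G->A at 5
        freq = edit_frequency(tab, [(2, "+"), (5, "-")])
        assert freq == pytest.approx(0.5)
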