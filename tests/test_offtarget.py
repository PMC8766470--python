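"""Genome-wide conversion tables, SNV masking, off-target calls, specificity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zfdkit import (
    Interval,
    InvalidArgumentError,
    OffTargetSpec,
    call_offtargets,
    context_matrix,
    dose_response_summary,
    genome_conversion_table,
    genome_pileup,
    mask_variants,
    simulate_mtdna_sample,
    specificity_report,
)
from zfdkit.align import PileupMatrix
from zfdkit.offtarget import OffTargetCallSet

from oracles import naive_offtarget_scan


def _conv_table(rows):
    """Hand-built conversion table: list of (pos, strand, rate [, context])."""
    recs = []
    for row in rows:
        pos, strand, rate = row[:3]
        ctx = row[3] if len(row) > 3 else "TC"
        recs.append({"pos": pos, "strand": strand, "depth": 1000,
                     "converted": int(round(rate * 1000)), "rate": rate,
                     "context": ctx})
    return pd.DataFrame(recs)


class TestConversionTable:
    def test_strand_rule_and_arithmetic(self):
        genome = "ACGTA" * 10
        pile = PileupMatrix(len(genome), circular=True)
        # reference C at 1: 98 C, 2 T; reference G at 2: 90 G, 10 A
        pile.counts[1, 1] = 98
        pile.counts[1, 3] = 2
        pile.counts[2, 2] = 90
        pile.counts[2, 0] = 10
        tab = genome_conversion_table(pile, genome, min_depth=10)
        c_row = tab[tab["pos"] == 1].iloc[0]
        g_row = tab[tab["pos"] == 2].iloc[0]
        assert c_row["strand"] == "+" and c_row["rate"] == pytest.approx(0.02)
        assert g_row["strand"] == "-" and g_row["rate"] == pytest.approx(0.10)

    def test_a_t_positions_absent(self):
        genome = "ACGTA" * 10
        pile = PileupMatrix(len(genome))
        pile.counts[:, 0] = 100
        tab = genome_conversion_table(pile, genome)
        assert set(tab["pos"]) == {p for p, b in enumerate(genome) if b in "CG"}

    def test_low_depth_positions_excluded(self):
        genome = "AACGAA"
        pile = PileupMatrix(len(genome))
        pile.counts[2, 1] = 5  # depth 5 < 10
        pile.counts[3, 2] = 50
        tab = genome_conversion_table(pile, genome, min_depth=10)
        assert list(tab["pos"]) == [3]


class TestMasking:
    def test_high_rate_in_all_samples_masked(self):
        t = _conv_table([(10, "+", 0.99), (20, "+", 0.99)])
        u = _conv_table([(10, "+", 0.99), (20, "+", 0.001)])
        assert mask_variants({"treated": t, "untreated": u}) == {10}

    def test_threshold_is_inclusive(self):
        t = _conv_table([(10, "+", 0.5)])
        u = _conv_table([(10, "+", 0.5)])
        assert mask_variants({"t": t, "u": u}, threshold=0.5) == {10}

    def test_idempotent_and_monotone_in_samples(self):
        t = _conv_table([(1, "+", 0.9), (2, "+", 0.6), (3, "+", 0.2)])
        u = _conv_table([(1, "+", 0.8), (2, "+", 0.4), (3, "+", 0.9)])
        v = _conv_table([(1, "+", 0.55), (2, "+", 0.9), (3, "+", 0.9)])
        two = mask_variants({"t": t, "u": u})
        assert mask_variants({"t": t, "u": u}) == two  # idempotent
        three = mask_variants({"t": t, "u": u, "v": v})
        assert three <= two  # adding a sample can only shrink the mask

    @given(
        rates=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=20
        )
    )
    def test_masked_iff_high_everywhere(self, rates):
        a = _conv_table([(i, "+", r1) for i, (r1, _) in enumerate(rates)])
        b = _conv_table([(i, "+", r2) for i, (_, r2) in enumerate(rates)])
        masked = mask_variants({"a": a, "b": b})
        expected = {i for i, (r1, r2) in enumerate(rates) if r1 >= 0.5 and r2 >= 0.5}
        assert masked == expected

    def test_empty_sample_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mask_variants({})


class TestCallOfftargets:
    def test_three_rules_on_four_positions(self):
        tab = _conv_table(
            [(5, "+", 0.005), (6, "+", 0.02), (7, "+", 0.6), (100, "+", 0.3)]
        )
        calls = call_offtargets(tab, masked={7}, on_target=Interval(100, 108),
                                min_rate=0.01)
        assert list(calls.calls["pos"]) == [6]

    def test_rate_threshold_inclusive(self):
        tab = _conv_table([(5, "+", 0.01)])
        calls = call_offtargets(tab, set(), Interval(100, 108), min_rate=0.01)
        assert calls.n_calls == 1

    def test_all_below_threshold_empty(self):
        tab = _conv_table([(5, "+", 0.005), (6, "+", 0.009)])
        calls = call_offtargets(tab, set(), Interval(100, 108))
        assert calls.n_calls == 0

    def test_matches_naive_scan_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 200
            pos = np.sort(rng.choice(5000, n, replace=False))
            rates = rng.choice([0.0, 0.005, 0.01, 0.02, 0.3, 0.6, 1.0], n)
            tab = _conv_table([(int(p), "+", float(r)) for p, r in zip(pos, rates)])
            masked = set(int(p) for p in rng.choice(pos, 20, replace=False))
            on = Interval(2000, 2015)
            calls = call_offtargets(tab, masked, on, min_rate=0.01)
            expected = naive_offtarget_scan(
                tab.to_dict("records"), masked, on.start, on.end, 0.01
            )
            assert list(calls.calls["pos"]) == expected


class TestSpecificity:
    def test_hand_arithmetic_ratio(self):
        tab = _conv_table(
            [(100, "+", 0.3), (103, "+", 0.1), (5, "+", 0.02), (9, "+", 0.02)]
        )
        calls = call_offtargets(tab, set(), Interval(100, 108), min_rate=0.01)
        rep = specificity_report(tab, Interval(100, 108), calls)
        assert rep.mean_on == pytest.approx(0.2)
        assert rep.mean_off == pytest.approx(0.02)
        assert rep.ratio == pytest.approx(10.0)

    def test_no_offtargets_ratio_undefined_not_infinite(self):
        tab = _conv_table([(100, "+", 0.3), (5, "+", 0.001)])
        calls = call_offtargets(tab, set(), Interval(100, 108))
        rep = specificity_report(tab, Interval(100, 108), calls)
        assert not rep.ratio_defined
        assert rep.to_dict()["specificity_ratio"] is None

    def test_equal_rates_ratio_one(self):
        tab = _conv_table([(100, "+", 0.05), (5, "+", 0.05)])
        calls = call_offtargets(tab, set(), Interval(100, 108))
        rep = specificity_report(tab, Interval(100, 108), calls)
        assert rep.ratio == pytest.approx(1.0)

    def test_ratio_scales_linearly_with_on_target_rates(self):
        base = [(100, "+", 0.2), (103, "+", 0.1), (5, "+", 0.02), (9, "+", 0.04)]
        for c in (0.5, 2.0, 3.0):
            scaled = [(p, s, r * c if 100 <= p < 108 else r) for p, s, r in base]
            r0 = specificity_report(
                _conv_table(base), Interval(100, 108),
                call_offtargets(_conv_table(base), set(), Interval(100, 108)),
            )
            r1 = specificity_report(
                _conv_table(scaled), Interval(100, 108),
                call_offtargets(_conv_table(scaled), set(), Interval(100, 108)),
            )
            assert r1.ratio == pytest.approx(c * r0.ratio)

    def test_empty_on_target_rejected(self):
        tab = _conv_table([(5, "+", 0.05)])
        calls = call_offtargets(tab, set(), Interval(100, 108))
        with pytest.raises(InvalidArgumentError):
            specificity_report(tab, Interval(100, 108), calls)


class TestContextMatrix:
    def test_tc_calls_put_t_at_minus_one(self):
        genome = ("A" * 10 + "TC" + "A" * 10) * 3
        pos = [i for i, b in enumerate(genome) if b == "C"]
        calls = OffTargetCallSet(
            calls=pd.DataFrame({"pos": pos, "strand": "+", "rate": 0.05,
                                "context": "TC"}),
            min_rate=0.01,
        )
        cm = context_matrix(calls, genome, flank=3)
        assert cm.loc[cm["offset"] == -1, "T"].iloc[0] == pytest.approx(1.0)
        assert cm.loc[cm["offset"] == 0, "C"].iloc[0] == pytest.approx(1.0)

    def test_minus_strand_call_is_reverse_complemented(self):
        genome = "A" * 10 + "GA" + "A" * 10  # G at 10: minus-strand C, 5' T
        calls = OffTargetCallSet(
            calls=pd.DataFrame({"pos": [10], "strand": ["-"], "rate": [0.05],
                                "context": ["TC"]}),
            min_rate=0.01,
        )
        cm = context_matrix(calls, genome, flank=2)
        assert cm.loc[cm["offset"] == 0, "C"].iloc[0] == 1.0
        assert cm.loc[cm["offset"] == -1, "T"].iloc[0] == 1.0

    def test_context_wraps_circular_origin(self):
        genome = "CAAAAAAAAT"  # C at 0; 5' neighbour is the last base T
        calls = OffTargetCallSet(
            calls=pd.DataFrame({"pos": [0], "strand": ["+"], "rate": [0.05],
                                "context": ["TC"]}),
            min_rate=0.01,
        )
        cm = context_matrix(calls, genome, flank=2)
        assert cm.loc[cm["offset"] == -1, "T"].iloc[0] == 1.0

    def test_empty_call_set_rejected(self):
        empty = OffTargetCallSet(
            calls=pd.DataFrame(columns=["pos", "strand", "rate", "context"]),
            min_rate=0.01,
        )
        with pytest.raises(InvalidArgumentError):
            context_matrix(empty, "ACGT" * 10)


class TestEndToEndRecovery:
    def test_planted_sites_recovered_and_false_calls_rare(self, toy_genome, on_model):
        spec = OffTargetSpec(n_sites=20, rate_range=(0.02, 0.10),
                             tc_context_fraction=0.8)
        reads, truth = simulate_mtdna_sample(toy_genome, on_model, spec,
                                             depth=200, seed=3)
        tab = genome_conversion_table(genome_pileup(reads, toy_genome), toy_genome)
        calls = call_offtargets(tab, set(), on_model.window, min_rate=0.01)
        planted = {e.pos for e in truth.planted_edits
                   if e.pos not in on_model.window and e.true_rate >= 0.02}
        called = set(calls.calls["pos"].astype(int))
        assert len(planted & called) / len(planted) >= 0.95
        n_cg = len(tab)
        false = called - {e.pos for e in truth.planted_edits}
        assert len(false) / n_cg <= 0.01

    def test_dose_series_is_monotone_and_shares_mask(self, toy_genome, on_model):
        spec = OffTargetSpec(n_sites=15, rate_range=(0.02, 0.10))
        snv_pos = toy_genome.index("C", 700)
        snvs = [(snv_pos, "T", 0.99)]
        samples = []
        for i, dose in enumerate((0.0, 0.3, 1.0)):
            model = on_model.with_dose(dose)
            reads, _ = simulate_mtdna_sample(toy_genome, model, spec, depth=150,
                                             seed=50 + i, snvs=snvs)
            tab = genome_conversion_table(genome_pileup(reads, toy_genome), toy_genome)
            samples.append((f"dose_{dose}", tab))
        frame, reports = dose_response_summary(samples, on_model.window)
        means = list(frame["mean_genome_rate"])
        assert means == sorted(means)
        # dose 0: sequencing error alone yields calls at <= 1% of C/G positions
        assert reports[0].n_offtargets <= 0.01 * len(samples[0][1])
        # the planted SNV is masked by the all-samples rule, never called
        masked = mask_variants({lab: t for lab, t in samples})
        assert snv_pos in masked
        for lab, tab in samples:
            calls = call_offtargets(tab, masked, on_model.window)
            assert snv_pos not in set(calls.calls["pos"])

    def test_duplicate_dose_labels_rejected(self):
        tab = _conv_table([(100, "+", 0.1)])
        with pytest.raises(InvalidArgumentError):
            dose_response_summary([("a", tab), ("a", tab)], Interval(100, 101))
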