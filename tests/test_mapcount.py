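import numpy as np
import pandas as pd
import pytest

import twocchip as tc
from twocchip.mapcount import (
    CATEGORY_ROWS,
    OUTCOME_AMBIGUOUS,
    OUTCOME_PRODUCT,
    OUTCOME_UNMAPPED,
    RUN_LEVEL,
    CountTable,
)
from twocchip.reference import UNPAIRED_BARCODE_FORWARD, UNPAIRED_REVERSE

from oracle import brute_force_assign


class TestMatchRead:
    def test_exact_read_gives_single_full_identity_hit(self, reference):
        p = reference.full_products[0]
        refs = [(x.product_id, x.sequence) for x in reference.full_products[:50]]
        hits = tc.match_read(p.sequence, refs, min_match=50)
        assert hits[0] == (p.product_id, float(len(p.sequence)))
        assert len([h for h in hits if h[1] == hits[0][1]]) == 1

    def test_read_below_min_match_gets_no_hits(self, reference):
        refs = [(p.product_id, p.sequence) for p in reference.full_products[:5]]
        assert tc.match_read("ACGTACGT", refs, min_match=50) == []

    def test_equidistant_references_both_returned(self):
        base = "GATTACAGATTACAGATTACAGATTACAGATTACAGATTACAGATTACAG"[:50]
        refs = [("a", base + "AAAAA"), ("b", base + "TTTTT")]
        read = base + "GGGGG"
        hits = tc.match_read(read, refs, min_match=22, min_identity=0.9)
        assert {h[0] for h in hits} == {"a", "b"}
        assert hits[0][1] == hits[1][1]


class TestTwoStepAssign:
    def test_noiseless_on_diagonal_reads_assigned_to_true_product(
            self, reference, panel):
        prof = tc.flat_profile(panel)
        reads, truth = tc.simulate_library(reference, prof, "BC01", 300, seed=1)
        asn = tc.two_step_assign(reads, reference)
        true_ref = dict(zip(truth.reads.read_id, truth.reads.ref_id))
        assert all(a.outcome == OUTCOME_PRODUCT and a.product_id == true_ref[a.read_id]
                   for a in asn)

    def test_barcode_forward_fragment_assigned_to_unpaired_category(
            self, reference, panel, barcodes):
        frag = barcodes[0].sequence + panel.forward_tail + panel.pairs[3].forward_homology
        [a] = tc.two_step_assign([("frag", frag)], reference)
        assert a.outcome == UNPAIRED_BARCODE_FORWARD
        assert a.barcode_id == barcodes[0].barcode_id

    def test_reverse_only_read_assigned_without_barcode(self, reference, panel):
        frag = panel.pairs[5].reverse_homology + panel.reverse_tail
        [a] = tc.two_step_assign([("rev", frag)], reference)
        assert a.outcome == UNPAIRED_REVERSE
        assert a.barcode_id is None

    def test_shared_forward_homology_gives_ambiguous_fragment(
            self, tiny_panel, tiny_barcodes):
        # two probes with identical forward homologies: a barcode+forward
        # fragment cannot be attributed to either
        p0, p1 = tiny_panel.pairs
        twin = tc.ProbePair(
            probe_id="TWIN", junction=p1.junction,
            forward_homology=p0.forward_homology,
            reverse_homology=p1.reverse_homology,
            forward_interval=tc.GenomicInterval(
                "chrT", p1.junction - len(p0.forward_homology), p1.junction),
            reverse_interval=p1.reverse_interval,
        )
        panel = tc.PrimerPanel([p0, twin])
        ref = tc.build_reference(panel, tiny_barcodes[:1])
        frag = tiny_barcodes[0].sequence + panel.forward_tail + p0.forward_homology
        [a] = tc.two_step_assign([("frag", frag)], ref)
        assert a.outcome == OUTCOME_AMBIGUOUS

    def test_random_read_unmapped(self, reference):
        rng = np.random.default_rng(0)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        [a] = tc.two_step_assign([("junk", junk)], reference)
        assert a.outcome == OUTCOME_UNMAPPED

    def test_malformed_record_skipped(self, reference, panel):
        p = reference.full_products[0]
        asn = tc.two_step_assign([("ok", p.sequence), ("bad", "")], reference)
        assert [a.read_id for a in asn] == ["ok"]

    def test_raising_identity_never_adds_product_assignments(
            self, reference, panel):
        prof = tc.flat_profile(panel)
        reads, _ = tc.simulate_library(reference, prof, "BC01", 400,
                                       error_rate=0.03, seed=4)
        counts = []
        for ident in (0.90, 0.95, 0.99, 1.0):
            asn = tc.two_step_assign(reads, reference,
                                     tc.MatchParams(min_identity=ident))
            counts.append(sum(a.outcome == OUTCOME_PRODUCT for a in asn))
        assert counts == sorted(counts, reverse=True)

    def test_fastq_path_input(self, reference, panel, tmp_path):
        prof = tc.flat_profile(panel)
        reads, _ = tc.simulate_library(reference, prof, "BC02", 50, seed=2)
        path = tmp_path / "reads.fastq"
        tc.write_fastq(reads, path)
        asn = tc.two_step_assign(path, reference)
        assert len(asn) == 50
        assert all(a.outcome == OUTCOME_PRODUCT for a in asn)


class TestBruteForceEquivalence:
    def test_two_step_equals_single_pass_on_mixed_reads(self, tiny_panel,
                                                        tiny_barcodes):
        ref = tc.build_reference(tiny_panel, tiny_barcodes)
        prof = tc.flat_profile(tiny_panel)
        reads, _ = tc.simulate_library(ref, prof, "BC01", 150,
                                       off_diagonal_rate=0.1,
                                       truncation_rate=0.1,
                                       error_rate=0.03, seed=9)
        pairs = [(r.id, str(r.seq)) for r in reads]
        params = tc.MatchParams()
        fast = tc.two_step_assign(pairs, ref, params)
        slow = brute_force_assign(pairs, ref, params)
        assert [(a.outcome, a.product_id, a.barcode_id) for a in fast] == \
               [(a.outcome, a.product_id, a.barcode_id) for a in slow]


class TestSplitAndTabulate:
    def test_split_partitions_by_barcode_with_residue(self, reference, panel,
                                                      barcodes):
        prof = tc.flat_profile(panel)
        r1, _ = tc.simulate_library(reference, prof, "BC01", 60, seed=1)
        r2, _ = tc.simulate_library(reference, prof, "BC02", 40, seed=2)
        rev = panel.pairs[0].reverse_homology + panel.reverse_tail
        asn = tc.two_step_assign(
            [(r.id, str(r.seq)) for r in r1 + r2] + [("rev", rev)], reference)
        split = tc.split_by_barcode(asn, [b.barcode_id for b in barcodes])
        assert len(split["BC01"]) == 60
        assert len(split["BC02"]) == 40
        assert len(split[None]) == 1  # the barcode-less reverse fragment

    def test_split_empty_input(self):
        assert tc.split_by_barcode([]) == {}

    def test_tabulate_counts_and_conservation(self, reference):
        a = [
            tc.ReadAssignment("r1", OUTCOME_PRODUCT, "BC01|P0001|P0001", "BC01", 72.0),
            tc.ReadAssignment("r2", OUTCOME_PRODUCT, "BC01|P0001|P0001", "BC01", 72.0),
            tc.ReadAssignment("r3", OUTCOME_PRODUCT, "BC01|P0001|P0001", "BC01", 72.0),
            tc.ReadAssignment("r4", OUTCOME_PRODUCT, "BC01|P0001|P0002", "BC01", 72.0),
            tc.ReadAssignment("r5", OUTCOME_UNMAPPED),
        ]
        table = tc.tabulate(tc.split_by_barcode(a), reference)
        assert table.probe_counts.loc["P0001", "BC01"] == 3
        assert table.categories.loc["off_diagonal", "BC01"] == 1
        assert table.categories.loc["unmapped", RUN_LEVEL] == 1
        assert table.total_reads == 5
        assert table.check_conservation()

    def test_tabulate_empty_is_all_zero(self, reference):
        table = tc.tabulate({}, reference)
        assert table.total_reads == 0
        assert (table.probe_counts.to_numpy() == 0).all()
        assert (table.categories.to_numpy() == 0).all()

    def test_noiseless_tabulation_reproduces_truth(self, reference, panel):
        prof = tc.simulate_profile(panel, n_peaks=3, seed=6)
        reads, truth = tc.simulate_library(reference, prof, "BC01", 800, seed=7)
        asn = tc.two_step_assign(reads, reference)
        table = tc.tabulate(tc.split_by_barcode(asn), reference)
        expected = truth.on_diagonal_probe_counts(reference)
        assert (table.probe_counts["BC01"].loc[expected.index] == expected).all()
        assert table.check_conservation()

    def test_count_table_tsv_round_trip(self, reference, panel, tmp_path):
        prof = tc.flat_profile(panel)
        reads, _ = tc.simulate_library(reference, prof, "BC01", 100,
                                       off_diagonal_rate=0.1, seed=3)
        asn = tc.two_step_assign(reads, reference)
        table = tc.tabulate(tc.split_by_barcode(asn), reference)
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = CountTable.from_tsv(path)
        assert back.total_reads == table.total_reads
        pd.testing.assert_frame_equal(
            back.probe_counts.sort_index(axis=1),
            table.probe_counts.sort_index(axis=1), check_names=False)
        assert list(back.categories.index) == list(CATEGORY_ROWS)
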