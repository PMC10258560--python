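"""Junction filtering, trimming, barcode extraction and clustering."""

import gzip

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tntrace._sequtil import random_dna
from tntrace.errors import FormatError, ValidationError
from tntrace.readprep import (
    PairRecord,
    cluster_barcodes,
    extract_barcode,
    filter_junction_pairs,
    match_terminus,
    tag_umi_and_trim,
)
from tntrace.simulate import FLANK3, FLANK5, TERMINUS, ProtocolProfile

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


def _mutate(seq, positions):
    out = list(seq)
    for i in positions:
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


class TestMatchTerminus:
    def test_exact_terminus_found_at_offset(self):
        seq = "GG" + TERMINUS + "ACGTACGT"
        assert match_terminus(seq, TERMINUS) == 2

    def test_two_mismatches_permitted(self):
        seq = "GG" + _mutate(TERMINUS, [3, 17]) + "ACGT"
        assert match_terminus(seq, TERMINUS, max_mismatches=2) == 2

    def test_three_mismatches_rejected(self):
        seq = "GG" + _mutate(TERMINUS, [3, 17, 25]) + "ACGT"
        assert match_terminus(seq, TERMINUS, max_mismatches=2) is None

    @given(dna, st.text(alphabet="ACGT", min_size=1, max_size=12), st.integers(0, 3))
    def test_equals_bruteforce_window_scan(self, seq, pattern, maxmm):
        expected = None
        for i in range(len(seq) - len(pattern) + 1):
            mm = sum(a != b for a, b in zip(seq[i : i + len(pattern)], pattern))
            if mm <= maxmm:
                expected = i
                break
        assert match_terminus(seq, pattern, maxmm) == expected


def _write_fastq(path, records):
    with gzip.open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'F' * len(seq)}\n")


class TestFilterJunctionPairs:
    def test_mixed_fixture_keeps_only_terminus_pairs(self, tmp_path):
        profile = ProtocolProfile.tnseq()
        rng = np.random.default_rng(0)
        r1, r2 = [], []
        for i in range(10):
            genomic = random_dna(rng, 100)
            if i < 6:  # terminus with 0..2 mismatches
                prefix = _mutate(TERMINUS, list(range(i % 3)))
                seq = prefix + genomic
            else:
                seq = random_dna(rng, 130)
            r1.append((f"r{i}", seq))
            r2.append((f"r{i}", random_dna(rng, 130)))
        _write_fastq(tmp_path / "r1.fq.gz", r1)
        _write_fastq(tmp_path / "r2.fq.gz", r2)
        kept, stats = filter_junction_pairs(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", profile)
        assert len(kept) == 6
        assert stats["terminus_matched"] == 6 and stats["input_r1"] == 10

    def test_orphan_forward_read_dropped_and_counted(self, tmp_path):
        profile = ProtocolProfile.tnseq()
        _write_fastq(tmp_path / "r1.fq.gz", [("a", TERMINUS + "A" * 40)])
        _write_fastq(tmp_path / "r2.fq.gz", [("b", "A" * 40)])
        kept, stats = filter_junction_pairs(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", profile)
        assert kept == [] and stats["orphans"] == 1

    def test_empty_input(self, tmp_path):
        profile = ProtocolProfile.tnseq()
        _write_fastq(tmp_path / "r1.fq.gz", [])
        _write_fastq(tmp_path / "r2.fq.gz", [])
        kept, stats = filter_junction_pairs(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", profile)
        assert kept == [] and stats["input_r1"] == 0

    def test_truncated_record_raises_format_error(self, tmp_path):
        (tmp_path / "r1.fq").write_text("@a\nACGT\n+\n")  # missing quality line
        _write_fastq(tmp_path / "r2.fq.gz", [])
        with pytest.raises(FormatError):
            filter_junction_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq.gz", ProtocolProfile.tnseq())

    def test_low_quality_pair_dropped(self, tmp_path):
        profile = ProtocolProfile.tnseq()
        seq = TERMINUS + "A" * 60
        with gzip.open(tmp_path / "r1.fq.gz", "wt") as fh:
            fh.write(f"@a\n{seq}\n+\n{'#' * len(seq)}\n")
        _write_fastq(tmp_path / "r2.fq.gz", [("a", "A" * 60)])
        kept, stats = filter_junction_pairs(tmp_path / "r1.fq.gz", tmp_path / "r2.fq.gz", profile)
        assert kept == [] and stats["qc_dropped"] == 1


class TestTagAndTrim:
    def test_anchor_mode_trims_through_terminus(self):
        profile = ProtocolProfile.rbtnseq()
        genomic = "ACGTACGTACGT"
        pair = PairRecord("r", "GG" + TERMINUS + genomic, "", "AAACCCGG" + "TTTT", "", 2)
        frag = tag_umi_and_trim(pair, profile, "anchor")
        assert frag.genomic_seq_r1 == genomic
        assert frag.umi == "AAACCCGG" and frag.genomic_seq_r2 == "TTTT"
        assert frag.read_id == "r:AAACCCGG"

    def test_fixed_mode_mirrors_stated_offsets(self):
        profile = ProtocolProfile.tnseq()  # umi_len 9
        r1 = "A" * 100
        r2 = "C" * 100
        frag = tag_umi_and_trim(PairRecord("r", r1, "", r2, "", 0), profile, "fixed", (27, 17))
        assert len(frag.genomic_seq_r1) == 100 - 27
        assert len(frag.genomic_seq_r2) == 100 - 9 - 17
        assert frag.umi == "C" * 9

    def test_short_reverse_read_dropped(self):
        profile = ProtocolProfile.rbtnseq()
        pair = PairRecord("r", TERMINUS + "ACGT", "", "ACG", "", 0)
        assert tag_umi_and_trim(pair, profile) is None


class TestExtractBarcode:
    def test_exact_n20_between_flanks(self):
        bc = "ACGTACGTACGTACGTACGT"
        read = "TT" + FLANK5 + bc + FLANK3 + TERMINUS + "AAAA"
        assert extract_barcode(read, FLANK5, FLANK3) == bc

    def test_off_length_insert_still_extracted(self):
        bc19 = "ACGTACGTACGTACGTACG"
        read = FLANK5 + bc19 + FLANK3 + "AAAA"
        out = extract_barcode(read, FLANK5, FLANK3)
        assert out == bc19 and len(out) != 20  # rejected later by the length filter

    def test_missing_flank5_returns_none(self):
        read = "ACGTACGTACGTACGTACGT" + FLANK3
        assert extract_barcode(read, FLANK5, FLANK3) is None

    def test_mismatch_budget_shared_across_flanks(self):
        bc = "ACGTACGTACGTACGTACGT"
        read = _mutate(FLANK5, [0, 5]) + bc + _mutate(FLANK3, [1, 7]) + "AA"
        assert extract_barcode(read, FLANK5, FLANK3, max_mismatches=4) == bc
        read5 = _mutate(FLANK5, [0, 2, 5]) + bc + _mutate(FLANK3, [1, 7]) + "AA"
        assert extract_barcode(read5, FLANK5, FLANK3, max_mismatches=4) is None


class TestClusterBarcodes:
    def test_near_identical_barcodes_consolidated(self):
        counts = {"A" * 20: 100, "A" * 19 + "T": 5}
        (cl,) = cluster_barcodes(counts, d=2)
        assert cl.center == "A" * 20 and cl.total == 105

    def test_distant_barcodes_stay_separate(self):
        counts = {"A" * 20: 10, "A" * 10 + "T" * 10: 10}
        assert len(cluster_barcodes(counts, d=2)) == 2

    def test_tie_centers_on_lexicographically_smaller(self):
        a, b = "A" * 20, "A" * 19 + "C"
        (cl,) = cluster_barcodes({a: 7, b: 7}, d=1)
        assert cl.center == a

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cluster_barcodes({"AAAA": 1, "AAA": 1})

    @given(st.dictionaries(st.text(alphabet="ACGT", min_size=8, max_size=8),
                           st.integers(1, 50), min_size=1, max_size=30))
    def test_clustering_conserves_reads(self, counts):
        clusters = cluster_barcodes(counts, d=2)
        assert sum(c.total for c in clusters) == sum(counts.values())
        members = [b for c in clusters for b in c.member_counts]
        assert sorted(members) == sorted(counts)

    def test_well_separated_truth_recovered_exactly(self):
        # true barcodes pairwise distance > 2d; raw reads perturbed by <= d
        rng = np.random.default_rng(42)
        truth = []
        while len(truth) < 30:
            cand = random_dna(rng, 20)
            if all(sum(a != b for a, b in zip(cand, t)) > 4 for t in truth):
                truth.append(cand)
        counts, origin = {}, {}
        for t in truth:
            counts[t] = 50
            origin[t] = t
            for _ in range(5):
                k = int(rng.integers(1, 3))
                pos = rng.choice(20, size=k, replace=False)
                raw = _mutate(t, pos)
                counts[raw] = counts.get(raw, 0) + 1
                origin[raw] = t
        clusters = cluster_barcodes(counts, d=2)
        assert len(clusters) == len(truth)
        for cl in clusters:
            assert all(origin[m] == cl.center for m in cl.member_counts)
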