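"""Built-in mapper, SAM import and UMI deduplication."""

import numpy as np
import pytest

import tntrace as tnt
from tntrace._sequtil import random_dna, revcomp
from tntrace.errors import FormatError
from tntrace.mapping import (
    FragmentAlignment,
    build_index,
    dedup_umi,
    import_sam,
    map_pair,
)
from tntrace.readprep import TaggedFragment
from tntrace.refdata import ReferenceGenome
from tntrace.simulate import ProtocolProfile


def _aln(umi, span=(100, 400), strand="+", read_id=None, chrom="g"):
    return FragmentAlignment(
        read_id=read_id or f"r:{umi}",
        umi=umi,
        barcode_cluster=None,
        chrom=chrom,
        junction_pos=span[0] if strand == "+" else span[1],
        strand=strand,
        span=span,
        insert_size=span[1] - span[0] + 1,
    )


class TestIndex:
    def test_kmer_positions(self):
        g = ReferenceGenome("g", "ACGTACGTAAAA")
        idx = build_index(g, k=4)
        assert idx.lookup("ACGT") == [0, 4]
        assert idx.lookup("TTTT") == []

    def test_k_longer_than_genome_warns_and_is_empty(self):
        g = ReferenceGenome("g", "ACGT")
        with pytest.warns(UserWarning):
            idx = build_index(g, k=10)
        assert idx.lookup("ACGTACGTAC") == []


def _pair_from_genome(genome, start0, frag_len, umi="AAAACCCC", r1_len=60, r2_len=50):
    frag = genome.sequence[start0 : start0 + frag_len]
    return TaggedFragment(
        read_id=f"r:{umi}", genomic_seq_r1=frag[:r1_len],
        genomic_seq_r2=revcomp(frag)[:r2_len], umi=umi,
    )


class TestMapPair:
    def test_error_free_pair_maps_to_true_junction(self):
        rng = np.random.default_rng(1)
        g = ReferenceGenome("g", random_dna(rng, 5000))
        idx = build_index(g)
        frag = _pair_from_genome(g, 1000, 300)
        aln = map_pair(frag, idx)
        assert aln.junction_pos == 1001 and aln.strand == "+"
        assert aln.span == (1001, 1300) and aln.insert_size == 300

    def test_minus_strand_junction_is_five_prime_end(self):
        rng = np.random.default_rng(2)
        g = ReferenceGenome("g", random_dna(rng, 5000))
        idx = build_index(g)
        frag_seq = g.sequence[1000:1300]
        frag = TaggedFragment(
            read_id="r:AAAACCCC", genomic_seq_r1=revcomp(frag_seq)[:60],
            genomic_seq_r2=frag_seq[:50], umi="AAAACCCC",
        )
        aln = map_pair(frag, idx)
        assert aln.strand == "-" and aln.junction_pos == 1300

    def test_oversized_insert_rejected(self):
        rng = np.random.default_rng(3)
        g = ReferenceGenome("g", random_dna(rng, 5000))
        idx = build_index(g)
        frag = _pair_from_genome(g, 1000, 1500)
        assert map_pair(frag, idx, max_insert=1000) is None
        assert map_pair(frag, idx, max_insert=2000) is not None

    def test_two_copy_repeat_is_ambiguous(self):
        rng = np.random.default_rng(4)
        unit = random_dna(rng, 400)
        pad = random_dna(rng, 500)
        g = ReferenceGenome("g", pad + unit + random_dna(rng, 500) + unit + pad[::-1])
        idx = build_index(g)
        frag = TaggedFragment(
            read_id="r:AAAACCCC", genomic_seq_r1=unit[:60],
            genomic_seq_r2=revcomp(unit[:300])[:50], umi="AAAACCCC",
        )
        assert map_pair(frag, idx) is None

    def test_mismatches_tolerated_up_to_limit(self):
        rng = np.random.default_rng(5)
        g = ReferenceGenome("g", random_dna(rng, 5000))
        idx = build_index(g)
        frag = _pair_from_genome(g, 2000, 300)
        s = list(frag.genomic_seq_r1)
        for i in (25, 30, 35):  # keep the first k-mer seed clean
            s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
        frag.genomic_seq_r1 = "".join(s)
        assert map_pair(frag, idx, max_mismatches_per_read=3) is not None
        assert map_pair(frag, idx, max_mismatches_per_read=2) is None


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:g\tLN:5000\n"


def _sam_line(name, flag, pos, mpos, tlen, seq="A" * 50):
    return (
        f"{name}\t{flag}\t g\t{pos}\t60\t50M\t=\t{mpos}\t{tlen}\t{seq}\t{'F' * len(seq)}\n"
    ).replace("\t g\t", "\tg\t")


class TestImportSam:
    def test_proper_pair_imported(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + _sam_line("r1:ACGTACGTA", 99, 101, 351, 300)
            + _sam_line("r1:ACGTACGTA", 147, 351, 101, -300)
        )
        alns, stats = import_sam(sam, ProtocolProfile.tnseq())
        assert stats["kept"] == 1
        (a,) = alns
        assert a.span == (101, 400) and a.insert_size == 300
        assert a.junction_pos == 101 and a.strand == "+" and a.umi == "ACGTACGTA"

    def test_unmapped_mate_skipped(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + _sam_line("r1:ACGTACGTA", 73, 101, 101, 0))
        alns, stats = import_sam(sam, ProtocolProfile.tnseq())
        assert alns == [] and stats["mate_unmapped"] == 1

    def test_oversized_tlen_skipped(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + _sam_line("r1:ACGTACGTA", 99, 101, 1251, 1200)
            + _sam_line("r1:ACGTACGTA", 147, 1251, 101, -1200)
        )
        alns, stats = import_sam(sam, ProtocolProfile.tnseq())
        assert alns == [] and stats["insert_rejected"] == 1

    def test_missing_umi_suffix_is_error(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + _sam_line("read_without_umi", 99, 101, 351, 300)
            + _sam_line("read_without_umi", 147, 351, 101, -300)
        )
        with pytest.raises(FormatError, match="read_without_umi"):
            import_sam(sam, ProtocolProfile.tnseq())


class TestDedupUmi:
    def test_directional_merge_of_error_umi(self):
        alns = [_aln("AAAAAAAA", read_id=f"a{i}") for i in range(10)]
        alns += [_aln("AAAAAAAT", read_id="b0")]
        assert len(dedup_umi(alns)) == 1  # 10 >= 2*1-1 at distance 1

    def test_distant_umis_stay_separate(self):
        alns = [_aln("AAAAAAAA", read_id=f"a{i}") for i in range(5)]
        alns += [_aln("TTTTTTTT", read_id=f"b{i}") for i in range(5)]
        assert len(dedup_umi(alns)) == 2

    def test_coordinate_is_part_of_the_key(self):
        alns = [_aln("AAAAAAAA", span=(100, 400)), _aln("AAAAAAAA", span=(200, 500))]
        assert len(dedup_umi(alns)) == 2

    def test_count_condition_blocks_merge_of_balanced_umis(self):
        # counts 5 and 5: 5 < 2*5-1, so distance-1 UMIs remain two molecules
        alns = [_aln("AAAAAAAA", read_id=f"a{i}") for i in range(5)]
        alns += [_aln("AAAAAAAT", read_id=f"b{i}") for i in range(5)]
        assert len(dedup_umi(alns)) == 2

    def test_idempotent_and_never_increasing(self):
        rng = np.random.default_rng(0)
        alns = [
            _aln(random_dna(rng, 8), span=(int(s), int(s) + 300), read_id=f"r{i}")
            for i, s in enumerate(rng.integers(1, 50, size=200))
        ]
        once = dedup_umi(alns)
        assert len(once) <= len(alns)
        assert dedup_umi(once) == once

    def test_exact_molecule_recovery_with_pcr_duplicates(
        self, tmp_path, small_genome, small_truth, rb_profile
    ):
        import pandas as pd

        from tests.conftest import expected_molecule_count, run_to_molecules

        genome, _ = small_genome
        sim = tnt.simulate_reads(
            genome, small_truth, rb_profile, 500, tmp_path / "d",
            pcr_duplication=4.0, error_rate=0.0, seed=31,
        )
        assert sim.n_pairs > 500
        _, alignments, molecules = run_to_molecules(sim, genome, rb_profile)
        assert len(alignments) == sim.n_pairs
        truth = pd.read_csv(sim.truth_path, sep="\t")
        # exact up to chance (coordinate, UMI) collisions, which the
        # truth-derived oracle collapses identically
        assert len(molecules) == expected_molecule_count(truth)
        assert abs(len(molecules) - sim.n_molecules) <= 2

    def test_mapper_recovers_true_junctions_on_simulated_reads(
        self, small_sim, small_genome, small_truth, small_molecules
    ):
        import pandas as pd

        _, alignments, _ = small_molecules
        truth = pd.read_csv(small_sim.truth_path, sep="\t")
        expected = {}
        for r in truth.itertuples():
            # forward reads sit on the strand opposite the promoter direction
            expected[r.molecule_id] = (
                r.position if r.orientation == "-" else r.position + 1
            )
        hit = sum(
            1 for a in alignments
            if a.junction_pos == expected[a.read_id.split(".")[2]]
        )
        assert hit / len(alignments) >= 0.999
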