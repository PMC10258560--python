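"""Fragment placement and UMI deduplication.

The built-in mapper is a desk-scale exact-seed + Hamming-extension aligner
with a unique-best requirement: a read places only where exactly one
location attains the minimal mismatch count (ambiguous reads, e.g. from
perfect repeats, are dropped).  Mates must align concordantly — opposite
strands, fragment length within ``max_insert``.  Externally produced SAM/BAM
alignments can be imported instead (``import_sam``), with the UMI recovered
from the read-name suffix after ':'.

Deduplication collapses PCR copies by (coordinate, UMI) using the
directional adjacency rule: within one fragment-coordinate group, UMI ``a``
absorbs UMI ``b`` when they differ at a single base and
``count(a) >= 2 * count(b) - 1``; each connected component of that directed
graph is one molecule.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from ._sequtil import revcomp, seq_to_u8
from .errors import FormatError, ValidationError
from .readprep import TaggedFragment
from .refdata import ReferenceGenome
from .simulate import ProtocolProfile


@dataclass(frozen=True)
class FragmentAlignment:
    """One concordantly placed read pair (pre- or post-dedup)."""

    read_id: str
    umi: str
    barcode_cluster: Optional[str]
    chrom: str
    junction_pos: int  # 1-based genomic position of the forward read's 5'-most base
    strand: str  # strand of the forward read
    span: tuple[int, int]  # fragment, 1-based inclusive
    insert_size: int
    sample: str = ""

    def __post_init__(self):
        if self.insert_size != self.span[1] - self.span[0] + 1:
            raise ValidationError("insert_size inconsistent with fragment span")


class GenomeIndex:
    """Exact k-mer -> genomic positions (0-based) lookup table."""

    def __init__(self, genome: ReferenceGenome, k: int = 20):
        self.genome = genome
        self.k = k
        self.arr = seq_to_u8(genome.sequence)
        self.table: dict[str, list[int]] = defaultdict(list)
        if k > genome.length:
            warnings.warn(
                f"seed length {k} exceeds genome length {genome.length}; index is empty"
            )
            return
        seq = genome.sequence
        for i in range(genome.length - k + 1):
            self.table[seq[i : i + k]].append(i)

    def lookup(self, kmer: str) -> list[int]:
        return self.table.get(kmer, [])


def build_index(genome: ReferenceGenome, k: int = 20) -> GenomeIndex:
    return GenomeIndex(genome, k)


def _place_read(
    seq: str, index: GenomeIndex, max_mismatches: int, n_seeds: int = 4
) -> Optional[tuple[int, str, int]]:
    """Unique best placement of ``seq``: (0-based start, strand, mismatches) or None.

    Seeds are non-overlapping k-mers at offsets 0, k, 2k, ... on both strands;
    each candidate start is scored by full-length Hamming comparison.  Ties
    between distinct placements at the minimal mismatch count are ambiguous.
    """
    k = index.k
    n = len(seq)
    if n < k:
        return None
    garr = index.arr
    L = garr.size
    candidates: dict[tuple[int, str], int] = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        sarr = seq_to_u8(s)
        offsets = [o for o in range(0, min(n - k, (n_seeds - 1) * k) + 1, k)]
        for off in offsets:
            for pos in index.lookup(s[off : off + k]):
                start = pos - off
                if start < 0 or start + n > L:
                    continue
                key = (start, strand)
                if key in candidates:
                    continue
                mm = int(np.count_nonzero(garr[start : start + n] != sarr))
                candidates[key] = mm
    if not candidates:
        return None
    best_mm = min(candidates.values())
    if best_mm > max_mismatches:
        return None
    winners = [key for key, mm in candidates.items() if mm == best_mm]
    if len(winners) != 1:
        return None
    (start, strand) = winners[0]
    return start, strand, best_mm


def map_pair(
    fragment: TaggedFragment,
    index: GenomeIndex,
    max_mismatches_per_read: int = 3,
    max_insert: int = 1000,
) -> Optional[FragmentAlignment]:
    """Concordant unique placement of a tagged pair, or None.

    The junction position is the forward read's 5'-most genomic base: the
    alignment start for '+' placements, the alignment end for '-' placements.
    """
    p1 = _place_read(fragment.genomic_seq_r1, index, max_mismatches_per_read)
    if p1 is None:
        return None
    p2 = _place_read(fragment.genomic_seq_r2, index, max_mismatches_per_read)
    if p2 is None:
        return None
    s1, strand1, _ = p1
    s2, strand2, _ = p2
    if strand1 == strand2:
        return None
    n1 = len(fragment.genomic_seq_r1)
    n2 = len(fragment.genomic_seq_r2)
    if strand1 == "+":
        start = s1 + 1
        end = s2 + n2  # 1-based inclusive end of the mate
        junction = start
    else:
        start = s2 + 1
        end = s1 + n1
        junction = end
    insert = end - start + 1
    if insert <= 0 or insert > max_insert:
        return None
    return FragmentAlignment(
        read_id=fragment.read_id,
        umi=fragment.umi,
        barcode_cluster=fragment.barcode_cluster,
        chrom=index.genome.name,
        junction_pos=junction,
        strand=strand1,
        span=(start, end),
        insert_size=insert,
        sample=fragment.sample,
    )


def map_fragments(
    fragments: Iterable[TaggedFragment],
    index: GenomeIndex,
    max_mismatches_per_read: int = 3,
    max_insert: int = 1000,
) -> tuple[list[FragmentAlignment], dict]:
    out = []
    stats = {"input": 0, "mapped": 0, "unmapped": 0}
    for frag in fragments:
        stats["input"] += 1
        aln = map_pair(frag, index, max_mismatches_per_read, max_insert)
        if aln is None:
            stats["unmapped"] += 1
        else:
            stats["mapped"] += 1
            out.append(aln)
    return out, stats


def import_sam(path, profile: ProtocolProfile, sample: str = "") -> tuple[list[FragmentAlignment], dict]:
    """Import proper pairs from SAM/BAM produced by an external aligner.

    Keeps primary alignments of read 1 in proper pairs with both mates
    mapped and |TLEN| <= max_insert; coordinates convert to 1-based
    inclusive.  The UMI must be the read-name field after the last ':'.
    """
    stats = {"records": 0, "kept": 0, "not_proper": 0, "mate_unmapped": 0, "insert_rejected": 0}
    out: list[FragmentAlignment] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            stats["records"] += 1
            if rec.is_secondary or rec.is_supplementary or not rec.is_read1:
                continue
            if rec.is_unmapped or rec.mate_is_unmapped:
                stats["mate_unmapped"] += 1
                continue
            if not rec.is_proper_pair:
                stats["not_proper"] += 1
                continue
            tlen = abs(rec.template_length)
            if tlen == 0 or tlen > profile.max_insert:
                stats["insert_rejected"] += 1
                continue
            name = rec.query_name
            if ":" not in name:
                raise FormatError(f"read {name!r}: no ':'-separated UMI suffix in name")
            umi = name.rsplit(":", 1)[1]
            if not umi or any(c not in "ACGTN" for c in umi):
                raise FormatError(f"read {name!r}: name suffix {umi!r} is not a UMI")
            frag_start0 = min(rec.reference_start, rec.next_reference_start)
            start = frag_start0 + 1
            end = frag_start0 + tlen
            strand = "-" if rec.is_reverse else "+"
            junction = start if strand == "+" else end
            out.append(
                FragmentAlignment(
                    read_id=name,
                    umi=umi,
                    barcode_cluster=None,
                    chrom=rec.reference_name,
                    junction_pos=junction,
                    strand=strand,
                    span=(start, end),
                    insert_size=tlen,
                    sample=sample,
                )
            )
            stats["kept"] += 1
    return out, stats


def _directional_components(counts: Counter) -> list[list[str]]:
    """Connected components of the directional UMI graph, seeded by count rank."""
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    arrs = {u: seq_to_u8(u) for u in umis}
    visited: set[str] = set()
    components: list[list[str]] = []
    for seed in umis:
        if seed in visited:
            continue
        comp = [seed]
        visited.add(seed)
        queue = [seed]
        while queue:
            a = queue.pop()
            ca = counts[a]
            for b in umis:
                if b in visited:
                    continue
                if int(np.count_nonzero(arrs[a] != arrs[b])) == 1 and ca >= 2 * counts[b] - 1:
                    visited.add(b)
                    comp.append(b)
                    queue.append(b)
        components.append(comp)
    return components


def dedup_umi(alignments: Sequence[FragmentAlignment]) -> list[FragmentAlignment]:
    """One representative alignment per molecule, by coordinate group + UMI network.

    Grouping key is (chrom, fragment span, strand); within each group the
    directional rule merges sequencing-error UMIs into their parent.  The
    representative is the highest-count UMI's earliest-seen read.  Output is
    deterministically ordered by coordinate then UMI.
    """
    groups: dict[tuple, list[FragmentAlignment]] = defaultdict(list)
    for aln in alignments:
        groups[(aln.chrom, aln.span, aln.strand, aln.sample)].append(aln)
    out: list[FragmentAlignment] = []
    for key in sorted(groups):
        alns = groups[key]
        counts = Counter(a.umi for a in alns)
        first_seen: dict[str, FragmentAlignment] = {}
        for a in alns:
            first_seen.setdefault(a.umi, a)
        for comp in _directional_components(counts):
            rep_umi = min(comp, key=lambda u: (-counts[u], u))
            out.append(first_seen[rep_umi])
    out.sort(key=lambda a: (a.chrom, a.span, a.strand, a.umi))
    return out
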