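"""Junction filtering, trimming, UMI tagging and barcode handling.

A read pair enters the pipeline only if its forward read crosses the
transposon-genome junction, i.e. contains the expected transposon terminus
within two mismatches.  The reverse read contributes the UMI (its first
``umi_len`` bases).  For RB libraries the forward-read prefix also carries a
20-nt random barcode between two fixed flanking sequences; raw barcodes are
consolidated by greedy abundance-ranked Hamming clustering (distance 2 by
default), mirroring the error-correction step that merges barcodes differing
only by sequencing errors.

All matching here is substitution-only (Hamming): the simulator's error model
emits no indels, and the downstream contracts are stated in terms of
mismatch counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._sequtil import mean_quality, open_maybe_gzip, revcomp, seq_to_u8, sliding_mismatches
from .errors import FormatError, ValidationError
from .simulate import ProtocolProfile


@dataclass
class TaggedFragment:
    """A read pair reduced to genomic sequence + tags after junction trimming."""

    read_id: str
    genomic_seq_r1: str
    genomic_seq_r2: str
    umi: str
    barcode_raw: Optional[str] = None
    barcode_cluster: Optional[str] = None
    sample: str = ""


@dataclass
class BarcodeCluster:
    center: str
    member_counts: dict
    total: int


class PairRecord(NamedTuple):
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    terminus_offset: int


def match_terminus(seq: str, terminus: str, max_mismatches: int = 2) -> Optional[int]:
    """Leftmost 0-based offset where ``terminus`` matches within ``max_mismatches``.

    Pure Hamming windows — no indels.  Returns None when no window qualifies.
    """
    mm = sliding_mismatches(seq, terminus)
    hits = np.flatnonzero(mm <= max_mismatches)
    return int(hits[0]) if hits.size else None


def _iter_fastq(path):
    with open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: truncated/invalid FASTQ at record {idx}: {exc}")
            idx += 1
            yield rec


def _read_name(title: str) -> str:
    return title.split()[0]


def filter_junction_pairs(
    r1_path,
    r2_path,
    profile: ProtocolProfile,
    max_mismatches: int = 2,
    min_mean_q: float = 15.0,
) -> tuple[list[PairRecord], dict]:
    """Keep pairs whose forward read carries the terminus and whose mate exists.

    Mates are re-synchronised by read name, so unpaired leftovers in either
    file are tolerated (and counted).  Pairs where either mate's mean base
    quality falls below ``min_mean_q`` are dropped (quality filter).
    """
    r2_by_name: dict[str, tuple[str, str]] = {}
    for title, seq, qual in _iter_fastq(r2_path):
        r2_by_name[_read_name(title)] = (seq.upper(), qual)

    stats = {
        "input_r1": 0,
        "input_r2": len(r2_by_name),
        "terminus_matched": 0,
        "paired": 0,
        "orphans": 0,
        "qc_dropped": 0,
        "kept": 0,
    }
    kept: list[PairRecord] = []
    for title, seq, qual in _iter_fastq(r1_path):
        stats["input_r1"] += 1
        seq = seq.upper()
        off = match_terminus(seq, profile.terminus, max_mismatches)
        if off is None:
            continue
        stats["terminus_matched"] += 1
        name = _read_name(title)
        mate = r2_by_name.get(name)
        if mate is None:
            stats["orphans"] += 1
            continue
        stats["paired"] += 1
        seq2, qual2 = mate
        if min(mean_quality(qual), mean_quality(qual2)) < min_mean_q:
            stats["qc_dropped"] += 1
            continue
        kept.append(PairRecord(name, seq, qual, seq2, qual2, off))
        stats["kept"] += 1
    return kept, stats


def tag_umi_and_trim(
    pair: PairRecord,
    profile: ProtocolProfile,
    trim_mode: str = "anchor",
    fixed_offsets: tuple[int, int] = (0, 0),
    sample: str = "",
) -> Optional[TaggedFragment]:
    """UMI-tag and trim one pair; returns None (drop) if a read is too short.

    The UMI is the first ``umi_len`` bases of the reverse read, removed from
    the sequence and appended to the read identifier after a ':' separator.
    ``anchor`` mode trims the forward read through the end of its terminus
    match; ``fixed`` mode removes exactly ``fixed_offsets`` extra bases
    (mirroring fixed-front trimming on positionally fixed amplicons).
    """
    if len(pair.seq2) < profile.umi_len:
        return None
    umi = pair.seq2[: profile.umi_len]
    if trim_mode == "anchor":
        cut1 = pair.terminus_offset + len(profile.terminus)
        cut2 = profile.umi_len
    elif trim_mode == "fixed":
        cut1 = fixed_offsets[0]
        cut2 = profile.umi_len + fixed_offsets[1]
    else:
        raise ValidationError(f"unknown trim_mode {trim_mode!r}")
    if len(pair.seq1) <= cut1 or len(pair.seq2) <= cut2:
        return None
    return TaggedFragment(
        read_id=f"{pair.read_id}:{umi}",
        genomic_seq_r1=pair.seq1[cut1:],
        genomic_seq_r2=pair.seq2[cut2:],
        umi=umi,
        sample=sample,
    )


def extract_barcode(
    forward_seq: str,
    flank5: str,
    flank3: str,
    max_mismatches: int = 4,
    search_revcomp: bool = False,
) -> Optional[str]:
    """Sequence strictly between the two barcode flanks, or None.

    Both flanks are located by leftmost Hamming match with at most
    ``max_mismatches`` substitutions combined across the two flanks.  The
    caller applies the length filter (== 20 nt).  ``search_revcomp``
    additionally tries the reverse-complement strand (off by default; the
    simulator emits forward-strand barcodes only).
    """
    for seq in (forward_seq, revcomp(forward_seq)) if search_revcomp else (forward_seq,):
        mm5 = sliding_mismatches(seq, flank5)
        for i in np.flatnonzero(mm5 <= max_mismatches):
            budget = max_mismatches - int(mm5[i])
            rest_start = int(i) + len(flank5)
            rest = seq[rest_start:]
            mm3 = sliding_mismatches(rest, flank3)
            hits3 = np.flatnonzero(mm3 <= budget)
            if hits3.size:
                j = int(hits3[0])
                return rest[:j]
    return None


def cluster_barcodes(counts: Mapping[str, int], d: int = 2) -> list[BarcodeCluster]:
    """Greedy abundance-ranked consolidation of nearly identical barcodes.

    Barcodes are visited by descending read count (ties lexicographic); each
    joins the first existing cluster whose center lies within Hamming
    distance ``d``, otherwise founds a new cluster.  Deterministic, and
    conserves reads: sum of cluster totals equals sum of input counts.
    """
    if not counts:
        return []
    lengths = {len(b) for b in counts}
    if len(lengths) != 1:
        raise ValidationError(f"mixed barcode lengths in clustering input: {sorted(lengths)}")
    (blen,) = lengths
    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    clusters: list[BarcodeCluster] = []
    centers = np.zeros((0, blen), dtype=np.uint8)
    for bc, n in order:
        arr = seq_to_u8(bc)
        if centers.shape[0]:
            dists = (centers != arr).sum(axis=1)
            hit = np.flatnonzero(dists <= d)
        else:
            hit = np.zeros(0, dtype=int)
        if hit.size:
            cl = clusters[int(hit[0])]
            cl.member_counts[bc] = n
            cl.total += n
        else:
            clusters.append(BarcodeCluster(center=bc, member_counts={bc: n}, total=n))
            centers = np.vstack([centers, arr])
    return clusters


def barcode_assignment(clusters: Sequence[BarcodeCluster]) -> dict[str, str]:
    """Raw barcode -> cluster center mapping."""
    out: dict[str, str] = {}
    for cl in clusters:
        for bc in cl.member_counts:
            out[bc] = cl.center
    return out


def prep_pairs(
    pairs: Iterable[PairRecord],
    profile: ProtocolProfile,
    trim_mode: str = "anchor",
    fixed_offsets: tuple[int, int] = (0, 0),
    sample: str = "",
    cluster_distance: int = 2,
    barcode_mismatches: int = 4,
) -> tuple[list[TaggedFragment], dict]:
    """Tag/trim a batch of junction-filtered pairs; extract + cluster barcodes (RB mode).

    Only barcodes matching the expected length (``profile.barcode_len``) are
    kept; fragments whose barcode is absent or off-length carry
    ``barcode_raw=None``.
    """
    frags: list[TaggedFragment] = []
    stats = {"trimmed": 0, "trim_dropped": 0, "barcode_found": 0, "barcode_rejected": 0}
    for pair in pairs:
        frag = tag_umi_and_trim(pair, profile, trim_mode, fixed_offsets, sample=sample)
        if frag is None:
            stats["trim_dropped"] += 1
            continue
        if profile.mode == "rbtnseq":
            bc = extract_barcode(
                pair.seq1, profile.flank5, profile.flank3, barcode_mismatches
            )
            if bc is not None and len(bc) == profile.barcode_len:
                frag.barcode_raw = bc
                stats["barcode_found"] += 1
            else:
                stats["barcode_rejected"] += 1
        frags.append(frag)
        stats["trimmed"] += 1
    if profile.mode == "rbtnseq":
        counts: dict[str, int] = {}
        for f in frags:
            if f.barcode_raw is not None:
                counts[f.barcode_raw] = counts.get(f.barcode_raw, 0) + 1
        clusters = cluster_barcodes(counts, d=cluster_distance)
        assign = barcode_assignment(clusters)
        for f in frags:
            if f.barcode_raw is not None:
                f.barcode_cluster = assign[f.barcode_raw]
        stats["barcode_clusters"] = len(clusters)
    return frags, stats
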