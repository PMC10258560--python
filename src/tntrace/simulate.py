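"""Synthetic genomes, barcoded insertion populations and paired-end reads.

The generator emulates the amplicon structure of mariner Tn-Seq / RB-Tn-Seq
libraries: the forward read crosses the transposon-genome junction (for RB
libraries it first carries the barcode between its two flanking sequences,
then the 30-nt transposon terminus), and the reverse read begins with a short
unique molecular identifier (UMI) ligated before PCR, followed by genomic
sequence from the far end of the fragment.  PCR duplication re-emits a
molecule (same UMI) a 1 + Poisson(mean-1) number of times, and sequencing
introduces i.i.d. substitution errors per base.

Orientation convention: ``TrueInsertion.orientation`` is the direction the
transposon's outward-facing promoter points along the genome.  Junction reads
run out of the opposite transposon end, so aligned forward reads accumulate
on the strand opposite the promoter direction — the property the orientation
caller inverts downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._sequtil import revcomp, random_dna
from .errors import ValidationError
from .refdata import GeneFeature, ReferenceGenome, TASiteIndex, index_ta_sites

#: 30-nt transposon terminus crossed by every junction read (2 mismatches
#: tolerated downstream when filtering).
TERMINUS = "CAGACCGGGGACTTATCAGCCAACCTGTTA"
#: Barcode flanking sequences for RB libraries (barcode extraction anchors).
FLANK5 = "GATGTCCACGAGGTCTCT"
FLANK3 = "GCCGGCCGTCGACCTGCAGCGTACG"


@dataclass(frozen=True)
class ProtocolProfile:
    """Library-structure constants for one protocol.

    ``umi_len`` defaults to 9 for plain Tn-Seq and 8 for RB-Tn-Seq (the RB
    adapter carries an 8N UMI; the extra base in the plain protocol is a
    ligation-scar base kept with the UMI).
    """

    mode: str = "rbtnseq"
    terminus: str = TERMINUS
    flank5: str = FLANK5
    flank3: str = FLANK3
    barcode_len: int = 20
    umi_len: int | None = None
    read_len: int = 150
    max_insert: int = 1000
    min_insert: int | None = None

    def __post_init__(self):
        if self.mode not in ("tnseq", "rbtnseq"):
            raise ValidationError(f"unknown protocol mode {self.mode!r}")
        if self.umi_len is None:
            object.__setattr__(self, "umi_len", 8 if self.mode == "rbtnseq" else 9)
        if self.min_insert is None:
            object.__setattr__(self, "min_insert", self.read_len)
        if self.barcode_len <= 0 or self.umi_len <= 0:
            raise ValidationError("barcode_len and umi_len must be positive")
        if self.read_len <= len(self.terminus):
            raise ValidationError("read_len must exceed the terminus length")

    @property
    def prefix(self) -> str:
        """Fixed forward-read prefix up to the first genomic base (sans barcode)."""
        return self.terminus

    def forward_prefix(self, barcode: str | None) -> str:
        if self.mode == "rbtnseq":
            if barcode is None:
                raise ValidationError("rbtnseq read construction requires a barcode")
            return self.flank5 + barcode + self.flank3 + self.terminus
        return self.terminus

    @classmethod
    def tnseq(cls, **kw) -> "ProtocolProfile":
        return cls(mode="tnseq", **kw)

    @classmethod
    def rbtnseq(cls, **kw) -> "ProtocolProfile":
        return cls(mode="rbtnseq", **kw)


@dataclass(frozen=True)
class TrueInsertion:
    """Ground-truth insertion: TA position, promoter direction, lineage barcode, abundance."""

    position: int
    orientation: str
    barcode: str | None
    abundance: float
    founder: int = 0


def simulate_genome(
    length: int,
    n_genes: int,
    gc: float = 0.5,
    seed: int = 0,
    max_resample: int = 20,
) -> tuple[ReferenceGenome, list[GeneFeature]]:
    """Random genome with at least length/50 TA sites plus non-overlapping genes.

    Base composition follows ``gc``; the sequence is resampled (up to
    ``max_resample`` times) if the TA-site guarantee fails, which effectively
    rejects extreme compositions.
    """
    if length < 1000:
        raise ValidationError("genome length must be >= 1000")
    if not (0 < gc < 1):
        raise ValidationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    need = length // 50
    seq = None
    for _ in range(max_resample):
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
        cand = arr.tobytes().decode("ascii")
        n_ta = len(index_ta_sites(ReferenceGenome("tmp", cand)))
        if n_ta >= need:
            seq = cand
            break
    if seq is None:
        raise ValidationError(
            f"could not draw a genome with >= {need} TA sites at gc={gc} "
            f"after {max_resample} attempts"
        )
    genome = ReferenceGenome(name="synthetic", sequence=seq)

    features: list[GeneFeature] = []
    occupied: list[tuple[int, int]] = []
    for i in range(n_genes):
        placed = False
        for _ in range(200):
            glen = int(rng.integers(150, min(1200, max(151, length // max(n_genes, 1)))))
            start = int(rng.integers(1, length - glen + 1))
            end = start + glen - 1
            if all(not (start <= e and s <= end) for s, e in occupied):
                strand = "+" if rng.random() < 0.5 else "-"
                features.append(GeneFeature(f"gene{i:04d}", start, end, strand))
                occupied.append((start, end))
                placed = True
                break
        if not placed:
            raise ValidationError(f"infeasible gene packing: placed {i} of {n_genes} genes")
    features.sort(key=lambda f: f.start)
    return genome, features


def _draw_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = random_dna(rng, length)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_population(
    genome: ReferenceGenome,
    ta_index: TASiteIndex,
    n_founders: int,
    insertions_per_founder: int = 1,
    seed: int = 0,
    alpha: float = 1.0,
    barcoded: bool = True,
    barcode_len: int = 20,
    edge_margin: int = 200,
) -> list[TrueInsertion]:
    """Draw founder lineages: one barcode per founder, TA positions without replacement.

    Insertions belonging to the same founder share that founder's barcode (the
    barcode travels with the transposon when it re-hops).  Abundances over the
    whole sample are symmetric-Dirichlet distributed.  TA sites closer than
    ``edge_margin`` to a linear genome end are excluded so that read pairs are
    always constructible.
    """
    rng = np.random.default_rng(seed)
    n_total = n_founders * insertions_per_founder
    eligible = ta_index.positions[
        (ta_index.positions > edge_margin)
        & (ta_index.positions <= genome.length - edge_margin)
    ]
    if n_total > eligible.size:
        raise ValidationError(
            f"requested {n_total} insertions but only {eligible.size} eligible TA sites"
        )
    positions = rng.choice(eligible, size=n_total, replace=False)
    orientations = rng.choice(np.array(["+", "-"]), size=n_total)
    abundances = rng.dirichlet(np.full(n_total, alpha))
    barcodes = _draw_barcodes(rng, n_founders, barcode_len) if barcoded else [None] * n_founders
    out = []
    for i in range(n_total):
        f = i // insertions_per_founder
        out.append(
            TrueInsertion(
                position=int(positions[i]),
                orientation=str(orientations[i]),
                barcode=barcodes[f],
                abundance=float(abundances[i]),
                founder=f,
            )
        )
    return out


def simulate_selection(
    truth: Sequence[TrueInsertion],
    ta_index: TASiteIndex,
    target_position: int,
    gain_fraction: float = 0.6,
    jitter_sites: int = 3,
    seed: int = 0,
) -> list[TrueInsertion]:
    """End-point truth after selection: each founder gains an insertion near a target locus.

    Models the convergent-adaptation readout: every founder lineage keeps its
    original insertion(s) at reduced abundance (donor-site preservation) and
    acquires a new, selected insertion at a TA site within ``jitter_sites``
    sites of ``target_position``, holding ``gain_fraction`` of the lineage.
    """
    rng = np.random.default_rng(seed)
    i0 = int(np.searchsorted(ta_index.positions, target_position))
    lo = max(0, i0 - jitter_sites)
    hi = min(len(ta_index) - 1, i0 + jitter_sites)
    founders = sorted({t.founder for t in truth})
    out: list[TrueInsertion] = []
    for f in founders:
        mine = [t for t in truth if t.founder == f]
        total0 = sum(t.abundance for t in mine)
        site = int(ta_index.positions[int(rng.integers(lo, hi + 1))])
        orient = "+" if rng.random() < 0.5 else "-"
        for t in mine:
            out.append(
                TrueInsertion(
                    position=t.position,
                    orientation=t.orientation,
                    barcode=t.barcode,
                    abundance=t.abundance / total0 * (1 - gain_fraction) * total0,
                    founder=f,
                )
            )
        out.append(
            TrueInsertion(
                position=site,
                orientation=orient,
                barcode=mine[0].barcode,
                abundance=gain_fraction * total0,
                founder=f,
            )
        )
    norm = sum(t.abundance for t in out)
    return [
        TrueInsertion(t.position, t.orientation, t.barcode, t.abundance / norm, t.founder)
        for t in out
    ]


class SimulatedReads(NamedTuple):
    r1_path: Path
    r2_path: Path
    truth_path: Path
    n_molecules: int
    n_pairs: int


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, error_rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    chars = list(seq)
    for i in pos:
        cur = chars[i]
        alts = [b for b in "ACGT" if b != cur]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    genome: ReferenceGenome,
    truth: Sequence[TrueInsertion],
    profile: ProtocolProfile,
    n_pairs: int,
    out_prefix,
    pcr_duplication: float = 1.0,
    error_rate: float = 0.0,
    seed: int = 0,
    sample: str = "sample1",
    lowq_fraction: float = 0.0,
) -> SimulatedReads:
    """Emit gzip FASTQ read pairs plus a molecule-level truth table (TSV).

    ``n_pairs`` is the number of unique molecules; each is re-emitted
    ``1 + Poisson(pcr_duplication - 1)`` times so the expected total pair
    count is ``n_pairs * pcr_duplication``.  ``lowq_fraction`` of molecules
    are emitted with uniformly low base qualities (Q2) to exercise the
    downstream quality filter; all other bases carry constant Q37.
    """
    if not truth:
        raise ValidationError("truth must be non-empty")
    if pcr_duplication < 1:
        raise ValidationError("pcr_duplication is a mean copy number, must be >= 1")
    rng = np.random.default_rng(seed)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = out_prefix.with_name(out_prefix.name + "_R1.fastq.gz")
    r2_path = out_prefix.with_name(out_prefix.name + "_R2.fastq.gz")
    truth_path = out_prefix.with_name(out_prefix.name + "_truth.tsv")

    ab = np.array([t.abundance for t in truth], dtype=float)
    ab = ab / ab.sum()
    assignment = rng.choice(len(truth), size=n_pairs, p=ab)
    copies = 1 + rng.poisson(max(pcr_duplication - 1.0, 0.0), size=n_pairs)
    lowq = rng.random(n_pairs) < lowq_fraction

    L = genome.length
    seqstr = genome.sequence
    rows = []
    total_pairs = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        for mid in range(n_pairs):
            ins = truth[int(assignment[mid])]
            p = ins.position
            read_strand = "-" if ins.orientation == "+" else "+"
            prefix = profile.forward_prefix(ins.barcode)
            r1_genomic_len = profile.read_len - len(prefix)
            r2_genomic_len = profile.read_len - profile.umi_len
            if read_strand == "+":
                room = L - p + 1
            else:
                room = p + 1
            min_frag = max(profile.min_insert, r1_genomic_len, r2_genomic_len)
            if room < min_frag:
                raise ValidationError(
                    f"insertion at {p} too close to the genome edge for a "
                    f">= {min_frag} nt fragment"
                )
            frag = int(rng.integers(min_frag, min(profile.max_insert, room) + 1))
            if read_strand == "+":
                frag_seq = seqstr[p - 1 : p - 1 + frag]
            else:
                # junction at the A of the TA; fragment extends leftwards
                frag_seq = revcomp(seqstr[p + 1 - frag : p + 1])
            if read_strand == "+":
                span = (p, p + frag - 1)
            else:
                span = (p - frag + 2, p + 1)
            umi = random_dna(rng, profile.umi_len)
            r1 = (prefix + frag_seq[:r1_genomic_len])[: profile.read_len]
            r2 = (umi + revcomp(frag_seq)[:r2_genomic_len])[: profile.read_len]
            qual1 = ("#" if lowq[mid] else "F") * len(r1)
            qual2 = ("#" if lowq[mid] else "F") * len(r2)
            for c in range(int(copies[mid])):
                e1 = _apply_errors(r1, rng, error_rate)
                e2 = _apply_errors(r2, rng, error_rate)
                name = f"SIM.{sample}.M{mid:07d}.{c}"
                f1.write(f"@{name} 1:N:0:1\n{e1}\n+\n{qual1}\n")
                f2.write(f"@{name} 2:N:0:1\n{e2}\n+\n{qual2}\n")
                total_pairs += 1
            rows.append(
                (
                    f"M{mid:07d}",
                    ins.position,
                    ins.orientation,
                    ins.barcode or "",
                    umi,
                    int(copies[mid]),
                    read_strand,
                    span[0],
                    span[1],
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "molecule_id",
            "position",
            "orientation",
            "barcode",
            "umi",
            "copies",
            "read_strand",
            "span_start",
            "span_end",
        ],
    ).to_csv(truth_path, sep="\t", index=False)
    return SimulatedReads(r1_path, r2_path, truth_path, n_pairs, total_pairs)
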