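"""Reference genomes, gene annotations and TA-site indexing.

The mariner (himar1C9) transposase inserts exclusively at TA dinucleotides,
so the "insertion alphabet" of a genome is the index of its TA sites.  All
internal coordinates are 1-based inclusive (GFF3 convention); BED input is
converted at the boundary and BED output converts back.  An insertion site is
keyed by the 1-based position of the T of its TA dinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._sequtil import open_maybe_gzip, seq_to_u8
from .errors import ConfigError, FormatError, ValidationError


@dataclass(frozen=True)
class ReferenceGenome:
    """A single contig: name, uppercase sequence over {A,C,G,T,N}, circular flag."""

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValidationError(f"genome {self.name!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval, 1-based inclusive, with coding strand."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.gene_id!r}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.gene_id!r}: bad strand {self.strand!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class TASiteIndex:
    """Sorted 1-based positions of the T of every TA dinucleotide in a genome."""

    positions: np.ndarray
    genome_length: int = 0

    def __len__(self) -> int:
        return int(self.positions.size)

    def __contains__(self, pos: int) -> bool:
        i = int(np.searchsorted(self.positions, pos))
        return i < self.positions.size and int(self.positions[i]) == pos

    def nearest(self, pos: int) -> tuple[int, int]:
        """Nearest TA site to ``pos`` and its absolute distance.

        Exact ties between an upstream and a downstream site resolve to the
        upstream (smaller-coordinate) site.
        """
        if self.positions.size == 0:
            raise ValidationError("empty TA index")
        i = int(np.searchsorted(self.positions, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < self.positions.size:
                p = int(self.positions[j])
                d = abs(p - pos)
                if best is None or d < best[1] or (d == best[1] and p < best[0]):
                    best = (p, d)
        return best

    def to_bed(self, chrom: str) -> pd.DataFrame:
        """TA sites as a BED frame (0-based half-open, each spanning the TA)."""
        pos = self.positions.astype(int)
        return pd.DataFrame(
            {"chrom": chrom, "start": pos - 1, "end": pos + 1, "name": "TA"}
        )


def read_fasta(path) -> list[ReferenceGenome]:
    """Read a (possibly gzipped) multi-record FASTA into ReferenceGenome objects.

    Sequences are uppercased and U is mapped to T.
    """
    with open_maybe_gzip(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: first record line does not start with '>': {first.strip()!r}")
        fh.seek(0)
        genomes = []
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has no sequence")
            genomes.append(ReferenceGenome(name=rec.id, sequence=seq))
    return genomes


def _features_from_bed(path) -> list[GeneFeature]:
    feats = []
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            start0, end0 = int(cols[1]), int(cols[2])
            if start0 >= end0:
                raise ValidationError(
                    f"{path}:{lineno}: empty/inverted BED interval [{start0}, {end0})"
                )
            name = cols[3] if len(cols) > 3 and cols[3] != "." else f"feature{lineno}"
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+"
            feats.append(GeneFeature(gene_id=name, start=start0 + 1, end=end0, strand=strand))
    return feats


def _gff3_attr(attrs: str, keys=("ID", "Name", "locus_tag", "gene_id")) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            if k in keys:
                return v
    return None


def _features_from_gff3(path, feature_types=("gene",)) -> list[GeneFeature]:
    rows = []
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(cols)} columns, expected 9")
            rows.append((lineno, cols))
    keep = [r for r in rows if r[1][2] in feature_types] or rows
    feats = []
    for lineno, cols in keep:
        gid = _gff3_attr(cols[8]) or f"feature{lineno}"
        strand = cols[6] if cols[6] in ("+", "-") else "+"
        feats.append(GeneFeature(gene_id=gid, start=int(cols[3]), end=int(cols[4]), strand=strand))
    return feats


def read_features(path, format: str = None, genome_length: int | None = None) -> list[GeneFeature]:
    """Read gene features from GFF3 or BED into the 1-based inclusive convention.

    A BED interval [10, 20) becomes start=11, end=20.  ``format`` defaults from
    the file suffix.  If ``genome_length`` is given, any feature extending past
    it raises a ValidationError naming the feature.
    """
    if format is None:
        suffix = Path(str(path)).name.lower()
        format = "bed" if ".bed" in suffix else "gff3"
    if format == "bed":
        feats = _features_from_bed(path)
    elif format in ("gff", "gff3"):
        feats = _features_from_gff3(path)
    else:
        raise ConfigError(f"unknown annotation format {format!r} (expected 'gff3' or 'bed')")
    seen = set()
    for f in feats:
        if f.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {f.gene_id!r} in {path}")
        seen.add(f.gene_id)
        if genome_length is not None and f.end > genome_length:
            raise ValidationError(
                f"feature {f.gene_id!r} [{f.start},{f.end}] exceeds genome length {genome_length}"
            )
    return feats


def index_ta_sites(genome: ReferenceGenome) -> TASiteIndex:
    """Index every TA dinucleotide; circular genomes also check the end->start junction.

    N bases never participate in TA sites (only literal T followed by A counts).
    """
    s = seq_to_u8(genome.sequence)
    t, a = ord("T"), ord("A")
    mask = (s[:-1] == t) & (s[1:] == a)
    pos = np.flatnonzero(mask) + 1  # 1-based T position
    if genome.circular and genome.length >= 2 and s[-1] == t and s[0] == a:
        pos = np.append(pos, genome.length)
    return TASiteIndex(positions=pos.astype(np.int64), genome_length=genome.length)


def write_fasta(path, genomes: Iterable[ReferenceGenome], width: int = 80) -> None:
    with open_maybe_gzip(path, "wt") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def write_gff3(path, features: Sequence[GeneFeature], chrom: str) -> None:
    with open_maybe_gzip(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{chrom}\ttntrace\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.gene_id}\n"
            )
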