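"""Insertion spectra, transposon orientation, peak calling, gene annotation.

A deduplicated fragment's junction position is snapped to the nearest TA
site within a small tolerance (mariner inserts only at TA; junction reads on
the '-' strand start one base into the dinucleotide, and small discrepancies
arise from soft edges in real alignments).  Counts are kept stranded; the
transposon's outward-facing promoter points opposite to the strand on which
junction reads accumulate.

Peak calling follows the local-Poisson model familiar from coverage-based
peak callers: a sliding window's pileup is tested against the maximum of the
genome-wide and local (5 kb / 10 kb) background rates with an upper-tail
Poisson survival probability, Benjamini-Hochberg corrected across all tested
windows, and adjacent significant windows are merged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .enrichment import bh_adjust
from .errors import ValidationError
from .mapping import FragmentAlignment
from .refdata import GeneFeature, TASiteIndex


@dataclass
class InsertionSpectrum:
    """Per-position deduplicated insertion counts for one sample (stranded)."""

    sample: str
    counts: dict  # (chrom, ta_position, strand) -> molecule count
    total_mapped: int
    off_ta: int = 0
    off_ta_positions: dict = field(default_factory=dict)

    @property
    def normalized(self) -> dict:
        if self.total_mapped == 0:
            return {}
        return {k: v / self.total_mapped for k, v in self.counts.items()}

    def site_counts(self) -> dict:
        """Strand-collapsed counts keyed by (chrom, position)."""
        out: dict[tuple[str, int], int] = defaultdict(int)
        for (chrom, pos, _), n in self.counts.items():
            out[(chrom, pos)] += n
        return dict(out)

    def site_fractions(self) -> dict:
        if self.total_mapped == 0:
            return {}
        return {k: v / self.total_mapped for k, v in self.site_counts().items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (chrom, pos, strand, n, n / self.total_mapped if self.total_mapped else 0.0)
            for (chrom, pos, strand), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "position", "strand", "count", "fraction"])

    def to_bedgraph(self, path) -> None:
        """Normalized strand-collapsed coverage as bedGraph (0-based half-open)."""
        sites = sorted(self.site_counts().items())
        with open(path, "w") as fh:
            for (chrom, pos), n in sites:
                frac = n / self.total_mapped if self.total_mapped else 0.0
                fh.write(f"{chrom}\t{pos - 1}\t{pos + 1}\t{frac:.6g}\n")


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    pileup: int
    fold_enrichment: float
    p: float
    q: float
    nearest_gene: Optional[str] = None
    distance: Optional[int] = None


@dataclass(frozen=True)
class OrientationCall:
    promoter_strand: str  # '+', '-' or 'ambiguous'
    plus_reads: int
    minus_reads: int

    @property
    def minority_fraction(self) -> float:
        total = self.plus_reads + self.minus_reads
        if total == 0:
            return 0.0
        return min(self.plus_reads, self.minus_reads) / total


def build_spectrum(
    molecules: Sequence[FragmentAlignment],
    ta_index: TASiteIndex,
    snap_tolerance: int = 2,
    sample: str = "sample",
) -> InsertionSpectrum:
    """Snap deduplicated junctions to TA sites and tally per-site molecule counts.

    Junctions with no TA site within ``snap_tolerance`` go to an off-TA
    bucket (tracked, excluded from ``counts`` and ``total_mapped``); exact
    ties snap to the upstream site.
    """
    counts: dict[tuple[str, int, str], int] = defaultdict(int)
    off_ta: dict[tuple[str, int], int] = defaultdict(int)
    total = 0
    for aln in molecules:
        site, dist = ta_index.nearest(aln.junction_pos)
        if dist <= snap_tolerance:
            counts[(aln.chrom, site, aln.strand)] += 1
            total += 1
        else:
            off_ta[(aln.chrom, aln.junction_pos)] += 1
    return InsertionSpectrum(
        sample=sample,
        counts=dict(counts),
        total_mapped=total,
        off_ta=sum(off_ta.values()),
        off_ta_positions=dict(off_ta),
    )


def infer_orientation(spectrum: InsertionSpectrum) -> dict:
    """Per-site promoter direction from the strand of junction-read accumulation.

    Reads pile up on the side opposite the outward-facing promoter, so
    all-'+' reads mean the promoter faces '-'.  A 50/50 strand split is
    ambiguous; otherwise the majority strand decides and the minority
    fraction is reported alongside.
    """
    by_site: dict[tuple[str, int], dict[str, int]] = defaultdict(lambda: {"+": 0, "-": 0})
    for (chrom, pos, strand), n in spectrum.counts.items():
        by_site[(chrom, pos)][strand] += n
    calls = {}
    for site, sc in by_site.items():
        plus, minus = sc["+"], sc["-"]
        if plus == minus:
            promoter = "ambiguous"
        elif plus > minus:
            promoter = "-"
        else:
            promoter = "+"
        calls[site] = OrientationCall(promoter, plus, minus)
    return calls


def _window_sums(pos_counts: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    csum = np.concatenate([[0], np.cumsum(pos_counts)])
    L = pos_counts.size
    lo = np.clip(starts, 0, L)
    hi = np.clip(starts + width, 0, L)
    return csum[hi] - csum[lo]


def call_peaks(
    spectrum: InsertionSpectrum,
    genome_length: int,
    window: int = 200,
    q_max: float = 0.01,
    step: Optional[int] = None,
    local_windows: tuple[int, int] = (5000, 10000),
    lambda_floor: float = 1e-6,
) -> list[Peak]:
    """Sliding-window Poisson peak calling against a local background.

    Each window's background rate is max(genome-wide, 5 kb, 10 kb local)
    scaled to the window width and floored at ``lambda_floor``; p-values are
    upper-tail Poisson survival probabilities, BH-adjusted across all tested
    windows.  Adjacent/overlapping significant windows are merged; the summit
    is the maximum-count position; fold enrichment is pileup over the local
    rate of the peak's best window.
    """
    if spectrum.total_mapped == 0 or not spectrum.counts:
        return []
    chroms = {chrom for (chrom, _, _) in spectrum.counts}
    if len(chroms) != 1:
        raise ValidationError("call_peaks expects a single-chromosome spectrum")
    (chrom,) = chroms
    step = step or max(window // 2, 1)

    pos_counts = np.zeros(genome_length, dtype=np.int64)  # index = position - 1
    for (_, pos, _), n in spectrum.counts.items():
        pos_counts[pos - 1] += n
    total = spectrum.total_mapped

    starts = np.arange(0, max(genome_length - window, 0) + 1, step)
    pileups = _window_sums(pos_counts, starts, window)
    lam_genome = total * window / genome_length
    centers = starts + window // 2
    lams = np.full(starts.size, lam_genome)
    for w in local_windows:
        local = _window_sums(pos_counts, centers - w // 2, w)
        width = np.clip(centers + w // 2, 0, genome_length) - np.clip(
            centers - w // 2, 0, genome_length
        )
        lams = np.maximum(lams, local * window / np.maximum(width, 1))
    lams = np.maximum(lams, lambda_floor)

    pvals = sstats.poisson.sf(pileups - 1, lams)
    qvals = bh_adjust(pvals)
    sig = np.flatnonzero((qvals <= q_max) & (pileups > 0))
    if sig.size == 0:
        return []

    peaks: list[Peak] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        s = int(starts[run_idx[0]]) + 1
        e = int(min(starts[run_idx[-1]] + window, genome_length))
        region = pos_counts[s - 1 : e]
        summit = s + int(np.argmax(region))
        best = max(run_idx, key=lambda i: pileups[i])
        fold = float(pileups[best] / max(lams[best], lambda_floor))
        peaks.append(
            Peak(
                chrom=chrom,
                start=s,
                end=e,
                summit=summit,
                pileup=int(pileups[best]),
                fold_enrichment=fold,
                p=float(min(pvals[i] for i in run_idx)),
                q=float(min(qvals[i] for i in run_idx)),
            )
        )

    for i in sig:
        if run and starts[i] - (starts[run[-1]] + window) > 0:
            flush(run)
            run = []
        run.append(int(i))
    if run:
        flush(run)
    return peaks


def nearest_gene(peak: Peak, features: Sequence[GeneFeature]) -> tuple[str, int]:
    """Closest gene to a peak with a signed distance.

    Distance 0 on overlap; otherwise the gap to the closest feature edge,
    negative when the peak lies 5' of the feature on its coding strand
    (upstream of a '+' gene, or downstream coordinate-wise of a '-' gene).
    Exact ties resolve to the lexicographically smallest gene_id.
    """
    if not features:
        raise ValidationError("nearest_gene requires a non-empty annotation")
    best: tuple[int, str, int] | None = None  # (|distance|, gene_id, signed)
    for f in features:
        if f.overlaps(peak.start, peak.end):
            cand = (0, f.gene_id, 0)
        elif peak.end < f.start:
            gap = f.start - peak.end
            cand = (gap, f.gene_id, -gap if f.strand == "+" else gap)
        else:
            gap = peak.start - f.end
            cand = (gap, f.gene_id, gap if f.strand == "+" else -gap)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return best[1], best[2]


def annotate_peaks(peaks: Sequence[Peak], features: Sequence[GeneFeature]) -> list[Peak]:
    for p in peaks:
        gid, dist = nearest_gene(p, features)
        p.nearest_gene = gid
        p.distance = dist
    return list(peaks)


def peaks_to_dataframe(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.chrom,
                p.start,
                p.end,
                p.summit,
                p.pileup,
                p.fold_enrichment,
                p.p,
                p.q,
                p.nearest_gene or "",
                p.distance if p.distance is not None else "",
            )
            for p in peaks
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "summit",
            "pileup",
            "fold_enrichment",
            "p",
            "q",
            "nearest_gene",
            "distance",
        ],
    )
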