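"""Barcode-defined lineage reconstruction across time points.

In RB-Tn-Seq, the transposon's random barcode travels with it when it
re-hops, so samples from different time points that contain the same barcode
belong to one lineage.  Pooled sequencing runs are demultiplexed by barcode
cluster; per-lineage insertion spectra are renormalized within the lineage so
pooled depth differences do not distort longitudinal comparisons.  The
earliest time point defines the lineage's founder insertion(s); end-point
spectra reveal donor-site preservation, multisite lineages, convergent loci
shared across independent lineages, and cross-well contamination (end-point
molecules carrying a barcode that belongs to another replicate's founder).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .insertions import InsertionSpectrum, build_spectrum
from .mapping import FragmentAlignment
from .refdata import TASiteIndex


@dataclass
class Lineage:
    barcode_center: str
    spectra: dict  # time point -> InsertionSpectrum (renormalized within lineage)
    founder_sites: list = field(default_factory=list)  # [(position, fraction)]
    flags: set = field(default_factory=set)

    @property
    def timepoints(self) -> list:
        return sorted(self.spectra)


@dataclass(frozen=True)
class ConvergenceReport:
    chrom: str
    start: int
    end: int
    lineages_supporting: tuple

    @property
    def n_lineages(self) -> int:
        return len(self.lineages_supporting)


@dataclass(frozen=True)
class ContaminationEvent:
    replicate: str
    barcode: str
    n_molecules: int
    source_replicate: Optional[str]


def demultiplex(
    molecules_by_sample: Mapping[str, Sequence[FragmentAlignment]],
    sample_manifest: Mapping[str, object],
    ta_index: TASiteIndex,
    snap_tolerance: int = 2,
) -> tuple[dict, list]:
    """Split pooled molecules into barcode-keyed lineages with per-timepoint spectra.

    Every molecule with a barcode cluster lands in exactly one lineage;
    molecules without barcodes are returned separately (the "unassigned"
    pool).  Samples sharing a manifest time point are merged.  A sample
    absent from the manifest is an error.
    """
    for sample in molecules_by_sample:
        if sample not in sample_manifest:
            raise ValidationError(f"sample {sample!r} missing from the sample manifest")
    unassigned: list[FragmentAlignment] = []
    pools: dict[tuple[str, object], list[FragmentAlignment]] = defaultdict(list)
    for sample, mols in molecules_by_sample.items():
        tp = sample_manifest[sample]
        for m in mols:
            if m.barcode_cluster is None:
                unassigned.append(m)
            else:
                pools[(m.barcode_cluster, tp)].append(m)
    timepoints = sorted(set(sample_manifest.values()))
    earliest = timepoints[0] if timepoints else None
    lineages: dict[str, Lineage] = {}
    for (bc, tp), mols in sorted(pools.items()):
        lin = lineages.setdefault(bc, Lineage(barcode_center=bc, spectra={}))
        lin.spectra[tp] = build_spectrum(
            mols, ta_index, snap_tolerance=snap_tolerance, sample=f"{bc}@{tp}"
        )
    for lin in lineages.values():
        first = lin.spectra.get(earliest)
        if first is None or first.total_mapped == 0:
            lin.flags.add("ambiguous_founder")
    return lineages, unassigned


def identify_founder(lineage: Lineage, min_fraction: float = 0.5) -> list:
    """Founder sites: positions holding >= min_fraction of the earliest spectrum.

    Typically a single site; multiple qualifying sites are allowed (multicopy
    loci).  No qualifying site sets the ``ambiguous_founder`` flag and
    returns an empty list.
    """
    tps = lineage.timepoints
    if not tps:
        lineage.flags.add("ambiguous_founder")
        return []
    first = lineage.spectra[tps[0]]
    if first.total_mapped == 0:
        lineage.flags.add("ambiguous_founder")
        return []
    founders = [
        (pos, frac)
        for (_, pos), frac in sorted(
            first.site_fractions().items(), key=lambda kv: -kv[1]
        )
        if frac >= min_fraction
    ]
    lineage.founder_sites = founders
    if not founders:
        lineage.flags.add("ambiguous_founder")
    return founders


def barcode_counts(molecules: Sequence[FragmentAlignment]) -> dict[str, int]:
    """Molecule count per barcode cluster (barcode-less molecules ignored)."""
    return dict(Counter(m.barcode_cluster for m in molecules if m.barcode_cluster))


def detect_contamination(
    endpoint_counts_by_replicate: Mapping[str, Mapping[str, int]],
    replicate_manifest: Mapping[str, Sequence[str]],
    min_reads: int = 10,
) -> list[ContaminationEvent]:
    """Flag replicates whose end-point molecules carry foreign founder barcodes.

    A replicate is flagged when at least ``min_reads`` end-point molecules
    carry a barcode cluster absent from its expected founder set (from the
    t=0 sequencing).  When the foreign barcode matches another replicate's
    founder set, that replicate is reported as the likely source.
    """
    events: list[ContaminationEvent] = []
    expected = {rep: set(bcs) for rep, bcs in replicate_manifest.items()}
    for rep in sorted(endpoint_counts_by_replicate):
        own = expected.get(rep, set())
        for bc, n in sorted(endpoint_counts_by_replicate[rep].items()):
            if bc in own or n < min_reads:
                continue
            source = next(
                (r for r in sorted(expected) if r != rep and bc in expected[r]), None
            )
            events.append(ContaminationEvent(rep, bc, int(n), source))
    return events


def find_convergent_loci(
    lineages: Mapping[str, Lineage],
    window: int = 1000,
    min_lineages: int = 2,
    min_fraction: float = 0.05,
    multisite_fraction: float = 0.2,
) -> tuple[list[ConvergenceReport], dict]:
    """Windows of the genome where independent lineages converge at end-point.

    End-point spectra are binned into ``window``-nt windows; a lineage
    supports a window when it places >= ``min_fraction`` of its end-point
    molecules there.  Windows supported by >= ``min_lineages`` lineages are
    reported.  Per-lineage annotations also flag donor-site retention (the
    founder site still holds >= ``min_fraction`` at end-point) and multisite
    lineages (>= 2 windows each >= ``multisite_fraction`` at end-point).
    """
    support: dict[tuple[str, int], list[str]] = defaultdict(list)
    annotations: dict[str, dict] = {}
    for bc in sorted(lineages):
        lin = lineages[bc]
        tps = lin.timepoints
        if not tps:
            continue
        last = lin.spectra[tps[-1]]
        bins: dict[tuple[str, int], float] = defaultdict(float)
        for (chrom, pos), frac in last.site_fractions().items():
            bins[(chrom, (pos - 1) // window)] += frac
        for key, frac in bins.items():
            if frac >= min_fraction:
                support[key].append(bc)
        donor_retained = False
        if lin.founder_sites:
            chroms = {c for (c, _) in last.site_fractions()} or {""}
            for fpos, _ in lin.founder_sites:
                fbin = (fpos - 1) // window
                for chrom in chroms:
                    if bins.get((chrom, fbin), 0.0) >= min_fraction:
                        donor_retained = True
        multisite = sum(1 for f in bins.values() if f >= multisite_fraction) >= 2
        annotations[bc] = {"donor_retained": donor_retained, "multisite": multisite}
        if multisite:
            lin.flags.add("multisite")
    reports = [
        ConvergenceReport(
            chrom=chrom,
            start=b * window + 1,
            end=(b + 1) * window,
            lineages_supporting=tuple(sorted(bcs)),
        )
        for (chrom, b), bcs in sorted(support.items())
        if len(bcs) >= min_lineages
    ]
    return reports, annotations


def lineage_trace_table(lineages: Mapping[str, Lineage]) -> pd.DataFrame:
    """Long-format lineage traces: (barcode, time_point, chrom, position, fraction)."""
    rows = []
    for bc in sorted(lineages):
        lin = lineages[bc]
        for tp in lin.timepoints:
            spec = lin.spectra[tp]
            for (chrom, pos), frac in sorted(spec.site_fractions().items()):
                rows.append((bc, tp, chrom, pos, frac))
    return pd.DataFrame(
        rows, columns=["barcode", "time_point", "chrom", "position", "fraction"]
    )
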