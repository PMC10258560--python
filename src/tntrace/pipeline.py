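"""End-to-end orchestration and TSV/JSON interchange.

``run_pipeline`` executes simulate -> readprep -> mapping -> dedup ->
spectra/peaks and, when two time points are configured, differential
enrichment and lineage reconstruction.  All tabular outputs are TSV with
fixed column order; re-running with the same config and seed produces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .enrichment import build_count_table, differential_enrichment
from .errors import ConfigError, ValidationError
from .insertions import (
    InsertionSpectrum,
    annotate_peaks,
    build_spectrum,
    call_peaks,
    infer_orientation,
    peaks_to_dataframe,
)
from .lineage import (
    demultiplex,
    find_convergent_loci,
    identify_founder,
    lineage_trace_table,
)
from .mapping import FragmentAlignment, build_index, dedup_umi, map_fragments
from .readprep import filter_junction_pairs, prep_pairs
from .refdata import (
    GeneFeature,
    ReferenceGenome,
    index_ta_sites,
    read_fasta,
    read_features,
    write_fasta,
    write_gff3,
)
from .simulate import (
    ProtocolProfile,
    simulate_genome,
    simulate_population,
    simulate_reads,
    simulate_selection,
)

ALIGNMENT_COLUMNS = [
    "read_id",
    "umi",
    "barcode_cluster",
    "chrom",
    "junction_pos",
    "strand",
    "start",
    "end",
    "insert_size",
    "sample",
]


def alignments_to_tsv(alignments: Sequence[FragmentAlignment], path) -> None:
    rows = [
        (
            a.read_id,
            a.umi,
            a.barcode_cluster or "",
            a.chrom,
            a.junction_pos,
            a.strand,
            a.span[0],
            a.span[1],
            a.insert_size,
            a.sample,
        )
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def alignments_from_tsv(path) -> list[FragmentAlignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"barcode_cluster": str})
    return [
        FragmentAlignment(
            read_id=str(r.read_id),
            umi=str(r.umi),
            barcode_cluster=str(r.barcode_cluster) or None,
            chrom=str(r.chrom),
            junction_pos=int(r.junction_pos),
            strand=str(r.strand),
            span=(int(r.start), int(r.end)),
            insert_size=int(r.insert_size),
            sample=str(r.sample),
        )
        for r in df.itertuples()
    ]


def spectrum_to_tsv(spectrum: InsertionSpectrum, path) -> None:
    spectrum.to_dataframe().to_csv(path, sep="\t", index=False)


def spectrum_from_tsv(path, sample: str = "sample") -> InsertionSpectrum:
    df = pd.read_csv(path, sep="\t")
    counts = {
        (str(r.chrom), int(r.position), str(r.strand)): int(r.count)
        for r in df.itertuples()
    }
    return InsertionSpectrum(sample=sample, counts=counts, total_mapped=sum(counts.values()))


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the documented per-stage defaults."""

    mode: str = "rbtnseq"
    seed: Optional[int] = None
    outdir: str = "tntrace_out"
    # simulation (used when fastq inputs are not given)
    simulate: bool = True
    genome_length: int = 100_000
    n_genes: int = 40
    gc: float = 0.5
    n_founders: int = 3
    insertions_per_founder: int = 2
    n_pairs: int = 50_000
    pcr_duplication: float = 1.0
    error_rate: float = 0.0
    selection: bool = True  # simulate a selected end point (enables diff + lineage)
    gain_fraction: float = 0.6
    # real inputs
    fastq_r1: Optional[str] = None
    fastq_r2: Optional[str] = None
    genome_fasta: Optional[str] = None
    annotation: Optional[str] = None
    # stage parameters
    read_len: int = 150
    max_insert: int = 1000
    terminus_mismatches: int = 2
    min_mean_q: float = 15.0
    seed_k: int = 20
    max_mismatches_per_read: int = 3
    snap_tolerance: int = 2
    peak_window: int = 200
    peak_q_max: float = 0.01
    count_threshold: int = 128
    founder_min_fraction: float = 0.5
    convergence_window: int = 1000
    convergence_min_fraction: float = 0.05
    run_diff: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in ("tnseq", "rbtnseq"):
            raise ConfigError(f"mode must be tnseq or rbtnseq, got {self.mode!r}")
        if self.simulate and self.seed is None:
            raise ConfigError("seed is required when simulating")
        if not self.simulate:
            if not (self.fastq_r1 and self.fastq_r2 and self.genome_fasta):
                raise ConfigError("fastq_r1, fastq_r2 and genome_fasta required without simulation")
            if self.run_diff and self.selection and not self.annotation:
                raise ConfigError("differential enrichment requires an annotation")
        for name, lo, hi in [
            ("peak_q_max", 0.0, 1.0),
            ("gc", 0.0, 1.0),
            ("founder_min_fraction", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo < v < 1.0) and not (lo < v <= hi):
                raise ConfigError(f"{name}={v} outside ({lo}, {hi}]")

    def profile(self) -> ProtocolProfile:
        return ProtocolProfile(mode=self.mode, read_len=self.read_len, max_insert=self.max_insert)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def process_sample(
    r1_path,
    r2_path,
    genome: ReferenceGenome,
    config: RunConfig,
    sample: str,
    outdir: Path,
    features: Sequence[GeneFeature] | None = None,
):
    """readprep -> map -> dedup -> spectrum -> peaks for one sample; writes TSVs."""
    profile = config.profile()
    ta_index = index_ta_sites(genome)
    pairs, prep_stats = filter_junction_pairs(
        r1_path, r2_path, profile, config.terminus_mismatches, config.min_mean_q
    )
    frags, tag_stats = prep_pairs(pairs, profile, sample=sample)
    index = build_index(genome, config.seed_k)
    alignments, map_stats = map_fragments(
        frags, index, config.max_mismatches_per_read, config.max_insert
    )
    molecules = dedup_umi(alignments)
    spectrum = build_spectrum(molecules, ta_index, config.snap_tolerance, sample=sample)
    peaks = call_peaks(spectrum, genome.length, config.peak_window, config.peak_q_max)
    if features:
        annotate_peaks(peaks, features)
    orientation = infer_orientation(spectrum)

    alignments_to_tsv(molecules, outdir / f"{sample}.dedup.tsv")
    spectrum_to_tsv(spectrum, outdir / f"{sample}.spectrum.tsv")
    spectrum.to_bedgraph(outdir / f"{sample}.spectrum.bedgraph")
    peaks_to_dataframe(peaks).to_csv(outdir / f"{sample}.peaks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (c, pos, call.promoter_strand, call.plus_reads, call.minus_reads)
            for (c, pos), call in sorted(orientation.items())
        ],
        columns=["chrom", "position", "promoter_strand", "plus_reads", "minus_reads"],
    ).to_csv(outdir / f"{sample}.orientation.tsv", sep="\t", index=False)
    stats = {"prep": prep_stats, "tag": tag_stats, "map": map_stats,
             "molecules": len(molecules), "off_ta": spectrum.off_ta}
    with open(outdir / f"{sample}.stats.json", "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    return {
        "molecules": molecules,
        "spectrum": spectrum,
        "peaks": peaks,
        "stats": stats,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a result bundle of key objects."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result: dict = {"outdir": str(outdir)}
    inputs: dict[str, str] = {}

    if config.simulate:
        genome, features = simulate_genome(
            config.genome_length, config.n_genes, config.gc, config.seed
        )
        ta_index = index_ta_sites(genome)
        write_fasta(outdir / "genome.fasta", [genome])
        write_gff3(outdir / "genes.gff3", features, genome.name)
        profile = config.profile()
        truth0 = simulate_population(
            genome,
            ta_index,
            config.n_founders,
            config.insertions_per_founder,
            seed=config.seed,
            barcoded=config.mode == "rbtnseq",
        )
        samples: dict[str, tuple] = {}
        sim0 = simulate_reads(
            genome, truth0, profile, config.n_pairs, outdir / "t0",
            config.pcr_duplication, config.error_rate, seed=config.seed + 1, sample="t0",
        )
        samples["t0"] = sim0
        if config.selection:
            mid = features[len(features) // 2]
            target = int(ta_index.nearest((mid.start + mid.end) // 2)[0])
            truth1 = simulate_selection(
                truth0, ta_index, target, config.gain_fraction, seed=config.seed + 2
            )
            sim1 = simulate_reads(
                genome, truth1, profile, config.n_pairs, outdir / "t1",
                config.pcr_duplication, config.error_rate, seed=config.seed + 3, sample="t1",
            )
            samples["t1"] = sim1
            result["target_position"] = target
        result["truth"] = truth0
    else:
        genomes = read_fasta(config.genome_fasta)
        genome = genomes[0]
        features = (
            read_features(config.annotation, genome_length=genome.length)
            if config.annotation
            else []
        )
        inputs["genome_fasta"] = _sha256(config.genome_fasta)
        samples = {"sample": (config.fastq_r1, config.fastq_r2)}

    processed = {}
    for sample, sim in samples.items():
        if config.simulate:
            r1, r2 = sim.r1_path, sim.r2_path
            inputs[f"{sample}_R1"] = _sha256(r1)
            inputs[f"{sample}_R2"] = _sha256(r2)
        else:
            r1, r2 = sim
            inputs[f"{sample}_R1"] = _sha256(r1)
            inputs[f"{sample}_R2"] = _sha256(r2)
        processed[sample] = process_sample(r1, r2, genome, config, sample, outdir, features)
    result["samples"] = processed

    if config.run_diff and len(processed) == 2 and features:
        s0, s1 = sorted(processed)
        table = build_count_table(processed[s0]["spectrum"], processed[s1]["spectrum"], features)
        diff = differential_enrichment(table, count_threshold=config.count_threshold)
        diff.to_csv(outdir / "differential.tsv", sep="\t")
        result["differential"] = diff

    if config.mode == "rbtnseq" and len(processed) >= 2:
        ta_index = index_ta_sites(genome)
        manifest = {s: s for s in processed}
        lineages, unassigned = demultiplex(
            {s: processed[s]["molecules"] for s in processed}, manifest, ta_index,
            config.snap_tolerance,
        )
        for lin in lineages.values():
            identify_founder(lin, config.founder_min_fraction)
        reports, annotations = find_convergent_loci(
            lineages, config.convergence_window, min_fraction=config.convergence_min_fraction
        )
        lineage_trace_table(lineages).to_csv(outdir / "lineage_traces.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (r.chrom, r.start, r.end, r.n_lineages, ",".join(r.lineages_supporting))
                for r in reports
            ],
            columns=["chrom", "start", "end", "n_lineages", "barcodes"],
        ).to_csv(outdir / "convergence.tsv", sep="\t", index=False)
        result["lineages"] = lineages
        result["convergence"] = reports
        result["lineage_annotations"] = annotations
        result["unassigned"] = len(unassigned)

    manifest = {
        "tntrace_version": __version__,
        "config": asdict(config),
        "input_checksums": inputs,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
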