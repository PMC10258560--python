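# Methods

## Scope and data model

`tntrace` turns paired-end reads from mariner-transposon insertion
libraries into per-TA-site molecule counts and the derived readouts (peaks,
gene-level differential enrichment, barcode lineages).  All internal
coordinates are 1-based inclusive; BED input/output converts at the
boundary.  An insertion site is keyed by the 1-based position of the T of
its TA dinucleotide — the mariner transposase inserts only at TA, so the TA
index of the reference is the complete insertion alphabet.  N bases never
form TA sites; circular genomes additionally test the end→start junction.

## Library structure and read preparation

The forward read crosses the transposon-genome junction.  Its fixed prefix
is, for plain Tn-Seq, the 30-nt transposon terminus
(`CAGACCGGGGACTTATCAGCCAACCTGTTA`), and for RB-Tn-Seq the barcode cassette
followed by the terminus: `flank5 (18 nt) + N20 barcode + flank3 (25 nt) +
terminus`.  The reverse read begins with the UMI ligated before PCR — 8 nt
in the RB protocol, 9 nt in the plain protocol (the extra base is a
ligation-scar base kept with the UMI); both are configurable.

Junction filtering keeps pairs whose forward read contains the terminus at
Hamming distance ≤ 2 (leftmost window; no indels).  Mates are re-paired by
read name, so unpaired leftovers are tolerated and counted.  Pairs with
mean base quality < Q15 on either mate are dropped; the threshold is
configurable, and the simulator exercises it through an explicit
low-quality injection option rather than a full quality model, since
quality modeling is not part of the method.

Trimming is anchor-based by default: the forward read is cut through the
end of its terminus match, which is robust to the exact amplicon geometry;
a fixed-offset mode (e.g. 27/17 for the plain protocol, 30/0 for RB) is
retained for positionally fixed amplicons.  The UMI is removed from the
reverse read and appended to the read identifier after a `:` separator, so
externally aligned BAMs keep the UMI recoverable.

Barcodes are extracted as the sequence strictly between the two flanks,
located by leftmost Hamming matches with ≤ 4 mismatches combined across
both flanks; only length-20 barcodes are kept.  Raw barcodes are
consolidated by greedy abundance-ranked clustering: barcodes are visited by
descending read count (ties lexicographic) and join the first existing
cluster whose center is within Hamming distance 2, else found a new
cluster.  The algorithm is deterministic and conserves reads.  Matching is
substitution-only throughout: the simulator's error model emits no indels,
and the contracts are stated as mismatch counts.

## Mapping and deduplication

The built-in mapper is a desk-scale exact-seed + Hamming-extension aligner:
non-overlapping 20-mers at offsets 0, k, 2k, 3k seed candidate placements
on both strands (multiple seeds so one substitution in the first k-mer does
not lose the read), each candidate is scored by full-length Hamming
comparison, and a read places only if a unique minimum exists — reads
matching two repeat copies equally are dropped as ambiguous.  Mates must
align on opposite strands with fragment length in (0, 1000].  The junction
position is the forward read's 5′-most genomic base.  For real data of any
scale, SAM/BAM from an external aligner can be imported instead; proper
pairs with |TLEN| ≤ 1000 are kept.

PCR duplicates are collapsed by (chromosome, fragment span, strand) groups.
Within a group, UMIs form a directed graph with an edge a→b when they
differ at exactly one base and count(a) ≥ 2·count(b) − 1; each connected
component (built outward from the highest-count UMIs) is one molecule, and
the representative read is the highest-count UMI's earliest-seen alignment.
Output order is deterministic (coordinate, then UMI).

Two true molecules that happen to share a fragment span and draw UMIs at
Hamming distance ≤ 1 are indistinguishable under this rule — for an 8-nt
UMI this occurs roughly once per 10⁴ molecules at typical fragment-length
diversity, which is the accuracy floor of any (coordinate, UMI)
deduplicator.  Tests therefore validate dedup output against an oracle that
applies the same rule to ground-truth (span, UMI, copy-count) records, and
separately report closeness to the raw molecule count.  With 1 %
substitution errors, UMIs carrying ≥ 2 errors form spurious singleton
clusters (distance 2 from their parent, hence unmergeable at distance-1
edges); at mean 5 copies per molecule this inflates the molecule count by
~1 %, a known property of directional UMI collapse at this error rate.

## Spectra, orientation and peaks

Junction positions are snapped to the nearest TA site within 2 nt (ties to
the upstream site — junction reads on the '-' strand start one base into
the dinucleotide, so this tolerance also absorbs soft alignment edges);
molecules without a TA site within tolerance are tracked in an off-TA
bucket, reported, and excluded from peak calling (the simulator guarantees
on-TA truth, and off-TA junctions in real data indicate artifacts).
Normalized spectra divide by the total snapped molecule count.

The transposon's outward-facing promoter points opposite to the strand on
which junction reads accumulate; per site, the majority read strand decides
the orientation, a 50/50 split is flagged ambiguous, and the minority
fraction is reported.

Peak calling mirrors coverage-based peak callers at desk scale: 200-nt
windows sliding by 100 nt are tested against λ_local = max(λ_genome,
λ_5kb, λ_10kb) scaled to the window (floored at 10⁻⁶); p-values are
upper-tail Poisson survival probabilities, Benjamini–Hochberg corrected
across all tested windows, and windows with q ≤ 0.01 are merged into
peaks.  The summit is the maximum-count position; fold enrichment is the
best window's pileup over its local rate.  The 5/10-kb local backgrounds
and the 0.01 q cutoff follow standard peak-caller defaults; the 200-nt
window approximates the fragment scale.  BH across windows is simpler and
more conservative than a peak-caller's internal correction, and is fully
testable: on Poisson-uniform null spectra the mean significant-window count
stays below 0.01 × windows (in practice near zero, since the discrete
Poisson p-values make BH strongly conservative).

Nearest-gene annotation reports distance 0 on overlap, otherwise the gap to
the closest feature edge, negative when the peak lies 5′ of the feature on
its coding strand; exact ties resolve to the lexicographically smallest
gene id (a deterministic stand-in for "one gene name was used").

## Differential enrichment

Molecules are counted per gene over the full annotated span (no 3′-tail
trimming — a deliberate simplification, noted as a difference from Tn
analysis tools that trim gene tails).  Genes with summed start+end counts
< 128 are removed.  Each gene is tested with a two-sided NB exact test
conditioned on its total n: under the null of a common normalized mean, the
probability of the split (a, n−a) is proportional to
NB(a; μ₁, φ)·NB(n−a; μ₂, φ) with μᵢ proportional to library size, and the
two-sided p sums all outcomes no more probable than the observed one.  The
common dispersion φ is estimated across genes by the method of moments on
library-size-rescaled counts, floored at 0.01.  As φ → 0 the conditional
law is Binomial(n, s₂/(s₁+s₂)) — the closed-form limit used as the test
oracle.  Fold changes use library-size-normalized counts with a 0.5
pseudocount per condition; normalization choice is recorded in the output
metadata.  BH adjustment is the standard step-up (delegated to
statsmodels, cross-checked against the hand formula in tests).

## Lineages

Pooled molecules are demultiplexed by barcode cluster; samples sharing a
manifest time point are merged, and per-lineage spectra are renormalized
within the lineage so pooled depth differences do not distort longitudinal
comparisons.  Founder sites are the positions holding ≥ 0.5 of the
earliest time point's molecules (threshold configurable; figures in this
field show near-clonal founders, but multicopy loci can yield several
qualifying sites).  Convergence is windowed at 1 kb rather than
exact-position because independent lineages hit nearby TA sites of the same
locus; a lineage supports a window when ≥ 5 % of its end-point molecules
fall there, and windows supported by ≥ 2 lineages are reported.  Donor-site
retention (founder window still ≥ 5 % at end point) and multisite lineages
(≥ 2 windows each ≥ 20 %) are flagged per lineage.  A replicate is flagged
as contaminated when ≥ 10 end-point molecules carry a barcode cluster
absent from its expected founder set; the source replicate is reported when
the foreign barcode matches another replicate's founders.  The 0.5, 5 %,
20 % and 10-molecule thresholds are exposed configuration keys; they are
package defaults, chosen to be conservative at the simulated depths.

## The simulator

`simulate_genome` draws i.i.d. bases at a given GC content and rejects
(resamples) sequences with fewer than length/50 TA sites, then places
non-overlapping genes on random strands.  `simulate_population` assigns one
barcode per founder (shared by all of that founder's insertions — the
barcode travels with the transposon), samples TA positions without
replacement, and draws abundances from a symmetric Dirichlet(α=1).  TA
sites within 200 nt of a linear genome's ends are excluded so that every
fragment is constructible; fragment lengths are uniform on
[read_len, min(1000, available room)].  `simulate_selection` produces an
end-point truth in which each lineage keeps its donor insertion at reduced
abundance and gains a selected insertion at a TA site near a target locus.
`simulate_reads` emits each molecule 1 + Poisson(mean−1) times with i.i.d.
per-base substitution errors and constant Q37 qualities.

What the generator does **not** emulate: indels, adapter read-through,
quality-score structure, chimeric PCR products, GC-coverage bias, or
multi-contig references.  Passing tests therefore demonstrate correctness
of the algorithms under a substitution-only error model with uniform
fragment sampling — not robustness to every artifact of real libraries;
the SAM import path exists precisely so real data can be aligned with a
production aligner first.

## Problem sizes and determinism

The shipped tests and the acceptance script run, per quantity: the full
pipeline on a 100-kb genome with 3 founders × 2 insertions at 50k read
pairs (error-free recovery) and 10k molecules × mean 5 PCR copies (dedup
fidelity); 200 Poisson-uniform null simulations and 50 spike simulations
for peak calibration; 200 replicates of 500 genes (3 enriched 20×,
NB dispersion 0.05, depth 10⁵ per condition) for power and null FDR; and
50 clean plus 50 injected contamination simulations.  These sizes make the
whole suite run in a few minutes on one CPU while keeping Monte-Carlo error
small relative to the tested margins.  Every stochastic component takes an
explicit seed; identical config + seed reproduces byte-identical outputs.

## Known limitations

- The built-in mapper is substitution-only and unique-best; it is meant for
  simulated and small data, with SAM import as the path for real genomes.
- Whole-genome spectra assume a single contig; multi-contig support is
  limited to independent processing.
- Intra-genome vs. co-resident-lineage disambiguation of multisite
  insertions is out of scope (unresolvable from barcode counts alone).
- Gene essentiality calling and multi-condition GLMs are not implemented.
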