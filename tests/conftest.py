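"""Shared fixtures: small synthetic genomes and simulated read sets."""

import numpy as np
import pytest

import tntrace as tnt
from tntrace.mapping import build_index, dedup_umi, map_fragments
from tntrace.readprep import filter_junction_pairs, prep_pairs

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_genome():
    genome, features = tnt.simulate_genome(20_000, 10, gc=0.5, seed=11)
    return genome, features


@pytest.fixture(scope="session")
def small_ta(small_genome):
    genome, _ = small_genome
    return tnt.index_ta_sites(genome)


@pytest.fixture(scope="session")
def rb_profile():
    return tnt.ProtocolProfile.rbtnseq()


@pytest.fixture(scope="session")
def small_truth(small_genome, small_ta):
    genome, _ = small_genome
    return tnt.simulate_population(genome, small_ta, n_founders=3,
                                   insertions_per_founder=2, seed=7)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory, small_genome, small_truth, rb_profile):
    genome, _ = small_genome
    out = tmp_path_factory.mktemp("sim") / "reads"
    return tnt.simulate_reads(genome, small_truth, rb_profile, n_pairs=2_000,
                              out_prefix=out, seed=13)


def expected_molecule_count(truth_df) -> int:
    """Oracle: molecule count recoverable from ground truth under the stated dedup rule.

    Groups true molecules by (fragment span, read strand) and applies the
    directional UMI rule to their copy counts; molecules indistinguishable by
    (coordinate, UMI) are collapsed, exactly as any deduplicator must.
    """
    from collections import defaultdict

    groups = defaultdict(lambda: defaultdict(int))
    for r in truth_df.itertuples():
        groups[(r.span_start, r.span_end, r.read_strand)][r.umi] += int(r.copies)
    n = 0
    for counts in groups.values():
        umis = sorted(counts, key=lambda u: (-counts[u], u))
        visited = set()
        for seed in umis:
            if seed in visited:
                continue
            n += 1
            stack = [seed]
            visited.add(seed)
            while stack:
                a = stack.pop()
                for b in umis:
                    if b in visited:
                        continue
                    dist = sum(x != y for x, y in zip(a, b))
                    if dist == 1 and counts[a] >= 2 * counts[b] - 1:
                        visited.add(b)
                        stack.append(b)
    return n


def run_to_molecules(sim, genome, profile, **map_kw):
    """Convenience: readprep + map + dedup on a simulated read set."""
    pairs, _ = filter_junction_pairs(sim.r1_path, sim.r2_path, profile)
    frags, _ = prep_pairs(pairs, profile)
    index = build_index(genome)
    alignments, _ = map_fragments(frags, index, **map_kw)
    return frags, alignments, dedup_umi(alignments)


@pytest.fixture(scope="session")
def small_molecules(small_sim, small_genome, rb_profile):
    genome, _ = small_genome
    return run_to_molecules(small_sim, genome, rb_profile)
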