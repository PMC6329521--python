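"""Shared synthetic fixtures.

Everything is generated programmatically at session scope with fixed
seeds so that the closed-loop tests (generator truth vs pipeline
recovery) are cheap to share across modules.
"""
from __future__ import annotations

import pytest

from uvhotspot import synth
from uvhotspot.hotspots import MotifLocus


@pytest.fixture(scope="session")
def genome_trio():
    """Default synthetic genome with planted TTCCG promoters."""
    return synth.gen_genome(synth.SyntheticGenomeSpec(seed=1))


@pytest.fixture(scope="session")
def genome(genome_trio):
    return genome_trio[0]


@pytest.fixture(scope="session")
def tss_list(genome_trio):
    return genome_trio[1]


@pytest.fixture(scope="session")
def planted(genome_trio):
    return genome_trio[2]


@pytest.fixture(scope="session")
def truth_loci(planted):
    """Planted motifs as MotifLocus records (ground-truth anchors)."""
    loci = []
    for p in planted:
        if p.motif_class is None:
            continue
        start = p.motif_start + 2 if p.motif_strand == "+" else p.motif_start
        loci.append(MotifLocus(p.chrom, start, p.motif_strand, p.motif_class,
                               0, ()))
    return loci


@pytest.fixture(scope="session")
def cohort(genome, planted):
    """Default-condition cohort: 221 tumors, UV signature, phi = 300."""
    return synth.gen_cohort(genome, planted, synth.CohortSpec(seed=2))


@pytest.fixture(scope="session")
def cell_library(genome, planted, tmp_path_factory):
    """Cellular CPD-seq library (motif multiplier 10), zero background."""
    path = tmp_path_factory.mktemp("cpd") / "cellular.sam"
    spec = synth.CpdReadSpec(n_fragments=100_000, background_rate=0.0, seed=3)
    truth = synth.gen_cpd_reads(genome, planted, spec, path)
    return path, truth, spec


@pytest.fixture(scope="session")
def naked_library(genome, planted, tmp_path_factory):
    """Naked-DNA control library: motif multiplier 1, zero background."""
    path = tmp_path_factory.mktemp("cpd") / "naked.sam"
    spec = synth.CpdReadSpec(n_fragments=100_000, background_rate=0.0,
                             motif_multiplier=1.0, seed=4)
    truth = synth.gen_cpd_reads(genome, planted, spec, path)
    return path, truth, spec
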