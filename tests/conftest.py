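"""Shared fixtures: a deterministic toy reference and simulated cohorts.

Cohorts are session-scoped and shared across test modules; every group uses
the same reference bundle so group contrasts are not confounded by genome
realization.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from uvscape import synthetic_cohort as sc
from uvscape.classify import assign_gene, records_frame
from uvscape.genome_model import GeneSet, Gene, ReferenceBundle, encode

N_TUMORS = 6
GROUP_SEEDS = {"sporadic": 101, "xpe": 102, "xpc": 103, "xpa": 104, "xpv": 105}


@pytest.fixture(scope="session")
def toy_bundle():
    return sc.build_toy_reference(sc.preset("sporadic"), seed=7)


@pytest.fixture(scope="session")
def cohorts(toy_bundle):
    return {name: sc.simulate_cohort(sc.preset(name), N_TUMORS, seed=seed,
                                     bundle=toy_bundle)
            for name, seed in GROUP_SEEDS.items()}


@pytest.fixture(scope="session")
def frames(cohorts, toy_bundle):
    return {name: assign_gene(records_frame(c.all_records, toy_bundle), toy_bundle)
            for name, c in cohorts.items()}


@pytest.fixture(scope="session")
def small_bundle():
    """Compact genome (120 kb total) for brute-force oracle comparisons."""
    cfg = sc.preset("sporadic")
    cfg.genome.n_contigs = 2
    cfg.genome.contig_length = 60_000
    cfg.genes.n_genes = 2
    cfg.genes.edge_margin = 15_000
    cfg.genes.length_min, cfg.genes.length_max = 6_000, 9_000
    return sc.build_toy_reference(cfg, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    cfg = sc.preset("sporadic")
    cfg.genome.n_contigs = 2
    cfg.genome.contig_length = 60_000
    cfg.genes.n_genes = 2
    return sc.simulate_cohort(cfg, 2, seed=17, bundle=small_bundle)


@pytest.fixture(scope="session")
def ffpe_cohort(toy_bundle):
    """Dose-controlled FFPE cohort: exposure variation off so every sample
    carries labeled doublet classes at the size the per-sample training
    procedure assumes (real genomes supply thousands of labeled doublets;
    the toy genome at a low-exposure draw would starve the calibration)."""
    cfg = sc.preset("sporadic")
    cfg.ffpe.enabled = True
    cfg.lesions.exposure_sigma = 0.0
    return sc.simulate_cohort(cfg, 2, seed=201, bundle=toy_bundle)


@pytest.fixture()
def tiny_bundle():
    """Hand-built two-contig bundle with two genes, for exact unit checks."""
    seq1 = "ACGTACGTTACGTTCCAGGTACCATTAACCGGTTAACCGGATCGATCGAT" * 4  # 200 bp
    seq2 = "TTTTCCCCGGGGAAAATACGTACGTACGTACG" * 5  # 160 bp
    genes = GeneSet([
        Gene("gA", "chr1", "+", 20, 120, expression=10.0),
        Gene("gB", "chr2", "-", 30, 130, expression=2.0),
    ])
    return ReferenceBundle({"chr1": encode(seq1), "chr2": encode(seq2)}, genes)
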