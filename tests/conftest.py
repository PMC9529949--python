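import logging

import numpy as np
import pytest

from errg.genome_io import EnhancerRecord, GeneRecord, GenomicInterval
from errg.synthetic_data import SimConfig, generate_bundle

logging.getLogger("errg").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def demo_bundle():
    """One demo-config synthetic study shared across the suite."""
    return generate_bundle(SimConfig(seed=7))


def random_gene_set(rng, n_genes, n_chrom=2, chrom_length=50_000_000, max_len=50_000):
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, chrom_length))
        genes.append(
            GeneRecord(
                GenomicInterval(chrom, start, start + int(rng.integers(500, max_len))),
                f"G{i}",
                f"G{i}",
                "+" if rng.random() < 0.5 else "-",
                "protein_coding" if rng.random() < 0.6 else "lncRNA",
            )
        )
    return genes


def random_enhancers(rng, resource, n, n_chrom=2, chrom_length=50_000_000):
    records = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chrom + 1)}"
        start = int(rng.integers(0, chrom_length))
        records.append(
            EnhancerRecord(
                GenomicInterval(chrom, start, start + int(rng.integers(100, 2_000))),
                f"{resource}:e{i}",
                resource,
            )
        )
    return records


def random_instance(rng, n_enh_per_resource=5_000, n_genes=1_000, resources=("r1", "r2", "r3", "r4")):
    genes = random_gene_set(rng, n_genes)
    enhancers = {r: random_enhancers(rng, r, n_enh_per_resource) for r in resources}
    return enhancers, genes
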