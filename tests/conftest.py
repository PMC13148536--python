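import numpy as np
import pandas as pd
import pytest

import codonopt as co


@pytest.fixture(scope="session")
def code():
    return co.STANDARD_CODE


@pytest.fixture(scope="session")
def small_world():
    """A scaled-down synthetic world shared by integration-style tests."""
    cfg = co.SimConfig(
        seed=11,
        n_genes={"testis": 120, "ovary": 70, "unbiased": 100, "ribosomal": 60},
        median_codons={"testis": 150, "ovary": 180, "unbiased": 150, "ribosomal": 200},
    )
    return co.simulate(cfg)


@pytest.fixture(scope="session")
def small_classification(small_world):
    """A-priori codon classification computed from the small world's own files."""
    ribo = co.concatenate_counts(small_world.cds["ribosomal"].values(), source="ribo")
    background = co.concatenate_counts(
        [g for genes in small_world.cds.values() for g in genes.values()],
        source="all",
    )
    return co.classify_codons(ribo, background, small_world.trna)


@pytest.fixture(scope="session")
def truth_classification(small_world):
    """Classification fixed to the generator's designated codons."""
    table = co.STANDARD_CODE
    delta = {}
    for aa in table.degenerate_aas:
        for c in table.aa_to_codons[aa]:
            delta[c] = 0.5 if c == small_world.truth.optimal[aa] else -0.1
    cls = co.assign_optimal(delta, table)
    return co.trna_status(small_world.trna, cls)


def make_cds(gene_id, codons):
    return co.CodingSequence(gene_id=gene_id, codons=tuple(codons))


@pytest.fixture
def make_sequence():
    return make_cds
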