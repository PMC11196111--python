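import numpy as np
import pandas as pd
import pytest

from tadakit.gatc import GenomeSequence, find_gatc_sites, build_fragments
from tadakit.synthetic import gen_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb single-contig genome with a handful of genes (session-cached)."""
    genome, genes, truth = gen_genome(length=60_000, seed=7)
    return genome, genes, truth


@pytest.fixture(scope="session")
def recovery_genome():
    """The 500-gene genome used by the DamID spike-in recovery runs."""
    genome, genes, truth = gen_genome(length=500 * 10_000 + 5_000, seed=1)
    assert len(genes) == 500
    return genome, genes, truth


@pytest.fixture()
def toy_fragments():
    sites = find_gatc_sites(GenomeSequence({"c": "GATC" + "A" * 6 + "GATC" + "T" * 6 + "GATC"}))
    return build_fragments(sites)
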