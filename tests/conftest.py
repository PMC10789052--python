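import numpy as np
import pandas as pd
import pytest

from pausekit import simulate
from pausekit.regions import GeneModel


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(seed=11, n_genes=60, library_size=200_000)


@pytest.fixture(scope="session")
def small_genes(small_config):
    return simulate.make_annotation(small_config)


@pytest.fixture
def plus_gene():
    return GeneModel("gp", "chr1", 10_000, 16_000, "+",
                     exons=((10_000, 10_400), (12_000, 12_500), (15_600, 16_000)),
                     cds=(10_300, 15_700))


@pytest.fixture
def minus_gene():
    return GeneModel("gm", "chr1", 30_000, 36_000, "-",
                     exons=((30_000, 30_400), (33_000, 33_500), (35_600, 36_000)),
                     cds=(30_300, 35_700))
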