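import numpy as np
import pytest

from proteogut.codes import Contig
from proteogut.synthetic import SimulationConfig, ToolErrorModel, make_contigs


@pytest.fixture
def poly_a_contig():
    """A 200-nt contig with no stop codons in any frame (AAA = Lys, TTT =
    Phe on the reverse strand), convenient for coordinate-level merge tests."""
    return Contig("c1", "A" * 200)


@pytest.fixture
def small_truth():
    cfg = SimulationConfig(seed=7, n_contigs=4, genes_per_contig=3,
                           n_edge_genes=2, n_short_genes=2, n_decoys=2)
    contigs, truth = make_contigs(cfg)
    return cfg, contigs, truth


@pytest.fixture
def three_tool_model():
    return {t: ToolErrorModel(miss=0.2, start_shift=0.2, spurious=0.1)
            for t in ("toolA", "toolB", "toolC")}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
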