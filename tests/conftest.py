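import numpy as np
import pytest

from isopipe import simulate as sim
from isopipe.roi import PolymeraseRead


def to_polymerase(reads):
    return [
        PolymeraseRead(r.read_id, r.sequence, accuracy=r.true_accuracy,
                       bin_hint=r.library_bin)
        for r in reads
    ]


@pytest.fixture(scope="session")
def small_models():
    """20 genes, 30% with a skipped-exon second isoform, planted SSRs/ORFs."""
    return sim.generate_gene_models(
        20, as_fraction=0.3, ssr_fraction=0.5, orf_fraction=0.5,
        length_range=(500, 1500), seed=101,
    )


@pytest.fixture(scope="session")
def small_reads(small_models):
    return sim.simulate_reads(
        small_models, reads_per_isoform=4, error_rate=0.04,
        chimera_rate=0.05, seed=102,
    )


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of order
    return np.random.default_rng(7)
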