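import numpy as np
import pytest

from wgdkit.model import GeneModel, assign_ranks


def make_genes(layout, proteins=None, spacing=100, length=90):
    """Build ranked GeneModels from a per-chromosome list of (id, name) pairs."""
    genes = []
    for chrom, entries in layout.items():
        cursor = 0
        for gid, name in entries:
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    start=cursor,
                    end=cursor + length,
                    strand="+",
                    name=name,
                    protein=(proteins or {}).get(gid, ""),
                )
            )
            cursor += length + spacing
    assign_ranks(genes)
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(0)
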