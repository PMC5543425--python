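import random

import pytest

from supertranscripts.graph import assemble_cluster
from supertranscripts.simulate import simulate_gene, simulate_isoforms


@pytest.fixture(scope="session")
def gene_suite():
    """200 seeded synthetic genes with isoforms, truths and assemblies."""
    suite = []
    for i in range(200):
        rng = random.Random(9000 + i)
        gene = simulate_gene(rng.randint(2, 5), seed=10_000 + i, gene_id=f"g{i:03d}")
        cluster, truth = simulate_isoforms(gene, rng.randint(1, 8), seed=20_000 + i)
        st = assemble_cluster(cluster)
        suite.append((gene, cluster, truth, st))
    return suite
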