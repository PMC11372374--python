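import numpy as np
import pytest

from forkswitch.io import ExpressionMatrix
from forkswitch.simulate import (
    PlantedDesign,
    PlantedModule,
    generate_planted_data,
)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples with simple exact structure."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],  # exact affine copy of g1
            [4.0, 3.0, 2.0, 1.0],  # exact negation pattern
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_planted(
    rng_seed=0,
    n_genes=120,
    n_samples=60,
    genes_per_group=15,
    samples_per_fork=12,
    effect=2.0,
    noise_sd=1.0,
):
    """A compact planted single-module dataset for unit tests."""
    design = PlantedDesign(n_genes, n_samples, [], noise_sd, rng_seed)
    genes = design.gene_ids()
    samples = design.sample_ids()
    module = PlantedModule(
        uf_samples=samples[:samples_per_fork],
        lf_samples=samples[samples_per_fork : 2 * samples_per_fork],
        pos_genes=genes[:genes_per_group],
        neg_genes=genes[genes_per_group : 2 * genes_per_group],
        effect=effect,
    )
    design.modules = [module]
    return generate_planted_data(design)


@pytest.fixture
def planted_small():
    return small_planted(rng_seed=3)
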