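import numpy as np
import pytest

from myonet import RegTParams, SyntheticConfig, generate_compendium
from myonet.preprocessing import ExpressionStudy, intersect_genes, merge_batches, ztransform


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_genes=300, effect_genes_per_cluster=30, samples_per_arm=8, seed=11
    )


@pytest.fixture(scope="session")
def small_compendium(small_config):
    return generate_compendium(small_config)


@pytest.fixture(scope="session")
def prepared_studies(small_compendium):
    studies, _ = small_compendium
    merged = [ztransform(merge_batches([s])) for s in studies]
    _, merged = intersect_genes(merged)
    return merged


@pytest.fixture(scope="session")
def reg_params():
    return RegTParams(window=51)


def make_study(values, disease_id="D", arms=None, batches=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if arms is None:
        half = n_samples // 2
        arms = ["disease"] * half + ["control"] * (n_samples - half)
    if batches is None:
        batches = ["b0"] * n_samples
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    return ExpressionStudy(
        disease_id=disease_id,
        gene_ids=list(gene_ids),
        values=values,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        arms=np.array(arms),
        batches=np.array(batches),
    )
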