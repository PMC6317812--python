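import numpy as np
import pandas as pd
import pytest

from pcca import preprocess as pp
from pcca.pcca_core import pca, pcca_fit
from pcca.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Two diverged populations with batches and planted shifted/cis genes."""
    cfg = SimulationConfig(
        n_populations=2,
        samples_per_population=30,
        n_snps=400,
        n_genes=120,
        frac_pop_genes=0.2,
        pop_effect_size=1.2,
        n_batches=3,
        batch_effect_size=1.0,
        cis_fraction=0.05,
        cis_beta=0.6,
        fst=0.12,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Preprocessed matrices plus fitted PCAs and PCCA model for the small dataset."""
    ds = small_dataset
    with pytest.warns(UserWarning):
        expr = pp.preprocess_expression(
            ds.expression, metadata=ds.metadata, gene_annotation=ds.gene_annotation
        )
    geno = pp.preprocess_genotypes(ds.genotypes, ds.snp_annotation, maf_min=0.05)
    pca_x = pca(pp.standardize_dosages(geno), 4)
    pca_y = pca(expr.values, 15)
    model = pcca_fit(pca_x.scores, pca_y.scores, 2)
    return {"ds": ds, "expr": expr, "geno": geno, "pca_x": pca_x, "pca_y": pca_y, "model": model}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_orthonormal(rng, n, k, index=None):
    """Random n x k matrix with orthonormal, column-mean-zero columns."""
    raw = rng.standard_normal((n, k + 1))
    raw[:, 0] = 1.0  # force the span to contain the constant vector
    q, _ = np.linalg.qr(raw)
    u = q[:, 1 : k + 1]  # orthogonal to constant => zero column means
    if index is None:
        return u
    return pd.DataFrame(u, index=index, columns=[f"PC{i+1}" for i in range(k)])
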