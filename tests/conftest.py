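import logging
import warnings

import numpy as np
import pytest

from bgpwas import genome, phenome, synthetic

logging.getLogger("bgpwas").setLevel(logging.ERROR)
logging.getLogger("bgpwas.phenome").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=RuntimeWarning, message="R-hat")


@pytest.fixture(scope="session")
def small_pop():
    """200 accessions, 300 variants on 2 chromosomes, no deme structure."""
    return synthetic.simulate_population(200, 300, n_chrom=2, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def tiny_pop():
    return synthetic.simulate_population(30, 60, n_chrom=3, maf_range=(0.2, 0.5), seed=5)


@pytest.fixture
def toy_gene_plus():
    return synthetic.make_toy_gene(n_exons=2, strand="+", seed=23)


@pytest.fixture
def toy_gene_minus():
    return synthetic.make_toy_gene(n_exons=2, strand="-", seed=23)


def trait_matrix(values, names=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return phenome.TraitMatrix(
        values=values,
        mask=~np.isnan(values),
        accession_ids=[f"a{i}" for i in range(n)],
        trait_names=names or [f"t{j}" for j in range(p)],
    )


def recovery_r(fit_imputed, held_out):
    idx = list(held_out)
    pred = np.array([fit_imputed[i, j] for i, j in idx])
    true = np.array([held_out[k] for k in idx])
    if np.ptp(pred) == 0:
        return 0.0
    return float(np.corrcoef(pred, true)[0, 1])
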