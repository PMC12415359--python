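import numpy as np
import pytest

import domcode as dc
from domcode.gblup import build_model_grms


@pytest.fixture(scope="session")
def small_sim():
    """A dominance-rich desk-scale dataset: n=300, m=500, h2=(0.3, 0.2)."""
    cfg = dc.SimConfig(n_individuals=300, n_markers=500, n_qtl=50, seed=11)
    geno = dc.simulate_genotypes(cfg)
    pheno, truth = dc.simulate_phenotypes(geno, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def small_grms(small_sim):
    _, geno, _, _ = small_sim
    GA, GD_het = build_model_grms(geno, "het")
    return GA, GD_het


@pytest.fixture
def tiny_geno():
    """3 individuals x 2 markers, handmade."""
    return dc.GenotypeData(
        genotypes=np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8),
        marker_ids=np.array(["snp1", "snp2"]),
        chrom=np.array(["1", "1"]),
        bp=np.array([100, 200]),
        allele_a=np.array(["A", "G"]),
        allele_b=np.array(["C", "T"]),
        sample_ids=np.array(["s1", "s2", "s3"]),
    )
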