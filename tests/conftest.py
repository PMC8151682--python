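import numpy as np
import pandas as pd
import pytest

from hensnp.io_qc import GenotypeMatrix


def make_matrix(codes, oriented=True, chrom="1", ea_freq=0.3) -> GenotypeMatrix:
    """Wrap a raw code array in a GenotypeMatrix with placeholder metadata."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    snps = pd.DataFrame(
        dict(
            snp_id=[f"S{j}" for j in range(m)],
            chrom=[chrom] * m,
            pos=np.arange(1, m + 1) * 1000,
            allele_a=["A"] * m,
            allele_b=["C"] * m,
            ea=["C"] * m,
            oa=["A"] * m,
            ea_freq=[ea_freq] * m,
        )
    )
    return GenotypeMatrix([f"H{i}" for i in range(n)], snps, codes, oriented=oriented)


@pytest.fixture
def small_sim():
    """A small simulated study: 240 hens, 60 SNPs, one strong QTL per trait."""
    from hensnp.simulate import SimConfig, simulate_genotypes, simulate_phenotypes

    cfg = SimConfig(
        n_hens=240, n_sires=40, n_snps=60, n_qtl=2,
        qtl_a=(8.0, 8.0), qtl_d=(2.0, 2.0),
        traits=("Tib_BBS", "Hum_BBS"), seed=11,
    )
    g = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, cfg)
    return cfg, g, pheno, truth
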