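"""Synthetic-data generator: determinism, Hardy-Weinberg structure, truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hensnp.io_qc import MISSING
from hensnp.simulate import (
    SimConfig,
    qtl_effect_values,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotypes,
)


def _one_trait_cfg(**kw):
    base = dict(
        n_lines=1, n_generations=1, n_sires=10, n_hens=100, n_snps=20,
        line_allele_freq_ranges=((0.1, 0.5),), line_effects=(0.0,),
        generation_effects=(0.0,), traits=("Tib_BBS",),
        n_qtl=0, qtl_a=(), qtl_d=(), seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


def test_config_validation_names_field():
    with pytest.raises(ValueError, match="missing_rate"):
        _one_trait_cfg(missing_rate=1.5)
    with pytest.raises(ValueError, match="n_hens"):
        _one_trait_cfg(n_hens=0)
    with pytest.raises(ValueError, match="allele_freq"):
        _one_trait_cfg(line_allele_freq_ranges=((0.2, 0.7),))
    with pytest.raises(ValueError, match="n_qtl"):
        _one_trait_cfg(n_qtl=50, qtl_a=(1,) * 50, qtl_d=(0,) * 50)


def test_missing_rate_zero_and_determinism():
    cfg = _one_trait_cfg(missing_rate=0.0)
    g1, g2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
    assert not (g1.codes == MISSING).any()
    assert np.array_equal(g1.codes, g2.codes)
    assert g1.snps.equals(g2.snps)
    p1, t1 = simulate_phenotypes(g1, cfg)
    p2, t2 = simulate_phenotypes(g2, cfg)
    pd.testing.assert_frame_equal(p1, p2)
    assert t1.sire_effects == t2.sire_effects
    g3 = simulate_genotypes(_one_trait_cfg(seed=2))
    assert not np.array_equal(g1.codes, g3.codes)


def test_missing_rate_injected_at_configured_level():
    cfg = _one_trait_cfg(n_hens=500, n_snps=100, missing_rate=0.05, n_sires=50)
    g = simulate_genotypes(cfg)
    rate = float((g.codes == MISSING).mean())
    lo, hi = stats.binom.ppf([0.001, 0.999], 500 * 100, 0.05) / (500 * 100)
    assert lo <= rate <= hi


def test_empirical_maf_matches_configured_frequency():
    """One line, MAF fixed at 0.3, 5000 hens: per-SNP empirical frequency
    within +/-0.02 for at least 48/50 SNPs (binomial-CI-derived check)."""
    cfg = _one_trait_cfg(
        n_hens=5000, n_sires=100, n_snps=50, line_allele_freq_ranges=((0.3, 0.3),)
    )
    g = simulate_genotypes(cfg)
    freqs = g.codes.mean(axis=0) / 2
    assert (np.abs(freqs - 0.3) <= 0.02).sum() >= 48


def test_hardy_weinberg_within_line():
    """Genotype counts consistent with HWE at the realized allele frequency
    (chi-square not rejected at alpha=0.001 for >=99% of SNPs)."""
    cfg = _one_trait_cfg(n_hens=5000, n_sires=100, n_snps=100,
                         line_allele_freq_ranges=((0.05, 0.5),))
    g = simulate_genotypes(cfg)
    rejected = 0
    for j in range(g.n_snps):
        counts = np.bincount(g.codes[:, j], minlength=3)
        n = counts.sum()
        p = (counts[1] + 2 * counts[2]) / (2 * n)
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        keep = expected > 0
        chi2 = float(((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        df = keep.sum() - 1 - 1  # estimated allele frequency costs one df
        if df > 0 and chi2 > stats.chi2.ppf(0.999, df):
            rejected += 1
    assert rejected <= 1


def test_no_variance_sources_collapse_to_cell_means():
    cfg = SimConfig(
        n_lines=2, n_generations=1, n_sires=4, n_hens=40, n_snps=5,
        line_allele_freq_ranges=((0.2, 0.4),) * 2, line_effects=(0.0, 10.0),
        generation_effects=(0.0,), sire_sd=0.0, resid_sd=0.0,
        n_qtl=0, qtl_a=(), qtl_d=(), traits=("Tib_BBS",), seed=5,
    )
    g = simulate_genotypes(cfg)
    pheno, _ = simulate_phenotypes(g, cfg)
    for _, grp in pheno.groupby("line"):
        assert grp["Tib_BBS"].nunique() == 1
    assert pheno.groupby("line")["Tib_BBS"].first().diff().dropna().iloc[0] == pytest.approx(10.0)


def test_single_qtl_homozygote_spread_is_2a():
    cfg = _one_trait_cfg(n_hens=300, n_sires=30, sire_sd=0.0, resid_sd=0.0,
                         n_qtl=1, qtl_a=(5.0,), qtl_d=(0.0,))
    g = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, cfg)
    assert pheno["Tib_BBS"].max() - pheno["Tib_BBS"].min() == pytest.approx(10.0)


def test_truth_reconstructs_phenotypes_exactly():
    """With resid_sd=0, trait values equal mean + fixed + sire + QTL effects
    rebuilt from the truth record."""
    cfg = SimConfig(
        n_hens=120, n_sires=12, n_snps=30, n_qtl=3, qtl_a=(4.0, 2.0, 1.0),
        qtl_d=(1.0, 0.0, -1.0), sire_sd=3.0, resid_sd=0.0,
        traits=("Tib_BBS", "Hum_BMD"), seed=9,
    )
    g = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(g, cfg)
    for trait in cfg.traits:
        y = np.full(cfg.n_hens, truth.trait_means[trait])
        y += np.asarray(truth.generation_effects[trait])[pheno["generation"] - 1]
        y += np.asarray(truth.line_effects[trait])[pheno["line"] - 1]
        y += pheno["sire_id"].map(truth.sire_effects[trait]).to_numpy()
        for q, sid in enumerate(truth.qtl_snp_ids):
            if truth.qtl_trait[q] != trait:
                continue
            j = g.snps.index[g.snps["snp_id"] == sid][0]
            y += qtl_effect_values(g.codes[:, j], truth.qtl_a[q], truth.qtl_d[q])
        assert np.allclose(pheno[trait].to_numpy(), y, atol=1e-10)
    assert set(truth.qtl_snp_ids) <= set(g.snps["snp_id"])


def test_qtl_count_validation():
    cfg = _one_trait_cfg(n_snps=20)
    g = simulate_genotypes(cfg)
    bad = _one_trait_cfg(n_snps=20, n_qtl=10, qtl_a=(1,) * 10, qtl_d=(0,) * 10)
    g_small = simulate_genotypes(_one_trait_cfg(n_snps=20))
    g_small.snps = g_small.snps.iloc[:5].reset_index(drop=True)
    g_small.codes = g_small.codes[:, :5]
    with pytest.raises(ValueError, match="n_qtl exceeds"):
        simulate_phenotypes(g_small, bad)


def test_gene_annotation_fraction_bounds(tmp_path):
    cfg = SimConfig(n_hens=60, n_sires=8, n_snps=40, n_qtl=4,
                    qtl_a=(5,) * 4, qtl_d=(0,) * 4, seed=13)
    g = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(g, cfg)
    qtl_pos = g.snps.set_index("snp_id").loc[truth.qtl_snp_ids]

    genes1, sets1 = simulate_gene_annotation(g, truth, cfg, qtl_near_gene_fraction=1.0)
    for _, s in qtl_pos.iterrows():
        near = genes1[
            (genes1["chrom"] == s["chrom"])
            & (genes1["start"] - 5000 <= s["pos"])
            & (genes1["end"] + 5000 >= s["pos"])
        ]
        assert len(near) >= 1

    genes0, _ = simulate_gene_annotation(g, truth, cfg, qtl_near_gene_fraction=0.0)
    for _, s in qtl_pos.iterrows():
        near = genes0[
            (genes0["chrom"] == s["chrom"])
            & (genes0["start"] - 5000 <= s["pos"])
            & (genes0["end"] + 5000 >= s["pos"])
        ]
        assert len(near) == 0

    # genes never overlap within a chromosome
    for _, grp in genes1.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].iloc[1:].to_numpy() > grp["end"].iloc[:-1].to_numpy()).all()
    # gene-set membership partitions the genes; the planted term holds QTL genes
    all_members = [m for _, (_, ms) in sets1.items() for m in ms]
    assert len(all_members) == len(set(all_members)) == len(genes1)

    with pytest.raises(ValueError, match="too small"):
        simulate_gene_annotation(g, truth, cfg, chrom_length_bp=10_000)


def test_gff3_round_trip(tmp_path):
    from hensnp.annotate import read_gff3
    from hensnp.simulate import write_gff3

    cfg = SimConfig(n_hens=60, n_sires=8, n_snps=30, n_qtl=2,
                    qtl_a=(5, 5), qtl_d=(0, 0), seed=17)
    g = simulate_genotypes(cfg)
    _, truth = simulate_phenotypes(g, cfg)
    genes, _ = simulate_gene_annotation(g, truth, cfg, n_genes=15)
    write_gff3(genes, tmp_path / "g.gff3")
    back = read_gff3(tmp_path / "g.gff3")
    left = genes.sort_values("gene_id").reset_index(drop=True)
    right = back.sort_values("gene_id").reset_index(drop=True)
    for col in ("gene_id", "chrom", "start", "end", "strand"):
        assert left[col].tolist() == right[col].tolist()
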