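"""Synthetic genotypes, phenotypes, gene models and gene sets.

The generator emulates the structure of a multi-line layer-hen breeding
study: ~524 hens from four phylogenetically distinct purebred layer lines
and two generations, sired by up to 145 cocks nested within line.  Per SNP
and line, a minor-allele frequency is drawn from a configurable range and
genotypes follow Hardy-Weinberg proportions within the line, so lines are
differentiated (the population stratification the adjustment model is there
to absorb) while individual SNPs are unlinked.

Phenotypes are built additively:

    y = mean + generation + line + sire + sum_q QTL_q(genotype) + e

with the QTL contribution following the classical biometric coding: the
homozygote of the major allele contributes +a, the heterozygote d, and the
homozygote of the minor (effect) allele -a.  Sire effects are N(0,
sire_sd^2), residuals N(0, resid_sd^2).  Everything planted is returned in
a :class:`SyntheticTruth` record so recovery tests can compare estimates
against what was actually simulated.

Bone traits live on very different scales (breaking strength ~150 N,
mineral density ~0.25 g/cm^2), so effect-size parameters are specified once
in newton-scale units and multiplied by a per-trait scale factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix, SNP_COLUMNS

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_gene_annotation",
    "write_vcf",
    "write_gff3",
    "write_gmt",
]

DEFAULT_TRAITS = ("Tib_BBS", "Tib_BMD", "Hum_BBS", "Hum_BMD")

# Baseline trait means and per-trait multipliers applied to all effect-size
# parameters (which are specified on the breaking-strength scale, in N).
# Means mirror the magnitudes seen in adult laying hens: BBS of order
# 120-160 N, areal BMD of order 0.17-0.26 g/cm^2.
DEFAULT_TRAIT_MEANS = {
    "Tib_BBS": 155.0,
    "Tib_BMD": 0.26,
    "Hum_BBS": 120.0,
    "Hum_BMD": 0.17,
}
_BMD_SCALE = 1.0 / 600.0  # ~0.25 g/cm^2 per ~150 N


def _default_scale(trait: str) -> float:
    return _BMD_SCALE if trait.endswith("BMD") else 1.0


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Effect sizes (``qtl_a``, ``qtl_d``, ``line_effects``,
    ``generation_effects``, ``sire_sd``, ``resid_sd``) are in newtons on the
    breaking-strength scale; BMD traits apply a fixed 1/600 multiplier.
    """

    n_lines: int = 4
    n_generations: int = 2
    n_sires: int = 145
    n_hens: int = 524
    n_snps: int = 2000
    chroms: tuple = tuple(str(c) for c in range(1, 29))
    line_allele_freq_ranges: tuple = ((0.05, 0.5), (0.05, 0.5), (0.05, 0.5), (0.05, 0.5))
    n_qtl: int = 5
    qtl_a: tuple = (8.0, 8.0, 8.0, 8.0, 8.0)
    qtl_d: tuple = (2.0, 2.0, 2.0, 2.0, 2.0)
    line_effects: tuple = (0.0, 15.0, 30.0, 45.0)
    generation_effects: tuple = (0.0, 10.0)
    sire_sd: float = 5.0
    resid_sd: float = 15.0
    missing_rate: float = 0.0
    traits: tuple = DEFAULT_TRAITS
    seed: int = 0

    def __post_init__(self):
        for name in ("n_lines", "n_generations", "n_sires", "n_hens", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be > 0")
        if self.n_qtl < 0 or self.n_qtl > self.n_snps:
            raise ValueError("SimConfig.n_qtl must be in [0, n_snps]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("SimConfig.missing_rate must be in [0, 1)")
        if self.sire_sd < 0 or self.resid_sd < 0:
            raise ValueError("SimConfig.sire_sd and resid_sd must be >= 0")
        if len(self.line_allele_freq_ranges) != self.n_lines:
            raise ValueError("SimConfig.line_allele_freq_ranges must have one range per line")
        for lo, hi in self.line_allele_freq_ranges:
            if not (0 < lo <= hi <= 0.5):
                raise ValueError(
                    "SimConfig.line_allele_freq_ranges entries must lie within (0, 0.5]"
                )
        if len(self.line_effects) != self.n_lines:
            raise ValueError("SimConfig.line_effects must have one entry per line")
        if len(self.generation_effects) != self.n_generations:
            raise ValueError("SimConfig.generation_effects must have one entry per generation")
        if len(self.qtl_a) != self.n_qtl or len(self.qtl_d) != self.n_qtl:
            raise ValueError("SimConfig.qtl_a and qtl_d must have n_qtl entries")
        if self.n_sires < self.n_lines:
            raise ValueError("SimConfig.n_sires must be >= n_lines (sires are nested in lines)")
        if not self.chroms:
            raise ValueError("SimConfig.chroms must be non-empty")
        if not set(map(str, self.chroms)) <= {str(c) for c in range(1, 29)}:
            raise ValueError("SimConfig.chroms must be a subset of autosomes 1..28")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated phenotype draw, for recovery tests."""

    qtl_snp_ids: list
    qtl_trait: list  # trait each QTL acts on
    qtl_a: list  # planted additive effect, in the target trait's units
    qtl_d: list
    trait_means: dict
    line_effects: dict  # trait -> per-line shifts (trait units)
    generation_effects: dict
    sire_effects: dict  # trait -> {sire_id: realized effect}
    sire_sd: dict
    resid_sd: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def design_frame(config: SimConfig) -> pd.DataFrame:
    """Hen -> (line, generation, sire) assignment: balanced, sires nested.

    Hens are dealt round-robin across line x generation cells; each line's
    share of the 145 sires is assigned round-robin to its hens, so family
    sizes are as even as the counts allow.  Deterministic (no RNG).
    """
    hens = np.arange(config.n_hens)
    line = hens % config.n_lines
    generation = (hens // config.n_lines) % config.n_generations
    sires_per_line = [
        config.n_sires // config.n_lines + (1 if l < config.n_sires % config.n_lines else 0)
        for l in range(config.n_lines)
    ]
    sire = np.empty(config.n_hens, dtype=object)
    for l in range(config.n_lines):
        idx = np.flatnonzero(line == l)
        ids = [f"S{l + 1}_{k + 1}" for k in range(sires_per_line[l])]
        sire[idx] = [ids[i % len(ids)] for i in range(len(idx))]
    return pd.DataFrame(
        dict(
            hen_id=[f"H{i + 1}" for i in hens],
            generation=generation + 1,
            line=line + 1,
            sire_id=sire,
        )
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw genotypes Hardy-Weinberg within line at line-specific MAFs.

    Per SNP and line, the frequency of the B allele is uniform on the
    line's configured range (so B is the minor allele within every line);
    genotype codes count B copies.  Missing calls are injected uniformly at
    random at ``missing_rate``.  The returned matrix is unoriented.
    """
    rng = np.random.default_rng(config.seed)
    design = design_frame(config)
    line_idx = design["line"].to_numpy() - 1

    n, m = config.n_hens, config.n_snps
    freqs = np.empty((config.n_lines, m))
    for l, (lo, hi) in enumerate(config.line_allele_freq_ranges):
        freqs[l] = rng.uniform(lo, hi, size=m)
    p = freqs[line_idx]  # per-hen, per-SNP B-allele frequency
    codes = rng.binomial(2, p).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        codes[miss] = MISSING

    chroms = np.sort(rng.choice(len(config.chroms), size=m))
    positions = np.empty(m, dtype=int)
    for c in np.unique(chroms):
        sel = chroms == c
        positions[sel] = np.sort(
            rng.choice(np.arange(1, 5_000_001), size=int(sel.sum()), replace=False)
        )
    allele_pairs = _BASES[rng.integers(0, 4, size=(m, 2))]
    same = allele_pairs[:, 0] == allele_pairs[:, 1]
    allele_pairs[same, 1] = _BASES[(np.searchsorted(_BASES, allele_pairs[same, 0]) + 1) % 4]

    snps = pd.DataFrame(
        dict(
            snp_id=[f"SNP{j + 1:06d}" for j in range(m)],
            chrom=[str(config.chroms[c]) for c in chroms],
            pos=positions,
            allele_a=allele_pairs[:, 0],
            allele_b=allele_pairs[:, 1],
            ea=None,
            oa=None,
            ea_freq=np.nan,
        )
    )[SNP_COLUMNS]
    return GenotypeMatrix(design["hen_id"].tolist(), snps, codes, oriented=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def qtl_effect_values(codes: np.ndarray, a: float, d: float) -> np.ndarray:
    """Genotypic value by B-copy count: 0 -> +a, 1 -> d, 2 -> -a."""
    vals = np.array([a, d, -a])
    out = np.where(codes == MISSING, 0.0, vals[np.clip(codes, 0, 2)])
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate trait values on top of a genotype matrix.

    QTL SNPs are assigned round-robin to the configured traits, so each
    planted signal is specific to one trait.  Fixed and random effects use
    the same realized sire draw per trait but independent residuals.
    """
    rng = np.random.default_rng(config.seed + 1)
    design = design_frame(config)
    if design["hen_id"].tolist() != list(genotypes.sample_ids):
        raise ValueError("genotype matrix does not match the design for this config")
    if config.n_qtl > genotypes.n_snps:
        raise ValueError("n_qtl exceeds the number of simulated SNPs")

    qtl_idx = np.sort(rng.choice(genotypes.n_snps, size=config.n_qtl, replace=False))
    qtl_ids = genotypes.snps["snp_id"].iloc[qtl_idx].tolist()
    qtl_traits = [config.traits[i % len(config.traits)] for i in range(config.n_qtl)]

    sire_ids = sorted(design["sire_id"].unique())
    line_idx = design["line"].to_numpy() - 1
    gen_idx = design["generation"].to_numpy() - 1

    pheno = design.copy()
    truth = SyntheticTruth(
        qtl_snp_ids=qtl_ids,
        qtl_trait=qtl_traits,
        qtl_a=[],
        qtl_d=[],
        trait_means={},
        line_effects={},
        generation_effects={},
        sire_effects={},
        sire_sd={},
        resid_sd={},
    )
    for trait in config.traits:
        scale = _default_scale(trait)
        mean = DEFAULT_TRAIT_MEANS.get(trait, 100.0 * scale)
        sire_eff = rng.normal(0.0, config.sire_sd * scale, size=len(sire_ids))
        sire_map = dict(zip(sire_ids, sire_eff))
        y = (
            mean
            + np.asarray(config.generation_effects)[gen_idx] * scale
            + np.asarray(config.line_effects)[line_idx] * scale
            + design["sire_id"].map(sire_map).to_numpy()
        )
        a_list, d_list = [], []
        for q, (j, t) in enumerate(zip(qtl_idx, qtl_traits)):
            a = config.qtl_a[q] * scale
            d = config.qtl_d[q] * scale
            if t == trait:
                y = y + qtl_effect_values(genotypes.codes[:, j], a, d)
            a_list.append(a)
            d_list.append(d)
        y = y + rng.normal(0.0, config.resid_sd * scale, size=config.n_hens)
        pheno[trait] = y
        truth.trait_means[trait] = mean
        truth.line_effects[trait] = [e * scale for e in config.line_effects]
        truth.generation_effects[trait] = [e * scale for e in config.generation_effects]
        truth.sire_effects[trait] = {k: float(v) for k, v in sire_map.items()}
        truth.sire_sd[trait] = config.sire_sd * scale
        truth.resid_sd[trait] = config.resid_sd * scale
    # per-QTL effects in the units of the trait each QTL acts on
    truth.qtl_a = [config.qtl_a[q] * _default_scale(qtl_traits[q]) for q in range(config.n_qtl)]
    truth.qtl_d = [config.qtl_d[q] * _default_scale(qtl_traits[q]) for q in range(config.n_qtl)]
    return pheno, truth


# ---------------------------------------------------------------------------
# gene models and gene sets
# ---------------------------------------------------------------------------


def simulate_gene_annotation(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    config: SimConfig,
    n_genes: int = 40,
    gene_length: tuple[int, int] = (2_000, 20_000),
    qtl_near_gene_fraction: float = 1.0,
    window_bp: int = 5_000,
    n_sets: int = 10,
    chrom_length_bp: int = 5_200_000,
) -> tuple[pd.DataFrame, dict]:
    """Place non-overlapping protein-coding genes and partition them into sets.

    A ``qtl_near_gene_fraction`` share of the planted QTL SNPs get a gene
    within ``window_bp``; the remaining QTL (and background genes) are kept
    at least ``window_bp`` away from any QTL SNP.  Gene sets partition the
    genes into ``n_sets`` terms with the first term collecting the
    QTL-adjacent genes (the planted enrichment signal).

    Returns the gene table (gene_id, name, biotype, chrom, start, end,
    strand) and a dict term_id -> (description, list of gene ids).
    """
    if not (0 <= qtl_near_gene_fraction <= 1):
        raise ValueError("qtl_near_gene_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 2)
    snps = genotypes.snps
    qtl = snps[snps["snp_id"].isin(truth.qtl_snp_ids)]
    n_near = int(round(qtl_near_gene_fraction * len(qtl)))
    near_ids = list(qtl["snp_id"].iloc[:n_near])

    max_len = gene_length[1]
    if chrom_length_bp < 2 * (max_len + 2 * window_bp + 2):
        raise ValueError("chromosome length too small to place genes")

    genes = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    def _claim(chrom: str, start: int, end: int) -> bool:
        spans = occupied.setdefault(chrom, [])
        for s, e in spans:
            if start <= e and s <= end:
                return False
        spans.append((start, end))
        return True

    gid = 0

    def _add(chrom, start, end, near_qtl):
        nonlocal gid
        gid += 1
        genes.append(
            dict(
                gene_id=f"GENE{gid:04d}",
                name=f"gene{gid}",
                biotype="protein_coding",
                chrom=str(chrom),
                start=int(start),
                end=int(end),
                strand="+" if rng.random() < 0.5 else "-",
                near_qtl=near_qtl,
            )
        )

    qtl_pos = {str(r.chrom): [] for r in qtl.itertuples()}
    for r in qtl.itertuples():
        qtl_pos[str(r.chrom)].append(int(r.pos))

    # genes covering the designated QTL SNPs (placed so the SNP is intragenic
    # or just within the window, which exercises all three location labels)
    for snp_id in near_ids:
        row = snps[snps["snp_id"] == snp_id].iloc[0]
        length = int(rng.integers(gene_length[0], max_len + 1))
        offset = int(rng.integers(-length, window_bp + 1))  # SNP to gene start
        start = max(1, int(row.pos) + offset - length // 2)
        end = start + length - 1
        if end > chrom_length_bp:
            start, end = chrom_length_bp - length + 1, chrom_length_bp
        if not _claim(str(row.chrom), start, end):
            raise ValueError(f"could not place a gene near QTL SNP {snp_id}")
        _add(row.chrom, start, end, True)

    # background genes, kept clear of every QTL SNP's window
    tries = 0
    while gid < n_genes:
        tries += 1
        if tries > 200 * n_genes:
            raise ValueError("chromosome length too small to place genes")
        chrom = str(config.chroms[rng.integers(0, len(config.chroms))])
        length = int(rng.integers(gene_length[0], max_len + 1))
        start = int(rng.integers(1, chrom_length_bp - length + 1))
        end = start + length - 1
        near = any(
            start - window_bp <= pos <= end + window_bp for pos in qtl_pos.get(chrom, [])
        )
        if near:
            continue
        if _claim(chrom, start, end):
            _add(chrom, start, end, False)

    gene_df = pd.DataFrame(genes)

    # gene sets: term 1 holds the QTL-adjacent genes plus fillers; the rest
    # of the genes are dealt round-robin into the remaining terms
    qtl_genes = gene_df.loc[gene_df["near_qtl"], "gene_id"].tolist()
    others = gene_df.loc[~gene_df["near_qtl"], "gene_id"].tolist()
    rng.shuffle(others)
    sets: dict[str, tuple[str, list]] = {}
    fill = max(0, len(gene_df) // n_sets - len(qtl_genes))
    sets["TERM0001"] = ("planted bone-integrity term", qtl_genes + others[:fill])
    rest = others[fill:]
    for t in range(1, n_sets):
        members = rest[t - 1 :: n_sets - 1] if n_sets > 1 else rest
        if members:
            sets[f"TERM{t + 1:04d}"] = (f"background term {t}", list(members))
    gene_df = gene_df.drop(columns="near_qtl")
    return gene_df, sets


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT only (allele A = REF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(g.snps["chrom"]), key=lambda x: (len(x), x)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        order = np.lexsort((g.snps["pos"].to_numpy(), g.snps["chrom"].to_numpy()))
        for j in order:
            row = g.snps.iloc[j]
            gts = "\t".join(gt_map[int(c)] for c in g.codes[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.allele_a}\t{row.allele_b}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_gff3(gene_df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in gene_df.itertuples():
            attrs = f"ID=gene:{r.gene_id};Name={r.name};biotype={r.biotype}"
            fh.write(
                f"{r.chrom}\tsim\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, genes) in sets.items():
            fh.write("\t".join([term_id, desc] + list(genes)) + "\n")
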