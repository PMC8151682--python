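"""Per-SNP effect estimation: allele substitution, LSMs, additive/dominance.

Two models, both with fixed generation + layer-line effects and a random
sire intercept, are fitted per SNP and trait:

* **SMR** (single marker regression): the 0/1/2 effect-allele count enters
  as a covariate; its slope is the allele substitution effect.  The
  standardised variant z-scores both the trait and the genotype code first,
  so the slope is in phenotypic SD units.
* **DRM** (dominant-recessive model): genotype enters as a three-level
  class variable.  Least-squares means per genotype are formed on an
  equally weighted generation x line reference grid, pairwise genotype
  differences are t-tested with a Bonferroni factor of 3, and the biometric
  effects are the contrasts

      a = (mu_AA - mu_BB) / 2        d = mu_AB - (mu_AA + mu_BB) / 2

  where AA is the homozygote of the other (major) allele and BB the
  homozygote of the effect (minor) allele.  Both are linear contrasts of
  the same fit, so their SEs come from the fixed-effect covariance.  A
  positive ``a`` means the major allele raises the trait.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .adjust import build_design
from .io_qc import MISSING, GenotypeMatrix
from .lmm import contrast, fit_random_intercept

__all__ = [
    "SmrResult",
    "DrmResult",
    "additive_dominance",
    "fit_smr",
    "fit_drm",
    "significance_letters",
    "effects_report",
    "load_candidate_loci",
    "load_candidate_lsms",
]

GENOTYPE_LABELS = ("AA", "AB", "BB")  # code 0 / 1 / 2 effect-allele copies


def additive_dominance(mu_aa: float, mu_ab: float, mu_bb: float) -> tuple[float, float]:
    """Additive and dominance effects from the three genotypic values.

    ``a = (mu_AA - mu_BB)/2`` is half the homozygote gap (the effect of the
    major allele); ``d = mu_AB - (mu_AA + mu_BB)/2`` is the heterozygote's
    deviation from the homozygote midpoint.
    """
    a = (mu_aa - mu_bb) / 2.0
    d = mu_ab - (mu_aa + mu_bb) / 2.0
    return a, d


@dataclass
class SmrResult:
    snp_id: str
    trait: str
    beta: float  # trait units per effect-allele copy
    se_beta: float
    t_value: float
    p_value: float
    beta_std: float  # SD units (trait and code both z-scored)
    se_beta_std: float
    n_used: int
    estimable: bool = True


@dataclass
class DrmResult:
    snp_id: str
    trait: str
    lsm: pd.Series  # index AA/AB/BB; NaN for absent genotype classes
    lsm_se: pd.Series
    pairwise_p: pd.Series  # Bonferroni-adjusted, index ("AA","AB") etc.
    a: float
    se_a: float
    t_a: float
    p_a: float
    d: float
    se_d: float
    t_d: float
    p_d: float
    n_used: int
    letters: dict = field(default_factory=dict)


def _snp_column(g: GenotypeMatrix, snp_id: str) -> np.ndarray:
    idx = g.snps.index[g.snps["snp_id"] == snp_id]
    if len(idx) == 0:
        raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
    return g.codes[:, idx[0]].astype(float)


def _aligned(g: GenotypeMatrix, pheno: pd.DataFrame, snp_id: str, trait: str):
    if not g.oriented:
        raise ValueError("genotype matrix must be oriented to the minor allele")
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    code = pd.Series(_snp_column(g, snp_id), index=g.sample_ids)
    sub = pheno.set_index("hen_id").reindex(g.sample_ids)
    keep = sub[trait].notna().to_numpy() & (code != MISSING).to_numpy()
    return sub.loc[keep].reset_index(names="hen_id"), code.to_numpy()[keep]


def fit_smr(
    g: GenotypeMatrix, pheno: pd.DataFrame, snp_id: str, trait: str
) -> SmrResult:
    """Allele substitution effect by single marker regression (raw and SD units)."""
    sub, code = _aligned(g, pheno, snp_id, trait)
    if np.var(code) == 0:
        return SmrResult(snp_id, trait, *([float("nan")] * 6), n_used=len(sub), estimable=False)
    y = sub[trait].to_numpy(dtype=float)
    groups = sub["sire_id"].to_numpy()

    X = build_design(sub, extra=pd.DataFrame({"snp": code}, index=sub.index))
    fit = fit_random_intercept(y, X, groups)
    c = np.zeros(len(fit.beta))
    c[list(fit.beta.index).index("snp")] = 1.0
    beta, se, t, p = contrast(fit, c)

    ys = (y - y.mean()) / y.std(ddof=1)
    cs = (code - code.mean()) / code.std(ddof=1)
    Xs = build_design(sub, extra=pd.DataFrame({"snp": cs}, index=sub.index))
    fit_s = fit_random_intercept(ys, Xs, groups)
    beta_s, se_s, _, _ = contrast(fit_s, c)

    return SmrResult(snp_id, trait, beta, se, t, p, beta_s, se_s, n_used=len(sub))


def fit_drm(
    g: GenotypeMatrix, pheno: pd.DataFrame, snp_id: str, trait: str, alpha: float = 0.05
) -> DrmResult:
    """Genotype LSMs with pairwise tests and the a/d contrasts.

    Genotype classes absent from the data get NaN LSMs, and any contrast
    involving them is flagged not-estimable (NaN).
    """
    sub, code = _aligned(g, pheno, snp_id, trait)
    present = sorted(int(k) for k in np.unique(code))
    if len(present) < 2:
        raise ValueError(f"SNP {snp_id!r} has fewer than two genotype classes for {trait!r}")
    y = sub[trait].to_numpy(dtype=float)
    groups = sub["sire_id"].to_numpy()

    geno = pd.DataFrame(index=sub.index)
    for k in present[1:]:
        geno[f"geno[{GENOTYPE_LABELS[k]}]"] = (code == k).astype(float)
    X = build_design(sub, extra=geno)
    fit = fit_random_intercept(y, X, groups)

    cols = list(fit.beta.index)
    n_gen = sum(c.startswith("generation[") for c in cols) + 1
    n_line = sum(c.startswith("line[") for c in cols) + 1

    def lsm_contrast(k: int) -> np.ndarray:
        """Reference-grid weights: equal averaging over generation and line."""
        c = np.zeros(len(cols))
        for i, col in enumerate(cols):
            if col == "Intercept":
                c[i] = 1.0
            elif col.startswith("generation["):
                c[i] = 1.0 / n_gen
            elif col.startswith("line["):
                c[i] = 1.0 / n_line
            elif col == f"geno[{GENOTYPE_LABELS[k]}]":
                c[i] = 1.0
        return c

    lsm = pd.Series(np.nan, index=list(GENOTYPE_LABELS), dtype=float)
    lsm_se = pd.Series(np.nan, index=list(GENOTYPE_LABELS), dtype=float)
    grid = {}
    for k in present:
        cvec = lsm_contrast(k)
        est, se, _, _ = contrast(fit, cvec)
        lsm[GENOTYPE_LABELS[k]] = est
        lsm_se[GENOTYPE_LABELS[k]] = se
        grid[k] = cvec

    pair_index = list(itertools.combinations(GENOTYPE_LABELS, 2))
    pairwise = pd.Series(np.nan, index=pd.Index(pair_index), dtype=float)
    for ka, kb in itertools.combinations(present, 2):
        _, _, _, p = contrast(fit, grid[ka] - grid[kb])
        pairwise[(GENOTYPE_LABELS[ka], GENOTYPE_LABELS[kb])] = min(1.0, 3 * p)

    if 0 in grid and 2 in grid:
        a, se_a, t_a, p_a = contrast(fit, (grid[0] - grid[2]) / 2.0)
    else:
        a = se_a = t_a = p_a = float("nan")
    if set(present) == {0, 1, 2}:
        d, se_d, t_d, p_d = contrast(fit, grid[1] - (grid[0] + grid[2]) / 2.0)
    else:
        d = se_d = t_d = p_d = float("nan")

    letters = significance_letters(pairwise.dropna(), [GENOTYPE_LABELS[k] for k in present], alpha)
    return DrmResult(
        snp_id, trait, lsm, lsm_se, pairwise,
        a, se_a, t_a, p_a, d, se_d, t_d, p_d,
        n_used=len(sub), letters=letters,
    )


def significance_letters(pairwise_p: pd.Series, groups: list, alpha: float = 0.05) -> dict:
    """Compact letter display from adjusted pairwise p-values.

    Groups that do not differ significantly must share a letter; groups
    that do differ must not.  Letters therefore correspond to the maximal
    cliques of the graph whose edges join non-significant pairs (brute
    force over subsets; fine for the handful of genotype classes here).
    """
    groups = list(groups)
    nonsig = {g: {g} for g in groups}
    for (ga, gb), p in pairwise_p.items():
        if not (p < alpha):
            nonsig[ga].add(gb)
            nonsig[gb].add(ga)

    cliques = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            s = set(combo)
            if any(s <= c for c in cliques):
                continue
            if all(s <= nonsig[g] for g in combo):
                cliques.append(s)
    cliques.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, c in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in c:
                letters[g] += ch
    return letters


def effects_report(
    smr_results: list[SmrResult], drm_results: list[DrmResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate SMR and DRM results (one trait per call, as published)."""
    for results in (smr_results, drm_results):
        traits = {r.trait for r in results}
        if len(traits) > 1:
            raise ValueError(f"mixed traits in one table: {sorted(traits)}")
    smr = pd.DataFrame(
        dict(
            snp_id=[r.snp_id for r in smr_results],
            trait=[r.trait for r in smr_results],
            beta=[r.beta for r in smr_results],
            se=[r.se_beta for r in smr_results],
            beta_std=[r.beta_std for r in smr_results],
            se_std=[r.se_beta_std for r in smr_results],
            t=[r.t_value for r in smr_results],
            p=[r.p_value for r in smr_results],
            n=[r.n_used for r in smr_results],
        )
    )
    rows = []
    for r in drm_results:
        row = dict(snp_id=r.snp_id, trait=r.trait)
        for gl in GENOTYPE_LABELS:
            se = r.lsm_se[gl]
            row[f"lsm_{gl}"] = (
                f"{r.lsm[gl]:.2f} ({se:.2f}) {r.letters.get(gl, '')}".strip()
                if np.isfinite(r.lsm[gl])
                else "NE"
            )
        row.update(
            a=r.a, se_a=r.se_a, t_a=r.t_a, p_a=r.p_a,
            d=r.d, se_d=r.se_d, t_d=r.t_d, p_d=r.p_d, n=r.n_used,
        )
        rows.append(row)
    return smr, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundled example data: published candidate-SNP summaries
# ---------------------------------------------------------------------------


def _load_data(name: str) -> pd.DataFrame:
    with resources.files("hensnp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_candidate_loci() -> pd.DataFrame:
    """Published genotype counts for 17 candidate SNPs from a four-line
    laying-hen bone-stability study (one SNP genotyped in 527 hens, the
    rest in 524)."""
    return _load_data("candidate_loci.tsv")


def load_candidate_lsms() -> pd.DataFrame:
    """Published genotype least-squares means (with SEs) for the candidate
    SNP x trait combinations of the same study; input for the a/d contrast
    arithmetic."""
    return _load_data("candidate_lsms.tsv")
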