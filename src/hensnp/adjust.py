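"""Phenotype adjustment: mixed-model pre-correction before SNP selection.

Raw bone traits differ systematically between generations and layer lines
and are correlated within paternal half-sib families.  Feeding raw values
to a random forest would let it "discover" line-tagging SNPs instead of
bone biology.  The adjustment model

    y = mu + generation + line + sire + e          (sire random)

is therefore fitted per trait by REML and its residuals become the response
for feature selection.  By default the residuals are *conditional* — the
predicted (BLUP) sire effect is subtracted along with the fixed effects —
so family means are removed as well; marginal residuals (fixed effects
only) are available via ``conditional=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import LmmFit, fit_random_intercept

__all__ = ["AdjustmentFit", "build_design", "fit_adjustment_model", "attach_residuals"]


@dataclass
class AdjustmentFit:
    """Per-trait adjustment model estimates and residuals."""

    trait: str
    mu: float  # intercept plus the mean of each factor's level effects
    generation_effects: pd.Series  # treatment-coded, first level = 0
    line_effects: pd.Series
    sire_variance: float
    resid_variance: float
    sire_blups: pd.Series
    residuals: pd.Series  # indexed by hen_id; conditional unless requested otherwise
    conditional: bool
    lmm: LmmFit

    def summary_frame(self) -> pd.DataFrame:
        rows = [("mu", self.mu)]
        rows += [(f"generation[{k}]", v) for k, v in self.generation_effects.items()]
        rows += [(f"line[{k}]", v) for k, v in self.line_effects.items()]
        rows += [("sire_variance", self.sire_variance), ("resid_variance", self.resid_variance)]
        return pd.DataFrame(rows, columns=["term", "estimate"])


def build_design(pheno: pd.DataFrame, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Treatment-coded design: intercept + generation + line dummies.

    The first (sorted) level of each factor is the reference.  ``extra``
    columns (e.g. a genotype covariate) are appended unchanged.
    """
    X = pd.DataFrame({"Intercept": np.ones(len(pheno))}, index=pheno.index)
    for factor in ("generation", "line"):
        levels = sorted(pheno[factor].unique())
        for lev in levels[1:]:
            X[f"{factor}[{lev}]"] = (pheno[factor] == lev).astype(float)
    if extra is not None:
        for col in extra.columns:
            X[col] = extra[col].astype(float)
    return X


def fit_adjustment_model(
    pheno: pd.DataFrame, trait: str, conditional: bool = True
) -> AdjustmentFit:
    """Fit the adjustment model for one trait and return residuals.

    Hens with a missing trait value are dropped from the fit; their
    residuals come back missing from :func:`attach_residuals`.
    """
    if trait not in pheno.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    sub = pheno.loc[pheno[trait].notna()].copy()
    if sub["sire_id"].value_counts().ge(2).sum() < 2:
        raise ValueError("need at least two sires with two or more hens each")
    X = build_design(sub)
    fit = fit_random_intercept(sub[trait].to_numpy(), X, sub["sire_id"].to_numpy())

    gen_cols = [c for c in X.columns if c.startswith("generation[")]
    line_cols = [c for c in X.columns if c.startswith("line[")]
    gen_eff = pd.Series(
        {c.split("[")[1].rstrip("]"): fit.beta[c] for c in gen_cols}, dtype=float
    )
    line_eff = pd.Series(
        {c.split("[")[1].rstrip("]"): fit.beta[c] for c in line_cols}, dtype=float
    )
    n_gen = len(gen_cols) + 1
    n_line = len(line_cols) + 1
    # report mu as the grand mean over the factor grid, not the reference cell
    mu = float(fit.beta["Intercept"] + gen_eff.sum() / n_gen + line_eff.sum() / n_line)

    resid = fit.resid_conditional if conditional else fit.resid_marginal
    return AdjustmentFit(
        trait=trait,
        mu=mu,
        generation_effects=gen_eff,
        line_effects=line_eff,
        sire_variance=fit.sigma2_u,
        resid_variance=fit.sigma2_e,
        sire_blups=fit.blups,
        residuals=pd.Series(resid, index=sub["hen_id"].to_numpy()),
        conditional=conditional,
        lmm=fit,
    )


def attach_residuals(pheno: pd.DataFrame, fits: dict[str, AdjustmentFit]) -> pd.DataFrame:
    """Add one ``resid_<trait>`` column per fitted trait.

    Hens absent from a fit (missing trait value) get NaN for that trait's
    residual; other columns are untouched.
    """
    out = pheno.copy()
    for trait, fit in fits.items():
        if trait not in pheno.columns:
            raise KeyError(f"trait {trait!r} not in phenotype table")
        out[f"resid_{trait}"] = out["hen_id"].map(fit.residuals)
    return out
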