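"""Boruta all-relevant SNP selection around a random-forest regressor.

Boruta asks, for every SNP, whether its forest importance is better than
chance.  "Chance" is estimated empirically: each iteration the active SNP
columns are copied and row-shuffled ("shadow attributes"), a regression
forest is fitted on real plus shadow columns, and a SNP scores a *hit* when
its impurity importance strictly exceeds the ``perc``-th percentile of the
shadow importances (``perc=99`` by default: a SNP must beat essentially all
of its shadows).  Under the null, hits are Binomial(iterations, 1/2), so an
exact two-sided binomial test — Bonferroni-corrected across the SNPs still
in play — promotes SNPs to *confirmed* or demotes them to *rejected*;
whatever is left when the iteration budget runs out stays *tentative*.

The forest is a plain ``RandomForestRegressor`` (the response is a
continuous adjusted phenotype) with square-root feature subsampling and
impurity-based importances.  Each iteration draws its RNG from the master
seed plus the iteration index, so runs are bit-reproducible and histories
do not depend on when the loop stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .io_qc import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BorutaConfig",
    "BorutaResult",
    "make_shadow",
    "iteration_hits",
    "decide_statuses",
    "boruta_run",
]

CONFIRMED, TENTATIVE, REJECTED = "confirmed", "tentative", "rejected"


@dataclass
class BorutaConfig:
    perc: float = 99.0  # percentile of shadow importances a SNP must beat
    alpha: float = 0.05
    max_iter: int = 100
    n_trees: int = 500
    correction: str = "bonferroni"  # or "none"
    seed: int = 0
    resolve_tentative: str = "exclude"  # or "median-rule"

    def __post_init__(self):
        if not (0 <= self.perc <= 100):
            raise ValueError("perc must be in [0, 100]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iter < 8:
            raise ValueError("max_iter must be >= 8")
        if self.n_trees <= 0:
            raise ValueError("n_trees must be > 0")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")
        if self.resolve_tentative not in ("exclude", "median-rule"):
            raise ValueError("resolve_tentative must be 'exclude' or 'median-rule'")


@dataclass
class BorutaResult:
    statuses: pd.Series  # per snp_id: confirmed / tentative / rejected
    hits: pd.Series
    n_iterations_active: pd.Series
    importance_history: pd.DataFrame  # iteration, snp_id, importance
    shadow_history: pd.DataFrame  # iteration, shadow_max, shadow_perc
    n_iterations: int
    seed: int

    @property
    def confirmed(self) -> list:
        return self.statuses.index[self.statuses == CONFIRMED].tolist()

    def to_frame(self, snps: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            dict(
                snp_id=self.statuses.index,
                status=self.statuses.values,
                hits=self.hits.reindex(self.statuses.index).values,
                iterations=self.n_iterations_active.reindex(self.statuses.index).values,
            )
        )
        if snps is not None:
            out = out.merge(snps[["snp_id", "chrom", "pos"]], on="snp_id", how="left")
            out = out[["snp_id", "chrom", "pos", "status", "hits", "iterations"]]
        return out


def make_shadow(
    codes: np.ndarray, rng: np.random.Generator, pool: np.ndarray | None = None
) -> np.ndarray:
    """Append one independently row-permuted copy of every column.

    The shadows keep each SNP's marginal genotype distribution but destroy
    any association with the response, giving the null importance scale.
    When ``pool`` is given, additional shadows are drawn (with replacement)
    from its columns until the shadow block is as wide as the pool: the
    percentile threshold is an extreme order statistic, so letting the
    shadow pool shrink as SNPs are rejected would silently lower the bar
    for the survivors.
    """
    codes = np.asarray(codes)
    if codes.ndim != 2 or codes.shape[1] == 0:
        raise ValueError("need a 2-D matrix with at least one active SNP")
    n = codes.shape[0]
    shadow = codes.copy()
    if pool is not None and pool.shape[1] > codes.shape[1]:
        extra = pool[:, rng.choice(pool.shape[1], size=pool.shape[1] - codes.shape[1])]
        shadow = np.hstack([shadow, extra.copy()])
    for j in range(shadow.shape[1]):
        shadow[:, j] = shadow[rng.permutation(n), j]
    return np.hstack([codes, shadow])


def iteration_hits(
    importances: np.ndarray, n_real: int, perc: float, n_shadow: int | None = None
) -> np.ndarray:
    """Hit flags for one iteration.

    ``importances`` holds the ``n_real`` real columns first, then the
    shadows (``n_real`` of them unless ``n_shadow`` says otherwise).  The
    threshold is the ``perc``-th percentile of the shadow importances
    (linear interpolation between order statistics); a SNP hits when its
    importance is strictly greater.
    """
    if n_shadow is None:
        n_shadow = n_real
    importances = np.asarray(importances, dtype=float)
    if importances.shape != (n_real + n_shadow,):
        raise ValueError(f"expected {n_real + n_shadow} importances, got {importances.shape}")
    if not np.all(np.isfinite(importances)):
        raise ValueError("non-finite importances")
    threshold = np.percentile(importances[n_real:], perc)
    return importances[:n_real] > threshold


def decide_statuses(
    hits: int, n_iter: int, n_active: int, alpha: float = 0.05, correction: str = "bonferroni"
) -> str:
    """Classify one SNP from its hit count by an exact binomial test.

    Under the null the hit count is Binomial(n_iter, 0.5).  With
    ``correction='bonferroni'`` the per-tail level ``alpha/2`` is divided by
    the number of features still in play.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be > 0")
    level = alpha / 2
    if correction == "bonferroni":
        level /= max(n_active, 1)
    if stats.binom.sf(hits - 1, n_iter, 0.5) < level:  # P(X >= hits)
        return CONFIRMED
    if stats.binom.cdf(hits, n_iter, 0.5) < level:  # P(X <= hits)
        return REJECTED
    return TENTATIVE


def boruta_run(
    g: GenotypeMatrix, response: pd.Series | np.ndarray, config: BorutaConfig | None = None
) -> BorutaResult:
    """Run the full Boruta loop over all SNPs of an oriented matrix.

    ``response`` is the adjusted phenotype, aligned with ``g.sample_ids``
    (a Series is reindexed by sample id).  Samples with a missing response
    are dropped.  Zero-variance SNPs never beat a shadow and are rejected
    up front with a warning.  Confirmed and rejected SNPs both leave the
    active matrix; the loop stops when nothing is left undecided or at
    ``max_iter``, at which point ``resolve_tentative`` says what to do with
    the remainder ("exclude" keeps them tentative; "median-rule" confirms
    those whose median importance beat the median shadow maximum).
    """
    config = config or BorutaConfig()
    if not g.oriented:
        raise ValueError("genotype matrix must be oriented to the minor allele first")
    if isinstance(response, pd.Series):
        response = response.reindex(g.sample_ids).to_numpy(dtype=float)
    else:
        response = np.asarray(response, dtype=float)
    if response.shape != (g.n_samples,):
        raise ValueError("response length does not match the sample count")
    keep = np.isfinite(response)
    y = response[keep]
    X_all = g.codes[keep].astype(np.float32)
    if np.any(X_all == MISSING):
        raise ValueError("genotype matrix contains missing calls; impute first")
    if y.size < 10:
        raise ValueError("fewer than 10 samples with a response")
    if np.var(y) == 0:
        raise ValueError("response has zero variance")

    snp_ids = g.snps["snp_id"].to_numpy()
    m = len(snp_ids)
    statuses = pd.Series(TENTATIVE, index=snp_ids, dtype=object)
    hits = pd.Series(0, index=snp_ids, dtype=int)
    n_active_iter = pd.Series(0, index=snp_ids, dtype=int)

    zero_var = X_all.std(axis=0) == 0
    if zero_var.any():
        logger.warning("rejecting %d zero-variance SNPs before the loop", int(zero_var.sum()))
        statuses.iloc[np.flatnonzero(zero_var)] = REJECTED

    # "active" SNPs stay in the forest design (tentative + confirmed); only
    # rejected ones leave.  Keeping confirmed SNPs and their shadows in the
    # matrix preserves the null importance scale for the remaining tests.
    imp_rows, shadow_rows = [], []
    n_iter_done = 0

    for it in range(1, config.max_iter + 1):
        tentative = np.flatnonzero((statuses == TENTATIVE).to_numpy())
        active = np.flatnonzero((statuses != REJECTED).to_numpy())
        if tentative.size == 0 or active.size == 0:
            break
        # per-iteration stream: reproducible regardless of stopping iteration
        rng = np.random.default_rng([config.seed, it])
        X = make_shadow(X_all[:, active], rng, pool=X_all[:, ~zero_var])
        forest = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X, y)
        imp = forest.feature_importances_
        flags = iteration_hits(imp, active.size, config.perc, n_shadow=X.shape[1] - active.size)
        is_tent = np.isin(active, tentative)
        tent_ids = snp_ids[active[is_tent]]
        hits[tent_ids] += flags[is_tent].astype(int)
        n_active_iter[tent_ids] += 1
        n_iter_done = it

        imp_rows.append(
            pd.DataFrame(dict(iteration=it, snp_id=snp_ids[active], importance=imp[: active.size]))
        )
        shadow_imp = imp[active.size :]
        shadow_rows.append(
            dict(
                iteration=it,
                shadow_max=float(shadow_imp.max()),
                shadow_perc=float(np.percentile(shadow_imp, config.perc)),
            )
        )

        n_tested = tentative.size
        for j in tentative:
            s = decide_statuses(
                int(hits.iloc[j]), int(n_active_iter.iloc[j]), n_tested,
                config.alpha, config.correction,
            )
            if s != TENTATIVE:
                statuses.iloc[j] = s

    history = (
        pd.concat(imp_rows, ignore_index=True)
        if imp_rows
        else pd.DataFrame(columns=["iteration", "snp_id", "importance"])
    )
    shadow_history = pd.DataFrame(shadow_rows, columns=["iteration", "shadow_max", "shadow_perc"])

    if config.resolve_tentative == "median-rule" and (statuses == TENTATIVE).any():
        med_shadow = shadow_history["shadow_max"].median()
        med_imp = history.groupby("snp_id")["importance"].median()
        for sid in statuses.index[statuses == TENTATIVE]:
            if med_imp.get(sid, -np.inf) > med_shadow:
                statuses[sid] = CONFIRMED

    return BorutaResult(
        statuses=statuses,
        hits=hits,
        n_iterations_active=n_active_iter,
        importance_history=history,
        shadow_history=shadow_history,
        n_iterations=n_iter_done,
        seed=config.seed,
    )
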