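# Methods

`hensnp` re-implements, as a tested library, a SNP-discovery and
effect-annotation workflow for bone-stability traits in laying hens: bone
breaking strength (BBS, N) and bone mineral density (BMD, g/cm²) of the
tibiotarsus and humerus, measured on hens from four purebred layer lines
across two generations with paternal half-sib family structure (up to 145
sires). This note records the models, the defaults and why, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would want to know.

## The mixed-model core

Every model in the pipeline shares one structure: fixed effects plus a
single random sire intercept,

    y = Xβ + Zu + e,  u ~ N(0, σ²_s I),  e ~ N(0, σ²_e I).

Because there is exactly one variance component, the restricted likelihood
profiles down to a univariate function of λ = σ²_s/σ²_e. `hensnp.lmm`
exploits this: per-sire closed forms for the GLS cross-products and
log-determinants make one likelihood evaluation O(n p²), and a bounded
scalar search maximises the profile to 1e-8. The generic optimisers behind
off-the-shelf mixed-model fitters proved fragile on exactly this design
(they can converge far from the balanced-case closed form); the profiled
search cannot, and the test suite pins the engine against both the
closed-form balanced one-way REML estimator and an independent
mixed-model fit.

Fixed-effect tests use residual degrees of freedom (n minus the rank of
X). Variance-component standard errors come from the observed information
of the restricted log-likelihood in (σ²_s, σ²_e), by central differences
with relative step 1e-3 (small enough for curvature, large enough that
round-off in the log-likelihood does not pollute the quotient). Wald
intervals on a variance scale are asymptotic and mildly undercover in
skewed small-family settings; the calibration tests quantify this.

A σ²_s estimate at the zero boundary is allowed (with a warning); its SE
is reported as NaN because the information is one-sided there.

## Stage by stage

**QC** (`io_qc`). Keep autosomes 1–28, then SNPs with call rate ≥ 99%,
then animals with call rate ≥ 95% (rates recomputed on surviving SNPs).
The order is logged in the report object so deviations are visible. There
is no MAF filter; monomorphic SNPs pass QC flagged with effect-allele
frequency 0 and are skipped by the selection and effect stages. The naive
imputation fills each missing call from the SNP's within-line empirical
genotype distribution — it preserves marginal frequencies but, unlike
haplotype-based imputation, uses no linkage information, which is adequate
here because no downstream stage exploits LD.

**Orientation.** Codes count copies of the minor ("effect") allele;
exact-0.5 ties resolve to the lexicographically smaller allele string so
the choice is format-independent.

**Adjustment** (`adjust`). Trait ~ mean + generation + line + sire(random),
fitted by REML; the residuals are the response for feature selection, so
line and family structure cannot masquerade as SNP signal. Residuals are
*conditional* by default (BLUP sire effect subtracted; family means
removed); marginal residuals are available via `conditional=False`.
Conditional residuals are exactly orthogonal to the fixed-effect columns
(r_c = σ̂²_e V̂⁻¹ r_marginal), which the tests assert. Note that their
sums vanish per generation level and per line level, not per
generation×line cell — the model is additive, without interaction.

**Boruta selection** (`boruta`). Each iteration permutes every active SNP
column ("shadow attributes"), fits a `RandomForestRegressor`
(n_trees = 500 by default, square-root feature subsampling, impurity
importances), and scores a *hit* for SNPs whose importance strictly
exceeds the `perc` = 99th percentile (linear interpolation) of the shadow
importances. Hits are tested against Binomial(iterations, ½) two-sided,
Bonferroni-corrected across the SNPs still undecided; confirmed and
rejected SNPs stop being tested, and rejected ones leave the design
matrix. Two deliberate choices:

* *Confirmed SNPs stay in the forest.* Removing strong predictors would
  reshape the conditional importance distribution for the remainder.
* *The shadow pool never shrinks.* The hit threshold is an extreme order
  statistic of the shadow importances; if shadows were drawn only for the
  surviving SNPs, rejection of the bulk would collapse the threshold to
  the maximum of a handful of weak columns, and any chance-correlated
  survivor would then hit every iteration. Shadows are therefore topped
  up with permuted copies of columns drawn from the full input matrix so
  the pool keeps its original width. Measured on pure-noise responses
  (100 SNPs), this keeps the mean confirmed count well below 1; without
  it the count is ~4.

Boruta is an *all-relevant* selector: on a fixed dataset, a noise SNP
whose realized correlation with the response is extreme (|r| ≈ 0.2 is
typical for the best of 50 at n = 200) is genuinely informative about
that realization and may be confirmed alongside a planted signal. The
power tests therefore assert that the planted SNP is confirmed and
attains the top hit count, not that it is the sole confirmation.

Per-iteration RNG streams derive from (seed, iteration), so histories are
bit-reproducible and independent of when the loop stops.

**Gene annotation** (`annotate`). A SNP maps to every protein-coding gene
whose body, expanded by 5 kb on both sides, contains it (1-based,
inclusive). This is equivalent to SNP-centric distance-to-gene ≤ 5 kb.
Upstream/downstream labels are strand-aware (5′ side = upstream) — a
convention choice, stated here because the convention used for the
published tables is not documented. No nearest-gene collapsing. The
interval index is cross-checked against a brute-force O(S·G) scan.

**Effect estimation** (`effects`). For each candidate SNP × trait:
single-marker regression (genotype code as covariate; the slope is the
allele-substitution effect, also reported in SD units after z-scoring
both response and code) and the dominant–recessive model (genotype as a
3-level factor). Least-squares means average equally over the generation
and line levels (reference-grid style); the biometric effects

    a = (μ_AA − μ_BB)/2,  d = μ_AB − (μ_AA + μ_BB)/2

are linear contrasts of the same fit (AA = major-allele homozygote), so
their SEs come from the fixed-effect covariance and the a/d identities
hold exactly regardless of the factor weighting. Pairwise genotype
contrasts are t-tested with a Bonferroni factor of 3 per locus (no
cross-SNP correction, mirroring per-locus reporting). Compact letter
displays are the maximal cliques of the non-significance graph.
With a purely additive locus (d = 0), the substitution effect satisfies
β = −(a + d(p − q)) = −a under this coding, which the consistency test
exercises.

**Enrichment** (`enrich`). Hypergeometric upper-tail over-representation
of a query gene list per GMT term, Benjamini–Hochberg (default) or
Bonferroni adjusted. The universe defaults to the union of term genes;
pass an explicit universe for "all known genes" semantics. The
proprietary multiple-testing scheme of the original web tool is not
reproduced; with database-version-dependent term content, published
enriched-term counts are not reproducible by design.

**Pipeline** (`pipeline`, `cli`). One master seed fans out per stage via
SHA-256 of "seed:stage", so each stage is independently re-runnable. The
manifest records per-stage row counts and SHA-256 hashes of every output;
re-running an identical config must reproduce identical hashes, which the
end-to-end test asserts.

## The synthetic-data generator

`simulate` emulates the study design: hens dealt evenly across 4 lines ×
2 generations, sires nested within line with near-equal family sizes,
per-SNP/per-line minor-allele frequencies drawn uniformly (default range
0.05–0.5 per line) and genotypes in Hardy–Weinberg proportions within
line. Phenotypes are mean + generation + line + sire + QTL + residual,
with the QTL contribution coded +a / d / −a for 0/1/2 effect-allele
copies — the same sign convention the estimators use, so recovery tests
are sign-consistent. Defaults: 524 hens, 145 sires, line shifts 0/15/30/45
N, generation shift 10 N, sire SD 5 N, residual SD 15 N — magnitudes in
line with adult-hen BBS variation; BMD traits use the same machinery
scaled by 1/600 (≈0.25 g/cm² per ≈150 N). Planted QTL effects default to
a = 8 N, d = 2 N — deliberately supra-polygenic so that desk-scale
selection has signals to find. QTL are assigned round-robin to traits;
every planted quantity is returned in a `SyntheticTruth` record, and a
zero-residual simulation is exactly reconstructable from it.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent given line), sex chromosomes, multi-generation pedigree,
genotyping batch effects, or array ascertainment. Passing tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to LD-induced redundancy — on real array data, clusters of
linked SNPs would share credit and confirmed-SNP counts would depend
strongly on LD structure (and on the iteration/tree budget, which the
original study did not report).

Gene models are placed non-overlapping, with a configurable fraction of
QTL SNPs guaranteed a gene within the 5 kb window; gene sets partition
genes with one term collecting the QTL-adjacent genes, giving the
enrichment stage a planted positive.

## Test and acceptance problem sizes

Simulation-backed checks run at desk scale, chosen once: Boruta null
calibration at 100 hens × 100 SNPs, 60 trees, 60 iterations, 50 seeds;
Boruta power at 200 hens × 51 SNPs, 75 trees, 24 iterations, 100 seeds;
effect-recovery and REML calibration at n = 2000 with 100 sires (100 and
50 replicates); the end-to-end determinism check at 260 hens × 400 SNPs
with 80 trees. Seed conventions are a priori (replicate r uses seed r).

One calibration check is expected to sit on a knife edge: the ±2·SE
recovery criterion for the dominant–recessive model demands ≥95% coverage
from an interval whose true coverage, measured over 500 independent
replicates, is ≈94.8% (nominal 95.45% minus the usual plug-in effect of
estimating the variance parameters). The estimator itself is unbiased and
its SEs match an independent mixed-model implementation to four decimals;
the additive-effect count at the frozen seeds is 94/100 and the test is
left asserting the stated bar rather than widening it.

## Known limitations

* Published standard errors, t- and p-values for the candidate SNPs
  depend on the unavailable study data and on the original software's
  degrees-of-freedom conventions; only the LSM → (a, d) arithmetic is
  claimed exactly reproducible, and the bundled tables carry the printed
  (rounded) means.
* Confirmed-SNP counts from Boruta depend on unstated run parameters
  (iterations, trees, tentative handling) even before data access; they
  are not reproduction targets.
* The naive imputation is not a substitute workflow for reference-panel
  imputation when downstream analyses exploit LD.
* Classification-mode forests (binary traits) are out of scope; the
  response is always a continuous adjusted phenotype.
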