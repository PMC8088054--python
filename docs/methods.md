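# Methods

## Phenotype model

eGFR is computed from serum creatinine with the CKD-EPI 2009 equation,

eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.209) · 0.993^age ·
1.018[female] · 1.159[black],

with κ = 0.7/0.9 and α = −0.329/−0.411 for women/men. The constants live in
`PhenotypeParams` and are overridable but fixed by default. The function is
strictly decreasing in creatinine and age; non-positive inputs are rejected.

## Per-cohort association model

Each probe is analyzed by OLS of eGFR on beta with covariates (age, sex,
smoking-status dummies plus pack-years jointly — the two capture different
aspects of exposure and are deliberately entered together — leukocyte
proportions with one category dropped, genotype PCs, batch dummies).
Standard errors use the sandwich estimator; the default weight is HC3
(1/(1−hᵢ)², the common default of robust-SE software), configurable to
HC0/HC1 or the classical homoscedastic formula (`hc="classical"`, for studies
analyzed without robust estimation). p-values use the standard normal
reference rather than t: downstream fixed-effect combination works on z
statistics, and at study sample sizes the difference is negligible.

`run_ewas` vectorizes the scan with the Frisch–Waugh–Lovell identity: the
probe coefficient equals the simple regression of covariate-residualized eGFR
on the covariate-residualized probe, the full-model residual equals the
residual of that simple regression, and the full-model leverage decomposes as
h = h_covariates + x̃²/Σx̃². Every HC variant of the (probe, probe) sandwich
element is therefore computable for all probes from one QR decomposition of
the covariate design, in chunked dense algebra. Tests pin the dense path to
the single-probe `fit_probe` and both to an explicit-matrix oracle.

Family studies use a random-intercept-per-family model, V = σ²(I + θZZ').
θ = τ²/σ² is profiled by REML using closed-form per-family block inverses
(Woodbury: A_f⁻¹ = I − θ/(1+θn_f)·J), optimized on [0, 200] by bounded scalar
minimization with an explicit boundary comparison at θ = 0, and the fixed
effect and SE come from GLS at the estimates, i.e. the plug-in covariance
σ̂²(X'Â⁻¹X)⁻¹. statsmodels' MixedLM serves as an independent cross-check in
the tests; its reported SEs derive from the joint information matrix and
agree with the plug-in GLS covariance to ~1% at the sample sizes tested.
Numerical failure of the REML solve falls back to the sandwich OLS fit with a
cluster flag.

Degenerate exact fits (zero residual variance) report se = 0 with the
sentinel p = 1e−300 and a `degenerate` flag; all p-values are floored there.
Rank-deficient designs and probes with fewer than `min_n` complete cases
(default: parameters + 2) are skipped with a reason.

Genomic inflation is λ = median(χ²₁(p_obs)) / 0.454936, the median of the
χ²₁ distribution taken from scipy at full precision.

## Meta-analysis, discovery, replication

Fixed-effect inverse-variance combination: effect = Σwᵢbᵢ/Σwᵢ with
wᵢ = 1/SEᵢ², SE = (Σwᵢ)^(−1/2), Q = Σwᵢ(bᵢ−effect)², I² = max(0, (Q−df)/Q).
Probes in fewer than two studies are excluded. Discovery uses
Benjamini–Hochberg at FDR 0.05; replication requires p ≤ α/m over the m hits
carried forward plus direction concordance. The boundary counts as passing
("≤"): at printed precision the strict/non-strict distinction is not
observable. Direction strings order studies by study id for determinism.
BH and BY adjustments are delegated to statsmodels' `multipletests` behind
the package's `bh_fdr`/`by_correct` surface; the test suite verifies both
against an independent step-up enumeration.

`se_from_effect_p` inverts a printed (effect, p) pair through the normal
quantile, which is what lets the bundled 13-DMP worked-example table — printed
discovery and replication pairs from a published multi-ethnic EWAS — be
re-combined; the recombined effects match the published combined column to
±0.05, the slack induced by 2-decimal rounding of the printed inputs.

## Open-chromatin overlap enrichment

A probe overlaps an interval by its single interrogated base: a 1-based
position pos hits a 0-based half-open [start, end) iff start < pos ≤ end.
Backgrounds are matched on the island-relation × gene-relation strata (the
matching criteria are configurable): each background set reproduces the
query's stratum composition exactly, sampled without replacement within a
set, never intersecting the query, and raising a named error when a stratum
has fewer than twice the needed candidates. The empirical p uses a +1
pseudocount, (#{bg ≥ obs}+1)/(B+1), so 1000 backgrounds floor it at ~0.001
rather than 0; z-scores accompany it. Per-tissue p-values are BY-corrected
across tissues (BY rather than BH because the per-tissue statistics share
backgrounds and are positively dependent in an uncontrolled way). Ranked
probe batches ("1–1000, 1001–2000, …") are disjoint rank windows; ties at a
window edge break lexicographically by probe id.

## cis-meQTL scan and overlap tests

Cis pairs are same-chromosome SNP–CpG pairs with distance ≤ 1 Mb, boundary
inclusive. The scan residualizes M-values and dosages on the covariates once
and fits each pair by simple regression, with the classical SE and a
two-sided p from the t reference at full-model degrees of freedom;
monomorphic SNPs are skipped. CpGs are "associated" when any of their records
has p < 0.05 and "non-associated" when all have p > 0.95.

The empirical overlap tests count *distinct* CpGs (a CpG targeted by several
query SNPs counts once) that are significant (p < 0.05 by default) meQTL
targets of ≥1 query SNP and that belong to a DMP set (variant a) or fall
inside a tissue's intervals (variant b). Background simulations redraw
equally sized SNP sets uniformly without replacement from the supplied pool
(the original pool composition is unknown, so matching is left to the
caller's choice of pool), with the same +1-pseudocount empirical p. On small
pools the simulated p converges to the exhaustively enumerated tail
probability; the tests check this on ≤8-SNP pools.

## Synthetic-cohort generator

The generator emulates what the downstream stages consume, not raw array
data: it emits already-normalized betas (no IDATs, no BMIQ/NOOB-type
normalization, no Houseman deconvolution — cell fractions are known by
construction), covariates from documented distributions (age U(45,75), sex
Bernoulli, smoking never/past/current at 0.55/0.30/0.15 with gamma
pack-years for smokers, Dirichlet leukocyte fractions centred on whole-blood
means, standard-normal PCs, uniform batches), and creatinine lognormal with
sex-specific location near κ and log-SD 0.2, giving eGFR distributions
centred near 80–90 with SD ≈ 15.

Methylation is built on the logit scale: logit(β) = a_j + s_j·c_i + b_j·z_i +
u_family + ε, where c is a standardized confounder score loading on age, sex,
smoking, pack-years, granulocyte fraction and batch (per-probe loadings s_j ~
N(0, 0.5)), z is standardized eGFR, and ε ~ N(0, noise_sd) with noise_sd = 1.0
by default (≈1.4 in M-value units, within the range of variably methylated
blood probes). Association is planted on the methylation side to keep betas
bounded; the slope b_j for a planted probe is calibrated numerically — the
expected covariate-adjusted regression coefficient of eGFR on β is evaluated
by Gauss–Hermite integration over the probe noise, with the between-sample
variance taken after residualizing on the analysis design, and inverted by
root bracketing on the attenuated-signal branch. Unattainable targets raise a
calibration error instead of silently saturating. Planted probes draw their
baseline logit from the intermediate range (−1.5, 1.5), since a
trait-associated CpG must be variably — hence intermediately — methylated;
null probes span (−3, 3). With these defaults, planted effects of the
magnitude seen in published kidney-function EWAS (−30 to +15 eGFR units per
unit beta) are recovered with ≈2–3% bias and detected with essentially full
power at n = 2000, and the effect-to-noise ratio is deliberately more
favorable than in typical blood EWAS so that desk-scale simulations exercise
the full discovery–replication path; passing tests therefore demonstrate the
statistical machinery, not field-realistic power.

Family structure draws independent per-family intercepts for the phenotype
(on log-creatinine, partitioning its variance by the requested within-family
correlation) and for each probe's noise. Independent rather than literally
shared intercepts are used because a common intercept on both sides would
confound every null probe — which no mixed model corrects — whereas
independent intercepts produce exactly the within-family error correlation
that distinguishes the REML estimator from OLS.

Side fixtures: detection-p matrices (background U(0, 0.005), designated
failures in (0.01, 1]); Hardy–Weinberg dosage matrices with planted
SNP→CpG M-value effects; hotspot interval collections covering probes at a
base rate with one tissue covering an enriched probe set at a chosen
fraction (intervals of 301 bp centred on the probe base, merged per tissue —
the realized base rate is approximate to the extent merged neighbours
capture extra probes). All generators are pure functions of their spec and
seed.

## Numerical and design choices

- Strict ">" inequalities in the detection filter, probes removed before
  samples (sample fractions evaluated against retained probes); the filter is
  idempotent and the ordering is pinned by a test where the two orders differ.
- Beta clamp for the M transform: 1e−6 (keeps M finite at the boundaries);
  generated betas are clipped away from 0/1 at 1e−12.
- Empirical p-values never reach 0 by construction; BY q ≥ empirical p.
- Probes constant after covariate adjustment are skipped, not fit.
- Seeds: every stochastic routine takes an explicit seed; identical inputs
  give bitwise-identical outputs.

## Problem sizes used in the checks

Null calibration runs 20 cohorts of n = 2000 × 10,000 null probes;
effect-recovery runs 50 cohorts of n = 2000 with 2000 probes and two planted
effects; enrichment power uses 20 planted collections over 11 tissues and the
null calibration 500 runs × 10 tissues with 199 matched background sets
(3000-probe manifest, 300-probe queries — sizes chosen so the discrete
overlap statistic has enough resolution for a meaningful 5% rejection rate);
the end-to-end pipeline in `scripts/acceptance.py` uses seven discovery
strata (n = 3600 total, one family-based study fit by REML) and three
replication cohorts (n = 2760) on a 4000-probe manifest with six planted
DMPs. These sizes are the package's own trade-off between Monte-Carlo error
and turnaround; all thresholds they are checked against are stated in the
tests.

## Known limitations

- No linkage disequilibrium in genotypes, no realistic CpG co-methylation
  structure (probes are independent given the confounder score), no
  array-normalization artefacts.
- The FastQTL permutation/beta-approximation p-values are not reimplemented;
  the scan reports nominal p only.
- The family model supports one variance component (random intercept);
  no kinship matrices or nested random effects.
- Ethnicity enters the phenotype only through the CKD-EPI ancestry constant
  and sampling design; there is no ancestry-specific methylation structure.
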