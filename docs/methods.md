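# Methods

This note records the modelling choices, defaults and numerical details
behind `aasub`, and what the synthetic-data experiments do and do not
establish.

## From exchangeabilities to pair rates

Reversible models (lower-triangular `s_ij` + frequencies `π`, PAML dialect)
are converted to directed rates `Q_ij = s_ij · π_j`; detailed balance
`π_i Q_ij = π_j Q_ji` then holds by construction. Non-reversible models are
taken as full matrices of directed rates; their diagonal is ignored and never
enters a pair table. Two tabulations are supported: **directed** (380 rows,
the default) and **unordered** (190 rows, each rate the arithmetic mean of
the two directions). Directed is the default because the model's crossed
random-intercept structure (donor and acceptor identity) is defined on
directions and keeps the non-reversible case fully general; for reversible
inputs the two modes carry the same information. The response is the natural
log of the rate (base configurable, recorded in output metadata). Rates are
used as published; an optional normalization (divide by the mean rate) only
shifts the intercept and is off by default.

Amino acids are ordered everywhere as `A R N D C Q E G H I L K M F P S T W Y V`
(the PAML convention); the genetic code is fixed to NCBI translation table 1,
and alternative codes are rejected rather than silently substituted.

## Mutational covariates

Per amino acid: mean codon GC fraction and mean codon pyrimidine fraction,
averaging uniformly over that amino acid's sense codons (no codon-usage
weighting). Per pair: absolute differences of these two means, and the
minimum Hamming distance between codon sets ("minimum mutational steps",
1–3). Intermediate codons are not required to be sense codons; the
constrained-path variant is out of scope. The pyrimidine-fraction difference
serves as a pair-level transition:transversion proxy — a large difference
means interchanging the two amino acids tends to require transversions — and
is used under that definition, whatever it is called elsewhere.

## Property scales and PCA

The embedded default set is eight published AAIndex records, each pinned to
its accession: hydropathy KYTJ820101, contact energy MIYS990105, flexibility
BHAR880101, polarity GRAR740102, net charge KLEP840101, molecular weight
FASG760101, volume GRAR740103, maximum accessible surface area CHOC760101.
CHOC760101 was preferred over RADA880106 for accessible area because the
latter lacks a proline value. Users can substitute any AAIndex1 flat file or
a 20-row CSV; records containing `NA` are dropped with a warning (imputation
is deliberately not offered). Differences are computed on raw scale units;
standardization happens in the PCA, not earlier.

The PCA is correlation-based (center + unit variance) on the **190 unordered
pairs**; directed tables reuse scores by symmetry rather than duplicating
rows, which would distort variance fractions. Signs of principal axes are
arbitrary, so a deterministic convention is applied: PC1 is anchored to a
positive hydropathy loading and PC2 to a positive molecular-weight loading
when those columns exist, otherwise each axis's largest-magnitude loading is
made positive. Slope signs in fitted models are interpretable only relative
to this convention. Variable diagnostics follow the usual definitions:
contribution = 100 × squared loading, cos² = squared variable–component
correlation. With the embedded set, the size family (ASA, weight, volume)
leads the first axis and the charge/hydrophobicity family the second
(~36% + ~31% of variance); which family comes first depends on the property
list supplied.

## The mixed model

Response and all fixed covariates are z-scored by default (slopes are then
in SD units and the intercept is ~0); the interaction column is the product
of the two scaled main effects, not rescaled again. The scaling policy is
recorded in the fit report, and a raw-scale option exists. Random structure:
directed mode fits one variance component for donor identity and one for
acceptor identity; unordered mode fits a single shared component whose
design row has unit loadings on both pair members (so its variance enters
the total-variance decomposition twice).

Fitting goes through statsmodels `MixedLM` (variance components). The
optimizer cascade starts with BFGS at gradient tolerance 1e-10, which
resolves variance components to near machine precision when it converges;
on non-convergence (common at a variance boundary) CG, Powell and the
default cascade are tried, the candidate with the best likelihood is kept,
and that point is accepted only if a direct coordinate probe of the profiled
(RE)ML log-likelihood confirms no feasible improvement. Optimizer success
flags alone are not trusted: an optimizer can report convergence at a
clearly inferior point. Variance components below 1e-6 of the residual
variance are flagged as boundary estimates, not errors.

Reported standard errors are GLS standard errors at the estimated variance
components, `sqrt(diag((XᵀV⁻¹X)⁻¹))` — the convention of the mixed-model
literature (this matches `lmerTest`; statsmodels' own `bse_fe` differs
slightly). Denominator degrees of freedom are Satterthwaite:
`df_j = 2 f_j² / (g_jᵀ A g_j)` with `f_j` the coefficient variance, `g_j`
its central-difference gradient in the variance components (relative step
1e-6, absolute floor 1e-8 so boundary components stay differentiable), and
`A` the inverse negative Hessian of the profiled REML log-likelihood
(relative step 1e-4 — second differences at 1e-6 would be dominated by
cancellation). df are clipped to (1, n − p]; a normal-approximation fallback
(`satterthwaite=False`) uses n − p. The test suite cross-checks estimates,
SEs, df and p-values against R `lmerTest` to ≤2% on df and ~1e-4 elsewhere.

Coefficients are reported from REML fits; all model comparisons refit by ML
and use the likelihood-ratio χ² with df equal to the difference in
fixed-effect count, alongside ΔAIC (AIC = −2·logLik + 2·(p + #variance
components + 1)). Marginal and conditional R² follow Nakagawa–Schielzeth:
var(Xβ̂) over (var(Xβ̂) + Σ random variances + residual), with the random
variances added to the numerator for the conditional version. The
"mutational parameters as random factors" variant is available by listing
`min_steps`/`pyr_diff` in `ModelSpec.random`.

Per-step-class subset fits drop the `min_steps` fixed term and refit on each
stratum (75 one-step, 101 two-step, 14 three-step unordered pairs; ×2 when
directed); the small three-step stratum routinely produces boundary variance
estimates, which are surfaced as warnings. Welch's heteroscedastic ANOVA
(via pingouin) and Welch's t-test (via scipy) compare the pyrimidine proxy
and the PC scores across step classes.

## Synthetic data: what it emulates, what it does not

The generator draws 20 × P property values from a two-block correlation
structure (a charge-like and a size-like cluster, within-block r = 0.7,
between-block r = 0 by default, P = 8) so that difference-PCA yields two
dominant interpretable axes, and then log directed rates

    log q(a→b) = β·x_ab + u[a] + u[b] + ε_ab,  u ~ N(0, var_u), ε ~ N(0, σ²)

on the z-scored covariates. The mutational covariates are taken from the
*real* genetic code, keeping the collinearity between steps and property
differences realistic (one-step pairs genuinely tend to be more similar).
Defaults are var_u = 0.05, σ² = 0.15 and slopes (−0.4, −0.3, −0.4, −0.2,
interaction +0.08): with the ~0.49 variance of the fixed predictor this puts
the fixed-effect share of variance near 0.7 — the regime empirical Pfam-scale
matrices produce — so recovery experiments exercise a realistic
signal-to-noise ratio. These values are configuration, not claims about any
dataset.

All randomness flows through one `numpy` Generator seeded per scenario;
outputs are byte-reproducible, and generated model files round-trip through
the same readers used for empirical files.

What passing recovery tests show: the pipeline is unbiased and calibrated
*when the generating model is true* — linear effects, Gaussian noise,
homoscedastic residuals, exchangeable random intercepts. Real exchangeability
matrices can violate all of these (estimation error correlated across pairs,
non-linear property effects, lineage-specific composition), so recovery
results validate the machinery, not the biological model.

## Problem sizes and determinism

The acceptance script and test suite use 200 replicates for recovery and
null-LRT calibration, 380-row directed tables, and a 40-observation balanced
one-way design for the closed-form REML check — sizes chosen so the whole
battery runs in a few minutes on one CPU while leaving Monte-Carlo error
well inside the asserted tolerances (slope bias tolerance 0.02 vs. empirical
SE/√200 ≈ 0.002). Coverage is computed with normal-quantile intervals
(β̂ ± 1.96·SE); at 340–370 Satterthwaite df the t correction is negligible.

## Known limitations

* Criterion-level reproduction of published Pfam-matrix coefficient tables
  requires the exact external matrix and property files; the pipeline reads
  them (PAML/IQ-TREE dialects, AAIndex1, CSV) but does not bundle them.
* Random slopes, phylogenetically correlated errors and Bayesian fitting are
  out of scope; so are codon-level (61-state) models and estimating matrices
  from alignments.
* The Welch ANOVA requires every group to have ≥2 observations and positive
  variance; degenerate strata raise instead of silently collapsing.
* `min_steps` treats all single-nucleotide changes equally; a
  mutation-spectrum-weighted step count is not implemented.
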