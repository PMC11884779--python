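"""The full analysis: are dissimilar amino acids exchanged more slowly?

Runs every pipeline stage on a synthetic model with known ground truth
(slopes near the empirically observed regime) and prints the coefficient
table of the linear mixed model

    log rate ~ PC1 + PC2 + steps + pyr_diff + PC1:PC2
               + (1 | donor amino acid) + (1 | acceptor amino acid)

with Satterthwaite degrees of freedom, plus the variance decomposition and
the likelihood-ratio model comparisons.
"""

import tempfile

from aasub import RunConfig, run_full_analysis

with tempfile.TemporaryDirectory() as td:
    res = run_full_analysis(
        RunConfig(synthetic=True, seed=1, outdir=td, name="demo")
    )
    fit = res["fit_full"]

    print("fixed effects (z-scored response and covariates):")
    print(fit.summary_table(p_floor=2e-16).to_string(index=False))

    print("\nNegative PC1/PC2 slopes: pairs differing more in charge or size "
          "substitute more slowly. The negative steps slope shows exchanges "
          "needing several mutations are rarer still.")

    print(f"\nrandom-intercept variances: "
          + ", ".join(f"{k}={v:.4f}" for k, v in fit.var_u.items())
          + f"; residual = {fit.sigma2:.4f}")
    print(f"marginal R2 = {fit.r2_marginal:.2f} "
          f"(fixed effects), conditional R2 = {fit.r2_conditional:.2f} "
          "(fixed + amino-acid identity)")

    comp = res["comparisons"]
    print(f"\nmodel comparisons (ML likelihood-ratio tests):")
    print(f"  adding GC difference:      p = {comp['gc_term']['p']:.3f} "
          f"(delta AIC = {comp['gc_term']['delta_aic']:+.2f})")
    print(f"  dropping PC1:PC2:          p = {comp['interaction']['p']:.2e}")
    print("A non-significant GC term and an informative interaction mirror "
          "the structure the generator encodes.")
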