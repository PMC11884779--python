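"""Does the whole pipeline recover known coefficients without bias?

Repeatedly simulates an exchangeability model from a fixed covariate design,
re-runs the rate-table + mixed-model pipeline, and summarizes per-coefficient
bias, RMSE and 95% interval coverage.  (The acceptance checks run 200
replicates; 30 keep this example quick.)
"""

from aasub import SynthScenario, recovery_experiment

scenario = SynthScenario(seed=2)
report = recovery_experiment(scenario, replicates=30)

print(f"scenario: var_u = {scenario.var_u}, sigma2 = {scenario.sigma2}, "
      f"mode = {scenario.mode}")
print(f"replicates: {report.n_replicates}, fit failures: {report.n_failures}\n")
print(report.to_frame().round(4).to_string())
print("\nbias near zero and coverage near 0.95 mean the pipeline's estimates "
      "and standard errors can be taken at face value in this regime; "
      "empirical_se close to mean_model_se shows the SEs are calibrated.")
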