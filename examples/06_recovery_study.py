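"""Monte-Carlo recovery of a scaled variance parameter.

Draws repeated samples from a p = 8, lambda = 0.4, phi = 1 population,
refits the one-factor model (variance fixed to 1) on each sample covariance
and rescales by the squared-loadings criterion with p_c = 8.  The recovered
scaled variances scatter around the population value 8 * 0.16 / 8 = 0.16.
"""

from latentscale import GeneratorConfig, ModelSpec, recovery_study

config = GeneratorConfig(p=8, q=1, loadings=[[0.4, None]], n=1000)
spec = ModelSpec.one_factor(8, "reference_group")
report = recovery_study(config, spec, replicates=20, seed=7, scaling_params=[8.0])

print(f"population phi_sc : {report.population_value[0]:.4f}")
print(f"mean estimate     : {report.replicates['phi_sc[F1]'].mean():.4f}")
print(f"bias              : {report.bias[0]:+.4f}")
print(f"RMSE              : {report.rmse[0]:.4f}")
print(f"non-converged     : {report.n_nonconverged} of 20 replicates")
print(
    "\nAt n = 1000 the criterion-scaled variance is recovered essentially"
    "\nwithout bias; the RMSE reflects pure sampling error."
)
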