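"""Fit one population covariance under three identification conventions.

The same two-factor population is fitted by maximum likelihood with (a) one
marker loading per factor fixed to 1, (b) the latent variances fixed to 1,
and (c) the loadings of each factor constrained to sum to 3.  The parameter
estimates differ — they sit in different scales — but the true part
Lambda Phi Lambda' and the comparison-scaled variances are identical.
"""

import numpy as np

from latentscale import (
    GeneratorConfig,
    ModelSpec,
    SampleCovariance,
    comparison_scaling,
    constancy_distance,
    fit,
    generate_model,
    implied_covariance,
)

truth = generate_model(
    GeneratorConfig(
        p=6, q=2,
        loadings=[(0.7, [0, 1, 2]), (0.5, [3, 4, 5])],
        latent_cov=[1.0, 1.0],
    )
)
S = SampleCovariance(implied_covariance(truth).values, n=500)
factors = {"F1": [0, 1, 2], "F2": [3, 4, 5]}

specs = {
    "marker": ModelSpec.from_factors(6, factors, "marker", markers=[0, 3]),
    "reference_group": ModelSpec.from_factors(6, factors, "reference_group"),
    "effect_coding": ModelSpec.from_factors(6, factors, "effect_coding", p_c=[3.0, 3.0]),
}

results = {}
for name, spec in specs.items():
    r = fit(S, spec)
    results[name] = r
    phi = np.diag(r.estimates.latent_cov.values)
    contributions = comparison_scaling(r.estimates).table["scaled_variance"].to_numpy()
    print(f"{name:16s} F = {r.discrepancy:.2e}  phi-hat = {np.round(phi, 4)}  "
          f"comparison-scaled = {np.round(contributions, 4)}")

base = results["marker"].estimates
for name in ("reference_group", "effect_coding"):
    d = constancy_distance(base, results[name].estimates)
    print(f"constancy distance marker vs {name}: {d:.2e}")

print(
    "\nThe variance parameters phi-hat depend on the identification choice,"
    "\nbut every identification reproduces the same Lambda Phi Lambda'"
    "\n(distances ~1e-9) and the same comparison-scaled variances"
    "\n(1.47 and 0.75 here) — scaling changes the reference system, not the"
    "\nresult of the factor investigation."
)
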