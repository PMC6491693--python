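"""Rescale one factor solution by each scaling method.

Builds a small one-factor solution, computes the scaling constant under the
marker-variable, reference-group, effect-coding and squared-loadings
criterion methods, and shows that all four leave the true part
Lambda Phi Lambda' untouched while producing different variance parameters.
"""

import numpy as np

from latentscale import (
    CFAModel,
    ErrorCovariance,
    FactorLoadings,
    LatentCovariance,
    build_plan,
    constancy_distance,
    rescale,
)

model = CFAModel(
    loadings=FactorLoadings(np.array([[0.5], [0.8], [0.4]])),
    latent_cov=LatentCovariance([[1.0]]),
    error_cov=ErrorCovariance([0.75, 0.36, 0.84]),
)

print("original loadings:", model.loadings.values.ravel(), "phi = 1.0\n")
for method, param in [
    ("marker", 0),          # fix the first loading to 1
    ("reference_group", 1.0),  # fix the variance parameter to 1
    ("effect_coding", 3.0),    # loadings sum to p_c = 3
    ("sum_squares", 1.0),      # squared loadings sum to p_c = 1
]:
    plan = build_plan(model, method, [param])
    solution = rescale(model, plan)
    print(f"{method:16s} c = {plan.constants[0]:.4f}  "
          f"lambda* = {np.round(solution.loadings_star.values.ravel(), 4)}  "
          f"phi* = {solution.latent_cov_star.values[0, 0]:.4f}  "
          f"constancy distance = {constancy_distance(model, solution):.2e}")

print(
    "\nEach method picks a different scale (different phi*), but the model's"
    "\nreconstruction of the covariances is bit-for-bit preserved: the"
    "\nconstancy distance (max change in Lambda Phi Lambda') is ~0 throughout."
)
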