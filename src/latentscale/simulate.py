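"""Synthetic factor-model populations and Gaussian score sampling.

Builds population models x = mu + Lambda xi + delta — including two-source
designs where a trait factor loads on all indicators and a method (or other
auxiliary-process) factor on a subset — and draws raw scores with Gaussian
latent and error terms, matching the distributional assumptions of the ML
fitter.  Sample covariances use the n - 1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CFAModel,
    DimensionError,
    ErrorCovariance,
    FactorLoadings,
    ImpliedCovariance,
    LatentCovariance,
    implied_covariance,
)
from .estimation import ModelSpec, SampleCovariance, fit
from .scaling import build_plan, rescale

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "RecoveryReport",
    "generate_model",
    "sample_study",
    "recovery_study",
]


@dataclass
class GeneratorConfig:
    """Population design for the generator.

    ``loadings`` is either an explicit p x q matrix (lists of rows) or a
    per-factor shorthand: a list of ``(value, indicator_indices)`` pairs,
    one per factor, placing ``value`` at the given 0-based rows (``None``
    for all rows).  ``latent_cov`` defaults to identity; a vector is taken
    as variances.  ``error_variances`` may be a scalar or a length-p vector
    and defaults to 1 - lambda'phi lambda per indicator truncated below at
    ``0.1`` — i.e. roughly unit-variance indicators.
    """

    p: int
    q: int = 1
    loadings: Sequence | None = None
    latent_cov: Sequence | None = None
    error_variances: Sequence | float | None = None
    intercepts: Sequence | float = 0.0
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or self.q < 1:
            raise ValueError("p and q must be positive")


def _build_loadings(config: GeneratorConfig) -> np.ndarray:
    p, q = config.p, config.q
    if config.loadings is None:
        return np.full((p, q), 0.5)
    spec = config.loadings
    # shorthand: list of (value, indices) pairs, one per factor
    if (
        isinstance(spec, (list, tuple))
        and len(spec) == q
        and all(
            isinstance(entry, (list, tuple))
            and len(entry) == 2
            and np.isscalar(entry[0])
            and (entry[1] is None or not np.isscalar(entry[1]))
            for entry in spec
        )
    ):
        lam = np.zeros((p, q))
        for k, (value, indices) in enumerate(spec):
            rows = np.arange(p) if indices is None else np.asarray(list(indices), int)
            if rows.size == 0 or rows.min() < 0 or rows.max() >= p:
                raise ValueError(f"factor {k}: invalid indicator indices")
            lam[rows, k] = float(value)
        return lam
    lam = np.asarray(spec, dtype=float)
    if lam.ndim == 1:
        lam = lam[:, None]
    if lam.shape != (p, q):
        raise DimensionError(f"loadings must be {p} x {q}, got {lam.shape}")
    return lam


def _build_latent_cov(config: GeneratorConfig) -> np.ndarray:
    if config.latent_cov is None:
        return np.eye(config.q)
    phi = np.asarray(config.latent_cov, dtype=float)
    if phi.ndim <= 1:
        phi = np.diag(np.atleast_1d(phi).astype(float))
    if phi.shape != (config.q, config.q):
        raise DimensionError(f"latent covariance must be {config.q} x {config.q}")
    eigs = np.linalg.eigvalsh((phi + phi.T) / 2.0)
    if eigs[0] <= 0:
        raise ValueError(
            f"latent covariance is not positive definite (min eigenvalue {eigs[0]:.3e})"
        )
    return phi


def generate_model(config: GeneratorConfig) -> CFAModel:
    """Deterministic population model for the given design."""
    lam = _build_loadings(config)
    phi = _build_latent_cov(config)
    if config.error_variances is None:
        communality = np.diag(lam @ phi @ lam.T)
        theta = np.maximum(1.0 - communality, 0.1)
    elif np.isscalar(config.error_variances):
        theta = np.full(config.p, float(config.error_variances))
    else:
        theta = np.asarray(config.error_variances, dtype=float).ravel()
        if theta.shape[0] != config.p:
            raise DimensionError("error variance vector length does not match p")
    mu = (
        np.full(config.p, float(config.intercepts))
        if np.isscalar(config.intercepts)
        else np.asarray(config.intercepts, dtype=float).ravel()
    )
    return CFAModel(
        loadings=FactorLoadings(lam),
        latent_cov=LatentCovariance(phi),
        error_cov=ErrorCovariance(theta),
        intercepts=mu,
    )


@dataclass
class SyntheticStudy:
    """A population model with one sampled data set drawn from it."""

    truth: CFAModel
    population_cov: ImpliedCovariance
    sample_cov: SampleCovariance
    scores: np.ndarray | None = None
    seed: int | None = None


def sample_study(model: CFAModel, n: int, seed: int) -> SyntheticStudy:
    """Draw n score vectors x = mu + Lambda xi + delta and their covariance.

    xi ~ N(0, Phi) and delta ~ N(0, Theta), independent across rows; requires
    Phi positive definite and Theta diagonal non-negative.  Deterministic
    given the seed.
    """
    if n < 2:
        raise ValueError("need n >= 2 to form a sample covariance")
    phi = model.latent_cov.values
    eigs = np.linalg.eigvalsh(phi)
    if eigs[0] < -1e-12:
        raise ValueError("latent covariance does not admit sampling (not PSD)")
    theta_diag = model.error_cov.diagonal
    if np.any(theta_diag < 0):
        raise ValueError("negative error variances do not admit sampling")

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(phi + 1e-15 * np.eye(model.q))
    xi = rng.standard_normal((n, model.q)) @ chol.T
    delta = rng.standard_normal((n, model.p)) * np.sqrt(theta_diag)[None, :]
    mu = model.intercepts if model.intercepts is not None else np.zeros(model.p)
    scores = mu[None, :] + xi @ model.loadings.values.T + delta

    s = np.cov(scores, rowvar=False, ddof=1)
    sample = SampleCovariance(
        values=s, n=n, variable_names=list(model.loadings.variable_names)
    )
    return SyntheticStudy(
        truth=model,
        population_cov=implied_covariance(model),
        sample_cov=sample,
        scores=scores,
        seed=seed,
    )


@dataclass
class RecoveryReport:
    """Replicate-level and summary recovery of scaled variance parameters."""

    replicates: pd.DataFrame
    population_value: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    n_nonconverged: int
    factor_names: list[str] = field(default_factory=list)
    degenerate: bool = False


def recovery_study(
    config: GeneratorConfig,
    spec: ModelSpec,
    replicates: int,
    seed: int,
    scaling_method: str = "sum_squares",
    scaling_params: Sequence | None = None,
) -> RecoveryReport:
    """Repeated sample -> fit -> rescale; bias and RMSE of scaled variances.

    Each replicate draws a fresh sample of ``config.n`` scores from the
    population, fits ``spec`` by ML, applies the requested scaling to the
    estimated solution and records the scaled variance parameter of every
    factor.  The population value is the same scaling applied to the truth.
    Non-converged replicates are counted and excluded from the summaries,
    never fatal.  Seeds for the replicates are spawned from one stream.
    """
    truth = generate_model(config)
    if spec.p != truth.p:
        raise DimensionError("spec dimensions do not match the generator config")

    lam = truth.loadings.values
    if float(np.max(np.abs(lam), initial=0.0)) <= 1e-12:
        return RecoveryReport(
            replicates=pd.DataFrame(),
            population_value=np.full(truth.q, np.nan),
            bias=np.full(truth.q, np.nan),
            rmse=np.full(truth.q, np.nan),
            n_nonconverged=0,
            factor_names=list(truth.loadings.factor_names),
            degenerate=True,
        )

    if scaling_params is None:
        if scaling_method == "marker":
            scaling_params = [0] * truth.q
        elif scaling_method == "reference_group":
            scaling_params = [1.0] * truth.q
        else:
            scaling_params = [float(truth.p)] * truth.q

    pop_plan = build_plan(truth, scaling_method, scaling_params)
    pop_solution = rescale(truth, pop_plan)
    pop_value = np.diag(pop_solution.latent_cov_star.values).copy()

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    rows = []
    n_nonconverged = 0
    for r in range(replicates):
        study = sample_study(truth, config.n, int(rep_seeds[r]))
        result = fit(study.sample_cov, spec, compute_indices=False)
        if not result.converged:
            n_nonconverged += 1
            continue
        plan = build_plan(result.estimates, scaling_method, scaling_params)
        solution = rescale(result.estimates, plan)
        phi_sc = np.diag(solution.latent_cov_star.values)
        rows.append(
            {"replicate": r, "seed": int(rep_seeds[r])}
            | {
                f"phi_sc[{name}]": float(phi_sc[k])
                for k, name in enumerate(truth.loadings.factor_names)
            }
        )

    table = pd.DataFrame(rows)
    cols = [f"phi_sc[{name}]" for name in truth.loadings.factor_names]
    if len(table):
        est = table[cols].to_numpy()
        bias = est.mean(axis=0) - pop_value
        rmse = np.sqrt(np.mean((est - pop_value[None, :]) ** 2, axis=0))
    else:
        bias = np.full(truth.q, np.nan)
        rmse = np.full(truth.q, np.nan)
    return RecoveryReport(
        replicates=table,
        population_value=pop_value,
        bias=bias,
        rmse=rmse,
        n_nonconverged=n_nonconverged,
        factor_names=list(truth.loadings.factor_names),
    )
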