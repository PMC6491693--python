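"""Scaling constants and rescaling under the constancy framework.

Multiplying a loading column by a positive constant c while dividing the
corresponding latent variance by c^2 leaves the true part Lambda Phi Lambda'
— and hence model fit — unchanged.  Every identification convention in CFA
picks a particular c:

* marker variable: fix one loading to 1, so c = 1 / lambda_i;
* reference group: fix the latent variance to a target (usually 1), so
  c = sqrt(phi / target);
* effect coding: make the loadings sum to a criterion number p_c, so
  c = p_c / sum(lambda);
* squared-loadings criterion: make the squared loadings sum to p_c, so
  c = sqrt(p_c / lambda'lambda).

The scaled variance parameter is phi_sc = phi / c^2 in every case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    CFAModel,
    DimensionError,
    FactorLoadings,
    LatentCovariance,
    constancy_distance,
)

__all__ = [
    "MarkerError",
    "ScalingPlan",
    "ScaledSolution",
    "marker_constant",
    "reference_constant",
    "effect_coding_constant",
    "sum_squares_constant",
    "scaled_variance",
    "build_plan",
    "rescale",
    "criterion_sensitivity_table",
    "METHODS",
]

METHODS = ("marker", "reference_group", "effect_coding", "sum_squares")

_DEGENERATE = 1e-12


class MarkerError(ValueError):
    """The chosen marker indicator cannot anchor the scale."""


def marker_constant(column: Sequence[float], marker_index: int) -> float:
    """Constant that fixes the loading at ``marker_index`` (0-based) to one.

    Requires a strictly positive marker loading; a zero or negative loading
    cannot serve as marker (pick another indicator).
    """
    lam = np.asarray(column, dtype=float).ravel()
    if not (0 <= marker_index < lam.size):
        raise DimensionError(f"marker index {marker_index} out of range for p={lam.size}")
    li = lam[marker_index]
    if li <= 0:
        raise MarkerError(
            f"marker loading {li} at index {marker_index} is not strictly positive; "
            "choose another indicator"
        )
    return 1.0 / float(li)


def reference_constant(phi: float, target: float = 1.0) -> float:
    """Constant c = sqrt(phi / target) that maps the variance parameter to ``target``."""
    if phi <= 0:
        raise ValueError(f"variance parameter {phi} must be positive for reference scaling")
    if target <= 0:
        raise ValueError(f"target variance {target} must be positive")
    return float(np.sqrt(phi / target))


def effect_coding_constant(column: Sequence[float], p_c: float) -> float:
    """Constant c = p_c / sum(lambda), making the rescaled loadings sum to p_c."""
    if p_c <= 0:
        raise ValueError(f"criterion number {p_c} must be positive")
    lam = np.asarray(column, dtype=float).ravel()
    s = float(lam.sum())
    if s <= _DEGENERATE:
        raise ValueError(
            f"loading sum {s} is not strictly positive; effect coding is degenerate"
        )
    return float(p_c) / s


def sum_squares_constant(column: Sequence[float], p_c: float) -> float:
    """Constant c = sqrt(p_c / lambda'lambda), making the squared loadings sum to p_c."""
    if p_c <= 0:
        raise ValueError(f"criterion number {p_c} must be positive")
    lam = np.asarray(column, dtype=float).ravel()
    ss = float(lam @ lam)
    if ss <= _DEGENERATE:
        raise ValueError("all-zero loading column; squared-loadings criterion is degenerate")
    return float(np.sqrt(float(p_c) / ss))


def scaled_variance(phi: float, c: float) -> float:
    """Scaled variance parameter phi_sc = phi / c^2 for scaling constant c > 0."""
    if c <= 0:
        raise ValueError(f"scaling constant {c} must be positive")
    return float(phi) / float(c) ** 2


@dataclass
class ScalingPlan:
    """Per-factor scaling constants plus the method and parameters that produced them."""

    method: str
    constants: np.ndarray
    per_factor_params: list = field(default_factory=list)
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown scaling method {self.method!r}; choose from {METHODS}")
        c = np.asarray(self.constants, dtype=float).ravel()
        if c.size < 1 or not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("every scaling constant must be finite and > 0")
        self.constants = c
        if not self.factor_names:
            self.factor_names = [f"F{i + 1}" for i in range(c.size)]

    @property
    def q(self) -> int:
        return self.constants.size

    def inverse(self) -> "ScalingPlan":
        """Plan with reciprocal constants; rescaling by it undoes this plan."""
        return ScalingPlan(
            method=self.method,
            constants=1.0 / self.constants,
            per_factor_params=list(self.per_factor_params),
            factor_names=list(self.factor_names),
        )


@dataclass
class ScaledSolution:
    """Rescaled (Lambda*, Phi*) with the plan and source model attached.

    Lambda* column k = c_k * Lambda column k and Phi*_jk = Phi_jk / (c_j c_k),
    so the true part equals the source's exactly.
    """

    loadings_star: FactorLoadings
    latent_cov_star: LatentCovariance
    plan: ScalingPlan
    source: CFAModel

    def true_part(self) -> np.ndarray:
        lam = self.loadings_star.values
        m = lam @ self.latent_cov_star.values @ lam.T
        return (m + m.T) / 2.0

    def as_model(self) -> CFAModel:
        """The rescaled solution as a CFAModel (Theta is unchanged by scaling)."""
        return CFAModel(
            loadings=self.loadings_star,
            latent_cov=self.latent_cov_star,
            error_cov=self.source.error_cov,
            intercepts=self.source.intercepts,
        )


def _constant_for(method: str, model: CFAModel, k: int, param) -> float:
    column = model.loadings.column(k)
    if method == "marker":
        return marker_constant(column, int(param))
    if method == "reference_group":
        target = 1.0 if param is None else float(param)
        return reference_constant(model.latent_cov.values[k, k], target)
    if method == "effect_coding":
        return effect_coding_constant(column, float(param))
    if method == "sum_squares":
        return sum_squares_constant(column, float(param))
    raise ValueError(f"unknown scaling method {method!r}")


def build_plan(model: CFAModel, method: str, per_factor_params: Sequence) -> ScalingPlan:
    """Compute one scaling constant per factor.

    ``per_factor_params`` holds one entry per factor: the 0-based marker index
    (marker), the target variance (reference_group, ``None`` for 1), or the
    criterion number p_c (effect_coding / sum_squares).
    """
    if method not in METHODS:
        raise ValueError(f"unknown scaling method {method!r}; choose from {METHODS}")
    params = list(per_factor_params)
    if len(params) != model.q:
        raise DimensionError(
            f"{len(params)} per-factor parameters for {model.q} factors"
        )
    constants = np.empty(model.q)
    for k in range(model.q):
        try:
            constants[k] = _constant_for(method, model, k, params[k])
        except ValueError as exc:
            name = model.loadings.factor_names[k]
            raise type(exc)(f"factor {name!r}: {exc}") from exc
    return ScalingPlan(
        method=method,
        constants=constants,
        per_factor_params=params,
        factor_names=list(model.loadings.factor_names),
    )


def rescale(model: CFAModel, plan: ScalingPlan) -> ScaledSolution:
    """Apply a scaling plan: Lambda* = Lambda diag(c), Phi*_jk = Phi_jk/(c_j c_k).

    Latent covariances are divided by the product of the two factors'
    constants, which keeps Lambda Phi Lambda' constant for any symmetric Phi.
    Theta is untouched.
    """
    if plan.q != model.q:
        raise DimensionError(f"plan has {plan.q} constants for {model.q} factors")
    c = plan.constants
    lam_star = model.loadings.values * c[None, :]
    phi_star = model.latent_cov.values / np.outer(c, c)
    solution = ScaledSolution(
        loadings_star=FactorLoadings(
            lam_star,
            variable_names=list(model.loadings.variable_names),
            factor_names=list(model.loadings.factor_names),
        ),
        latent_cov_star=LatentCovariance(
            phi_star, factor_names=list(model.latent_cov.factor_names)
        ),
        plan=plan,
        source=model,
    )
    return solution


def _criterion_number(criterion, p: int) -> tuple[float, str]:
    """Resolve a criterion spec to (p_c, label).

    Strings like ``"1/2"`` or ``"1"`` are proportions r of p (p_c = r * p);
    numbers are absolute criterion numbers.
    """
    if isinstance(criterion, str):
        parts = criterion.split("/")
        if len(parts) == 1:
            r = float(parts[0])
        elif len(parts) == 2:
            r = float(parts[0]) / float(parts[1])
        else:
            raise ValueError(f"cannot parse proportion {criterion!r}")
        return r * p, criterion
    return float(criterion), str(criterion)


def criterion_sensitivity_table(
    loading_values: Sequence[float],
    p_values: Sequence[int],
    criteria: Sequence,
    phi: float = 1.0,
) -> pd.DataFrame:
    """Scaled variance parameters over a grid of equal-loading designs.

    For a one-factor model with ``p`` manifest variables all loading
    ``lambda`` and variance parameter ``phi``, the squared-loadings criterion
    with criterion number p_c gives

        phi_sc = phi * p * lambda^2 / p_c.

    Each criterion may be a proportion of p given as a string (``"1"``,
    ``"1/2"``, ``"1/4"``) or an absolute number.  Returns one row per
    (criterion, p) pair and one column per loading value.
    """
    rows = []
    index = []
    for criterion in criteria:
        for p in p_values:
            p_c, label = _criterion_number(criterion, int(p))
            if p_c <= 0:
                raise ValueError(f"criterion number {p_c} must be positive")
            cells = []
            for lam in loading_values:
                column = np.full(int(p), float(lam))
                ss = float(column @ column)
                if ss <= _DEGENERATE:
                    cells.append(0.0)
                else:
                    c = sum_squares_constant(column, p_c)
                    cells.append(scaled_variance(phi, c))
            rows.append(cells)
            index.append((label, int(p)))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["criterion", "p"]),
        columns=[f"loading {lam:g}" for lam in loading_values],
    )
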