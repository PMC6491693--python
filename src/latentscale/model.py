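"""Factor-model containers and the model-implied covariance.

A confirmatory factor model reconstructs a p x p covariance matrix of
manifest variables as

    Sigma = Lambda Phi Lambda' + Theta

where ``Lambda`` (p x q) holds the factor loadings, ``Phi`` (q x q) the
variances and covariances of the latent variables, and ``Theta`` (p x p,
diagonal) the error variances.  The product ``Lambda Phi Lambda'`` is the
*true part* of the implied covariance; everything in this package either
preserves it (rescaling) or perturbs it (sampling, estimation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DimensionError",
    "FactorLoadings",
    "LatentCovariance",
    "ErrorCovariance",
    "CFAModel",
    "ImpliedCovariance",
    "implied_covariance",
    "true_part_entry",
    "constancy_distance",
]

#: default absolute tolerance for symmetry and constancy checks; dense
#: double-precision arithmetic at p <= ~50 keeps round-off far below this
DEFAULT_TOL = 1e-10


class DimensionError(ValueError):
    """Raised when matrix dimensions do not conform."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def _default_names(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


@dataclass
class FactorLoadings:
    """The p x q loading matrix Lambda.

    A single factor may be given as a length-p vector; it is stored as a
    p x 1 matrix.
    """

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "loadings")
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DimensionError("loadings must be a p x q matrix with p, q >= 1")
        self.values = arr
        if not self.variable_names:
            self.variable_names = _default_names("x", arr.shape[0])
        if not self.factor_names:
            self.factor_names = _default_names("F", arr.shape[1])
        if len(self.variable_names) != arr.shape[0]:
            raise DimensionError(
                f"{len(self.variable_names)} variable names for {arr.shape[0]} rows"
            )
        if len(self.factor_names) != arr.shape[1]:
            raise DimensionError(
                f"{len(self.factor_names)} factor names for {arr.shape[1]} columns"
            )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def column(self, k: int) -> np.ndarray:
        """Loading vector of factor ``k`` (0-based)."""
        return self.values[:, k]


@dataclass
class LatentCovariance:
    """The q x q matrix Phi of latent variance/covariance parameters.

    Diagonal entries are the variance parameters phi_kk.  A variance
    parameter is a model parameter, not a sum of squared deviations, and
    estimation can assign it a negative value; such entries are kept and
    flagged through :attr:`is_admissible`, never clamped.
    """

    values: np.ndarray
    factor_names: list[str] = field(default_factory=list)
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "latent covariance")
        if arr.ndim == 0:
            arr = arr.reshape(1, 1)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise DimensionError("latent covariance must be square")
        if np.max(np.abs(arr - arr.T), initial=0.0) > self.tol:
            raise ValueError("latent covariance is not symmetric within tolerance")
        self.values = (arr + arr.T) / 2.0
        if not self.factor_names:
            self.factor_names = _default_names("F", arr.shape[0])
        if len(self.factor_names) != arr.shape[0]:
            raise DimensionError("factor names do not match dimension")
        if not self.is_admissible:
            warnings.warn(
                "latent covariance has a non-positive variance parameter",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def q(self) -> int:
        return self.values.shape[0]

    @property
    def is_diagonal(self) -> bool:
        off = self.values - np.diag(np.diag(self.values))
        return bool(np.max(np.abs(off), initial=0.0) <= self.tol)

    @property
    def is_admissible(self) -> bool:
        """True when every variance parameter on the diagonal is positive."""
        return bool(np.all(np.diag(self.values) > 0))


@dataclass
class ErrorCovariance:
    """Diagonal p x p matrix Theta of error-variance parameters.

    Negative diagonal entries (Heywood cases) are permitted but flagged via
    :attr:`has_heywood`.
    """

    values: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = _as_float_array(self.values, "error covariance")
        if arr.ndim == 1:
            arr = np.diag(arr)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise DimensionError("error covariance must be square or a vector")
        off = arr - np.diag(np.diag(arr))
        if np.any(off != 0.0):
            raise ValueError("error covariance must be exactly diagonal")
        self.values = arr
        if not self.variable_names:
            self.variable_names = _default_names("x", arr.shape[0])
        if len(self.variable_names) != arr.shape[0]:
            raise DimensionError("variable names do not match dimension")
        if self.has_heywood:
            warnings.warn(
                "negative error variance (Heywood case) present",
                RuntimeWarning,
                stacklevel=2,
            )

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.values)

    @property
    def has_heywood(self) -> bool:
        return bool(np.any(np.diag(self.values) < 0))


@dataclass
class CFAModel:
    """Bundle of Lambda, Phi and Theta with conformance invariants.

    ``intercepts`` (mu) are carried for score generation only; the
    covariance-structure machinery ignores them.
    """

    loadings: FactorLoadings
    latent_cov: LatentCovariance
    error_cov: ErrorCovariance
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.latent_cov.q != self.loadings.q:
            raise DimensionError(
                f"Phi is {self.latent_cov.q} x {self.latent_cov.q} but Lambda has "
                f"{self.loadings.q} columns"
            )
        if self.error_cov.p != self.loadings.p:
            raise DimensionError(
                f"Theta is {self.error_cov.p} x {self.error_cov.p} but Lambda has "
                f"{self.loadings.p} rows"
            )
        if self.intercepts is not None:
            mu = _as_float_array(self.intercepts, "intercepts").ravel()
            if mu.shape[0] != self.loadings.p:
                raise DimensionError("intercept vector length does not match p")
            self.intercepts = mu

    @property
    def p(self) -> int:
        return self.loadings.p

    @property
    def q(self) -> int:
        return self.loadings.q

    def true_part(self) -> np.ndarray:
        """Lambda Phi Lambda', symmetrised against round-off."""
        lam = self.loadings.values
        m = lam @ self.latent_cov.values @ lam.T
        return (m + m.T) / 2.0


@dataclass
class ImpliedCovariance:
    """Model-implied covariance Sigma together with its true part Sigma - Theta."""

    values: np.ndarray
    true_part: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = _as_float_array(self.values, "implied covariance")
        t = _as_float_array(self.true_part, "true part")
        if v.shape != t.shape or v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError("implied covariance and true part must be square and conforming")
        self.values = v
        self.true_part = t
        if not self.variable_names:
            self.variable_names = _default_names("x", v.shape[0])

    @property
    def p(self) -> int:
        return self.values.shape[0]


def implied_covariance(model: CFAModel) -> ImpliedCovariance:
    """Model-implied covariance Sigma = Lambda Phi Lambda' + Theta.

    Returns both Sigma and the true part Lambda Phi Lambda'.  Symmetric as
    stored (the product is symmetrised before Theta is added).
    """
    tau = model.true_part()
    return ImpliedCovariance(
        values=tau + model.error_cov.values,
        true_part=tau,
        variable_names=list(model.loadings.variable_names),
    )


def true_part_entry(model: CFAModel, i: int, j: int) -> float:
    """Entry (i, j) of the true part by the scalar sum over factors.

    sigma_tau_ij = lambda_i1 phi_11 lambda_j1 + ... + lambda_iq phi_qq lambda_jq

    Indices are 0-based.  Defined for diagonal Phi only; with latent
    covariances present the cross terms are missing from this sum, so the
    call is refused — use :func:`implied_covariance` instead.
    """
    p = model.p
    if not (0 <= i < p and 0 <= j < p):
        raise DimensionError(f"indices ({i}, {j}) out of range for p={p}")
    if not model.latent_cov.is_diagonal:
        raise ValueError(
            "true_part_entry requires diagonal Phi; use implied_covariance for "
            "models with latent covariances"
        )
    lam = model.loadings.values
    phi = np.diag(model.latent_cov.values)
    total = 0.0
    for k in range(model.q):
        total += lam[i, k] * phi[k] * lam[j, k]
    return float(total)


def _extract_true_part(obj) -> np.ndarray:
    if isinstance(obj, CFAModel):
        return obj.true_part()
    if isinstance(obj, ImpliedCovariance):
        return obj.true_part
    if hasattr(obj, "true_part"):
        tp = obj.true_part
        return tp() if callable(tp) else np.asarray(tp, dtype=float)
    raise TypeError(f"cannot extract a true part from {type(obj).__name__}")


def constancy_distance(a, b) -> float:
    """Maximum absolute difference between the true parts of two solutions.

    Rescaling a solution by any positive constant leaves Lambda Phi Lambda'
    unchanged, so this distance is (numerically) zero between a model and any
    valid rescaling of it.  Accepts :class:`CFAModel`, a scaled solution, or
    anything exposing a true part.
    """
    ta = _extract_true_part(a)
    tb = _extract_true_part(b)
    if ta.shape != tb.shape:
        raise DimensionError(f"true parts have shapes {ta.shape} and {tb.shape}")
    return float(np.max(np.abs(ta - tb), initial=0.0))
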