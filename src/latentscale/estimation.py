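"""Minimal maximum-likelihood CFA fitter with selectable identification.

Fits Sigma(theta) = Lambda Phi Lambda' + Theta to a sample covariance matrix
S by minimising the normal-theory ML discrepancy

    F(theta) = log|Sigma| + trace(S Sigma^-1) - log|S| - p,

which is zero iff Sigma = S.  Each factor's scale is identified by one of

* ``marker``          — one loading per factor fixed to 1;
* ``reference_group`` — the latent variance fixed to 1 (all loadings free);
* ``effect_coding``   — the loadings of each factor constrained to sum to a
  criterion number p_c, enforced by exact reparameterisation (one loading per
  factor is computed as p_c minus the sum of the others), so the constraint
  holds to machine precision.

The same population covariance fitted under any of these identifications
yields the same true part Lambda Phi Lambda' — the different solutions are
rescalings of one another.

Heywood cases (negative error-variance estimates) are returned as estimated,
flagged through the model containers, never bounded away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import (
    CFAModel,
    DimensionError,
    ErrorCovariance,
    FactorLoadings,
    ImpliedCovariance,
    LatentCovariance,
)

__all__ = [
    "NonPositiveDefiniteError",
    "SpecificationError",
    "SampleCovariance",
    "ModelSpec",
    "FitResult",
    "ml_discrepancy",
    "fit",
    "fit_indices",
    "standard_errors",
    "adjust_diagonal",
    "CAMPBELL_FISKE_RELIABILITIES",
    "MTMM_ADJUSTED_DIAGONAL",
]

logger = logging.getLogger(__name__)

#: reliability estimates along the main diagonal of the classic 3-trait x
#: 3-method correlation matrix used in the multitrait-multimethod demo
CAMPBELL_FISKE_RELIABILITIES = (0.89, 0.89, 0.76, 0.93, 0.94, 0.84, 0.94, 0.92, 0.85)

#: replacement main diagonal that restores positive error variances and the
#: expected relationship with the reliability complements in that demo
MTMM_ADJUSTED_DIAGONAL = (1.145, 1.140, 1.145, 1.005, 0.965, 0.965, 0.940, 1.010, 0.980)

_PENALTY = 1e10


class NonPositiveDefiniteError(np.linalg.LinAlgError):
    """A covariance matrix required to be positive definite is not."""


class SpecificationError(ValueError):
    """The model specification is not identified or not well-formed."""


@dataclass
class SampleCovariance:
    """Symmetric p x p sample covariance (or correlation) matrix with sample size."""

    values: np.ndarray
    n: int | None = None
    is_correlation: bool = False
    variable_names: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise DimensionError("sample covariance must be square")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample covariance contains non-finite entries")
        if np.max(np.abs(arr - arr.T), initial=0.0) > 1e-8:
            raise ValueError("sample covariance is not symmetric within 1e-8")
        self.values = (arr + arr.T) / 2.0
        if self.n is not None:
            self.n = int(self.n)
            if self.n < 2:
                raise ValueError("sample size must be at least 2")
        if not self.variable_names:
            self.variable_names = [f"x{i + 1}" for i in range(arr.shape[0])]
        if len(self.variable_names) != arr.shape[0]:
            raise DimensionError("variable names do not match dimension")

    @property
    def p(self) -> int:
        return self.values.shape[0]


def adjust_diagonal(R: SampleCovariance, new_diagonal: Sequence[float]) -> SampleCovariance:
    """Copy of ``R`` with its main diagonal replaced, off-diagonals untouched.

    Raising selected diagonal entries (a ridge-style adjustment) affects the
    error components of the variances but not the systematic components, and
    is used to repair negative error-variance estimates when fitting a
    correlation matrix whose diagonal understates the indicator variances.
    The substitution is recorded in ``metadata['diagonal_adjustment']``.
    """
    diag = np.asarray(new_diagonal, dtype=float).ravel()
    if diag.shape[0] != R.p:
        raise DimensionError(f"diagonal of length {diag.shape[0]} for p={R.p}")
    if np.any(diag <= 0):
        raise ValueError("adjusted diagonal entries must be positive")
    values = R.values.copy()
    old = np.diag(values).copy()
    values[np.diag_indices(R.p)] = diag
    meta = dict(R.metadata)
    meta["diagonal_adjustment"] = {"old": old.tolist(), "new": diag.tolist()}
    return SampleCovariance(
        values=values,
        n=R.n,
        is_correlation=False if not np.allclose(diag, 1.0) else R.is_correlation,
        variable_names=list(R.variable_names),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Pattern matrices plus the identification rule.

    ``loading_pattern`` is p x q with ``nan`` marking a free loading and a
    number a fixed value (0 for an excluded path).  ``phi_pattern`` (q x q,
    symmetric structure) and ``theta_pattern`` (length-p diagonal) follow the
    same convention; their defaults are free variances with zero (fixed)
    latent covariances.  Exactly one identification mechanism applies per
    factor:

    * ``marker``: ``markers[k]`` gives the 0-based indicator whose loading is
      fixed to 1; the latent variance stays free.
    * ``reference_group``: the latent variance is fixed (to
      ``reference_targets[k]``, default 1); all patterned loadings stay free.
    * ``effect_coding``: the free loadings of factor ``k`` are constrained to
      sum to ``p_c[k]`` by reparameterising one of them; the latent variance
      stays free.

    ``equality_groups`` optionally ties sets of free loading positions
    ``[(row, col), ...]`` to a single parameter.
    """

    loading_pattern: np.ndarray
    identification: str
    phi_pattern: np.ndarray | None = None
    theta_pattern: np.ndarray | None = None
    markers: Sequence[int] | None = None
    p_c: Sequence[float] | None = None
    reference_targets: Sequence[float] | None = None
    equality_groups: list[list[tuple[int, int]]] = field(default_factory=list)
    variable_names: list[str] = field(default_factory=list)
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lam = np.asarray(self.loading_pattern, dtype=float)
        if lam.ndim == 1:
            lam = lam[:, None]
        if lam.ndim != 2:
            raise SpecificationError("loading pattern must be a p x q matrix")
        self.loading_pattern = lam
        p, q = lam.shape
        if self.phi_pattern is None:
            phi = np.zeros((q, q))
            np.fill_diagonal(phi, np.nan)
            self.phi_pattern = phi
        else:
            phi = np.asarray(self.phi_pattern, dtype=float)
            if phi.shape != (q, q):
                raise SpecificationError(f"phi pattern must be {q} x {q}")
            # a position is free if either triangle marks it free
            free = np.isnan(phi) | np.isnan(phi.T)
            sym = np.where(np.isnan(phi), 0.0, phi)
            sym = np.where(free, np.nan, (sym + sym.T) / 2.0)
            self.phi_pattern = sym
        if self.theta_pattern is None:
            self.theta_pattern = np.full(p, np.nan)
        else:
            th = np.asarray(self.theta_pattern, dtype=float).ravel()
            if th.shape[0] != p:
                raise SpecificationError(f"theta pattern must have length {p}")
            self.theta_pattern = th

        if self.identification not in ("marker", "reference_group", "effect_coding"):
            raise SpecificationError(
                f"unknown identification {self.identification!r}"
            )
        if self.identification == "marker":
            if self.markers is None or len(self.markers) != q:
                raise SpecificationError("marker identification needs one marker index per factor")
            for k, idx in enumerate(self.markers):
                if not (0 <= idx < p):
                    raise SpecificationError(f"marker index {idx} out of range for factor {k}")
        if self.identification == "effect_coding":
            if self.p_c is None or len(self.p_c) != q:
                raise SpecificationError("effect coding needs one criterion number per factor")
            if any(pc <= 0 for pc in self.p_c):
                raise SpecificationError("criterion numbers must be positive")
        if self.identification == "reference_group" and self.reference_targets is not None:
            if len(self.reference_targets) != q:
                raise SpecificationError("need one reference target per factor")

        if not self.variable_names:
            self.variable_names = [f"x{i + 1}" for i in range(p)]
        if not self.factor_names:
            self.factor_names = [f"F{i + 1}" for i in range(q)]

    @property
    def p(self) -> int:
        return self.loading_pattern.shape[0]

    @property
    def q(self) -> int:
        return self.loading_pattern.shape[1]

    # -- convenience constructors ------------------------------------------

    @classmethod
    def one_factor(
        cls,
        p: int,
        identification: str = "marker",
        marker: int = 0,
        p_c: float | None = None,
    ) -> "ModelSpec":
        """Congeneric one-factor model with all loadings patterned free."""
        pattern = np.full((p, 1), np.nan)
        if identification == "effect_coding" and p_c is None:
            p_c = float(p)
        return cls(
            loading_pattern=pattern,
            identification=identification,
            markers=[marker] if identification == "marker" else None,
            p_c=[p_c] if identification == "effect_coding" else None,
        )

    @classmethod
    def from_factors(
        cls,
        p: int,
        factors: Mapping[str, Sequence[int]],
        identification: str = "reference_group",
        free_correlations: Sequence[tuple[str, str]] = (),
        markers: Sequence[int] | None = None,
        p_c: Sequence[float] | None = None,
        variable_names: Sequence[str] | None = None,
    ) -> "ModelSpec":
        """Simple-structure spec from factor -> indicator-index lists.

        Indicator sets may overlap (as in trait x method designs).  Latent
        covariances are fixed at zero except for the named
        ``free_correlations`` pairs.
        """
        names = list(factors)
        q = len(names)
        pattern = np.zeros((p, q))
        for k, name in enumerate(names):
            idx = np.asarray(list(factors[name]), dtype=int)
            if idx.size == 0 or idx.min() < 0 or idx.max() >= p:
                raise SpecificationError(f"factor {name!r} has invalid indicator indices")
            pattern[idx, k] = np.nan
        phi = np.zeros((q, q))
        np.fill_diagonal(phi, np.nan)
        for a, b in free_correlations:
            ia, ib = names.index(a), names.index(b)
            phi[ia, ib] = phi[ib, ia] = np.nan
        return cls(
            loading_pattern=pattern,
            identification=identification,
            phi_pattern=phi,
            markers=markers,
            p_c=p_c,
            factor_names=names,
            variable_names=list(variable_names) if variable_names else [],
        )


# ---------------------------------------------------------------------------
# parameterisation: spec -> free-parameter vector and back


class _Parameterization:
    """Maps a free-parameter vector to (Lambda, Phi, Theta) and supports the
    analytic gradient of the ML discrepancy under that map."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p, q = spec.p, spec.q

        lam_pattern = spec.loading_pattern.copy()
        phi_pattern = spec.phi_pattern.copy()
        self.ref_targets = None
        self.dep_positions: dict[int, tuple[int, int]] = {}

        if spec.identification == "marker":
            for k, idx in enumerate(spec.markers):
                lam_pattern[idx, k] = 1.0
        elif spec.identification == "reference_group":
            targets = (
                list(spec.reference_targets)
                if spec.reference_targets is not None
                else [1.0] * q
            )
            for k in range(q):
                phi_pattern[k, k] = targets[k]
        elif spec.identification == "effect_coding":
            grouped = {pos for group in spec.equality_groups for pos in group}
            for k in range(q):
                free_rows = [i for i in range(p) if np.isnan(lam_pattern[i, k])]
                candidates = [i for i in free_rows if (i, k) not in grouped]
                if not candidates:
                    raise SpecificationError(
                        f"factor {spec.factor_names[k]!r} has no free loading to "
                        "reparameterise for effect coding"
                    )
                self.dep_positions[k] = (candidates[-1], k)

        self.lam_pattern = lam_pattern
        self.phi_pattern = phi_pattern
        self.theta_pattern = spec.theta_pattern.copy()

        # equality groups: first position carries the parameter
        pos_to_group: dict[tuple[int, int], int] = {}
        for g, group in enumerate(spec.equality_groups):
            for pos in group:
                i, k = pos
                if not np.isnan(lam_pattern[i, k]):
                    raise SpecificationError(
                        f"equality-group position {pos} is not a free loading"
                    )
                pos_to_group[pos] = g

        self.lam_slots: list[list[tuple[int, int]]] = []  # one entry per parameter
        seen_groups: dict[int, int] = {}
        dep_set = set(self.dep_positions.values())
        for k in range(q):
            for i in range(p):
                if not np.isnan(lam_pattern[i, k]) or (i, k) in dep_set:
                    continue
                g = pos_to_group.get((i, k))
                if g is None:
                    self.lam_slots.append([(i, k)])
                elif g not in seen_groups:
                    seen_groups[g] = len(self.lam_slots)
                    self.lam_slots.append([(i, k)])
                else:
                    self.lam_slots[seen_groups[g]].append((i, k))

        self.phi_slots = [
            (j, k)
            for j in range(q)
            for k in range(j, q)
            if np.isnan(phi_pattern[j, k])
        ]
        self.theta_slots = [i for i in range(p) if np.isnan(self.theta_pattern[i])]

        self.n_lam = len(self.lam_slots)
        self.n_phi = len(self.phi_slots)
        self.n_free = self.n_lam + self.n_phi + len(self.theta_slots)

    # -- labels -------------------------------------------------------------

    def param_names(self) -> list[str]:
        spec = self.spec
        names = []
        for positions in self.lam_slots:
            i, k = positions[0]
            names.append(f"lambda[{spec.variable_names[i]},{spec.factor_names[k]}]")
        for j, k in self.phi_slots:
            if j == k:
                names.append(f"phi[{spec.factor_names[j]}]")
            else:
                names.append(f"phi[{spec.factor_names[j]},{spec.factor_names[k]}]")
        for i in self.theta_slots:
            names.append(f"theta[{spec.variable_names[i]}]")
        return names

    # -- vector <-> matrices -------------------------------------------------

    def start_values(self, S: np.ndarray) -> np.ndarray:
        """Scale-aware start: loadings 0.5*sqrt(s_ii), variances 1, errors 0.5*s_ii."""
        sdiag = np.diag(S)
        x = np.empty(self.n_free)
        pos = 0
        for positions in self.lam_slots:
            i, _ = positions[0]
            x[pos] = 0.5 * np.sqrt(max(sdiag[i], 1e-8))
            pos += 1
        for j, k in self.phi_slots:
            x[pos] = 1.0 if j == k else 0.0
            pos += 1
        for i in self.theta_slots:
            x[pos] = 0.5 * max(sdiag[i], 1e-8)
            pos += 1
        return x

    def matrices(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        spec = self.spec
        lam = np.where(np.isnan(self.lam_pattern), 0.0, self.lam_pattern)
        phi = np.where(np.isnan(self.phi_pattern), 0.0, self.phi_pattern)
        theta = np.where(np.isnan(self.theta_pattern), 0.0, self.theta_pattern)
        pos = 0
        for positions in self.lam_slots:
            for i, k in positions:
                lam[i, k] = x[pos]
            pos += 1
        for j, k in self.phi_slots:
            phi[j, k] = phi[k, j] = x[pos]
            pos += 1
        for i in self.theta_slots:
            theta[i] = x[pos]
            pos += 1
        # effect coding: the dependent loading closes the sum constraint
        for k, (i, _) in self.dep_positions.items():
            col = lam[:, k]
            lam[i, k] = spec.p_c[k] - (col.sum() - col[i])
        return lam, phi, np.diag(theta)

    def gradient(
        self, x: np.ndarray, lam: np.ndarray, phi: np.ndarray, G: np.ndarray
    ) -> np.ndarray:
        """Gradient of F given G = Sigma^-1 - Sigma^-1 S Sigma^-1.

        dF/dlambda_ik = 2 (G Lambda Phi)_ik, dF/dphi_jk = (2 - delta_jk)
        (Lambda' G Lambda)_jk, dF/dtheta_i = G_ii; effect-coding dependent
        loadings contribute through the chain rule with coefficient -1.
        """
        B = 2.0 * (G @ lam @ phi)
        M = lam.T @ G @ lam
        g = np.empty(self.n_free)
        pos = 0
        for positions in self.lam_slots:
            total = 0.0
            for i, k in positions:
                total += B[i, k]
                dep = self.dep_positions.get(k)
                if dep is not None:
                    total -= B[dep[0], k]
            g[pos] = total
            pos += 1
        for j, k in self.phi_slots:
            g[pos] = M[j, k] if j == k else 2.0 * M[j, k]
            pos += 1
        for i in self.theta_slots:
            g[pos] = G[i, i]
            pos += 1
        return g


# ---------------------------------------------------------------------------
# discrepancy and fitting


def _check_pd(sigma: np.ndarray, what: str) -> np.ndarray:
    """Cholesky factor of ``sigma`` or a NonPositiveDefiniteError with diagnostics."""
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        eigs = np.linalg.eigvalsh(sigma)
        cond = eigs[-1] / eigs[0] if eigs[0] != 0 else np.inf
        raise NonPositiveDefiniteError(
            f"{what} is not positive definite "
            f"(min eigenvalue {eigs[0]:.3e}, condition number {cond:.3e})"
        ) from exc


def ml_discrepancy(S: SampleCovariance, sigma: ImpliedCovariance) -> float:
    """Normal-theory ML fit function log|Sigma| + tr(S Sigma^-1) - log|S| - p.

    Zero iff Sigma equals S; requires Sigma positive definite.
    """
    s = S.values
    sig = np.asarray(sigma.values if isinstance(sigma, ImpliedCovariance) else sigma, float)
    if sig.shape != s.shape:
        raise DimensionError(f"S is {s.shape} but Sigma is {sig.shape}")
    p = s.shape[0]
    L = _check_pd(sig, "model-implied covariance")
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise NonPositiveDefiniteError("sample covariance is not positive definite")
    sig_inv = np.linalg.inv(sig)
    return float(logdet_sigma + np.trace(s @ sig_inv) - logdet_s - p)


@dataclass
class FitResult:
    """Estimates, discrepancy, fit indices and convergence diagnostics."""

    estimates: CFAModel
    discrepancy: float
    df: int
    n_free: int
    converged: bool
    iterations: int
    gradient_norm: float
    param_names: list[str] = field(default_factory=list)
    param_values: np.ndarray | None = None
    chi_square: float | None = None
    normed_chi_square: float | None = None
    rmsea: float | None = None
    srmr: float | None = None
    cfi: float | None = None
    gfi: float | None = None
    se: np.ndarray | None = None
    z: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None


def fit(
    S: SampleCovariance,
    spec: ModelSpec,
    compute_indices: bool = True,
    compute_se: bool = False,
    max_iterations: int = 2000,
    gtol: float = 1e-7,
) -> FitResult:
    """Minimise the ML discrepancy over the free parameters of ``spec``.

    Quasi-Newton (BFGS) with analytic gradients; convergence when the
    gradient norm drops below ``gtol``.  Identification constraints are built
    into the parameterisation, so they hold exactly at every iterate.  Fit
    indices are filled in when the sample size is known; Heywood estimates
    are returned as estimated (flagged by the containers), never bounded.
    """
    if spec.p != S.p:
        raise SpecificationError(f"spec is for p={spec.p} but S is {S.p} x {S.p}")
    par = _Parameterization(spec)
    p = S.p
    df = p * (p + 1) // 2 - par.n_free
    if df < 0:
        raise SpecificationError(
            f"model has {par.n_free} free parameters but only {p * (p + 1) // 2} "
            "distinct covariance moments (df < 0)"
        )
    if S.is_correlation:
        logger.info(
            "correlation matrix treated as a covariance matrix; chi-square-based "
            "indices assume covariance input"
        )

    s = S.values
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise NonPositiveDefiniteError("sample covariance is not positive definite")

    def objective(x: np.ndarray):
        lam, phi, theta = par.matrices(x)
        sigma = lam @ phi @ lam.T + theta
        sigma = (sigma + sigma.T) / 2.0
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            # steer the line search back toward the interior
            return _PENALTY * (1.0 + float(x @ x)), 2.0 * _PENALTY * x
        logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
        sig_inv = np.linalg.inv(sigma)
        f = logdet_sigma + float(np.sum(sig_inv * s)) - logdet_s - p
        G = sig_inv - sig_inv @ s @ sig_inv
        return f, par.gradient(x, lam, phi, G)

    x0 = par.start_values(s)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iterations},
    )
    f_val, g_val = objective(res.x)
    gnorm = float(np.max(np.abs(g_val), initial=0.0))
    converged = bool(res.success or gnorm < 1e-6)

    lam, phi, theta = par.matrices(res.x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # Heywood flags are inspected downstream
        estimates = CFAModel(
            loadings=FactorLoadings(
                lam,
                variable_names=list(spec.variable_names),
                factor_names=list(spec.factor_names),
            ),
            latent_cov=LatentCovariance(phi, factor_names=list(spec.factor_names)),
            error_cov=ErrorCovariance(
                theta, variable_names=list(spec.variable_names)
            ),
        )

    result = FitResult(
        estimates=estimates,
        discrepancy=float(f_val),
        df=df,
        n_free=par.n_free,
        converged=converged,
        iterations=int(res.nit),
        gradient_norm=gnorm,
        param_names=par.param_names(),
        param_values=res.x.copy(),
        spec=spec,
    )
    if estimates.error_cov.has_heywood:
        result.notes.append("Heywood case: negative error-variance estimate(s)")
    if compute_indices and S.n is not None and converged:
        result = fit_indices(result, S)
    if compute_se and S.n is not None:
        se, z = standard_errors(result, S)
        result.se, result.z = se, z
    return result


def _independence_fit(S: SampleCovariance) -> tuple[float, int]:
    """Discrepancy and df of the independence baseline (free diagonal only).

    The baseline minimiser is Sigma = diag(S), giving
    F_b = sum(log s_ii) - log|S| and df_b = p(p-1)/2 in closed form.
    """
    s = S.values
    p = s.shape[0]
    _, logdet_s = np.linalg.slogdet(s)
    f_b = float(np.sum(np.log(np.diag(s))) - logdet_s)
    return f_b, p * (p - 1) // 2


def fit_indices(
    result: FitResult, S: SampleCovariance, baseline: FitResult | None = None
) -> FitResult:
    """Populate chi-square and descriptive fit indices on a fitted result.

    chi^2 = (n-1) F; RMSEA = sqrt(max(chi^2 - df, 0) / (df (n-1)));
    SRMR is the root mean squared standardized residual over the lower
    triangle including the diagonal; CFI compares excess chi-square against
    the independence baseline (fitted internally in closed form when not
    supplied); GFI = 1 - tr[(Sigma^-1(S - Sigma))^2] / tr[(Sigma^-1 S)^2].
    """
    if S.n is None:
        raise ValueError("fit indices require the sample size n")
    n = S.n
    p = S.p
    out = replace(result, notes=list(result.notes))

    F = result.discrepancy
    chi2 = (n - 1) * F
    out.chi_square = float(chi2)
    df = result.df
    if df > 0:
        out.normed_chi_square = float(chi2 / df)
        out.rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        out.normed_chi_square = None
        out.rmsea = 0.0
        out.notes.append("df = 0: RMSEA reported as 0 (saturated model)")

    est = result.estimates
    sig = est.true_part() + est.error_cov.values
    s = S.values
    sd = np.sqrt(np.diag(s))
    resid = (s - sig) / np.outer(sd, sd)
    tri = np.tril_indices(p)
    out.srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))

    if baseline is not None:
        f_b, df_b = baseline.discrepancy, baseline.df
    else:
        f_b, df_b = _independence_fit(S)
    chi2_b = (n - 1) * f_b
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    out.cfi = 1.0 if den == 0.0 else float(1.0 - num / den)

    sig_inv = np.linalg.inv(sig)
    r = sig_inv @ (s - sig)
    d = sig_inv @ s
    out.gfi = float(1.0 - np.trace(r @ r) / np.trace(d @ d))
    return out


def standard_errors(
    result: FitResult, S: SampleCovariance
) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic standard errors and z ratios for the free parameters.

    The parameter covariance is (2 / (n - 1)) H^-1 with H the Hessian of the
    discrepancy at the optimum, obtained by central differences of the
    analytic gradient.  The z ratio estimate/SE is invariant to the scale
    choice (e.g. to the criterion number under effect coding).
    """
    if S.n is None:
        raise ValueError("standard errors require the sample size n")
    if result.spec is None or result.param_values is None:
        raise ValueError("result does not carry its specification")
    par = _Parameterization(result.spec)
    s = S.values
    p = S.p
    _, logdet_s = np.linalg.slogdet(s)

    def grad(x: np.ndarray) -> np.ndarray:
        lam, phi, theta = par.matrices(x)
        sigma = lam @ phi @ lam.T + theta
        sigma = (sigma + sigma.T) / 2.0
        sig_inv = np.linalg.inv(sigma)
        G = sig_inv - sig_inv @ s @ sig_inv
        return par.gradient(x, lam, phi, G)

    x = result.param_values
    m = x.size
    H = np.empty((m, m))
    for i in range(m):
        h = 1e-5 * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (grad(xp) - grad(xm)) / (2.0 * h)
    H = (H + H.T) / 2.0
    cov = 2.0 / (S.n - 1) * np.linalg.inv(H)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = x / se
    return se, z
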