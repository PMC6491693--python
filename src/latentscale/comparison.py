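"""Comparison-ready scaled variances: each factor's contribution to responding.

Setting the squared-loadings criterion number to 1 transfers the whole
explained variance lambda'lambda * phi of a factor into its scaled variance
parameter.  The resulting numbers are comparable across factors of the same
model — e.g. trait versus method factors in a multitrait-multimethod design —
much like standardized regression weights, and for a one-factor model the
number equals the nonzero eigenvalue of lambda phi lambda'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import CFAModel
from .scaling import ScaledSolution, ScalingPlan, rescale, sum_squares_constant, scaled_variance

__all__ = [
    "ContributionReport",
    "explained_variance",
    "comparison_scaling",
    "rank1_eigen_check",
]

_DEGENERATE = 1e-12


def explained_variance(column: Sequence[float], phi: float) -> float:
    """Variance explained by one factor: lambda'lambda * phi = trace(lambda phi lambda')."""
    lam = np.asarray(column, dtype=float).ravel()
    if not np.all(np.isfinite(lam)) or not np.isfinite(phi):
        raise ValueError("explained_variance requires finite inputs")
    return float(lam @ lam) * float(phi)


@dataclass
class ContributionReport:
    """Per-factor contributions after criterion-1 scaling.

    ``table`` has one row per factor: original variance parameter phi, the
    scaling constant c, the scaled variance phi* (the contribution), the rank
    by descending phi* (ties broken by input factor order), and a flag for
    degenerate (all-zero-loading) factors.  ``shared_variance`` is the summed
    contribution of latent covariance terms to the total true-part trace; the
    per-factor numbers deliberately use the diagonal of Phi only.
    """

    table: pd.DataFrame
    total: float
    shared_variance: float
    solution: ScaledSolution | None = None
    flagged_factors: list[str] = field(default_factory=list)

    def contribution(self, factor: str) -> float:
        return float(self.table.loc[factor, "scaled_variance"])

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def comparison_scaling(model: CFAModel) -> ContributionReport:
    """Scale every factor by the squared-loadings criterion with p_c = 1.

    Each factor's scaled variance then equals its explained variance
    lambda'lambda * phi_kk.  Factors whose loading column is entirely zero
    cannot anchor a scale; they are flagged, reported with contribution 0 and
    constant 1, never dropped.  The returned scaled solution preserves the
    true part of the input model.
    """
    lam = model.loadings.values
    phi = model.latent_cov.values
    names = list(model.loadings.factor_names)

    constants = np.ones(model.q)
    flagged: list[str] = []
    rows = []
    for k, name in enumerate(names):
        column = lam[:, k]
        ss = float(column @ column)
        phi_k = float(phi[k, k])
        if ss <= _DEGENERATE:
            flagged.append(name)
            contribution = 0.0
            c_k = 1.0
        else:
            c_k = sum_squares_constant(column, 1.0)
            contribution = scaled_variance(phi_k, c_k)
        constants[k] = c_k
        rows.append(
            {
                "phi": phi_k,
                "constant": c_k,
                "scaled_variance": contribution,
                "degenerate": ss <= _DEGENERATE,
            }
        )

    table = pd.DataFrame(rows, index=pd.Index(names, name="factor"))
    # stable sort: ties keep input factor order
    order = np.argsort(-table["scaled_variance"].to_numpy(), kind="stable")
    rank = np.empty(model.q, dtype=int)
    rank[order] = np.arange(1, model.q + 1)
    table["rank"] = rank

    plan = ScalingPlan(
        method="sum_squares",
        constants=constants,
        per_factor_params=[1.0] * model.q,
        factor_names=names,
    )
    solution = rescale(model, plan)

    # trace of the full true part splits into per-factor diagonal terms plus
    # the cross terms due to latent covariances
    total_trace = float(np.trace(model.true_part()))
    diag_total = float(table["scaled_variance"].sum())
    shared = total_trace - sum(
        float(lam[:, k] @ lam[:, k]) * float(phi[k, k]) for k in range(model.q)
    )

    return ContributionReport(
        table=table,
        total=diag_total,
        shared_variance=shared,
        solution=solution,
        flagged_factors=flagged,
    )


def rank1_eigen_check(column: Sequence[float], phi: float) -> float:
    """Largest eigenvalue of the rank-1 true part lambda phi lambda'.

    For a one-factor model with phi > 0 this equals the explained variance
    lambda'lambda * phi, which is why criterion-1 scaled variances can be
    read like eigenvalues of a unidimensional solution.
    """
    lam = np.asarray(column, dtype=float).ravel()
    m = np.outer(lam, lam) * float(phi)
    return float(np.linalg.eigvalsh(m)[-1])
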