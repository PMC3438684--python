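"""Dirichlet-multinomial marginal likelihoods and log Bayes factors.

Each contingency-table row (one phenotype class) is scored as a
Dirichlet-multinomial compound probability with a symmetric per-cell
pseudo-count ``alpha``; rows are independent given the phenotype classes, so
the table's log marginal likelihood is the sum over rows:

    ln p(S | D, M) = sum_j [ lnG(c*a) - lnG(n_j. + c*a)
                             + sum_s ( lnG(n_js + a) - lnG(a) ) ]

with ``c`` genotype categories and row totals ``n_j.``.  The Bayes factor of
an association model against the null compares the likelihood of the same
coded observations arranged in q rows versus one pooled row.

The default pseudo-count follows the smoothing convention used for
prediction, ``alpha = 4 / q`` of the model being scored (so the null, q = 1,
uses alpha = 4); it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import AssociationModel, ContingencyTable, InheritanceMode


@dataclass(frozen=True)
class DirichletPrior:
    """Symmetric per-cell Dirichlet pseudo-count."""

    alpha: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")

    @classmethod
    def for_model(cls, model: AssociationModel) -> "DirichletPrior":
        return cls(alpha=4.0 / AssociationModel(model).q)


@dataclass(frozen=True)
class ModelScore:
    snp_id: str
    model: AssociationModel
    mode: InheritanceMode
    log_marginal: float
    ln_bf: float


def log_dirichlet_multinomial_rows(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized row-wise DM log probability, summed over the row axis.

    ``counts`` has shape (..., q, c, p) or (q, c); the sum runs over q and the
    result drops the q and c axes.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if counts.ndim == 2:  # (q, c) single table
        c = counts.shape[1]
        row_tot = counts.sum(axis=1)
        per_row = (
            gammaln(c * alpha)
            - gammaln(row_tot + c * alpha)
            + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=1)
        )
        return per_row.sum()
    # (..., q, c, p): genotype categories on axis -2
    c = counts.shape[-2]
    row_tot = counts.sum(axis=-2)
    per_row = (
        gammaln(c * alpha)
        - gammaln(row_tot + c * alpha)
        + (gammaln(counts + alpha) - gammaln(alpha)).sum(axis=-2)
    )
    return per_row.sum(axis=-2)


def log_marginal_likelihood(
    table: ContingencyTable, prior: DirichletPrior | None = None
) -> float:
    """ln p(coded observations | model) for one contingency table."""
    counts = np.asarray(table.counts)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if prior is None:
        prior = DirichletPrior.for_model(table.model)
    return float(log_dirichlet_multinomial_rows(counts, prior.alpha))


def log_bayes_factor(
    model_table: ContingencyTable,
    null_table: ContingencyTable,
    model_prior: DirichletPrior | None = None,
    null_prior: DirichletPrior | None = None,
) -> float:
    """ln BF of an association model against the null on the same coded data.

    Both tables must use the same inheritance coding so that the factor
    compares identical data representations.
    """
    if model_table.mode is not null_table.mode:
        raise ValueError("model and null tables must share an inheritance mode")
    return log_marginal_likelihood(model_table, model_prior) - log_marginal_likelihood(
        null_table, null_prior
    )
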