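"""Bayesian classifiers over nested SNP sets.

Each ranked SNP contributes a smoothed conditional probability table (CPT)
of its genotype given the phenotype classes of its assigned model.  CPTs are
always fitted under the genotypic coding (3 categories), which subsumes the
other inheritance codings, with the Bayesian smoothing estimate

    P(S_i = s | D = d, M_i) = (n_ijs + av) / (n_ij. + 3 * av),   av = 4 / q,

where ``q`` is the number of phenotype rows of the assigned model.  The joint
phenotype posterior for a genotype profile is the prior times the product of
per-SNP CPT entries over the top-r SNPs (naive-Bayes factorization), and the
prediction statistics are posterior-odds ratios:

* marginal  — predict Da from genotype alone, summing over unknown Db;
* conditional — predict Da given genotype and the known Db value;
* naive     — two-class statistic from a Da-only (naive) search and series.

Each comes in a single-classifier form (posterior at Sigma_r) and an ensemble
form (ratio of the means over k = 1..r of the class posteriors at Sigma_k).
The decision rule assigns class 2 when the statistic exceeds the threshold T
(strictly); T = 1 is the Bayesian classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AssociationModel,
    ContingencyTable,
    GenotypeMatrix,
    InheritanceMode,
    PhenotypeTable,
    joint_class_counts,
)
from .search import ModelAssignment, RankedSNPList

KINDS = ("marginal", "conditional", "naive")
VARIANTS = ("single", "ensemble")


@dataclass
class SmoothedCPT:
    """P(S = s | phenotype row j) with per-cell pseudo-count av = 4/q."""

    probs: np.ndarray  # (q, 3), rows sum to 1
    av: float
    model: AssociationModel

    @property
    def q(self) -> int:
        return self.probs.shape[0]


def fit_cpt(table: ContingencyTable, model: AssociationModel | None = None) -> SmoothedCPT:
    """Smoothed genotype-given-phenotype table from genotypic-coded counts."""
    if table.mode is not InheritanceMode.GENOTYPIC:
        raise ValueError("prediction CPTs require the genotypic coding")
    model = AssociationModel(model) if model is not None else table.model
    q = table.counts.shape[0]
    av = 4.0 / q
    counts = table.counts.astype(np.float64)
    probs = (counts + av) / (counts.sum(axis=1, keepdims=True) + 3.0 * av)
    return SmoothedCPT(probs=probs, av=av, model=model)


@dataclass
class PredictionStatistic:
    value: float
    kind: str
    variant: str
    r: int
    db: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.db is not None and self.db not in (1, 2):
            raise ValueError("db must be 1 or 2")


@dataclass
class NestedClassifierSeries:
    """Ranked SNPs with smoothed CPTs and a prior over phenotype classes.

    ``n_classes`` is 4 for the pleiotropic series (joint (Da, Db) classes in
    the order (1,1), (1,2), (2,1), (2,2)) and 2 for the naive Da-only series.
    ``log_cpt[i, d, g]`` is the log CPT entry of ranked SNP i for class d and
    genotype g, with a fourth genotype slot (g = 3) fixed at 0 so missing
    genotypes drop out of the product.
    """

    assignments: list[ModelAssignment]
    cpts: list[SmoothedCPT]
    prior: np.ndarray
    n_classes: int
    log_cpt: np.ndarray  # (r_avail, n_classes, 4)

    @property
    def r_avail(self) -> int:
        return len(self.assignments)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.array([a.snp_index for a in self.assignments], dtype=np.int64)


def _expand_rows(model: AssociationModel, n_classes: int) -> np.ndarray:
    """Map phenotype-class index -> CPT row index for a model."""
    if n_classes == 2:  # naive series: classes are Da values
        return np.array([0, 1]) if model is not AssociationModel.M0 else np.zeros(2, int)
    if model is AssociationModel.Ma:
        return np.array([0, 0, 1, 1])  # row = da - 1
    if model is AssociationModel.Mb:
        return np.array([0, 1, 0, 1])  # row = db - 1
    if model is AssociationModel.Mab:
        return np.arange(4)
    return np.zeros(4, int)  # M0: one pooled row


def build_series(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    ranked: RankedSNPList,
    r_max: int = 200,
    prior: str | np.ndarray = "uniform",
    naive: bool = False,
) -> NestedClassifierSeries:
    """Fit the nested classifier series on training data.

    ``naive=True`` builds the two-class Da-only series (ranked list from the
    naive search); otherwise the four-joint-class pleiotropic series.
    """
    assignments = ranked.sigma(min(ranked.t, r_max))
    n_classes = 2 if naive else 4
    if naive:
        labels = (phenotypes.da - 1).astype(np.int64)
    else:
        labels = phenotypes.joint_class()
    idx = np.array([a.snp_index for a in assignments], dtype=np.int64)
    counts = joint_class_counts(genotypes.genotypes[:, idx], labels, n_classes)

    if isinstance(prior, str):
        if prior == "uniform":
            prior_vec = np.full(n_classes, 1.0 / n_classes)
        elif prior == "empirical":
            cls = np.bincount(labels, minlength=n_classes).astype(np.float64)
            prior_vec = cls / cls.sum()
        else:
            raise ValueError("prior must be 'uniform', 'empirical', or a vector")
    else:
        prior_vec = np.asarray(prior, dtype=np.float64)
        if prior_vec.shape != (n_classes,) or not np.isclose(prior_vec.sum(), 1.0):
            raise ValueError("prior vector must have n_classes entries summing to 1")

    cpts, log_cpt = [], np.zeros((len(assignments), n_classes, 4))
    for k, a in enumerate(assignments):
        model = a.model if not naive else AssociationModel.Ma
        rows = _expand_rows(model, n_classes)
        q = rows.max() + 1
        row_counts = np.stack(
            [counts[rows == j, :, k].sum(axis=0) for j in range(q)]
        )
        table = ContingencyTable(
            counts=row_counts.astype(np.int64),
            model=model,
            mode=InheritanceMode.GENOTYPIC,
        )
        cpt = fit_cpt(table, model)
        cpts.append(cpt)
        log_cpt[k, :, :3] = np.log(cpt.probs[rows])
    return NestedClassifierSeries(
        assignments=assignments,
        cpts=cpts,
        prior=prior_vec,
        n_classes=n_classes,
        log_cpt=log_cpt,
    )


def posterior_curves(series: NestedClassifierSeries, profiles: np.ndarray) -> np.ndarray:
    """Normalized class posteriors for every subject at every cutoff r.

    ``profiles`` is (n_subjects, r_avail) genotypes aligned to the series'
    ranked SNPs (missing = -1).  Returns (n_subjects, r_avail, n_classes);
    entry [., r-1, .] is p(class | profile, Sigma_r).
    """
    profiles = np.asarray(profiles)
    n, r = profiles.shape
    if r != series.r_avail:
        raise ValueError("profile columns must match the series' ranked SNPs")
    g = np.where(profiles < 0, 3, profiles).astype(np.int64)
    # gather per-SNP log CPT contributions: (n, r, C)
    contrib = series.log_cpt[
        np.arange(r)[None, :, None],
        np.arange(series.n_classes)[None, None, :],
        g[:, :, None],
    ]
    logp = np.log(series.prior)[None, None, :] + np.cumsum(contrib, axis=1)
    logp -= logp.max(axis=2, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=2, keepdims=True)
    return post


def joint_posterior(
    profile: np.ndarray, series: NestedClassifierSeries, r: int
) -> np.ndarray:
    """Posterior over phenotype classes for one genotype profile at cutoff r.

    ``profile`` supplies a genotype (0/1/2, -1 = missing) for each of the
    series' ranked SNPs; r = 0 returns the prior.
    """
    if r < 0 or r > series.r_avail:
        raise ValueError(f"r must be in 0..{series.r_avail}")
    if r == 0:
        return series.prior.copy()
    post = posterior_curves(series, np.asarray(profile)[None, : series.r_avail])
    return post[0, r - 1]


def curves_from_posteriors(
    post: np.ndarray,
    kind: str,
    variant: str = "single",
    db: np.ndarray | None = None,
) -> np.ndarray:
    """Statistic curves (n, r) from a precomputed posterior array (n, r, C).

    The same posterior array serves all kinds and variants of one series, so
    callers evaluating several methods should compute it once with
    :func:`posterior_curves` and reuse it here.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    n_classes = post.shape[2]
    if kind == "naive":
        if n_classes != 2:
            raise ValueError("naive statistics require a naive (2-class) series")
        num, den = post[:, :, 1], post[:, :, 0]
    elif kind == "marginal":
        if n_classes != 4:
            raise ValueError("marginal statistics require the pleiotropic series")
        num, den = post[:, :, 2] + post[:, :, 3], post[:, :, 0] + post[:, :, 1]
    else:  # conditional
        if n_classes != 4:
            raise ValueError("conditional statistics require the pleiotropic series")
        if db is None:
            raise ValueError("conditional statistics require the known Db value")
        db = np.asarray(db, dtype=np.int64)
        if not np.isin(db, (1, 2)).all():
            raise ValueError("db values must be 1 or 2")
        sel2 = (2 + (db - 1))[:, None]  # class (Da=2, db)
        sel1 = (db - 1)[:, None]  # class (Da=1, db)
        rcols = np.arange(post.shape[1])[None, :]
        rows = np.arange(post.shape[0])[:, None]
        p2 = post[rows, rcols, sel2]
        p1 = post[rows, rcols, sel1]
        if variant == "ensemble":
            # the ensemble averages the conditional posteriors p(Da | Db=db, .)
            tot = p1 + p2
            num, den = p2 / tot, p1 / tot
        else:
            num, den = p2, p1
    if variant == "ensemble":
        k = np.arange(1, num.shape[1] + 1, dtype=np.float64)
        num = np.cumsum(num, axis=1) / k
        den = np.cumsum(den, axis=1) / k
    return num / den


def statistic_curves(
    series: NestedClassifierSeries,
    profiles: np.ndarray,
    kind: str,
    variant: str = "single",
    db: np.ndarray | None = None,
) -> np.ndarray:
    """Prediction statistics for every subject at every cutoff r; (n, r_avail)."""
    post = posterior_curves(series, profiles)
    return curves_from_posteriors(post, kind, variant, db)


def prediction_statistic(
    profile: np.ndarray,
    series: NestedClassifierSeries,
    r: int,
    kind: str,
    variant: str = "single",
    db: int | None = None,
) -> PredictionStatistic:
    """Posterior-odds prediction statistic C1 for one subject at cutoff r."""
    if r < 1 or r > series.r_avail:
        raise ValueError(f"r must be in 1..{series.r_avail}")
    db_arr = None if db is None else np.array([db])
    curves = statistic_curves(
        series, np.asarray(profile)[None, : series.r_avail], kind, variant, db_arr
    )
    return PredictionStatistic(
        value=float(curves[0, r - 1]), kind=kind, variant=variant, r=r, db=db
    )


def decide(statistic, threshold: float = 1.0):
    """Bayesian classification rule: class 2 iff C1 > T (strict), else 1."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if isinstance(statistic, PredictionStatistic):
        return 2 if statistic.value > threshold else 1
    values = np.asarray(statistic, dtype=np.float64)
    return np.where(values > threshold, 2, 1).astype(np.int8)
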