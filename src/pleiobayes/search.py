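"""Phase I model search: per-SNP Bayesian model selection and ranking.

For every SNP, eight single-phenotype models (Ma, Mb crossed with the
genotypic, allelic, dominant, and recessive codings) are compared against the
matched null by Bayes factor.  The best of the eight is kept when
``ln BF > threshold`` (default 1).  A second pass then tests the pleiotropic
model Mab under the winning mode: the SNP is upgraded to Mab iff the Mab
marginal likelihood strictly exceeds the first-pass model's.  Retained SNPs
are ranked by the ln Bayes factor of their assigned model against the null,
descending, ties broken by input (genomic) order, yielding the nested sets
``Sigma_r = {S_1, ..., S_r}``.

The naive variant restricts the search to the four Ma models and skips the
pleiotropy pass; it is the single-phenotype baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    MODES,
    AssociationModel,
    GenotypeMatrix,
    InheritanceMode,
    PhenotypeTable,
    joint_class_counts,
    mode_collapse,
)
from .scoring import log_dirichlet_multinomial_rows

#: symmetric Dirichlet pseudo-count used for every model in BF scoring.
#: A common per-cell alpha makes a model that merely adds empty phenotype
#: rows score identically to its reduced form, so Bayes factors compare
#: fit rather than prior sharpness; alpha = 1 is the uniform prior on each
#: row's genotype frequencies.
SCAN_ALPHA = 1.0


@dataclass
class ModelAssignment:
    snp_index: int
    snp_id: str
    model: AssociationModel
    mode: InheritanceMode
    ln_bf: float
    first_pass_phenotype: str  # "a" or "b"


@dataclass
class RankedSNPList:
    """SNPs passing the threshold, in descending ln-BF order."""

    assignments: list[ModelAssignment] = field(default_factory=list)

    @property
    def t(self) -> int:
        return len(self.assignments)

    def sigma(self, r: int) -> list[ModelAssignment]:
        if r < 0 or r > self.t:
            raise ValueError(f"r must be in 0..{self.t}")
        return self.assignments[:r]

    @property
    def snp_indices(self) -> np.ndarray:
        return np.array([a.snp_index for a in self.assignments], dtype=np.int64)

    @property
    def ln_bfs(self) -> np.ndarray:
        return np.array([a.ln_bf for a in self.assignments], dtype=np.float64)


@dataclass
class _Scores:
    """Per-SNP log marginals of every model under every mode."""

    logml_null: dict[InheritanceMode, np.ndarray]
    logml_a: dict[InheritanceMode, np.ndarray]
    logml_b: dict[InheritanceMode, np.ndarray] | None
    logml_ab: dict[InheritanceMode, np.ndarray] | None
    observed: np.ndarray  # per-SNP count of non-missing genotypes


def _score_all_models(
    genotypes: np.ndarray,
    phenotypes: PhenotypeTable,
    with_b: bool,
    alpha: float = SCAN_ALPHA,
) -> _Scores:
    if with_b:
        counts = joint_class_counts(genotypes, phenotypes.joint_class(), 4)
        rows_a = counts[:2].sum(axis=0, keepdims=True), counts[2:].sum(
            axis=0, keepdims=True
        )
        rows_a = np.concatenate(rows_a, axis=0)
        rows_b = np.stack([counts[0] + counts[2], counts[1] + counts[3]], axis=0)
    else:
        counts = joint_class_counts(
            genotypes, (phenotypes.da - 1).astype(np.int64), 2
        )
        rows_a = counts
        rows_b = None
    null_rows = counts.sum(axis=0, keepdims=True)

    logml_null, logml_a, logml_b, logml_ab = {}, {}, {}, {}
    for mode in MODES:
        logml_null[mode] = log_dirichlet_multinomial_rows(
            mode_collapse(null_rows, mode), alpha
        )
        logml_a[mode] = log_dirichlet_multinomial_rows(
            mode_collapse(rows_a, mode), alpha
        )
        if with_b:
            logml_b[mode] = log_dirichlet_multinomial_rows(
                mode_collapse(rows_b, mode), alpha
            )
            logml_ab[mode] = log_dirichlet_multinomial_rows(
                mode_collapse(counts, mode), alpha
            )
    observed = null_rows[0].sum(axis=0)
    return _Scores(
        logml_null=logml_null,
        logml_a=logml_a,
        logml_b=logml_b if with_b else None,
        logml_ab=logml_ab if with_b else None,
        observed=observed,
    )


def _check_classes(labels: np.ndarray, what: str, skip: bool = True) -> bool:
    """Warn on a degenerate phenotype (< 2 subjects in a class).

    A degenerate target phenotype makes the scan meaningless (``skip``);
    a degenerate secondary phenotype only collapses Mb/Mab onto simpler
    models, which the scoring handles, so the scan proceeds.
    """
    counts = np.bincount(labels - 1, minlength=2)
    if counts.min() < 2:
        warnings.warn(
            f"fewer than 2 subjects in a {what} phenotype class"
            + ("; scan skipped" if skip else ""),
            stacklevel=3,
        )
        return not skip
    return True


def first_pass_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    threshold: float = 1.0,
) -> list[ModelAssignment]:
    """Best single-phenotype model per SNP; retains SNPs with ln BF > threshold.

    Evaluates Ma and Mb under all four inheritance codings (8 models) against
    matched nulls; SNPs with no non-missing genotype are skipped.
    """
    if phenotypes.db is None:
        raise ValueError("pleiotropic first pass requires both phenotypes")
    if not _check_classes(phenotypes.da, "Da"):
        return []
    _check_classes(phenotypes.db, "Db", skip=False)
    scores = _score_all_models(genotypes.genotypes, phenotypes, with_b=True)
    return _select_first_pass(genotypes, scores, threshold, with_b=True)


def _select_first_pass(
    genotypes: GenotypeMatrix, scores: _Scores, threshold: float, with_b: bool
) -> list[ModelAssignment]:
    p = genotypes.n_snps
    stacked = []
    labels = []
    for mode in MODES:
        stacked.append(scores.logml_a[mode] - scores.logml_null[mode])
        labels.append(("a", mode))
    if with_b:
        for mode in MODES:
            stacked.append(scores.logml_b[mode] - scores.logml_null[mode])
            labels.append(("b", mode))
    bf = np.vstack(stacked)  # (n_models, p)
    best = bf.argmax(axis=0)
    best_bf = bf[best, np.arange(p)]
    keep = (best_bf > threshold) & (scores.observed > 0)
    out = []
    for idx in np.flatnonzero(keep):
        pheno, mode = labels[best[idx]]
        out.append(
            ModelAssignment(
                snp_index=int(idx),
                snp_id=str(genotypes.snp_ids[idx]),
                model=AssociationModel.Ma if pheno == "a" else AssociationModel.Mb,
                mode=mode,
                ln_bf=float(best_bf[idx]),
                first_pass_phenotype=pheno,
            )
        )
    return out


def pleiotropy_pass(
    candidates: list[ModelAssignment],
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
) -> list[ModelAssignment]:
    """Second pass: upgrade a candidate to Mab when the pleiotropic marginal
    likelihood strictly exceeds the first-pass model's, under the first-pass
    winning mode; the final ln BF is recomputed for the assigned model against
    the matched null."""
    if phenotypes.db is None:
        raise ValueError("pleiotropic search requires both phenotypes")
    if not candidates:
        return []
    scores = _score_all_models(genotypes.genotypes, phenotypes, with_b=True)
    out = []
    for cand in candidates:
        i, mode = cand.snp_index, cand.mode
        single = (
            scores.logml_a[mode][i]
            if cand.first_pass_phenotype == "a"
            else scores.logml_b[mode][i]
        )
        if scores.logml_ab[mode][i] > single:  # strict: ties keep simpler model
            model = AssociationModel.Mab
            ln_bf = float(scores.logml_ab[mode][i] - scores.logml_null[mode][i])
        else:
            model = cand.model
            ln_bf = cand.ln_bf
        out.append(
            ModelAssignment(
                snp_index=i,
                snp_id=cand.snp_id,
                model=model,
                mode=mode,
                ln_bf=ln_bf,
                first_pass_phenotype=cand.first_pass_phenotype,
            )
        )
    return out


def rank_and_nest(assignments: list[ModelAssignment]) -> RankedSNPList:
    """Stable descending sort by ln BF; ties keep input (genomic) order."""
    for a in assignments:
        if not np.isfinite(a.ln_bf):
            raise ValueError(f"non-finite ln BF for SNP {a.snp_id}")
    order = np.argsort([-a.ln_bf for a in assignments], kind="stable")
    return RankedSNPList(assignments=[assignments[i] for i in order])


def pleiotropic_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    threshold: float = 1.0,
) -> RankedSNPList:
    """Full phase I: first pass, pleiotropy pass, ranking."""
    if phenotypes.db is None:
        raise ValueError("pleiotropic search requires both phenotypes")
    if not _check_classes(phenotypes.da, "Da"):
        return RankedSNPList()
    _check_classes(phenotypes.db, "Db", skip=False)
    scores = _score_all_models(genotypes.genotypes, phenotypes, with_b=True)
    candidates = _select_first_pass(genotypes, scores, threshold, with_b=True)
    out = []
    for cand in candidates:
        i, mode = cand.snp_index, cand.mode
        single = (
            scores.logml_a[mode][i]
            if cand.first_pass_phenotype == "a"
            else scores.logml_b[mode][i]
        )
        if scores.logml_ab[mode][i] > single:
            cand = ModelAssignment(
                snp_index=i,
                snp_id=cand.snp_id,
                model=AssociationModel.Mab,
                mode=mode,
                ln_bf=float(scores.logml_ab[mode][i] - scores.logml_null[mode][i]),
                first_pass_phenotype=cand.first_pass_phenotype,
            )
        out.append(cand)
    return rank_and_nest(out)


def naive_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    threshold: float = 1.0,
) -> RankedSNPList:
    """Single-phenotype search: Ma under the four codings only, no Mab pass."""
    if not _check_classes(phenotypes.da, "Da"):
        return RankedSNPList()
    da_only = PhenotypeTable(da=phenotypes.da)
    scores = _score_all_models(genotypes.genotypes, da_only, with_b=False)
    candidates = _select_first_pass(genotypes, scores, threshold, with_b=False)
    return rank_and_nest(candidates)
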