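"""Genotype/phenotype containers, inheritance-mode recoding, contingency tables.

Genotypes are stored as an ``int8`` matrix with the coding
``0 = AA`` (homozygous A1), ``1 = AB`` (heterozygous), ``2 = BB``
(homozygous A2), ``-1 = missing``.  "A" refers to the A1 allele of the
input file throughout; orientation is never flipped silently.

Association models relate a SNP ``S`` to two dichotomous phenotypes
``Da`` and ``Db`` (each coded 1/2):

* ``M0``  — S independent of both phenotypes (one pooled row, q = 1);
* ``Ma``  — S depends on Da only (q = 2 rows);
* ``Mb``  — S depends on Db only (q = 2 rows);
* ``Mab`` — pleiotropic, S depends on the joint class (Da, Db)
  (q = 4 rows, fixed order (1,1), (1,2), (2,1), (2,2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

MISSING = -1

#: joint phenotype classes in fixed order: index = (Da - 1) * 2 + (Db - 1)
JOINT_CLASSES = ((1, 1), (1, 2), (2, 1), (2, 2))


class InheritanceMode(str, Enum):
    """Mapping of the three genotypes onto the categories of the model."""

    GENOTYPIC = "genotypic"
    ALLELIC = "allelic"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @property
    def n_categories(self) -> int:
        return 3 if self is InheritanceMode.GENOTYPIC else 2


class AssociationModel(str, Enum):
    M0 = "M0"
    Ma = "Ma"
    Mb = "Mb"
    Mab = "Mab"

    @property
    def q(self) -> int:
        """Number of phenotype rows in the model's contingency table."""
        return {"M0": 1, "Ma": 2, "Mb": 2, "Mab": 4}[self.value]


MODES = tuple(InheritanceMode)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs genotype categories with SNP metadata."""

    genotypes: np.ndarray  # int8, shape (n_subjects, n_snps)
    snp_ids: np.ndarray  # str, shape (n_snps,)
    alleles: np.ndarray | None = None  # shape (n_snps, 2): (A1, A2) labels

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (subjects x SNPs)")
        if self.genotypes.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match genotype columns")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype entries must be in {0, 1, 2, -1}")
        if self.alleles is None:
            self.alleles = np.array([("A", "B")] * self.n_snps, dtype=object)

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class PhenotypeTable:
    """Two dichotomous phenotypes coded 1/2; ``db`` optional for naive runs."""

    da: np.ndarray
    db: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.da = np.asarray(self.da, dtype=np.int8)
        if not np.isin(self.da, (1, 2)).all():
            raise ValueError("Da values must be 1 or 2")
        if self.db is not None:
            self.db = np.asarray(self.db, dtype=np.int8)
            if not np.isin(self.db, (1, 2)).all():
                raise ValueError("Db values must be 1 or 2")
            if len(self.db) != len(self.da):
                raise ValueError("Da and Db lengths differ")

    @property
    def n_subjects(self) -> int:
        return len(self.da)

    def joint_class(self) -> np.ndarray:
        """Joint class index (Da-1)*2 + (Db-1), order (1,1),(1,2),(2,1),(2,2)."""
        if self.db is None:
            raise ValueError("joint class requires Db")
        return ((self.da - 1) * 2 + (self.db - 1)).astype(np.int64)


@dataclass
class ContingencyTable:
    """Phenotype-class (rows) x genotype-category (columns) counts."""

    counts: np.ndarray  # (q, c) non-negative integers
    model: AssociationModel
    mode: InheritanceMode

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if self.counts.shape != (self.model.q, self.mode.n_categories):
            raise ValueError(
                f"table shape {self.counts.shape} does not match model "
                f"{self.model.value} (q={self.model.q}) under {self.mode.value} "
                f"(c={self.mode.n_categories})"
            )
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def recode_genotypes(
    snp_column: np.ndarray, mode: InheritanceMode
) -> tuple[np.ndarray, np.ndarray]:
    """Recode one SNP's genotypes under an inheritance mode.

    Returns ``(coded, subject_index)`` where ``coded`` holds the 1-based
    category labels and ``subject_index`` maps each observation back to its
    subject row.  Missing genotypes are dropped; under the allelic coding each
    non-missing genotype emits two allele observations (AA -> 1,1; AB -> 1,2;
    BB -> 2,2) and a missing genotype drops both.
    """
    g = np.asarray(snp_column)
    if not np.isin(g, (MISSING, 0, 1, 2)).all():
        raise ValueError("unknown genotype symbol; expected {0, 1, 2, -1}")
    mode = InheritanceMode(mode)
    obs = np.flatnonzero(g != MISSING)
    gv = g[obs].astype(np.int64)
    if mode is InheritanceMode.GENOTYPIC:
        return gv + 1, obs
    if mode is InheritanceMode.DOMINANT:  # 1={AA}, 2={AB|BB}
        return np.where(gv == 0, 1, 2), obs
    if mode is InheritanceMode.RECESSIVE:  # 1={AA|AB}, 2={BB}
        return np.where(gv == 2, 2, 1), obs
    # allelic: each allele is an observation, 1={A}, 2={B}
    first = np.where(gv == 0, 1, np.where(gv == 1, 1, 2))
    second = np.where(gv == 0, 1, 2)
    coded = np.column_stack([first, second]).ravel()
    return coded, np.repeat(obs, 2)


def build_contingency_table(
    coded: np.ndarray,
    subject_index: np.ndarray,
    phenotypes: PhenotypeTable,
    model: AssociationModel,
    mode: InheritanceMode,
) -> ContingencyTable:
    """Tally a coded SNP against the phenotype classes required by a model."""
    model = AssociationModel(model)
    mode = InheritanceMode(mode)
    c = mode.n_categories
    coded = np.asarray(coded, dtype=np.int64)
    if coded.size and (coded.min() < 1 or coded.max() > c):
        raise ValueError(f"coded categories outside 1..{c} for mode {mode.value}")
    if model is AssociationModel.M0:
        rows = np.zeros(len(coded), dtype=np.int64)
        q = 1
    elif model is AssociationModel.Ma:
        rows = phenotypes.da[subject_index].astype(np.int64) - 1
        q = 2
    elif model is AssociationModel.Mb:
        if phenotypes.db is None:
            raise ValueError("model Mb requires Db")
        rows = phenotypes.db[subject_index].astype(np.int64) - 1
        q = 2
    else:  # Mab
        if phenotypes.db is None:
            raise ValueError("model Mab requires Db")
        rows = phenotypes.joint_class()[subject_index]
        q = 4
    counts = np.zeros((q, c), dtype=np.int64)
    np.add.at(counts, (rows, coded - 1), 1)
    return ContingencyTable(counts=counts, model=model, mode=mode)


def joint_class_counts(
    genotypes: np.ndarray, joint: np.ndarray, n_classes: int = 4
) -> np.ndarray:
    """Genotype counts per phenotype class for every SNP at once.

    Parameters
    ----------
    genotypes : (n, p) int8 matrix, missing = -1.
    joint : (n,) class index per subject in ``0..n_classes-1``.

    Returns
    -------
    (n_classes, 3, p) int64 array of genotype-category counts; missing
    genotypes contribute to no cell.
    """
    n, p = genotypes.shape
    counts = np.empty((n_classes, 3, p), dtype=np.int64)
    # one-hot class indicator matmul against per-category genotype indicators;
    # float32 is exact for counts < 2**24
    cls = np.zeros((n_classes, n), dtype=np.float32)
    cls[joint, np.arange(n)] = 1.0
    for g in range(3):
        counts[:, g, :] = np.rint(cls @ (genotypes == g).astype(np.float32)).astype(
            np.int64
        )
    return counts


def mode_collapse(counts3: np.ndarray, mode: InheritanceMode) -> np.ndarray:
    """Collapse genotypic-category counts (..., 3, p) into a mode's categories.

    The genotype axis is the second-to-last axis.  Under the allelic coding
    each genotype contributes its two alleles, so the total doubles.
    """
    mode = InheritanceMode(mode)
    n0, n1, n2 = counts3[..., 0, :], counts3[..., 1, :], counts3[..., 2, :]
    if mode is InheritanceMode.GENOTYPIC:
        return counts3
    if mode is InheritanceMode.DOMINANT:
        return np.stack([n0, n1 + n2], axis=-2)
    if mode is InheritanceMode.RECESSIVE:
        return np.stack([n0 + n1, n2], axis=-2)
    return np.stack([2 * n0 + n1, n1 + 2 * n2], axis=-2)  # allelic
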