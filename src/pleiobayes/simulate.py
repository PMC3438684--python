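"""Case-control GWAS simulator with two dichotomous phenotypes.

Subjects are first assigned joint phenotype classes (Da, Db) with exact
per-class counts set by the scenario; genotypes are then drawn per subject
from the 3-category genotype distribution of the subject's class, every SNP
independent of every other.

Non-causal SNPs follow Hardy-Weinberg equilibrium (HWE) frequencies
(p^2, 2pq, q^2) in every class.  A causal SNP keeps HWE frequencies in the
classes unaffected by its target trait(s) and, in an affected class, tilts
them multiplicatively and renormalizes:

    f(g) = f_HWE(g) * w(g) / Z,

where w(g) = OR^{I[g in risk set]} for the dominant/recessive modes and
w(g) = sqrt(OR)^{x(g)} (x = disease-allele count) for the additive mode, so
that the homozygote-versus-homozygote odds ratio equals the assigned OR.
Pleiotropic SNPs act on both traits; in the doubly affected class the two
weights multiply (effects additive on the log-odds scale).

Causal parameters (MAF, disease allele, OR within the scenario bounds, mode)
are drawn independently and uniformly per SNP.  The default MAF pool is
Uniform(0.05, 0.5); a user-supplied MAF list may be given instead.

Sixteen scenario presets mirror the four published simulation sets: six
balanced scenarios crossing sample size (1500/4000) with effect strength,
six 1000-subject scenarios with Da unbalanced (10% cases), two scenarios
without pleiotropy (75/75/0 causal), and two wide-effect scenarios
(OR 1.1-2.5).  All default to a 500,150-SNP assay and a 4000-subject
validation set; ``n_snps_total`` is configurable for reduced-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import JOINT_CLASSES, GenotypeMatrix, PhenotypeTable

SIM_MODES = ("dominant", "recessive", "additive")
TARGETS = ("both", "a", "b")

_SNP_CHUNK = 8192  # columns generated per block to bound memory


@dataclass(frozen=True)
class CausalSpec:
    """Randomly drawn parameters of one causal SNP."""

    snp_index: int
    target: str  # "a", "b", or "both"
    maf: float
    disease_allele: str  # "A" or "B"
    mode: str  # dominant / recessive / additive
    or_a: float | None = None
    or_b: float | None = None

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        if not 0.05 < self.maf <= 0.5:
            raise ValueError("MAF must be in (0.05, 0.5]")
        if self.disease_allele not in ("A", "B"):
            raise ValueError("disease allele must be 'A' or 'B'")
        if self.mode not in SIM_MODES:
            raise ValueError(f"mode must be one of {SIM_MODES}")
        if self.target in ("a", "both") and (self.or_a is None or self.or_a < 1):
            raise ValueError("or_a must be >= 1 for Da-affecting SNPs")
        if self.target in ("b", "both") and (self.or_b is None or self.or_b < 1):
            raise ValueError("or_b must be >= 1 for Db-affecting SNPs")


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation scenario: sample sizes, class counts, causal structure."""

    name: str
    discovery_counts: tuple[int, int, int, int]  # joint classes (1,1),(1,2),(2,1),(2,2)
    validation_counts: tuple[int, int, int, int]
    or_bounds_a: tuple[float, float]
    or_bounds_b: tuple[float, float]
    n_pleiotropic: int = 50
    n_da_only: int = 50
    n_db_only: int = 50
    n_snps_total: int = 500_150

    def __post_init__(self) -> None:
        for lo, hi in (self.or_bounds_a, self.or_bounds_b):
            if not (lo >= 1 and hi >= lo):
                raise ValueError("OR bounds must satisfy 1 <= OR_min <= OR_max")
        if self.n_causal > self.n_snps_total:
            raise ValueError("more causal SNPs than SNPs")

    @property
    def n_discovery(self) -> int:
        return sum(self.discovery_counts)

    @property
    def n_validation(self) -> int:
        return sum(self.validation_counts)

    @property
    def n_causal(self) -> int:
        return self.n_pleiotropic + self.n_da_only + self.n_db_only

    def at_scale(self, n_snps_total: int) -> "ScenarioConfig":
        """Same scenario with the assay size (null SNP count) changed."""
        return replace(self, n_snps_total=n_snps_total)


@dataclass
class SimulatedStudy:
    discovery_genotypes: GenotypeMatrix
    discovery_phenotypes: PhenotypeTable
    validation_genotypes: GenotypeMatrix
    validation_phenotypes: PhenotypeTable
    specs: list[CausalSpec]
    config: ScenarioConfig

    @property
    def truth(self) -> dict[int, str | None]:
        """SNP index -> causal type ('both'/'a'/'b') or None."""
        out: dict[int, str | None] = {
            i: None for i in range(self.config.n_snps_total)
        }
        for s in self.specs:
            out[s.snp_index] = s.target
        return out


def draw_causal_specs(
    config: ScenarioConfig,
    rng: np.random.Generator,
    maf_pool: np.ndarray | None = None,
) -> list[CausalSpec]:
    """Draw per-SNP causal parameters: MAF from the pool, disease allele
    uniform on {A, B}, OR uniform within the scenario bounds, mode uniform
    over dominant/recessive/additive.  Causal SNP positions are drawn without
    replacement from the assay."""
    if maf_pool is not None:
        maf_pool = np.asarray(maf_pool, dtype=np.float64)
        if maf_pool.size == 0:
            raise ValueError("maf_pool is empty")
        if not (maf_pool > 0.05).all():
            raise ValueError("maf_pool entries must all exceed 0.05")
    n_causal = config.n_causal
    indices = np.sort(rng.choice(config.n_snps_total, size=n_causal, replace=False))
    targets = ["both"] * config.n_pleiotropic + ["a"] * config.n_da_only + [
        "b"
    ] * config.n_db_only
    specs = []
    for idx, target in zip(indices, targets):
        maf = (
            float(rng.choice(maf_pool))
            if maf_pool is not None
            else float(rng.uniform(0.05, 0.5))
        )
        allele = "A" if rng.random() < 0.5 else "B"
        mode = SIM_MODES[rng.integers(3)]
        or_a = (
            float(rng.uniform(*config.or_bounds_a)) if target in ("a", "both") else None
        )
        or_b = (
            float(rng.uniform(*config.or_bounds_b)) if target in ("b", "both") else None
        )
        specs.append(
            CausalSpec(
                snp_index=int(idx),
                target=target,
                maf=maf,
                disease_allele=allele,
                mode=mode,
                or_a=or_a,
                or_b=or_b,
            )
        )
    return specs


def hwe_frequencies(maf: float) -> np.ndarray:
    """HWE genotype frequencies (AA, AB, BB) with B the minor allele."""
    p = 1.0 - maf
    return np.array([p * p, 2.0 * p * maf, maf * maf])


def _trait_weights(disease_allele: str, odds_ratio: float, mode: str) -> np.ndarray:
    """Per-genotype multiplicative odds weight of one trait's effect."""
    if odds_ratio < 1:
        raise ValueError("simulator ORs must be >= 1; protective effects are "
                         "encoded by the disease-allele choice")
    x = np.array([0, 1, 2]) if disease_allele == "B" else np.array([2, 1, 0])
    if mode == "dominant":
        return np.where(x >= 1, odds_ratio, 1.0)
    if mode == "recessive":
        return np.where(x == 2, odds_ratio, 1.0)
    if mode == "additive":
        return np.sqrt(odds_ratio) ** x
    raise ValueError(f"unknown mode {mode!r}")


def class_genotype_freqs(
    maf: float,
    disease_allele: str,
    mode: str,
    or_a: float | None = None,
    or_b: float | None = None,
) -> np.ndarray:
    """Genotype frequencies (AA, AB, BB) for each joint phenotype class.

    Returns a (4, 3) array over the classes (1,1), (1,2), (2,1), (2,2).
    Classes unaffected by the SNP's trait(s) keep HWE frequencies; affected
    classes are tilted by the trait weight(s) and renormalized.  For a
    pleiotropic SNP the doubly affected class multiplies both weights.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("MAF must be in (0, 0.5]")
    base = hwe_frequencies(maf)
    w_a = _trait_weights(disease_allele, or_a, mode) if or_a is not None else np.ones(3)
    w_b = _trait_weights(disease_allele, or_b, mode) if or_b is not None else np.ones(3)
    out = np.empty((4, 3))
    for j, (da, db) in enumerate(JOINT_CLASSES):
        w = np.ones(3)
        if da == 2:
            w = w * w_a
        if db == 2:
            w = w * w_b
        f = base * w
        out[j] = f / f.sum()
    return out


def _draw_block(
    rng: np.random.Generator, cum: np.ndarray, n: int
) -> np.ndarray:
    """Categorical genotype draws for one class block.

    ``cum`` is (p, 2): per-SNP cumulative frequencies (f_AA, f_AA + f_AB).
    """
    p = cum.shape[0]
    g = np.empty((n, p), dtype=np.int8)
    for lo in range(0, p, _SNP_CHUNK):
        hi = min(lo + _SNP_CHUNK, p)
        u = rng.random((n, hi - lo), dtype=np.float32)
        g[:, lo:hi] = (u > cum[lo:hi, 0]).astype(np.int8) + (
            u > cum[lo:hi, 1]
        ).astype(np.int8)
    return g


def _class_cumfreqs(
    config: ScenarioConfig, specs: list[CausalSpec], null_mafs: np.ndarray
) -> np.ndarray:
    """Per-class per-SNP cumulative genotype frequencies, shape (4, p, 2)."""
    p = config.n_snps_total
    base = np.empty((p, 3))
    pa = 1.0 - null_mafs
    base[:, 0] = pa * pa
    base[:, 1] = 2.0 * pa * null_mafs
    base[:, 2] = null_mafs * null_mafs
    freqs = np.broadcast_to(base, (4, p, 3)).copy()
    for s in specs:
        freqs[:, s.snp_index, :] = class_genotype_freqs(
            s.maf, s.disease_allele, s.mode, s.or_a, s.or_b
        )
    cum = np.cumsum(freqs, axis=2)[:, :, :2]
    return np.ascontiguousarray(cum)


def _phenotype_table(counts: tuple[int, int, int, int]) -> PhenotypeTable:
    da = np.concatenate(
        [np.full(c, cls[0], dtype=np.int8) for c, cls in zip(counts, JOINT_CLASSES)]
    )
    db = np.concatenate(
        [np.full(c, cls[1], dtype=np.int8) for c, cls in zip(counts, JOINT_CLASSES)]
    )
    return PhenotypeTable(da=da, db=db)


def simulate_study(
    config: ScenarioConfig,
    specs: list[CausalSpec] | None = None,
    rng: np.random.Generator | int | None = None,
    maf_pool: np.ndarray | None = None,
) -> SimulatedStudy:
    """Generate a discovery + validation study under a scenario.

    Phenotype class counts are exact; genotypes are conditionally independent
    given the class.  Deterministic for a given seed/generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if specs is None:
        specs = draw_causal_specs(config, rng, maf_pool)
    if len(specs) != config.n_causal:
        raise ValueError("spec count does not match the scenario's causal counts")
    p = config.n_snps_total
    if maf_pool is not None:
        null_mafs = rng.choice(np.asarray(maf_pool, dtype=np.float64), size=p)
    else:
        null_mafs = rng.uniform(0.05, 0.5, size=p)
    cum = _class_cumfreqs(config, specs, null_mafs)
    snp_ids = np.array([f"snp{i}" for i in range(p)], dtype=object)

    def _make(counts: tuple[int, int, int, int]):
        pheno = _phenotype_table(counts)
        blocks = [_draw_block(rng, cum[j], c) for j, c in enumerate(counts)]
        geno = np.concatenate(blocks, axis=0)
        return GenotypeMatrix(geno, snp_ids), pheno

    disc_g, disc_p = _make(config.discovery_counts)
    val_g, val_p = _make(config.validation_counts)
    return SimulatedStudy(
        discovery_genotypes=disc_g,
        discovery_phenotypes=disc_p,
        validation_genotypes=val_g,
        validation_phenotypes=val_p,
        specs=list(specs),
        config=config,
    )


def _balanced(n: int) -> tuple[int, int, int, int]:
    q, rem = divmod(n, 4)
    counts = [q] * 4
    for i in range(rem):
        counts[i] += 1
    return tuple(counts)


_SET1_OR = {
    1: (1.10, 1.50),
    2: (1.10, 1.50),
    3: (1.25, 2.00),
    4: (1.25, 2.00),
    5: (1.75, 2.50),
    6: (1.75, 2.50),
}
# scenario NAME is authoritative for sample size: odd = 1.5k, even = 4k
_SET1_N = {1: 1500, 2: 4000, 3: 1500, 4: 4000, 5: 1500, 6: 4000}

_SET2_OR = {
    1: ((1.1, 1.5), (1.5, 2.0)),
    2: ((1.1, 1.5), (2.0, 2.5)),
    3: ((1.5, 2.0), (1.5, 2.0)),
    4: ((1.5, 2.0), (2.0, 2.5)),
    5: ((2.0, 2.5), (1.5, 2.0)),
    6: ((2.0, 2.5), (1.5, 2.5)),
}

_SET3_OR = {"moderate": (1.25, 2.00), "strong": (1.75, 2.50)}
_SET4 = {1: 4000, 2: 1500}


def scenario_presets(name: str, set3_n: int = 4000) -> ScenarioConfig:
    """The 16 documented scenarios by name.

    Names: ``set1_scenario1..6``, ``set2_scenario1..6``, ``set3_moderate``,
    ``set3_strong``, ``set4_scenario1..2``.  ``set3_n`` sets the set-3
    discovery sample size, which the scenario tables leave open.
    """
    val_balanced = _balanced(4000)
    if name.startswith("set1_scenario"):
        i = int(name.removeprefix("set1_scenario"))
        if i not in _SET1_OR:
            raise ValueError(f"unknown scenario {name!r}")
        orr = _SET1_OR[i]
        return ScenarioConfig(
            name=name,
            discovery_counts=_balanced(_SET1_N[i]),
            validation_counts=val_balanced,
            or_bounds_a=orr,
            or_bounds_b=orr,
        )
    if name.startswith("set2_scenario"):
        i = int(name.removeprefix("set2_scenario"))
        if i not in _SET2_OR:
            raise ValueError(f"unknown scenario {name!r}")
        or_a, or_b = _SET2_OR[i]
        return ScenarioConfig(
            name=name,
            discovery_counts=(450, 450, 50, 50),
            validation_counts=(1800, 1800, 200, 200),
            or_bounds_a=or_a,
            or_bounds_b=or_b,
        )
    if name.startswith("set3_"):
        kind = name.removeprefix("set3_")
        if kind not in _SET3_OR:
            raise ValueError(f"unknown scenario {name!r}")
        orr = _SET3_OR[kind]
        return ScenarioConfig(
            name=name,
            discovery_counts=_balanced(set3_n),
            validation_counts=val_balanced,
            or_bounds_a=orr,
            or_bounds_b=orr,
            n_pleiotropic=0,
            n_da_only=75,
            n_db_only=75,
        )
    if name.startswith("set4_scenario"):
        i = int(name.removeprefix("set4_scenario"))
        if i not in _SET4:
            raise ValueError(f"unknown scenario {name!r}")
        return ScenarioConfig(
            name=name,
            discovery_counts=_balanced(_SET4[i]),
            validation_counts=val_balanced,
            or_bounds_a=(1.1, 2.5),
            or_bounds_b=(1.1, 2.5),
        )
    raise ValueError(f"unknown scenario {name!r}")


SCENARIO_NAMES = tuple(
    [f"set1_scenario{i}" for i in range(1, 7)]
    + [f"set2_scenario{i}" for i in range(1, 7)]
    + ["set3_moderate", "set3_strong"]
    + [f"set4_scenario{i}" for i in range(1, 3)]
)
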