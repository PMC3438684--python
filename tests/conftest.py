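import numpy as np
import pytest

from pleiobayes.core import GenotypeMatrix, PhenotypeTable
from pleiobayes.simulate import ScenarioConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20123)


def tiny_scenario(**overrides) -> ScenarioConfig:
    """A desk-sized scenario with strong, easily detected effects."""
    defaults = dict(
        name="tiny",
        discovery_counts=(100, 100, 100, 100),
        validation_counts=(50, 50, 50, 50),
        or_bounds_a=(2.0, 3.0),
        or_bounds_b=(2.0, 3.0),
        n_pleiotropic=4,
        n_da_only=4,
        n_db_only=4,
        n_snps_total=60,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture
def tiny_study():
    return simulate_study(tiny_scenario(), rng=7)


def snp_from_class_freqs(
    freqs: np.ndarray, class_counts: list[int], rng: np.random.Generator
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """One-SNP study: draw genotype counts per joint class from given freqs.

    ``freqs`` is (4, 3) over the joint classes (1,1),(1,2),(2,1),(2,2).
    """
    das, dbs, gs = [], [], []
    for j, ((da, db), n_c) in enumerate(zip(((1, 1), (1, 2), (2, 1), (2, 2)), class_counts)):
        counts = rng.multinomial(n_c, freqs[j])
        gs.append(np.repeat([0, 1, 2], counts))
        das.append(np.full(n_c, da))
        dbs.append(np.full(n_c, db))
    g = np.concatenate(gs).astype(np.int8)[:, None]
    return (
        GenotypeMatrix(g, ["s0"]),
        PhenotypeTable(da=np.concatenate(das), db=np.concatenate(dbs)),
    )
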