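"""End-to-end scenario replication: simulate, search, cross-validate, predict.

One replicate = one simulated study.  Phase I is run on the discovery set
(pleiotropic and naive searches), classifiers are fitted on the full
discovery set, and every prediction method is evaluated on the independent
validation set at each SNP-set size r.  When phase II is requested, the
SNP-set size r* and Youden threshold T* are selected by stratified 10-fold
cross-validation within the discovery set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import build_series, curves_from_posteriors, posterior_curves
from .core import GenotypeMatrix, PhenotypeTable
from .crossval import (
    METHODS,
    cross_validate,
    make_folds,
    select_r,
    select_threshold_youden,
    split_method,
)
from .evaluate import confusion_metrics
from .search import RankedSNPList, naive_scan, pleiotropic_scan
from .simulate import ScenarioConfig, SimulatedStudy, simulate_study


@dataclass
class MethodResult:
    """Validation performance of one prediction method in one replicate."""

    method: str
    accuracy_curve: np.ndarray  # per r at T = 1
    mss_curve: np.ndarray  # mean(sens, spec) per r at T = 1
    r_star: int | None = None
    t_star: float | None = None
    accuracy_at_r_star: float | None = None
    mss_at_r_star: float | None = None
    accuracy_at_t_star: float | None = None
    mss_at_t_star: float | None = None

    @property
    def peak_accuracy(self) -> float:
        return float(np.max(self.accuracy_curve))

    @property
    def peak_mss(self) -> float:
        return float(np.max(self.mss_curve))


@dataclass
class ReplicateResult:
    methods: dict[str, MethodResult]
    ranked: RankedSNPList
    ranked_naive: RankedSNPList
    study: SimulatedStudy | None = None


def _validation_curves(
    series, profiles: np.ndarray, methods: list[str], db: np.ndarray | None
):
    post = posterior_curves(series, profiles)
    out = {}
    for m in methods:
        kind, variant = split_method(m)
        out[m] = curves_from_posteriors(
            post, kind, variant, db if kind == "conditional" else None
        )
    return out


def evaluate_methods(
    ranked: RankedSNPList,
    ranked_naive: RankedSNPList,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    val_genotypes: GenotypeMatrix,
    val_phenotypes: PhenotypeTable,
    r_max: int = 200,
    prior: str = "uniform",
    methods: tuple[str, ...] = METHODS,
) -> dict[str, np.ndarray]:
    """Per-method validation statistic curves (n_val, r) at every cutoff."""
    curves: dict[str, np.ndarray] = {}
    pleio_methods = [m for m in methods if not m.startswith("naive")]
    naive_methods = [m for m in methods if m.startswith("naive")]
    if pleio_methods and ranked.t:
        series = build_series(genotypes, phenotypes, ranked, r_max, prior)
        prof = val_genotypes.genotypes[:, series.snp_indices]
        curves.update(
            _validation_curves(series, prof, pleio_methods, val_phenotypes.db)
        )
    if naive_methods and ranked_naive.t:
        series_n = build_series(
            genotypes, phenotypes, ranked_naive, r_max, prior, naive=True
        )
        prof = val_genotypes.genotypes[:, series_n.snp_indices]
        curves.update(_validation_curves(series_n, prof, naive_methods, None))
    return curves


def _metric_curves(stat_curves: np.ndarray, truth_da: np.ndarray, threshold: float):
    pred = np.where(stat_curves > threshold, 2, 1)
    case = truth_da == 2
    sens = (pred[case] == 2).mean(axis=0)
    spec = (pred[~case] == 1).mean(axis=0)
    acc = (pred == truth_da[:, None]).mean(axis=0)
    return acc, (sens + spec) / 2.0


def run_replicate(
    config: ScenarioConfig,
    seed: int | np.random.Generator,
    r_max: int = 200,
    threshold: float = 1.0,
    prior: str = "uniform",
    methods: tuple[str, ...] = METHODS,
    do_cv: bool = True,
    cv_folds: int = 10,
    keep_study: bool = False,
) -> ReplicateResult:
    """Simulate one study under a scenario and evaluate all requested methods."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    study = simulate_study(config, rng=rng)
    return analyze_study(
        study,
        rng,
        r_max=r_max,
        threshold=threshold,
        prior=prior,
        methods=methods,
        do_cv=do_cv,
        cv_folds=cv_folds,
        keep_study=keep_study,
    )


def analyze_study(
    study: SimulatedStudy,
    rng: np.random.Generator | int | None = None,
    r_max: int = 200,
    threshold: float = 1.0,
    prior: str = "uniform",
    methods: tuple[str, ...] = METHODS,
    do_cv: bool = True,
    cv_folds: int = 10,
    keep_study: bool = False,
) -> ReplicateResult:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    disc_g, disc_p = study.discovery_genotypes, study.discovery_phenotypes
    val_g, val_p = study.validation_genotypes, study.validation_phenotypes
    ranked = pleiotropic_scan(disc_g, disc_p, threshold)
    ranked_naive = naive_scan(disc_g, disc_p, threshold)
    stat_curves = evaluate_methods(
        ranked, ranked_naive, disc_g, disc_p, val_g, val_p, r_max, prior, methods
    )
    cv = None
    if do_cv:
        folds = make_folds(
            disc_p.n_subjects,
            cv_folds,
            strata=disc_p.joint_class(),
            seed=int(rng.integers(2**31)),
        )
        cv = cross_validate(
            disc_g, disc_p, folds, r_max, threshold, prior, methods
        )
    results = {}
    for m in methods:
        if m not in stat_curves:
            continue
        acc, mss = _metric_curves(stat_curves[m], val_p.da, 1.0)
        res = MethodResult(method=m, accuracy_curve=acc, mss_curve=mss)
        if cv is not None:
            r_star = select_r(cv, m)
            r_used = min(r_star, stat_curves[m].shape[1])
            pool = cv.stats[m][:, r_used - 1]
            ok = ~np.isnan(pool)
            t_star = select_threshold_youden(pool[ok], cv.labels[ok])
            res.r_star = r_star
            res.t_star = t_star
            at1 = confusion_metrics(
                np.where(stat_curves[m][:, r_used - 1] > 1.0, 2, 1), val_p.da
            )
            at_ts = confusion_metrics(
                np.where(stat_curves[m][:, r_used - 1] > t_star, 2, 1), val_p.da
            )
            res.accuracy_at_r_star = at1.accuracy
            res.mss_at_r_star = at1.mean_sens_spec
            res.accuracy_at_t_star = at_ts.accuracy
            res.mss_at_t_star = at_ts.mean_sens_spec
        results[m] = res
    return ReplicateResult(
        methods=results,
        ranked=ranked,
        ranked_naive=ranked_naive,
        study=study if keep_study else None,
    )


def assignment_rates(
    ranked: RankedSNPList, truth: dict[int, str | None], config: ScenarioConfig
) -> dict[str, float]:
    """Fractions of each true SNP type assigned the pleiotropic model.

    Unretained SNPs count as unassigned (null), matching an
    assignment-by-type summary over the whole assay.
    """
    n_noncausal = config.n_snps_total - config.n_causal
    n_single = config.n_da_only + config.n_db_only
    mab_noncausal = mab_single = mab_pleio = 0
    for a in ranked.assignments:
        if a.model.value != "Mab":
            continue
        kind = truth[a.snp_index]
        if kind is None:
            mab_noncausal += 1
        elif kind == "both":
            mab_pleio += 1
        else:
            mab_single += 1
    return {
        "mab_rate_noncausal": mab_noncausal / n_noncausal if n_noncausal else 0.0,
        "mab_rate_single_causal": mab_single / n_single if n_single else 0.0,
        "mab_rate_pleiotropic": (
            mab_pleio / config.n_pleiotropic if config.n_pleiotropic else 0.0
        ),
    }
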