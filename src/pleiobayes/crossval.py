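"""Phase II: cross-validated selection of the SNP-set size and threshold.

The discovery set is split into stratified folds (10-fold by default, or
leave-one-out).  For every fold, the full phase-I model search is repeated on
the training split, nested classifiers are fitted, and prediction statistics
are computed for the held-out subjects at every cutoff r.  Statistics are
pooled across folds per r; the selected size r* is the smallest r attaining
the maximal pooled AUC, and the optional decision threshold T* maximizes
Youden's J on the pooled statistics at r*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import build_series, curves_from_posteriors, posterior_curves
from .core import GenotypeMatrix, PhenotypeTable
from .evaluate import auc_mann_whitney
from .search import naive_scan, pleiotropic_scan

#: the six prediction methods: (kind, variant)
METHODS = (
    "naive_single",
    "naive_ensemble",
    "marginal_single",
    "marginal_ensemble",
    "conditional_single",
    "conditional_ensemble",
)


def split_method(method: str) -> tuple[str, str]:
    kind, variant = method.rsplit("_", 1)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    return kind, variant


@dataclass
class FoldPlan:
    """Per-subject fold index for k-fold or leave-one-out CV."""

    fold_index: np.ndarray
    k: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_index == fold
        return np.flatnonzero(~test), np.flatnonzero(test)


def make_folds(
    n: int,
    k_or_loo: int | str,
    strata: np.ndarray | None = None,
    seed: int | None = None,
) -> FoldPlan:
    """Deterministic stratified fold assignment.

    ``k_or_loo`` is a fold count or the string "loo".  Within each stratum,
    subjects are shuffled and dealt round-robin, so per-stratum fold counts
    differ by at most one.
    """
    if k_or_loo == "loo":
        return FoldPlan(fold_index=np.arange(n, dtype=np.int64), k=n)
    k = int(k_or_loo)
    if n < k:
        raise ValueError("need at least one subject per fold")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    strata = np.zeros(n, dtype=np.int64) if strata is None else np.asarray(strata)
    if len(strata) != n:
        raise ValueError("strata length must match n")
    start = 0  # continue the deal across strata to balance fold sizes
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        if len(members) < k:
            warnings.warn(
                f"stratum {s} has fewer members ({len(members)}) than folds ({k})",
                stacklevel=2,
            )
        perm = rng.permutation(members)
        fold[perm] = (start + np.arange(len(perm))) % k
        start = (start + len(perm)) % k
    return FoldPlan(fold_index=fold, k=k)


@dataclass
class CVResult:
    """Pooled out-of-fold statistics per method and cutoff r.

    ``stats[method]`` is (n_subjects, r_max) with NaN where a fold's ranked
    list was shorter than r.
    """

    stats: dict[str, np.ndarray]
    labels: np.ndarray  # out-of-fold truth (Da)
    r_max: int
    _auc_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def auc_curve(self, method: str) -> np.ndarray:
        """Pooled AUC per r (NaN where undefined)."""
        if method in self._auc_cache:
            return self._auc_cache[method]
        s = self.stats[method]
        out = np.full(self.r_max, np.nan)
        for r in range(self.r_max):
            ok = ~np.isnan(s[:, r])
            lab = self.labels[ok]
            if ok.sum() and (lab == 2).any() and (lab == 1).any():
                out[r] = auc_mann_whitney(s[ok, r], lab)
        self._auc_cache[method] = out
        return out

    def sens_spec_curve(self, method: str, threshold: float = 1.0):
        """(sensitivity, specificity) arrays per r at a decision threshold."""
        s = self.stats[method]
        pred = np.where(s > threshold, 2, 1)
        case = self.labels == 2
        sens = np.empty(self.r_max)
        spec = np.empty(self.r_max)
        for r in range(self.r_max):
            ok = ~np.isnan(s[:, r])
            sens[r] = np.mean(pred[ok & case, r] == 2) if (ok & case).any() else np.nan
            spec[r] = np.mean(pred[ok & ~case, r] == 1) if (ok & ~case).any() else np.nan
        return sens, spec


def cross_validate(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    folds: FoldPlan,
    r_max: int = 200,
    threshold: float = 1.0,
    prior: str = "uniform",
    methods: tuple[str, ...] = METHODS,
) -> CVResult:
    """Repeat phase I per training split and score held-out subjects.

    ``threshold`` is the phase-I ln-BF retention threshold.  Methods needing
    Db require ``phenotypes.db``.
    """
    n = phenotypes.n_subjects
    need_pleio = any(m.startswith(("marginal", "conditional")) for m in methods)
    need_naive = any(m.startswith("naive") for m in methods)
    if need_pleio and phenotypes.db is None:
        raise ValueError("pleiotropic methods require Db")
    stats = {m: np.full((n, r_max), np.nan) for m in methods}
    for f in range(folds.k):
        train, test = folds.train_test(f)
        if len(test) == 0:
            continue
        g_train = GenotypeMatrix(
            genotypes.genotypes[train], genotypes.snp_ids, genotypes.alleles
        )
        p_train = PhenotypeTable(
            da=phenotypes.da[train],
            db=None if phenotypes.db is None else phenotypes.db[train],
        )
        if need_pleio and (ranked := pleiotropic_scan(g_train, p_train, threshold)).t:
            series = build_series(g_train, p_train, ranked, r_max, prior)
            prof = genotypes.genotypes[np.ix_(test, series.snp_indices)]
            post = posterior_curves(series, prof)
            db_test = phenotypes.db[test]
            for m in methods:
                if m.startswith("naive"):
                    continue
                kind, variant = split_method(m)
                curves = curves_from_posteriors(
                    post, kind, variant, db_test if kind == "conditional" else None
                )
                stats[m][test[:, None], np.arange(curves.shape[1])[None, :]] = curves
        if need_naive and (ranked_n := naive_scan(g_train, p_train, threshold)).t:
            series_n = build_series(
                g_train, p_train, ranked_n, r_max, prior, naive=True
            )
            prof = genotypes.genotypes[np.ix_(test, series_n.snp_indices)]
            post_n = posterior_curves(series_n, prof)
            for m in methods:
                if not m.startswith("naive"):
                    continue
                _, variant = split_method(m)
                curves = curves_from_posteriors(post_n, "naive", variant)
                stats[m][test[:, None], np.arange(curves.shape[1])[None, :]] = curves
    return CVResult(stats=stats, labels=phenotypes.da.copy(), r_max=r_max)


def select_r(cv: CVResult, method: str) -> int:
    """Smallest r attaining the maximal pooled out-of-fold AUC (1-based)."""
    auc = cv.auc_curve(method)
    if np.all(np.isnan(auc)):
        raise ValueError("AUC undefined at every r (single-class labels?)")
    best = np.nanmax(auc)
    return int(np.flatnonzero(auc == best)[0]) + 1


def select_threshold_youden(statistics: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between consecutive distinct sorted values,
    plus one below the minimum and one above the maximum; the smallest
    maximizing threshold wins ties.  The decision rule is class 2 iff the
    statistic strictly exceeds the threshold.
    """
    statistics = np.asarray(statistics, dtype=np.float64)
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 2).any()):
        raise ValueError("both classes must be present")
    vals = np.unique(statistics)
    below = vals[0] / 2.0 if vals[0] > 0 else vals[0] - 1.0
    candidates = np.concatenate([[below], (vals[:-1] + vals[1:]) / 2.0, [vals[-1] + 1.0]])
    case = labels == 2
    n_case, n_ctrl = case.sum(), (~case).sum()
    best_j, best_t = -np.inf, None
    for t in candidates:
        pred2 = statistics > t
        j = (pred2 & case).sum() / n_case + (~pred2 & ~case).sum() / n_ctrl - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t
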