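"""Pareto-optimised gene-panel selection over cohort-swap AUC objectives.

Rather than merging cohorts with a batch-effect correction, panel selection
treats the two training cohorts as two objectives: the AUC obtained by
fitting the linear risk score on cohort 1 and validating on cohort 2, and
the AUC with the roles swapped. A panel dominates another when it is at
least as good on both objectives and strictly better on one; the
nondominated panels form the Pareto frontier, which is then validated on an
independent testing cohort to pick the final panel.

Small panel sizes are enumerated exhaustively; larger cardinality ranges
use a discrete NSGA-II-style genetic algorithm over bitstring genomes with
repair to the cardinality range. An L1-penalised logistic regression
baseline (the standard single-cohort feature selector, with per-cohort
mean-centering as the batch-correction surrogate) is provided for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV

from npcrisk.risk import LinearRiskScore, auc

__all__ = [
    "ParetoCandidate",
    "FrontierSet",
    "dominates",
    "nondominated_mask",
    "hypervolume",
    "evaluate_subset",
    "exhaustive_frontier",
    "genetic_frontier",
    "validate_frontier",
    "l1_baseline",
]


def dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff objective pair ``a`` Pareto-dominates ``b`` (maximising)."""
    if not all(np.isfinite(v) for v in (*a, *b)):
        raise ValueError("objective pairs must be finite")
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


def nondominated_mask(objectives: np.ndarray) -> np.ndarray:
    """Boolean mask of nondominated rows of an (n, 2) objective array.

    Exactly-tied objective pairs are all retained: nothing discriminates
    them until test-cohort validation.
    """
    obj = np.asarray(objectives, float)
    n = obj.shape[0]
    order = np.lexsort((-obj[:, 1], -obj[:, 0]))
    mask = np.ones(n, bool)
    best_a2_strict = -np.inf  # max obj2 among points with strictly larger obj1
    i = 0
    while i < n:
        j = i
        while j < n and obj[order[j], 0] == obj[order[i], 0]:
            j += 1
        group = order[i:j]
        group_max_a2 = obj[group, 1].max()
        for g in group:
            a2 = obj[g, 1]
            if best_a2_strict >= a2 or group_max_a2 > a2:
                mask[g] = False
        best_a2_strict = max(best_a2_strict, group_max_a2)
        i = j
    return mask


def hypervolume(objectives, ref: tuple[float, float] = (0.0, 0.0)) -> float:
    """Dominated hypervolume (area) of a 2-D maximisation frontier."""
    pts = np.asarray(objectives, float)
    pts = pts[nondominated_mask(pts)]
    pts = pts[np.argsort(-pts[:, 0])]
    hv, prev_a2 = 0.0, ref[1]
    for a1, a2 in pts:
        if a2 > prev_a2:
            hv += (a1 - ref[0]) * (a2 - prev_a2)
            prev_a2 = a2
    return hv


@dataclass(frozen=True)
class ParetoCandidate:
    """A gene subset with its two cohort-swap AUC objectives."""

    genes: tuple[str, ...]
    auc_1to2: float
    auc_2to1: float
    dominated: bool = False

    @property
    def objectives(self) -> tuple[float, float]:
        return (self.auc_1to2, self.auc_2to1)


@dataclass
class FrontierSet:
    """A Pareto frontier plus the full evaluation log that produced it."""

    candidates: list[ParetoCandidate]
    gene_count_constraint: tuple[int, int]
    n_evaluated: int
    evaluation_log: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        k_min, k_max = self.gene_count_constraint
        for c in self.candidates:
            if not k_min <= len(c.genes) <= k_max:
                raise ValueError("frontier member violates cardinality constraint")

    def __len__(self) -> int:
        return len(self.candidates)

    def to_json(self) -> list[dict]:
        return [
            {"genes": list(c.genes), "auc_1to2": c.auc_1to2, "auc_2to1": c.auc_2to1}
            for c in self.candidates
        ]


class _SubsetEvaluator:
    """Vectorised cohort-swap objective evaluation over a fixed pool.

    Pre-extracts the pool expression of both cohorts once; per subset,
    fits the OLS score directly with lstsq and computes the rank-based
    (Mann-Whitney) AUC. The group-mean calibration is a positive affine
    map of the raw OLS score, so it is skipped: AUC is unchanged.
    """

    def __init__(self, pool, cohort1, cohort2):
        self.pool = list(pool)
        self.X1 = cohort1.expression(self.pool).T.to_numpy(float)
        self.y1 = np.asarray(cohort1.labels, float)
        self.X2 = cohort2.expression(self.pool).T.to_numpy(float)
        self.y2 = np.asarray(cohort2.labels, float)

    @staticmethod
    def _auc(scores, y):
        if np.ptp(scores) == 0:
            return 0.5
        from scipy.stats import rankdata

        r = rankdata(scores)
        n1 = int(y.sum())
        n0 = len(y) - n1
        return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    def _one_way(self, idx, Xtr, ytr, Xte, yte):
        A = np.column_stack([Xtr[:, idx], np.ones(len(ytr))])
        beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
        scores = Xte[:, idx] @ beta[:-1] + beta[-1]
        return self._auc(scores, yte)

    def __call__(self, idx) -> tuple[float, float]:
        idx = list(idx)
        return (
            float(self._one_way(idx, self.X1, self.y1, self.X2, self.y2)),
            float(self._one_way(idx, self.X2, self.y2, self.X1, self.y1)),
        )


def evaluate_subset(subset, cohort1, cohort2) -> tuple[float, float]:
    """Cohort-swap objectives for one gene subset.

    Fit the linear risk score on cohort 1 restricted to the subset and
    compute its AUC on cohort 2 (``auc_1to2``); then swap the cohorts.
    A degenerate fit (constant expression) scores AUC 0.5 with a warning
    raised by the fitting routine.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")

    def _one_way(train, test):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = LinearRiskScore.from_cohort(train, subset).fit().model
        scores = model.evaluate(test.expression(subset).T)
        return auc(scores, test.labels)

    return (_one_way(cohort1, cohort2), _one_way(cohort2, cohort1))


def _frontier_from_log(log: pd.DataFrame, constraint) -> FrontierSet:
    obj = log[["auc_1to2", "auc_2to1"]].to_numpy()
    mask = nondominated_mask(obj)
    cands = [
        ParetoCandidate(tuple(row.genes), row.auc_1to2, row.auc_2to1)
        for row in log[mask].itertuples()
    ]
    return FrontierSet(cands, constraint, len(log), log)


def exhaustive_frontier(
    pool,
    k: int,
    cohort1,
    cohort2,
    budget: int = 500_000,
) -> FrontierSet:
    """Enumerate all C(|pool|, k) subsets and return the nondominated set.

    Enumeration is plain lexicographic over k-combinations. ``budget``
    guards against infeasible enumerations; exceeding it raises with a
    pointer to :func:`genetic_frontier`.
    """
    pool = list(pool)
    n_total = comb(len(pool), k)
    if n_total > budget:
        raise ValueError(
            f"C({len(pool)},{k}) = {n_total} exceeds the enumeration budget "
            f"({budget}); use genetic_frontier for this cardinality"
        )
    evaluator = _SubsetEvaluator(pool, cohort1, cohort2)
    rows = []
    for idx in combinations(range(len(pool)), k):
        a12, a21 = evaluator(idx)
        rows.append((tuple(pool[i] for i in idx), a12, a21))
    log = pd.DataFrame(rows, columns=["genes", "auc_1to2", "auc_2to1"])
    return _frontier_from_log(log, (k, k))


# ----------------------------------------------------------------- NSGA-II


def _fast_nondominated_sort(obj: np.ndarray) -> list[np.ndarray]:
    """Rank objective rows into nondomination fronts (maximising)."""
    n = obj.shape[0]
    ge = (obj[:, None, 0] >= obj[None, :, 0]) & (obj[:, None, 1] >= obj[None, :, 1])
    gt = (obj[:, None, 0] > obj[None, :, 0]) | (obj[:, None, 1] > obj[None, :, 1])
    dom = ge & gt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.arange(n)
    counts = n_dominators.copy()
    while remaining.size:
        in_front = remaining[counts[remaining] == 0]
        if in_front.size == 0:  # numerical safety; cannot happen for finite obj
            in_front = remaining
        fronts.append(in_front)
        remaining = np.setdiff1d(remaining, in_front, assume_unique=True)
        for i in in_front:
            counts[dom[i]] -= 1
    return fronts


def _crowding_distance(obj: np.ndarray) -> np.ndarray:
    n = obj.shape[0]
    dist = np.zeros(n)
    for m in range(obj.shape[1]):
        order = np.argsort(obj[:, m])
        span = obj[order[-1], m] - obj[order[0], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (obj[order[2:], m] - obj[order[:-2], m]) / span
    return dist


def _repair(genome: np.ndarray, k_min: int, k_max: int, rng) -> np.ndarray:
    k = int(genome.sum())
    if k < k_min:
        off = np.flatnonzero(~genome)
        genome[rng.choice(off, k_min - k, replace=False)] = True
    elif k > k_max:
        on = np.flatnonzero(genome)
        genome[rng.choice(on, k - k_max, replace=False)] = False
    return genome


def genetic_frontier(
    pool,
    k_range: tuple[int, int],
    cohort1,
    cohort2,
    population: int = 200,
    generations: int = 100,
    crossover_rate: float = 0.9,
    mutation_rate: float | None = None,
    seed: int | None = None,
) -> FrontierSet:
    """Discrete GA search of the frontier over a cardinality range.

    NSGA-II-style: bitstring genomes over the candidate pool,
    fast-nondominated-sort + crowding-distance selection, uniform
    crossover, per-bit mutation (default rate 1/|pool|), and repair of
    offspring to the [k_min, k_max] cardinality range by random bit
    add/drop. All distinct subsets ever evaluated form the archive; the
    returned frontier is the nondominated subset of that archive.
    """
    pool = list(pool)
    k_min, k_max = k_range
    if not 1 <= k_min <= k_max <= len(pool):
        raise ValueError("need 1 <= k_min <= k_max <= |pool|")
    rng = np.random.default_rng(seed)
    p_mut = mutation_rate if mutation_rate is not None else 1.0 / len(pool)
    evaluator = _SubsetEvaluator(pool, cohort1, cohort2)
    cache: dict[frozenset, tuple[float, float]] = {}

    def evaluate(genome: np.ndarray) -> tuple[float, float]:
        key = frozenset(np.flatnonzero(genome).tolist())
        if key not in cache:
            cache[key] = evaluator(sorted(key))
        return cache[key]

    pop = []
    for _ in range(population):
        g = np.zeros(len(pool), bool)
        k = rng.integers(k_min, k_max + 1)
        g[rng.choice(len(pool), k, replace=False)] = True
        pop.append(g)
    obj = np.array([evaluate(g) for g in pop])

    for _ in range(generations):
        fronts = _fast_nondominated_sort(obj)
        rank = np.empty(len(pop), int)
        crowd = np.empty(len(pop))
        for fi, front in enumerate(fronts):
            rank[front] = fi
            crowd[front] = _crowding_distance(obj[front])

        def better(i, j):
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            return i if crowd[i] >= crowd[j] else j

        children = []
        while len(children) < population:
            pa = better(*rng.integers(len(pop), size=2))
            pb = better(*rng.integers(len(pop), size=2))
            c1, c2 = pop[pa].copy(), pop[pb].copy()
            if rng.random() < crossover_rate:
                swap = rng.random(len(pool)) < 0.5
                c1[swap], c2[swap] = pop[pb][swap], pop[pa][swap]
            for c in (c1, c2):
                flip = rng.random(len(pool)) < p_mut
                c[flip] = ~c[flip]
                children.append(_repair(c, k_min, k_max, rng))
        children = children[:population]
        child_obj = np.array([evaluate(g) for g in children])

        merged = pop + children
        merged_obj = np.vstack([obj, child_obj])
        fronts = _fast_nondominated_sort(merged_obj)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= population:
                keep.extend(front.tolist())
            else:
                cd = _crowding_distance(merged_obj[front])
                order = front[np.argsort(-cd)]
                keep.extend(order[: population - len(keep)].tolist())
                break
        pop = [merged[i] for i in keep]
        obj = merged_obj[keep]

    rows = [
        (tuple(pool[i] for i in sorted(key)), a12, a21)
        for key, (a12, a21) in cache.items()
    ]
    log = pd.DataFrame(rows, columns=["genes", "auc_1to2", "auc_2to1"])
    return _frontier_from_log(log, (k_min, k_max))


def validate_frontier(frontier: FrontierSet, train_cohort, test_cohort) -> pd.DataFrame:
    """Score every frontier member on the held-out testing cohort.

    Each member is refitted on the primary training cohort and its AUC on
    the testing cohort reported; the arg-max row is flagged ``best``.
    """
    rows = []
    for cand in frontier.candidates:
        subset = list(cand.genes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = LinearRiskScore.from_cohort(train_cohort, subset).fit().model
        scores = model.evaluate(test_cohort.expression(subset).T)
        rows.append((cand.genes, cand.auc_1to2, cand.auc_2to1, auc(scores, test_cohort.labels)))
    table = pd.DataFrame(rows, columns=["genes", "auc_1to2", "auc_2to1", "test_auc"])
    table["best"] = False
    if len(table):
        table.loc[table["test_auc"].idxmax(), "best"] = True
    return table


def l1_baseline(
    train_cohorts,
    test_cohort,
    pool,
    merge_strategy: str = "pooled-with-location-shift",
    seed: int | None = None,
) -> tuple[list[str], float]:
    """LASSO-style baseline: L1 logistic regression over the marker pool.

    ``merge_strategy`` is either ``"pooled-with-location-shift"`` (each
    gene mean-centred within each cohort before pooling — the
    batch-correction surrogate) or ``"cohort1-only"``. The penalty is
    chosen by cross-validated AUC. Returns the selected genes and the AUC
    on the testing cohort (0.5 when nothing is selected).
    """
    pool = list(pool)

    def _features(cohort, center):
        x = cohort.expression(pool).T.to_numpy(float)
        return x - x.mean(axis=0) if center else x

    if merge_strategy == "pooled-with-location-shift":
        X = np.vstack([_features(c, True) for c in train_cohorts])
        y = np.concatenate([np.asarray(c.labels) for c in train_cohorts])
        X_test = _features(test_cohort, True)
    elif merge_strategy == "cohort1-only":
        X = _features(train_cohorts[0], False)
        y = np.asarray(train_cohorts[0].labels)
        X_test = _features(test_cohort, False)
    else:
        raise ValueError(f"unknown merge_strategy {merge_strategy!r}")

    lr = LogisticRegressionCV(
        penalty="l1",
        solver="liblinear",
        Cs=np.logspace(-2, 2, 12),
        cv=5,
        scoring="roc_auc",
        random_state=seed,
        max_iter=2000,
    )
    lr.fit(X, y)
    coef = lr.coef_.ravel()
    selected = [g for g, c in zip(pool, coef) if c != 0.0]
    if not selected:
        return [], 0.5
    scores = X_test @ coef + lr.intercept_[0]
    return selected, auc(scores, test_cohort.labels)
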