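"""Pareto panel selection: dominance, enumeration, GA, validation."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcrisk.pareto import (
    _SubsetEvaluator,
    dominates,
    evaluate_subset,
    exhaustive_frontier,
    genetic_frontier,
    hypervolume,
    l1_baseline,
    nondominated_mask,
    validate_frontier,
)
from npcrisk.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="module")
def two_cohorts():
    """Two n=80 cohorts over a 12-gene pool with mixed signal strength."""
    cfg = SimulationConfig(
        seed=31,
        n_genes=60,
        cohort_sizes=[(40, 40), (40, 40)],
        n_de_genes_up=3,
        n_de_genes_down=3,
        de_log2fc=0.6,
        cohort_effect_sd=0.3,
    )
    cohorts, truth = simulate_cohorts(cfg)
    planted = sorted(truth.de_gene_signs)
    noise = [g for g in cohorts[0].counts.index if g not in truth.de_gene_signs]
    pool = planted + noise[:6]
    return cohorts[0], cohorts[1], pool, truth


# ------------------------------------------------------------ dominance


def test_dominates_examples():
    assert dominates((0.8, 0.6), (0.7, 0.5))
    assert not dominates((0.8, 0.5), (0.7, 0.6))  # incomparable
    assert not dominates((0.7, 0.6), (0.8, 0.5))
    assert not dominates((0.8, 0.6), (0.8, 0.6))  # equal pairs do not dominate


def test_dominates_rejects_nonfinite():
    with pytest.raises(ValueError):
        dominates((np.nan, 0.5), (0.5, 0.5))


def test_frontier_of_four_point_toy():
    pts = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9], [0.4, 0.4]])
    np.testing.assert_array_equal(
        nondominated_mask(pts), [True, True, True, False]
    )


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 2**31 - 1))
def test_nondominated_mask_matches_pairwise_bruteforce(seed):
    rng = np.random.default_rng(seed)
    pts = rng.choice(np.linspace(0, 1, 6), size=(rng.integers(2, 40), 2))
    mask = nondominated_mask(pts)
    brute = np.array(
        [
            not any(dominates(tuple(q), tuple(p)) for q in pts)
            for p in pts
        ]
    )
    np.testing.assert_array_equal(mask, brute)


def test_hypervolume_single_point_rectangle():
    assert hypervolume([[0.8, 0.5]]) == pytest.approx(0.4)
    assert hypervolume([[0.8, 0.2], [0.4, 0.6]]) == pytest.approx(
        0.8 * 0.2 + 0.4 * 0.4
    )


# ----------------------------------------------------------- evaluation


def test_evaluate_subset_is_symmetric_under_cohort_swap(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    a = evaluate_subset(pool[:3], c1, c2)
    b = evaluate_subset(pool[:3], c2, c1)
    assert a == (b[1], b[0])


def test_fast_evaluator_matches_reference_path(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    ev = _SubsetEvaluator(pool, c1, c2)
    rng = np.random.default_rng(0)
    for _ in range(5):
        idx = sorted(rng.choice(len(pool), size=3, replace=False).tolist())
        subset = [pool[i] for i in idx]
        np.testing.assert_allclose(
            ev(idx), evaluate_subset(subset, c1, c2), atol=1e-12
        )


def test_label_feature_scores_perfectly():
    # one "gene" whose expression is the label separates both cohorts
    rng = np.random.default_rng(1)
    from npcrisk.datasets import CohortDataset

    def mk(n):
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        counts = pd.DataFrame(
            np.vstack([1000 * y + 100, rng.integers(50, 150, (4, n))]),
            index=["sep", "a", "b", "c", "d"],
            columns=[f"s{i}" for i in range(n)],
        )
        return CohortDataset(counts, pd.Series(y, index=counts.columns))

    c1, c2 = mk(20), mk(20)
    assert evaluate_subset(["sep"], c1, c2) == (1.0, 1.0)


def test_noise_genes_score_near_half():
    cfg = SimulationConfig(
        seed=5, n_genes=40, cohort_sizes=[(150, 150), (150, 150)],
        n_de_genes_up=0, n_de_genes_down=0, cohort_effect_sd=0.0,
    )
    (c1, c2), _ = simulate_cohorts(cfg)
    a12, a21 = evaluate_subset(list(c1.counts.index[:3]), c1, c2)
    assert abs(a12 - 0.5) < 0.12 and abs(a21 - 0.5) < 0.12


# ----------------------------------------------------------- exhaustive


def test_exhaustive_counts_all_subsets(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    f = exhaustive_frontier(pool[:5], 1, c1, c2)
    assert f.n_evaluated == 5
    f3 = exhaustive_frontier(pool[:6], 3, c1, c2)
    assert f3.n_evaluated == comb(6, 3)


def test_exhaustive_budget_guard(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    with pytest.raises(ValueError, match="genetic_frontier"):
        exhaustive_frontier(pool, 6, c1, c2, budget=100)


def test_frontier_members_not_dominated_by_any_evaluated(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    f = exhaustive_frontier(pool, 3, c1, c2)
    log_obj = f.evaluation_log[["auc_1to2", "auc_2to1"]].to_numpy()
    for cand in f.candidates:
        assert not any(
            dominates((a, b), cand.objectives) for a, b in log_obj
        )


# -------------------------------------------------------------- genetic


def test_ga_deterministic_under_seed(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    kw = dict(population=30, generations=8, seed=42)
    f1 = genetic_frontier(pool, (1, 4), c1, c2, **kw)
    f2 = genetic_frontier(pool, (1, 4), c1, c2, **kw)
    assert f1.to_json() == f2.to_json()


def test_ga_respects_cardinality_range(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    f = genetic_frontier(pool, (2, 4), c1, c2, population=30, generations=8, seed=3)
    sizes = {len(c.genes) for c in f.candidates}
    assert sizes <= {2, 3, 4}


def test_ga_attains_exhaustive_frontier_hypervolume(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    logs = [
        exhaustive_frontier(pool, k, c1, c2).evaluation_log for k in (1, 2, 3)
    ]
    all_obj = pd.concat(logs)[["auc_1to2", "auc_2to1"]].to_numpy()
    hv_ex = hypervolume(all_obj)
    ga = genetic_frontier(pool, (1, 3), c1, c2, population=80, generations=30, seed=7)
    hv_ga = hypervolume(
        np.array([[c.auc_1to2, c.auc_2to1] for c in ga.candidates])
    )
    assert hv_ga >= 0.99 * hv_ex


def test_ga_invalid_range(two_cohorts):
    c1, c2, pool, _ = two_cohorts
    with pytest.raises(ValueError):
        genetic_frontier(pool, (0, 3), c1, c2)


# ----------------------------------------------------------- validation


def test_validate_single_candidate_one_row(two_cohorts, study):
    c1, c2, pool, _ = two_cohorts
    f = exhaustive_frontier(pool[:3], 1, c1, c2)
    one = f
    one.candidates = one.candidates[:1]
    table = validate_frontier(one, c1, c2)
    assert len(table) == 1 and table["best"].iloc[0]


def test_planted_panels_beat_noise_panels(study):
    cohorts, truth = study
    c1, c2, test = cohorts
    planted = sorted(truth.de_gene_signs)[:5]
    noise = [g for g in c1.counts.index if g not in truth.de_gene_signs][:5]
    a_planted = validate_frontier(
        exhaustive_frontier(planted, 5, c1, c2), c1, test
    )["test_auc"].iloc[0]
    a_noise = validate_frontier(
        exhaustive_frontier(noise, 5, c1, c2), c1, test
    )["test_auc"].iloc[0]
    assert a_planted > a_noise + 0.2


# ------------------------------------------------------------- baseline


def test_l1_selects_perfectly_predictive_gene():
    from npcrisk.datasets import CohortDataset

    rng = np.random.default_rng(10)

    def mk(n, seed):
        r = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        counts = pd.DataFrame(
            np.vstack([2000 * y + 50, r.integers(50, 150, (5, n))]),
            index=["sep", "a", "b", "c", "d", "e"],
            columns=[f"s{i}" for i in range(n)],
        )
        return CohortDataset(counts, pd.Series(y, index=counts.columns))

    c1, c2, test = mk(40, 1), mk(40, 2), mk(40, 3)
    selected, test_auc = l1_baseline(
        [c1, c2], test, ["sep", "a", "b", "c", "d", "e"], seed=0
    )
    assert "sep" in selected
    assert test_auc > 0.95


def test_l1_zero_signal_auc_near_half():
    cfg = SimulationConfig(
        seed=17, n_genes=30, cohort_sizes=[(60, 60), (60, 60), (60, 60)],
        n_de_genes_up=0, n_de_genes_down=0,
    )
    cohorts, _ = simulate_cohorts(cfg)
    pool = list(cohorts[0].counts.index[:10])
    _, test_auc = l1_baseline(cohorts[:2], cohorts[2], pool, seed=0)
    assert abs(test_auc - 0.5) < 0.15


def test_pareto_winner_matches_or_beats_l1_with_cohort_effects(study):
    cohorts, truth = study
    c1, c2, test = cohorts
    pool = sorted(truth.de_gene_signs)
    frontier = genetic_frontier(
        pool, (1, 5), c1, c2, population=60, generations=15, seed=2
    )
    best_auc = validate_frontier(frontier, c1, test)["test_auc"].max()
    _, l1_auc = l1_baseline([c1, c2], test, pool, seed=0)
    assert best_auc >= l1_auc - 0.05
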