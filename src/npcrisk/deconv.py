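"""Variance-weighted deconvolution of bulk RNA-seq into cell-type proportions.

The reference carries, for each cell type, both the mean and the variance
of every gene's expression across single cells of that type. The estimator
minimises, over the probability simplex,

    sum_i (bulk_i * s - sum_j P_j * mu_ij)^2 / max(sum_j P_j * var_ij, eps)

so genes whose expression is intrinsically variable within the mixture are
penalised less for residual misfit. ``s`` is a per-sample scaling factor
matching the bulk total to the equal-proportion reference total. The
search is a particle swarm over a softmax reparameterisation of the
simplex, polished with a projected local solver.

Expression enters on the normalised linear scale (not log): the mixture
model is linear in expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DeconvReference",
    "ProportionEstimate",
    "build_reference",
    "default_scaling_factor",
    "deconv_objective",
    "estimate_proportions",
    "compare_groups",
]


@dataclass
class DeconvReference:
    """Per-cell-type per-gene mean and variance expression profiles."""

    mean_expr: pd.DataFrame  # genes x types
    var_expr: pd.DataFrame  # genes x types

    def __post_init__(self) -> None:
        if self.mean_expr.shape != self.var_expr.shape:
            raise ValueError("mean and variance matrices must have equal shape")
        if (self.mean_expr.to_numpy() < 0).any() or (self.var_expr.to_numpy() < 0).any():
            raise ValueError("reference means and variances must be nonnegative")
        zero_rows = (self.mean_expr.to_numpy() == 0).all(axis=1)
        if zero_rows.any():
            raise ValueError("reference contains all-zero gene rows")

    @property
    def cell_types(self) -> list[str]:
        return list(self.mean_expr.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.mean_expr.index)

    @property
    def n_types(self) -> int:
        return self.mean_expr.shape[1]

    @property
    def G(self) -> int:
        return self.mean_expr.shape[0]

    def to_dir(self, path) -> None:
        from pathlib import Path

        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.mean_expr.to_csv(p / "means.tsv", sep="\t")
        self.var_expr.to_csv(p / "variances.tsv", sep="\t")

    @classmethod
    def from_dir(cls, path) -> "DeconvReference":
        from pathlib import Path

        p = Path(path)
        return cls(
            pd.read_csv(p / "means.tsv", sep="\t", index_col=0),
            pd.read_csv(p / "variances.tsv", sep="\t", index_col=0),
        )


def build_reference(
    expression: pd.DataFrame,
    cell_types,
    candidate_G_grid=None,
) -> DeconvReference:
    """Build a reference from labelled single-cell expression profiles.

    Parameters
    ----------
    expression : DataFrame, genes x cells
        Normalised linear expression per cell.
    cell_types : sequence
        Cell-type label per cell (column).
    candidate_G_grid : sequence of int, optional
        Candidate per-type marker counts. For each type, genes are ranked
        by the p-value of a two-sided t-test of in-type vs all-other-type
        expression; the union of each type's top-G genes forms the
        candidate reference. The G minimising the condition number of the
        resulting mean matrix is selected, smallest G on ties. Defaults to
        a sweep from 5 markers per type up to the full ranked list.
    """
    types = pd.Series(list(cell_types))
    names = sorted(types.unique())
    if any((types == t).sum() < 2 for t in names):
        raise ValueError("need at least 2 cells per type")
    X = expression.to_numpy(float)

    ranks = {}
    for t in names:
        inside = X[:, (types == t).to_numpy()]
        outside = X[:, (types != t).to_numpy()]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(inside, outside, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, float)
        p[~np.isfinite(p)] = np.inf  # degenerate (zero-variance) genes rank last
        ranks[t] = np.argsort(p, kind="stable")

    n_genes = X.shape[0]
    if candidate_G_grid is None:
        candidate_G_grid = range(5, n_genes + 1, max(1, n_genes // 50))
    grid = sorted(int(g) for g in candidate_G_grid)

    means = pd.DataFrame(
        {t: X[:, (types == t).to_numpy()].mean(axis=1) for t in names},
        index=expression.index,
    )
    best = None
    for G in grid:
        union = sorted(set(np.concatenate([ranks[t][:G] for t in names]).tolist()))
        sub = means.to_numpy()[union]
        keep = ~(sub == 0).all(axis=1)
        if keep.sum() < len(names):
            continue
        kappa = np.linalg.cond(sub[keep])
        if best is None or kappa < best[0]:  # strict: smallest G wins ties
            best = (kappa, G, [u for u, k in zip(union, keep) if k])
    if best is None:
        raise ValueError("no candidate G yields a usable reference matrix")
    _, _, rows = best

    variances = pd.DataFrame(
        {t: X[:, (types == t).to_numpy()].var(axis=1, ddof=1) for t in names},
        index=expression.index,
    )
    idx = expression.index[rows]
    return DeconvReference(means.loc[idx], variances.loc[idx])


def default_scaling_factor(bulk, reference: DeconvReference) -> float:
    """Match the bulk total to the equal-proportion reference total."""
    bulk_total = float(np.asarray(bulk, float).sum())
    if bulk_total <= 0:
        raise ValueError("bulk profile must have positive total expression")
    ref_total = float(reference.mean_expr.to_numpy().mean(axis=1).sum())
    return ref_total / bulk_total


def deconv_objective(
    P,
    bulk,
    reference: DeconvReference,
    scaling_factor: float | None = None,
) -> float:
    """Variance-weighted residual sum of squares at proportion vector P."""
    P = np.asarray(P, float)
    b = np.asarray(bulk, float)
    mu = reference.mean_expr.to_numpy(float)
    var = reference.var_expr.to_numpy(float)
    if P.shape[0] != reference.n_types or b.shape[0] != reference.G:
        raise ValueError("dimension mismatch with reference")
    if (P < -1e-9).any() or abs(P.sum() - 1.0) > 1e-6:
        raise ValueError("P must lie on the probability simplex")
    s = default_scaling_factor(b, reference) if scaling_factor is None else scaling_factor
    eps = 1e-6 * max(var.max(), 1e-300)
    resid = b * s - mu @ P
    denom = np.maximum(var @ P, eps)
    return float(np.sum(resid**2 / denom))


@dataclass
class ProportionEstimate:
    """A solved proportion vector with solver diagnostics."""

    P: pd.Series
    objective_value: float
    scaling_factor: float
    iterations: int
    converged: bool


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def estimate_proportions(
    bulk,
    reference: DeconvReference,
    swarm_size: int = 40,
    iterations: int = 200,
    tol: float = 1e-10,
    seed: int | None = None,
    scaling_factor: float | None = None,
    optimise_scale: bool = True,
) -> ProportionEstimate:
    """Global-then-local minimisation of the variance-weighted objective.

    A particle swarm explores softmax-reparameterised proportion vectors
    (one particle starts at the uniform mixture, one at each pure type);
    the swarm optimum is then polished by iteratively reweighted
    constrained least squares: with the variance weights frozen at the
    current P the problem is a simplex-constrained linear least squares,
    solved exactly via NNLS on an augmented system, and the weights are
    re-estimated until the fixed point.

    By default the scaling factor is also refined (closed-form weighted
    least-squares step) rather than frozen at the totals-matching value:
    an exact mixture has a scale mismatch of a few permille against the
    equal-proportion reference total, and freezing the scale would bias
    the recovered proportions by the same order. ``optimise_scale=False``
    keeps the scale fixed at ``scaling_factor`` (or the totals-matching
    default). The returned estimate is never worse than the uniform start.
    """
    b = np.asarray(bulk, float)
    n = reference.n_types
    mu = reference.mean_expr.to_numpy(float)
    var = reference.var_expr.to_numpy(float)
    eps = 1e-6 * max(var.max(), 1e-300)
    s = default_scaling_factor(b, reference) if scaling_factor is None else scaling_factor
    rng = np.random.default_rng(seed)

    def f(P, s_val):
        resid = b * s_val - mu @ np.maximum(P, 0.0)
        return float(np.sum(resid**2 / np.maximum(var @ np.maximum(P, 0.0), eps)))

    # --- particle swarm over z in R^n, P = softmax(z), scale frozen
    z = rng.normal(0.0, 1.5, size=(swarm_size, n))
    z[0] = 0.0  # uniform mixture
    for j in range(min(n, swarm_size - 1)):
        z[j + 1] = -4.0
        z[j + 1, j] = 4.0  # near-pure type j
    vel = np.zeros_like(z)
    pbest = z.copy()
    pbest_val = np.array([f(_softmax(zz), s) for zz in z])
    gbest = pbest[pbest_val.argmin()].copy()
    gbest_val = pbest_val.min()

    stall, it = 0, 0
    for it in range(1, iterations + 1):
        r1, r2 = rng.random(z.shape), rng.random(z.shape)
        vel = 0.7 * vel + 1.5 * r1 * (pbest - z) + 1.5 * r2 * (gbest - z)
        z = z + vel
        vals = np.array([f(_softmax(zz), s) for zz in z])
        improved = vals < pbest_val
        pbest[improved] = z[improved]
        pbest_val[improved] = vals[improved]
        if pbest_val.min() < gbest_val - tol:
            gbest_val = pbest_val.min()
            gbest = pbest[pbest_val.argmin()].copy()
            stall = 0
        else:
            stall += 1
            if stall >= 25:
                break

    # --- IRLS polish with optional scale step
    def _irls(P0, s0, iters=80):
        P, s_cur = P0.copy(), s0
        lam = 10.0 * max(np.abs(mu).max(), 1.0)
        for _ in range(iters):
            w = 1.0 / np.sqrt(np.maximum(var @ P, eps))
            A = np.vstack([w[:, None] * mu, np.full((1, n), lam)])
            rhs = np.append(w * b * s_cur, lam)
            x, _ = optimize.nnls(A, rhs)
            total = x.sum()
            Pn = x / total if total > 0 else np.full(n, 1.0 / n)
            if optimise_scale:
                w2 = 1.0 / np.maximum(var @ Pn, eps)
                denom = np.sum(w2 * b * b)
                if denom > 0:
                    s_cur = float(np.sum(w2 * b * (mu @ Pn)) / denom)
            if np.abs(Pn - P).max() < 1e-15:
                P = Pn
                break
            P = Pn
        return P, s_cur

    best_P, best_s = _softmax(gbest), s
    best_val = gbest_val
    starts = [(_softmax(gbest), s), (np.full(n, 1.0 / n), s)]
    for j in range(n):
        pure = np.full(n, 1e-6)
        pure[j] = 1.0
        starts.append((pure / pure.sum(), s))
    for P0, s0 in starts:
        cand_P, cand_s = _irls(P0, s0)
        cand_val = f(cand_P, cand_s)
        if cand_val < best_val:
            best_P, best_s, best_val = cand_P, cand_s, cand_val

    # --- full-gradient projected-gradient refinement at the final scale:
    # IRLS freezes the variance weights each step, so its fixed point ignores
    # the denominator's dependence on P; a few projected-gradient steps with
    # the exact gradient close that gap
    def _pg(P0, s_val, max_iter=2000):
        target_s = b * s_val

        def fg(P):
            v = np.maximum(var @ P, eps)
            r = target_s - mu @ P
            val = float(np.sum(r**2 / v))
            g = -2.0 * mu.T @ (r / v) - var.T @ np.where(v > eps, r**2 / v**2, 0.0)
            return val, g

        P = P0.copy()
        fP, gP = fg(P)
        step = 1.0 / (np.linalg.norm(mu) ** 2 + 1.0)
        for _ in range(max_iter):
            Pn = project_simplex(P - step * gP)
            fn, gn = fg(Pn)
            if fn <= fP:
                done = fP - fn < 1e-15 * max(fP, 1.0)
                P, fP, gP = Pn, fn, gn
                if done:
                    break
                step *= 1.2
            else:
                step *= 0.5
                if step < 1e-18:
                    break
        return P, fP

    cand_P, cand_val = _pg(best_P, best_s)
    if cand_val < best_val:
        best_P, best_val = cand_P, cand_val

    uniform = np.full(n, 1.0 / n)
    if f(uniform, best_s) < best_val:  # never worse than the trivial start
        best_P, best_val = uniform, f(uniform, best_s)

    best_P = project_simplex(best_P)
    return ProportionEstimate(
        P=pd.Series(best_P, index=reference.cell_types),
        objective_value=best_val,
        scaling_factor=best_s,
        iterations=it,
        converged=stall < iterations,
    )


def compare_groups(proportions: pd.DataFrame, labels) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per cell type.

    ``proportions`` is samples x cell types; ``labels`` the binary group
    per sample (e.g. MET vs non-MET).
    """
    y = np.asarray(labels)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per group")
    out = {}
    for col in proportions.columns:
        x1 = proportions[col].to_numpy(float)[y == 1]
        x0 = proportions[col].to_numpy(float)[y == 0]
        out[col] = stats.mannwhitneyu(x1, x0, alternative="two-sided").pvalue
    return pd.Series(out, name="p")
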