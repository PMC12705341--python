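"""Cross-cohort differential-marker screening and power analysis.

The screen mirrors a standard bulk RNA-seq differential-expression workflow:
median-of-ratios library normalisation, a per-gene linear model on
``log10(normalised count + 1)`` with optional covariate adjustment, and
Benjamini-Hochberg control of the false-discovery rate. Markers are retained
when they pass per-cohort fold-change and significance thresholds in two
independent training cohorts with the same direction of change.

Significance thresholds are chosen from a two-sample t-test power analysis
(:func:`power_two_sample_t`): the screen is calibrated so each cohort has
adequate power (at Cohen's d = 0.8) at its own alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalise",
    "size_factors",
    "de_screen",
    "intersect_markers",
    "power_two_sample_t",
    "MarkerResult",
]


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample).

    The reference profile is the per-gene geometric mean over samples,
    computed over genes with all-positive counts; each sample's factor is
    the median ratio of its counts to the reference over those genes.
    A single-sample matrix gets factor 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("counts must be a nonempty 2-D matrix")
    if not np.any(x > 0):
        raise ValueError("all-zero count matrix cannot be normalised")
    if x.shape[1] == 1:
        return np.ones(1)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts; cannot form reference")
    logx = np.log(x[positive])
    ref = logx.mean(axis=1, keepdims=True)  # log geometric mean
    return np.exp(np.median(logx - ref, axis=0))


def normalise(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-normalise counts and return ``log10(normalised + 1)``."""
    sf = size_factors(counts)
    norm = np.asarray(counts, dtype=float) / sf
    out = np.log10(norm + 1.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return pd.DataFrame(out)


@dataclass
class MarkerResult:
    """Per-gene screen result table plus the thresholds that produced it.

    ``table`` columns: ``log2fc``, ``p``, ``adj_p``, ``direction`` (+1/-1),
    ``passed`` (bool).
    """

    table: pd.DataFrame
    lfc_min: float
    p_max: float
    adj_p_max: float | None

    @property
    def passed(self) -> pd.Index:
        return self.table.index[self.table["passed"]]

    def __len__(self) -> int:
        return len(self.table)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def de_screen(
    cohort,
    lfc_min: float = 0.5,
    p_max: float = 0.025,
    adj_p_max: float | None = 0.2,
    adjust_covariates: list[str] | None = None,
) -> MarkerResult:
    """Differential screen of MET vs non-MET expression in one cohort.

    Per gene, the normalised-log expression is regressed on the group
    indicator plus any listed clinical covariates; the two-sided t-test on
    the group coefficient gives the p-value, adjusted across genes by
    Benjamini-Hochberg. log2 fold-change is computed on normalised counts
    with a pseudo-count of 1. A gene passes when ``|log2fc| > lfc_min``,
    ``p < p_max`` and, if ``adj_p_max`` is given, ``adj_p < adj_p_max``.

    Covariates perfectly confounded with the group indicator make the
    design singular; the offending fit falls back to the pseudoinverse and
    the gene is flagged non-significant (p = 1).
    """
    y = np.asarray(cohort.labels, float)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per group")

    expr = np.asarray(cohort.normalised_log, float)  # genes x samples
    n_genes, n = expr.shape

    cols = [np.ones(n), y]
    for cov in adjust_covariates or []:
        if cohort.clinical is None or cov not in cohort.clinical.columns:
            raise KeyError(f"covariate {cov!r} not in cohort clinical table")
        cols.append(np.asarray(cohort.clinical[cov], float))
    X = np.column_stack(cols)
    k = X.shape[1]
    df = n - k

    # one shared design across genes: solve via pinv, vectorised over genes
    XtX = X.T @ X
    singular = np.linalg.matrix_rank(XtX) < k
    XtX_inv = np.linalg.pinv(XtX)
    beta = expr @ X @ XtX_inv.T  # genes x k
    resid = expr - beta @ X.T
    sigma2 = (resid**2).sum(axis=1) / max(df, 1)
    # genes fitted exactly (zero residual up to round-off) carry no evidence
    degenerate = sigma2 <= 1e-20 * ((expr**2).mean(axis=1) + 1.0)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where((se > 0) & ~degenerate, beta[:, 1] / se, 0.0)
    p = 2 * stats.t.sf(np.abs(tstat), max(df, 1))
    if singular:
        p = np.ones_like(p)

    # fold-change on the normalised (linear) scale with pseudo-count 1
    norm_linear = 10.0 ** expr - 1.0
    mean_met = norm_linear[:, y == 1].mean(axis=1)
    mean_non = norm_linear[:, y == 0].mean(axis=1)
    log2fc = np.log2(mean_met + 1.0) - np.log2(mean_non + 1.0)

    adj_p = _bh_adjust(p)
    passed = (np.abs(log2fc) > lfc_min) & (p < p_max)
    if adj_p_max is not None:
        passed &= adj_p < adj_p_max

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "adj_p": adj_p,
            "direction": np.where(log2fc >= 0, 1, -1),
            "passed": passed,
        },
        index=cohort.counts.index,
    )
    return MarkerResult(table, lfc_min, p_max, adj_p_max)


def intersect_markers(r1: MarkerResult, r2: MarkerResult) -> pd.DataFrame:
    """Markers passing both cohorts' thresholds with concordant direction.

    Returns a frame indexed by gene with the shared ``direction`` and both
    cohorts' log2 fold-changes; an empty frame is a legitimate outcome.
    """
    common = r1.passed.intersection(r2.passed)
    d1 = r1.table.loc[common, "direction"]
    d2 = r2.table.loc[common, "direction"]
    concordant = common[np.asarray(d1) == np.asarray(d2)]
    return pd.DataFrame(
        {
            "direction": r1.table.loc[concordant, "direction"],
            "log2fc_cohort1": r1.table.loc[concordant, "log2fc"],
            "log2fc_cohort2": r2.table.loc[concordant, "log2fc"],
        }
    )


def power_two_sample_t(
    n1: int,
    n2: int,
    d: float,
    alpha: float,
    two_sided: bool = True,
) -> float:
    """Power of the two-sample t-test at standardised effect size ``d``.

    Uses the noncentral-t distribution with noncentrality
    ``d * sqrt(n1*n2/(n1+n2))`` and ``n1+n2-2`` degrees of freedom. For a
    conventional "large" effect (d = 0.8) this reproduces the pwr-style
    sample-size planning used to set the screening alphas.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if two_sided:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))
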