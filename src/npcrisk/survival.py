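"""Kaplan-Meier estimation and weighted log-rank group comparison.

Risk-score stratification splits a cohort at the model's operating cutoff;
the high- and low-risk groups' progression/metastasis-free survival is then
compared with the log-rank test and its Tarone-Ware weighting (weights
equal to the square root of the number at risk, which up-weights early
event times).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["km_curve", "weighted_logrank", "stratify_by_score", "compare_survival"]


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a frame with columns ``time``, ``survival`` and ``n_at_risk``,
    one row per distinct event time, with S(0) = 1 prepended. Censoring at
    an event time is counted after the event (the standard convention).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("need at least one record")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [(0.0, 1.0, t.size)]
    s = 1.0
    for ti in np.unique(t[e == 1]):
        n_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        rows.append((float(ti), s, n_risk))
    return pd.DataFrame(rows, columns=["time", "survival", "n_at_risk"])


def weighted_logrank(times, events, groups, weight="logrank") -> tuple[float, float]:
    """Weighted log-rank test between two groups.

    At each distinct event time the observed minus expected events in
    group 1 and its hypergeometric variance (with the standard ties
    correction) are accumulated with weight ``w(t)``:

    - ``"logrank"``: w = 1,
    - ``"tarone-ware"``: w = sqrt(n at risk),
    - a callable ``w(n_at_risk) -> weight`` for custom weightings.

    The statistic ``(sum w (O - E))^2 / sum w^2 V`` is referred to a
    chi-square with 1 degree of freedom. Returns ``(statistic, p)``.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("weighted_logrank needs exactly two groups")
    if e.sum() == 0:
        raise ValueError("no events observed")
    in1 = g == labels[1]

    if callable(weight):
        wfun = weight
    elif weight == "logrank":
        wfun = lambda n: 1.0
    elif weight == "tarone-ware":
        wfun = lambda n: np.sqrt(n)
    else:
        raise ValueError(f"unknown weighting {weight!r}")

    num = 0.0
    den = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & in1).sum())
        if n == 0:
            continue
        exp1 = d * n1 / n
        var1 = 0.0
        if n > 1:
            var1 = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        w = float(wfun(n))
        num += w * (d1 - exp1)
        den += w * w * var1
    if den == 0:
        return 0.0, 1.0
    stat = num * num / den
    return float(stat), float(stats.chi2.sf(stat, df=1))


def stratify_by_score(scores, cutoff: float) -> np.ndarray:
    """High/low risk groups: ``"high"`` where score > cutoff."""
    s = np.asarray(scores, float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return np.where(s > cutoff, "high", "low")


def compare_survival(
    survival: pd.DataFrame,
    scores,
    cutoff: float,
    weight: str = "logrank",
) -> dict:
    """Stratify by score and compare the two groups' survival.

    ``survival`` needs ``time`` and ``event`` columns aligned with
    ``scores``. Returns the group sizes, both KM tables and the test.
    """
    groups = stratify_by_score(scores, cutoff)
    if len(np.unique(groups)) < 2:
        raise ValueError("all samples fall on one side of the cutoff")
    stat, p = weighted_logrank(survival["time"], survival["event"], groups, weight)
    out = {
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
        "statistic": stat,
        "p": p,
        "weight": weight,
    }
    for grp in ("high", "low"):
        sel = groups == grp
        out[f"km_{grp}"] = km_curve(
            survival["time"].to_numpy()[sel], survival["event"].to_numpy()[sel]
        )
    return out
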