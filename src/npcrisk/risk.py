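"""Linear metastasis risk scores: fitting, calibration, evaluation.

The modelling object is :class:`LinearRiskScore`, in the statsmodels mould:
it is built from a feature matrix and binary labels, and ``fit()`` returns a
:class:`LinearRiskScoreResults` carrying the calibrated
:class:`LinearRiskModel` artifact, training diagnostics and a ``summary()``
table.

The "linear prediction model" is ordinary least squares of the 0/1 label on
the features, followed by an affine group-mean calibration so that the
average score of the non-MET training samples is exactly 0 and of the MET
samples exactly 1. The published operating point is the ROC threshold
maximising Youden's J (TPR - FPR).

The published five-gene RNA score (on the log10(normalised count + 1)
scale) and the combined clinical+RNA score are instances of
:class:`LinearRiskModel`; the bootstrap comparison of the clinical-only and
combined models, including the integrated discrimination improvement (IDI),
lives in :func:`bootstrap_compare`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "LinearRiskModel",
    "LinearRiskScore",
    "LinearRiskScoreResults",
    "BootstrapReport",
    "fit_linear_score",
    "evaluate_linear_score",
    "combined_model",
    "auc",
    "roc_operating_point",
    "idi",
    "bootstrap_compare",
]


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney convention (ties count 1/2)."""
    y = np.asarray(labels, float)
    s = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def roc_operating_point(scores, labels) -> float:
    """Score threshold maximising Youden's J = TPR - FPR.

    Candidate thresholds are midpoints between adjacent distinct sorted
    scores (plus outer sentinels); ties in J are broken toward the higher
    threshold. Samples strictly above the threshold are called positive.
    """
    y = np.asarray(labels, float)
    s = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("operating point needs both classes present")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cands = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_j, best_t = -np.inf, cands[0]
    for t in cands:
        pred = s > t
        j = (pred & (y == 1)).sum() / n_pos - (pred & (y == 0)).sum() / n_neg
        if j >= best_j:  # >= so ties move toward the higher threshold
            best_j, best_t = j, t
    return float(best_t)


@dataclass
class LinearRiskModel:
    """A calibrated linear risk score.

    ``score = weights . features + intercept`` where the weights and
    intercept already include the affine group-mean calibration, so that
    on its training set the mean score is 0 for non-MET and 1 for MET.
    """

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    calibration: tuple[float, float]  # (mean_nonmet_raw, mean_met_raw)
    cutoff: float = np.nan

    def evaluate(self, features) -> np.ndarray:
        """Score samples. ``features`` is samples x features (array or frame)."""
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise KeyError(f"missing features: {missing}")
            x = features[self.feature_names].to_numpy(float)
        else:
            x = np.atleast_2d(np.asarray(features, float))
            if x.shape[1] != len(self.feature_names):
                raise ValueError("feature dimension mismatch")
        return x @ self.weights + self.intercept

    def stratify(self, features) -> np.ndarray:
        """High-risk indicator: score strictly above the operating cutoff."""
        return (self.evaluate(features) > self.cutoff).astype(int)

    # ------------------------------------------------------------- JSON I/O

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "feature_names": list(self.feature_names),
                "weights": np.asarray(self.weights, float).tolist(),
                "intercept": float(self.intercept),
                "calibration": [float(c) for c in self.calibration],
                "cutoff": float(self.cutoff),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearRiskModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            d["feature_names"],
            np.asarray(d["weights"], float),
            d["intercept"],
            tuple(d["calibration"]),
            d.get("cutoff", np.nan),
        )


class LinearRiskScore:
    """Model object: binary metastasis label regressed on risk features.

    Parameters
    ----------
    features : array or DataFrame, samples x features
        Gene expression on the log10(normalised count + 1) scale, clinical
        indicators, or a mixture of both.
    labels : array-like of {0, 1}
        1 = MET (metastasis within 3 years), 0 = non-MET.
    feature_names : list of str, optional
        Taken from DataFrame columns when available.
    """

    def __init__(self, features, labels, feature_names: list[str] | None = None):
        if isinstance(features, pd.DataFrame):
            feature_names = feature_names or list(features.columns)
            features = features.to_numpy(float)
        self.exog = np.atleast_2d(np.asarray(features, float))
        if self.exog.ndim == 2 and self.exog.shape[0] == 1 and len(labels) > 1:
            self.exog = self.exog.T
        self.endog = np.asarray(labels, float)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if not np.isfinite(self.exog).all():
            raise ValueError("features must be finite")
        if min((self.endog == 1).sum(), (self.endog == 0).sum()) < 2:
            raise ValueError("need at least 2 samples per class")
        self.feature_names = feature_names or [
            f"x{i}" for i in range(self.exog.shape[1])
        ]

    @classmethod
    def from_cohort(cls, cohort, genes) -> "LinearRiskScore":
        """Build from a :class:`~npcrisk.datasets.CohortDataset` gene subset."""
        expr = cohort.expression(genes)  # genes x samples
        return cls(expr.T, cohort.labels, feature_names=list(genes))

    def fit(self) -> "LinearRiskScoreResults":
        X = np.column_stack([self.exog, np.ones(len(self.endog))])
        beta, *_ = np.linalg.lstsq(X, self.endog, rcond=None)
        raw = X @ beta
        y = self.endog
        mean_non, mean_met = raw[y == 0].mean(), raw[y == 1].mean()
        span = mean_met - mean_non
        if span == 0 or not np.isfinite(span):
            warnings.warn(
                "degenerate fit: groups indistinguishable, returning constant score",
                RuntimeWarning,
                stacklevel=2,
            )
            model = LinearRiskModel(
                self.feature_names,
                np.zeros(self.exog.shape[1]),
                0.5,
                (mean_non, mean_met),
            )
        else:
            model = LinearRiskModel(
                self.feature_names,
                beta[:-1] / span,
                (beta[-1] - mean_non) / span,
                (mean_non, mean_met),
            )
        scores = model.evaluate(self.exog)
        model.cutoff = roc_operating_point(scores, y)
        return LinearRiskScoreResults(self, model, scores)


@dataclass
class LinearRiskScoreResults:
    """Fitted linear risk score with training diagnostics."""

    model_spec: LinearRiskScore = field(repr=False)
    model: LinearRiskModel
    fittedvalues: np.ndarray = field(repr=False)

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.append(self.model.weights, self.model.intercept),
            index=[*self.model.feature_names, "intercept"],
        )

    @property
    def cutoff(self) -> float:
        return self.model.cutoff

    @property
    def train_auc(self) -> float:
        return auc(self.fittedvalues, self.model_spec.endog)

    def predict(self, features) -> np.ndarray:
        return self.model.evaluate(features)

    def summary(self) -> str:
        y = self.model_spec.endog
        lines = [
            "Linear risk score (OLS, group-mean calibrated)",
            "=" * 52,
            f"{'n samples':<28}{len(y):>24}",
            f"{'n MET / non-MET':<28}{f'{int(y.sum())} / {int((1 - y).sum())}':>24}",
            f"{'training AUC':<28}{self.train_auc:>24.3f}",
            f"{'operating cutoff (Youden J)':<28}{self.model.cutoff:>24.3f}",
            "-" * 52,
            f"{'term':<28}{'coefficient':>24}",
        ]
        for name, w in self.params.items():
            lines.append(f"{name:<28}{w:>24.3f}")
        lines.append("=" * 52)
        return "\n".join(lines)


def fit_linear_score(features, labels, feature_names=None) -> LinearRiskModel:
    """Convenience wrapper: fit and return the calibrated model artifact."""
    return LinearRiskScore(features, labels, feature_names).fit().model


def evaluate_linear_score(model: LinearRiskModel, features) -> np.ndarray:
    """Apply a calibrated model: ``weights . features + intercept``."""
    return model.evaluate(features)


def combined_model(clinical_indicators, rna_scores, labels) -> LinearRiskModel:
    """Combined clinical + RNA risk model.

    ``clinical_indicators`` is a samples x 3 frame/array of the binary
    prognostic indicators (BMI >= 23, plasma EBV DNA >= 4000 copies/mL,
    TNM stage = 4); the RNA risk score enters as a single frozen column.
    """
    if isinstance(clinical_indicators, pd.DataFrame):
        names = list(clinical_indicators.columns)
        clin = clinical_indicators.to_numpy(float)
    else:
        clin = np.asarray(clinical_indicators, float)
        names = [f"clin{i}" for i in range(clin.shape[1])]
    vals = np.unique(clin)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("clinical indicators must be binary 0/1")
    X = np.column_stack([clin, np.asarray(rna_scores, float)])
    return fit_linear_score(X, labels, feature_names=[*names, "rna_score"])


def idi(old_probs, new_probs, labels) -> float:
    """Integrated discrimination improvement between two risk predictions.

    The gain in discrimination slope: (mean new prob among events - mean
    new prob among nonevents) minus the same difference for the old
    prediction. Antisymmetric in its two predictions.
    """
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("IDI needs both classes present")
    old = np.asarray(old_probs, float)
    new = np.asarray(new_probs, float)
    slope_new = new[y == 1].mean() - new[y == 0].mean()
    slope_old = old[y == 1].mean() - old[y == 0].mean()
    return float(slope_new - slope_old)


def _logistic_probs(train_scores, train_labels, eval_scores) -> np.ndarray:
    """Map scores to [0,1] risks via univariate logistic calibration."""
    lr = LogisticRegression(C=1e6, max_iter=1000)
    lr.fit(np.asarray(train_scores, float).reshape(-1, 1), train_labels)
    return lr.predict_proba(np.asarray(eval_scores, float).reshape(-1, 1))[:, 1]


@dataclass
class BootstrapReport:
    """Outcome of the repeated 70/30 clinical-vs-combined comparison."""

    n_reps: int
    auc_clinical: np.ndarray
    auc_combined: np.ndarray
    idi_values: np.ndarray
    comparison_p: float
    idi_p: float
    averaged_model: LinearRiskModel

    @property
    def mean_idi(self) -> float:
        return float(self.idi_values.mean())

    @property
    def mean_auc_clinical(self) -> float:
        return float(self.auc_clinical.mean())

    @property
    def mean_auc_combined(self) -> float:
        return float(self.auc_combined.mean())

    def summary(self) -> str:
        return "\n".join(
            [
                f"bootstrap replicates        {self.n_reps}",
                f"mean AUC clinical-only      {self.mean_auc_clinical:.3f}",
                f"mean AUC clinical+RNA       {self.mean_auc_combined:.3f}",
                f"AUC comparison p (MW)       {self.comparison_p:.2e}",
                f"mean IDI of RNA score       {self.mean_idi:.3f}",
                f"IDI sign-test p (Wilcoxon)  {self.idi_p:.2e}",
            ]
        )


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 4:
            raise ValueError("stratum too small to split 70/30")
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 2), len(idx) - 2)
        train_idx.append(rng.permutation(idx)[:n_train])
    train = np.concatenate(train_idx)
    mask = np.zeros(len(y), bool)
    mask[train] = True
    return mask, ~mask


def bootstrap_compare(
    labels,
    clinical_indicators,
    rna_scores,
    n_reps: int = 200,
    train_frac: float = 0.70,
    seed: int | None = None,
) -> BootstrapReport:
    """Repeated stratified 70/30 comparison of clinical vs combined models.

    Per replicate the cohort is split 70% train / 30% validation within
    each outcome stratum; a clinical-only and a clinical+RNA linear model
    are fitted on the training split (the RNA score itself stays frozen),
    and the validation AUC of each plus the replicate IDI (on logistically
    calibrated risks) is recorded. The two validation-AUC samples are
    compared with a two-sided Mann-Whitney U test; the IDI sample with a
    Wilcoxon signed-rank test against zero. The final reported model
    averages the replicate coefficient vectors and recalibrates the score
    to (0, 1) group means on the full cohort.
    """
    y = np.asarray(labels, float)
    if isinstance(clinical_indicators, pd.DataFrame):
        clin_names = list(clinical_indicators.columns)
        clin = clinical_indicators.to_numpy(float)
    else:
        clin = np.asarray(clinical_indicators, float)
        clin_names = [f"clin{i}" for i in range(clin.shape[1])]
    rna = np.asarray(rna_scores, float)
    rng = np.random.default_rng(seed)

    X_comb = np.column_stack([clin, rna])
    names = [*clin_names, "rna_score"]
    aucs_c, aucs_k, idis, coefs = [], [], [], []
    for _ in range(n_reps):
        tr, va = _stratified_split(y, train_frac, rng)
        m_clin = fit_linear_score(clin[tr], y[tr], feature_names=clin_names)
        m_comb = fit_linear_score(X_comb[tr], y[tr], feature_names=names)
        s_clin_tr, s_clin_va = m_clin.evaluate(clin[tr]), m_clin.evaluate(clin[va])
        s_comb_tr, s_comb_va = m_comb.evaluate(X_comb[tr]), m_comb.evaluate(X_comb[va])
        aucs_c.append(auc(s_clin_va, y[va]))
        aucs_k.append(auc(s_comb_va, y[va]))
        idis.append(
            idi(
                _logistic_probs(s_clin_tr, y[tr], s_clin_va),
                _logistic_probs(s_comb_tr, y[tr], s_comb_va),
                y[va],
            )
        )
        coefs.append(np.append(m_comb.weights, m_comb.intercept))

    aucs_c, aucs_k = np.asarray(aucs_c), np.asarray(aucs_k)
    idis = np.asarray(idis)
    comparison_p = float(stats.mannwhitneyu(aucs_k, aucs_c, alternative="two-sided").pvalue)
    if np.allclose(idis, 0):
        idi_p = 1.0
    else:
        idi_p = float(stats.wilcoxon(idis).pvalue)

    # average coefficients, recalibrate on the full cohort
    mean_coef = np.mean(coefs, axis=0)
    raw = X_comb @ mean_coef[:-1] + mean_coef[-1]
    mean_non, mean_met = raw[y == 0].mean(), raw[y == 1].mean()
    span = mean_met - mean_non
    averaged = LinearRiskModel(
        names,
        mean_coef[:-1] / span,
        (mean_coef[-1] - mean_non) / span,
        (mean_non, mean_met),
    )
    averaged.cutoff = roc_operating_point(averaged.evaluate(X_comb), y)

    return BootstrapReport(
        n_reps, aucs_c, aucs_k, idis, comparison_p, idi_p, averaged
    )
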