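"""Model fitting and evaluation statistics.

Covers the SDI model (shared LASSO machinery), the joint RIS + SDI logistic
model, and the evaluation toolkit: Mann-Whitney AUC, accuracy/sensitivity/
specificity at a frozen Youden cutoff, the DeLong test for correlated AUCs,
Cohen's kappa and Fisher's exact test.

Convention: the positive class is AS (the astrocytoma cohort), so
sensitivity is AS detection.  Labels passed to these functions are already
encoded 0/1 with 1 = positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import LinearScorer, fit_lasso_cv, youden_threshold

POSITIVE_CLASS = "AS"


def fit_spatial_model(
    table: pd.DataFrame, labels: np.ndarray, k: int = 10, seed: int = 0
) -> LinearScorer:
    """Fit the Spatial Distribution Index scorer on the 27-column table.

    Identical machinery to the radiomics LASSO, applied per scan rather than
    per lesion.
    """
    feature_cols = [c for c in table.columns if c not in ("subject_id",)]
    return fit_lasso_cv(table[feature_cols], labels, k=k, seed=seed)


@dataclass
class JointModel:
    """Logistic combination of RIS and SDI + the frozen training cutoff."""

    coef_ris: float
    coef_sdi: float
    intercept: float
    cutoff: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    used_fallback: bool = False

    def predict_proba(self, ris: np.ndarray, sdi: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.coef_ris * np.asarray(ris) + self.coef_sdi * np.asarray(sdi)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_joint(ris: np.ndarray, sdi: np.ndarray, labels: np.ndarray) -> JointModel:
    """Maximum-likelihood logistic fit of labels on (RIS, SDI).

    On (quasi-)separation or collinearity the fit falls back to a tiny ridge
    penalty so the pipeline always produces finite coefficients; Wald
    p-values are only reported for the unpenalized fit.
    """
    import statsmodels.api as sm

    ris = np.asarray(ris, dtype=float)
    sdi = np.asarray(sdi, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("fit_joint requires both classes present")
    if np.allclose(np.corrcoef(ris, sdi)[0, 1], 1.0) or np.allclose(
        np.corrcoef(ris, sdi)[0, 1], -1.0
    ):
        warnings.warn("RIS and SDI are perfectly collinear; fitting under ridge fallback")
    design = sm.add_constant(np.column_stack([ris, sdi]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # perfect-separation warnings -> fallback
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.params).all() or np.abs(fit.params).max() > 1e6:
            raise np.linalg.LinAlgError("diverged coefficients")
        params = fit.params
        pvals = fit.pvalues
        return JointModel(
            coef_ris=float(params[1]),
            coef_sdi=float(params[2]),
            intercept=float(params[0]),
            p_values={"ris": float(pvals[1]), "sdi": float(pvals[2])},
        )
    except Exception:
        # ridge fallback, penalty 1e-4: finite optimum even under separation
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(C=1.0 / 1e-4, max_iter=10000)
        model.fit(np.column_stack([ris, sdi]), y)
        return JointModel(
            coef_ris=float(model.coef_[0][0]),
            coef_sdi=float(model.coef_[0][1]),
            intercept=float(model.intercept_[0]),
            p_values={"ris": float("nan"), "sdi": float("nan")},
            used_fallback=True,
        )


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc requires both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / len(neg) for p in pos])
    v01 = np.array([((pos > n).sum() + 0.5 * (pos == n).sum()) / len(pos) for n in neg])
    return v10, v01


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong comparison of two correlated AUCs on the same subjects.

    Returns (z, two-sided p).  Zero variance with zero AUC difference yields
    p = 1.0 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("delong_test requires paired scores on identical subjects")
    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_a - auc_b
    if var <= 0:
        return (0.0, 1.0) if delta == 0 else (np.inf * np.sign(delta), 0.0)
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def cohens_kappa(ratings1, ratings2) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e); 1.0 when both raters agree
    constantly (p_e = 1 convention)."""
    r1 = np.asarray(ratings1)
    r2 = np.asarray(ratings2)
    if len(r1) != len(r2):
        raise ValueError("rating vectors must have equal length")
    cats = np.unique(np.concatenate([r1, r2]))
    n = len(r1)
    p_o = float((r1 == r2).sum() / n)
    p_e = float(sum((r1 == c).sum() / n * (r2 == c).sum() / n for c in cats))
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (probability ordering);
    a zero margin yields p = 1.0."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("fisher_exact requires a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classification_metrics(
    scores: np.ndarray, labels: np.ndarray, cutoff: float
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity at a frozen cutoff (pos iff >=)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    return {
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
    }


def evaluate(
    split_scores: dict[str, dict[str, np.ndarray]],
    split_labels: dict[str, np.ndarray],
    cutoffs: dict[str, float],
) -> dict:
    """Evaluation report over splits x models.

    Parameters
    ----------
    split_scores : {split: {model: scores}}
    split_labels : {split: labels} (1 = positive class)
    cutoffs : {model: frozen training Youden cutoff}

    Returns a report dict with per-split per-model AUC/accuracy/sensitivity/
    specificity and pairwise DeLong p-values per split.  Splits without both
    classes are skipped with a warning.
    """
    report: dict = {"splits": {}, "positive_class": POSITIVE_CLASS}
    for split, models in split_scores.items():
        labels = split_labels[split]
        if len(np.unique(labels)) != 2:
            warnings.warn(f"split {split!r} lacks both classes; skipped")
            continue
        entry: dict = {"n": int(len(labels)), "models": {}, "delong": {}}
        for model, scores in models.items():
            metrics = {"auc": auc(scores, labels)}
            metrics.update(classification_metrics(scores, labels, cutoffs[model]))
            entry["models"][model] = metrics
        names = list(models)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                z, p = delong_test(models[a], models[b], labels)
                entry["delong"][f"{a}_vs_{b}"] = {"z": z, "p": p}
        report["splits"][split] = entry
    return report


def report_table(report: dict) -> pd.DataFrame:
    """Summary table: metric rows x (model, split) columns."""
    rows = ["auc", "accuracy", "sensitivity", "specificity"]
    data = {}
    for split, entry in report["splits"].items():
        for model, metrics in entry["models"].items():
            data[(model, split)] = [metrics[r] for r in rows]
    return pd.DataFrame(data, index=rows)
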