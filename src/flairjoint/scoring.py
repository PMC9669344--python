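"""Feature selection and lesion-to-subject scoring.

The chain is: Spearman-correlation reduction -> L1-penalized logistic
selection with k-fold cross-validation -> per-lesion Radiomics Index for
Lesion (RIL) -> Youden-optimal threshold T on training lesions -> piecewise
court merging of a scan's lesion RILs into the Radiomics Index for Subject
(RIS).

RIS merging: lesions split into a negativity-like court (RIL < T) and a
positivity-like court (RIL >= T).  Whichever court's summed |RIL - T|
distance is larger speaks for the scan, and the RIS is that court's mean
RIL; an exact tie goes to the positive court.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold


@dataclass
class CorrelationReduction:
    """Result of correlation-based redundancy removal."""

    retained: list[str]
    clusters: dict[str, int]
    threshold: float
    dropped_constant: list[str] = field(default_factory=list)


def reduce_by_correlation(
    table: pd.DataFrame, threshold: float = 0.90
) -> CorrelationReduction:
    """Collapse highly correlated features to one representative each.

    Average-linkage hierarchical clustering on distance 1 - |rho_Spearman|,
    cut at 1 - threshold; the highest-variance member represents each
    cluster.  Constant columns carry no rank information and are dropped
    with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    variances = table.var(axis=0, ddof=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature column(s): {constant[:5]}...",
            stacklevel=2,
        )
    cols = [c for c in table.columns if c not in constant]
    if len(cols) == 0:
        raise ValueError("all feature columns are constant")
    if len(cols) == 1:
        return CorrelationReduction(cols, {cols[0]: 1}, threshold, constant)
    rho = spearmanr(table[cols].to_numpy()).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")
    retained = []
    for lab in np.unique(labels):
        members = [c for c, l in zip(cols, labels) if l == lab]
        retained.append(max(members, key=lambda c: variances[c]))
    # keep catalog (column) order
    retained = [c for c in cols if c in set(retained)]
    return CorrelationReduction(retained, dict(zip(cols, labels.tolist())), threshold, constant)


@dataclass
class LinearScorer:
    """Selected features + weights on standardized inputs (a RIL/SDI scorer).

    ``score(x) = intercept + sum_i w_i * (x_i - mean_i) / sd_i`` over the
    selected features; standardization parameters are frozen from the
    training table so validation data never leaks into them.
    """

    feature_ids: list[str]
    weights: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    penalty: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = len(self.feature_ids)
        if not (len(self.weights) == len(self.means) == len(self.sds) == n):
            raise ValueError("scorer arrays must all match the number of selected features")
        if (self.sds <= 0).any():
            raise ValueError("standardization sds must be positive for selected features")

    def score(self, features: pd.DataFrame | pd.Series) -> np.ndarray | float:
        """Evaluate the linear score on a feature row or table."""
        if isinstance(features, pd.Series):
            return float(self.score(features.to_frame().T)[0])
        missing = [f for f in self.feature_ids if f not in features.columns]
        if missing:
            raise KeyError(f"missing required feature(s): {missing}")
        x = features[self.feature_ids].to_numpy(dtype=float)
        z = (x - self.means) / self.sds
        return z @ self.weights + self.intercept

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "penalty": self.penalty,
            "seed": self.seed,
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearScorer":
        d = json.loads(Path(path).read_text())
        return cls(
            d["feature_ids"],
            np.array(d["weights"]),
            d["intercept"],
            np.array(d["means"]),
            np.array(d["sds"]),
            d.get("penalty"),
            d.get("seed"),
        )


def fit_lasso_cv(
    x: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    penalty_rule: str = "1se",
) -> LinearScorer:
    """L1-penalized logistic selection with k-fold CV.

    Features are standardized with training means/sds (frozen into the
    scorer).  The penalty is chosen from the mean CV deviance curve over the
    regularisation path: ``penalty_rule="1se"`` (default) takes the strongest
    penalty within one standard error of the optimum — the conventional guard
    against spurious selections under weak signal — while ``"cv-min"`` takes
    the deviance minimiser.  Nonzero-weight features become the scorer.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"y must be binary, got classes {classes}")
    n = len(y)
    if n < k:
        raise ValueError(f"cannot run {k}-fold CV on {n} samples")
    variances = x.var(axis=0, ddof=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant column(s) before LASSO: {constant[:5]}",
            stacklevel=2,
        )
    cols = [c for c in x.columns if c not in constant]
    xv = x[cols].to_numpy(dtype=float)
    means = xv.mean(axis=0)
    sds = xv.std(axis=0)
    z = (xv - means) / sds
    if penalty_rule not in ("1se", "cv-min"):
        raise ValueError(f"penalty_rule must be '1se' or 'cv-min', got {penalty_rule!r}")
    y01 = (y == classes[1]).astype(int)
    cs = np.logspace(-3, 2, 40)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # sklearn is migrating penalty="l1" -> l1_ratio; silence the notices
        warnings.simplefilter("ignore", FutureWarning)
        warnings.filterwarnings("ignore", message="Inconsistent values.*penalty")
        path = LogisticRegressionCV(
            Cs=cs,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            cv=cv,
            refit=True,
            max_iter=5000,
            random_state=seed,
        )
        path.fit(z, y01)
        scores = path.scores_[1]  # (k folds, len(cs)) mean neg log loss
        mean_score = scores.mean(axis=0)
        if penalty_rule == "cv-min":
            c_chosen = float(path.C_[0])
            model = path
        else:
            best = int(np.argmax(mean_score))
            se_best = scores[:, best].std(ddof=1) / np.sqrt(k)
            # smallest C (strongest penalty) within one SE of the optimum
            within = np.flatnonzero(mean_score >= mean_score[best] - se_best)
            c_chosen = float(cs[within[0]])
            model = LogisticRegression(
                penalty="l1",
                solver="liblinear",
                C=c_chosen,
                max_iter=5000,
                random_state=seed,
            )
            model.fit(z, y01)
    coefs = model.coef_.ravel()
    nz = np.flatnonzero(coefs != 0)
    sel = [cols[i] for i in nz]
    return LinearScorer(
        feature_ids=sel,
        weights=coefs[nz],
        intercept=float(model.intercept_[0]),
        means=means[nz],
        sds=sds[nz],
        penalty=c_chosen,
        seed=seed,
    )


def score_ril(features: pd.DataFrame | pd.Series, scorer: LinearScorer):
    """Per-lesion Radiomics Index for Lesion: the scorer's linear value."""
    return scorer.score(features)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Youden-optimal cutoff T; classification rule: positive iff score >= T.

    Candidates are midpoints between adjacent sorted unique scores (the
    single unique value when all scores tie).  Ties in J break toward higher
    sensitivity, then toward the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("youden_threshold requires both classes present")
    uniq = np.unique(scores)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def merge_ris(rils: np.ndarray, threshold: float) -> float:
    """Merge a scan's lesion RILs into the subject-level RIS.

    The positivity court holds lesions with RIL >= T, the negativity court
    RIL < T.  The court with the larger summed distance to T wins (ties to
    the positive court) and the RIS is the winning court's mean RIL.
    """
    rils = np.asarray(rils, dtype=float)
    if rils.size == 0:
        raise ValueError("merge_ris requires at least one lesion RIL")
    pos = rils[rils >= threshold]
    neg = rils[rils < threshold]
    d_pos = float(np.abs(pos - threshold).sum())
    d_neg = float(np.abs(neg - threshold).sum())
    if d_pos >= d_neg:
        # the tie rule guarantees the positive court is non-empty here
        # (an empty positive court has distance 0 and every negative lesion
        # lies strictly below T, so d_neg > 0 unless there are no lesions)
        assert pos.size > 0, "winning positive court unexpectedly empty"
        return float(pos.mean())
    return float(neg.mean())


def subject_ris(
    lesion_table: pd.DataFrame, scorer: LinearScorer, threshold: float
) -> pd.Series:
    """RIS per subject from a per-lesion feature table (needs subject_id)."""
    rils = pd.Series(scorer.score(lesion_table), index=lesion_table.index)
    out = {}
    for sid, idx in lesion_table.groupby("subject_id").groups.items():
        out[sid] = merge_ris(rils.loc[idx].to_numpy(), threshold)
    return pd.Series(out, name="ris")
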