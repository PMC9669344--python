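"""End-to-end orchestration: simulate -> extract -> select/fit -> merge ->
joint -> evaluate, with the cohort-and-scanner stratified 3:1 split.

Every stochastic stage draws its own seed derived from one master seed, so a
rerun with the same config reproduces every table bit-for-bit.  Training-set
quantities (standardization parameters, LASSO selections, the lesion
threshold T, subject-level cutoffs, the joint fit) are frozen before any
test or validation subject is touched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evalstats import (
    POSITIVE_CLASS,
    evaluate,
    fit_joint,
    fit_spatial_model,
    report_table,
)
from .phantom import PhantomConfig, PhantomSubject, simulate_cohort
from .radiomics import (
    DiscretizationConfig,
    FeatureCatalog,
    LesionImage,
    extract_features,
    feature_table,
)
from .scoring import (
    fit_lasso_cv,
    merge_ris,
    reduce_by_correlation,
    subject_ris,
    youden_threshold,
)
from .spatial import LabeledScanMask, label_components, spatial_table

logger = logging.getLogger("flairjoint")


@dataclass
class RunConfig:
    """Everything a reproducible run depends on."""

    out_dir: str = "flairjoint_run"
    seed: int = 0
    # cohort sizes: development era (split 3:1) and independent validation era
    n_ae_dev: int = 59
    n_as_dev: int = 79
    n_ae_val: int = 22
    n_as_val: int = 28
    scanner_mix: dict = field(
        default_factory=lambda: {"scanner_0": 0.5, "scanner_1": 0.3, "scanner_2": 0.2}
    )
    test_fraction: float = 0.25
    lasso_folds: int = 10
    correlation_threshold: float = 0.90
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    slice_axis: int = 2
    positive_class: str = POSITIVE_CLASS

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(5) % (2**31 - 1)
        names = ["dev_cohort", "val_cohort", "split", "lasso_radiomics", "lasso_spatial"]
        return dict(zip(names, (int(s) for s in state)))

    def digest(self) -> str:
        blob = json.dumps(
            {
                k: (v if isinstance(v, (int, float, str)) else str(v))
                for k, v in vars(self).items()
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stratified_split(
    roster: pd.DataFrame, ratio: float = 0.25, seed: int = 0
) -> pd.Series:
    """Assign development subjects to train/test at ``ratio`` test fraction,
    stratified by scanner within each disease cohort.

    Per cohort x scanner stratum the test count is round(stratum * ratio);
    strata smaller than 4 go wholly to training (warned).  Residual
    adjustments on the largest strata make each cohort hit its global
    round(n * ratio) test count.  Returns a subject_id-indexed Series of
    "train"/"test".
    """
    if roster.empty:
        return pd.Series(dtype=object, name="split")
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for cls, cls_df in roster.groupby("class", sort=True):
        target = round(len(cls_df) * ratio)
        strata = {k: df for k, df in cls_df.groupby("scanner_id", sort=True)}
        counts: dict[str, int] = {}
        for k, df in strata.items():
            if len(df) < 4:
                warnings.warn(
                    f"stratum ({cls}, {k}) has {len(df)} subjects (<4); "
                    "assigning all to training"
                )
                counts[k] = 0
            else:
                counts[k] = round(len(df) * ratio)
        eligible = sorted(
            (k for k in strata if len(strata[k]) >= 4),
            key=lambda k: -len(strata[k]),
        )
        diff = target - sum(counts.values())
        guard = 0
        while diff != 0 and eligible and guard < 1000:
            k = eligible[guard % len(eligible)]
            if diff > 0 and counts[k] < len(strata[k]) - 1:
                counts[k] += 1
                diff -= 1
            elif diff < 0 and counts[k] > 0:
                counts[k] -= 1
                diff += 1
            guard += 1
        for k, df in strata.items():
            ids = np.sort(df["subject_id"].to_numpy())
            picked = rng.choice(ids, size=counts[k], replace=False)
            test_ids.extend(picked.tolist())
    out = pd.Series(
        "train", index=roster["subject_id"].to_numpy(), name="split", dtype=object
    )
    out.loc[test_ids] = "test"
    return out


def lesions_from_subject(
    subject: PhantomSubject, spacing, margin: int = 4
) -> list[LesionImage]:
    """Crop each valid (>= 8 mm^3, 26-connected) lesion component."""
    lab, _sizes = label_components(subject.mask, spacing)
    lesions = []
    for i in range(1, int(lab.max()) + 1):
        comp = lab == i
        idx = np.argwhere(comp)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + margin + 1, comp.shape)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        lesions.append(
            LesionImage(
                subject.image[sl],
                comp[sl],
                tuple(spacing),
                lesion_id=f"{subject.subject_id}_lesion{i}",
                subject_id=subject.subject_id,
            )
        )
    return lesions


@dataclass
class PipelineResult:
    roster: pd.DataFrame
    lesion_features: pd.DataFrame
    spatial_features: pd.DataFrame
    scores: pd.DataFrame
    radiomics_scorer: object
    spatial_scorer: object
    joint_model: object
    lesion_threshold: float
    cutoffs: dict
    report: dict
    summary: pd.DataFrame


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run the full synthetic study; optionally write all artifacts."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = config.stage_seeds()
    logger.info("run digest %s, stage seeds %s", config.digest(), seeds)

    # --- stage: simulate --------------------------------------------------
    try:
        dev_subjects, dev_truth = simulate_cohort(
            config.phantom,
            config.n_ae_dev,
            config.n_as_dev,
            config.scanner_mix,
            seed=seeds["dev_cohort"],
        )
        val_subjects, val_truth = simulate_cohort(
            config.phantom,
            config.n_ae_val,
            config.n_as_val,
            config.scanner_mix,
            seed=seeds["val_cohort"],
        )
        val_truth = val_truth.assign(
            subject_id=lambda d: "val_" + d["subject_id"]
        )
        for s in val_subjects:
            s.subject_id = "val_" + s.subject_id
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err
    dev_truth["era"] = "development"
    val_truth["era"] = "independent"
    roster = pd.concat([dev_truth, val_truth], ignore_index=True)

    # --- stage: split (development era only) ------------------------------
    try:
        assignment = stratified_split(
            dev_truth, ratio=config.test_fraction, seed=seeds["split"]
        )
    except Exception as err:
        raise RuntimeError(f"stage 'split' failed: {err}") from err
    roster["split"] = roster["subject_id"].map(assignment).fillna("validation")
    logger.info("split sizes: %s", roster["split"].value_counts().to_dict())

    # --- stage: radiomics extraction --------------------------------------
    try:
        catalog = FeatureCatalog()
        vectors = []
        for subj in dev_subjects + val_subjects:
            for lesion in lesions_from_subject(subj, config.phantom.voxel_spacing):
                vectors.append(
                    extract_features(
                        lesion, catalog, config.discretization, config.slice_axis
                    )
                )
        lesion_df = feature_table(vectors)
    except Exception as err:
        raise RuntimeError(f"stage 'extract-radiomics' failed: {err}") from err
    logger.info("extracted %d lesions x %d features", len(lesion_df), len(catalog))

    # --- stage: spatial extraction ----------------------------------------
    try:
        scans = [
            LabeledScanMask(
                s.mask, s.atlas, config.phantom.voxel_spacing, s.subject_id
            )
            for s in dev_subjects + val_subjects
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spatial_df = spatial_table(scans)
    except Exception as err:
        raise RuntimeError(f"stage 'extract-spatial' failed: {err}") from err

    result = train_from_tables(
        lesion_df,
        spatial_df,
        roster,
        seed=config.seed,
        folds=config.lasso_folds,
        correlation_threshold=config.correlation_threshold,
        positive_class=config.positive_class,
        feature_cols=catalog.feature_ids,
        config_digest=config.digest(),
    )
    if write:
        _write_artifacts(result, catalog, config, out)
    return result


def train_from_tables(
    lesion_df: pd.DataFrame,
    spatial_df: pd.DataFrame,
    roster: pd.DataFrame,
    seed: int = 0,
    folds: int = 10,
    correlation_threshold: float = 0.90,
    test_fraction: float = 0.25,
    positive_class: str = POSITIVE_CLASS,
    feature_cols: list[str] | None = None,
    out_dir: str | Path | None = None,
    config_digest: str = "",
) -> PipelineResult:
    """Model stages from pre-extracted tables: select, fit, merge, evaluate.

    ``roster`` needs subject_id, class, scanner_id and either a ``split``
    column or an ``era`` column (development subjects get the stratified 3:1
    split; independent-era subjects become the validation split and never
    influence training).
    """
    lesion_df = lesion_df.copy()
    spatial_df = spatial_df.copy()
    roster = roster.copy()
    seeds = RunConfig(seed=seed).stage_seeds()
    if "split" not in roster.columns:
        era = roster.get("era", pd.Series("development", index=roster.index))
        dev = roster[era == "development"]
        assignment = stratified_split(dev, ratio=test_fraction, seed=seeds["split"])
        roster["split"] = roster["subject_id"].map(assignment).fillna("validation")

    label_of = dict(zip(roster["subject_id"], roster["class"]))
    split_of = dict(zip(roster["subject_id"], roster["split"]))

    # --- stage: radiomics model (training lesions only) -------------------
    try:
        lesion_df["split"] = lesion_df["subject_id"].map(split_of)
        lesion_df["class"] = lesion_df["subject_id"].map(label_of)
        feat_cols = feature_cols or [
            c
            for c in lesion_df.columns
            if c not in ("subject_id", "lesion_id", "split", "class")
        ]
        train_lesions = lesion_df[lesion_df["split"] == "train"]
        y_lesion = (train_lesions["class"] == positive_class).to_numpy().astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduction = reduce_by_correlation(
                train_lesions[feat_cols], correlation_threshold
            )
            scorer = fit_lasso_cv(
                train_lesions[reduction.retained],
                y_lesion,
                k=folds,
                seed=seeds["lasso_radiomics"],
            )
        train_rils = np.asarray(scorer.score(train_lesions))
        t_lesion = youden_threshold(train_rils, y_lesion)
        logger.info(
            "radiomics scorer: %d/%d features selected, T=%.4f",
            len(scorer.feature_ids),
            len(reduction.retained),
            t_lesion,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'train-radiomics' failed: {err}") from err

    # --- stage: RIS merging, per subject ----------------------------------
    ris = subject_ris(lesion_df, scorer, t_lesion)

    # --- stage: spatial model ----------------------------------------------
    try:
        spatial_df["split"] = spatial_df["subject_id"].map(split_of)
        spatial_df["class"] = spatial_df["subject_id"].map(label_of)
        train_spatial = spatial_df[spatial_df["split"] == "train"]
        y_spatial = (train_spatial["class"] == positive_class).to_numpy().astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sdi_scorer = fit_spatial_model(
                train_spatial.drop(columns=["split", "class"]),
                y_spatial,
                k=folds,
                seed=seeds["lasso_spatial"],
            )
        logger.info("spatial scorer: %d features selected", len(sdi_scorer.feature_ids))
    except Exception as err:
        raise RuntimeError(f"stage 'train-spatial' failed: {err}") from err
    sdi = pd.Series(
        np.asarray(sdi_scorer.score(spatial_df)), index=spatial_df["subject_id"], name="sdi"
    )

    # --- stage: joint model -----------------------------------------------
    scores = roster[["subject_id", "class", "scanner_id", "split"]].copy()
    scores["ris"] = scores["subject_id"].map(ris)
    scores["sdi"] = scores["subject_id"].map(sdi)
    scores["y"] = (scores["class"] == positive_class).astype(int)
    train_scores = scores[scores["split"] == "train"]
    try:
        joint = fit_joint(
            train_scores["ris"].to_numpy(),
            train_scores["sdi"].to_numpy(),
            train_scores["y"].to_numpy(),
        )
    except Exception as err:
        raise RuntimeError(f"stage 'train-joint' failed: {err}") from err
    scores["joint_prob"] = joint.predict_proba(
        scores["ris"].to_numpy(), scores["sdi"].to_numpy()
    )
    logger.info(
        "joint model: coef_ris=%.3f coef_sdi=%.3f (fallback=%s)",
        joint.coef_ris,
        joint.coef_sdi,
        joint.used_fallback,
    )

    # --- stage: evaluate ---------------------------------------------------
    cutoffs = {
        "radiomics": youden_threshold(
            train_scores["ris"].to_numpy(), train_scores["y"].to_numpy()
        ),
        "spatial": youden_threshold(
            train_scores["sdi"].to_numpy(), train_scores["y"].to_numpy()
        ),
        "joint": youden_threshold(
            joint.predict_proba(
                train_scores["ris"].to_numpy(), train_scores["sdi"].to_numpy()
            ),
            train_scores["y"].to_numpy(),
        ),
    }
    joint.cutoff = cutoffs["joint"]
    split_scores = {}
    split_labels = {}
    for split in ["train", "test", "validation"]:
        sub = scores[scores["split"] == split]
        if sub.empty:
            warnings.warn(f"split {split!r} is empty; skipped")
            continue
        split_scores[split] = {
            "radiomics": sub["ris"].to_numpy(),
            "spatial": sub["sdi"].to_numpy(),
            "joint": sub["joint_prob"].to_numpy(),
        }
        split_labels[split] = sub["y"].to_numpy()
    report = evaluate(split_scores, split_labels, cutoffs)
    report["lesion_threshold"] = t_lesion
    report["joint_coefficients"] = {
        "ris": joint.coef_ris,
        "sdi": joint.coef_sdi,
        "intercept": joint.intercept,
        "p_values": joint.p_values,
    }
    report["selected_features"] = {
        "radiomics": scorer.feature_ids,
        "spatial": sdi_scorer.feature_ids,
    }
    report["seeds"] = seeds
    report["config_digest"] = config_digest
    summary = report_table(report)

    result = PipelineResult(
        roster=roster,
        lesion_features=lesion_df,
        spatial_features=spatial_df,
        scores=scores,
        radiomics_scorer=scorer,
        spatial_scorer=sdi_scorer,
        joint_model=joint,
        lesion_threshold=t_lesion,
        cutoffs=cutoffs,
        report=report,
        summary=summary,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.scores.to_csv(out / "subject_scores.csv", index=False)
        result.radiomics_scorer.to_json(
            out / "radiomics_model.json",
            extra={"lesion_threshold": result.lesion_threshold},
        )
        result.spatial_scorer.to_json(out / "spatial_model.json")
        (out / "cutoffs.json").write_text(json.dumps(result.cutoffs, indent=1))
        (out / "evaluation_report.json").write_text(json.dumps(result.report, indent=1))
        result.summary.to_csv(out / "summary_table.csv")
    return result


def _write_artifacts(
    result: PipelineResult, catalog: FeatureCatalog, config: RunConfig, out: Path
) -> None:
    result.roster.to_csv(out / "roster.csv", index=False)
    result.lesion_features.to_csv(out / "lesion_features.csv", index=False)
    result.spatial_features.to_csv(out / "spatial_features.csv", index=False)
    result.scores.to_csv(out / "subject_scores.csv", index=False)
    catalog.to_manifest(out / "feature_catalog.json")
    result.radiomics_scorer.to_json(
        out / "radiomics_model.json",
        extra={"lesion_threshold": result.lesion_threshold},
    )
    result.spatial_scorer.to_json(out / "spatial_model.json")
    (out / "joint_model.json").write_text(
        json.dumps(
            {
                "coef_ris": result.joint_model.coef_ris,
                "coef_sdi": result.joint_model.coef_sdi,
                "intercept": result.joint_model.intercept,
                "cutoff": result.joint_model.cutoff,
                "p_values": result.joint_model.p_values,
                "used_fallback": result.joint_model.used_fallback,
            },
            indent=1,
        )
    )
    (out / "evaluation_report.json").write_text(json.dumps(result.report, indent=1))
    result.summary.to_csv(out / "summary_table.csv")
    logger.info("artifacts written to %s", out)
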